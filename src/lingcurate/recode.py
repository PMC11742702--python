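"""Logical curation: recoding operators driven by a machine-readable plan.

Logical dependencies between categorical features (one feature's state being
entailed by another's) inflate similarity between taxa in any analysis that
assumes feature independence. The operators here remove such dependencies
without inventing any decisions: *which* features to exclude, adapt, merge,
derive or condition is always input data (a :class:`RecodePlan`, the
machine-readable form of a curation decisions log).

Operators
---------
``state_adapt``
    rewrite / merge / exclude states of a single feature (excluded states
    become unknown: the taxon has a real value that was discarded);
``derive_meta_feature``
    binary presence summary over several binary manifestation features;
``condition_feature``
    restrict a feature to taxa where it is applicable given another
    feature's state, conservatively or liberally;
``merge_combined``
    combine two features covering the same phenomenon from different
    sources into one, with a priority rule for conflicts.

Two automatic filters (minimum coding, minimum variability) and the feature
naming conventions of the two published curation styles round the module off.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import pandas as pd

from .core import (
    NOT_APPLICABLE,
    RESERVED,
    UNKNOWN,
    FeatureDef,
    TraitMatrix,
    TraitMatrixError,
    state_counts,
)

logger = logging.getLogger(__name__)

MOD_TYPES = ("design", "logical", "design.automated", "design.manual", "statistical")
OP_KINDS = (
    "exclude",
    "state_exclude",
    "state_adapt",
    "merge_meta",
    "merge_combined",
    "decompose",
    "condition",
)


class PlanError(ValueError):
    """Raised for inconsistent recode plans (dangling references, cycles)."""


@dataclass
class Modification:
    """One curation operation of the decisions log.

    ``params`` is the op-specific payload:

    * ``state_adapt`` / ``state_exclude``: ``{"mapping": {old: new-or-"?"}}``
    * ``merge_meta``: ``{"present": "1", "absent": "0"}`` (output tokens)
    * ``condition``: ``{"condition": fid, "allowed": [tokens], "mode": ...}``
    * ``merge_combined``: ``{"priority": fid, "state_map": {fid: {old: new}}}``
    * ``decompose``: ``{"parts": [{"output": fid, "mapping": ...,
      "condition": ..., "allowed": ..., "mode": ...}, ...]}``
    """

    id: str
    mtype: str
    op_kind: str
    input_features: list[str]
    output_features: list[str]
    params: dict = field(default_factory=dict)
    rationale: str = ""

    def __post_init__(self) -> None:
        if self.mtype not in MOD_TYPES:
            raise PlanError(f"{self.id}: unknown modification type {self.mtype!r}")
        if self.op_kind not in OP_KINDS:
            raise PlanError(f"{self.id}: unknown op kind {self.op_kind!r}")
        if self.op_kind == "exclude" and self.output_features:
            raise PlanError(f"{self.id}: exclude must not declare outputs")
        if self.op_kind != "exclude" and not self.output_features:
            raise PlanError(f"{self.id}: {self.op_kind} requires output features")


@dataclass
class RecodePlan:
    """Ordered ledger of modifications plus the per-feature link table."""

    modifications: list[Modification] = field(default_factory=list)

    def feature_table(self) -> pd.DataFrame:
        """Per-feature record of producing / consuming modification ids."""
        rows: dict[str, dict[str, list[str]]] = {}
        for mod in self.modifications:
            for fid in mod.input_features:
                rows.setdefault(fid, {"consumed_by": [], "produced_by": []})
                rows[fid]["consumed_by"].append(mod.id)
            for fid in mod.output_features:
                rows.setdefault(fid, {"consumed_by": [], "produced_by": []})
                rows[fid]["produced_by"].append(mod.id)
        return pd.DataFrame(
            [
                {"feature": fid,
                 "produced_by": ";".join(r["produced_by"]),
                 "consumed_by": ";".join(r["consumed_by"])}
                for fid, r in sorted(rows.items())
            ]
        )

    def check_order(self, initial_features: Iterable[str]) -> None:
        """Verify dependency order: consumers appear after producers."""
        available = set(initial_features)
        for mod in self.modifications:
            refs = list(mod.input_features)
            if mod.op_kind == "condition":
                refs.append(mod.params["condition"])
            for fid in refs:
                if fid not in available:
                    raise PlanError(
                        f"modification {mod.id}: feature {fid!r} not available "
                        "(dangling reference or ordering violation)"
                    )
            available |= set(mod.output_features)


# -- automatic filters -----------------------------------------------------


def min_coding_filter(m: TraitMatrix, threshold: int = 100) -> list[str]:
    """Feature ids coded for fewer than ``threshold`` taxa."""
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    coded = m.coded_mask().sum(axis=0)
    return [str(f) for f in coded.index[coded < threshold]]


def min_variability_filter(m: TraitMatrix, k: int = 3) -> list[str]:
    """Feature ids whose second-most-frequent state is attested in < k taxa.

    Features with a single attested state have a second count of zero and
    always fail.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    failing = []
    for fid in m.feature_ids:
        counts = sorted(state_counts(m, fid).values(), reverse=True)
        second = counts[1] if len(counts) > 1 else 0
        if second < k:
            failing.append(fid)
    return failing


# -- recoding operators ----------------------------------------------------


def state_adapt(col: pd.Series, mapping: Mapping[str, str],
                states: Sequence[str]) -> tuple[pd.Series, tuple[str, ...]]:
    """Rewrite coded states through ``mapping``; return column + new space.

    Tokens mapped to the unknown literal are discarded (the taxon has a real
    value that was dropped, so the cell becomes unknown, not not-applicable).
    Unknown / not-applicable cells pass through. The new state space is the
    image of the mapping; the feature must stay variable (>= 2 tokens).
    """
    extra = set(mapping) - set(states)
    if extra:
        raise TraitMatrixError(f"mapping domain outside state space: {sorted(extra)}")
    full = {s: mapping.get(s, s) for s in states}
    new_states = tuple(dict.fromkeys(v for v in full.values() if v != UNKNOWN))
    if len(new_states) < 2:
        raise TraitMatrixError(
            f"state adaptation leaves < 2 states ({new_states!r}); "
            "feature would no longer be variable"
        )
    out = col.map(lambda v: v if v in RESERVED else full[v]).astype(object)
    return out, new_states


def derive_meta_feature(cols: Sequence[pd.Series], present: str = "1",
                        absent: str = "0") -> pd.Series:
    """Binary presence summary over binary manifestation features.

    Per taxon: any input coded ``present`` → ``present``; all inputs coded
    ``absent`` → ``absent``; anything else (some unknown / not-applicable,
    no attested presence) → unknown, so that ``absent`` keeps meaning
    *known* absence.
    """
    if len(cols) == 0:
        raise TraitMatrixError("meta-feature needs at least one input column")
    df = pd.concat(list(cols), axis=1)
    any_present = (df == present).any(axis=1)
    all_absent = (df == absent).all(axis=1)
    out = pd.Series(UNKNOWN, index=df.index, dtype=object)
    out[all_absent] = absent
    out[any_present] = present
    return out


def condition_feature(
    target: pd.Series,
    cond: pd.Series,
    allowed: Iterable[str],
    mode: Literal["conservative", "liberal"] = "conservative",
) -> pd.Series:
    """Restrict ``target`` to taxa where it is applicable given ``cond``.

    Rules per taxon (cond cell kind → result):

    * coded, state in ``allowed``  → target value unchanged;
    * coded, state not allowed     → not applicable;
    * unknown                      → conservative: unknown (we are forced to
      be agnostic); liberal: target value unchanged (information from the
      original feature is preserved, at the cost of coding some taxa that
      may in truth be inapplicable);
    * not applicable               → not applicable (a feature conditioned
      on an inapplicable condition is itself inapplicable).

    A coded target value is never rewritten to a different coded value.
    """
    if target is cond:
        raise TraitMatrixError("cannot condition a feature on itself")
    if mode not in ("conservative", "liberal"):
        raise ValueError(f"unknown conditioning mode {mode!r}")
    allowed = set(allowed)
    cond = cond.reindex(target.index)
    out = target.copy().astype(object)
    coded = ~cond.isin(RESERVED)
    out[coded & ~cond.isin(allowed)] = NOT_APPLICABLE
    if mode == "conservative":
        out[cond == UNKNOWN] = UNKNOWN
    out[cond == NOT_APPLICABLE] = NOT_APPLICABLE
    return out


def merge_combined(
    a: pd.Series,
    b: pd.Series,
    priority: Literal["a", "b"],
    state_map_a: Mapping[str, str] | None = None,
    state_map_b: Mapping[str, str] | None = None,
) -> pd.Series:
    """Combine two features covering one phenomenon from different sources.

    Both inputs are first mapped into the shared output state space. Per
    taxon: agreement → that value; coded-vs-coded conflict → the priority
    input's value; exactly one coded → its value; neither coded → unknown
    (not-applicable only when both inputs are not-applicable).
    """
    state_map_a = dict(state_map_a or {})
    state_map_b = dict(state_map_b or {})
    ma = a.map(lambda v: v if v in RESERVED else state_map_a.get(v, v)).astype(object)
    mb = b.reindex(a.index).map(
        lambda v: v if v in RESERVED else state_map_b.get(v, v)).astype(object)
    a_coded = ~ma.isin(RESERVED)
    b_coded = ~mb.isin(RESERVED)
    out = pd.Series(UNKNOWN, index=a.index, dtype=object)
    out[(ma == NOT_APPLICABLE) & (mb == NOT_APPLICABLE)] = NOT_APPLICABLE
    out[a_coded & ~b_coded] = ma[a_coded & ~b_coded]
    out[b_coded & ~a_coded] = mb[b_coded & ~a_coded]
    both = a_coded & b_coded
    agree = both & (ma == mb)
    out[agree] = ma[agree]
    conflict = both & (ma != mb)
    winner = ma if priority == "a" else mb
    out[conflict] = winner[conflict]
    return out


# -- naming conventions ----------------------------------------------------


def name_feature(base_ids: Sequence[str], op_trail: Sequence[str],
                 scheme: Literal["GBI", "TLI"] = "GBI",
                 decompose_index: int | None = None) -> str:
    """Build a feature identifier from its inputs and operation trail.

    GBI style: retained features keep their id; recoding appends lower-case
    suffixes (``e`` state exclusion, ``m`` meta, ``drm`` dimensionality
    recomposition, ``c`` conditioning) and statistical curation appends
    capitalized ones (``C``, ``F``, ``EO``, ``EON``), e.g. ``GB553drmc``.

    TLI style: retained features get the prefix ``o_``; recoded features get
    ``rec_`` plus the ordered operation letters, e.g. ``rec_da_WALS_110A_1``
    for part 1 of a decomposed-and-adapted feature, and merges join their
    inputs with ``+`` as in ``rec_m+WALS_10A+PHOIBLE_BAF_x``.
    """
    if scheme == "GBI":
        if len(base_ids) != 1:
            raise ValueError("GBI naming takes a single base id")
        return base_ids[0] + "".join(op_trail)
    if scheme == "TLI":
        if not op_trail:
            return "o_" + base_ids[0]
        letters = "".join(op_trail)
        if len(base_ids) > 1 or any(t in ("m", "EO", "EON", "F") for t in op_trail):
            return "rec_" + letters + "+" + "+".join(base_ids)
        name = "rec_" + letters + "_" + base_ids[0]
        if decompose_index is not None:
            name += f"_{decompose_index}"
        return name
    raise ValueError(f"unknown naming scheme {scheme!r}")


# -- plan execution --------------------------------------------------------

#: op kinds whose inputs are replaced by their outputs
_REPLACING = {"exclude", "state_exclude", "state_adapt", "merge_combined",
              "decompose", "condition"}


def _output_def(m: TraitMatrix, fid: str, states: Sequence[str],
                template: FeatureDef | None, mod: Modification) -> FeatureDef:
    base = template or FeatureDef(id=fid, states=tuple(states))
    return base.replace(
        id=fid, states=tuple(states),
        provenance=(base.provenance + "+" if base.provenance else "") + mod.id,
    )


def apply_plan(
    m: TraitMatrix,
    plan: RecodePlan,
    min_coding: int = 100,
    min_variability: int = 3,
    enforce_filters: bool = True,
) -> tuple[TraitMatrix, pd.DataFrame]:
    """Execute a recode plan strictly in order; return matrix + audit log.

    Inputs of replacing operations (exclusion, adaptation, decomposition,
    conditioning, combination merges) are removed; meta-feature derivation
    keeps its inputs, which are typically replaced later by conditioned
    versions. After the last modification the automatic filters run over the
    final feature set: every feature must satisfy minimum variability, and
    plan-produced features must additionally satisfy minimum coding (unless
    ``enforce_filters`` is off, for small fixtures).

    The audit log records, per applied modification, the before/after coded
    cell counts of the touched columns.
    """
    plan.check_order(m.feature_ids)
    cur = m.copy()
    audit: list[dict] = []
    produced: set[str] = set()

    def coded_count(mat: TraitMatrix, fids: Iterable[str]) -> int:
        fids = [f for f in fids if f in mat.data.columns]
        if not fids:
            return 0
        return int(mat.coded_mask()[fids].to_numpy().sum())

    for mod in plan.modifications:
        for fid in mod.input_features:
            if fid not in cur.data.columns:
                raise PlanError(f"modification {mod.id}: dangling feature {fid!r}")
        before = coded_count(cur, mod.input_features)
        p = mod.params

        if mod.op_kind == "exclude":
            cur = cur.drop_features(mod.input_features)

        elif mod.op_kind in ("state_adapt", "state_exclude"):
            (src,) = mod.input_features
            (out,) = mod.output_features
            col, new_states = state_adapt(
                cur.column(src), p["mapping"], cur.features[src].states)
            fdef = _output_def(cur, out, new_states, cur.features.get(src), mod)
            cur = cur.drop_features([src]).with_column(fdef, col)

        elif mod.op_kind == "merge_meta":
            (out,) = mod.output_features
            present, absent = p.get("present", "1"), p.get("absent", "0")
            col = derive_meta_feature(
                [cur.column(f) for f in mod.input_features], present, absent)
            fdef = _output_def(cur, out, (present, absent), None, mod)
            cur = cur.with_column(fdef, col)  # inputs retained

        elif mod.op_kind == "condition":
            (src,) = mod.input_features
            (out,) = mod.output_features
            if p["condition"] == src:
                raise TraitMatrixError(
                    f"modification {mod.id}: cannot condition {src!r} on itself")
            col = condition_feature(
                cur.column(src), cur.column(p["condition"]),
                p["allowed"], p.get("mode", "conservative"))
            fdef = _output_def(cur, out, cur.features[src].states,
                               cur.features.get(src), mod)
            cur = cur.drop_features([src]).with_column(fdef, col)

        elif mod.op_kind == "merge_combined":
            fa, fb = mod.input_features
            (out,) = mod.output_features
            smap = p.get("state_map", {})
            col = merge_combined(
                cur.column(fa), cur.column(fb),
                "a" if p.get("priority", fa) == fa else "b",
                smap.get(fa), smap.get(fb))
            states = tuple(dict.fromkeys(
                [smap.get(fa, {}).get(s, s) for s in cur.features[fa].states]
                + [smap.get(fb, {}).get(s, s) for s in cur.features[fb].states]))
            fdef = _output_def(cur, out, states, None, mod)
            cur = cur.drop_features([fa, fb]).with_column(fdef, col)

        elif mod.op_kind == "decompose":
            # expressed as state adaptations optionally conditioned on an
            # earlier part; the worked example is a presence/position split
            (src,) = mod.input_features
            src_col = cur.column(src)
            src_states = cur.features[src].states
            new_cols: list[tuple[FeatureDef, pd.Series]] = []
            built: dict[str, tuple[pd.Series, tuple[str, ...]]] = {}
            for part in p["parts"]:
                col, new_states = state_adapt(src_col, part.get("mapping", {}),
                                              src_states)
                if "condition" in part:
                    cref = part["condition"]
                    cond_col = (built[cref][0] if cref in built
                                else cur.column(cref))
                    col = condition_feature(col, cond_col, part["allowed"],
                                            part.get("mode", "conservative"))
                fdef = _output_def(cur, part["output"], new_states, None, mod)
                new_cols.append((fdef, col))
                built[part["output"]] = (col, new_states)
            cur = cur.drop_features([src])
            for fdef, col in new_cols:
                cur = cur.with_column(fdef, col)

        after = coded_count(cur, mod.output_features)
        produced |= set(mod.output_features)
        audit.append({
            "modification": mod.id, "op_kind": mod.op_kind,
            "inputs": ";".join(mod.input_features),
            "outputs": ";".join(mod.output_features),
            "coded_before": before, "coded_after": after,
        })

    if enforce_filters and cur.shape[1] > 0:
        drop = set(min_variability_filter(cur, min_variability))
        drop |= {f for f in min_coding_filter(cur, min_coding) if f in produced}
        if drop:
            logger.info("post-filters dropped %d features: %s",
                        len(drop), sorted(drop))
            for fid in sorted(drop):
                audit.append({
                    "modification": "postfilter", "op_kind": "exclude",
                    "inputs": fid, "outputs": "",
                    "coded_before": coded_count(cur, [fid]), "coded_after": 0,
                })
            cur = cur.drop_features(sorted(drop))

    return cur, pd.DataFrame(audit)
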