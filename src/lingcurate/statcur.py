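"""Statistical curation: acting on confirmed dependency decisions.

Once an expectation earns an ``act`` decision, the dependency is removed
from the matrix by one of a small set of declared actions (the action kind
and direction are always inputs — choosing between conditioning and merging
was a case-by-case expert decision in the original workflow):

* ``condition`` — condition one feature on the other's state; the mode is
  chosen automatically by state prevalence (liberal when the condition
  state covers at least 90% of coded taxa, else conservative);
* ``merge_F``   — four-state combination of two binary features;
* ``merge_EO``  — exclusionary merge with states {a-only, b-only};
* ``merge_EON`` — exclusionary merge with an additional neither state;
* ``exclude``   — drop a feature without replacement.

Expectations that referenced a replaced feature are re-tested against the
replacement using the *same* diversity samples, so second-round decisions
are comparable to the first round.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .config import CurationConfig, DEFAULT_CONFIG
from .core import NOT_APPLICABLE, RESERVED, UNKNOWN, FeatureDef, TraitMatrix, TraitMatrixError
from .dependencies import Expectation, ExpectationResult, evaluate_expectation
from .recode import condition_feature
from .sampling import DiversitySample

MERGE_KINDS = ("F", "EO", "EON")


@dataclass
class ActionSpec:
    """Declared action for one acted-on expectation.

    ``direction`` names the feature to be conditioned (the target); the
    other feature of the expectation supplies the condition. For merges the
    direction is ignored. ``condition_state`` is the state of the condition
    feature under which the target stays applicable.
    """

    expectation_id: str
    kind: str  # condition | merge_F | merge_EO | merge_EON | exclude
    target: str | None = None
    condition_state: str | None = None
    output_id: str | None = None
    params: dict = field(default_factory=dict)


def choose_conditioning_mode(cond: pd.Series, state: str,
                             liberal_prevalence: float = 0.90) -> str:
    """Pick conservative vs liberal conditioning by state prevalence.

    Liberal conditioning (carrying target values through unknown condition
    cells) is only safe when the condition state is overwhelmingly common;
    the cutoff is a coded-taxa prevalence of at least
    ``liberal_prevalence``.
    """
    coded = cond[~cond.isin(RESERVED)]
    if len(coded) == 0:
        raise TraitMatrixError("conditioning feature has no coded taxa")
    prevalence = float((coded == state).mean())
    return "liberal" if prevalence >= liberal_prevalence else "conservative"


def merge_dependent(a: pd.Series, b: pd.Series, kind: str,
                    tokens_a: tuple[str, str] = ("1", "0"),
                    tokens_b: tuple[str, str] = ("1", "0")) -> pd.Series:
    """Merge two binary features whose dependency was confirmed.

    ``F``: four states ``11/10/01/00``; unknown wherever either input is
    uncoded (the combination cannot be recovered from one side alone).
    ``EO``: the two mutually exclusive states ``a_only`` / ``b_only``;
    both-present and both-absent taxa (contradicting exclusivity, or
    outside it) become unknown. ``EON``: adds a ``neither`` state for
    both-absent taxa; only both-present becomes unknown.
    """
    if kind not in MERGE_KINDS:
        raise ValueError(f"unknown merge kind {kind!r}")
    b = b.reindex(a.index)
    pa, na = tokens_a
    pb, nb = tokens_b
    out = pd.Series(UNKNOWN, index=a.index, dtype=object)
    both_na = (a == NOT_APPLICABLE) & (b == NOT_APPLICABLE)
    out[both_na] = NOT_APPLICABLE
    a1, a0 = a == pa, a == na
    b1, b0 = b == pb, b == nb
    if kind == "F":
        out[a1 & b1] = "11"
        out[a1 & b0] = "10"
        out[a0 & b1] = "01"
        out[a0 & b0] = "00"
    else:
        out[a1 & b0] = "a_only"
        out[a0 & b1] = "b_only"
        if kind == "EON":
            out[a0 & b0] = "neither"
        # a1 & b1 contradicts exclusivity -> stays unknown
    return out


def merge_states(kind: str) -> tuple[str, ...]:
    return {
        "F": ("11", "10", "01", "00"),
        "EO": ("a_only", "b_only"),
        "EON": ("a_only", "b_only", "neither"),
    }[kind]


def apply_actions(
    m: TraitMatrix,
    actions: list[ActionSpec],
    expectations: dict[str, Expectation],
    config: CurationConfig = DEFAULT_CONFIG,
) -> tuple[TraitMatrix, dict[str, str | None], pd.DataFrame]:
    """Apply declared actions for acted-on expectations.

    Returns the modified matrix, a map of replaced feature id → replacement
    id (None when excluded without replacement), and an audit table.
    """
    cur = m.copy()
    replaced: dict[str, str | None] = {}
    audit = []
    for act in actions:
        e = expectations[act.expectation_id]
        f1, f2 = e.features
        if act.kind == "exclude":
            target = act.target or f1
            cur = cur.drop_features([target])
            replaced[target] = None
            audit.append({"expectation": e.id, "action": "exclude",
                          "target": target, "output": "", "mode": ""})
            continue
        if act.kind == "condition":
            target = act.target
            if target not in (f1, f2):
                raise ValueError(
                    f"{e.id}: condition target {target!r} not part of the expectation")
            cond_fid = f2 if target == f1 else f1
            state = act.condition_state
            if state is None:
                state = e.side2[1] if cond_fid == f2 else e.side1[1]
            mode = choose_conditioning_mode(
                cur.column(cond_fid), state, config.liberal_prevalence)
            col = condition_feature(cur.column(target), cur.column(cond_fid),
                                    {state}, mode)
            out_id = act.output_id or target + "C"
            fdef = cur.features[target].replace(
                id=out_id, provenance=cur.features[target].provenance + "+" + e.id)
            cur = cur.drop_features([target]).with_column(fdef, col)
            replaced[target] = out_id
            audit.append({"expectation": e.id, "action": "condition",
                          "target": target, "output": out_id, "mode": mode})
            continue
        if act.kind.startswith("merge_"):
            kind = act.kind.split("_", 1)[1]
            if kind in ("EO", "EON") and e.etype != "OR":
                raise ValueError(f"{e.id}: merge_{kind} requires an OR expectation")
            col = merge_dependent(cur.column(f1), cur.column(f2), kind,
                                  act.params.get("tokens_a", ("1", "0")),
                                  act.params.get("tokens_b", ("1", "0")))
            out_id = act.output_id or f"{f1}+{f2}{kind}"
            fdef = FeatureDef(id=out_id, states=merge_states(kind),
                              provenance=e.id)
            cur = cur.drop_features([f1, f2]).with_column(fdef, col)
            replaced[f1] = out_id
            replaced[f2] = out_id
            audit.append({"expectation": e.id, "action": act.kind,
                          "target": f"{f1};{f2}", "output": out_id, "mode": ""})
            continue
        raise ValueError(f"unknown action kind {act.kind!r}")
    return cur, replaced, pd.DataFrame(audit)


def retest_replacements(
    m: TraitMatrix,
    expectations: list[Expectation],
    replaced: dict[str, str | None],
    samples: list[DiversitySample],
    config: CurationConfig = DEFAULT_CONFIG,
) -> tuple[list[ExpectationResult], pd.DataFrame]:
    """Re-run expectations that referenced replaced features.

    Each touched expectation is rewritten against the replacement feature
    (same state tokens) and re-tested on the original diversity samples. If
    a replacement no longer carries the referenced state, the expectation
    is marked inapplicable and logged; expectations on features excluded
    without replacement are dropped with a log entry.
    """
    results: list[ExpectationResult] = []
    log = []
    for e in expectations:
        if not (set(e.features) & set(replaced)):
            continue
        sides = []
        dropped = inapplicable = False
        for fid, state in (e.side1, e.side2):
            if fid in replaced:
                new = replaced[fid]
                if new is None:
                    dropped = True
                    break
                if state not in m.features[new].states:
                    inapplicable = True
                    break
                fid = new
            sides.append((fid, state))
        if dropped:
            log.append({"expectation": e.id, "status": "dropped",
                        "reason": "feature excluded without replacement"})
            continue
        if inapplicable:
            log.append({"expectation": e.id, "status": "inapplicable",
                        "reason": "replacement lacks the referenced state"})
            continue
        e2 = Expectation(e.id + ".retest", e.etype, sides[0], sides[1],
                         motivation=e.motivation)
        results.append(evaluate_expectation(m, e2, samples, config))
        log.append({"expectation": e.id, "status": "retested",
                    "reason": results[-1].decision})
    return results, pd.DataFrame(log)
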