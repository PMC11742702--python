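"""Fusing multiple source datasets into one trait matrix.

Multi-database inputs are keyed by taxon identifier (glottocode-style).
Fusion takes the union of taxa and features — feature ids must be globally
unique, namespaced by origin — and fills cells absent from a source with
unknown. Identifier-update maps handle taxa whose ids changed between
catalogue releases, merging rows when old and new ids co-occur (a coded
value beats an uncoded one; coded-vs-coded conflicts become unknown and
are logged).

Phonological inventories become binary presence/absence features via
segment-class definitions: each definition carries a boolean predicate
over a segment's distinctive-feature attribute vector, and the feature is
"present" for a taxon iff at least one segment of its (largest) inventory
satisfies the predicate. The predicate language is conjunction /
disjunction / negation over ``attribute=value`` atoms, supplied as data.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .core import UNKNOWN, FeatureDef, TraitMatrix

logger = logging.getLogger(__name__)

PRESENT, ABSENT = "present", "absent"


class FusionError(ValueError):
    pass


# -- identifier updates ----------------------------------------------------


@dataclass
class IdUpdateMap:
    """Mapping old taxon id -> new taxon id; injective and chain-free."""

    pairs: dict[str, str]

    def __post_init__(self) -> None:
        values = list(self.pairs.values())
        if len(set(values)) != len(values):
            raise FusionError("id update map is not injective")
        chained = set(values) & set(self.pairs)
        if chained:
            raise FusionError(f"id update map has chains via {sorted(chained)}")

    @classmethod
    def from_csv(cls, path: str | Path) -> "IdUpdateMap":
        df = pd.read_csv(path, dtype=str)
        return cls(dict(zip(df["old_id"], df["new_id"])))


def apply_id_updates(m: TraitMatrix, u: IdUpdateMap) -> TraitMatrix:
    """Rewrite taxon ids; merge rows when old and new ids both occur.

    Merge rule per cell: a coded value beats an uncoded one; a
    coded-vs-coded conflict yields unknown with a logged warning.
    """
    df = m.data.copy()
    new_index = [u.pairs.get(t, t) for t in df.index]
    df.index = pd.Index(new_index, name=m.data.index.name)
    if not df.index.has_duplicates:
        return TraitMatrix(df, m.features, validate=False)
    out_rows = {}
    for tid, group in df.groupby(level=0, sort=False):
        if len(group) == 1:
            out_rows[tid] = group.iloc[0]
            continue
        merged = {}
        for fid in df.columns:
            vals = [v for v in group[fid] if v != UNKNOWN]
            coded = [v for v in vals if v != "NA"]
            if len(set(coded)) > 1:
                logger.warning(
                    "id merge %s: conflicting coded values %s for %s -> unknown",
                    tid, sorted(set(coded)), fid)
                merged[fid] = UNKNOWN
            elif coded:
                merged[fid] = coded[0]
            elif vals:
                merged[fid] = vals[0]  # NA
            else:
                merged[fid] = UNKNOWN
        out_rows[tid] = pd.Series(merged)
    out = pd.DataFrame(out_rows).T.reindex(columns=df.columns)
    out = out.loc[list(dict.fromkeys(df.index))]
    return TraitMatrix(out, m.features, validate=False)


# -- dataset fusion --------------------------------------------------------


def fuse(sources: list[TraitMatrix]) -> TraitMatrix:
    """Union of taxa and features; cells absent in a source become unknown."""
    if not sources:
        raise FusionError("no sources to fuse")
    seen: dict[str, int] = {}
    for i, src in enumerate(sources):
        for fid in src.feature_ids:
            if fid in seen:
                raise FusionError(
                    f"feature id {fid!r} occurs in sources {seen[fid]} and {i}; "
                    "namespace feature ids by origin")
            seen[fid] = i
    all_taxa = sorted(set().union(*[set(s.taxa) for s in sources]))
    frames = [
        s.data.reindex(index=all_taxa, fill_value=UNKNOWN) for s in sources
    ]
    data = pd.concat(frames, axis=1).fillna(UNKNOWN)
    feats = {}
    for s in sources:
        feats.update(s.features)
    return TraitMatrix(data, feats, validate=False)


# -- segment-class predicates ----------------------------------------------

_TOKEN_RE = re.compile(
    r"\s*(\(|\)|&|\||!|[A-Za-z_][A-Za-z0-9_+-]*\s*=\s*[A-Za-z0-9_+-]+)")


class Predicate:
    """Boolean expression over attribute=value atoms (&, |, !, parens)."""

    def __init__(self, text: str):
        self.text = text
        self._ast = _parse(text)

    def attributes(self) -> set[str]:
        out: set[str] = set()

        def walk(node):
            kind = node[0]
            if kind == "atom":
                out.add(node[1])
            else:
                for child in node[1:]:
                    walk(child)

        walk(self._ast)
        return out

    def __call__(self, segment: Mapping[str, str]) -> bool:
        def ev(node):
            kind = node[0]
            if kind == "atom":
                attr, val = node[1], node[2]
                if attr not in segment:
                    raise FusionError(
                        f"predicate references attribute {attr!r} missing "
                        "from the inventory schema")
                return str(segment[attr]) == val
            if kind == "not":
                return not ev(node[1])
            if kind == "and":
                return ev(node[1]) and ev(node[2])
            return ev(node[1]) or ev(node[2])

        return ev(self._ast)


def _tokenize(text: str) -> list[str]:
    tokens, pos = [], 0
    while pos < len(text):
        mt = _TOKEN_RE.match(text, pos)
        if not mt:
            if text[pos:].strip():
                raise FusionError(f"cannot parse predicate near {text[pos:]!r}")
            break
        tokens.append(mt.group(1).replace(" ", ""))
        pos = mt.end()
    return tokens


def _parse(text: str):
    tokens = _tokenize(text)
    pos = 0

    def peek():
        return tokens[pos] if pos < len(tokens) else None

    def expect(tok):
        nonlocal pos
        if peek() != tok:
            raise FusionError(f"expected {tok!r} in predicate {text!r}")
        pos += 1

    def parse_or():
        node = parse_and()
        while peek() == "|":
            expect("|")
            node = ("or", node, parse_and())
        return node

    def parse_and():
        node = parse_unary()
        while peek() == "&":
            expect("&")
            node = ("and", node, parse_unary())
        return node

    def parse_unary():
        nonlocal pos
        tok = peek()
        if tok == "!":
            expect("!")
            return ("not", parse_unary())
        if tok == "(":
            expect("(")
            node = parse_or()
            expect(")")
            return node
        if tok is None or "=" not in tok:
            raise FusionError(f"malformed predicate {text!r}")
        pos += 1
        attr, val = tok.split("=", 1)
        return ("atom", attr, val)

    node = parse_or()
    if pos != len(tokens):
        raise FusionError(f"trailing tokens in predicate {text!r}")
    return node


@dataclass
class SegmentClassDef:
    """One binary segment-class feature: id, origin tag and predicate."""

    id: str
    origin_tag: str  # "WALS-enriching" | "independent"
    predicate: Predicate
    description: str = ""


def load_segment_class_defs(path: str | Path | None = None) -> list[SegmentClassDef]:
    """Load segment-class definitions (default: the bundled table)."""
    if path is None:
        ref = resources.files("lingcurate.data") / "segment_class_definitions.csv"
        with resources.as_file(ref) as p:
            df = pd.read_csv(p, dtype=str)
    else:
        df = pd.read_csv(path, dtype=str)
    return [
        SegmentClassDef(r["id"], r["origin_tag"], Predicate(r["predicate"]),
                        r.get("description", ""))
        for r in df.to_dict("records")
    ]


# -- inventories -----------------------------------------------------------


def largest_inventory(inventories: pd.DataFrame,
                      taxon_col: str = "taxon",
                      inventory_col: str = "inventory_id") -> pd.DataFrame:
    """One inventory per taxon: most segments; ties to the smallest id.

    ``inventories`` has one row per (taxon, inventory, segment) with
    attribute columns; taxa with zero inventories are simply absent.
    """
    sizes = (inventories.groupby([taxon_col, inventory_col])
             .size().rename("n").reset_index())
    sizes = sizes.sort_values([taxon_col, "n", inventory_col],
                              ascending=[True, False, True])
    chosen = sizes.drop_duplicates(taxon_col)[[taxon_col, inventory_col]]
    return inventories.merge(chosen, on=[taxon_col, inventory_col])


def derive_inventory_features(
    inventory: pd.DataFrame,
    defs: Iterable[SegmentClassDef],
) -> dict[str, str]:
    """Binary presence row for one taxon's segment inventory.

    Each definition yields "present" iff at least one segment satisfies its
    predicate; an empty inventory is all "absent" — never unknown, since an
    attested inventory is positive evidence of absence.
    """
    defs = list(defs)
    if not defs:
        raise FusionError("no segment-class definitions given")
    segments = inventory.to_dict("records")
    return {
        d.id: PRESENT if any(d.predicate(seg) for seg in segments) else ABSENT
        for d in defs
    }


def inventory_matrix(
    inventories: pd.DataFrame,
    defs: Iterable[SegmentClassDef] | None = None,
    taxon_col: str = "taxon",
    inventory_col: str = "inventory_id",
) -> TraitMatrix:
    """Binary feature matrix from a multi-taxon inventory table."""
    defs = list(defs) if defs is not None else load_segment_class_defs()
    best = largest_inventory(inventories, taxon_col, inventory_col)
    attr_cols = [c for c in best.columns if c not in (taxon_col, inventory_col)]
    rows = {
        str(tid): derive_inventory_features(group[attr_cols], defs)
        for tid, group in best.groupby(taxon_col, sort=True)
    }
    fdefs = {
        d.id: FeatureDef(id=d.id, states=(PRESENT, ABSENT),
                         label=d.description, group="phonology",
                         provenance=d.origin_tag)
        for d in defs
    }
    return TraitMatrix(pd.DataFrame.from_dict(rows, orient="index"),
                       fdefs)
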