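"""Trait-matrix data model with three-way cell semantics.

A trait matrix is a taxa x features grid of categorical cells. Every cell is
in exactly one of three conditions:

* **coded** — it carries a state token from the owning feature's state space;
* **unknown** (``?``) — the taxon was not surveyed for the feature, or the
  source explicitly coded it as unknown;
* **not applicable** (``NA``) — the cell is logically impossible to fill,
  e.g. the number of genders in a language without gender.

The distinction between unknown and not-applicable is deliberate and is
preserved through every curation stage: both count as *uncoded* for density
purposes, but they mean different things for imputation and for further data
collection, and conditioning operators produce them under different rules.

Internally the grid is a :class:`pandas.DataFrame` of string tokens with two
reserved literals (``"?"`` and ``"NA"`` by default, configurable at the I/O
boundary). The :class:`TraitMatrix` wrapper owns feature definitions and the
counting primitives every later stage builds on.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

#: Reserved literal for cells coded as unknown / missing.
UNKNOWN = "?"
#: Reserved literal for cells that are logically impossible to fill.
NOT_APPLICABLE = "NA"

RESERVED = (UNKNOWN, NOT_APPLICABLE)

#: Closed set of feature groups.
FEATURE_GROUPS = (
    "lexical semantics",
    "lexical classes",
    "grammatical categories",
    "grammar",
    "phonology",
)

#: Default closed set of macroareas used for areal stratification.
MACROAREAS = (
    "Africa",
    "Eurasia",
    "Papunesia",
    "Australia",
    "North America",
    "South America",
)


class TraitMatrixError(ValueError):
    """Raised for degenerate or inconsistent trait-matrix input."""


@dataclass
class FeatureDef:
    """Definition of one categorical feature.

    Parameters
    ----------
    id : str
        Feature identifier, unique within a dataset.
    states : sequence of str
        Ordered state space; at least two distinct tokens, none equal to the
        reserved unknown / not-applicable literals.
    label : str
        Free-text description.
    group : str
        One of :data:`FEATURE_GROUPS`, optionally with a sub-flag suffix
        separated by ``_`` (e.g. ``"grammar_linear_order"``).
    provenance : str
        Origin database tag plus derivation-operation codes.
    known_remaining_dependencies : list of str
        Identifiers of logged-but-not-acted-on dependency expectations this
        feature participates in.
    """

    id: str
    states: tuple[str, ...]
    label: str = ""
    group: str = "grammar"
    sub_flag: str | None = None
    provenance: str = ""
    known_remaining_dependencies: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.states = tuple(str(s) for s in self.states)
        if len(self.states) < 2:
            raise TraitMatrixError(
                f"feature {self.id!r} needs >= 2 states, got {self.states!r}"
            )
        if len(set(self.states)) != len(self.states):
            raise TraitMatrixError(f"feature {self.id!r} has duplicate states")
        for s in self.states:
            if s in RESERVED:
                raise TraitMatrixError(
                    f"feature {self.id!r}: state {s!r} collides with a reserved literal"
                )
        if self.group not in FEATURE_GROUPS:
            raise TraitMatrixError(
                f"feature {self.id!r}: group {self.group!r} not in {FEATURE_GROUPS}"
            )

    def replace(self, **kw) -> "FeatureDef":
        return dataclasses.replace(self, **kw)


@dataclass(frozen=True)
class Taxon:
    """One taxon (language) with genealogical and areal metadata."""

    id: str
    lineage: str
    macroarea: str
    lat: float | None = None
    lon: float | None = None


def _as_frame(cells) -> pd.DataFrame:
    df = pd.DataFrame(cells)
    df = df.astype(object)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


class TraitMatrix:
    """Dense taxa x features grid with tri-valued cells.

    Every (taxon, feature) pair has a cell; cells hold a coded state token or
    one of the reserved literals. Coded tokens are validated against the
    feature definitions on construction.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        features: Mapping[str, FeatureDef] | Iterable[FeatureDef] | None = None,
        validate: bool = True,
    ):
        self.data = _as_frame(data)
        if features is None:
            features = {}
            for fid in self.data.columns:
                col = self.data[fid]
                tokens = sorted(set(col) - set(RESERVED))
                if len(tokens) < 2:
                    # degenerate observed column: pad the state space so the
                    # definition stays legal; curation filters will drop it
                    tokens = sorted(set(tokens) | {"0", "1"})[:2] if not tokens else tokens + ["_pad"]
                features[fid] = FeatureDef(id=fid, states=tuple(tokens))
        elif not isinstance(features, Mapping):
            features = {f.id: f for f in features}
        self.features: dict[str, FeatureDef] = dict(features)
        if validate:
            self._validate()

    # -- construction -----------------------------------------------------

    @classmethod
    def from_records(
        cls,
        rows: Mapping[str, Mapping[str, str]],
        features: Mapping[str, FeatureDef] | Iterable[FeatureDef] | None = None,
    ) -> "TraitMatrix":
        """Build from ``{taxon: {feature: token}}``; absent cells → unknown."""
        df = pd.DataFrame.from_dict(rows, orient="index").fillna(UNKNOWN)
        return cls(df, features)

    def _validate(self) -> None:
        if self.data.index.has_duplicates:
            raise TraitMatrixError("duplicate taxon ids")
        if self.data.columns.has_duplicates:
            raise TraitMatrixError("duplicate feature ids")
        missing = set(self.data.columns) - set(self.features)
        if missing:
            raise TraitMatrixError(f"features without definition: {sorted(missing)}")
        for fid in self.data.columns:
            col = self.data[fid]
            bad = set(col) - set(self.features[fid].states) - set(RESERVED)
            if bad:
                raise TraitMatrixError(
                    f"feature {fid!r}: tokens {sorted(bad)} outside state space"
                )

    # -- basic accessors --------------------------------------------------

    @property
    def taxa(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def coded_mask(self) -> pd.DataFrame:
        """Boolean frame, True where the cell carries a coded state."""
        return ~self.data.isin(RESERVED)

    def column(self, fid: str) -> pd.Series:
        if fid not in self.data.columns:
            raise KeyError(f"unknown feature id {fid!r}")
        return self.data[fid]

    def subset(self, taxa: Sequence[str] | None = None,
               features: Sequence[str] | None = None) -> "TraitMatrix":
        df = self.data
        if taxa is not None:
            df = df.loc[list(taxa)]
        if features is not None:
            df = df[list(features)]
        feats = {f: self.features[f] for f in df.columns}
        return TraitMatrix(df.copy(), feats, validate=False)

    def with_column(self, fdef: FeatureDef, col: pd.Series) -> "TraitMatrix":
        """Return a copy with ``col`` appended (or replaced) under ``fdef.id``."""
        df = self.data.copy()
        df[fdef.id] = col.reindex(df.index, fill_value=UNKNOWN).astype(object)
        feats = dict(self.features)
        feats[fdef.id] = fdef
        return TraitMatrix(df, feats, validate=False)

    def drop_features(self, fids: Iterable[str]) -> "TraitMatrix":
        fids = [f for f in fids]
        df = self.data.drop(columns=fids)
        feats = {f: d for f, d in self.features.items() if f not in set(fids)}
        return TraitMatrix(df, feats, validate=False)

    def copy(self) -> "TraitMatrix":
        return TraitMatrix(self.data.copy(), dict(self.features), validate=False)

    def __eq__(self, other) -> bool:
        if not isinstance(other, TraitMatrix):
            return NotImplemented
        return self.data.equals(other.data)

    def __repr__(self) -> str:
        n, m = self.shape
        return f"<TraitMatrix {n} taxa x {m} features>"


# -- counting primitives ---------------------------------------------------


def coding_density(
    m: TraitMatrix,
    scope: Literal["whole", "per_taxon", "per_feature"] = "whole",
):
    """Fraction of cells carrying a coded state.

    Unknown and not-applicable cells both count as uncoded: gaps introduced
    deliberately by conditioning reduce density exactly like survey gaps.

    Returns a float for ``scope="whole"``, otherwise a Series indexed by
    taxon or feature id.
    """
    n, k = m.shape
    if n == 0 or k == 0:
        raise TraitMatrixError("coding density of an empty matrix is undefined")
    coded = m.coded_mask()
    if scope == "whole":
        return float(coded.to_numpy().mean())
    if scope == "per_taxon":
        return coded.mean(axis=1)
    if scope == "per_feature":
        return coded.mean(axis=0)
    raise ValueError(f"unknown scope {scope!r}")


def state_counts(m: TraitMatrix, fid: str) -> dict[str, int]:
    """Counts of taxa per coded state token of feature ``fid``.

    Unknown / not-applicable cells are excluded; the counts therefore sum to
    the number of coded taxa for the feature.
    """
    col = m.column(fid)
    counts = col[~col.isin(RESERVED)].value_counts()
    return {str(k): int(v) for k, v in counts.items()}


def taxonomy_frame(taxa: Iterable[Taxon]) -> pd.DataFrame:
    """Tabulate taxa as a DataFrame indexed by taxon id."""
    rows = [
        {"id": t.id, "lineage": t.lineage, "macroarea": t.macroarea,
         "lat": t.lat, "lon": t.lon}
        for t in taxa
    ]
    df = pd.DataFrame(rows).set_index("id")
    if df.index.has_duplicates:
        raise TraitMatrixError("duplicate taxon ids in taxonomy")
    return df
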