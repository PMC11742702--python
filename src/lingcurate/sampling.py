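"""Genealogically and areally stratified diversity samples.

Languages are not independent observations: relatedness and geographic
proximity induce correlation. The sampling scheme used for all statistical
dependency tests controls both by stratifying on (macroarea, lineage): from
each of the six macroareas it draws ``n_per_area`` distinct lineages
(families or isolates) uniformly without replacement, then one eligible
taxon uniformly per drawn lineage — a 120-language sample under defaults.

A lineage spanning several macroareas may contribute to each area it has
taxa in: stratification operates on (area, lineage) pairs defined by the
taxon-level macroarea assignment, so "distinct lineages" is enforced within,
not across, areas.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import TraitMatrix


class SamplingError(ValueError):
    """Raised when an area cannot supply the requested number of lineages."""


@dataclass
class DiversitySample:
    """One stratified sample: (taxon, macroarea, lineage) triples."""

    members: pd.DataFrame  # columns: taxon, macroarea, lineage
    seed: int
    index: int = 0

    @property
    def taxa(self) -> list[str]:
        return list(self.members["taxon"])

    def __len__(self) -> int:
        return len(self.members)


def _eligible_taxa(m: TraitMatrix | None, tax: pd.DataFrame,
                   min_features_coded: int) -> pd.DataFrame:
    tax = tax[tax.index.notna()]
    if min_features_coded > 0:
        if m is None:
            raise ValueError("eligibility by coding needs a trait matrix")
        coded = m.coded_mask().sum(axis=1)
        ok = coded.index[coded >= min_features_coded]
        tax = tax.loc[tax.index.intersection(ok)]
    return tax


def build_strata(m: TraitMatrix | None, tax: pd.DataFrame,
                 min_features_coded: int = 0) -> dict[str, dict[str, np.ndarray]]:
    """Pre-index eligible taxa as {area: {lineage: taxon array}}.

    Useful when drawing many samples from the same matrix: the grouping is
    computed once and passed to :func:`sample_diversity`.
    """
    tax = _eligible_taxa(m, tax, min_features_coded)
    strata: dict[str, dict[str, np.ndarray]] = {}
    for (area, lineage), group in tax.groupby(["macroarea", "lineage"], sort=True):
        strata.setdefault(str(area), {})[str(lineage)] = group.index.to_numpy()
    return strata


def sample_diversity(
    m: TraitMatrix | None,
    tax: pd.DataFrame,
    n_per_area: int = 20,
    min_features_coded: int = 0,
    seed: int = 0,
    index: int = 0,
    strata: dict[str, dict[str, np.ndarray]] | None = None,
) -> DiversitySample:
    """Draw one stratified diversity sample, reproducible from ``seed``.

    Parameters
    ----------
    m
        Trait matrix used only for the coding-eligibility rule; may be None
        when ``min_features_coded`` is 0.
    tax
        Taxonomy frame indexed by taxon id with ``lineage`` and ``macroarea``
        columns.
    n_per_area
        Lineages (and hence taxa) per macroarea.
    min_features_coded
        A taxon is eligible only if coded for at least this many features.
    strata
        Optional pre-built grouping from :func:`build_strata`.

    Raises
    ------
    SamplingError
        If any macroarea has fewer than ``n_per_area`` lineages with at
        least one eligible taxon (the shortfall is named).
    """
    if strata is None:
        strata = build_strata(m, tax, min_features_coded)
    rng = np.random.default_rng(seed)
    rows = []
    for area in sorted(strata):
        lineages = sorted(strata[area])
        if len(lineages) < n_per_area:
            raise SamplingError(
                f"macroarea {area!r} has only {len(lineages)} lineages with "
                f"eligible taxa; {n_per_area} required "
                f"(shortfall {n_per_area - len(lineages)})"
            )
        chosen = rng.choice(len(lineages), size=n_per_area, replace=False)
        for li in sorted(chosen):
            lineage = lineages[li]
            taxa = strata[area][lineage]
            taxon = taxa[rng.integers(len(taxa))]
            rows.append({"taxon": taxon, "macroarea": area, "lineage": lineage})
    return DiversitySample(pd.DataFrame(rows), seed=seed, index=index)


def generate_samples(
    n: int,
    m: TraitMatrix | None,
    tax: pd.DataFrame,
    n_per_area: int = 20,
    min_features_coded: int = 0,
    master_seed: int = 0,
) -> list[DiversitySample]:
    """Draw ``n`` samples with per-sample seeds derived from a master seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    strata = build_strata(m, tax, min_features_coded)
    seeds = np.random.default_rng(master_seed).integers(0, 2**31 - 1, size=n)
    return [
        sample_diversity(None, tax, n_per_area, 0, seed=int(s), index=i,
                         strata=strata)
        for i, s in enumerate(seeds)
    ]


def samples_to_frame(samples: list[DiversitySample]) -> pd.DataFrame:
    """Flatten samples into the persisted CSV layout."""
    frames = []
    for s in samples:
        df = s.members.copy()
        df.insert(0, "sample_index", s.index)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def write_samples(samples: list[DiversitySample], path: str | Path) -> None:
    samples_to_frame(samples).to_csv(path, index=False)


def read_samples(path: str | Path) -> list[DiversitySample]:
    df = pd.read_csv(path)
    out = []
    for idx, group in df.groupby("sample_index", sort=True):
        out.append(DiversitySample(
            group[["taxon", "macroarea", "lineage"]].reset_index(drop=True),
            seed=-1, index=int(idx)))
    return out
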