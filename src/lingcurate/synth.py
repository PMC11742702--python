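"""Synthetic taxonomies and trait matrices with known ground truth.

The generator emulates the statistical structure of real cross-linguistic
trait databases so that every curation stage is testable without external
downloads:

* a multi-family taxonomy spread over the six macroareas, with at least 20
  lineages per area and family sizes drawn from a truncated power law
  (mimicking the heavy skew of real family sizes that taxonomy-sensitive
  densification must handle);
* binary and multi-state features with controllable state frequencies,
  sampled independently per taxon unless structure is planted;
* planted *logical* structure: a latent presence meta-feature with
  subordinate manifestation features, either properly conditioned (absent
  → not-applicable) or deliberately un-conditioned (absent → known-absent
  everywhere) to reproduce the similarity-boosting pathology that logical
  curation removes;
* planted *statistical* dependencies (THEN/OR/AND) with a controllable
  exception rate ``epsilon``;
* missingness applied last: cell-level MCAR plus per-source block gaps
  (database-style coverage), since real multi-source sparsity is
  source-structured rather than random.

Everything is reproducible from the :class:`SynthSpec` master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    MACROAREAS,
    NOT_APPLICABLE,
    UNKNOWN,
    FeatureDef,
    Taxon,
    TraitMatrix,
    taxonomy_frame,
)


@dataclass
class SynthFeature:
    """One synthetic feature: state space + baseline state frequencies."""

    id: str
    states: tuple[str, ...] = ("1", "0")
    freqs: tuple[float, ...] | None = None  # None -> drawn per SynthSpec


@dataclass
class PlantedBlock:
    """A latent presence meta-structure: meta feature + subordinates.

    ``conditioned`` controls the target semantics: True writes
    not-applicable into subordinates where the phenomenon is absent (the
    curated design); False writes known absence everywhere (the
    pathological input design that curation should fix).
    """

    meta_id: str
    subordinate_ids: tuple[str, ...]
    p_present: float = 0.5
    conditioned: bool = False

    def __post_init__(self) -> None:
        if not self.subordinate_ids:
            raise ValueError(f"block {self.meta_id}: no subordinate features")


@dataclass
class PlantedDependency:
    """A planted statistical dependency with exception rate epsilon."""

    id: str
    etype: str  # THEN | OR | AND
    f1: str
    s1: str
    f2: str
    s2: str
    epsilon: float = 0.02

    def __post_init__(self) -> None:
        if not 0.0 <= self.epsilon <= 1.0:
            raise ValueError("epsilon must lie in [0, 1]")


@dataclass
class SourceBlock:
    """A simulated origin database: a feature block with partial coverage."""

    name: str
    features: tuple[str, ...]
    coverage: float  # fraction of taxa coded by this source


@dataclass
class SynthSpec:
    """Generator configuration; defaults give a mid-sized dense dataset."""

    areas: tuple[str, ...] = MACROAREAS
    lineages_per_area: int = 25
    max_family_size: int = 12
    power_law_alpha: float = 2.0
    features: list[SynthFeature] = field(default_factory=list)
    n_features: int = 30
    freq_range: tuple[float, float] = (0.2, 0.8)
    unknown_rate: float = 0.0
    blocks: list[PlantedBlock] = field(default_factory=list)
    dependencies: list[PlantedDependency] = field(default_factory=list)
    sources: list[SourceBlock] = field(default_factory=list)
    seed: int = 0

    def resolved_features(self) -> list[SynthFeature]:
        if self.features:
            feats = list(self.features)
        else:
            feats = [SynthFeature(f"F{i:03d}") for i in range(self.n_features)]
        ids = [f.id for f in feats]
        for block in self.blocks:
            for fid in (block.meta_id, *block.subordinate_ids):
                if fid not in ids:
                    raise ValueError(
                        f"planted block references unknown feature {fid!r}")
        for dep in self.dependencies:
            for fid in (dep.f1, dep.f2):
                if fid not in ids:
                    raise ValueError(
                        f"planted dependency references unknown feature {fid!r}")
        return feats


def _sample_taxonomy(spec: SynthSpec, rng: np.random.Generator) -> pd.DataFrame:
    taxa = []
    counter = 0
    # areas get disjoint longitude bands so that grid diagnostics see
    # spatial structure; coordinates jitter within the band
    for ai, area in enumerate(spec.areas):
        lon0 = -180 + 360 * ai / len(spec.areas)
        for li in range(spec.lineages_per_area):
            lineage = f"{area[:3]}_fam{li:03d}"
            # truncated power law family size
            size = int(min(rng.zipf(spec.power_law_alpha), spec.max_family_size))
            for _ in range(size):
                taxa.append(Taxon(
                    id=f"tax{counter:05d}", lineage=lineage, macroarea=area,
                    lat=float(rng.uniform(-55, 65)),
                    lon=float(lon0 + rng.uniform(0, 360 / len(spec.areas))),
                ))
                counter += 1
    return taxonomy_frame(taxa)


def _sample_column(n: int, feat: SynthFeature, spec: SynthSpec,
                   rng: np.random.Generator) -> np.ndarray:
    freqs = feat.freqs
    if freqs is None:
        if len(feat.states) == 2:
            p = rng.uniform(*spec.freq_range)
            freqs = (p, 1 - p)
        else:
            w = rng.dirichlet(np.ones(len(feat.states)))
            freqs = tuple(w)
    return rng.choice(np.array(feat.states, dtype=object), size=n, p=freqs)


def generate(spec: SynthSpec) -> tuple[TraitMatrix, pd.DataFrame, dict]:
    """Generate (trait matrix, taxonomy, ground-truth ledger) from a spec."""
    rng = np.random.default_rng(spec.seed)
    tax = _sample_taxonomy(spec, rng)
    n = len(tax)
    feats = spec.resolved_features()
    cols: dict[str, np.ndarray] = {
        f.id: _sample_column(n, f, spec, rng) for f in feats
    }
    fdefs = {f.id: FeatureDef(id=f.id, states=f.states) for f in feats}

    # planted logical blocks: meta first, subordinates follow the meta
    for block in spec.blocks:
        meta = np.where(rng.random(n) < block.p_present, "1", "0").astype(object)
        cols[block.meta_id] = meta
        absent = meta == "0"
        for sid in block.subordinate_ids:
            sub = cols[sid]
            sub[absent] = NOT_APPLICABLE if block.conditioned else "0"
            cols[sid] = sub

    # planted statistical dependencies overwrite f2 conditionally on f1
    for dep in spec.dependencies:
        f2def = fdefs[dep.f2]
        others = [s for s in f2def.states if s != dep.s2]
        ant = cols[dep.f1] == dep.s1
        out = cols[dep.f2].copy()
        if dep.etype == "THEN":
            hold = rng.random(n) < 1 - dep.epsilon
            out[ant & hold] = dep.s2
            out[ant & ~hold] = rng.choice(np.array(others, dtype=object),
                                          size=int((ant & ~hold).sum()))
        elif dep.etype in ("OR", "AND"):
            p_s2_given_ant = dep.epsilon if dep.etype == "OR" else 1 - dep.epsilon
            p_s2_given_not = 1 - dep.epsilon if dep.etype == "OR" else dep.epsilon
            u = rng.random(n)
            take = np.where(ant, u < p_s2_given_ant, u < p_s2_given_not)
            out[take] = dep.s2
            idx = ~take
            out[idx] = rng.choice(np.array(others, dtype=object),
                                  size=int(idx.sum()))
        cols[dep.f2] = out

    data = pd.DataFrame(cols, index=tax.index).astype(object)

    # missingness last: source blocks, then cell-level MCAR
    for src in spec.sources:
        uncovered = rng.random(n) >= src.coverage
        data.loc[uncovered, list(src.features)] = UNKNOWN
    if spec.unknown_rate > 0:
        mcar = rng.random(data.shape) < spec.unknown_rate
        values = data.to_numpy(dtype=object)
        keep_na = values == NOT_APPLICABLE  # planted NA semantics survive
        values[mcar & ~keep_na] = UNKNOWN
        data = pd.DataFrame(values, index=data.index, columns=data.columns)

    ledger = {
        "seed": spec.seed,
        "n_taxa": n,
        "blocks": [vars(b) for b in spec.blocks],
        "dependencies": [vars(d) for d in spec.dependencies],
        "sources": [vars(s) for s in spec.sources],
    }
    return TraitMatrix(data, fdefs), tax, ledger


# -- bundled fixtures ------------------------------------------------------


def grambank_like_fixture(seed: int = 42) -> tuple[TraitMatrix, pd.DataFrame, dict]:
    """Dense binary fixture (~300 taxa, 40 features) with planted structure.

    Shaped like a single densely coded morphosyntactic database: mostly
    independent binary features, one un-conditioned gender-style block
    (1 latent presence + 3 manifestations, reproducing the boosted-
    similarity pathology), and one strong planted THEN dependency.
    """
    feats = [SynthFeature(f"GB{i:03d}") for i in range(1, 41)]
    feats[9] = SynthFeature("GB010", freqs=(0.4, 0.6))   # planted antecedent
    feats[10] = SynthFeature("GB011", freqs=(0.5, 0.5))  # planted consequent
    spec = SynthSpec(
        lineages_per_area=22,
        max_family_size=4,
        features=feats,
        unknown_rate=0.25,
        blocks=[PlantedBlock("GB001", ("GB002", "GB003", "GB004"),
                             p_present=0.45, conditioned=False)],
        dependencies=[PlantedDependency("dep-then", "THEN",
                                        "GB010", "1", "GB011", "1",
                                        epsilon=0.02)],
        seed=seed,
    )
    return generate(spec)


def tli_like_fixture(seed: int = 43) -> tuple[TraitMatrix, pd.DataFrame, dict]:
    """Sparse multi-source multistate fixture (~300 taxa, 40 features).

    Four simulated origin databases with differing coverage produce
    block-structured missingness on top of light cell-level MCAR; a third
    of the features are three-state.
    """
    feats = [
        SynthFeature(f"S{i:02d}", states=("x", "y", "z") if i % 3 == 0
                     else ("1", "0"))
        for i in range(40)
    ]
    fids = [f.id for f in feats]
    spec = SynthSpec(
        lineages_per_area=22,
        max_family_size=4,
        features=feats,
        unknown_rate=0.05,
        sources=[
            SourceBlock("walslike", tuple(fids[0:12]), coverage=0.55),
            SourceBlock("autotyplike", tuple(fids[12:24]), coverage=0.30),
            SourceBlock("lexibanklike", tuple(fids[24:32]), coverage=0.45),
            SourceBlock("phoiblelike", tuple(fids[32:40]), coverage=0.50),
        ],
        seed=seed,
    )
    return generate(spec)
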