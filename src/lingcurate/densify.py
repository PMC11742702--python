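"""Taxonomy-sensitive matrix densification.

Sparse trait matrices are iteratively pruned — one taxon or feature per
step — to raise coding density, with a trade-off that protects taxonomic
diversity: a taxon from a well-represented lineage is cheaper to drop than
an isolate of the same coding density. The whole pruning trajectory is
recorded, and the optimal sub-matrix is then selected by a user-composable
scoring function over the per-step summaries.

Element scores (lower is pruned first)::

    taxon score   = density(taxon)^coding_weight * (1/redundancy)^taxonomy_weight
    feature score = density(feature)

where ``redundancy`` is the number of remaining taxa sharing the taxon's
lineage. Ties break deterministically: features before taxa, then
lexicographic id.

The minimum-variability rule (second-most-frequent state attested in at
least ``min_variability`` taxa) is enforced at the boundaries of the run:
features violating it in the input are dropped before step 0, and the
selected sub-matrix is filtered again after selection. It is deliberately
*not* re-applied inside the pruning loop: a feature that loses variability
mid-trajectory can be arbitrarily densely coded, and removing it there
would break the defining behavior of the procedure — overall coding
density never decreases along the trajectory (each step removes the
minimum-density element of its kind, which is necessarily at or below its
kind's mean density when redundancy is uniform).

Step summaries carry ``n_data_points`` (coded cells), ``coding_density``,
``row_coding_density_min`` (minimum per-taxon density) and
``taxonomic_index`` (retained lineages / input lineages); the selection
score is the product of these terms raised to configurable exponents.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import TraitMatrix, state_counts


@dataclass
class DensifyParams:
    """Pruning weights, variability rule and selection exponents."""

    taxonomy_weight: float = 1.0
    coding_weight: float = 0.999
    min_variability: int = 3
    scoring_exponents: dict = field(default_factory=lambda: {
        "n_data_points": 1.0,
        "coding_density": 1.0,
        "row_coding_density_min": 1.0,
        "taxonomic_index": 3.0,
    })

    def __post_init__(self) -> None:
        if self.taxonomy_weight <= 0 and self.coding_weight <= 0:
            raise ValueError("at least one pruning weight must be positive")
        if any(v < 0 for v in self.scoring_exponents.values()):
            raise ValueError("scoring exponents must be >= 0")


@dataclass
class TrajectoryStep:
    step: int
    removed: str  # "taxon:<id>" / "feature:<id>" ("" for the input state)
    cascade: tuple[str, ...]  # features dropped for variability (step 0 only)
    n_taxa: int
    n_features: int
    n_data_points: int
    coding_density: float
    row_coding_density_min: float
    taxonomic_index: float


@dataclass
class DensifyTrajectory:
    """Ordered pruning record; step 0 is the (variability-filtered) input."""

    steps: list[TrajectoryStep]
    matrices: list[TraitMatrix]  # matrix state per step

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"step": s.step, "removed": s.removed,
             "cascade": ";".join(s.cascade),
             "n_taxa": s.n_taxa, "n_features": s.n_features,
             "n_data_points": s.n_data_points,
             "coding_density": s.coding_density,
             "row_coding_density_min": s.row_coding_density_min,
             "taxonomic_index": s.taxonomic_index}
            for s in self.steps
        ])


def element_scores(m: TraitMatrix, tax: pd.DataFrame,
                   p: DensifyParams) -> tuple[pd.Series, pd.Series]:
    """(taxon scores, feature scores); the lowest-scoring element is pruned."""
    if m.shape[0] == 0 or m.shape[1] == 0:
        raise ValueError("cannot score an empty matrix")
    coded = m.coded_mask()
    taxon_density = coded.mean(axis=1)
    feature_density = coded.mean(axis=0)
    lineages = tax.loc[m.taxa, "lineage"]
    redundancy = lineages.map(lineages.value_counts()).astype(float)
    taxon_scores = (taxon_density ** p.coding_weight
                    * (1.0 / redundancy) ** p.taxonomy_weight)
    return taxon_scores, feature_density


def _summary(m: TraitMatrix, tax: pd.DataFrame, n_lineages_input: int,
             step: int, removed: str, cascade: tuple[str, ...]) -> TrajectoryStep:
    coded = m.coded_mask()
    n_taxa, n_features = m.shape
    if n_taxa and n_features:
        density = float(coded.to_numpy().mean())
        row_min = float(coded.mean(axis=1).min())
        n_lin = tax.loc[m.taxa, "lineage"].nunique()
    else:
        density = row_min = 0.0
        n_lin = 0
    return TrajectoryStep(
        step=step, removed=removed, cascade=cascade,
        n_taxa=n_taxa, n_features=n_features,
        n_data_points=int(coded.to_numpy().sum()),
        coding_density=density, row_coding_density_min=row_min,
        taxonomic_index=(n_lin / n_lineages_input) if n_lineages_input else 0.0,
    )


def _variability_violations(m: TraitMatrix, k: int) -> list[str]:
    out = []
    for fid in m.feature_ids:
        counts = sorted(state_counts(m, fid).values(), reverse=True)
        if (counts[1] if len(counts) > 1 else 0) < k:
            out.append(fid)
    return out


def densify_run(m: TraitMatrix, tax: pd.DataFrame,
                p: DensifyParams | None = None) -> DensifyTrajectory:
    """Prune until the matrix is empty or fully dense, recording each step.

    Features violating the minimum-variability rule in the input are
    dropped before step 0 so that the recorded baseline already satisfies
    the rule, mirroring the curation criterion; inside the loop pruning is
    purely score-driven (see the module docstring).
    """
    p = p or DensifyParams()
    cur = m.copy()
    initial_drop = _variability_violations(cur, p.min_variability)
    if initial_drop:
        cur = cur.drop_features(initial_drop)
    n_lineages_input = tax.loc[cur.taxa, "lineage"].nunique() if cur.taxa else 0

    steps = [_summary(cur, tax, n_lineages_input, 0, "", tuple(initial_drop))]
    matrices = [cur]
    step = 0
    while cur.shape[0] > 0 and cur.shape[1] > 0:
        coded = cur.coded_mask().to_numpy()
        if coded.all():
            break
        taxon_scores, feature_scores = element_scores(cur, tax, p)
        # tie-break: features before taxa, then lexicographic id
        candidates = sorted(
            [(float(v), 0, str(f)) for f, v in feature_scores.items()]
            + [(float(v), 1, str(t)) for t, v in taxon_scores.items()]
        )
        score, kind, elem = candidates[0]
        if kind == 0:
            cur = cur.drop_features([elem])
            removed = f"feature:{elem}"
        else:
            cur = cur.subset(taxa=[t for t in cur.taxa if t != elem])
            removed = f"taxon:{elem}"
        step += 1
        steps.append(_summary(cur, tax, n_lineages_input, step, removed, ()))
        matrices.append(cur)
    return DensifyTrajectory(steps, matrices)


def step_score(s: TrajectoryStep, exponents: dict) -> float:
    terms = {
        "n_data_points": float(s.n_data_points),
        "coding_density": s.coding_density,
        "row_coding_density_min": s.row_coding_density_min,
        "taxonomic_index": s.taxonomic_index,
    }
    score = 1.0
    for name, exp in exponents.items():
        score *= terms[name] ** exp
    return score


def select_optimal(t: DensifyTrajectory,
                   exponents: dict | None = None,
                   min_variability: int = 3) -> tuple[int, TraitMatrix]:
    """Pick the trajectory step maximizing the scoring product.

    Ties resolve to the earliest (largest) matrix; an already-dense input
    yields step 0, i.e. the input itself. The returned matrix is filtered
    once more for minimum variability, so the curation criterion holds for
    the delivered sub-matrix regardless of what pruning did to state
    counts mid-trajectory.
    """
    if exponents is None:
        exponents = DensifyParams().scoring_exponents
    if not t.steps:
        raise ValueError("empty trajectory")
    scores = [step_score(s, exponents) for s in t.steps]
    best = int(np.argmax(scores))  # argmax returns the first maximum
    selected = t.matrices[best]
    if selected.shape[0] and selected.shape[1]:
        viol = _variability_violations(selected, min_variability)
        if viol:
            selected = selected.drop_features(viol)
    return best, selected
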