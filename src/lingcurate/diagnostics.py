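"""Validation diagnostics: local entropy maps and family-level ordination.

Two numeric analyses assess what a curation does to the signal in a trait
matrix:

1. **Local typological diversity.** Taxa with coordinates are assigned to
   their nearest point of a near-equal-area spherical grid (Fibonacci
   lattice); at each grid point with enough taxa, the normalized Shannon
   entropy of the coded state distribution is computed per feature and
   averaged. Datasets that repeat the same signal across many dependent
   features underestimate local diversity; differences between entropy maps
   of two curations quantify the correction.

2. **Family-aggregated ordination.** The matrix is aggregated to language
   families as per-state proportions (dropping each feature's globally most
   frequent state as redundant), decomposed by a missing-data-tolerant PCA
   (NIPALS), and two datasets are compared by per-component score
   correlations over their shared families.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import RESERVED, TraitMatrix

EARTH_RADIUS_KM = 6371.0


# -- spherical grid --------------------------------------------------------


def fibonacci_grid(n_points: int = 500) -> pd.DataFrame:
    """Near-equal-area spherical lattice of ``n_points`` (id, lat, lon)."""
    i = np.arange(n_points)
    golden = (1 + 5**0.5) / 2
    lat = np.degrees(np.arcsin(1 - 2 * (i + 0.5) / n_points))
    lon = np.degrees((2 * np.pi * i / golden) % (2 * np.pi)) - 180.0
    return pd.DataFrame({"grid_id": [f"g{k}" for k in i],
                         "lat": lat, "lon": lon}).set_index("grid_id")


def _haversine(lat1, lon1, lat2, lon2):
    lat1, lon1, lat2, lon2 = map(np.radians, (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(h))


def assign_to_grid(tax: pd.DataFrame, grid: pd.DataFrame) -> pd.Series:
    """Nearest grid point (great-circle) per taxon with coordinates."""
    has = tax.dropna(subset=["lat", "lon"])
    if has.empty:
        return pd.Series(dtype=object)
    d = _haversine(
        has["lat"].to_numpy()[:, None], has["lon"].to_numpy()[:, None],
        grid["lat"].to_numpy()[None, :], grid["lon"].to_numpy()[None, :],
    )
    nearest = grid.index.to_numpy()[np.argmin(d, axis=1)]
    return pd.Series(nearest, index=has.index, name="grid_id")


# -- entropy ---------------------------------------------------------------


def normalized_entropy(counts, k: int) -> float | None:
    """Shannon entropy of a state distribution, normalized by log K.

    ``counts`` are per-state counts over coded taxa only; ``k`` is the
    feature's state-space size (>= 2), kept global across grid points for
    comparability. A single represented state gives 0; zero coded taxa is
    undefined and returns None.
    """
    if k < 2:
        raise ValueError("state-space size must be >= 2")
    c = np.asarray([v for v in (counts.values() if isinstance(counts, dict)
                                else counts) if v > 0], dtype=float)
    if c.size == 0:
        return None
    p = c / c.sum()
    return float(-(p * np.log(p)).sum() / math.log(k))


@dataclass
class EntropyCell:
    grid_id: str
    mean_entropy: float
    n_taxa: int
    n_features: int  # features that cleared the coded-fraction rule


def entropy_map(
    m: TraitMatrix,
    assignment: pd.Series,
    min_taxa: int = 2,
    min_coded_fraction: float = 0.5,
) -> pd.DataFrame:
    """Mean normalized entropy per grid point.

    Per grid point with at least ``min_taxa`` assigned taxa, each feature
    coded for more than ``min_coded_fraction`` of those taxa contributes
    its normalized entropy; the cell value is the arithmetic mean over
    contributing features. Points with no contributing feature drop out.
    """
    cells = []
    for gid, taxa in assignment.groupby(assignment):
        ids = [t for t in taxa.index if t in m.data.index]
        if len(ids) < min_taxa:
            continue
        sub = m.data.loc[ids]
        entropies = []
        for fid in m.feature_ids:
            col = sub[fid]
            coded = col[~col.isin(RESERVED)]
            if len(coded) / len(ids) <= min_coded_fraction:
                continue
            h = normalized_entropy(coded.value_counts().to_dict(),
                                   len(m.features[fid].states))
            if h is not None:
                entropies.append(h)
        if entropies:
            cells.append(EntropyCell(str(gid), float(np.mean(entropies)),
                                     len(ids), len(entropies)))
    return pd.DataFrame(
        [{"grid_id": c.grid_id, "mean_entropy": c.mean_entropy,
          "n_taxa": c.n_taxa, "n_features": c.n_features} for c in cells]
    ).set_index("grid_id") if cells else pd.DataFrame(
        columns=["mean_entropy", "n_taxa", "n_features"])


def entropy_diff(map1: pd.DataFrame, map2: pd.DataFrame) -> pd.Series:
    """Per-point ``map1 - map2`` difference of mean entropies."""
    shared = map1.index.intersection(map2.index)
    if len(shared) == 0:
        raise ValueError("entropy maps share no grid points")
    return (map1.loc[shared, "mean_entropy"]
            - map2.loc[shared, "mean_entropy"]).rename("entropy_diff")


# -- family proportions and ordination ------------------------------------


def family_proportions(m: TraitMatrix, tax: pd.DataFrame) -> pd.DataFrame:
    """Family x state-proportion table for ordination.

    For every feature, the globally most frequent state (ties: the
    lexicographically smallest token is dropped) is omitted as redundant;
    each remaining state yields a column holding, per family, the
    proportion of that family's coded taxa bearing the state. Families
    with no coded taxa for a feature get missing cells.
    """
    lineages = tax.loc[[t for t in m.taxa if t in tax.index], "lineage"]
    cols = {}
    for fid in m.feature_ids:
        col = m.data.loc[lineages.index, fid]
        coded = col[~col.isin(RESERVED)]
        if coded.empty:
            continue
        counts = coded.value_counts()
        top = counts.max()
        drop = sorted(counts.index[counts == top])[0]
        fam = lineages.loc[coded.index]
        denom = fam.value_counts()
        for state in m.features[fid].states:
            if state == drop:
                continue
            num = fam[coded == state].value_counts()
            cols[f"{fid}={state}"] = (num.reindex(denom.index, fill_value=0)
                                      / denom)
    table = pd.DataFrame(cols)
    table = table.reindex(sorted(lineages.unique()))  # keep uncoded families
    table.index.name = "lineage"
    return table


def nipals_pca(X: np.ndarray, n_components: int = 3, max_iter: int = 1000,
               tol: float = 1e-9, seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """NIPALS principal components tolerant of missing cells.

    Columns are mean-centered over observed entries; scores ``T`` (rows x
    components) and loadings ``P`` are fit one component at a time by
    alternating least squares restricted to observed cells, deflating the
    observed residuals after each component.
    """
    X = np.asarray(X, dtype=float).copy()
    mask = ~np.isnan(X)
    mu = np.nanmean(X, axis=0)
    X = X - mu
    X[~mask] = 0.0
    n, m = X.shape
    T = np.zeros((n, n_components))
    P = np.zeros((m, n_components))
    rng = np.random.default_rng(seed)
    for comp in range(n_components):
        # start from the column with the largest observed variance
        var = (X**2).sum(axis=0)
        t = X[:, int(np.argmax(var))].copy()
        if not np.any(t):
            t = rng.standard_normal(n)
        for _ in range(max_iter):
            denom_p = (mask * t[:, None] ** 2).sum(axis=0)
            p = (X * t[:, None]).sum(axis=0) / np.where(denom_p > 0, denom_p, 1.0)
            norm = np.linalg.norm(p)
            if norm == 0:
                break
            p /= norm
            denom_t = (mask * p[None, :] ** 2).sum(axis=1)
            t_new = (X * p[None, :]).sum(axis=1) / np.where(denom_t > 0, denom_t, 1.0)
            if np.linalg.norm(t_new - t) <= tol * max(np.linalg.norm(t), 1e-12):
                t = t_new
                break
            t = t_new
        X = X - np.outer(t, p) * mask
        T[:, comp] = t
        P[:, comp] = p
    return T, P


def ordination_compare(table_a: pd.DataFrame, table_b: pd.DataFrame,
                       n_components: int = 3, seed: int = 0) -> np.ndarray:
    """Per-component |correlation| of PCA scores over shared families."""
    shared = table_a.index.intersection(table_b.index)
    if len(shared) < n_components + 2:
        raise ValueError(
            f"only {len(shared)} shared families; need >= {n_components + 2}")
    Ta, _ = nipals_pca(table_a.loc[shared].to_numpy(float), n_components,
                       seed=seed)
    Tb, _ = nipals_pca(table_b.loc[shared].to_numpy(float), n_components,
                       seed=seed)
    out = np.empty(n_components)
    for i in range(n_components):
        out[i] = abs(np.corrcoef(Ta[:, i], Tb[:, i])[0, 1])
    return out
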