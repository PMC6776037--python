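"""Phage-host coevolution ordination from USS frequencies and GC content.

Entities (bacterial clades and phage clusters) are described by three variables:
ΔGC (GC% minus the dataset-minimum GC%), Hin-USS frequency and Apl-USS frequency
per Mb, each standardized so its maximum is 100.  Bray-Curtis dissimilarities over
this feature matrix are embedded in two dimensions by non-metric multidimensional
scaling (nMDS), and variable vectors are fitted post hoc: direction from the Pearson
correlations of each variable with the two ordination axes, length from the multiple
correlation of a linear regression on the axes.  Phages that co-evolved with a host
long enough to pick up its USS dialect and GC% land near that host in the ordination.

The nMDS is Kruskal stress-1 minimized by SMACOF majorization alternated with
isotonic regression of configuration distances on the rank order of the input
dissimilarities (primary tie approach); the best of several random restarts is kept
and per-iteration stress traces are retained so convergence can be audited.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform
from scipy.stats import pearsonr
from sklearn.isotonic import IsotonicRegression

from .uss import USSProfile

__all__ = [
    "FeatureMatrix",
    "OrdinationResult",
    "build_features",
    "bray_curtis",
    "nmds",
    "fit_vectors",
]

FEATURE_COLUMNS = ["delta_gc", "hin_per_mb", "apl_per_mb"]


@dataclass
class FeatureMatrix:
    """Entity x (ΔGC, Hin-USS, Apl-USS) matrix, each column standardized to max 100.

    ``degenerate_columns`` lists columns whose maximum was 0 (left all-zero).
    """

    values: pd.DataFrame
    degenerate_columns: list[str]

    @property
    def entities(self) -> list[str]:
        return list(self.values.index)


@dataclass
class OrdinationResult:
    """A 2D (or 3D) nMDS configuration with its stress and fitted variable vectors."""

    coordinates: pd.DataFrame
    stress: float
    n_restarts: int
    seed: int
    stress_trace: np.ndarray  # per-iteration stress of the winning restart
    vectors: pd.DataFrame | None = None


def build_features(
    profiles: Sequence[USSProfile], grouping: Mapping[str, str]
) -> FeatureMatrix:
    """Aggregate profiles into entities and build the standardized feature matrix.

    ``grouping`` maps record id -> entity label (a bacterial clade or a phage
    cluster); profiles of the same entity are averaged.  ΔGC is the entity mean
    GC% minus the minimum entity mean GC%, so the minimum-GC entity sits at 0.
    Each column is then rescaled to maximum 100; an all-zero column is left
    untouched and flagged.
    """
    rows = []
    for p in profiles:
        if p.record_id not in grouping:
            raise ValueError(f"no entity label for record {p.record_id!r}")
        rows.append(
            {
                "entity": grouping[p.record_id],
                "gc": p.gc_percent,
                "hin_per_mb": p.hin_per_mb,
                "apl_per_mb": p.apl_per_mb,
            }
        )
    df = pd.DataFrame(rows).groupby("entity").mean()
    if df.shape[0] < 2:
        raise ValueError("need at least two entities")
    feats = pd.DataFrame(index=df.index)
    feats["delta_gc"] = df["gc"] - df["gc"].min()
    feats["hin_per_mb"] = df["hin_per_mb"]
    feats["apl_per_mb"] = df["apl_per_mb"]
    degenerate = []
    for col in FEATURE_COLUMNS:
        top = feats[col].max()
        if top > 0:
            feats[col] = 100.0 * feats[col] / top
        else:
            degenerate.append(col)
    return FeatureMatrix(values=feats, degenerate_columns=degenerate)


def bray_curtis(features: FeatureMatrix | pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity: sum|x-y| / sum(x+y), in [0, 1].

    A pair of all-zero rows is 0 by convention (identical absence).
    """
    df = features.values if isinstance(features, FeatureMatrix) else features
    x = df.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValueError("Bray-Curtis requires non-negative features")
    n = x.shape[0]
    out = np.zeros((n, n), dtype=float)
    for i in range(n):
        num = np.abs(x[i] - x[i + 1 :]).sum(axis=1)
        den = (x[i] + x[i + 1 :]).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            d = np.where(den > 0, num / den, 0.0)
        out[i, i + 1 :] = d
        out[i + 1 :, i] = d
    return pd.DataFrame(out, index=df.index, columns=df.index)


def _stress1(d_config: np.ndarray, disparities: np.ndarray) -> float:
    denom = float(np.sum(d_config**2))
    if denom == 0:
        return 0.0
    return float(np.sqrt(np.sum((d_config - disparities) ** 2) / denom))


def _condensed_distances(coords: np.ndarray) -> np.ndarray:
    from scipy.spatial.distance import pdist

    return pdist(coords)


def _classical_mds(delta: np.ndarray, n: int, dims: int) -> np.ndarray:
    """Classical (metric) MDS / PCoA configuration, used as the first start."""
    D2 = squareform(delta) ** 2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    vals, vecs = np.linalg.eigh(B)
    idx = np.argsort(vals)[::-1][:dims]
    lam = np.clip(vals[idx], 0.0, None)
    return vecs[:, idx] * np.sqrt(lam)


def _nmds_single(
    delta: np.ndarray, n: int, dims: int, max_iter: int, tol: float,
    rng: np.random.Generator, init: np.ndarray | None = None,
) -> tuple[np.ndarray, float, np.ndarray]:
    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
    coords = rng.normal(size=(n, dims)) if init is None else init.copy()
    trace = []
    prev = np.inf
    n_pairs = delta.size
    for _ in range(max_iter):
        d = _condensed_distances(coords)
        # primary tie approach: within tied delta, order by current d so ties
        # impose no constraint
        tie_order = np.lexsort((d, delta))
        fitted = np.empty_like(d)
        fitted[tie_order] = iso.fit_transform(np.arange(n_pairs), d[tie_order])
        # rescale disparities to the size of the configuration (avoids collapse)
        ssq = float(np.sum(fitted**2))
        if ssq > 0:
            fitted = fitted * np.sqrt(np.sum(d**2) / ssq)
        stress = _stress1(d, fitted)
        trace.append(stress)
        if prev - stress < tol:
            break
        prev = stress
        # Guttman transform
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(d > 0, fitted / d, 0.0)
        B = -squareform(ratio)
        np.fill_diagonal(B, -B.sum(axis=1))
        coords = B @ coords / n
    d = _condensed_distances(coords)
    tie_order = np.lexsort((d, delta))
    fitted = np.empty_like(d)
    fitted[tie_order] = iso.fit_transform(np.arange(n_pairs), d[tie_order])
    ssq = float(np.sum(fitted**2))
    if ssq > 0:
        fitted = fitted * np.sqrt(np.sum(d**2) / ssq)
    final = _stress1(d, fitted)
    trace.append(final)
    return coords, final, np.array(trace)


def _canonicalize(coords: np.ndarray) -> np.ndarray:
    """Center, rotate to principal axes, and fix axis signs for reproducibility."""
    coords = coords - coords.mean(axis=0)
    _, _, vt = np.linalg.svd(coords, full_matrices=False)
    coords = coords @ vt.T
    for ax in range(coords.shape[1]):
        pivot = np.flatnonzero(np.abs(coords[:, ax]) > 1e-12)
        if pivot.size and coords[pivot[0], ax] < 0:
            coords[:, ax] = -coords[:, ax]
    return coords


def nmds(
    dissimilarities: pd.DataFrame,
    dims: int = 2,
    n_restarts: int = 20,
    max_iter: int = 300,
    tol: float = 1e-7,
    seed: int = 0,
) -> OrdinationResult:
    """Non-metric MDS by SMACOF with isotonic regression; best of random restarts.

    Minimizes Kruskal stress-1
    ``sqrt(sum((d - d_hat)^2) / sum(d^2))`` where ``d`` are configuration
    distances and ``d_hat`` their monotone regression on the input dissimilarity
    ranks.  Coordinates are centered, rotated to principal axes, and sign-fixed
    (first entity non-negative on each axis).  Deterministic given the seed;
    more restarts can only lower the reported stress.
    """
    mat = dissimilarities.to_numpy(dtype=float)
    if mat.shape[0] != mat.shape[1] or not np.allclose(mat, mat.T, atol=1e-12):
        raise ValueError("dissimilarity matrix must be square and symmetric")
    if not np.allclose(np.diag(mat), 0.0):
        raise ValueError("dissimilarity matrix must have zero diagonal")
    n = mat.shape[0]
    if n < dims + 2:
        raise ValueError(f"need at least {dims + 2} entities for dims={dims}")
    delta = squareform(mat, checks=False)
    rng = np.random.default_rng(seed)
    best: tuple[np.ndarray, float, np.ndarray] | None = None
    for restart in range(n_restarts):
        # first restart from the classical-MDS solution (avoids the degenerate
        # collapsed configurations nMDS is prone to at small n), rest random
        init = _classical_mds(delta, n, dims) if restart == 0 else None
        coords, stress, trace = _nmds_single(delta, n, dims, max_iter, tol, rng, init)
        if best is None or stress < best[1]:
            best = (coords, stress, trace)
    assert best is not None
    coords = _canonicalize(best[0])
    axes = [f"axis{i + 1}" for i in range(dims)]
    return OrdinationResult(
        coordinates=pd.DataFrame(coords, index=dissimilarities.index, columns=axes),
        stress=best[1],
        n_restarts=n_restarts,
        seed=seed,
        stress_trace=best[2],
    )


def fit_vectors(result: OrdinationResult, features: FeatureMatrix) -> pd.DataFrame:
    """Post hoc variable vectors: axis correlations and multiple correlation R.

    For each feature column: direction = (r(var, axis1), r(var, axis2), ...);
    length = multiple correlation coefficient of the linear regression of the
    variable on the ordination coordinates.  Zero-variance (degenerate) variables
    get NaN direction and R with ``defined=False``.
    """
    coords = result.coordinates.loc[features.entities].to_numpy(dtype=float)
    axes = list(result.coordinates.columns)
    rows = []
    for col in features.values.columns:
        v = features.values[col].to_numpy(dtype=float)
        if np.allclose(v.var(), 0.0):
            rows.append(
                {"variable": col, **{f"r_{a}": np.nan for a in axes},
                 "multiple_r": np.nan, "defined": False}
            )
            continue
        dirs = {f"r_{a}": float(pearsonr(v, coords[:, i]).statistic)
                for i, a in enumerate(axes)}
        X = np.column_stack([np.ones(coords.shape[0]), coords])
        beta, *_ = np.linalg.lstsq(X, v, rcond=None)
        pred = X @ beta
        ss_res = float(np.sum((v - pred) ** 2))
        ss_tot = float(np.sum((v - v.mean()) ** 2))
        r2 = max(0.0, 1.0 - ss_res / ss_tot)
        rows.append({"variable": col, **dirs, "multiple_r": float(np.sqrt(r2)),
                     "defined": True})
    vectors = pd.DataFrame(rows).set_index("variable")
    result.vectors = vectors
    return vectors
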