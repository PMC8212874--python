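"""Shape clustering of harmonized peak profiles.

Each profile is max-min normalized (shape only, intensity removed), smoothed
with a regression spline, and summarized by three curve features — number of
local maxima, area under the curve, arc length. The smoothed profile plus
z-scored features are embedded to two dimensions with UMAP (5000 epochs,
min_dist 0.01, 5 neighbors) and clustered with k-means (100 initializations,
up to 10000 iterations). The cluster count k is chosen where the total
within-cluster sum of squares stops decreasing appreciably, with the AIC
curve reported as a cross-check; the user may force k instead.

A cluster is "sharp" when its median CV exceeds the median CV of the whole
peak set; a peak is sharp when its own CV exceeds 0.2 *and* it sits in a
sharp cluster. Everything else is broad.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.interpolate import BSpline
from scipy.signal import find_peaks
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .core import ShapeAssignment

UMAP_EPOCHS = 5000
UMAP_MIN_DIST = 0.01
UMAP_NEIGHBORS = 5
KMEANS_INITS = 100
KMEANS_MAX_ITER = 10_000


def normalize_profile(depths) -> np.ndarray:
    """Per-peak max-min normalization; a constant profile maps to all zeros."""
    x = np.asarray(depths, dtype=float)
    if x.size == 0:
        raise ValueError("empty profile")
    span = x.max() - x.min()
    if span == 0:
        return np.zeros_like(x)
    return (x - x.min()) / span


#: Base second-difference penalty of the smoothing spline at
#: smoothing_factor 1. Calibrated once on the four canonical synthetic
#: profile families (uniform / linear / unimodal / bimodal at 5% noise) so
#: that within-family noise wiggles are damped while the family shapes —
#: including both modes of a bimodal profile — survive.
SMOOTHING_BASE_PENALTY = 5.0


def smooth_profile(values, smoothing_factor: float = 1.0) -> np.ndarray:
    """Penalized regression-spline smoothing of one profile (P-spline).

    A cubic B-spline basis with a knot every other nucleotide is fit by
    ridge regression with a second-difference penalty on the coefficients
    (penalty ``SMOOTHING_BASE_PENALTY * smoothing_factor**4`` — the fourth
    power makes the factor act on the smoothing length scale, so doubling
    it doubles the width of the features that survive). The fit varies
    continuously with the data — unlike knot-selecting splines, nearly
    identical profiles smooth to nearly identical curves, which the
    downstream neighborhood embedding relies on. Raising the factor
    underfits (fewer maxima survive, hence fewer shape clusters); lowering
    it overfits. Profiles shorter than 4 points are returned unsmoothed
    with a warning. The fit is evaluated per nucleotide and clipped to
    >= 0.
    """
    y = np.asarray(values, dtype=float)
    n = y.size
    if smoothing_factor <= 0:
        raise ValueError("smoothing_factor must be positive")
    if n < 4:
        warnings.warn(f"profile of length {n} too short to smooth; returned as-is")
        return y.copy()
    x = np.arange(n, dtype=float)
    degree = 3
    interior = np.arange(2, n - 2, 2, dtype=float)
    knots = np.r_[[0.0] * (degree + 1), interior, [float(n - 1)] * (degree + 1)]
    basis = BSpline.design_matrix(x, knots, degree).toarray()
    n_coef = basis.shape[1]
    penalty = np.diff(np.eye(n_coef), 2, axis=0)
    lam = SMOOTHING_BASE_PENALTY * smoothing_factor**4
    coef = np.linalg.solve(
        basis.T @ basis + lam * (penalty.T @ penalty), basis.T @ y
    )
    return np.clip(basis @ coef, 0.0, None)


def count_maxima(values, min_prominence: float = 0.05) -> int:
    """Local maxima of a vector; plateau runs count once, boundaries eligible.

    A maximum must rise at least ``min_prominence`` above its surrounding
    saddles. The threshold is absolute, on the scale of the max-min
    normalized profiles this operates on ([0, 1]), so the near-flat wiggles
    of an essentially constant profile do not register as maxima. A
    constant vector has none.
    """
    y = np.asarray(values, dtype=float)
    if y.size == 0:
        return 0
    span = float(y.max() - y.min())
    if span == 0:
        return 0
    # pad below the minimum so boundary maxima are eligible
    pad = y.min() - max(span, min_prominence)
    peaks, _ = find_peaks(np.r_[pad, y, pad], prominence=min_prominence)
    return int(len(peaks))


def curve_features(smoothed) -> tuple[int, float, float]:
    """(n_maxima, area under the curve, arc length) of a smoothed profile.

    AUC is the trapezoidal integral at unit nucleotide spacing; arc length is
    ``sum_j sqrt(1 + (x_{j+1} - x_j)^2)`` (a flat profile of length n has arc
    length n - 1).
    """
    y = np.asarray(smoothed, dtype=float)
    if y.size == 0:
        raise ValueError("empty profile")
    n_max = count_maxima(y)
    auc = float(np.trapezoid(y)) if y.size > 1 else 0.0
    steps = np.diff(y)
    arc = float(np.sum(np.sqrt(1.0 + steps**2)))
    return n_max, auc, arc


def build_feature_matrix(profiles: Sequence[np.ndarray]) -> np.ndarray:
    """Row per peak: smoothed profile values plus the 3 z-scored curve features.

    The features are standardized column-wise across peaks so they are
    commensurate with the [0, 1] profile values; a zero-variance feature
    column becomes all zeros.
    """
    if len(profiles) == 0:
        raise ValueError("no profiles")
    lengths = {len(p) for p in profiles}
    if len(lengths) != 1:
        raise ValueError(f"profiles have unequal lengths: {sorted(lengths)}")
    matrix = np.asarray([np.asarray(p, dtype=float) for p in profiles])
    feats = np.asarray([curve_features(p) for p in profiles], dtype=float)
    mean = feats.mean(axis=0)
    std = feats.std(axis=0)
    std_safe = np.where(std > 0, std, 1.0)
    z = (feats - mean) / std_safe
    z[:, std == 0] = 0.0
    return np.hstack([matrix, z])


def embed_2d(matrix: np.ndarray, seed: int = 42) -> np.ndarray:
    """Nonlinear 2-D embedding of the feature matrix.

    UMAP with 5000 epochs, 2 components, min_dist 0.01 and 5 neighbors;
    the seed makes the embedding reproducible. Inputs too small for a
    5-neighbor graph fall back to the first two principal components.
    """
    X = np.asarray(matrix, dtype=float)
    n = X.shape[0]
    if n <= UMAP_NEIGHBORS + 1:
        warnings.warn(
            f"only {n} profiles: falling back to PCA for the 2-D embedding"
        )
        if n < 2:
            return np.zeros((n, 2))
        pca = PCA(n_components=2, random_state=seed)
        return pca.fit_transform(X)
    import umap  # deferred: numba compilation is expensive at import time

    reducer = umap.UMAP(
        n_components=2,
        n_neighbors=UMAP_NEIGHBORS,
        min_dist=UMAP_MIN_DIST,
        n_epochs=UMAP_EPOCHS,
        random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # umap warns about forced determinism
        return np.asarray(reducer.fit_transform(X), dtype=float)


@dataclass
class ClusteringResult:
    labels: np.ndarray  # 1-based cluster ids
    k: int
    forced: bool = False
    wss_by_k: dict[int, float] = field(default_factory=dict)
    aic_by_k: dict[int, float] = field(default_factory=dict)


def _kmeans(coords: np.ndarray, k: int, seed: int) -> KMeans:
    return KMeans(
        n_clusters=k,
        n_init=KMEANS_INITS,
        max_iter=KMEANS_MAX_ITER,
        random_state=seed,
    ).fit(coords)


def kmeans_aic(wss: float, n: int, k: int, d: int = 2) -> float:
    """AIC of a k-means solution: n d ln(WSS / (n d)) + 2 k d."""
    wss = max(wss, 1e-12)
    return n * d * float(np.log(wss / (n * d))) + 2 * k * d


def cluster_profiles(
    coords: np.ndarray,
    k_max: int = 15,
    k_forced: int | None = None,
    seed: int = 42,
    wss_tolerance: float = 0.05,
) -> ClusteringResult:
    """k-means clustering of the 2-D embedding with automatic k selection.

    Without *k_forced*, k-means is run for k = 1..k_max and the chosen k is
    the smallest one at which the WSS curve has converged: the improvement
    from k to k+1 drops below *wss_tolerance* times the improvement from
    k-1 to k (the elbow), or becomes negligible (< 1%) relative to the
    total k=1 WSS. The AIC curve is recorded alongside as a diagnostic.
    Cluster ids are 1-based.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if k_forced is not None:
        if not (1 <= k_forced <= n):
            raise ValueError(f"k_forced={k_forced} outside 1..{n}")
        model = _kmeans(coords, k_forced, seed)
        return ClusteringResult(labels=model.labels_ + 1, k=k_forced, forced=True)
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    k_cap = min(k_max, n)
    models = {}
    wss = {}
    for k in range(1, k_cap + 1):
        models[k] = _kmeans(coords, k, seed)
        wss[k] = float(models[k].inertia_)
    aic = {k: kmeans_aic(w, n, k) for k, w in wss.items()}
    total = wss[1]
    chosen = k_cap
    if total <= 0:
        chosen = 1
    else:
        for k in range(1, k_cap):
            drop = max(wss[k] - wss[k + 1], 0.0)
            converged = drop < 0.01 * total
            if k > 1:
                previous_drop = max(wss[k - 1] - wss[k], 0.0)
                converged = converged or drop < wss_tolerance * previous_drop
            if converged:
                chosen = k
                break
    return ClusteringResult(
        labels=models[chosen].labels_ + 1,
        k=chosen,
        forced=False,
        wss_by_k=wss,
        aic_by_k=aic,
    )


def flag_sharp(
    labels: Sequence[int], cvs: Sequence[float], cv_threshold: float = 0.2
) -> tuple[np.ndarray, dict[int, bool]]:
    """Sharp/broad call per peak and per cluster.

    A cluster is sharp iff its median CV strictly exceeds the median CV of
    the whole peak set; a peak is sharp iff its CV > *cv_threshold* and its
    cluster is sharp. Returns (per-peak boolean array, cluster -> sharp map).
    """
    labels = np.asarray(labels)
    cvs = np.asarray(cvs, dtype=float)
    if labels.shape != cvs.shape:
        raise ValueError("one CV per labeled peak required")
    global_median = float(np.median(cvs))
    cluster_sharp = {
        int(c): float(np.median(cvs[labels == c])) > global_median
        for c in np.unique(labels)
    }
    peak_sharp = (cvs > cv_threshold) & np.asarray(
        [cluster_sharp[int(c)] for c in labels]
    )
    return peak_sharp, cluster_sharp


def classify_profiles(
    depth_vectors: Sequence[np.ndarray],
    smoothing: bool = True,
    smoothing_factor: float = 1.0,
    k_max: int = 15,
    k_forced: int | None = None,
    seed: int = 42,
    cvs: Sequence[float] | None = None,
    cv_threshold: float = 0.2,
) -> tuple[list[ShapeAssignment], ClusteringResult, list[np.ndarray], list[np.ndarray]]:
    """Full shape-classification stage on raw depth vectors.

    Returns (assignments, clustering result, normalized profiles, smoothed
    profiles). When *cvs* is given, sharp/broad flags are filled in.
    """
    normalized = [normalize_profile(d) for d in depth_vectors]
    if smoothing:
        smoothed = [smooth_profile(p, smoothing_factor) for p in normalized]
    else:
        smoothed = [p.copy() for p in normalized]
    matrix = build_feature_matrix(smoothed)
    coords = embed_2d(matrix, seed=seed)
    result = cluster_profiles(coords, k_max=k_max, k_forced=k_forced, seed=seed)
    if cvs is not None:
        peak_sharp, cluster_sharp = flag_sharp(result.labels, cvs, cv_threshold)
    else:
        peak_sharp = np.zeros(len(normalized), dtype=bool)
        cluster_sharp = {int(c): False for c in np.unique(result.labels)}
    assignments = [
        ShapeAssignment(
            embedding=coords[i],
            cluster=int(result.labels[i]),
            is_sharp_cluster=cluster_sharp[int(result.labels[i])],
            is_sharp_peak=bool(peak_sharp[i]),
        )
        for i in range(len(normalized))
    ]
    return assignments, result, normalized, smoothed
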