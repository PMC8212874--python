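"""Peak specificity scoring via the negative-binomial coefficient of variation.

The per-nucleotide read count of a peak is modeled as a negative binomial
X ~ NB(r, p) in the trials-for-r-successes parameterization (mean r/p,
variance r(1-p)/p^2). The hyperparameters are estimated by moment matching,
under which the model CV

    CV = sqrt((1 - p) / r)

reduces exactly to the empirical sd/mean of the depth vector. A high CV
marks a sharp, specific profile; a flat (unspecific) profile has CV ~ 0.
CVs are min-max normalized across the peak set (or against a user-supplied
scale maximum), and each peak is labeled 0 (specific) or 1 (unspecific)
against a threshold, 0.2 by default.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
from scipy import stats

from .core import NBEstimate, PeakEvaluation


def estimate_nb(depths) -> NBEstimate:
    """Moment-matched negative-binomial hyperparameters of a depth vector.

    With sample mean m and (population) variance v: p = m/(v+m),
    r = m^2/(v+m). Degenerate cases: an all-zero profile maps to
    NB(r=1, p=1) and a zero-variance positive profile to NB(r=m, p=1),
    both of which give CV = 0.
    """
    x = np.asarray(depths, dtype=float)
    if x.size == 0:
        raise ValueError("empty depth vector")
    m = float(x.mean())
    v = float(x.var())
    if m <= 0:
        return NBEstimate(r=1.0, p=1.0)
    if v == 0:
        return NBEstimate(r=m, p=1.0)
    return NBEstimate(r=m * m / (v + m), p=m / (v + m))


def cv_score(est: NBEstimate) -> float:
    """Coefficient of variation sqrt((1-p)/r) of a negative binomial."""
    return float(np.sqrt((1.0 - est.p) / est.r))


def border_penalty(cv: float, depths) -> tuple[float, float]:
    """Down-weight the CV of peaks sitting on the edge of a read stack.

    A peak that covers a small appendage of a broad plateau has high
    boundary depths relative to its maximum; the penalty factor
    ``1 - min(1, (d_first + d_last) / (2 d_max))`` is 1 for a peak whose
    signal is fully interior and 0 for a flat plateau. Returns
    ``(cv * factor, factor)``.
    """
    x = np.asarray(depths, dtype=float)
    if x.size == 0:
        raise ValueError("empty depth vector")
    d_max = float(x.max())
    ratio = 0.0 if d_max <= 0 else (float(x[0]) + float(x[-1])) / (2.0 * d_max)
    factor = 1.0 - min(1.0, ratio)
    return cv * factor, factor


def normalize_cv(cvs: Sequence[float], scale_max: float | None = None) -> np.ndarray:
    """Normalize CV scores into [0, 1].

    Default: min-max over the whole set, ``(cv - min) / (max - min)``;
    an all-equal input maps to all zeros. With *scale_max* s the scores are
    instead clipped at s and divided by s (minimum taken as 0), which makes
    normalized CVs comparable across experiments.
    """
    x = np.asarray(cvs, dtype=float)
    if x.size == 0:
        raise ValueError("no CV values")
    if np.any(x < 0):
        raise ValueError("CV values must be non-negative")
    if scale_max is not None:
        if scale_max <= 0:
            raise ValueError(f"scale_max must be positive, got {scale_max}")
        return np.minimum(x, scale_max) / scale_max
    span = x.max() - x.min()
    if span == 0:
        return np.zeros_like(x)
    return (x - x.min()) / span


def label_specificity(score: float, threshold: float = 0.2, basis: str = "normalized") -> int:
    """Label one peak: 1 (unspecific) below *threshold*, else 0 (specific)."""
    if basis not in ("normalized", "raw"):
        raise ValueError(f"unknown threshold basis {basis!r}")
    if basis == "normalized" and not (0 < threshold < 1):
        warnings.warn(
            f"threshold {threshold} lies outside (0, 1) on the normalized scale"
        )
    return 1 if score < threshold else 0


def evaluate_profiles(
    profiles,
    use_border_penalty: bool = False,
    scale_max: float | None = None,
    threshold: float = 0.2,
    threshold_basis: str = "normalized",
) -> list[PeakEvaluation]:
    """Score a whole peak set: NB fit, CV, optional penalty, normalization, labels.

    *profiles* is a sequence of CoverageProfile objects or raw depth vectors.
    """
    cvs = []
    factors = []
    for profile in profiles:
        depths = getattr(profile, "depths", profile)
        cv = cv_score(estimate_nb(depths))
        factor = 1.0
        if use_border_penalty:
            cv, factor = border_penalty(cv, depths)
        cvs.append(cv)
        factors.append(factor)
    normalized = normalize_cv(cvs, scale_max=scale_max)
    evaluations = []
    for cv, cvn, factor in zip(cvs, normalized, factors):
        basis_score = cvn if threshold_basis == "normalized" else cv
        evaluations.append(
            PeakEvaluation(
                cv=cv,
                cv_normalized=float(cvn),
                label=label_specificity(basis_score, threshold, threshold_basis),
                penalty_factor=factor,
            )
        )
    return evaluations


def compare_cv_distributions(
    cvs_a: Sequence[float], cvs_b: Sequence[float], alternative: str = "two-sided"
) -> float:
    """Rank-sum (Mann-Whitney) p-value comparing two CV distributions.

    *alternative* is ``two-sided``, ``less`` or ``greater`` (a one-sided
    test that sample a is stochastically smaller resp. greater than b).
    Small untied samples use the exact null distribution, larger ones the
    tie-corrected normal approximation.
    """
    a = np.asarray(cvs_a, dtype=float)
    b = np.asarray(cvs_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        warnings.warn("all pooled values identical; rank-sum p-value set to 1")
        return 1.0
    method = "auto" if max(a.size, b.size) <= 50 else "asymptotic"
    result = stats.mannwhitneyu(a, b, alternative=alternative, method=method)
    return float(result.pvalue)
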