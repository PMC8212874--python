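"""Peak preparation: re-centering and length harmonization.

Peak callers often report windows that are offset from the actual signal,
and downstream shape comparison needs every profile on a common length.
The prep stage therefore (1) slides each peak onto the maximum of its
coverage signal — either the maximum of a Gaussian-kernel convolution of
the extended window, or the raw summit — and (2) extends or shrinks every
peak symmetrically about its midpoint to one common length, sliding windows
inward at chromosome edges so the length is preserved.
"""

from __future__ import annotations

import logging
from dataclasses import replace
from typing import Sequence

import numpy as np

from .core import CenteringConfig, ChromSizes, GenomicInterval

logger = logging.getLogger(__name__)


def gaussian_kernel(halfwidth: int) -> np.ndarray:
    """Discrete Gaussian kernel on [-halfwidth, halfwidth], sum 1.

    sigma = halfwidth / 3, so the kernel support covers three standard
    deviations on each side — a scale-free shape once halfwidth is tied to
    the harmonized peak length.
    """
    if halfwidth < 1:
        raise ValueError("halfwidth must be >= 1")
    offsets = np.arange(-halfwidth, halfwidth + 1, dtype=float)
    sigma = halfwidth / 3.0
    kernel = np.exp(-0.5 * (offsets / sigma) ** 2)
    return kernel / kernel.sum()


def center_shift(
    depths: np.ndarray,
    config: CenteringConfig,
    center_index: int | None = None,
) -> int:
    """Signed 5'->3' shift that centers the window on its signal.

    *depths* is the coverage over the peak plus its search flanks (profile
    coordinates, 5'->3'). The shift is the argmax of either the Gaussian
    convolution or the raw depths, relative to *center_index* (default:
    left-biased middle of the window), clamped to ``+-search_flank``. Ties
    pick the left-most maximum; an all-zero window yields shift 0.
    """
    depths = np.asarray(depths, dtype=float)
    n = len(depths)
    if n == 0:
        raise ValueError("empty profile")
    if center_index is None:
        center_index = (n - 1) // 2
    if depths.max() <= 0:
        return 0
    if config.scheme == "summit":
        score = depths
    else:
        score = np.convolve(depths, gaussian_kernel(config.kernel_halfwidth), mode="same")
    lo = max(0, center_index - config.search_flank)
    hi = min(n, center_index + config.search_flank + 1)
    window = score[lo:hi]
    return lo + int(np.argmax(window)) - center_index


def _slide_into_bounds(start: int, end: int, size: int) -> tuple[int, int]:
    """Translate [start, end) to lie inside [0, size), preserving length."""
    length = end - start
    if length > size:
        raise ValueError(f"window length {length} exceeds chromosome length {size}")
    if start < 0:
        return 0, length
    if end > size:
        return size - length, size
    return start, end


def apply_shift(
    peak: GenomicInterval, shift: int, sizes: ChromSizes
) -> GenomicInterval:
    """Translate *peak* by a 5'->3' *shift*, clamped to chromosome bounds.

    On the minus strand a positive 5'->3' shift moves the window toward
    smaller genomic coordinates.
    """
    genomic_shift = -shift if peak.strand == "-" else shift
    start, end = _slide_into_bounds(
        peak.start + genomic_shift, peak.end + genomic_shift, sizes[peak.chrom]
    )
    return replace(peak, start=start, end=end)


def harmonized_target_length(
    peaks: Sequence[GenomicInterval], target_length: int | None = None
) -> int:
    if target_length is not None:
        if target_length < 1:
            raise ValueError("target_length must be >= 1")
        return target_length
    if not peaks:
        raise ValueError("no peaks to harmonize")
    return max(p.length for p in peaks)


def harmonize_length(
    peaks: Sequence[GenomicInterval],
    target_length: int | None,
    sizes: ChromSizes,
) -> list[GenomicInterval]:
    """Bring every peak to one common length (default: max observed length).

    Extension/shrinkage is symmetric about the peak midpoint; an odd
    remainder goes to the 5' side (left on +/. strands, right on -).
    Windows hitting a chromosome edge slide inward to preserve the length;
    peaks on contigs shorter than the target are dropped with a warning.
    """
    target = harmonized_target_length(peaks, target_length)
    out: list[GenomicInterval] = []
    for peak in peaks:
        size = sizes[peak.chrom]
        if target > size:
            logger.warning(
                "dropping peak %s: harmonized length %d exceeds chromosome "
                "%s length %d",
                peak.name,
                target,
                peak.chrom,
                size,
            )
            continue
        diff = target - peak.length
        if peak.strand == "-":
            left, right = diff // 2, diff - diff // 2
        else:
            left = (diff + 1) // 2
            right = diff - left
        start, end = _slide_into_bounds(peak.start - left, peak.end + right, size)
        out.append(replace(peak, start=start, end=end))
    return out
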