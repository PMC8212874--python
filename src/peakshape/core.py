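"""Core domain types shared across the package.

Coordinates follow the BED convention throughout: 0-based, half-open
``[start, end)``. Coverage profiles are oriented 5'->3' on the strand of
their peak, so the first element of a minus-strand profile corresponds to
the *largest* genomic coordinate of the window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

VALID_STRANDS = frozenset({"+", "-", "."})


@dataclass(frozen=True)
class GenomicInterval:
    """A BED6 record: half-open interval with name, score and strand."""

    chrom: str
    start: int
    end: int
    name: str = "."
    score: float = 0.0
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        """Left-biased integer midpoint of the interval."""
        return (self.start + self.end - 1) // 2

    def to_bed6(self) -> str:
        score = self.score
        score_str = str(int(score)) if float(score).is_integer() else repr(score)
        return "\t".join(
            (self.chrom, str(self.start), str(self.end), self.name, score_str, self.strand)
        )


class ChromSizes(dict):
    """Mapping chromosome name -> length in nucleotides.

    Lengths must be positive; looking up an unknown chromosome raises a
    ``KeyError`` naming the chromosome.
    """

    def __setitem__(self, key: str, value: int) -> None:
        value = int(value)
        if value <= 0:
            raise ValueError(f"chromosome {key!r} has non-positive length {value}")
        super().__setitem__(key, value)

    def __missing__(self, key: str):
        raise KeyError(f"unknown chromosome {key!r}")

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, int]) -> "ChromSizes":
        sizes = cls()
        for name, length in mapping.items():
            sizes[name] = length
        return sizes

    def check(self, interval: GenomicInterval) -> None:
        """Raise if *interval* exceeds the bounds of its chromosome."""
        size = self[interval.chrom]
        if interval.end > size:
            raise ValueError(
                f"interval {interval.chrom}:{interval.start}-{interval.end} "
                f"exceeds chromosome length {size}"
            )


@dataclass
class CoverageProfile:
    """Per-nucleotide read depths over one peak, oriented 5'->3'."""

    peak: GenomicInterval
    depths: np.ndarray

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths)
        if self.depths.ndim != 1 or len(self.depths) != self.peak.length:
            raise ValueError(
                f"profile length {len(self.depths)} does not match peak length "
                f"{self.peak.length}"
            )
        if np.any(self.depths < 0):
            raise ValueError("coverage depths must be non-negative")

    def __len__(self) -> int:
        return len(self.depths)


@dataclass(frozen=True)
class NBEstimate:
    """Negative-binomial hyperparameters (trials-for-r-successes form).

    Under this parameterization the read count of a peak has mean ``r/p``
    and variance ``r (1-p) / p**2``; ``r`` is the number of hits and ``p``
    the probability of a hit.
    """

    r: float
    p: float

    def __post_init__(self) -> None:
        if not self.r > 0:
            raise ValueError(f"r must be positive, got {self.r}")
        if not (0 < self.p <= 1):
            raise ValueError(f"p must lie in (0, 1], got {self.p}")


@dataclass
class PeakEvaluation:
    """CV-based specificity assessment of one peak."""

    cv: float
    cv_normalized: float = float("nan")
    label: int = 1  # 0 = specific, 1 = unspecific
    penalty_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ValueError("cv must be non-negative")
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")


@dataclass
class ShapeAssignment:
    """Shape-cluster assignment of one peak profile."""

    embedding: np.ndarray  # 2 coordinates
    cluster: int  # 1-based cluster id
    is_sharp_cluster: bool = False
    is_sharp_peak: bool = False

    def __post_init__(self) -> None:
        self.embedding = np.asarray(self.embedding, dtype=float)
        if self.embedding.shape != (2,):
            raise ValueError("embedding must have exactly 2 coordinates")
        if self.cluster < 1:
            raise ValueError("cluster ids are 1-based")


@dataclass(frozen=True)
class CenteringConfig:
    """How to re-center a peak on its signal before length harmonization.

    scheme ``gaussian-convolution`` slides a Gaussian-shaped kernel over the
    extended coverage window and centers on the convolution maximum; scheme
    ``summit`` centers on the raw depth maximum (useful for single-nucleotide
    events such as crosslink truncations).
    """

    enabled: bool = True
    scheme: str = "gaussian-convolution"
    kernel_halfwidth: int = 15
    search_flank: int = 50

    def __post_init__(self) -> None:
        if self.scheme not in ("gaussian-convolution", "summit"):
            raise ValueError(f"unknown centering scheme {self.scheme!r}")
        if self.kernel_halfwidth < 1:
            raise ValueError("kernel_halfwidth must be >= 1")
        if self.search_flank < 0:
            raise ValueError("search_flank must be >= 0")
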