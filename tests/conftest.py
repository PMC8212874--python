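import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    max_examples=25,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from peakshape.core import GenomicInterval
from peakshape.simulate import CANONICAL_FAMILIES, ShapeSpec, generate_profile


def brute_force_coverage(reads, peak, same_strand):
    """O(reads x positions) per-base counting oracle, independent of io.py."""
    depths = np.zeros(peak.length, dtype=np.int64)
    for j in range(peak.length):
        position = peak.start + j
        for read in reads:
            if read.chrom != peak.chrom:
                continue
            if same_strand and peak.strand != "." and read.strand != peak.strand:
                continue
            if read.start <= position < read.end:
                depths[j] += 1
    return depths[::-1] if peak.strand == "-" else depths


def four_family_profiles(noise, base_seed, n_per_family=50, length=77, amplitude=100.0):
    """The canonical four-family synthetic test set with true labels."""
    profiles, labels = [], []
    index = 0
    for family in CANONICAL_FAMILIES:
        for _ in range(n_per_family):
            depths, _ = generate_profile(
                ShapeSpec(family, length, amplitude, noise, seed=base_seed * 10_000 + index)
            )
            profiles.append(depths)
            labels.append(family)
            index += 1
    return profiles, labels


@pytest.fixture
def chrom_sizes():
    from peakshape.core import ChromSizes

    return ChromSizes.from_mapping({"chr1": 100_000, "chrT": 1_000})


@pytest.fixture
def simple_peak():
    return GenomicInterval("chr1", 100, 130, "p1", 0.0, "+")
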