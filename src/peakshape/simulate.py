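"""Synthetic peaks, profiles and reads with known ground truth.

The profile families mirror the shape vocabulary of CLIP peak landscapes:
the four canonical test families (uniform, linear, unimodal Gaussian,
bimodal Gaussian) used to tune the classifier, plus plateau, constant and
sharp-spike profiles for CV contrasts. Reads realizing a target coverage
are built by a greedy stack construction, and a 50/50 pseudo-replicate
split (with or without replacement) supports reproducibility checks.
Everything is deterministic given a seed, so the whole pipeline is testable
without external data.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pysam
from scipy.ndimage import gaussian_filter1d

from .core import ChromSizes, GenomicInterval
from .io import write_bed6, write_chrom_sizes

FAMILIES = (
    "uniform",
    "linear",
    "unimodal-gaussian",
    "bimodal-gaussian",
    "plateau",
    "constant",
    "sharp-spike",
)

CANONICAL_FAMILIES = FAMILIES[:4]


@dataclass(frozen=True)
class ShapeSpec:
    """Recipe for one synthetic coverage profile."""

    family: str
    length: int = 77
    amplitude: float = 100.0
    noise: float = 0.0  # relative sd of multiplicative log-normal noise
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; choose from {FAMILIES}")
        if self.length < 4:
            raise ValueError("length must be >= 4")
        if self.amplitude < 1:
            raise ValueError("amplitude must be >= 1")
        if not (0 <= self.noise < 1):
            raise ValueError("noise must lie in [0, 1)")


def expected_curve(family: str, length: int, amplitude: float) -> np.ndarray:
    """Noise-free expected depth curve of a profile family."""
    pos = np.arange(length, dtype=float)
    center = (length - 1) / 2.0
    if family in ("uniform", "constant"):
        curve = np.full(length, amplitude)
    elif family == "linear":
        curve = amplitude * (pos + 1) / length
    elif family == "unimodal-gaussian":
        sigma = length / 8.0
        curve = amplitude * np.exp(-0.5 * ((pos - center) / sigma) ** 2)
    elif family == "bimodal-gaussian":
        # mode separation = half the profile length
        sigma = length / 16.0
        m1, m2 = center - length / 4.0, center + length / 4.0
        curve = amplitude * (
            np.exp(-0.5 * ((pos - m1) / sigma) ** 2)
            + np.exp(-0.5 * ((pos - m2) / sigma) ** 2)
        )
        curve *= amplitude / curve.max()
    elif family == "plateau":
        curve = np.full(length, 0.1 * amplitude)
        lo, hi = length // 4, length - length // 4
        curve[lo:hi] = amplitude
    elif family == "sharp-spike":
        sigma = max(length / 30.0, 1.0)
        curve = amplitude * np.exp(-0.5 * ((pos - center) / sigma) ** 2)
    else:  # pragma: no cover - guarded by ShapeSpec
        raise ValueError(f"unknown family {family!r}")
    return curve


def _jittered_curve(spec: ShapeSpec, rng: np.random.Generator) -> np.ndarray:
    """Family curve with peak-to-peak shape variability at relative sd = noise.

    Real binding sites within one shape class differ slightly in width,
    position and slope; mode widths get a log-normal factor and mode
    centers a normal offset (sd = noise * length), both scaled by the
    spec's noise level. At noise 0 this is exactly the canonical curve.
    """
    length, amplitude, noise = spec.length, spec.amplitude, spec.noise
    pos = np.arange(length, dtype=float)
    center = (length - 1) / 2.0
    width_factor = float(np.exp(rng.normal(0.0, noise)))
    shift = float(rng.normal(0.0, noise * length))
    family = spec.family
    if family in ("uniform", "constant"):
        return np.full(length, amplitude)
    if family == "linear":
        return amplitude * width_factor * (pos + 1) / length
    if family == "unimodal-gaussian":
        sigma = (length / 8.0) * width_factor
        return amplitude * np.exp(-0.5 * ((pos - center - shift) / sigma) ** 2)
    if family == "bimodal-gaussian":
        sigma = (length / 16.0) * width_factor
        shift2 = float(rng.normal(0.0, noise * length))
        m1 = center - length / 4.0 + shift
        m2 = center + length / 4.0 + shift2
        curve = np.exp(-0.5 * ((pos - m1) / sigma) ** 2) + np.exp(
            -0.5 * ((pos - m2) / sigma) ** 2
        )
        return curve * (amplitude / curve.max())
    if family == "plateau":
        curve = np.full(length, 0.1 * amplitude)
        lo, hi = length // 4, length - length // 4
        curve[lo:hi] = amplitude
        return curve
    if family == "sharp-spike":
        sigma = max(length / 30.0, 1.0) * width_factor
        return amplitude * np.exp(-0.5 * ((pos - center - shift) / sigma) ** 2)
    raise ValueError(f"unknown family {family!r}")  # pragma: no cover


#: Length scale (nt) of the correlated component of coverage noise;
#: coverage depths at nearby positions share the same reads, so their
#: noise is autocorrelated on roughly the read-length scale.
NOISE_CORRELATION_SCALE = 8.0


def generate_profile(spec: ShapeSpec) -> tuple[np.ndarray, str]:
    """Integer depth vector for *spec* plus its true family label.

    The noise level drives three things: mild peak-to-peak variability of
    the family's shape parameters (see :func:`_jittered_curve`), and
    multiplicative log-normal position noise with unit mean and relative sd
    ``spec.noise`` whose log-variance is split half i.i.d. and half
    smoothly autocorrelated on the read-length scale — coverage noise in
    real data is correlated because neighboring positions share reads.
    Depths are rounded to non-negative integers, so they stay valid
    counts. At noise 0 the output is the deterministic family curve.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.noise > 0:
        curve = _jittered_curve(spec, rng)
        total_sd = np.sqrt(np.log1p(spec.noise**2))
        component_sd = total_sd / np.sqrt(2.0)
        iid = rng.normal(0.0, component_sd, spec.length)
        rough = rng.normal(0.0, 1.0, spec.length)
        smooth = gaussian_filter1d(rough, NOISE_CORRELATION_SCALE, mode="reflect")
        smooth *= component_sd / max(float(smooth.std()), 1e-12)
        curve = curve * np.exp(iid + smooth - 0.5 * total_sd**2)
    else:
        curve = expected_curve(spec.family, spec.length, spec.amplitude)
    depths = np.rint(curve).astype(np.int64)
    return np.maximum(depths, 0), spec.family


def profile_to_reads(
    target_depths,
    read_length: int,
    strand: str = "+",
    chrom: str = "chrS",
    offset: int = 0,
    name_prefix: str = "read",
) -> list[GenomicInterval]:
    """Reads whose stacked coverage realizes *target_depths* over the window.

    Greedy stack construction: sweeping 5'->3' in genomic order, at each
    position start exactly enough reads to raise the running coverage to the
    target. Where the target never falls faster than reads expire the
    achieved coverage equals the target exactly (always true for
    read_length 1); steep drops can leave the coverage above target.
    """
    if read_length < 1:
        raise ValueError("read_length must be >= 1")
    target = np.asarray(target_depths, dtype=np.int64)
    if np.any(target < 0):
        raise ValueError("target depths must be non-negative")
    n = target.size
    reads: list[GenomicInterval] = []
    expire = np.zeros(n + read_length + 1, dtype=np.int64)
    current = 0
    for j in range(n):
        current -= expire[j]
        need = int(target[j]) - current
        for _ in range(max(need, 0)):
            reads.append(
                GenomicInterval(
                    chrom,
                    offset + j,
                    offset + j + read_length,
                    f"{name_prefix}_{len(reads)}",
                    0,
                    strand,
                )
            )
        if need > 0:
            current += need
            expire[j + read_length] += need
    return reads


def write_reads_bam(
    reads: Sequence[GenomicInterval], sizes: ChromSizes, path
) -> Path:
    """Write reads as a coordinate-sorted, indexed BAM (with .bai)."""
    path = Path(path)
    chroms = list(sizes.keys())
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": name, "LN": int(sizes[name])} for name in chroms],
    }
    tid = {name: i for i, name in enumerate(chroms)}
    ordered = sorted(reads, key=lambda r: (tid[r.chrom], r.start))
    with pysam.AlignmentFile(str(path), "wb", header=header) as bam:
        for read in ordered:
            seg = pysam.AlignedSegment(bam.header)
            seg.query_name = read.name
            seg.reference_id = tid[read.chrom]
            seg.reference_start = read.start
            seg.mapping_quality = 60
            seg.cigartuples = [(0, read.length)]
            seg.query_sequence = "A" * read.length
            seg.flag = 16 if read.strand == "-" else 0
            bam.write(seg)
    pysam.index(str(path))
    return path


def split_pseudo_replicates(
    reads: Sequence[GenomicInterval],
    fraction: float = 0.5,
    with_replacement: bool = False,
    seed: int = 0,
) -> tuple[list[GenomicInterval], list[GenomicInterval]]:
    """Split a read set into two pseudo-replicates.

    Without replacement: a disjoint partition, the first part holding
    ``round(fraction * n)`` reads and the second the rest. With replacement:
    two independent samples of size ``round(fraction * n)`` each.
    """
    reads = list(reads)
    n = len(reads)
    if n < 2:
        raise ValueError("need at least 2 reads to split")
    if not (0 < fraction < 1):
        raise ValueError("fraction must lie in (0, 1)")
    m = round(fraction * n)
    rng = np.random.default_rng(seed)
    if with_replacement:
        idx_a = rng.integers(0, n, size=m)
        idx_b = rng.integers(0, n, size=m)
        return [reads[i] for i in idx_a], [reads[i] for i in idx_b]
    perm = rng.permutation(n)
    return [reads[i] for i in perm[:m]], [reads[i] for i in perm[m:]]


@dataclass
class SyntheticDataset:
    """File bundle for an end-to-end run plus the underlying ground truth."""

    peaks_bed: Path
    reads_bam: Path
    chrom_sizes: Path
    labels_tsv: Path
    peaks: list[GenomicInterval]
    reads: list[GenomicInterval]
    families: list[str]
    target_profiles: list[np.ndarray]


def make_dataset(
    outdir,
    families: Sequence[str] = CANONICAL_FAMILIES,
    n_per_family: int = 50,
    length: int = 77,
    amplitude: float = 100.0,
    noise: float = 0.05,
    read_length: int = 30,
    seed: int = 0,
    chrom: str = "chrS",
    alternate_strands: bool = True,
) -> SyntheticDataset:
    """Write a complete synthetic dataset: BED6 peaks, indexed BAM, sizes, labels.

    Peaks are laid out along one synthetic chromosome with generous spacing
    so read stacks never overlap between peaks; strands alternate to
    exercise strand-specific counting. The labels TSV maps each peak name to
    its true profile family.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spacing = length + 6 * read_length + 100
    margin = 2 * length + 200
    peaks: list[GenomicInterval] = []
    reads: list[GenomicInterval] = []
    labels: list[str] = []
    targets: list[np.ndarray] = []
    position = margin
    index = 0
    for family in families:
        for rep in range(n_per_family):
            spec = ShapeSpec(
                family=family,
                length=length,
                amplitude=amplitude,
                noise=noise,
                seed=seed * 1_000_003 + index,
            )
            depths, _ = generate_profile(spec)
            strand = "-" if (alternate_strands and index % 2) else "+"
            peak = GenomicInterval(
                chrom, position, position + length, f"peak_{index}", 0, strand
            )
            # target depths are in 5'->3' profile order; lay them out in
            # genomic order for the read stack
            genomic_target = depths[::-1] if strand == "-" else depths
            reads.extend(
                profile_to_reads(
                    genomic_target,
                    read_length,
                    strand=strand,
                    chrom=chrom,
                    offset=peak.start,
                    name_prefix=f"read_p{index}",
                )
            )
            peaks.append(peak)
            labels.append(family)
            targets.append(depths)
            position += spacing
            index += 1
    sizes = ChromSizes.from_mapping({chrom: position + margin})
    peaks_bed = outdir / "peaks.bed"
    reads_bam = outdir / "reads.bam"
    sizes_path = outdir / "chrom.sizes"
    labels_tsv = outdir / "labels.tsv"
    write_bed6(peaks, peaks_bed)
    write_reads_bam(reads, sizes, reads_bam)
    write_chrom_sizes(sizes, sizes_path)
    with open(labels_tsv, "w") as handle:
        handle.write("peak\tfamily\n")
        for peak, family in zip(peaks, labels):
            handle.write(f"{peak.name}\t{family}\n")
    return SyntheticDataset(
        peaks_bed=peaks_bed,
        reads_bam=reads_bam,
        chrom_sizes=sizes_path,
        labels_tsv=labels_tsv,
        peaks=peaks,
        reads=reads,
        families=labels,
        target_profiles=targets,
    )
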