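"""Reading and writing the standard genomic formats the tool touches.

Peaks come in as BED6, reads either as an indexed BAM or as a BED interval
list, chromosome sizes as a two-column UCSC-style table. Coverage is counted
per nucleotide over the full aligned span of each read; spliced alignments
contribute only through their aligned blocks.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam

from .core import ChromSizes, CoverageProfile, GenomicInterval, ShapeAssignment, PeakEvaluation

STRAND_MODES = ("same-strand", "ignore-strand")


class ParseError(ValueError):
    """Malformed line in a tabular genomic file."""


def read_bed6(path) -> list[GenomicInterval]:
    """Parse a BED6 file into a list of intervals, order preserved.

    Lines starting with ``#``, ``track`` or ``browser`` are skipped.
    Strand characters other than ``+``/``-`` are normalized to ``.``.
    """
    intervals: list[GenomicInterval] = []
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ParseError(
                    f"{path}: line {lineno}: expected >=6 tab-separated columns, "
                    f"got {len(fields)}"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            if start >= end:
                raise ParseError(
                    f"{path}: line {lineno}: start ({start}) >= end ({end})"
                )
            if start < 0:
                raise ParseError(f"{path}: line {lineno}: negative start ({start})")
            try:
                score = float(fields[4])
            except ValueError:
                score = 0.0
            strand = fields[5] if fields[5] in ("+", "-") else "."
            intervals.append(
                GenomicInterval(fields[0], start, end, fields[3], score, strand)
            )
    return intervals


def write_bed6(intervals: Iterable[GenomicInterval], path) -> None:
    with open(path, "w") as handle:
        for interval in intervals:
            handle.write(interval.to_bed6() + "\n")


def read_chrom_sizes(path) -> ChromSizes:
    """Parse a two-column (name, length) chromosome-sizes table."""
    sizes = ChromSizes()
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2:
                raise ParseError(
                    f"{path}: line {lineno}: expected two columns (name, length)"
                )
            name = fields[0]
            if name in sizes:
                raise ParseError(f"{path}: line {lineno}: duplicate chromosome {name!r}")
            try:
                length = int(fields[1])
            except ValueError as exc:
                raise ParseError(
                    f"{path}: line {lineno}: non-integer length {fields[1]!r}"
                ) from exc
            if length <= 0:
                raise ParseError(
                    f"{path}: line {lineno}: non-positive length {length} for {name!r}"
                )
            sizes[name] = length
    return sizes


def write_chrom_sizes(sizes: ChromSizes, path) -> None:
    with open(path, "w") as handle:
        for name, length in sizes.items():
            handle.write(f"{name}\t{length}\n")


def _strand_ok(read_strand: str, peak_strand: str, same_strand: bool) -> bool:
    if not same_strand or peak_strand == ".":
        return True
    return read_strand == peak_strand


def _orient(depths: np.ndarray, strand: str) -> np.ndarray:
    # minus-strand profiles are reported 5'->3', i.e. reversed genomic order
    return depths[::-1].copy() if strand == "-" else depths


def _coverage_from_intervals(
    reads: Sequence[GenomicInterval],
    peaks: Sequence[GenomicInterval],
    same_strand: bool,
) -> list[CoverageProfile]:
    read_chroms = {r.chrom for r in reads}
    profiles = []
    for peak in peaks:
        depths = np.zeros(peak.length, dtype=np.int64)
        if peak.chrom not in read_chroms:
            warnings.warn(
                f"peak {peak.name!r} on {peak.chrom!r}: no reads on this "
                "chromosome, profile is all zeros"
            )
        else:
            for read in reads:
                if read.chrom != peak.chrom:
                    continue
                if not _strand_ok(read.strand, peak.strand, same_strand):
                    continue
                lo = max(read.start, peak.start)
                hi = min(read.end, peak.end)
                if lo < hi:
                    depths[lo - peak.start : hi - peak.start] += 1
        profiles.append(CoverageProfile(peak, _orient(depths, peak.strand)))
    return profiles


def _coverage_from_bam(
    path, peaks: Sequence[GenomicInterval], same_strand: bool
) -> list[CoverageProfile]:
    profiles = []
    with pysam.AlignmentFile(str(path), "rb") as bam:
        if not bam.has_index():
            raise FileNotFoundError(
                f"{path}: no BAM index found; run `samtools index` first"
            )
        references = set(bam.references)
        for peak in peaks:
            depths = np.zeros(peak.length, dtype=np.int64)
            if peak.chrom not in references:
                warnings.warn(
                    f"peak {peak.name!r} on {peak.chrom!r}: chromosome absent "
                    "from BAM header, profile is all zeros"
                )
            else:
                for read in bam.fetch(peak.chrom, peak.start, peak.end):
                    if read.is_unmapped:
                        continue
                    read_strand = "-" if read.is_reverse else "+"
                    if not _strand_ok(read_strand, peak.strand, same_strand):
                        continue
                    for block_start, block_end in read.get_blocks():
                        lo = max(block_start, peak.start)
                        hi = min(block_end, peak.end)
                        if lo < hi:
                            depths[lo - peak.start : hi - peak.start] += 1
            profiles.append(CoverageProfile(peak, _orient(depths, peak.strand)))
    return profiles


def compute_coverage(
    reads_source,
    peaks: Sequence[GenomicInterval],
    strand_mode: str = "same-strand",
) -> list[CoverageProfile]:
    """Per-nucleotide read coverage of each peak.

    Parameters
    ----------
    reads_source
        Path to an indexed BAM, path to a BED file of read intervals, or a
        sequence of :class:`GenomicInterval` reads.
    peaks
        Peaks to profile; each gets one :class:`CoverageProfile` whose depth
        vector is oriented 5'->3' on the peak strand.
    strand_mode
        ``same-strand`` counts only reads on the peak's strand (peaks with
        strand ``.`` accept every read); ``ignore-strand`` counts all reads.
    """
    if strand_mode not in STRAND_MODES:
        raise ValueError(f"strand_mode must be one of {STRAND_MODES}")
    same_strand = strand_mode == "same-strand"
    if isinstance(reads_source, (str, Path)):
        path = Path(reads_source)
        if path.suffix.lower() == ".bam":
            return _coverage_from_bam(path, peaks, same_strand)
        return _coverage_from_intervals(read_bed6(path), peaks, same_strand)
    return _coverage_from_intervals(list(reads_source), peaks, same_strand)


RESULT_COLUMNS = [
    "chrom",
    "start",
    "end",
    "peak_id",
    "score",
    "strand",
    "original_start",
    "original_end",
    "cv",
    "cv_normalized",
    "label",
    "cluster",
    "sharp",
]


def result_table(
    peaks: Sequence[GenomicInterval],
    evaluations: Sequence[PeakEvaluation],
    assignments: Sequence[ShapeAssignment],
    original_peaks: Sequence[GenomicInterval] | None = None,
) -> pd.DataFrame:
    """Assemble the final peak table, sorted by CV from highest to lowest.

    Ties in CV keep the input order (stable sort). ``peak_id`` combines the
    original peak name with a running index so duplicate names stay unique.
    """
    if not (len(peaks) == len(evaluations) == len(assignments)):
        raise ValueError(
            "peaks, evaluations and assignments must have matching lengths "
            f"(got {len(peaks)}, {len(evaluations)}, {len(assignments)})"
        )
    originals = original_peaks if original_peaks is not None else peaks
    if len(originals) != len(peaks):
        raise ValueError("original_peaks length mismatch")
    rows = []
    for idx, (peak, orig, ev, asg) in enumerate(
        zip(peaks, originals, evaluations, assignments)
    ):
        rows.append(
            {
                "chrom": peak.chrom,
                "start": peak.start,
                "end": peak.end,
                "peak_id": f"{peak.name}_{idx}",
                "score": peak.score,
                "strand": peak.strand,
                "original_start": orig.start,
                "original_end": orig.end,
                "cv": ev.cv,
                "cv_normalized": ev.cv_normalized,
                "label": ev.label,
                "cluster": asg.cluster,
                "sharp": int(asg.is_sharp_peak),
            }
        )
    table = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    return table.sort_values("cv", ascending=False, kind="stable", ignore_index=True)


def write_result_table(
    peaks: Sequence[GenomicInterval],
    evaluations: Sequence[PeakEvaluation],
    assignments: Sequence[ShapeAssignment],
    path,
    original_peaks: Sequence[GenomicInterval] | None = None,
) -> pd.DataFrame:
    """Write the CV-sorted result table as TSV (with header); returns it."""
    table = result_table(peaks, evaluations, assignments, original_peaks)
    table.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return table
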