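"""End-to-end orchestration: prep -> coverage -> evaluation -> classification -> reports.

The stage order follows the tool's pipeline: optional peak re-centering on
the coverage signal, harmonization of all peaks to one length, per-nucleotide
coverage, negative-binomial CV scoring with optional border penalty and
normalization, shape clustering of the profiles, and finally the plots plus
the CV-sorted result table.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .classify import classify_profiles
from .core import CenteringConfig, ChromSizes, GenomicInterval
from .evaluate import evaluate_profiles
from .io import compute_coverage, read_bed6, read_chrom_sizes, write_result_table
from .prep import apply_shift, center_shift, harmonize_length, harmonized_target_length
from .reporting import plot_cluster_panels, plot_cv_distributions, plot_k_diagnostics

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Run parameters; defaults mirror the documented tool behavior."""

    peak_correction: bool = False
    max_translocate: bool = False  # summit-based centering instead of convolution
    peak_length: int | None = None  # None: max observed peak length
    strand_mode: str = "same-strand"
    border_penalty: bool = False
    scale_max: float | None = None
    threshold: float = 0.2
    threshold_basis: str = "normalized"
    sm: bool = False  # spline smoothing of profiles before clustering
    smoothing_factor: float = 1.0
    k_max: int = 15
    k_forced: int | None = None
    seed: int = 42

    def __post_init__(self) -> None:
        if self.k_forced is not None and self.k_forced > self.k_max:
            raise ValueError(
                f"k_forced ({self.k_forced}) exceeds the cluster upper bound "
                f"k_max ({self.k_max})"
            )


@dataclass
class PipelineResult:
    table: "object"  # pandas DataFrame
    peaks: list[GenomicInterval]
    original_peaks: list[GenomicInterval]
    evaluations: list
    assignments: list
    clustering: "object"
    table_path: Path | None = None
    plot_paths: list[Path] = field(default_factory=list)


def prepare_peaks(
    peaks: list[GenomicInterval],
    reads_source,
    sizes: ChromSizes,
    config: PipelineConfig,
) -> list[GenomicInterval]:
    """Re-center (optional) and length-harmonize a peak set."""
    target = harmonized_target_length(peaks, config.peak_length)
    if config.peak_correction:
        scheme = "summit" if config.max_translocate else "gaussian-convolution"
        centering = CenteringConfig(
            enabled=True,
            scheme=scheme,
            kernel_halfwidth=max(1, target // 2),
            search_flank=target,
        )
        centered = []
        for peak in peaks:
            size = sizes[peak.chrom]
            window_start = max(0, peak.start - centering.search_flank)
            window_end = min(size, peak.end + centering.search_flank)
            window = GenomicInterval(
                peak.chrom, window_start, window_end, peak.name, peak.score, peak.strand
            )
            profile = compute_coverage(reads_source, [window], config.strand_mode)[0]
            # index of the peak's midpoint inside the 5'->3' window profile
            if peak.strand == "-":
                center_index = (window_end - 1) - peak.midpoint
            else:
                center_index = peak.midpoint - window_start
            shift = center_shift(profile.depths, centering, center_index=center_index)
            centered.append(apply_shift(peak, shift, sizes))
        peaks = centered
    return harmonize_length(peaks, target, sizes)


def run_pipeline(
    peaks_bed,
    reads_source,
    chrom_sizes_path,
    outdir,
    config: PipelineConfig | None = None,
    write_outputs: bool = True,
    sample_name: str = "sample",
) -> PipelineResult:
    """Run the full pipeline and (optionally) write table, plots and manifest."""
    config = config or PipelineConfig()
    outdir = Path(outdir)
    original_peaks = read_bed6(peaks_bed)
    if not original_peaks:
        raise ValueError(f"{peaks_bed}: no peaks found")
    sizes = read_chrom_sizes(chrom_sizes_path)
    for peak in original_peaks:
        sizes.check(peak)

    peaks = prepare_peaks(original_peaks, reads_source, sizes, config)
    if len(peaks) != len(original_peaks):
        # harmonization may drop peaks on too-short contigs; keep originals aligned
        kept = {p.name for p in peaks}
        original_peaks = [p for p in original_peaks if p.name in kept]
    profiles = compute_coverage(reads_source, peaks, config.strand_mode)
    depth_vectors = [p.depths for p in profiles]

    evaluations = evaluate_profiles(
        depth_vectors,
        use_border_penalty=config.border_penalty,
        scale_max=config.scale_max,
        threshold=config.threshold,
        threshold_basis=config.threshold_basis,
    )
    cvs = [ev.cv for ev in evaluations]

    assignments, clustering, normalized, smoothed = classify_profiles(
        depth_vectors,
        smoothing=config.sm,
        smoothing_factor=config.smoothing_factor,
        k_max=min(config.k_max, len(peaks)),
        k_forced=config.k_forced,
        seed=config.seed,
        cvs=cvs,
    )

    result = PipelineResult(
        table=None,
        peaks=peaks,
        original_peaks=original_peaks,
        evaluations=evaluations,
        assignments=assignments,
        clustering=clustering,
    )

    if write_outputs:
        results_dir = outdir / "results"
        plots_dir = outdir / "plots"
        results_dir.mkdir(parents=True, exist_ok=True)
        table_path = results_dir / "final_table.tsv"
        result.table = write_result_table(
            peaks, evaluations, assignments, table_path, original_peaks=original_peaks
        )
        result.table_path = table_path
        result.plot_paths += plot_cv_distributions(
            {sample_name: cvs},
            {sample_name: [ev.cv_normalized for ev in evaluations]},
            plots_dir,
        )
        result.plot_paths += plot_cluster_panels(
            normalized, smoothed, clustering.labels, plots_dir
        )
        result.plot_paths += plot_k_diagnostics(
            clustering.wss_by_k or None,
            clustering.aic_by_k or None,
            clustering.k,
            np.asarray([a.embedding for a in assignments]),
            clustering.labels,
            plots_dir,
        )
        manifest = {
            "package": "peakshape",
            "version": __version__,
            "python": sys.version.split()[0],
            "parameters": asdict(config),
            "n_peaks": len(peaks),
            "harmonized_length": peaks[0].length if peaks else None,
            "selected_k": int(clustering.k),
            "outputs": {
                "final_table": str(table_path),
                "plots": [str(p) for p in result.plot_paths],
            },
        }
        with open(outdir / "run_manifest.json", "w") as handle:
            json.dump(manifest, handle, indent=2, sort_keys=True)
        logger.info("final table: %s", table_path)
    else:
        from .io import result_table as _table

        result.table = _table(peaks, evaluations, assignments, original_peaks)
    return result
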