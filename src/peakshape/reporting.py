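"""Plots and summary artifacts of a run.

All figures are static (PNG and PDF side by side) with minimal labeled
defaults: CV / normalized-CV distributions, the 2-D embedding colored by
cluster, per-cluster example / smoothed / average profile panels, and the
k-selection diagnostic (WSS and AIC curves with the chosen k marked).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

logger = logging.getLogger(__name__)


def _save(fig, outdir: Path, stem: str) -> list[Path]:
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for ext in ("png", "pdf"):
        path = outdir / f"{stem}.{ext}"
        fig.savefig(path, dpi=120, bbox_inches="tight")
        paths.append(path)
    plt.close(fig)
    logger.info("wrote %s.{png,pdf} to %s", stem, outdir)
    return paths


def plot_cv_distributions(
    cvs_by_sample: Mapping[str, Sequence[float]],
    cvs_normalized_by_sample: Mapping[str, Sequence[float]],
    outdir,
) -> list[Path]:
    """Histograms of raw and normalized CV, one overlay per sample."""
    outdir = Path(outdir)
    if not cvs_by_sample or any(len(v) == 0 for v in cvs_by_sample.values()):
        raise ValueError("need at least one CV value per sample")
    written = []
    for data, stem, xlabel in (
        (cvs_by_sample, "cv_distribution", "CV"),
        (cvs_normalized_by_sample, "cv_normalized_distribution", "normalized CV"),
    ):
        fig, ax = plt.subplots(figsize=(6, 4))
        for sample, values in data.items():
            values = np.asarray(values, dtype=float)
            bins = min(30, max(1, len(values)))
            ax.hist(values, bins=bins, alpha=0.55, label=f"{sample} (n={len(values)})")
        ax.set_xlabel(xlabel)
        ax.set_ylabel("number of peaks")
        ax.legend(frameon=False)
        written.extend(_save(fig, outdir, stem))
    return written


def plot_cluster_panels(
    raw_profiles: Sequence[np.ndarray],
    smoothed_profiles: Sequence[np.ndarray],
    labels: Sequence[int],
    outdir,
    n_examples: int = 4,
) -> list[Path]:
    """Per-cluster panel: example raw profiles, smoothed versions, mean profile.

    Cluster sizes are annotated in the panel title. If a cluster has fewer
    members than *n_examples*, all of them are drawn.
    """
    outdir = Path(outdir)
    labels = np.asarray(labels)
    if len(raw_profiles) != len(labels) or len(smoothed_profiles) != len(labels):
        raise ValueError("one label per profile required")
    written = []
    for cluster in np.unique(labels):
        members = np.flatnonzero(labels == cluster)
        if members.size == 0:  # guarded: k-means never emits empty clusters
            continue
        shown = members[: min(n_examples, members.size)]
        fig, axes = plt.subplots(1, 3, figsize=(12, 3.2), sharex=True)
        for i in shown:
            axes[0].plot(np.asarray(raw_profiles[i], dtype=float), alpha=0.7)
            axes[1].plot(np.asarray(smoothed_profiles[i], dtype=float), alpha=0.7)
        mean_profile = np.mean(
            [np.asarray(smoothed_profiles[i], dtype=float) for i in members], axis=0
        )
        axes[2].plot(mean_profile, color="black")
        axes[0].set_title("example profiles")
        axes[1].set_title("smoothed")
        axes[2].set_title("cluster average")
        for ax in axes:
            ax.set_xlabel("position in peak (nt)")
        axes[0].set_ylabel("normalized coverage")
        fig.suptitle(f"cluster {cluster}: {members.size} peaks")
        written.extend(_save(fig, outdir, f"cluster_{cluster}_profiles"))
    return written


def cluster_average_profiles(
    smoothed_profiles: Sequence[np.ndarray], labels: Sequence[int]
) -> dict[int, np.ndarray]:
    """Positionwise mean smoothed profile of each cluster."""
    labels = np.asarray(labels)
    return {
        int(c): np.mean(
            [np.asarray(smoothed_profiles[i], dtype=float)
             for i in np.flatnonzero(labels == c)],
            axis=0,
        )
        for c in np.unique(labels)
    }


def plot_k_diagnostics(
    wss_by_k: Mapping[int, float] | None,
    aic_by_k: Mapping[int, float] | None,
    chosen_k: int,
    embedding: np.ndarray,
    labels: Sequence[int],
    outdir,
) -> list[Path]:
    """k-means optimization curves and the 2-D embedding scatter.

    The WSS curve must be non-increasing in k (a k-means guarantee with
    enough initializations); a violation raises. When k was forced the
    optimization plot is skipped with a log note, but the embedding scatter
    is still produced.
    """
    outdir = Path(outdir)
    written = []
    if wss_by_k:
        ks = sorted(wss_by_k)
        wss = np.asarray([wss_by_k[k] for k in ks], dtype=float)
        if np.any(np.diff(wss) > 1e-8 * max(wss[0], 1.0)):
            raise ValueError("WSS curve is not non-increasing in k")
        fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 3.5))
        ax1.plot(ks, wss, marker="o")
        ax1.axvline(chosen_k, color="red", linestyle="--", label=f"chosen k={chosen_k}")
        ax1.set_xlabel("k")
        ax1.set_ylabel("total within-cluster SS")
        ax1.legend(frameon=False)
        if aic_by_k:
            aic = [aic_by_k[k] for k in ks]
            ax2.plot(ks, aic, marker="o", color="darkorange")
            ax2.axvline(chosen_k, color="red", linestyle="--")
            ax2.set_xlabel("k")
            ax2.set_ylabel("AIC")
        written.extend(_save(fig, outdir, "kmeans_optimization"))
    else:
        logger.info("k was forced; skipping the k-means optimization plot")
    embedding = np.asarray(embedding, dtype=float)
    labels = np.asarray(labels)
    fig, ax = plt.subplots(figsize=(5, 4.5))
    scatter = ax.scatter(
        embedding[:, 0], embedding[:, 1], c=labels, cmap="tab10", s=14
    )
    ax.set_xlabel("UMAP 1")
    ax.set_ylabel("UMAP 2")
    ax.set_title(f"2-D embedding, {len(np.unique(labels))} clusters")
    fig.colorbar(scatter, ax=ax, label="cluster")
    written.extend(_save(fig, outdir, "umap_embedding"))
    return written
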