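"""Report figures: per-subject curve grid, metric scatter, regression grid."""

from __future__ import annotations

import math
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .errors import InputError
from .metrics import METRIC_NAMES, split_summary
from .stats import COVARIATE_NAMES

_BAND_COLORS = {"p<.05": "#d7301f", ".05<=p<.1": "#fdae61", "p>=.1": "#f0f0f0"}


def plot_curve_grid(curves: dict, path) -> Path:
    """One panel per subject: normalized lymphatic signal versus time."""
    if not curves:
        raise InputError("no curves to plot")
    n = len(curves)
    ncol = math.ceil(math.sqrt(n))
    nrow = math.ceil(n / ncol)
    fig, axes = plt.subplots(nrow, ncol, figsize=(2.4 * ncol, 1.8 * nrow), squeeze=False)
    for ax, (sid, curve) in zip(axes.ravel(), sorted(curves.items())):
        ax.plot(curve.times, curve.signal, "o-", ms=3, lw=1)
        ax.set_title(sid, fontsize=7)
        ax.tick_params(labelsize=6)
    for ax in axes.ravel()[n:]:
        ax.axis("off")
    fig.supxlabel("time (min)")
    fig.supylabel("S_lymph / brain median")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return Path(path)


def plot_metric_scatter(metrics, records, path) -> Path:
    """Per-subject metric values, colored by MS phenotype."""
    per_subject, _ = split_summary(metrics)
    if per_subject.empty:
        raise InputError("empty metrics table")
    phenotype = {r.subject_id: r.covariates.phenotype for r in records}
    colors = {"RRMS": "#1f77b4", "SPMS": "#d62728"}
    fig, axes = plt.subplots(1, len(METRIC_NAMES), figsize=(3 * len(METRIC_NAMES), 3))
    for ax, metric in zip(np.atleast_1d(axes), METRIC_NAMES):
        for i, (sid, row) in enumerate(per_subject.iterrows()):
            ax.scatter(
                i, row[metric], s=18,
                color=colors.get(phenotype.get(sid, "RRMS"), "gray"),
            )
        ax.set_title(metric)
        ax.set_xlabel("subject")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return Path(path)


def plot_stats_grid(grid, path) -> Path:
    """Metric x covariate panel matrix colored by p-value band."""
    if grid.empty:
        raise InputError("empty stats grid")
    nrow, ncol = len(METRIC_NAMES), len(COVARIATE_NAMES)
    fig, axes = plt.subplots(nrow, ncol, figsize=(2.2 * ncol, 1.8 * nrow), squeeze=False)
    by_cell = grid.set_index(["metric", "covariate"])
    for i, metric in enumerate(METRIC_NAMES):
        for j, cov in enumerate(COVARIATE_NAMES):
            ax = axes[i][j]
            row = by_cell.loc[(metric, cov)]
            ax.set_facecolor(_BAND_COLORS.get(row["band"], "white"))
            ax.text(
                0.5, 0.5, f"r={row['r']:+.2f}\np={row['p']:.3f}\nn={int(row['n'])}",
                ha="center", va="center", fontsize=7, transform=ax.transAxes,
            )
            ax.set_xticks([])
            ax.set_yticks([])
            if i == 0:
                ax.set_title(cov, fontsize=8)
            if j == 0:
                ax.set_ylabel(metric, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return Path(path)


def plot_outputs(bundle, out_dir) -> list[Path]:
    """Write the three report figures for a completed pipeline bundle."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    return [
        plot_curve_grid(bundle.curves, out / "curves_grid.png"),
        plot_metric_scatter(bundle.metrics, bundle.records, out / "metric_scatter.png"),
        plot_stats_grid(bundle.grid, out / "stats_grid.png"),
    ]
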