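"""Parameter-recovery experiments over replicate synthetic cohorts.

These drivers reproduce the study's cohort statistics from scratch: the
generator is calibrated against the published cohort targets at curve
level, replicate cohorts are simulated, and the full measurement chain
(render -> ROI extraction -> curve metrics -> regression grid) is applied
exactly as it would be to patient data.  Grand means over replicates are
the recovered statistics.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

from .calibrate import default_cohort_config
from .metrics import METRIC_NAMES, compute_metrics, metrics_table, split_summary
from .phantom import build_default_geometry
from .pipeline import simulate_curve_cohort, simulate_image_cohort
from .roi import extract_curve, place_roi
from .stats import correlate


def image_pipeline_grand_means(
    seeds: Sequence[int],
    n_subjects: int = 20,
    noise_sigma: float = 0.02,
    grid: tuple[int, int, int] = (10, 256, 256),
) -> dict[str, float]:
    """Grand means of the five dynamic metrics over full image-pipeline
    replicate cohorts (render at default noise, extract, measure).

    Subjects with an undefined washout are excluded from the washout mean,
    mirroring the cohort summary convention.
    """
    geometry = build_default_geometry(grid)
    values: dict[str, list[float]] = {name: [] for name in METRIC_NAMES}
    for seed in seeds:
        config = default_cohort_config(
            n_subjects=n_subjects, seed=int(seed), noise_sigma=noise_sigma
        )
        for _, series in simulate_image_cohort(config, geometry):
            roi = place_roi(series.roi_seed, image_shape=series.data.shape[1:])
            m = compute_metrics(extract_curve(series, roi))
            for name in METRIC_NAMES:
                values[name].append(getattr(m, name))
    out = {name: float(np.nanmean(values[name])) for name in METRIC_NAMES}
    out["n_subjects_total"] = len(values["p_enh"])
    return out


def curve_replicate_correlations(
    seeds: Sequence[int],
    n_subjects: int = 20,
    metrics: Iterable[str] = ("auc", "p_enh", "wash_in"),
) -> dict[str, float]:
    """Mean fitted Pearson r between BPF and selected metrics, plus the mean
    peak-to-last signal drop, over noiseless curve-level replicate cohorts.
    """
    metrics = tuple(metrics)
    rs: dict[str, list[float]] = {name: [] for name in metrics}
    drops: list[float] = []
    for seed in seeds:
        config = default_cohort_config(n_subjects=n_subjects, seed=int(seed))
        records, curves = simulate_curve_cohort(config)
        bpf = np.array([r.covariates.bpf for r in records])
        per_metric = {name: [] for name in metrics}
        for record in records:
            curve = curves[record.subject_id]
            m = compute_metrics(curve)
            for name in metrics:
                per_metric[name].append(getattr(m, name))
            s = curve.signal
            drops.append(100.0 * (s.max() - s[-1]) / s.max())
        for name in metrics:
            rs[name].append(correlate(per_metric[name], bpf).r)
    out = {f"r_bpf_{name}": float(np.mean(rs[name])) for name in metrics}
    out["drop_pct"] = float(np.mean(drops))
    out["n_cohorts"] = len(seeds)
    return out


def null_false_positive_rate(
    seeds: Sequence[int],
    n_subjects: int = 20,
    alpha: float = 0.05,
) -> dict[str, float]:
    """Fraction of regression cells significant at ``alpha`` when the BPF
    coupling is switched off (covariates independent of kinetics).

    Every metric x covariate cell of every replicate contributes one test;
    under the null the rate should sit at ``alpha``.
    """
    from dataclasses import replace

    from .io import cohort_to_frame
    from .stats import stats_grid

    n_sig = 0
    n_tests = 0
    for seed in seeds:
        config = replace(default_cohort_config(n_subjects=n_subjects, seed=int(seed)),
                         bpf_coupling=0.0)
        records, curves = simulate_curve_cohort(config)
        per, _ = split_summary(metrics_table(curves))
        grid = stats_grid(per, cohort_to_frame(records))
        n_sig += int((grid["p"] < alpha).sum())
        n_tests += len(grid)
    return {"false_positive_rate": n_sig / n_tests, "n_tests": n_tests}
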