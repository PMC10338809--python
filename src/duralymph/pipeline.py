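"""End-to-end orchestration: simulate -> extract -> metrics -> stats.

The pipeline is deterministic given its seed: the cohort draw, per-subject
acquisition-timing jitter and rendering noise all derive from independent
substreams of the one configured seed, and every artifact is accompanied by
a provenance block (package version, seed, configuration hash) so a run can
be reproduced bit-exactly from its outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .calibrate import default_cohort_config
from .cohort import CohortConfig, Moments, SubjectRecord, sample_cohort, subject_rngs
from .errors import ConfigurationError, InputError, StageError
from .io import cohort_to_frame, read_series, write_curve_csv, write_series
from .kinetics import true_curve
from .metrics import metrics_table, split_summary
from .phantom import DynamicSeries, PhantomGeometry, build_default_geometry, render_series
from .roi import DEFAULT_ROI_HEIGHT, DEFAULT_ROI_WIDTH, TimeIntensityCurve, extract_curve, place_roi
from .stats import stats_grid

log = logging.getLogger("duralymph")


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of one full pipeline run."""

    cohort: CohortConfig
    roi_height: int = DEFAULT_ROI_HEIGHT
    roi_width: int = DEFAULT_ROI_WIDTH
    grid: tuple[int, int, int] = (10, 256, 256)  # phantom (slices, rows, cols)
    bh_correction: bool = False
    write_images: bool = False
    make_plots: bool = False
    series_dir: str | None = None  # ingest an existing series tree instead of simulating
    log_level: str = "INFO"

    @property
    def seed(self) -> int:
        return self.cohort.seed

    def to_dict(self) -> dict:
        d = {
            "seed": self.cohort.seed,
            "n_subjects": self.cohort.n_subjects,
            "noise_sigma": self.cohort.noise_sigma,
            "render_mode": self.cohort.render_mode,
            "bpf_coupling": self.cohort.bpf_coupling,
            "kinetic_moments": {
                k: {f: getattr(m, f) for f in ("mean", "sd", "lo", "hi", "log")}
                for k, m in self.cohort.kinetic_moments.items()
            },
            "roi": {"height": self.roi_height, "width": self.roi_width},
            "grid": list(self.grid),
            "stats": {"bh_correction": self.bh_correction},
            "output": {"write_images": self.write_images, "make_plots": self.make_plots},
            "series_dir": self.series_dir,
            "log_level": self.log_level,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d or {})
        seed = int(d.get("seed", 0))
        n = int(d.get("n_subjects", 20))
        noise = float(d.get("noise_sigma", 0.02))
        mode = str(d.get("render_mode", "direct"))
        if "kinetic_moments" in d:
            kin = {
                k: Moments(**{f: v[f] for f in ("mean", "sd", "lo", "hi") if f in v},
                           log=v.get("log", False))
                for k, v in d["kinetic_moments"].items()
            }
            cohort = CohortConfig(
                n_subjects=n,
                kinetic_moments=kin,
                bpf_coupling=float(d.get("bpf_coupling", 0.0)),
                noise_sigma=noise,
                render_mode=mode,
                seed=seed,
            )
        else:
            cohort = default_cohort_config(
                n_subjects=n, seed=seed, noise_sigma=noise, render_mode=mode
            )
        roi = d.get("roi", {})
        return cls(
            cohort=cohort,
            roi_height=int(roi.get("height", DEFAULT_ROI_HEIGHT)),
            roi_width=int(roi.get("width", DEFAULT_ROI_WIDTH)),
            grid=tuple(d.get("grid", (10, 256, 256))),
            bh_correction=bool(d.get("stats", {}).get("bh_correction", False)),
            write_images=bool(d.get("output", {}).get("write_images", False)),
            make_plots=bool(d.get("output", {}).get("make_plots", False)),
            series_dir=d.get("series_dir"),
            log_level=str(d.get("log_level", "INFO")),
        )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


@dataclass
class ReportBundle:
    """Everything one pipeline run produced, in memory."""

    records: list[SubjectRecord]
    curves: dict[str, TimeIntensityCurve]
    metrics: pd.DataFrame
    grid: pd.DataFrame
    provenance: dict = field(default_factory=dict)


def simulate_curve_cohort(
    config: CohortConfig,
) -> tuple[list[SubjectRecord], dict[str, TimeIntensityCurve]]:
    """Noiseless curve-level cohort: true curves sampled at each subject's
    realized (jittered) acquisition times.  No image rendering."""
    records = sample_cohort(config)
    curves = {}
    for record, rng in zip(records, subject_rngs(config)):
        times = config.schedule.realize(rng)
        curves[record.subject_id] = TimeIntensityCurve(
            times=times, signal=true_curve(record.truth, times)
        )
    return records, curves


def simulate_image_cohort(
    config: CohortConfig, geometry: PhantomGeometry | None = None
) -> Iterator[tuple[SubjectRecord, DynamicSeries]]:
    """Yield rendered dynamic series subject by subject (memory-friendly)."""
    geometry = geometry or build_default_geometry()
    records = sample_cohort(config)
    for record, rng in zip(records, subject_rngs(config)):
        times = config.schedule.realize(rng)
        yield record, render_series(record, times, geometry, config, rng)


def _extract_from_series(series: DynamicSeries, config: PipelineConfig) -> TimeIntensityCurve:
    roi = place_roi(
        series.roi_seed, config.roi_height, config.roi_width, series.data.shape[1:]
    )
    return extract_curve(series, roi)


def run_full(config: PipelineConfig, out_dir) -> ReportBundle:
    """Run simulate (or ingest) -> extract -> metrics -> stats and write the
    report bundle (curves, metric table, stats grid, provenance) to disk."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))

    t0 = time.perf_counter()
    curves: dict[str, TimeIntensityCurve] = {}
    if config.series_dir is not None:
        stage = "extract"
        try:
            bases = sorted(
                p.with_name(p.name.replace("_sidecar.json", ""))
                for p in Path(config.series_dir).glob("*_sidecar.json")
            )
            if not bases:
                raise InputError(f"no series found under {config.series_dir}")
            records: list[SubjectRecord] = []
            for base in bases:
                series = read_series(base)
                curves[series.subject_id] = _extract_from_series(series, config)
        except Exception as exc:
            raise StageError(stage, str(exc)) from exc
        covariates = None
    else:
        stage = "simulate+extract"
        try:
            records = sample_cohort(config.cohort)
            geometry = build_default_geometry(config.grid)
            for record, rng in zip(records, subject_rngs(config.cohort)):
                times = config.cohort.schedule.realize(rng)
                series = render_series(record, times, geometry, config.cohort, rng)
                curves[record.subject_id] = _extract_from_series(series, config)
                if config.write_images:
                    write_series(series, out / "images" / record.subject_id)
        except Exception as exc:
            raise StageError(stage, str(exc)) from exc
        covariates = cohort_to_frame(records)
    log.info("simulate/extract: %d subjects in %.1f s", len(curves), time.perf_counter() - t0)

    try:
        table = metrics_table(curves)
    except Exception as exc:
        raise StageError("metrics", str(exc)) from exc

    try:
        if covariates is None:
            raise InputError("no covariate table available for the stats stage")
        per_subject, _ = split_summary(table)
        grid = stats_grid(per_subject, covariates, bh_correction=config.bh_correction)
    except Exception as exc:
        raise StageError("stats", str(exc)) from exc

    provenance = {
        "package": "duralymph",
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": config.to_dict(),
        "n_subjects": len(records),
    }
    curves_dir = out / "curves"
    for sid, curve in curves.items():
        write_curve_csv(curve, curves_dir / f"{sid}_curve.csv")
    table.to_csv(out / "metrics.csv")
    grid.to_csv(out / "stats_grid.csv", index=False)
    if covariates is not None:
        covariates.to_csv(out / "cohort.csv", index=False)
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2, sort_keys=True))

    bundle = ReportBundle(
        records=records, curves=curves, metrics=table, grid=grid, provenance=provenance
    )
    if config.make_plots:
        from .plotting import plot_outputs

        plot_outputs(bundle, out / "figures")
    log.info("full pipeline done in %.1f s", time.perf_counter() - t0)
    return bundle
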