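"""Semi-quantitative dynamic enhancement metrics of a time-intensity curve.

Five parameters summarize the lymphatic curve: peak enhancement
P_enh = 100 * (S_max - S_0)/S_0 (percent), time to peak T_max (earliest
acquisition achieving the maximum), baseline-subtracted trapezoidal AUC over
[0, T_last] (minutes, normalized units), wash-in slope (S_1 - S_0)/(T_1 - T_0)
and washout slope (S_max - S_last)/(T_last - T_max) (both min^-1).  The
washout slope is undefined (not zero) when the peak falls on the last
acquisition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ComputationError, InputError
from .roi import TimeIntensityCurve

METRIC_NAMES = ("p_enh", "t_max", "auc", "wash_in", "washout")


@dataclass(frozen=True)
class DynamicParams:
    """The five dynamic enhancement parameters of one curve."""

    p_enh: float
    t_max: float
    auc: float
    wash_in: float
    washout: float
    valid_washout: bool

    def as_dict(self) -> dict[str, float]:
        d = {name: getattr(self, name) for name in METRIC_NAMES}
        if not self.valid_washout:
            d["washout"] = np.nan
        return d


def metrics_arrays(times: np.ndarray, signal: np.ndarray) -> dict[str, np.ndarray]:
    """Vectorized metric computation for a stack of curves.

    ``signal`` has shape (n_subjects, n_times) sampled on a shared ``times``
    grid.  Invalid washouts (peak at the last acquisition) are NaN.  Also
    returns ``drop_pct`` = 100 * (S_max - S_last)/S_max, the percentage
    signal loss from peak to the end of the acquisition window.
    """
    t = np.asarray(times, float)
    s = np.atleast_2d(np.asarray(signal, float))
    n, m = s.shape
    if m != t.size or m < 3:
        raise InputError("need signal sampled on >= 3 shared time points")
    s0 = s[:, 0]
    if np.any(s0 <= 0):
        raise ComputationError("S_0 must be positive for enhancement metrics")
    imax = s.argmax(axis=1)  # argmax returns the earliest maximum
    smax = s[np.arange(n), imax]
    slast = s[:, -1]
    tmax = t[imax]
    # washout is undefined when the peak falls on the last acquisition or
    # the curve never rises above baseline (no peak to wash out)
    span = t[-1] - tmax
    defined = (imax < m - 1) & (smax > s0)
    washout = np.where(defined, (smax - slast) / np.where(span > 0, span, 1.0), np.nan)
    return {
        "p_enh": 100.0 * (smax - s0) / s0,
        "t_max": tmax,
        "auc": np.trapezoid(s - s0[:, None], t, axis=1),
        "wash_in": (s[:, 1] - s0) / (t[1] - t[0]),
        "washout": washout,
        "drop_pct": 100.0 * (smax - slast) / smax,
    }


def compute_metrics(curve: TimeIntensityCurve) -> DynamicParams:
    """Compute the five dynamic parameters of one curve (>= 3 points)."""
    if curve.times.size < 3:
        raise InputError("need at least 3 time points for dynamic metrics")
    out = metrics_arrays(curve.times, curve.signal[None, :])
    valid = bool(np.isfinite(out["washout"][0]))
    return DynamicParams(
        p_enh=float(out["p_enh"][0]),
        t_max=float(out["t_max"][0]),
        auc=float(out["auc"][0]),
        wash_in=float(out["wash_in"][0]),
        washout=float(out["washout"][0]) if valid else np.nan,
        valid_washout=valid,
    )


def metrics_table(
    curves: dict[str, TimeIntensityCurve] | list[TimeIntensityCurve],
) -> pd.DataFrame:
    """Per-subject metric table with cohort summary rows.

    Rows are indexed by subject id; three summary rows (``mean``, ``sd``,
    ``n``) are appended.  Subjects with an undefined washout are excluded
    from the washout summary, and the ``n`` row reports how many subjects
    each column's summary used.
    """
    if isinstance(curves, dict):
        items = list(curves.items())
    else:
        items = [(f"sub-{i + 1:03d}", c) for i, c in enumerate(curves)]
    if not items:
        raise InputError("metrics_table needs at least one curve")
    rows = {sid: compute_metrics(curve).as_dict() for sid, curve in items}
    df = pd.DataFrame.from_dict(rows, orient="index")[list(METRIC_NAMES)]
    df.index.name = "subject_id"
    summary = pd.DataFrame(
        {
            "mean": df.mean(skipna=True),
            "sd": df.std(ddof=1, skipna=True),
            "n": df.notna().sum(),
        }
    ).T
    summary.index.name = "subject_id"
    return pd.concat([df, summary])


def split_summary(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a :func:`metrics_table` result into subject rows and summary."""
    is_summary = table.index.isin(["mean", "sd", "n"])
    return table.loc[~is_summary], table.loc[is_summary]
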