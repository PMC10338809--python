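"""Ground-truth enhancement kinetics of the dural lymphatic vessel.

The lymphatic time-intensity curve is modeled as a piecewise-linear
trajectory in normalized signal units (fractions of the precontrast brain
median): baseline ``s0_lymph`` at t = 0, a linear rise to the peak
``s0_lymph * (1 + e_peak)`` at ``tau_peak`` minutes, then a linear decay at
rate ``s0_lymph * w_decay`` per minute.  The piecewise-linear form is chosen
so that every semi-quantitative curve metric (peak enhancement, time to
peak, wash-in/washout slope, AUC) has a closed-form ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, InputError


@dataclass(frozen=True)
class KineticTruth:
    """True kinetic parameters of one subject's lymphatic curve.

    Attributes
    ----------
    s0_lymph
        Precontrast lymphatic signal as a fraction of the brain median (> 0).
    e_peak
        True fractional peak enhancement (S_max - S_0)/S_0, >= 0.
    tau_peak
        True continuous time to peak, minutes, > 0.
    w_decay
        True linear washout rate in fractional-enhancement units per minute,
        >= 0.  Generation guarantees the signal never decays below baseline
        within the acquisition window.
    """

    s0_lymph: float
    e_peak: float
    tau_peak: float
    w_decay: float

    def __post_init__(self):
        if not self.s0_lymph > 0:
            raise ConfigurationError("s0_lymph must be > 0")
        if self.e_peak < 0:
            raise ConfigurationError("e_peak must be >= 0")
        if not self.tau_peak > 0:
            raise ConfigurationError("tau_peak must be > 0")
        if self.w_decay < 0:
            raise ConfigurationError("w_decay must be >= 0")

    def check_window(self, t_last: float) -> None:
        """Assert the signal stays above baseline through ``t_last``."""
        if self.tau_peak < t_last:
            if self.w_decay * (t_last - self.tau_peak) >= self.e_peak and self.e_peak > 0:
                raise ConfigurationError(
                    "w_decay would drive the signal below baseline within the window"
                )


def curve_values(
    s0: np.ndarray,
    e_peak: np.ndarray,
    tau_peak: np.ndarray,
    w_decay: np.ndarray,
    times: np.ndarray,
) -> np.ndarray:
    """Vectorized piecewise-linear curve evaluation.

    Parameters are 1-D arrays of length n (or scalars); ``times`` is a 1-D
    grid of length m.  Returns an (n, m) signal matrix.
    """
    s0 = np.atleast_1d(np.asarray(s0, float))[:, None]
    e = np.atleast_1d(np.asarray(e_peak, float))[:, None]
    tau = np.atleast_1d(np.asarray(tau_peak, float))[:, None]
    w = np.atleast_1d(np.asarray(w_decay, float))[:, None]
    t = np.asarray(times, float)[None, :]
    rising = s0 * (1.0 + e * t / tau)
    decaying = s0 * (1.0 + e) - s0 * w * (t - tau)
    return np.where(t <= tau, rising, decaying)


def true_curve(truth: KineticTruth, times) -> np.ndarray:
    """Evaluate one subject's noiseless curve at the given times (minutes).

    ``times`` must be sorted ascending with times[0] == 0 (the precontrast
    acquisition defines S_0).
    """
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or t.size == 0:
        raise InputError("times must be a non-empty 1-D sequence")
    if t[0] != 0:
        raise InputError("times must start at 0 (precontrast)")
    if np.any(np.diff(t) <= 0):
        raise InputError("times must be strictly increasing")
    return curve_values(truth.s0_lymph, truth.e_peak, truth.tau_peak, truth.w_decay, t)[0]


def continuous_metrics(truth: KineticTruth, t_last: float) -> dict[str, float]:
    """Closed-form curve metrics of the continuous (densely sampled) truth.

    These are the limits the sampled-grid metrics approach as the grid is
    refined; used as an independent oracle in tests.
    """
    s0, e, tau, w = truth.s0_lymph, truth.e_peak, truth.tau_peak, truth.w_decay
    tau_eff = min(tau, t_last)
    # Peak over [0, t_last]; if the rise outlasts the window the peak is at t_last.
    if tau >= t_last:
        e_eff = e * t_last / tau
        auc = s0 * e_eff * t_last / 2.0
        washout = np.nan
    else:
        e_eff = e
        auc = s0 * (e * tau / 2.0 + e * (t_last - tau) - w * (t_last - tau) ** 2 / 2.0)
        washout = s0 * w
    return {
        "p_enh": 100.0 * e_eff,
        "t_max": tau_eff,
        "auc": auc,
        "wash_in": s0 * e / tau if tau > 0 else np.nan,
        "washout": washout,
    }
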