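"""Dynamic FLAIR acquisition schedule: one precontrast scan plus seven
postcontrast scans at nominal delays, with per-acquisition timing jitter.

Times are minutes after contrast injection; the precontrast scan is pinned
at t = 0.  Realized schedules draw independent Gaussian jitter per
acquisition and are redrawn wholesale if the jittered delays are not
strictly increasing (patient-compliance drift never reorders scans).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, GenerationError

#: Nominal postcontrast delays of the dynamic protocol (minutes).
NOMINAL_DELAYS = (2.5, 5.0, 7.0, 9.0, 17.0, 20.0, 35.0)

#: Per-acquisition timing jitter SDs (minutes): ~1 min during the densely
#: sampled wash-in period, ~2.2 min for the sparse late acquisitions.
DEFAULT_JITTER_SD = (1.0, 1.0, 1.0, 1.0, 2.2, 2.2, 2.2)


@dataclass(frozen=True)
class AcquisitionSchedule:
    """Nominal acquisition timing and its jitter model.

    Parameters
    ----------
    nominal_delays
        Strictly increasing postcontrast delays in minutes, all > 0.
    jitter_sd
        Per-acquisition Gaussian SD of the realized delay (minutes).
    t0
        Precontrast acquisition time, fixed at 0 by convention.
    """

    nominal_delays: tuple[float, ...] = NOMINAL_DELAYS
    jitter_sd: tuple[float, ...] = DEFAULT_JITTER_SD
    t0: float = 0.0

    def __post_init__(self):
        delays = np.asarray(self.nominal_delays, dtype=float)
        sds = np.asarray(self.jitter_sd, dtype=float)
        if delays.ndim != 1 or delays.size == 0:
            raise ConfigurationError("nominal_delays must be a non-empty 1-D sequence")
        if sds.shape != delays.shape:
            raise ConfigurationError("jitter_sd must match nominal_delays in length")
        if np.any(delays <= self.t0):
            raise ConfigurationError("all postcontrast delays must exceed t0")
        if np.any(np.diff(delays) <= 0):
            raise ConfigurationError("nominal delays must be strictly increasing")
        if np.any(sds < 0):
            raise ConfigurationError("jitter SDs must be nonnegative")

    @property
    def n_acquisitions(self) -> int:
        """Total number of volumes (precontrast + postcontrast)."""
        return 1 + len(self.nominal_delays)

    @property
    def nominal_times(self) -> np.ndarray:
        """Full nominal time grid [t0, delays...] in minutes."""
        return np.concatenate(([self.t0], np.asarray(self.nominal_delays, float)))

    @property
    def t_last(self) -> float:
        return float(self.nominal_delays[-1])

    def realize(self, rng: np.random.Generator, max_tries: int = 100) -> np.ndarray:
        """Draw one realized time grid: t0 plus jittered delays.

        Jitter is zero-mean Gaussian per acquisition; the draw is repeated
        until the realized delays are strictly increasing and all > t0.
        """
        delays = np.asarray(self.nominal_delays, float)
        sds = np.asarray(self.jitter_sd, float)
        for _ in range(max_tries):
            realized = delays + rng.normal(0.0, sds)
            if realized[0] > self.t0 and np.all(np.diff(realized) > 0):
                return np.concatenate(([self.t0], realized))
        raise GenerationError(
            f"could not realize a strictly increasing schedule in {max_tries} tries"
        )


#: The study's default 8-point protocol.
DEFAULT_SCHEDULE = AcquisitionSchedule()
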