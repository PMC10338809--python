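"""Synthetic MS cohort generation: clinical covariates and ground-truth
lymphatic kinetics with a configurable BPF-enhancement coupling.

Covariates are drawn from truncated normals (log-normal for the T2 lesion
load, whose cohort distribution is heavily right-skewed) with moments taken
from the study-population characteristics.  The fractional peak enhancement
``e_peak`` is the single kinetically coupled quantity: it is a linear
function of centered BPF plus independent Gaussian noise, so that lower
brain parenchymal fraction (more atrophy) implies stronger lymphatic
enhancement; AUC and wash-in inherit their correlations structurally
through the curve shape.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .errors import ConfigurationError, GenerationError
from .kinetics import KineticTruth
from .schedule import DEFAULT_SCHEDULE, AcquisitionSchedule

PHENOTYPES = ("RRMS", "SPMS")

#: Fraction of relapsing-remitting subjects in the study population (13/20).
RRMS_FRACTION = 0.65

#: Lowest admissible fractional peak enhancement; keeps S_0 meaningful and
#: the washout-feasibility constraint satisfiable.
E_PEAK_FLOOR = 0.02

#: Safety margin (minutes) beyond the nominal last delay when enforcing the
#: never-below-baseline constraint, absorbing late-acquisition jitter.
WINDOW_MARGIN_MIN = 6.0


@dataclass(frozen=True)
class Moments:
    """Mean/SD/bounds of one truncated-normal covariate or kinetic field.

    With ``log=True`` the normal lives in log space (mean and sd are the
    log-scale parameters) and bounds apply on the natural scale.
    """

    mean: float
    sd: float
    lo: float
    hi: float
    log: bool = False

    def __post_init__(self):
        if self.sd < 0:
            raise ConfigurationError("SD must be nonnegative")
        if self.lo >= self.hi:
            raise ConfigurationError(f"invalid bounds: lo={self.lo} >= hi={self.hi}")

    def truncated_sd(self) -> float:
        """Realized SD of the truncated draw (natural scale, log excluded)."""
        if self.log:
            raise ConfigurationError("truncated_sd is defined for linear moments only")
        if self.sd == 0:
            return 0.0
        a = (self.lo - self.mean) / self.sd
        b = (self.hi - self.mean) / self.sd
        return float(stats.truncnorm.std(a, b, loc=self.mean, scale=self.sd))


#: Study-population covariate moments (age/BMI/duration as mean [range] with
#: SD = range/4; EDSS rounded to 0.5 steps; lesion load log-normal matched to
#: median and range; BPF as mean with range bounds).
STUDY_COVARIATE_MOMENTS: dict[str, Moments] = {
    "age": Moments(46.4, (65 - 27) / 4, 27.0, 65.0),
    "bmi": Moments(25.9, (35.9 - 17.1) / 4, 17.1, 35.9),
    "disease_duration": Moments(13.6, (38.0 - 2.1) / 4, 2.1, 38.0),
    "edss": Moments(2.0, 1.625, 0.0, 6.5),
    "t2lv": Moments(np.log(3.9), (np.log(75.1) - np.log(0.43)) / 4, 0.43, 75.1, log=True),
    "bpf": Moments(0.81, (0.92 - 0.67) / 4, 0.67, 0.92),
}


@dataclass(frozen=True)
class SubjectCovariates:
    """Clinical covariates of one (synthetic) subject."""

    age: float
    bmi: float
    disease_duration: float
    edss: float
    t2lv: float
    bpf: float
    phenotype: str

    def __post_init__(self):
        if min(self.age, self.bmi, self.disease_duration, self.edss, self.t2lv) < 0:
            raise ConfigurationError("covariates must be nonnegative")
        if not 0 < self.bpf < 1:
            raise ConfigurationError("bpf must lie in (0, 1)")
        if round(self.edss * 2) != self.edss * 2 or not 0 <= self.edss <= 10:
            raise ConfigurationError("edss must be in {0, 0.5, ..., 10}")
        if self.phenotype not in PHENOTYPES:
            raise ConfigurationError(f"phenotype must be one of {PHENOTYPES}")


@dataclass(frozen=True)
class SubjectRecord:
    """Covariates plus ground-truth kinetics for one synthetic subject."""

    subject_id: str
    covariates: SubjectCovariates
    truth: KineticTruth


@dataclass(frozen=True)
class CohortConfig:
    """Everything needed to generate one synthetic cohort deterministically.

    ``kinetic_moments`` holds :class:`Moments` for the four
    :class:`~duralymph.kinetics.KineticTruth` fields; the SD of ``e_peak`` is
    the SD of the *residual* noise around the BPF regression line, and
    ``bpf_coupling`` is the regression slope (enhancement units per unit
    BPF, negative in the calibrated default).
    """

    n_subjects: int
    kinetic_moments: dict[str, Moments]
    covariate_moments: dict[str, Moments] = field(
        default_factory=lambda: dict(STUDY_COVARIATE_MOMENTS)
    )
    bpf_coupling: float = 0.0
    noise_sigma: float = 0.02
    render_mode: str = "direct"
    seed: int = 0
    schedule: AcquisitionSchedule = DEFAULT_SCHEDULE

    def __post_init__(self):
        if self.n_subjects < 0:
            raise ConfigurationError("n_subjects must be >= 0")
        if self.noise_sigma < 0:
            raise ConfigurationError("noise_sigma must be >= 0")
        if self.render_mode not in ("direct", "physical"):
            raise ConfigurationError("render_mode must be 'direct' or 'physical'")
        required = {"s0_lymph", "e_peak", "tau_peak", "w_decay"}
        missing = required - set(self.kinetic_moments)
        if missing:
            raise ConfigurationError(f"kinetic_moments missing fields: {sorted(missing)}")

    def with_seed(self, seed: int) -> "CohortConfig":
        return replace(self, seed=seed)


def truncated_normal(
    rng: np.random.Generator,
    m: Moments,
    size: int,
    max_rounds: int = 1000,
) -> np.ndarray:
    """Vectorized rejection sampler for a (log-)truncated normal.

    Each element is redrawn until it falls inside [lo, hi]; more than
    ``max_rounds`` redraws for any element raises
    :class:`~duralymph.errors.GenerationError` (unsatisfiable truncation).
    """
    if size == 0:
        return np.empty(0)
    if m.sd == 0:
        centre = np.exp(m.mean) if m.log else m.mean
        if not m.lo <= centre <= m.hi:
            raise GenerationError("degenerate (sd=0) moments outside bounds")
        return np.full(size, centre)
    out = np.empty(size)
    pending = np.ones(size, dtype=bool)
    for _ in range(max_rounds):
        k = int(pending.sum())
        if k == 0:
            return out
        draw = rng.normal(m.mean, m.sd, size=k)
        if m.log:
            draw = np.exp(draw)
        ok = (draw >= m.lo) & (draw <= m.hi)
        idx = np.flatnonzero(pending)[ok]
        out[idx] = draw[ok]
        pending[idx] = False
    raise GenerationError(
        f"truncation [{m.lo}, {m.hi}] unsatisfied after {max_rounds} redraws "
        f"(mean={m.mean}, sd={m.sd})"
    )


def _sample_w_decay(
    rng: np.random.Generator, m: Moments, hi_per_subject: np.ndarray
) -> np.ndarray:
    """Washout rates from a truncated normal with subject-specific upper
    bounds (inverse-CDF sampling, exact even under extreme truncation).

    The per-subject bound enforces the never-below-baseline invariant
    ``w_decay * (t_guard - tau_peak) < e_peak`` by construction.
    """
    hi = np.minimum(m.hi, np.maximum(hi_per_subject, 1e-9))
    if m.sd == 0:
        return np.minimum(np.full(hi.shape, m.mean), hi)
    a = (m.lo - m.mean) / m.sd
    b = (hi - m.mean) / m.sd
    u = rng.random(hi.shape[0])
    w = stats.truncnorm.ppf(u, a, b, loc=m.mean, scale=m.sd)
    return np.minimum(np.maximum(w, m.lo), hi)  # guard ppf rounding at the edges


def sample_cohort_arrays(
    config: CohortConfig, n: int, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Vectorized cohort draw returning plain arrays (one entry per field).

    This is the sampling core shared by :func:`sample_cohort` and the
    calibration oracle, which needs cohorts of tens of thousands of
    subjects without dataclass overhead.
    """
    cov = config.covariate_moments
    kin = config.kinetic_moments
    out: dict[str, np.ndarray] = {}
    out["age"] = truncated_normal(rng, cov["age"], n)
    out["bmi"] = truncated_normal(rng, cov["bmi"], n)
    out["disease_duration"] = truncated_normal(rng, cov["disease_duration"], n)
    edss = truncated_normal(rng, cov["edss"], n)
    out["edss"] = np.clip(np.round(edss * 2) / 2, cov["edss"].lo, cov["edss"].hi)
    out["t2lv"] = truncated_normal(rng, cov["t2lv"], n)
    out["bpf"] = truncated_normal(rng, cov["bpf"], n)
    out["phenotype"] = np.where(rng.random(n) < RRMS_FRACTION, "RRMS", "SPMS")

    out["s0_lymph"] = truncated_normal(rng, kin["s0_lymph"], n)
    out["tau_peak"] = truncated_normal(rng, kin["tau_peak"], n)

    # e_peak: linear in centered BPF plus independent noise, floored by
    # redrawing the noise term (the floor keeps S_0 physically meaningful).
    e_m = kin["e_peak"]
    mean_shift = e_m.mean + config.bpf_coupling * (out["bpf"] - cov["bpf"].mean)
    e = mean_shift + rng.normal(0.0, e_m.sd, size=n) if n else np.empty(0)
    pending = e < E_PEAK_FLOOR
    for _ in range(1000):
        k = int(pending.sum())
        if k == 0:
            break
        e[pending] = mean_shift[pending] + rng.normal(0.0, e_m.sd, size=k)
        pending = e < E_PEAK_FLOOR
    else:
        raise GenerationError("could not satisfy the e_peak floor after 1000 redraws")
    out["e_peak"] = e

    t_guard = config.schedule.t_last + WINDOW_MARGIN_MIN
    w_hi = 0.95 * out["e_peak"] / np.maximum(t_guard - out["tau_peak"], 1e-6)
    out["w_decay"] = _sample_w_decay(rng, kin["w_decay"], w_hi)
    return out


def sample_cohort(config: CohortConfig) -> list[SubjectRecord]:
    """Draw ``config.n_subjects`` subjects, deterministic given the seed."""
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    arrays = sample_cohort_arrays(config, config.n_subjects, rng)
    records = []
    for i in range(config.n_subjects):
        covariates = SubjectCovariates(
            age=float(arrays["age"][i]),
            bmi=float(arrays["bmi"][i]),
            disease_duration=float(arrays["disease_duration"][i]),
            edss=float(arrays["edss"][i]),
            t2lv=float(arrays["t2lv"][i]),
            bpf=float(arrays["bpf"][i]),
            phenotype=str(arrays["phenotype"][i]),
        )
        truth = KineticTruth(
            s0_lymph=float(arrays["s0_lymph"][i]),
            e_peak=float(arrays["e_peak"][i]),
            tau_peak=float(arrays["tau_peak"][i]),
            w_decay=float(arrays["w_decay"][i]),
        )
        records.append(
            SubjectRecord(subject_id=f"sub-{i + 1:03d}", covariates=covariates, truth=truth)
        )
    return records


def subject_rngs(config: CohortConfig) -> list[np.random.Generator]:
    """Independent per-subject random substreams for image rendering.

    Substreams are spawned from the cohort seed, so the cohort draw itself
    (which consumes the root stream) and every subject's rendering noise are
    mutually independent and jointly reproducible.
    """
    children = np.random.SeedSequence(config.seed).spawn(config.n_subjects + 1)
    return [np.random.default_rng(s) for s in children[1:]]
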