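"""Digital head phantom and dynamic FLAIR series rendering.

The phantom is a coronal 10-slice grid mimicking the dynamic protocol's
field of view: an elliptical brain with an interhemispheric fissure, the
superior sagittal sinus at its apex, the falx cerebri descending below it,
and the inferior dural lymphatic vessel as a thin ribbon wedged between
sinus and falx — the anatomy the ROI measurement targets.  A pair of small
superior lymphatic vessels flank the sinus but are not measured.

Two render modes share the geometry:

* ``direct`` — intensities are expressed directly as fractions of the
  parenchyma baseline (the units contract of the pipeline): parenchyma 1,
  CSF/sinus 1 %, lymph voxels follow the subject's true enhancement curve.
* ``physical`` — intensities come from the inversion-recovery signal
  equation with per-tissue relaxometry, the lymph gadolinium concentration
  tracking the enhancement curve; volumes are normalized by the parenchyma
  signal so the units contract still holds approximately.

Magnitude-MR noise is Rician: sqrt((S + n1)^2 + n2^2) with i.i.d. Gaussian
n1, n2 of SD ``noise_sigma``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cohort import CohortConfig, SubjectRecord
from .errors import ConfigurationError, InputError
from .flair import DEFAULT_TISSUE_PROPERTIES, SequenceParams, flair_signal
from .kinetics import KineticTruth, true_curve

TISSUE_IDS = {
    "background": 0,
    "parenchyma": 1,
    "csf": 2,
    "sinus": 3,
    "falx": 4,
    "lymph_inferior": 5,
    "lymph_superior": 6,
}

#: Direct-mode baseline intensities as fractions of the parenchyma signal.
#: Sinus and CSF sit at 1 % (flow void / inversion nulling); the falx is
#: moderately hypointense dura.
DIRECT_BASELINES = {
    "background": 0.0,
    "parenchyma": 1.0,
    "csf": 0.01,
    "sinus": 0.01,
    "falx": 0.7,
}

DEFAULT_GRID = (10, 256, 256)


@dataclass(frozen=True)
class PhantomGeometry:
    """Per-voxel tissue labels on a (slices, rows, cols) grid."""

    labels: np.ndarray
    grid: tuple[int, int, int] = field(init=False)

    def __post_init__(self):
        labels = np.asarray(self.labels)
        if labels.ndim != 3:
            raise ConfigurationError("labels must be a 3-D (slice, row, col) array")
        known = set(TISSUE_IDS.values())
        if not set(np.unique(labels)).issubset(known):
            raise ConfigurationError("labels contain unknown tissue ids")
        if not (labels == TISSUE_IDS["lymph_inferior"]).any():
            raise ConfigurationError("lymph_inferior label is empty")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "grid", tuple(int(s) for s in labels.shape))

    def mask(self, tissue: str) -> np.ndarray:
        return self.labels == TISSUE_IDS[tissue]

    @property
    def brain_mask(self) -> np.ndarray:
        """Intracranial mask (everything except background)."""
        return self.labels != TISSUE_IDS["background"]

    @property
    def lymph_center(self) -> tuple[int, int, int]:
        """Voxel at the centroid of the inferior lymphatic ribbon — the
        ground-truth ROI seed recorded in series metadata."""
        idx = np.argwhere(self.mask("lymph_inferior"))
        return tuple(int(round(v)) for v in idx.mean(axis=0))


def build_default_geometry(grid: tuple[int, int, int] = DEFAULT_GRID) -> PhantomGeometry:
    """Construct the coronal head phantom on the given grid.

    Proportions are defined relative to the grid so smaller test grids
    remain anatomically valid (sinus above lymph above falx, all within the
    interhemispheric fissure).
    """
    n_sl, n_r, n_c = grid
    if n_sl < 1 or n_r < 32 or n_c < 32:
        raise ConfigurationError("phantom grid must be >= 1 slice of at least 32 x 32")
    rows = np.arange(n_r)[:, None]
    cols = np.arange(n_c)[None, :]
    cr, cc = n_r * 0.52, n_c * 0.5
    a, b = n_r * 0.42, n_c * 0.40
    inside = ((rows - cr) / a) ** 2 + ((cols - cc) / b) ** 2 <= 1.0
    rim = ((rows - cr) / (a * 0.97)) ** 2 + ((cols - cc) / (b * 0.97)) ** 2 > 1.0

    plane = np.zeros((n_r, n_c), dtype=np.uint8)
    plane[inside] = TISSUE_IDS["parenchyma"]
    plane[inside & rim] = TISSUE_IDS["csf"]  # subarachnoid rim

    # Interhemispheric fissure: a CSF-filled sagittal cleft.
    c_lo, c_hi = int(cc) - max(n_c // 43, 2), int(cc) + max(n_c // 43, 2) + 2
    r_top = int(cr - a) + 1
    r_mid = int(cr)
    fissure = np.zeros_like(inside)
    fissure[r_top:r_mid, c_lo:c_hi] = True
    plane[fissure & inside] = TISSUE_IDS["csf"]

    # Superior sagittal sinus at the fissure apex.
    s_h = max(n_r // 16, 4)
    s_top = r_top + 2
    sinus = np.zeros_like(inside)
    sinus[s_top : s_top + s_h, c_lo + 1 : c_hi - 1] = True
    plane[sinus & inside] = TISSUE_IDS["sinus"]

    # Inferior lymphatic vessel: 2-voxel-tall ribbon hugging the sinus base.
    l_top = s_top + s_h
    lymph_c_lo = c_lo + 2
    lymph_c_hi = c_hi - 2
    plane[l_top : l_top + 2, lymph_c_lo:lymph_c_hi] = TISSUE_IDS["lymph_inferior"]

    # Falx cerebri: thin dural sheet descending below the vessel.
    f_c = int(cc)
    plane[l_top + 2 : r_mid, f_c - 1 : f_c + 1] = TISSUE_IDS["falx"]

    # Superior lymphatic vessels lateral to the sinus (not measured).
    plane[s_top + 1 : s_top + 3, c_lo - 2 : c_lo] = TISSUE_IDS["lymph_superior"]
    plane[s_top + 1 : s_top + 3, c_hi : c_hi + 2] = TISSUE_IDS["lymph_superior"]

    labels = np.broadcast_to(plane, (n_sl, n_r, n_c)).copy()
    return PhantomGeometry(labels=labels)


@dataclass
class DynamicSeries:
    """A rendered 4-D dynamic series with its acquisition metadata."""

    data: np.ndarray  # (time, slice, row, col)
    times: np.ndarray  # minutes, times[0] = 0
    brain_mask: np.ndarray
    roi_seed: tuple[int, int, int]
    subject_id: str = "sub-001"
    truth: KineticTruth | None = None
    seed: int | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        self.times = np.asarray(self.times, dtype=np.float64)
        self.brain_mask = np.asarray(self.brain_mask, dtype=bool)
        if self.data.ndim != 4:
            raise InputError("data must be 4-D (time, slice, row, col)")
        if self.data.shape[0] != self.times.size:
            raise InputError("time axis length does not match times")
        if self.brain_mask.shape != self.data.shape[1:]:
            raise InputError("brain mask shape does not match volumes")


def add_rician_noise(signal: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Magnitude-MR (Rician) noise: both quadrature channels perturbed."""
    if sigma < 0:
        raise InputError("noise sigma must be >= 0")
    if sigma == 0:
        return np.asarray(signal, float).copy()
    # single-precision noise draws: ample for 2 % noise, twice as fast
    real = signal + sigma * rng.standard_normal(signal.shape, dtype=np.float32)
    imag = sigma * rng.standard_normal(signal.shape, dtype=np.float32)
    return np.hypot(real, imag)


def _direct_baseline_volume(geometry: PhantomGeometry) -> np.ndarray:
    vol = np.zeros(geometry.grid, dtype=np.float64)
    for tissue, value in DIRECT_BASELINES.items():
        vol[geometry.mask(tissue)] = value
    return vol


def render_series(
    record: SubjectRecord,
    times: np.ndarray,
    geometry: PhantomGeometry,
    config: CohortConfig,
    rng: np.random.Generator,
    seq: SequenceParams | None = None,
) -> DynamicSeries:
    """Render one subject's dynamic series at the given realized times.

    In direct mode the lymph voxels carry the true curve in
    parenchyma-median units; in physical mode all tissues are rendered
    through the IR signal equation with the lymph gadolinium concentration
    proportional to the fractional enhancement, and volumes normalized by
    the parenchyma signal.
    """
    times = np.asarray(times, float)
    curve = true_curve(record.truth, times)
    lymph_inf = geometry.mask("lymph_inferior")
    lymph_sup = geometry.mask("lymph_superior")

    if config.render_mode == "direct":
        base = _direct_baseline_volume(geometry)
        volumes = np.repeat(base[None], times.size, axis=0)
        volumes[:, lymph_inf] = curve[:, None]
        # The unmeasured superior vessels enhance similarly but fainter.
        volumes[:, lymph_sup] = 0.9 * curve[:, None]
    elif config.render_mode == "physical":
        seq = seq or SequenceParams(n_slices=geometry.grid[0])
        props = DEFAULT_TISSUE_PROPERTIES
        ref = flair_signal(props["parenchyma"], seq, 0.0)
        base = np.zeros(geometry.grid, dtype=np.float64)
        for tissue in ("parenchyma", "csf", "sinus", "falx"):
            base[geometry.mask(tissue)] = flair_signal(props[tissue], seq, 0.0) / ref
        volumes = np.repeat(base[None], times.size, axis=0)
        # Lymph [Gd] proportional to fractional enhancement; 0.5 mM at the
        # true peak keeps the signal on the T1-dominated (enhancing) branch.
        enh = curve / record.truth.s0_lymph - 1.0
        peak = max(record.truth.e_peak, 1e-9)
        conc = 0.5 * np.clip(enh, 0.0, None) / peak
        lymph_sig = flair_signal(props["lymph"], seq, conc) / ref
        volumes[:, lymph_inf] = lymph_sig[:, None]
        volumes[:, lymph_sup] = 0.9 * lymph_sig[:, None]
    else:  # pragma: no cover - CohortConfig already validates
        raise ConfigurationError(f"unknown render mode {config.render_mode!r}")

    noisy = add_rician_noise(volumes, config.noise_sigma, rng)
    return DynamicSeries(
        data=noisy,
        times=times,
        brain_mask=geometry.brain_mask,
        roi_seed=geometry.lymph_center,
        subject_id=record.subject_id,
        truth=record.truth,
        seed=config.seed,
    )
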