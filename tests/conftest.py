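import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import duralymph as dl
from duralymph.phantom import build_default_geometry

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def default_config():
    """Study-calibrated 20-subject configuration (calibration is cached)."""
    return dl.default_cohort_config(n_subjects=20, seed=1)


@pytest.fixture(scope="session")
def small_geometry():
    """A 4-slice 64x64 phantom for fast rendering tests."""
    return build_default_geometry((4, 64, 64))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


# --- shared demo subject for phantom/extraction tests ---------------------

DEMO_TRUTH = dl.KineticTruth(s0_lymph=0.85, e_peak=1.1, tau_peak=6.0, w_decay=0.009)
DEMO_TIMES = np.array([0.0, 2.5, 5.0, 7.0, 9.0, 17.0, 20.0, 35.0])


@pytest.fixture(scope="session")
def demo_record():
    covs = dl.SubjectCovariates(
        age=46.0, bmi=26.0, disease_duration=12.0, edss=2.0, t2lv=4.0, bpf=0.81,
        phenotype="RRMS",
    )
    return dl.SubjectRecord(subject_id="sub-001", covariates=covs, truth=DEMO_TRUTH)


@pytest.fixture(scope="session")
def demo_times():
    return DEMO_TIMES.copy()


@pytest.fixture(scope="session")
def render_config():
    """Render-mode/noise variants of the calibrated single-subject config."""

    def _make(noise=0.0, mode="direct", seed=0):
        return dl.default_cohort_config(
            n_subjects=1, seed=seed, noise_sigma=noise, render_mode=mode
        )

    return _make
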