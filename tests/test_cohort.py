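import numpy as np
import pytest

import duralymph as dl
from duralymph.cohort import (
    E_PEAK_FLOOR,
    STUDY_COVARIATE_MOMENTS,
    WINDOW_MARGIN_MIN,
    CohortConfig,
    Moments,
    sample_cohort,
    sample_cohort_arrays,
    truncated_normal,
)
from duralymph.errors import ConfigurationError, GenerationError


def _plain_kinetics(e_sd=0.3, coupling=0.0):
    return {
        "s0_lymph": Moments(0.85, 0.05, 0.2, 3.0),
        "e_peak": Moments(1.0, e_sd, 0.02, 8.0),
        "tau_peak": Moments(5.0, 2.0, 0.5, 34.5),
        "w_decay": Moments(0.009, 0.003, 0.0, 0.08),
    }


def _config(n, seed=0, coupling=0.0, e_sd=0.3, cov=None):
    return CohortConfig(
        n_subjects=n,
        kinetic_moments=_plain_kinetics(e_sd=e_sd),
        covariate_moments=cov or dict(STUDY_COVARIATE_MOMENTS),
        bpf_coupling=coupling,
        seed=seed,
    )


def test_empty_cohort():
    assert sample_cohort(_config(0)) == []


def test_same_seed_reproduces_records_exactly():
    a = sample_cohort(_config(12, seed=42))
    b = sample_cohort(_config(12, seed=42))
    assert a == b
    c = sample_cohort(_config(12, seed=43))
    assert a != c


def test_covariates_respect_bounds_and_granularity():
    records = sample_cohort(_config(300, seed=5))
    for rec in records:
        c = rec.covariates
        assert 27 <= c.age <= 65
        assert 17.1 <= c.bmi <= 35.9
        assert 2.1 <= c.disease_duration <= 38.0
        assert 0 <= c.edss <= 6.5 and (c.edss * 2) == int(c.edss * 2)
        assert 0.43 <= c.t2lv <= 75.1
        assert 0.67 <= c.bpf <= 0.92
        assert c.phenotype in ("RRMS", "SPMS")


def test_kinetic_truth_stays_above_baseline():
    cfg = _config(500, seed=9)
    t_guard = cfg.schedule.t_last + WINDOW_MARGIN_MIN
    for rec in sample_cohort(cfg):
        tr = rec.truth
        assert tr.e_peak >= E_PEAK_FLOOR
        assert tr.w_decay * (t_guard - tr.tau_peak) < tr.e_peak


def test_bpf_coupling_matches_closed_form_correlation():
    """corr(bpf, e_peak) = b*sigma_b / sqrt(b^2 sigma_b^2 + sigma_e^2) when
    the BPF bounds are wide enough not to truncate."""
    cov = dict(STUDY_COVARIATE_MOMENTS)
    cov["bpf"] = Moments(0.8, 0.05, 0.3, 0.99)  # ~±10 SD: effectively untruncated
    b, sigma_b, sigma_e = -4.0, 0.05, 0.3
    cfg = _config(10_000, seed=11, coupling=b, e_sd=sigma_e, cov=cov)
    arr = sample_cohort_arrays(cfg, cfg.n_subjects, np.random.default_rng(cfg.seed))
    expected = b * sigma_b / np.sqrt(b**2 * sigma_b**2 + sigma_e**2)
    observed = np.corrcoef(arr["bpf"], arr["e_peak"])[0, 1]
    assert observed == pytest.approx(expected, abs=0.02)


def test_stronger_coupling_strengthens_correlation():
    cov = dict(STUDY_COVARIATE_MOMENTS)
    cov["bpf"] = Moments(0.8, 0.05, 0.3, 0.99)
    rs = []
    for b in (-1.0, -3.0, -6.0):
        cfg = _config(10_000, seed=13, coupling=b, cov=cov)
        arr = sample_cohort_arrays(cfg, cfg.n_subjects, np.random.default_rng(cfg.seed))
        rs.append(abs(np.corrcoef(arr["bpf"], arr["e_peak"])[0, 1]))
    assert rs[0] < rs[1] < rs[2]


def test_invalid_bounds_rejected_at_construction():
    with pytest.raises(ConfigurationError):
        Moments(1.0, 0.5, 2.0, 1.0)  # lo >= hi
    with pytest.raises(ConfigurationError):
        Moments(1.0, -0.5, 0.0, 2.0)  # negative SD


def test_unsatisfiable_truncation_raises_generation_error():
    rng = np.random.default_rng(0)
    with pytest.raises(GenerationError):
        truncated_normal(rng, Moments(100.0, 0.01, 0.0, 1.0), size=5)


def test_config_validation():
    with pytest.raises(ConfigurationError):
        _config(-1)
    with pytest.raises(ConfigurationError):
        CohortConfig(n_subjects=2, kinetic_moments={"e_peak": Moments(1, 0.1, 0, 2)})
    with pytest.raises(ConfigurationError):
        CohortConfig(n_subjects=2, kinetic_moments=_plain_kinetics(), noise_sigma=-0.1)
    with pytest.raises(ConfigurationError):
        CohortConfig(n_subjects=2, kinetic_moments=_plain_kinetics(), render_mode="fancy")


def test_study_defaults_recover_table_moments():
    """Large-sample covariate means stay near the study population values."""
    cfg = dl.default_cohort_config(n_subjects=0, seed=1)
    arr = sample_cohort_arrays(cfg, 20_000, np.random.default_rng(3))
    assert np.mean(arr["age"]) == pytest.approx(46.4, rel=0.02)
    assert np.mean(arr["bmi"]) == pytest.approx(25.9, rel=0.02)
    assert np.median(arr["t2lv"]) == pytest.approx(3.9, rel=0.10)
    assert np.mean(arr["bpf"]) == pytest.approx(0.81, rel=0.01)
    assert np.mean(arr["phenotype"] == "RRMS") == pytest.approx(0.65, abs=0.02)
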