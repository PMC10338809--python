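import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import duralymph as dl
from duralymph.errors import ComputationError, InputError
from duralymph.io import cohort_to_frame
from duralymph.metrics import metrics_table, split_summary
from duralymph.stats import correlate, stats_grid, transform_t2lv


def test_cube_root_transform():
    assert transform_t2lv(8.0) == pytest.approx(2.0, abs=1e-12)
    assert transform_t2lv(0.0) == 0.0
    assert transform_t2lv(3.9) == pytest.approx(1.5741, abs=5e-4)
    with pytest.raises(InputError):
        transform_t2lv(-1.0)


def test_perfect_linear_relation():
    x = np.arange(1.0, 6.0)
    res = correlate(2 * x, x)
    assert res.r == pytest.approx(1.0, abs=1e-12)
    assert res.slope == pytest.approx(2.0, abs=1e-12)
    assert res.p < 1e-10
    assert res.significant and res.band == "p<.05"


def test_hand_worked_three_point_regression():
    """r = 0.5 and two-sided p = 2/3 from t = 0.577 on 1 df."""
    res = correlate([1.0, 3.0, 2.0], [1.0, 2.0, 3.0])
    assert res.r == pytest.approx(0.5, abs=1e-12)
    assert res.p == pytest.approx(2.0 / 3.0, abs=1e-6)
    assert res.band == "p>=.1"


def test_null_correlation_is_small():
    rng = np.random.default_rng(0)
    x = rng.normal(size=10_000)
    y = rng.permutation(rng.normal(size=10_000))
    assert abs(correlate(y, x).r) < 0.03


def test_agrees_with_covariance_formula_oracle():
    """1,000 random small problems against brute-force sums: slope, r from
    the covariance formula, p from the correlation t-test."""
    rng = np.random.default_rng(99)
    for _ in range(1000):
        n = int(rng.integers(3, 12))
        x = rng.normal(size=n)
        y = rng.normal(size=n) + rng.uniform(-2, 2) * x
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            continue
        res = correlate(y, x)
        sxx = ((x - x.mean()) ** 2).sum()
        sxy = ((x - x.mean()) * (y - y.mean())).sum()
        syy = ((y - y.mean()) ** 2).sum()
        r = sxy / np.sqrt(sxx * syy)
        assert res.slope == pytest.approx(sxy / sxx, rel=1e-12, abs=1e-12)
        assert res.intercept == pytest.approx(y.mean() - sxy / sxx * x.mean(), rel=1e-12, abs=1e-12)
        assert res.r == pytest.approx(r, rel=1e-12, abs=1e-12)
        if abs(r) < 1 - 1e-12:
            t = r * np.sqrt((n - 2) / (1 - r * r))
            assert res.p == pytest.approx(2 * sps.t.sf(abs(t), n - 2), rel=1e-9, abs=1e-12)


def test_r_invariant_under_affine_rescaling():
    rng = np.random.default_rng(4)
    x = rng.normal(size=30)
    y = rng.normal(size=30)
    base = correlate(y, x)
    assert correlate(y, 3.7 * x - 12.0).r == pytest.approx(base.r, rel=1e-12)
    assert correlate(5.0 * y + 2.0, x).r == pytest.approx(base.r, rel=1e-12)


def test_zero_variance_rejected():
    with pytest.raises(ComputationError):
        correlate([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def test_missing_values_dropped_pairwise():
    x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    y = np.array([2.0, np.nan, 6.0, 8.0, 10.0])
    res = correlate(y, x)
    assert res.n == 4
    assert res.r == pytest.approx(1.0, abs=1e-12)


@pytest.fixture(scope="module")
def synthetic_tables(default_config):
    records, curves = dl.simulate_curve_cohort(default_config)
    per, _ = split_summary(metrics_table(curves))
    return per, cohort_to_frame(records)


class TestStatsGrid:
    def test_full_grid_has_thirty_cells(self, synthetic_tables):
        per, cov = synthetic_tables
        grid = stats_grid(per, cov)
        assert len(grid) == 30
        assert set(grid["band"]).issubset({"p<.05", ".05<=p<.1", "p>=.1"})
        assert (grid["n"] >= 3).all()

    def test_duplicate_subjects_rejected(self, synthetic_tables):
        per, cov = synthetic_tables
        with pytest.raises(InputError, match="duplicated"):
            stats_grid(per, pd.concat([cov, cov.iloc[:1]]))

    def test_missing_subject_named(self, synthetic_tables):
        per, cov = synthetic_tables
        with pytest.raises(InputError, match="sub-001"):
            stats_grid(per, cov[cov.subject_id != "sub-001"])

    def test_bh_option_appends_q_column(self, synthetic_tables):
        per, cov = synthetic_tables
        grid = stats_grid(per, cov, bh_correction=True)
        assert "q" in grid.columns
        assert (grid["q"] >= grid["p"] - 1e-12).all()

    def test_coupling_sign_recovered_across_replicates(self):
        """With the calibrated negative BPF coupling, the fitted BPF-P_enh
        slope is negative in >= 95% of 200 replicate cohorts of n=20."""
        negative = 0
        for seed in range(1, 201):
            cfg = dl.default_cohort_config(n_subjects=20, seed=seed)
            records, curves = dl.simulate_curve_cohort(cfg)
            p_enh = [dl.compute_metrics(c).p_enh for c in curves.values()]
            bpf = [r.covariates.bpf for r in records]
            if correlate(p_enh, bpf).slope < 0:
                negative += 1
        assert negative >= 190
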