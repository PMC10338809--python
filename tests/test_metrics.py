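import numpy as np
import pytest

from duralymph.errors import ComputationError, InputError
from duralymph.metrics import compute_metrics, metrics_table, split_summary
from duralymph.roi import TimeIntensityCurve

HAND_TIMES = np.array([0.0, 2.5, 5.0, 7.0, 9.0, 17.0, 20.0, 35.0])
HAND_SIGNAL = np.array([1.00, 1.80, 2.00, 1.95, 1.90, 1.80, 1.75, 1.60])


def _curve(times=HAND_TIMES, signal=HAND_SIGNAL):
    return TimeIntensityCurve(times=np.asarray(times, float), signal=np.asarray(signal, float))


def test_hand_worked_eight_point_curve():
    """Hand trapezoid/slope arithmetic frozen as an oracle for the metric
    formulas (interval-by-interval trapezoids sum to 26.30)."""
    m = compute_metrics(_curve())
    assert m.p_enh == pytest.approx(100.0, abs=1e-9)
    assert m.t_max == pytest.approx(5.0, abs=1e-12)
    assert m.wash_in == pytest.approx(0.32, abs=1e-9)
    assert m.valid_washout
    assert m.washout == pytest.approx((2.00 - 1.60) / 30.0, abs=1e-9)
    assert m.auc == pytest.approx(26.30, abs=1e-9)


def test_flat_curve_degenerates_gracefully():
    m = compute_metrics(_curve(signal=np.ones(8)))
    assert m.p_enh == 0.0
    assert m.wash_in == 0.0
    assert m.auc == 0.0
    assert m.t_max == 0.0
    assert not m.valid_washout
    assert np.isnan(m.washout)


def test_plateau_takes_earliest_peak():
    m = compute_metrics(_curve(times=[0.0, 2.0, 4.0, 6.0], signal=[1.0, 2.0, 2.0, 1.5]))
    assert m.t_max == 2.0


def test_peak_on_last_point_invalidates_washout():
    m = compute_metrics(_curve(times=[0.0, 2.0, 4.0], signal=[1.0, 1.5, 2.0]))
    assert not m.valid_washout
    assert np.isnan(m.washout)


def test_zero_baseline_rejected():
    with pytest.raises(ComputationError):
        compute_metrics(_curve(signal=[0.0, 1.0, 2.0, 1.5, 1.2, 1.1, 1.0, 0.9]))


def test_too_few_points_rejected():
    with pytest.raises(InputError):
        compute_metrics(_curve(times=[0.0, 2.0], signal=[1.0, 2.0]))


@pytest.mark.parametrize("k", [0.25, 1.0, 7.3])
def test_scale_equivariance(k):
    base = compute_metrics(_curve())
    scaled = compute_metrics(_curve(signal=k * HAND_SIGNAL))
    assert scaled.p_enh == pytest.approx(base.p_enh, rel=1e-12)
    assert scaled.auc == pytest.approx(k * base.auc, rel=1e-12)
    assert scaled.wash_in == pytest.approx(k * base.wash_in, rel=1e-12)
    assert scaled.washout == pytest.approx(k * base.washout, rel=1e-12)


def test_postcontrast_time_shift():
    base = compute_metrics(_curve())
    delta = 1.75
    shifted_times = np.concatenate(([0.0], HAND_TIMES[1:] + delta))
    shifted = compute_metrics(_curve(times=shifted_times))
    assert shifted.p_enh == base.p_enh
    assert shifted.t_max == pytest.approx(base.t_max + delta, abs=1e-12)


def test_auc_positive_for_any_enhancing_curve():
    m = compute_metrics(_curve(times=[0.0, 2.0, 4.0, 6.0], signal=[1.0, 1.0, 1.01, 1.0]))
    assert m.auc > 0


class TestMetricsTable:
    def test_single_curve_summary_equals_row(self):
        table = metrics_table({"s1": _curve()})
        per, summary = split_summary(table)
        for col in per.columns:
            assert summary.loc["mean", col] == pytest.approx(per.iloc[0][col], abs=1e-12)

    def test_identical_curves_have_zero_sd(self):
        table = metrics_table({"a": _curve(), "b": _curve()})
        _, summary = split_summary(table)
        assert (summary.loc["sd"].fillna(0) == 0).all()

    def test_aggregation_matches_per_curve_loop(self):
        rng = np.random.default_rng(8)
        curves = {}
        for i in range(20):
            bump = rng.uniform(0.5, 2.0)
            curves[f"s{i:02d}"] = _curve(signal=1.0 + bump * (HAND_SIGNAL - 1.0))
        table = metrics_table(curves)
        per, summary = split_summary(table)
        # independent aggregation: loop + numpy over individual results
        loop = {name: [] for name in per.columns}
        for c in curves.values():
            m = compute_metrics(c)
            for name in loop:
                loop[name].append(getattr(m, name) if m.valid_washout or name != "washout" else np.nan)
        for name in loop:
            assert summary.loc["mean", name] == pytest.approx(
                np.nanmean(loop[name]), abs=1e-9
            )

    def test_invalid_washout_counted_separately(self):
        rising = _curve(times=[0.0, 2.0, 4.0], signal=[1.0, 1.5, 2.0])
        table = metrics_table({"peaked": _curve(HAND_TIMES, HAND_SIGNAL), "rising": rising})
        _, summary = split_summary(table)
        assert summary.loc["n", "washout"] == 1
        assert summary.loc["n", "p_enh"] == 2
        assert summary.loc["mean", "washout"] == pytest.approx((2.0 - 1.6) / 30.0)

    def test_empty_input_rejected(self):
        with pytest.raises(InputError):
            metrics_table({})
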