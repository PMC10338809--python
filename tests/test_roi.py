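import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import duralymph as dl
from duralymph.errors import InputError
from duralymph.phantom import DynamicSeries, render_series
from duralymph.roi import brain_reference, extract_curve, place_roi, robust_max
from tests.conftest import DEMO_TIMES, DEMO_TRUTH


class TestPlaceRoi:
    def test_odd_sizes_are_symmetric(self):
        roi = place_roi((5, 100, 100), 3, 3, (10, 256, 256))
        assert roi.rows == (99, 102) and roi.cols == (99, 102)

    def test_clipping_at_origin(self):
        roi = place_roi((0, 0, 0), 3, 3, (10, 256, 256))
        assert roi.rows == (0, 2) and roi.cols == (0, 2)

    def test_even_sizes_extend_toward_increasing_index(self):
        roi = place_roi((5, 100, 100), 4, 4, (10, 256, 256))
        assert roi.rows == (99, 103) and roi.cols == (99, 103)

    def test_seed_outside_image_rejected(self):
        with pytest.raises(InputError):
            place_roi((5, 300, 100), 3, 3, (10, 256, 256))


class TestRobustMax:
    def test_constant_array(self):
        assert robust_max(np.full(57, 3.25)) == 3.25

    def test_linear_interpolation_between_order_statistics(self):
        assert robust_max(np.arange(1, 101)) == pytest.approx(98.02, abs=1e-12)

    def test_single_value(self):
        assert robust_max([4.2]) == 4.2

    def test_pooled_two_slice_example(self):
        # slices contribute {1,2} and {3,10}; pooled percentile at rank 2.94
        assert robust_max([1.0, 2.0, 3.0, 10.0]) == pytest.approx(9.58, abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(InputError):
            robust_max([])

    @given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=50))
    def test_bounded_by_extremes(self, values):
        r = robust_max(values)
        assert min(values) - 1e-9 <= r <= max(values) + 1e-9

    @given(
        st.lists(st.floats(-100, 100), min_size=2, max_size=40),
        st.floats(0.1, 3.0),
        st.floats(-5.0, 5.0),
    )
    def test_monotone_under_increasing_affine_map(self, values, scale, shift):
        mapped = [scale * v + shift for v in values]
        assert robust_max(mapped) == pytest.approx(
            scale * robust_max(values) + shift, rel=1e-9, abs=1e-9
        )


class TestBrainReference:
    def test_uniform_brain(self):
        vol = np.full((2, 4, 4), 7.5)
        assert brain_reference(vol, np.ones_like(vol, bool)) == 7.5

    def test_even_count_median(self):
        vol = np.array([[[1.0, 2.0], [3.0, 4.0]]])
        assert brain_reference(vol, np.ones_like(vol, bool)) == 2.5

    def test_empty_mask_rejected(self):
        with pytest.raises(InputError):
            brain_reference(np.ones((1, 2, 2)), np.zeros((1, 2, 2), bool))


class TestExtractCurve:
    def _flat_series(self, value=3.0, n_t=4):
        data = np.full((n_t, 2, 8, 8), value)
        return DynamicSeries(
            data=data,
            times=np.array([0.0, 2.5, 5.0, 7.0])[:n_t],
            brain_mask=np.ones((2, 8, 8), bool),
            roi_seed=(1, 4, 4),
        )

    def test_constant_volumes_give_unit_curve(self):
        series = self._flat_series()
        roi = place_roi(series.roi_seed, 3, 3, series.data.shape[1:])
        curve = extract_curve(series, roi)
        np.testing.assert_allclose(curve.signal, 1.0)

    def test_scaling_equivariance(self):
        series = self._flat_series()
        rng = np.random.default_rng(3)
        series.data = series.data + rng.random(series.data.shape)
        roi = place_roi(series.roi_seed, 3, 3, series.data.shape[1:])
        base = extract_curve(series, roi).signal
        scaled = DynamicSeries(
            data=17.3 * series.data,
            times=series.times,
            brain_mask=series.brain_mask,
            roi_seed=series.roi_seed,
        )
        np.testing.assert_allclose(extract_curve(scaled, roi).signal, base, rtol=1e-12)

    def test_roi_outside_mask_warns_but_proceeds(self):
        series = self._flat_series()
        mask = np.zeros((2, 8, 8), bool)
        mask[:, 6:, 6:] = True
        roi = place_roi((0, 1, 1), 2, 2, series.data.shape[1:])
        with pytest.warns(UserWarning, match="outside the brain mask"):
            curve = extract_curve(series, roi, mask=mask)
        assert curve.signal.size == series.times.size

    def test_noiseless_phantom_recovers_truth(
        self, small_geometry, demo_record, render_config
    ):
        """End-to-end generator contract: extraction reproduces the true
        curve at the realized times to well under 0.5%."""
        series = render_series(
            demo_record, DEMO_TIMES, small_geometry, render_config(noise=0.0),
            np.random.default_rng(0),
        )
        roi = place_roi(series.roi_seed, 3, 5, series.data.shape[1:])
        curve = extract_curve(series, roi)
        expected = dl.true_curve(DEMO_TRUTH, DEMO_TIMES)
        np.testing.assert_allclose(curve.signal, expected, rtol=5e-3)
        np.testing.assert_allclose(curve.signal, expected, rtol=1e-12)  # exact here
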