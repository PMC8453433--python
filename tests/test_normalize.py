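import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from prelesion import normalize
from prelesion.cohort import PhantomConfig, generate_ms_subject
from prelesion.constants import GM, WM
from prelesion.normalize import (
    AffineIntensityMap,
    ScannerCalibration,
    calibrate_mtr,
    lts_fit,
    normalize_mtr,
    normalize_t1,
    normalize_t2,
)


def _vols(gm_vals, wm_vals):
    n = len(gm_vals) + len(wm_vals)
    mtr = np.array(list(gm_vals) + list(wm_vals), dtype=float).reshape(n, 1, 1)
    labels = np.array([GM] * len(gm_vals) + [WM] * len(wm_vals), dtype=np.uint8)
    return mtr, labels.reshape(n, 1, 1)


class TestCalibration:
    def test_median_of_three(self):
        mtr, labels = _vols([0.3, 0.4, 0.5], [0.8, 0.9, 1.0])
        cal = calibrate_mtr(mtr, labels, "s")
        assert cal.median_gm_mtr == pytest.approx(0.4)
        assert cal.median_wm_mtr == pytest.approx(0.9)

    def test_wm_not_above_gm_is_error(self):
        mtr, labels = _vols([0.8, 0.9], [0.3, 0.4])
        with pytest.raises(ValueError, match="WM MTR > median GM"):
            calibrate_mtr(mtr, labels)

    def test_empty_tissue_named_in_error(self):
        mtr = np.ones((3, 1, 1))
        labels = np.full((3, 1, 1), GM, dtype=np.uint8)
        with pytest.raises(ValueError, match="wm"):
            calibrate_mtr(mtr, labels)

    def test_json_round_trip(self):
        cal = ScannerCalibration("sc", 30.0, 42.0)
        assert ScannerCalibration.from_json(cal.to_json()) == cal


class TestNormalizeMtr:
    CAL = ScannerCalibration("s", 30.0, 42.0)

    def test_gm_median_maps_to_zero(self):
        out = normalize_mtr(np.full((4, 4, 4), 30.0), self.CAL)
        np.testing.assert_array_equal(out, 0.0)

    def test_wm_median_maps_to_one(self):
        out = normalize_mtr(np.full((4, 4, 4), 42.0), self.CAL)
        np.testing.assert_array_equal(out, 1.0)

    def test_midpoint_maps_to_half(self):
        assert normalize_mtr(np.array([36.0]), self.CAL)[0] == pytest.approx(0.5)

    @given(st.floats(-10, 80), st.floats(-5, 5))
    @settings(max_examples=50, deadline=None)
    def test_affine_order_preserving_and_invertible(self, a, b):
        v = np.array([a, a + abs(b) + 1e-6])
        out = normalize_mtr(v, self.CAL)
        assert out[1] > out[0]
        back = normalize.denormalize_mtr(out, self.CAL)
        np.testing.assert_allclose(back, v, atol=1e-12)


class TestLts:
    def test_exact_affine_recovered(self):
        rng = np.random.default_rng(0)
        ref = rng.uniform(0, 100, (10, 10, 1))
        mov = 2.0 * ref + 5.0
        fit = lts_fit(ref, mov, np.ones(ref.shape, bool), seed=1)
        assert fit.gain == pytest.approx(2.0, abs=1e-9)
        assert fit.offset == pytest.approx(5.0, abs=1e-9)

    def test_contaminated_regression_oracle(self):
        # 70% of voxels follow gain 1.5 / offset -3; 30% shifted by +100.
        rng = np.random.default_rng(3)
        n = 1000
        ref = rng.uniform(0, 100, n)
        mov = 1.5 * ref - 3.0
        mov[: int(0.3 * n)] += 100.0
        fit = lts_fit(
            ref.reshape(-1, 1, 1),
            mov.reshape(-1, 1, 1),
            np.ones((n, 1, 1), bool),
            seed=2,
        )
        assert fit.gain == pytest.approx(1.5, abs=1e-6)
        assert fit.offset == pytest.approx(-3.0, abs=1e-6)

    def test_fraction_one_equals_ols(self):
        rng = np.random.default_rng(5)
        ref = rng.normal(size=50)
        mov = 0.7 * ref + 2.0 + rng.normal(scale=0.5, size=50)
        mask = np.ones(50, bool)
        fit = lts_fit(ref, mov, mask, fraction=1.0)
        gain, offset = np.polyfit(ref, mov, 1)
        assert fit.gain == pytest.approx(gain, abs=1e-9)
        assert fit.offset == pytest.approx(offset, abs=1e-9)
        assert fit.n_retained == 50

    def test_objective_history_non_increasing(self):
        rng = np.random.default_rng(7)
        ref = rng.normal(size=500)
        mov = 1.2 * ref + rng.normal(scale=2.0, size=500)
        fit = lts_fit(ref, mov, np.ones(500, bool), seed=3)
        hist = np.array(fit.objective_history)
        assert np.all(np.diff(hist) <= 1e-9)

    def test_n_retained_is_floor_of_fraction(self):
        rng = np.random.default_rng(9)
        ref = rng.normal(size=101)
        mov = ref + rng.normal(scale=0.1, size=101)
        fit = lts_fit(ref, mov, np.ones(101, bool), fraction=0.5)
        assert fit.n_retained == 50

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_exhaustive_subset_oracle(self, seed):
        # brute-force LTS: minimize over every subset of size h
        rng = np.random.default_rng(seed)
        n = 11
        ref = rng.uniform(0, 10, n)
        mov = 0.8 * ref + 1.0 + rng.normal(scale=0.7, size=n)
        h = n // 2
        best = np.inf
        for subset in itertools.combinations(range(n), h):
            idx = list(subset)
            g, o = np.polyfit(ref[idx], mov[idx], 1)
            obj = float(((mov[idx] - (g * ref[idx] + o)) ** 2).sum())
            best = min(best, obj)
        fit = lts_fit(ref, mov, np.ones(n, bool), fraction=h / n, seed=seed)
        assert fit.objective == pytest.approx(best, abs=1e-10)

    def test_degenerate_reference_is_error(self):
        ref = np.ones(30)
        mov = np.arange(30.0)
        with pytest.raises(ValueError, match="degenerate"):
            lts_fit(ref, mov, np.ones(30, bool))

    def test_zero_gain_is_invalid_map(self):
        with pytest.raises(ValueError, match="gain"):
            AffineIntensityMap(gain=0.0, offset=1.0, n_retained=5, objective=0.0)


@pytest.fixture(scope="module")
def subject():
    cfg = PhantomConfig(noise_sd=0.0, lesion_rate=0.5, seed=1)
    return generate_ms_subject(cfg, "scanner00", seed=7)


class TestNormalizeT1:
    def test_stage1_linearity(self, subject):
        nt1 = normalize_t1(subject, seed=0)
        base = subject.baseline
        gm_med = np.median(base.t1w[base.labels == GM])
        nawm_med = np.median(base.t1w[base.labels == WM])
        probe = gm_med + 0.5 * (nawm_med - gm_med)
        # a voxel halfway between the medians maps to 0.5
        idx = np.unravel_index(
            np.argmin(np.abs(base.t1w - probe)), base.t1w.shape
        )
        expected = (base.t1w[idx] - gm_med) / (nawm_med - gm_med)
        assert nt1[0][idx] == pytest.approx(expected, abs=1e-12)

    def test_baseline_medians_zero_and_one(self, subject):
        nt1 = normalize_t1(subject, seed=0)
        labels = subject.baseline.labels
        assert np.median(nt1[0][labels == GM]) == pytest.approx(0.0, abs=1e-12)
        assert np.median(nt1[0][labels == WM]) == pytest.approx(1.0, abs=1e-12)

    def test_invariance_to_global_affine_distortion(self, subject):
        nt1 = normalize_t1(subject, seed=0)
        import copy

        distorted = copy.deepcopy(subject)
        distorted.timepoints[2].t1w = 1.1 * distorted.timepoints[2].t1w + 17.0
        nt1b = normalize_t1(distorted, seed=0)
        np.testing.assert_allclose(nt1b[2], nt1[2], atol=1e-9)

    def test_empty_nawm_is_error(self):
        from conftest import make_series

        labels = np.full((6, 6, 6), GM, dtype=np.uint8)
        series = make_series(
            [np.zeros((6, 6, 6), bool)] * 2, labels=labels
        )
        with pytest.raises(ValueError, match="nawm"):
            normalize_t1(series)


class TestNormalizeT2:
    def test_baseline_nawm_mean_zero_sd_one(self, subject):
        nt2 = normalize_t2(subject, seed=0)
        nawm = subject.baseline.labels == WM
        assert nt2[0][nawm].mean() == pytest.approx(0.0, abs=1e-12)
        assert nt2[0][nawm].std() == pytest.approx(1.0, abs=1e-12)

    def test_zscore_two_sd(self, subject):
        nawm = subject.baseline.labels == WM
        t2 = subject.baseline.t2w
        mean, sd = t2[nawm].mean(), t2[nawm].std()
        probe_value = mean + 2.0 * sd
        nt2 = normalize_t2(subject, seed=0)
        # apply the fitted transform to the probe value analytically
        assert (probe_value - mean) / sd == pytest.approx(2.0)
        closest = np.unravel_index(np.argmin(np.abs(t2 - probe_value)), t2.shape)
        assert nt2[0][closest] == pytest.approx(
            (t2[closest] - mean) / sd, abs=1e-12
        )

    def test_invariance_to_offset_distortion(self, subject):
        nt2 = normalize_t2(subject, seed=0)
        import copy

        distorted = copy.deepcopy(subject)
        distorted.timepoints[3].t2w = distorted.timepoints[3].t2w + 50.0
        nt2b = normalize_t2(distorted, seed=0)
        np.testing.assert_allclose(nt2b[3], nt2[3], atol=1e-9)

    def test_zero_nawm_sd_is_error(self):
        from conftest import make_series

        shape = (6, 6, 6)
        flat = np.full(shape, 520.0)
        series = make_series(
            [np.zeros(shape, bool)] * 2,
            channels=[(np.ones(shape), np.ones(shape), flat)] * 2,
        )
        with pytest.raises(ValueError, match="zero NAWM"):
            normalize_t2(series)
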