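"""Costes threshold search vs exhaustive oracle; Manders coefficient identities."""

import numpy as np
import pytest

import rimtrack as rt
from rimtrack.coloc import MIN_BELOW_PAIRS, orthogonal_regression


def full_roi(shape):
    return rt.RegionOfInterest(np.ones(shape, bool))


def img(values, role="lipid_dye"):
    return rt.Micrograph(pixels=np.asarray(values, dtype=float), channel_role=role)


def brute_force_manders(x, y, t1, t2):
    """Reference tM1/tM2 by explicit per-pixel loops."""
    s1 = s2 = num1 = num2 = 0.0
    for xi, yi in zip(x.ravel(), y.ravel()):
        s1 += xi
        s2 += yi
        if yi > t2:
            num1 += xi
        if xi > t1:
            num2 += yi
    return num1 / s1, num2 / s2


def exhaustive_costes(x, y):
    """Reference search: test every distinct ch1 value as threshold, pick the
    largest with below-pair Pearson r <= 0 (same >= 10-pair rule)."""
    slope, intercept = orthogonal_regression(x, y)
    best = None
    for t1 in np.unique(x):
        below = (x < t1) & (y < slope * t1 + intercept)
        if below.sum() < MIN_BELOW_PAIRS:
            continue
        xb, yb = x[below], y[below]
        if xb.std() == 0 or yb.std() == 0:
            continue
        r = np.corrcoef(xb, yb)[0, 1]
        if r <= 0 and (best is None or t1 > best):
            best = float(t1)
    return slope, intercept, best


class TestOrthogonalRegression:
    def test_exact_linear_relation(self, rng):
        x = rng.uniform(10, 100, size=200)
        y = 2.0 * x
        slope, intercept = orthogonal_regression(x, y)
        assert slope == pytest.approx(2.0)
        assert intercept == pytest.approx(0.0, abs=1e-9)

    def test_constant_channel_rejected(self):
        ch1 = img(np.ones((8, 8)))
        ch2 = img(np.arange(64.0).reshape(8, 8), role="protein")
        with pytest.raises(ValueError, match="channel 1"):
            rt.costes_threshold(ch1, ch2, full_roi((8, 8)))

    def test_tls_symmetric_in_perpendicular_sense(self, rng):
        # for equal-variance noise the TLS slope of y-on-x is the reciprocal
        # of the TLS slope of x-on-y, unlike ordinary least squares
        x = rng.uniform(0, 50, size=500)
        y = 1.7 * x + rng.normal(0, 3, size=500)
        x2 = x + rng.normal(0, 3, size=500)
        s_xy, _ = orthogonal_regression(x2, y)
        s_yx, _ = orthogonal_regression(y, x2)
        assert s_xy == pytest.approx(1.0 / s_yx, rel=1e-9)


class TestCostesSearch:
    def test_anticorrelated_ends_unconverged_at_minimum(self):
        # y = -x + c: the below set (ch1 < T1 AND ch2 < slope*T1 + intercept)
        # is empty at every threshold because the two conditions are
        # complementary, so no r can be computed and the search ends with
        # thresholds at the channel minimum — matching the exhaustive oracle
        rng = np.random.default_rng(0)
        x = rng.uniform(10, 100, size=(8, 8))
        y = -x + 120.0
        res = rt.costes_threshold(img(x), img(y, "protein"), full_roi((8, 8)))
        slope, intercept, best = exhaustive_costes(x.ravel(), y.ravel())
        assert best is None
        assert not res.converged
        assert res.slope == pytest.approx(-1.0)
        assert res.threshold_ch1 == pytest.approx(x.min())

    def test_independent_noise_thresholds_near_minimum(self):
        rng = np.random.default_rng(7)
        x = rng.uniform(0, 100, size=(32, 32))
        y = rng.uniform(0, 100, size=(32, 32))
        res = rt.costes_threshold(img(x), img(y, "protein"), full_roi((32, 32)))
        assert res.converged
        # uncorrelated channels: r <= 0 is hit within the lowest decile
        assert res.threshold_ch1 <= np.quantile(x, 0.9)
        full = rt.colocalize(img(x), img(y, "protein"), full_roi((32, 32)))
        assert 0.0 <= full.tM1 <= 1.0 and 0.0 <= full.tM2 <= 1.0

    def test_threshold_linkage_identity(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 100, size=(16, 16))
        y = 0.5 * x + rng.normal(0, 5, size=(16, 16)).clip(-10, 10) + 20
        res = rt.costes_threshold(img(x), img(y.clip(0), "protein"), full_roi((16, 16)))
        assert res.threshold_ch2 == res.slope * res.threshold_ch1 + res.intercept

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_exhaustive_oracle_on_8x8(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 50, size=(8, 8)).astype(float)
        y = (0.8 * x + rng.integers(0, 30, size=(8, 8))).astype(float)
        res = rt.costes_threshold(img(x), img(y, "protein"), full_roi((8, 8)))
        slope, intercept, best = exhaustive_costes(x.ravel(), y.ravel())
        assert res.slope == pytest.approx(slope)
        if best is None:
            assert not res.converged
        else:
            assert res.converged
            assert res.threshold_ch1 == pytest.approx(best)

    def test_tiny_roi_rejected(self):
        x = np.arange(16.0).reshape(4, 4)
        with pytest.raises(ValueError, match="50"):
            rt.costes_threshold(img(x), img(x, "protein"), full_roi((4, 4)))


class TestManders:
    def test_identical_channels_thresholds_zero(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(1, 10, size=(8, 8))
        tm1, tm2 = rt.manders_coefficients(
            img(x), img(x, "protein"), 0.0, 0.0, full_roi((8, 8))
        )
        assert tm1 == 1.0 and tm2 == 1.0

    def test_disjoint_supports_give_zero(self):
        x = np.zeros((8, 8))
        y = np.zeros((8, 8))
        x[:4] = 5.0
        y[4:] = 5.0
        tm1, tm2 = rt.manders_coefficients(
            img(x), img(y, "protein"), 0.0, 0.0, full_roi((8, 8))
        )
        assert tm1 == 0.0 and tm2 == 0.0

    def test_3x3_worked_instance(self):
        x = np.arange(1.0, 10.0).reshape(3, 3)  # 1..9, total 45
        y = np.zeros((3, 3))
        y.ravel()[::2] = 10.0  # even flat indices
        tm1, tm2 = rt.manders_coefficients(
            img(x), img(y, "protein"), 0.0, 5.0, full_roi((3, 3))
        )
        # ch1 sum where ch2 > 5: pixels 1,3,5,7,9 -> 25
        assert tm1 == pytest.approx(25.0 / 45.0)
        b1, b2 = brute_force_manders(x, y, 0.0, 5.0)
        assert tm1 == pytest.approx(b1) and tm2 == pytest.approx(b2)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        x = rng.integers(0, 40, size=(8, 8)).astype(float)
        y = rng.integers(0, 40, size=(8, 8)).astype(float)
        t1, t2 = rng.uniform(0, 30, size=2)
        tm1, tm2 = rt.manders_coefficients(
            img(x), img(y, "protein"), t1, t2, full_roi((8, 8))
        )
        b1, b2 = brute_force_manders(x, y, t1, t2)
        assert tm1 == pytest.approx(b1) and tm2 == pytest.approx(b2)

    def test_zero_denominator_flagged_nan(self):
        x = np.zeros((8, 8))
        y = np.ones((8, 8))
        tm1, tm2 = rt.manders_coefficients(
            img(x), img(y, "protein"), 0.0, 0.0, full_roi((8, 8))
        )
        assert np.isnan(tm1)
        assert tm2 == 0.0  # no ch1 pixel exceeds its threshold

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(0, 10, size=(12, 12))
        y = rng.uniform(0, 10, size=(12, 12))
        roi = full_roi((12, 12))
        tms = [
            rt.manders_coefficients(img(x), img(y, "protein"), 0.0, t2, roi)[0]
            for t2 in (0.0, 2.0, 5.0, 8.0)
        ]
        assert all(b <= a for a, b in zip(tms, tms[1:]))

    def test_scale_invariance(self):
        rng = np.random.default_rng(6)
        x = rng.uniform(1, 20, size=(10, 10))
        y = rng.uniform(1, 20, size=(10, 10))
        roi = full_roi((10, 10))
        k = 3.5
        tm1, tm2 = rt.manders_coefficients(img(x), img(y, "protein"), 4.0, 7.0, roi)
        sm1, sm2 = rt.manders_coefficients(
            img(k * x), img(y, "protein"), k * 4.0, 7.0, roi
        )
        assert sm1 == pytest.approx(tm1) and sm2 == pytest.approx(tm2)

    def test_joint_rescale_equivariance(self):
        # scaling BOTH channels by k rescales the regression intercept and
        # both thresholds by k and leaves the slope and tM unchanged
        # (one-channel scaling is not an equivariance of orthogonal
        # regression, which is anisotropic by construction)
        rng = np.random.default_rng(8)
        x = rng.uniform(0, 100, size=(16, 16))
        y = 0.6 * x + rng.uniform(0, 20, size=(16, 16))
        roi = full_roi((16, 16))
        res = rt.colocalize(img(x), img(y, "protein"), roi)
        k = 2.0
        scaled = rt.colocalize(img(k * x), img(k * y, "protein"), roi)
        assert scaled.slope == pytest.approx(res.slope)
        assert scaled.intercept == pytest.approx(k * res.intercept)
        assert scaled.threshold_ch1 == pytest.approx(k * res.threshold_ch1)
        assert scaled.threshold_ch2 == pytest.approx(k * res.threshold_ch2)
        assert scaled.tM1 == pytest.approx(res.tM1)
        assert scaled.tM2 == pytest.approx(res.tM2)


class TestRecruitmentTrend:
    def test_tm_rises_from_onset_to_peak(self, default_roi):
        # droplet rims empty at t=0 vs fully decorated at the schedule peak:
        # at a threshold pair held fixed across the two time-points, both
        # Manders coefficients must increase as the rim coat appears
        schedule = rt.protein_schedule("plin2_like")
        params = rt.SceneParams(image_size=(96, 96), seed=77, protein_scale_sd=0.0)
        early = rt.make_droplet_scene(params, schedule, 0.0, roi=default_roi)
        peak = rt.make_droplet_scene(params, schedule, 12.0, roi=default_roi)
        thr1 = (params.cytoplasm_dye_intensity + params.droplet_core_dye_intensity) / 2
        thr2 = (
            params.background_level
            + schedule.cyto_intensity(12.0)
            + schedule.rim_intensity(12.0) / 2
        )
        tm1_e, tm2_e = rt.manders_coefficients(early[0], early[1], thr1, thr2, default_roi)
        tm1_p, tm2_p = rt.manders_coefficients(peak[0], peak[1], thr1, thr2, default_roi)
        assert tm1_p > tm1_e
        assert tm2_p > tm2_e
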