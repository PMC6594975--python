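"""Vector averaging, Hotelling's T², and error-ellipse amplitude bounds."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from freqtag.vecstats import (
    error_ellipse_bounds,
    group_vector_stat,
    hotelling_one_sample,
    hotelling_two_sample,
    vector_average,
)


class TestVectorAverage:
    def test_componentwise_mean(self):
        mr, mi = vector_average([(1, 1), (3, -1)])
        assert (mr, mi) == (2.0, 0.0)
        assert np.hypot(mr, mi) == pytest.approx(2.0)

    def test_antiphase_responses_cancel(self):
        mr, mi = vector_average([(1, 0), (-1, 0)])
        assert np.hypot(mr, mi) == 0.0

    def test_single_response_phase(self):
        mr, mi = vector_average([(0, 2)])
        assert np.angle(complex(mr, mi)) == pytest.approx(np.pi / 2)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            vector_average([])


class TestHotellingOneSample:
    def test_zero_mean_gives_t2_zero_p_one(self):
        res = hotelling_one_sample([(1, 0), (-1, 0), (0, 1), (0, -1)])
        assert res.t_squared == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)
        assert (res.df1, res.df2) == (2, 2)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            hotelling_one_sample([(1, 0), (0, 1)])

    def test_collinear_sample_rejected(self):
        with pytest.raises(ValueError, match="singular|collinear"):
            hotelling_one_sample([(1, 1), (2, 2), (3, 3)])

    def test_matches_independent_implementation(self):
        """Agreement with pingouin's Hotelling test on random datasets."""
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(11)
        for _ in range(100):
            n = rng.integers(5, 30)
            x = rng.standard_normal((n, 2)) + rng.normal(0, 1, 2)
            ours = hotelling_one_sample(x)
            ref = pingouin.multivariate_ttest(x, Y=None)
            assert ours.t_squared == pytest.approx(float(ref["T2"].iloc[0]),
                                                   abs=1e-10, rel=1e-10)
            assert ours.p_value == pytest.approx(float(ref["pval"].iloc[0]),
                                                 abs=1e-10, rel=1e-10)

    def test_type_i_error_calibration_small(self):
        """Null rejection rate near alpha (coarse check; the full-size
        calibration runs in the acceptance suite)."""
        rng = np.random.default_rng(12)
        rejections = sum(
            hotelling_one_sample(rng.standard_normal((15, 2))).p_value < 0.05
            for _ in range(2000))
        assert rejections / 2000 == pytest.approx(0.05, abs=0.015)

    def test_power_monotone_in_effect_size(self):
        """Rejection rate never decreases as the true mean grows."""
        rng = np.random.default_rng(13)
        rates = []
        for mu in [0.0, 0.4, 0.8, 1.6]:
            rej = sum(
                hotelling_one_sample(
                    rng.standard_normal((12, 2)) + [mu, 0]).p_value < 0.05
                for _ in range(400))
            rates.append(rej / 400)
        assert all(b >= a - 0.03 for a, b in zip(rates, rates[1:]))
        assert rates[-1] > 0.95


class TestHotellingTwoSample:
    def test_identical_groups(self):
        rng = np.random.default_rng(14)
        x = rng.standard_normal((8, 2))
        res = hotelling_two_sample(x, x.copy())
        assert res.t_squared == pytest.approx(0.0, abs=1e-10)
        assert res.p_value == pytest.approx(1.0)
        assert (res.df1, res.df2) == (2, 13)

    def test_widely_separated_groups(self):
        rng = np.random.default_rng(15)
        a = rng.standard_normal((10, 2))
        b = rng.standard_normal((10, 2)) + [10.0, 0.0]
        assert hotelling_two_sample(a, b).p_value < 1e-6

    def test_group_order_symmetry(self):
        rng = np.random.default_rng(16)
        a = rng.standard_normal((7, 2))
        b = rng.standard_normal((9, 2)) + [0.5, -0.2]
        r1 = hotelling_two_sample(a, b)
        r2 = hotelling_two_sample(b, a)
        assert r1.p_value == pytest.approx(r2.p_value, abs=1e-12)
        assert r1.t_squared == pytest.approx(r2.t_squared, abs=1e-10)

    def test_matches_independent_implementation(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(17)
        for _ in range(25):
            a = rng.standard_normal((rng.integers(5, 15), 2))
            b = rng.standard_normal((rng.integers(5, 15), 2)) + [0.4, 0.1]
            ours = hotelling_two_sample(a, b)
            ref = pingouin.multivariate_ttest(a, b)
            assert ours.t_squared == pytest.approx(float(ref["T2"].iloc[0]),
                                                   abs=1e-10, rel=1e-10)
            assert ours.p_value == pytest.approx(float(ref["pval"].iloc[0]),
                                                 abs=1e-10, rel=1e-10)


class TestErrorEllipse:
    def _isotropic_sample(self, mean, sigma, n, rng):
        """Sample with exactly isotropic covariance sigma^2 I and exact mean."""
        x = rng.standard_normal((n, 2))
        x = x - x.mean(axis=0)
        # whiten then recolor to exactly sigma^2 I
        cov = np.cov(x, rowvar=False, ddof=1)
        l = np.linalg.cholesky(cov)
        x = x @ np.linalg.inv(l).T * sigma
        return x + np.asarray(mean)

    def test_isotropic_closed_form(self, rng):
        """Circular covariance: bounds are |mean| +/- sigma/sqrt(n)."""
        n, sigma, mean = 12, 0.8, (2.0, 1.0)
        x = self._isotropic_sample(mean, sigma, n, rng)
        lo, hi = error_ellipse_bounds(x)
        r = np.hypot(*mean)
        assert lo == pytest.approx(r - sigma / np.sqrt(n), abs=1e-6)
        assert hi == pytest.approx(r + sigma / np.sqrt(n), abs=1e-6)

    def test_origin_inside_gives_zero_lower_bound(self, rng):
        x = rng.standard_normal((10, 2))
        x = x - x.mean(axis=0)  # mean exactly at the origin
        lo, hi = error_ellipse_bounds(x)
        assert lo == 0.0
        assert hi > 0.0

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 2**32 - 1))
    def test_bounds_bracket_amplitude(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal((rng.integers(4, 20), 2)) + rng.normal(0, 2, 2)
        lo, hi = error_ellipse_bounds(x)
        amp = np.hypot(*x.mean(axis=0))
        assert 0.0 <= lo <= amp + 1e-9
        assert amp <= hi + 1e-9

    @settings(max_examples=20, deadline=None)
    @given(st.integers(0, 2**32 - 1))
    def test_matches_dense_parametrization_oracle(self, seed):
        """Geometric oracle: min/max over 10,000 ellipse points."""
        rng = np.random.default_rng(seed)
        x = rng.standard_normal((10, 2)) * [1.0, 3.0] + rng.normal(0, 2, 2)
        lo, hi = error_ellipse_bounds(x)
        m = x.mean(axis=0)
        s = np.cov(x, rowvar=False, ddof=1) / len(x)
        evals, evecs = np.linalg.eigh(s)
        a = evecs @ np.diag(np.sqrt(evals))
        theta = np.linspace(0, 2 * np.pi, 10_000, endpoint=False)
        pts = m[:, None] + a @ np.vstack([np.cos(theta), np.sin(theta)])
        r = np.hypot(pts[0], pts[1])
        origin_inside = float(m @ np.linalg.solve(s, m)) < 1.0
        assert hi == pytest.approx(r.max(), abs=1e-4)
        assert lo == pytest.approx(0.0 if origin_inside else r.min(), abs=1e-4)


class TestRotationEquivariance:
    @settings(max_examples=20, deadline=None)
    @given(st.integers(0, 2**32 - 1),
           st.floats(-np.pi, np.pi, allow_nan=False))
    def test_statistics_invariant_phase_rotates(self, seed, theta):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal((9, 2)) + [1.5, 0.5]
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        xr = x @ rot.T
        s0 = group_vector_stat(x)
        s1 = group_vector_stat(xr)
        assert s1.t_squared == pytest.approx(s0.t_squared, rel=1e-8, abs=1e-8)
        assert s1.p_value == pytest.approx(s0.p_value, rel=1e-8, abs=1e-10)
        assert s1.amplitude == pytest.approx(s0.amplitude, rel=1e-8)
        assert s1.error_lower == pytest.approx(s0.error_lower, abs=1e-5)
        assert s1.error_upper == pytest.approx(s0.error_upper, abs=1e-5)
        dphase = (s1.phase - s0.phase - theta + np.pi) % (2 * np.pi) - np.pi
        assert dphase == pytest.approx(0.0, abs=1e-8)
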