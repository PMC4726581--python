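"""Experimental variography and model fitting against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import soilbme as sb

from oracles import cross_variogram_pairs, variogram_pairs


def _collinear_samples():
    return sb.PointSamples([[0.0, 0.0], [5.0, 0.0], [10.0, 0.0]], [1.0, 3.0, 5.0])


class TestEmpiricalVariogram:
    def test_hand_enumerated_1d_example(self):
        # pairs at h=5: squared diffs 4 and 4 -> gamma 2; one pair at h=10 -> gamma 8
        emp = sb.empirical_variogram(_collinear_samples(), lag_width=5.0, max_lag=15.0)
        occupied = emp.pair_counts > 0
        assert list(emp.pair_counts[occupied]) == [2, 1]
        assert emp.semivariances[occupied] == pytest.approx([2.0, 8.0], abs=1e-15)

    def test_constant_field_warns_and_is_zero(self):
        s = sb.PointSamples([[0, 0], [5, 0], [0, 5]], [2.0, 2.0, 2.0])
        with pytest.warns(UserWarning, match="identical"):
            emp = sb.empirical_variogram(s, 5.0, 10.0)
        assert np.all(emp.semivariances[emp.pair_counts > 0] == 0.0)

    def test_permutation_invariance(self, rng):
        loc = rng.uniform(0, 30, size=(20, 2))
        val = rng.normal(size=20)
        s1 = sb.PointSamples(loc, val)
        perm = rng.permutation(20)
        s2 = sb.PointSamples(loc[perm], val[perm])
        e1 = sb.empirical_variogram(s1, 3.0, 20.0)
        e2 = sb.empirical_variogram(s2, 3.0, 20.0)
        assert np.array_equal(e1.pair_counts, e2.pair_counts)
        assert np.allclose(e1.semivariances, e2.semivariances, equal_nan=True)

    def test_matches_pair_enumeration_oracle_to_machine_precision(self, rng):
        loc = rng.uniform(0, 35, size=(50, 2))
        val = rng.normal(5, 0.6, size=50)
        emp = sb.empirical_variogram(sb.PointSamples(loc, val), 5.0, 25.0)
        _, gamma, counts = variogram_pairs(loc, val, 5.0, 25.0)
        assert np.array_equal(emp.pair_counts, counts)
        occ = counts > 0
        assert np.allclose(emp.semivariances[occ], gamma[occ], rtol=0, atol=1e-12)


class TestCrossVariogram:
    def test_identity_and_sign_symmetry(self, rng):
        loc = rng.uniform(0, 30, size=(15, 2))
        val = rng.normal(size=15)
        s = sb.PointSamples(loc, val)
        auto = sb.empirical_variogram(s, 4.0, 18.0)
        same = sb.empirical_cross_variogram(s, sb.PointSamples(loc, val), 4.0, 18.0)
        neg = sb.empirical_cross_variogram(s, sb.PointSamples(loc, -val), 4.0, 18.0)
        occ = auto.pair_counts > 0
        assert np.allclose(same.semivariances[occ], auto.semivariances[occ], atol=1e-14)
        assert np.allclose(neg.semivariances[occ], -auto.semivariances[occ], atol=1e-14)

    def test_hand_enumerated_toy(self):
        z = _collinear_samples()
        y = sb.PointSamples(z.locations, [2.0, 2.0, 8.0])
        emp = sb.empirical_cross_variogram(z, y, 5.0, 15.0)
        occ = emp.pair_counts > 0
        # h=5: (2*0 + 2*6)/(2*2) = 3; h=10: (4*6)/2 = 12
        assert emp.semivariances[occ] == pytest.approx([3.0, 12.0], abs=1e-15)

    def test_non_colocated_rejected(self):
        z = _collinear_samples()
        y = sb.PointSamples([[0, 0], [5, 0], [10, 1]], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="co-locat"):
            sb.empirical_cross_variogram(z, y, 5.0, 15.0)

    def test_matches_pair_enumeration_oracle(self, rng):
        loc = rng.uniform(0, 35, size=(50, 2))
        z = rng.normal(size=50)
        y = 0.5 * z + rng.normal(size=50)
        emp = sb.empirical_cross_variogram(
            sb.PointSamples(loc, z), sb.PointSamples(loc, y), 5.0, 25.0
        )
        _, gamma, counts = cross_variogram_pairs(loc, z, y, 5.0, 25.0)
        occ = counts > 0
        assert np.allclose(emp.semivariances[occ], gamma[occ], rtol=0, atol=1e-12)


class TestModelShapes:
    def test_gaussian_closed_form_points(self):
        m = sb.VariogramModel("gaussian", 0.031, 0.411, 32.11)
        assert m.gamma(1e-9) == pytest.approx(0.031, abs=1e-9)
        assert m.gamma(32.11) == pytest.approx(0.031 + 0.411 * (1 - np.exp(-3)), rel=1e-12)

    def test_spherical_sill_and_plateau(self):
        m = sb.VariogramModel("spherical", 0.232, 0.310, 30.59)
        assert m.gamma(30.59) == pytest.approx(m.sill, rel=1e-12)
        assert m.gamma(100.0) == pytest.approx(m.sill, rel=1e-12)
        assert m.covariance(100.0) == pytest.approx(0.0, abs=1e-12)


class TestFitVariogramModel:
    def test_exact_recovery_on_model_curve(self):
        truth = sb.VariogramModel("spherical", 0.031, 0.411, 32.11)
        h = np.arange(2.5, 40, 5.0)
        emp = sb.EmpiricalVariogram(h, truth.gamma(h), np.full(h.size, 50))
        fit = sb.fit_variogram_model(emp, "spherical")
        assert fit.nugget == pytest.approx(0.031, abs=1e-6)
        assert fit.partial_sill == pytest.approx(0.411, abs=1e-6)
        assert fit.range_ == pytest.approx(32.11, abs=1e-4)
        assert fit.fit_r2 == pytest.approx(1.0, abs=1e-9)

    def test_pure_nugget_flagged_not_crashed(self):
        h = np.array([2.5, 7.5, 12.5])
        emp = sb.EmpiricalVariogram(h, np.full(3, 0.4), np.full(3, 20))
        with pytest.warns(UserWarning, match="nugget"):
            fit = sb.fit_variogram_model(emp, "gaussian")
        assert fit.degenerate
        assert fit.sill == pytest.approx(0.4, rel=1e-9)

    def test_noisy_fit_within_grid_search_envelope(self, rng):
        """Fit on a 5%-noise variogram lands inside the envelope of an
        independent coarse grid search over (C0, C, a)."""
        truth = sb.VariogramModel("gaussian", 0.05, 0.40, 18.0)
        h = np.arange(2.5, 25, 2.5)
        g = truth.gamma(h) + rng.normal(0, 0.05 * truth.sill, h.size)
        emp = sb.EmpiricalVariogram(h, g, np.full(h.size, 100))
        fit = sb.fit_variogram_model(emp, "gaussian")

        best, best_sse = None, np.inf
        for c0 in np.linspace(0, 0.2, 21):
            for c in np.linspace(0.1, 0.8, 36):
                for a in np.linspace(4, 30, 53):
                    m = c0 + c * (1 - np.exp(-3 * h**2 / a**2))
                    sse = float(np.sum(100 * (m - g) ** 2))
                    if sse < best_sse:
                        best, best_sse = (c0, c, a), sse
        fit_sse = float(
            np.sum(100 * (sb.VariogramModel("gaussian", fit.nugget, fit.partial_sill, fit.range_).gamma(h) - g) ** 2)
        )
        assert fit_sse <= best_sse + 1e-9  # optimizer at least as good as the grid
        assert abs(fit.range_ - best[2]) < 2.0  # and in the same neighborhood

    def test_translation_invariance(self, rng):
        loc = rng.uniform(0, 30, size=(40, 2))
        val = rng.normal(size=40)
        f1 = sb.fit_variogram_model(
            sb.empirical_variogram(sb.PointSamples(loc, val), 4.0, 20.0), "spherical"
        )
        f2 = sb.fit_variogram_model(
            sb.empirical_variogram(sb.PointSamples(loc + [120.0, -40.0], val), 4.0, 20.0),
            "spherical",
        )
        assert f1.nugget == pytest.approx(f2.nugget, abs=1e-9)
        assert f1.range_ == pytest.approx(f2.range_, abs=1e-7)


class TestNuggetSillRatio:
    @pytest.mark.parametrize(
        "nugget,sill,expect_ratio,expect_class",
        [
            (0.035, 0.436, 0.080, "strong"),
            (0.031, 0.442, 0.070, "strong"),
            (0.181, 0.434, 0.417, "moderate"),
            (0.232, 0.542, 0.428, "moderate"),
            (0.0, 0.436, 0.0, "strong"),
        ],
    )
    def test_published_style_ratios(self, nugget, sill, expect_ratio, expect_class):
        m = sb.VariogramModel("gaussian", nugget, sill - nugget, 20.0)
        ratio, cls = sb.nugget_sill_ratio(m)
        assert round(ratio, 3) == expect_ratio
        assert cls == expect_class


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_variogram_oracle_property(seed):
    """Eq-style estimate equals direct pair enumeration for random layouts."""
    r = np.random.default_rng(seed)
    n = int(r.integers(5, 30))
    loc = r.uniform(0, 20, size=(n, 2))
    val = r.normal(size=n)
    try:
        s = sb.PointSamples(loc, val)
    except ValueError:  # astronomically unlikely duplicate draw
        return
    emp = sb.empirical_variogram(s, 2.0, 15.0)
    _, gamma, counts = variogram_pairs(loc, val, 2.0, 15.0)
    occ = counts > 0
    assert np.array_equal(emp.pair_counts, counts)
    assert np.allclose(emp.semivariances[occ], gamma[occ], atol=1e-12)
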