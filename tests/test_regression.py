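import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from sklearn.base import clone

from assayerror import (
    AssayErrorEquation,
    LeastSquaresAEE,
    SiegelAEE,
    TheilAEE,
    WeightedLeastSquaresAEE,
    fit_algorithm,
    fit_ols_linear,
    fit_ols_poly,
    fit_theil,
    fit_theil_siegel,
    fit_wls_inv_x2,
    make_estimator,
    predict_sd,
)
from assayerror.datamodel import ALGORITHMS
from assayerror.errors import DegenerateDesignError
from assayerror.profiles import PrecisionProfile

from _oracles import brute_ols_poly, brute_siegel, brute_theil, brute_wls
from conftest import random_profile


def _profile(x, sd):
    return PrecisionProfile(tuple(x), tuple(sd), tuple([6] * len(x)))


LINE = _profile([0.0, 1.0, 2.0], [1.0, 2.0, 3.0])
OUTLIER4 = _profile([0.0, 1.0, 2.0, 3.0], [0.0, 1.0, 2.0, 30.0])


class TestFrozenOracles:
    """Expected values computed with the independent brute-force oracles."""

    def test_ols_line_exact(self):
        aee = fit_ols_linear(LINE).aee
        assert aee.c0 == pytest.approx(1.0) and aee.c1 == pytest.approx(1.0)

    def test_ols_outlier_values(self):
        # normal equations on {(0,0),(1,1),(2,2),(3,30)}: Sxy/Sxx = 45.5/5
        aee = fit_ols_linear(OUTLIER4).aee
        assert aee.c1 == pytest.approx(9.1)
        assert aee.c0 == pytest.approx(-5.4)

    def test_theil_outlier_values(self):
        # pairwise slopes {1,1,10,1,14.5,28} -> median 5.5;
        # residuals {0,-4.5,-9,13.5} -> median -2.25
        aee = fit_theil(OUTLIER4).aee
        assert aee.c1 == pytest.approx(5.5)
        assert aee.c0 == pytest.approx(-2.25)

    def test_siegel_rejects_single_outlier(self):
        # per-point slope medians {1,1,1,14.5} -> 1;
        # per-point intercept medians {0,0,0,-13.5} -> 0
        aee = fit_theil_siegel(OUTLIER4).aee
        assert aee.c1 == pytest.approx(1.0)
        assert aee.c0 == pytest.approx(0.0)

    def test_poly2_exact_on_quadratic(self):
        x = [0.0, 1.0, 2.0, 3.0]
        sd = [1 + xi + xi ** 2 for xi in x]
        aee = fit_ols_poly(_profile(x, sd), 2).aee
        assert aee.coefficients == pytest.approx((1.0, 1.0, 1.0, 0.0))

    def test_wls_low_level_dominated(self):
        x, sd = [1.0, 10.0, 100.0], [1.0, 2.0, 13.0]
        aee = fit_wls_inv_x2(_profile(x, sd)).aee
        ref = brute_wls(x, sd, [1.0, 0.01, 0.0001])
        assert aee.c0 == pytest.approx(ref[0], rel=1e-9)
        assert aee.c1 == pytest.approx(ref[1], rel=1e-9)


class TestOracleEquivalence:
    """Vectorized fits agree with exhaustive/brute-force enumeration."""

    @pytest.mark.parametrize("m", [3, 4, 5, 6, 7, 8])
    def test_theil_and_siegel_match_enumeration(self, m):
        rng = np.random.default_rng(100 + m)
        for _ in range(34):  # ~200 cases over the six sizes
            p = random_profile(rng, m)
            t = fit_theil(p).aee
            c0, c1 = brute_theil(p.x, p.sd)
            assert (t.c0, t.c1) == pytest.approx((c0, c1), rel=1e-12, abs=1e-12)
            s = fit_theil_siegel(p).aee
            c0, c1 = brute_siegel(p.x, p.sd)
            assert (s.c0, s.c1) == pytest.approx((c0, c1), rel=1e-12, abs=1e-12)

    @pytest.mark.parametrize("degree", [1, 2, 3])
    def test_least_squares_match_normal_equations(self, degree):
        rng = np.random.default_rng(degree)
        for _ in range(20):
            p = random_profile(rng, 8)
            aee = fit_ols_poly(p, degree).aee if degree > 1 else fit_ols_linear(p).aee
            ref = brute_ols_poly(p.x, p.sd, degree)
            assert np.allclose(aee.coefficients[: degree + 1], ref,
                               rtol=1e-9, atol=1e-9)

    def test_wls_matches_weighted_normal_equations(self):
        rng = np.random.default_rng(77)
        for _ in range(20):
            p = random_profile(rng, 7)
            aee = fit_wls_inv_x2(p).aee
            x = p.x
            w = np.where(x > 0, 1.0 / np.where(x > 0, x, 1) ** 2, 0.0)
            if (x == 0).any():
                w[x == 0] = 1.0 / np.min(x[x > 0]) ** 2
            ref = brute_wls(x, p.sd, w)
            assert np.allclose((aee.c0, aee.c1), ref, rtol=1e-9)

    def test_slopes_agree_with_scipy(self):
        """Dual route: scipy's Theil-Sen slope and Siegel repeated-median
        fit share the slope (and, for Siegel's 'separate' intercept, the
        intercept) conventions implemented here."""
        rng = np.random.default_rng(5)
        for _ in range(10):
            p = random_profile(rng, 8)
            assert fit_theil(p).aee.c1 == pytest.approx(
                stats.theilslopes(p.sd, p.x).slope, rel=1e-12)
            sg = stats.siegelslopes(p.sd, p.x, method="separate")
            aee = fit_theil_siegel(p).aee
            assert aee.c1 == pytest.approx(sg.slope, rel=1e-12)
            assert aee.c0 == pytest.approx(sg.intercept, rel=1e-12)


class TestMedianFitProperties:
    """Hypothesis-driven equivalence with the brute-force enumerations."""

    points = st.lists(
        st.tuples(
            st.floats(0.0, 100.0, allow_nan=False, allow_infinity=False),
            st.floats(0.001, 10.0, allow_nan=False, allow_infinity=False),
        ),
        min_size=3, max_size=7, unique_by=lambda t: t[0],
    )

    @settings(max_examples=80, deadline=None, derandomize=True)
    @given(points)
    def test_theil_and_siegel_equal_bruteforce(self, pts):
        pts.sort(key=lambda t: t[0])
        x = np.array([p[0] for p in pts])
        sd = np.array([p[1] for p in pts])
        profile = _profile(x, sd)
        t = fit_theil(profile).aee
        assert (t.c0, t.c1) == pytest.approx(brute_theil(x, sd),
                                             rel=1e-12, abs=1e-12)
        s = fit_theil_siegel(profile).aee
        assert (s.c0, s.c1) == pytest.approx(brute_siegel(x, sd),
                                             rel=1e-12, abs=1e-12)


class TestInvariants:
    @pytest.mark.parametrize("algorithm", ALGORITHMS)
    def test_exact_on_collinear_profiles(self, algorithm):
        x = np.array([0.0, 0.5, 2.0, 8.0, 20.0, 50.0])
        sd = 0.01 + 0.05 * x
        aee = fit_algorithm(_profile(x, sd), algorithm).aee
        assert aee.c0 == pytest.approx(0.01, abs=1e-9)
        assert aee.c1 == pytest.approx(0.05, abs=1e-9)
        assert abs(aee.c2) < 1e-9 and abs(aee.c3) < 1e-9

    @pytest.mark.parametrize("algorithm", ALGORITHMS)
    def test_scale_equivariance(self, algorithm):
        rng = np.random.default_rng(31)
        p = random_profile(rng, 9)
        k = 3.7
        scaled = PrecisionProfile(p.concentrations,
                                  tuple(k * s for s in p.sds), p.ns)
        a = fit_algorithm(_profile(p.x, p.sd), algorithm).aee
        b = fit_algorithm(scaled, algorithm).aee
        assert np.allclose(np.array(b.coefficients),
                           k * np.array(a.coefficients), rtol=1e-9, atol=1e-12)

    def test_robustness_to_quarter_contamination(self, outlier_profile):
        siegel = fit_theil_siegel(outlier_profile).aee
        ols = fit_ols_linear(outlier_profile).aee
        assert abs(siegel.c1 / 0.05 - 1) < 0.05
        assert abs(ols.c1 / 0.05 - 1) > 0.20


class TestDegenerateDesigns:
    def test_identical_concentrations_rejected(self):
        with pytest.raises(DegenerateDesignError):
            fit_ols_linear(_profile([0.0, 1.0], [0.1, 0.2]))
        with pytest.raises(DegenerateDesignError):
            TheilAEE().fit([[2.0]] * 3, [0.1, 0.2, 0.3])

    def test_poly3_needs_five_points(self):
        p = _profile([0.0, 1.0, 2.0, 3.0], [0.1, 0.2, 0.3, 0.4])
        with pytest.raises(DegenerateDesignError):
            fit_ols_poly(p, 3)

    def test_wls_needs_two_nonzero_levels(self):
        with pytest.raises(DegenerateDesignError):
            WeightedLeastSquaresAEE().fit([[0.0], [0.0], [5.0]],
                                          [0.1, 0.1, 0.3])

    def test_negative_intercept_flagged_not_clamped(self):
        res = fit_ols_linear(OUTLIER4)
        assert res.aee.c0 < 0
        assert any("negative intercept" in n for n in res.notes)


class TestSklearnProtocol:
    def test_clone_and_params_roundtrip(self):
        est = LeastSquaresAEE(degree=2)
        assert clone(est).get_params() == {"degree": 2}
        est.set_params(degree=3)
        assert est.degree == 3
        assert WeightedLeastSquaresAEE(blank_policy="drop").get_params() == {
            "blank_policy": "drop"
        }

    def test_fit_predict_shapes(self):
        est = SiegelAEE().fit(np.array([[0.0], [1.0], [2.0]]),
                              np.array([1.0, 2.0, 3.0]))
        pred = est.predict([[0.5], [1.5]])
        assert pred == pytest.approx([1.5, 2.5])
        assert est.intercept_ == pytest.approx(1.0)
        assert est.coef_[0] == pytest.approx(1.0)

    def test_blank_policy_changes_fit(self):
        p = _profile([0.0, 1.0, 10.0, 100.0], [0.5, 0.06, 0.5, 5.0])
        cap = fit_wls_inv_x2(p, "cap").aee
        drop = fit_wls_inv_x2(p, "drop").aee
        assert cap.c0 != pytest.approx(drop.c0)


class TestPredictSD:
    def test_reference_intercept_at_zero(self):
        aee = AssayErrorEquation("theil_siegel", 0.001459, 0.056877)
        assert predict_sd(aee, 0.0) == pytest.approx(0.001459)

    def test_zero_equation(self):
        aee = AssayErrorEquation("ols_linear", 0.0, 0.0)
        assert predict_sd(aee, 123.4) == 0.0

    def test_cubic_matches_horner(self):
        aee = AssayErrorEquation("ols_poly3", 0.0359, 0.03182,
                                 0.000816, -0.000003368)
        expected = 0.0359 + 0.03182 * 10 + 0.000816 * 100 - 0.000003368 * 1000
        assert predict_sd(aee, 10.0) == pytest.approx(expected, rel=1e-12)

    def test_vectorized(self):
        aee = AssayErrorEquation("theil", 0.1, 0.05)
        out = predict_sd(aee, np.array([0.0, 2.0]))
        assert np.allclose(out, [0.1, 0.2])
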