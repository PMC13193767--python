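import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seedassay import (
    RegressionModel,
    fit_cubic,
    fit_log,
    predict,
    r_squared,
    select_model,
)
from seedassay.exceptions import InsufficientDataError, InvalidParameterError
from seedassay.regression import poly_r2

# The facility's published calibration equations (fitted in a spreadsheet
# to its unrounded cumulative means).
PUBLISHED_CUBIC = (-0.502, 6.0869, -25.309, 122.28)
PUBLISHED_LOG = (-11.42, 101.57)


class TestFitCubic:
    def test_exact_cubic_recovered(self):
        pts = [(x, float(x**3)) for x in range(1, 6)]
        model = fit_cubic(pts)
        assert model.kind == "cubic_poly"
        assert model.coefficients == pytest.approx((1, 0, 0, 0), abs=1e-8)
        assert model.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_facility_means_fit(self, small_pack_points):
        model = fit_cubic(small_pack_points)
        # closed form on 5 equally spaced points: the residual is the
        # projection onto the 4th-difference vector (1,-4,6,-4,1), giving
        # leading coefficient -0.5, constant 122.12 and SSE = 1.96/70
        assert model.coefficients[0] == pytest.approx(-0.5, abs=1e-9)
        assert model.coefficients[3] == pytest.approx(122.12, abs=1e-9)
        y = np.array([p[1] for p in small_pack_points])
        x = np.array([p[0] for p in small_pack_points])
        sse = float(((y - np.polyval(model.coefficients, x)) ** 2).sum())
        assert sse == pytest.approx(1.96 / 70, rel=1e-9)
        assert round(model.r_squared, 4) == 0.9999

    def test_facility_means_near_published_equation(self, small_pack_points):
        # the published coefficients embed unrounded means; 1% relative
        model = fit_cubic(small_pack_points)
        for ours, printed in zip(model.coefficients, PUBLISHED_CUBIC):
            assert ours == pytest.approx(printed, rel=0.01)

    def test_four_points_interpolate_exactly(self):
        pts = [(1, 10.0), (2, 7.0), (3, 9.0), (4, 4.0)]
        model = fit_cubic(pts)
        assert model.r_squared == pytest.approx(1.0, abs=1e-9)
        for x, y in pts:
            assert predict(model, x) == pytest.approx(y, rel=1e-9)

    def test_too_few_distinct_x(self):
        with pytest.raises(InsufficientDataError):
            fit_cubic([(1, 1.0), (2, 2.0), (3, 3.0)])
        with pytest.raises(InsufficientDataError):
            fit_cubic([(1, 1.0), (1, 2.0), (2, 3.0), (2, 4.0)])


class TestFitLog:
    def test_two_points_exact(self):
        model = fit_log([(1, 100.0), (np.e, 90.0)])
        assert model.r_squared == pytest.approx(1.0, abs=1e-12)
        assert model.coefficients == pytest.approx((-10.0, 100.0), rel=1e-9)

    def test_facility_means_fit(self, all_pack_points):
        model = fit_log(all_pack_points)
        # frozen oracle: normal equations on the six printed means
        assert model.coefficients[0] == pytest.approx(-11.404049392525, rel=1e-10)
        assert model.coefficients[1] == pytest.approx(101.560045185897, rel=1e-10)
        assert model.r_squared == pytest.approx(0.985355196788, abs=1e-10)

    def test_facility_means_near_published_equation(self, all_pack_points):
        model = fit_log(all_pack_points)
        assert model.coefficients[0] == pytest.approx(PUBLISHED_LOG[0], rel=0.01)
        assert model.coefficients[1] == pytest.approx(PUBLISHED_LOG[1], rel=0.001)
        assert model.r_squared == pytest.approx(0.9848, abs=0.001)
        assert model.coefficients[0] < 0  # monotone decline in pack size

    def test_domain_and_data_errors(self):
        with pytest.raises(InvalidParameterError):
            fit_log([(0.5, 1.0), (2, 2.0)])
        with pytest.raises(InsufficientDataError):
            fit_log([(3, 1.0), (3, 2.0)])


class TestRSquared:
    def test_perfect_fit(self):
        assert r_squared([1, 2, 3], [1, 2, 3]) == 1.0

    def test_mean_prediction_scores_zero(self):
        assert r_squared([1.0, 2.0, 3.0], [2.0, 2.0, 2.0]) == 0.0

    def test_constant_response_undefined(self):
        with pytest.raises(InvalidParameterError):
            r_squared([5.0, 5.0, 5.0], [5.0, 4.0, 6.0])

    def test_published_cubic_on_the_means(self, small_pack_points):
        x = np.array([p[0] for p in small_pack_points])
        y = np.array([p[1] for p in small_pack_points])
        r2 = r_squared(y, np.polyval(PUBLISHED_CUBIC, x))
        assert r2 == pytest.approx(1 - 0.0331 / 201.29, abs=2e-5)


class TestPredict:
    def test_published_cubic_at_three(self):
        model = RegressionModel("cubic_poly", PUBLISHED_CUBIC, 0.9999, (1, 5))
        assert predict(model, 3) == pytest.approx(87.5811, abs=1e-4)

    def test_published_log_at_one_is_intercept(self):
        model = RegressionModel("log_linear", PUBLISHED_LOG, 0.9848, (1, 20))
        assert predict(model, 1) == PUBLISHED_LOG[1]

    def test_published_log_at_twenty(self):
        model = RegressionModel("log_linear", PUBLISHED_LOG, 0.9848, (1, 20))
        assert predict(model, 20) == pytest.approx(67.3587, abs=1e-4)

    def test_extrapolation_warns_log_below_one_errors(self):
        model = RegressionModel("log_linear", PUBLISHED_LOG, 0.9848, (1, 20))
        with pytest.warns(UserWarning, match="outside the fitted"):
            predict(model, 25)
        with pytest.raises(InvalidParameterError):
            predict(model, 0.5)

    def test_model_serialization_round_trip(self, tmp_path):
        model = RegressionModel("log_linear", PUBLISHED_LOG, 0.9848, (1, 20))
        path = tmp_path / "model.json"
        model.to_json(path)
        assert RegressionModel.from_json(path) == model


class TestSelectModel:
    def test_small_pack_regime_chooses_cubic(self, small_pack_points):
        sel = select_model(small_pack_points)
        assert sel.model.kind == "cubic_poly"
        assert set(sel.r2_by_kind) == {"cubic_poly", "log_linear"}

    def test_large_packs_force_log(self, all_pack_points):
        sel = select_model(all_pack_points)
        assert sel.model.kind == "log_linear"
        # both candidates' goodness of fit is recorded
        assert set(sel.r2_by_kind) == {"cubic_poly", "log_linear"}

    def test_three_points_fall_back_to_log(self):
        sel = select_model([(1, 100.0), (2, 92.0), (3, 88.0)])
        assert sel.model.kind == "log_linear"
        assert "cubic_poly" not in sel.r2_by_kind


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_least_squares_matches_numeric_minimizer(seed):
    """SVD solution agrees with direct numeric minimisation of the SSE."""
    from scipy.optimize import minimize

    rng = np.random.default_rng(seed)
    x = np.sort(rng.uniform(1, 6, 8))
    y = 100 - 5 * x + rng.normal(0, 2, 8)
    model = fit_cubic(list(zip(x, y)))

    design = np.vander(x, 4)

    def sse(beta):
        return float(((y - design @ beta) ** 2).sum())

    def grad(beta):
        return -2.0 * design.T @ (y - design @ beta)

    res = minimize(sse, np.zeros(4), jac=grad, method="BFGS",
                   options={"gtol": 1e-12, "maxiter": 10_000})
    assert np.allclose(model.coefficients, res.x, rtol=1e-6, atol=1e-8)
    assert sse(np.array(model.coefficients)) <= res.fun * (1 + 1e-9) + 1e-12


@pytest.mark.parametrize("seed", [3, 4, 5])
def test_nested_polynomial_r2_monotone(seed):
    rng = np.random.default_rng(seed)
    x = np.arange(1, 9, dtype=float)
    y = 90 - 8 * np.log(x) + rng.normal(0, 1.5, x.size)
    pts = list(zip(x, y))
    r2s = [poly_r2(pts, degree) for degree in (1, 2, 3)]
    assert r2s[0] <= r2s[1] + 1e-12
    assert r2s[1] <= r2s[2] + 1e-12


@pytest.mark.filterwarnings("ignore::UserWarning")
@given(
    st.lists(
        st.tuples(st.floats(1, 30), st.floats(0, 200)),
        min_size=2,
        max_size=2,
        unique_by=lambda p: round(p[0], 6),
    )
)
@settings(deadline=None)
def test_log_fit_interpolates_when_saturated(pts):
    (x1, y1), (x2, y2) = pts
    if abs(np.log(x1) - np.log(x2)) < 1e-3:  # near-singular designs excluded
        return
    model = fit_log(pts)
    assert predict(model, x1) == pytest.approx(y1, rel=1e-6, abs=1e-6)
    assert predict(model, x2) == pytest.approx(y2, rel=1e-6, abs=1e-6)
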