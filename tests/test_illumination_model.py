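"""Shadow geometry, the quadratic illuminance surface, and its OLS fit."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from canopylight.errors import DomainError, SingularDesignError
from canopylight.illumination_model import (
    ExtrapolationWarning,
    LightSample,
    PolyCoefficients,
    StageParams,
    compensation_value,
    design_matrix,
    direct_illuminance,
    fit_polynomial,
    predict_intensity,
    shadow_illuminance,
    shadow_length,
)
from conftest import H_VALUES, ROW_POSITIONS, STAGE_GRID, THETA_VALUES


def poly_oracle(a, h, th, l):
    """Term-by-term loop evaluation of the ten-term quadratic surface."""
    terms = [1.0, h, th, l, h * h, h * th, th * l, th * th, h * l, l * l]
    return sum(ai * t for ai, t in zip(a, terms))


def grid_samples(coeff_vec):
    """Noise-free samples over the full-rank h x theta x l cross product."""
    a = list(coeff_vec)
    return [
        LightSample(h, th, l, poly_oracle(a, h, th, l))
        for h in H_VALUES
        for th in THETA_VALUES
        for l in ROW_POSITIONS
    ]


class TestTrig:
    @pytest.mark.parametrize(
        "E0,theta,expected",
        [
            (1000, 0, 1000.0),
            (1000, 60, 500.0),
            (2000, 33.8, 2000 * math.cos(math.radians(33.8))),
        ],
    )
    def test_direct_illuminance_values(self, E0, theta, expected):
        assert direct_illuminance(E0, theta) == pytest.approx(expected, rel=1e-12)

    def test_direct_illuminance_decreasing_and_linear_in_E0(self):
        thetas = np.linspace(0, 89, 50)
        vals = [direct_illuminance(1.0, t) for t in thetas]
        assert all(a > b for a, b in zip(vals, vals[1:]))
        assert direct_illuminance(7.0, 33.8) == pytest.approx(
            7.0 * direct_illuminance(1.0, 33.8)
        )

    @pytest.mark.parametrize("bad", [(-1, 30), (1000, 90), (1000, -5), (float("nan"), 30)])
    def test_direct_illuminance_domain_errors(self, bad):
        with pytest.raises(DomainError):
            direct_illuminance(*bad)

    @pytest.mark.parametrize(
        "h,theta,mode,expected",
        [
            (100, 45, "as-written", 100.0),
            (0, 30, "as-written", 0.0),
            (113, 27.0, "as-written", 113 * math.tan(math.radians(27.0))),
            (100, 45, "geometric", 100.0),
        ],
    )
    def test_shadow_length_values(self, h, theta, mode, expected):
        assert shadow_length(h, theta, mode) == pytest.approx(expected, rel=1e-12)

    @given(
        h=st.floats(0.1, 500),
        theta=st.floats(1.0, 89.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_shadow_modes_multiply_to_h_squared(self, h, theta):
        # h*tan(theta) * h/tan(theta) == h^2 cross-checks both modes
        prod = shadow_length(h, theta, "as-written") * shadow_length(h, theta, "geometric")
        assert prod == pytest.approx(h * h, rel=1e-9)

    def test_shadow_length_rejects_unknown_mode(self):
        with pytest.raises(DomainError):
            shadow_length(10, 30, "sideways")

    @pytest.mark.parametrize(
        "E0,theta,Df,alpha,f,expected",
        [
            (1000, 60, 0.0, 0.0, 0.0, 500.0),
            (1000, 1e-9, 0.1, 0.1, 0.0, 1200.0),
            (1000, 60, 0.15, 0.1, 0.2, 550.0),
        ],
    )
    def test_shadow_illuminance(self, E0, theta, Df, alpha, f, expected):
        stage = StageParams(
            height_difference_cm=100,
            solar_elevation_deg=theta,
            direct_solar_intensity=E0,
            diffuse_coefficient=Df,
            reflectance=alpha,
        )
        assert shadow_illuminance(stage, f) == pytest.approx(expected, rel=1e-6)


class TestPredict:
    def test_intercept_only_is_constant(self):
        c = PolyCoefficients((7.5,) + (0.0,) * 9)
        for h, th, l in [(0, 10, 30), (113, 27, 180), (50, 45, 90)]:
            assert predict_intensity(c, h, th, l) == 7.5

    def test_all_zero_coefficients(self):
        c = PolyCoefficients((0.0,) * 10)
        assert predict_intensity(c, 113, 27.0, 90) == 0.0

    def test_published_vector_matches_term_by_term_oracle(self, coeffs):
        got = predict_intensity(coeffs, 113, 27.0, 30)
        assert got == pytest.approx(poly_oracle(coeffs.values, 113, 27.0, 30), rel=1e-12)

    def test_matches_loop_oracle_on_random_inputs(self, coeffs, rng):
        h = rng.uniform(0, 150, 1000)
        th = rng.uniform(5, 85, 1000)
        l = rng.uniform(30, 180, 1000)
        got = predict_intensity(coeffs, h, th, l)
        want = np.array(
            [poly_oracle(coeffs.values, *xyz) for xyz in zip(h, th, l)]
        )
        scale = np.maximum(np.abs(want), 1.0)
        assert np.max(np.abs(got - want) / scale) < 1e-9

    def test_extrapolation_warning_outside_calibrated_range(self, coeffs):
        with pytest.warns(ExtrapolationWarning):
            predict_intensity(coeffs, 113, 27.0, 10)
        with pytest.warns(ExtrapolationWarning):
            predict_intensity(coeffs, 113, 27.0, 200)

    def test_coefficients_require_ten_finite_entries(self):
        with pytest.raises(DomainError):
            PolyCoefficients((1.0,) * 9)
        with pytest.raises(DomainError):
            PolyCoefficients((float("inf"),) + (0.0,) * 9)

    def test_coefficient_dict_round_trip_is_exact(self, coeffs):
        assert PolyCoefficients.from_dict(coeffs.to_dict()).values == coeffs.values


class TestCompensationValue:
    def test_delta_90_kills_everything(self, coeffs):
        stage = StageParams(113, 27.0, planting_direction_deg=90.0)
        assert compensation_value(coeffs, stage, 90) == pytest.approx(0.0, abs=1e-6)

    def test_reduces_to_prediction_when_unit_scale(self, coeffs):
        stage = StageParams(
            113, 27.0, planting_direction_deg=0.0, direct_solar_intensity=1.0,
            diffuse_coefficient=0.0, reflectance=0.0,
        )
        assert compensation_value(coeffs, stage, 90) == pytest.approx(
            predict_intensity(coeffs, 113, 27.0, 90), rel=1e-12
        )

    def test_matches_hand_composed_formula(self, coeffs):
        stage = StageParams(
            113, 27.0, planting_direction_deg=0.0, direct_solar_intensity=1.0,
            diffuse_coefficient=0.15, reflectance=0.1,
        )
        want = (poly_oracle(coeffs.values, 113, 27.0, 90) + 0.15 + 0.1) * 1.0 * math.cos(0.0)
        assert compensation_value(coeffs, stage, 90) == pytest.approx(want, rel=1e-12)

    def test_linear_in_E0(self, coeffs):
        kwargs = dict(diffuse_coefficient=0.15, reflectance=0.1)
        s1 = StageParams(113, 27.0, 10.0, direct_solar_intensity=1.0, **kwargs)
        s3 = StageParams(113, 27.0, 10.0, direct_solar_intensity=3.0, **kwargs)
        assert compensation_value(coeffs, s3, 60) == pytest.approx(
            3.0 * compensation_value(coeffs, s1, 60), rel=1e-12
        )


class TestFit:
    def test_recovers_published_vector_from_noise_free_grid(self, coeffs):
        result = fit_polynomial(grid_samples(coeffs.values))
        got = np.array(result.coefficients.values)
        want = coeffs.as_array()
        assert np.max(np.abs((got - want) / want)) < 1e-6
        assert result.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_recovers_random_vectors_on_full_rank_grid(self, rng):
        for _ in range(5):
            a = rng.uniform(-100, 100, 10)
            a[np.abs(a) < 1e-3] = 1.0  # keep relative error meaningful
            result = fit_polynomial(grid_samples(a))
            got = np.array(result.coefficients.values)
            assert np.max(np.abs((got - a) / a)) < 1e-6

    def test_constant_response_gives_pure_intercept(self):
        result = fit_polynomial(grid_samples([4.25] + [0.0] * 9))
        vals = result.coefficients.values
        assert vals[0] == pytest.approx(4.25, rel=1e-9)
        assert np.max(np.abs(vals[1:])) < 1e-9

    def test_noisy_fit_r2_below_one_and_error_shrinks_with_n(self, coeffs, rng):
        errors = []
        for n in (30, 300, 3000):
            h = rng.uniform(0, 150, n)
            th = rng.uniform(5, 85, n)
            l = rng.uniform(30, 180, n)
            X = design_matrix(h, th, l)
            y = X @ coeffs.as_array() + rng.normal(0, 1000.0, n)
            samples = [LightSample(*row, yi) for row, yi in zip(zip(h, th, l), y)]
            result = fit_polynomial(samples)
            assert result.r_squared < 1.0
            got = np.array(result.coefficients.values)
            errors.append(np.linalg.norm(got - coeffs.as_array()))
        assert errors[2] < errors[0]

    def test_underdetermined_raises_singular_design(self):
        samples = grid_samples([1.0] * 10)[:9]
        with pytest.raises(SingularDesignError):
            fit_polynomial(samples)

    def test_rank_deficient_design_names_columns(self):
        # a single stage: h and theta are constant, so 1, h, theta, h^2,
        # h*theta, theta^2 are collinear and h*l/theta*l collapse onto l
        samples = [
            LightSample(113, 27.0, l, 5.0 * l) for l in range(30, 190, 10)
        ]
        with pytest.raises(SingularDesignError) as exc:
            fit_polynomial(samples)
        assert len(exc.value.deficient_columns) >= 1
        assert all(name for name in exc.value.column_names)


class TestStageParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"height_difference_cm": -1, "solar_elevation_deg": 30},
            {"height_difference_cm": 5, "solar_elevation_deg": 0},
            {"height_difference_cm": 5, "solar_elevation_deg": 95},
            {"height_difference_cm": 5, "solar_elevation_deg": 30, "diffuse_coefficient": 1.5},
            {"height_difference_cm": 5, "solar_elevation_deg": 30, "direct_solar_intensity": 0},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(DomainError):
            StageParams(**kwargs)

    def test_shipped_stage_table(self, stages):
        observed = {
            (s.height_difference_cm, s.solar_elevation_deg) for s in stages.values()
        }
        assert observed == set(STAGE_GRID)
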