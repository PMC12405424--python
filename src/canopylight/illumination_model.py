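"""Shadow-geometry physics and the quadratic illuminance regression.

The scene is a tall/short strip-intercropping canopy: a taller crop strip
(maize) shades an adjacent shorter strip (soybean).  The illuminance that
reaches the top of the shorter canopy is modelled in two complementary
ways:

* simple physical identities for direct, diffuse and reflected light as a
  function of the solar elevation angle and the canopy height difference;
* an empirical degree-2 polynomial in ``(h, theta, l)`` — height difference
  (cm), solar elevation angle (degrees) and position across the shaded
  strip (cm) — fitted to illuminometer readings by ordinary least squares.

The polynomial is the component the column-wise image compensation
(:mod:`canopylight.icnet`) consumes: it predicts a target intensity for
every image column.

Angle convention: every public function takes angles in **degrees** and
converts to radians only inside trigonometric calls.  The published
regression coefficients are meaningful only with degree-valued angles, so
the regression surface never converts at all — ``theta`` enters the
polynomial numerically as printed in the field tables.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import scipy.linalg

from .errors import DomainError, SingularDesignError

#: Names of the ten polynomial terms, in the fixed design-matrix order.
TERM_NAMES = ("1", "h", "theta", "l", "h^2", "h*theta", "theta*l", "theta^2", "h*l", "l^2")

#: Calibrated range of the strip-position coordinate l (cm); predictions
#: outside it are extrapolations and trigger a warning.
L_CALIBRATED_RANGE = (30.0, 180.0)


class ExtrapolationWarning(UserWarning):
    """Prediction requested outside the calibrated strip-position range."""


@dataclass(frozen=True)
class StageParams:
    """Physical scene parameters for one growth stage.

    Parameters
    ----------
    height_difference_cm:
        Vertical distance h between the tall and short canopy tops (cm).
    solar_elevation_deg:
        Solar elevation angle theta, degrees above the horizon.
    planting_direction_deg:
        Angle delta between the planting direction and the north–south
        axis, degrees.
    direct_solar_intensity:
        Direct-beam intensity E0 in instrument units.
    diffuse_coefficient:
        Fraction Df of total radiation arriving as scattered skylight
        (0.1–0.2 on a clear day).
    reflectance:
        Fraction alpha reflected from the adjacent crop strip (0.1 for a
        soybean row).
    """

    height_difference_cm: float
    solar_elevation_deg: float
    planting_direction_deg: float = 0.0
    direct_solar_intensity: float = 1.0
    diffuse_coefficient: float = 0.15
    reflectance: float = 0.1

    def __post_init__(self):
        if not math.isfinite(self.height_difference_cm) or self.height_difference_cm < 0:
            raise DomainError("height_difference_cm must be finite and >= 0")
        if not 0.0 < self.solar_elevation_deg < 90.0:
            raise DomainError("solar_elevation_deg must lie in (0, 90)")
        if not math.isfinite(self.planting_direction_deg):
            raise DomainError("planting_direction_deg must be finite")
        if not self.direct_solar_intensity > 0:
            raise DomainError("direct_solar_intensity must be > 0")
        if not 0.0 <= self.diffuse_coefficient <= 1.0:
            raise DomainError("diffuse_coefficient must lie in [0, 1]")
        if not 0.0 <= self.reflectance <= 1.0:
            raise DomainError("reflectance must lie in [0, 1]")


@dataclass(frozen=True)
class PolyCoefficients:
    """The ten coefficients a0..a9 of the quadratic illuminance surface.

    Term order is fixed: ``(1, h, theta, l, h^2, h*theta, theta*l,
    theta^2, h*l, l^2)``.
    """

    values: tuple

    def __post_init__(self):
        vals = tuple(float(v) for v in self.values)
        if len(vals) != 10:
            raise DomainError(f"expected exactly 10 coefficients, got {len(vals)}")
        if not all(math.isfinite(v) for v in vals):
            raise DomainError("coefficients must all be finite")
        object.__setattr__(self, "values", vals)

    @classmethod
    def from_sequence(cls, seq: Iterable[float]) -> "PolyCoefficients":
        return cls(tuple(seq))

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)

    def to_dict(self) -> dict:
        return {f"a{i}": v for i, v in enumerate(self.values)}

    @classmethod
    def from_dict(cls, d: dict) -> "PolyCoefficients":
        try:
            return cls(tuple(d[f"a{i}"] for i in range(10)))
        except KeyError as exc:
            raise DomainError(f"missing coefficient key {exc}") from exc


@dataclass(frozen=True)
class LightSample:
    """One illuminometer reading: intensity at position l for a stage."""

    height_difference_cm: float
    solar_elevation_deg: float
    position_cm: float
    intensity: float

    def __post_init__(self):
        if not self.position_cm > 0:
            raise DomainError("position_cm must be > 0")
        if not math.isfinite(self.intensity):
            raise DomainError("intensity must be finite")


@dataclass(frozen=True)
class FitResult:
    """Outcome of an ordinary-least-squares fit of the quadratic surface."""

    coefficients: PolyCoefficients
    r_squared: float
    residual_sd: float
    n_samples: int


def _check_finite_scalar(name: str, x: float) -> float:
    x = float(x)
    if not math.isfinite(x):
        raise DomainError(f"{name} must be finite")
    return x


def direct_illuminance(E0: float, theta_deg: float) -> float:
    """Direct-beam illuminance E = E0 * cos(theta).

    ``theta_deg`` is the solar elevation angle in degrees.  The cosine
    form is the model as published for this scene; it is decreasing in
    theta on [0, 90).
    """
    E0 = _check_finite_scalar("E0", E0)
    theta_deg = _check_finite_scalar("theta_deg", theta_deg)
    if E0 <= 0:
        raise DomainError("E0 must be > 0")
    if not 0.0 <= theta_deg < 90.0:
        raise DomainError("theta_deg must lie in [0, 90)")
    return E0 * math.cos(math.radians(theta_deg))


def shadow_length(h_cm: float, theta_deg: float, mode: str = "as-written") -> float:
    """Length of the shadow cast by a canopy step of height ``h_cm``.

    ``mode="as-written"`` returns ``h * tan(theta)``, the published form.
    ``mode="geometric"`` returns ``h / tan(theta)``, the standard
    flat-ground shadow of a vertical edge under elevation angle theta.
    The two modes multiply to ``h**2`` for any theta, which tests exploit
    as a cross-check.
    """
    h_cm = _check_finite_scalar("h_cm", h_cm)
    theta_deg = _check_finite_scalar("theta_deg", theta_deg)
    if h_cm < 0:
        raise DomainError("h_cm must be >= 0")
    if not 0.0 < theta_deg < 90.0:
        raise DomainError("theta_deg must lie in (0, 90)")
    if mode == "as-written":
        return h_cm * math.tan(math.radians(theta_deg))
    if mode == "geometric":
        t = math.tan(math.radians(theta_deg))
        if t == 0.0:
            raise DomainError("theta_deg = 0 gives an infinite geometric shadow")
        return h_cm / t
    raise DomainError(f"unknown mode {mode!r}; expected 'as-written' or 'geometric'")


def shadow_illuminance(stage: StageParams, f_value: float = 0.0) -> float:
    """Illuminance in the shaded strip: E0*(cos theta - f) + E0*Df + E0*alpha.

    ``f_value`` is the shading-attenuation term f(h, d).  Its functional
    form is not specified by the model, so the caller supplies its value
    directly (default 0, i.e. no geometric attenuation); in the image
    pipeline the fitted polynomial supersedes this identity anyway.
    """
    f_value = _check_finite_scalar("f_value", f_value)
    E0 = stage.direct_solar_intensity
    cos_t = math.cos(math.radians(stage.solar_elevation_deg))
    return E0 * (cos_t - f_value) + E0 * stage.diffuse_coefficient + E0 * stage.reflectance


def design_matrix(h, theta_deg, l_cm) -> np.ndarray:
    """Ten-column quadratic design matrix in the fixed term order.

    Inputs broadcast against each other; the result has shape
    ``(n, 10)`` with columns ``(1, h, theta, l, h^2, h*theta, theta*l,
    theta^2, h*l, l^2)``.
    """
    h, theta_deg, l_cm = np.broadcast_arrays(
        np.asarray(h, dtype=float),
        np.asarray(theta_deg, dtype=float),
        np.asarray(l_cm, dtype=float),
    )
    cols = [
        np.ones_like(h),
        h,
        theta_deg,
        l_cm,
        h * h,
        h * theta_deg,
        theta_deg * l_cm,
        theta_deg * theta_deg,
        h * l_cm,
        l_cm * l_cm,
    ]
    return np.stack([c.ravel() for c in cols], axis=1)


def predict_intensity(coeffs: PolyCoefficients, h_cm, theta_deg, l_cm):
    """Evaluate the quadratic illuminance surface at ``(h, theta, l)``.

    theta is in degrees and enters the polynomial numerically (no radian
    conversion).  Accepts scalars or arrays (broadcast); returns a scalar
    for scalar input, otherwise an array.  Positions outside the
    calibrated range ``L_CALIBRATED_RANGE`` raise
    :class:`ExtrapolationWarning` but are still evaluated.
    """
    arrs = [np.asarray(x, dtype=float) for x in (h_cm, theta_deg, l_cm)]
    if any(not np.all(np.isfinite(a)) for a in arrs):
        raise DomainError("h_cm, theta_deg and l_cm must all be finite")
    lo, hi = L_CALIBRATED_RANGE
    l_arr = arrs[2]
    if np.any(l_arr < lo) or np.any(l_arr > hi):
        warnings.warn(
            f"position l outside the calibrated range [{lo:g}, {hi:g}] cm; "
            "the polynomial is extrapolating",
            ExtrapolationWarning,
            stacklevel=2,
        )
    X = design_matrix(*arrs)
    y = X @ coeffs.as_array()
    shape = np.broadcast_shapes(*(a.shape for a in arrs))
    if shape == ():
        return float(y[0])
    return y.reshape(shape)


def compensation_value(coeffs: PolyCoefficients, stage: StageParams, l_cm):
    """Planting-direction-adjusted compensation value Ed.

    ``Ed = (y(h, theta, l) + Df + alpha) * E0 * cos(delta)`` with delta the
    angle between the planting direction and the north–south axis, in
    degrees.  The sum of a model intensity with the dimensionless Df and
    alpha is reproduced exactly as published (the quantity is used only
    ever as a relative compensation scale).  Linear in E0.
    """
    y = predict_intensity(
        coeffs, stage.height_difference_cm, stage.solar_elevation_deg, l_cm
    )
    scale = stage.direct_solar_intensity * math.cos(
        math.radians(stage.planting_direction_deg)
    )
    return (y + stage.diffuse_coefficient + stage.reflectance) * scale


def fit_polynomial(samples: Sequence[LightSample]) -> FitResult:
    """Ordinary-least-squares fit of the ten-term quadratic surface.

    Solves ``min ||X a - y||`` on the column-normalized design (the raw
    columns span eight orders of magnitude, so normalization keeps the
    solve well conditioned without changing the solution).  Rank
    deficiency is a hard error naming the non-identifiable terms, never a
    silent pseudo-inverse.

    Returns the coefficients, R^2 = 1 - SS_res/SS_tot, the residual
    standard deviation (SS_res / (n - 10), square-rooted) and n.
    """
    samples = list(samples)
    n = len(samples)
    if n < 10:
        raise SingularDesignError(range(10), TERM_NAMES)
    h = np.array([s.height_difference_cm for s in samples], dtype=float)
    th = np.array([s.solar_elevation_deg for s in samples], dtype=float)
    l = np.array([s.position_cm for s in samples], dtype=float)
    y = np.array([s.intensity for s in samples], dtype=float)
    X = design_matrix(h, th, l)

    # Rank-revealing QR with column pivoting: trailing near-zero diagonal
    # entries of R identify the deficient pivot columns by name.
    norms = np.linalg.norm(X, axis=0)
    Xn = X / norms  # l > 0 and the intercept guarantee nonzero norms
    _, R, piv = scipy.linalg.qr(Xn, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = max(X.shape) * np.finfo(float).eps * diag.max()
    deficient = [piv[i] for i in range(10) if diag[i] <= tol]
    if deficient:
        deficient = sorted(deficient)
        raise SingularDesignError(deficient, [TERM_NAMES[i] for i in deficient])

    beta_n, _, _, _ = np.linalg.lstsq(Xn, y, rcond=None)
    beta = beta_n / norms
    resid = y - X @ beta
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0.0 else 1.0 - ss_res / ss_tot
    r2 = min(max(r2, 0.0), 1.0)
    dof = n - 10
    residual_sd = math.sqrt(ss_res / dof) if dof > 0 else float("nan")
    return FitResult(
        coefficients=PolyCoefficients(tuple(beta)),
        r_squared=r2,
        residual_sd=residual_sd,
        n_samples=n,
    )
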