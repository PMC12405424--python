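"""Synthetic canopy scenes and illuminometer tables.

No field imagery or raw light measurements are publicly deposited for
this cropping system, so the test and evaluation harness runs on
generated analogs:

* ``generate_measurements`` draws noisy illuminometer readings from the
  quadratic illuminance surface, for exercising the regression fit;
* ``generate_canopy_image`` builds a green-dominant canopy-like texture
  (uniformly lit ground truth) and a shaded copy whose left-to-right
  brightness gradient follows the same illuminance model, so an
  enhancement can be scored against a known truth.

Shading is multiplicative on the texture (image = reflectance x
illumination, the Retinex image-formation model).  Because the model's
instrument-unit intensities have no absolute mapping onto 8-bit pixels,
the per-column shading field is the model profile affinely rescaled so
the brightest column keeps factor 1.0 and the darkest gets
``shade_floor``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import DomainError
from .icnet import column_positions, round_half_away
from .illumination_model import (
    LightSample,
    PolyCoefficients,
    StageParams,
    predict_intensity,
)

#: Unshaded texture channel means (R, G, B): green-dominant canopy.
TEXTURE_MEANS = (140.0, 190.0, 120.0)
#: Coarse canopy-structure layer: Gaussian-smoothed noise sigma (px) and sd.
COARSE_SIGMA, COARSE_SD = 25.0, 18.0
#: Fine leaf-speckle layer.
FINE_SIGMA, FINE_SD = 2.0, 10.0


@dataclass(frozen=True)
class SceneSpec:
    """Parameters for one synthetic shaded-canopy scene."""

    width: int
    height: int
    stage: StageParams
    coeffs: PolyCoefficients
    texture_seed: int = 0
    shade_floor: float = 0.6
    noise_sd: float = 0.0

    def __post_init__(self):
        if self.width < 2 or self.height < 1:
            raise DomainError("scene needs width >= 2 and height >= 1")
        if not 0.0 < self.shade_floor <= 1.0:
            raise DomainError("shade_floor must lie in (0, 1]")
        if self.noise_sd < 0:
            raise DomainError("noise_sd must be >= 0")


@dataclass(frozen=True)
class CanopyScene:
    """Generated scene: shaded image, uniformly lit truth, shading field."""

    shaded: np.ndarray
    ground_truth: np.ndarray
    shading_field: np.ndarray
    #: True when the shading field never decreases left to right.
    shading_monotone: bool = field(default=False)

    def __iter__(self):
        return iter((self.shaded, self.ground_truth, self.shading_field))


def generate_measurements(
    coeffs: PolyCoefficients,
    stages: Sequence[StageParams],
    positions_cm: Sequence[float],
    noise_sd: float = 0.0,
    n_reps: int = 1,
    seed: int = 0,
) -> List[LightSample]:
    """Noisy illuminometer table drawn from the quadratic surface.

    For every stage x position, ``n_reps`` readings are drawn as the
    model value plus i.i.d. Gaussian noise with standard deviation
    ``noise_sd`` (instrument units).  Reproducible under ``seed``;
    ``noise_sd=0`` returns exact model values.
    """
    if len(stages) == 0:
        raise DomainError("stages must be non-empty")
    if len(positions_cm) == 0:
        raise DomainError("positions_cm must be non-empty")
    if n_reps < 1:
        raise DomainError("n_reps must be >= 1")
    if noise_sd < 0:
        raise DomainError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    samples: List[LightSample] = []
    for stage in stages:
        for l in positions_cm:
            y = predict_intensity(
                coeffs, stage.height_difference_cm, stage.solar_elevation_deg, l
            )
            for _ in range(n_reps):
                noise = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
                samples.append(
                    LightSample(
                        height_difference_cm=stage.height_difference_cm,
                        solar_elevation_deg=stage.solar_elevation_deg,
                        position_cm=float(l),
                        intensity=float(y + noise),
                    )
                )
    return samples


def _texture(height: int, width: int, rng: np.random.Generator) -> np.ndarray:
    """Green-dominant canopy-like texture, float, clipped to [0, 255].

    Two seeded smoothed-noise layers shared across channels: a coarse
    layer for canopy-scale structure and a fine layer for leaf speckle,
    added to fixed green-dominant channel means.
    """
    coarse = gaussian_filter(rng.normal(0.0, 1.0, (height, width)), COARSE_SIGMA)
    std = coarse.std()
    if std > 0:
        coarse *= COARSE_SD / std
    fine = gaussian_filter(rng.normal(0.0, 1.0, (height, width)), FINE_SIGMA)
    std = fine.std()
    if std > 0:
        fine *= FINE_SD / std
    tex = np.empty((height, width, 3))
    for c, mean in enumerate(TEXTURE_MEANS):
        tex[..., c] = mean + coarse + fine
    return np.clip(tex, 0.0, 255.0)


def generate_canopy_image(spec: SceneSpec) -> CanopyScene:
    """Build a shaded canopy image plus its uniformly lit ground truth.

    The ground truth is a seeded pseudo-random texture whose green
    channel mean strictly exceeds the red and blue means.  The shading
    field evaluates the illuminance model per column (positions 30–180
    cm left to right) and affinely rescales it to ``[shade_floor, 1]``;
    the shaded image is ``round(truth * field)`` per column, plus
    optional Gaussian pixel noise, clipped to [0, 255].

    With ``shade_floor = 1`` and ``noise_sd = 0`` the shaded image is
    bit-identical to the ground truth.
    """
    rng = np.random.default_rng(spec.texture_seed)
    truth_f = round_half_away(_texture(spec.height, spec.width, rng))
    truth = np.clip(truth_f, 0, 255).astype(np.uint8)

    positions = column_positions(spec.width)
    y = np.asarray(
        predict_intensity(
            spec.coeffs,
            spec.stage.height_difference_cm,
            spec.stage.solar_elevation_deg,
            positions,
        ),
        dtype=float,
    )
    span = y.max() - y.min()
    if span > 0:
        field_vals = spec.shade_floor + (1.0 - spec.shade_floor) * (y - y.min()) / span
    else:
        field_vals = np.ones_like(y)  # flat model profile: no shading
    monotone = bool(np.all(np.diff(field_vals) >= 0))

    shaded_f = truth.astype(float) * field_vals[np.newaxis, :, np.newaxis]
    if spec.noise_sd > 0:
        shaded_f = shaded_f + rng.normal(0.0, spec.noise_sd, shaded_f.shape)
    shaded = np.clip(round_half_away(shaded_f), 0, 255).astype(np.uint8)
    return CanopyScene(
        shaded=shaded,
        ground_truth=truth,
        shading_field=field_vals,
        shading_monotone=monotone,
    )
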