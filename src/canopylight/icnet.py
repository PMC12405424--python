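"""Column-wise illumination compensation for shaded canopy strips.

The algorithm assumes a fixed orientation: image column 0 is the edge of
the short-crop strip nearest the tall crop (south, shaded) and the last
column the far (north, bright) edge.  Each column is assigned a physical
strip position l, the regression surface predicts the illuminance the
column received, and the column's pixels are multiplied by a clamped
ratio of a reference illuminance to that prediction:

    ratio_c = clamp(reference / target_c, 0.5, 1.2)

so columns predicted darker than the reference are brightened and
brighter ones dimmed, with the clamp preventing runaway correction.  The
same scalar multiplies R, G and B, which preserves hue for pixels that do
not clip.  After scaling, values are rounded half-away-from-zero and
clipped to the 8-bit display range.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple, Union

import numpy as np

from .errors import DomainError
from .illumination_model import PolyCoefficients, StageParams, predict_intensity

DEFAULT_CLAMP = (0.5, 1.2)
DEFAULT_L_RANGE = (30.0, 180.0)


@dataclass(frozen=True)
class ColumnIlluminationProfile:
    """Audit record of one compensation run.

    ``positions_cm`` maps each pixel column to its strip position l;
    ``targets`` is the model-predicted illuminance per column;
    ``reference`` the scalar the columns are aligned to; ``ratios`` the
    clamped per-column multipliers actually applied.
    """

    positions_cm: np.ndarray
    targets: np.ndarray
    reference: float
    ratios: np.ndarray


def validate_image(image: np.ndarray) -> np.ndarray:
    """Check an (H, W, 3) 8-bit RGB raster and return it as uint8."""
    arr = np.asarray(image)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise DomainError(f"expected an (H, W, 3) raster, got shape {arr.shape}")
    if arr.shape[0] < 1 or arr.shape[1] < 2:
        raise DomainError("image must have height >= 1 and width >= 2")
    if arr.dtype != np.uint8:
        if np.any(arr < 0) or np.any(arr > 255):
            raise DomainError("pixel values must lie in [0, 255]")
        arr = arr.astype(np.uint8)
    return arr


def round_half_away(x: np.ndarray) -> np.ndarray:
    """Round half away from zero (ties at .5 go up in magnitude).

    numpy's ``rint`` rounds half to even; a fixed half-away rule keeps
    enhanced images bit-reproducible across platforms and libraries.
    """
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def column_positions(
    width: int, l_min: float = DEFAULT_L_RANGE[0], l_max: float = DEFAULT_L_RANGE[1]
) -> np.ndarray:
    """Linear map from pixel columns to strip positions l (cm), inclusive.

    Column 0 maps to ``l_min`` and the last column to ``l_max``; the
    defaults span the instrumented rows (30–180 cm).
    """
    if width < 2:
        raise DomainError("width must be >= 2")
    if not l_min < l_max:
        raise DomainError("l_min must be < l_max")
    return np.linspace(l_min, l_max, int(width))


def compute_ratios(
    targets: np.ndarray,
    reference: float,
    clamp_lo: float = DEFAULT_CLAMP[0],
    clamp_hi: float = DEFAULT_CLAMP[1],
) -> np.ndarray:
    """Clamped per-column adjustment ratios reference/target.

    All targets and the reference must be strictly positive; columns
    predicted dimmer than the reference receive ratios above 1
    (brightening) up to ``clamp_hi``, brighter columns ratios below 1
    down to ``clamp_lo``.
    """
    targets = np.asarray(targets, dtype=float)
    if not np.all(np.isfinite(targets)) or np.any(targets <= 0):
        raise DomainError("all targets must be finite and > 0")
    if not (np.isfinite(reference) and reference > 0):
        raise DomainError("reference must be finite and > 0")
    if not clamp_lo < clamp_hi:
        raise DomainError("clamp_lo must be < clamp_hi")
    return np.clip(reference / targets, clamp_lo, clamp_hi)


def apply_compensation(image: np.ndarray, ratios: np.ndarray) -> np.ndarray:
    """Multiply every column by its ratio on all three channels.

    Output pixels are ``clip(round_half_away(v * ratio), 0, 255)``;
    columns with ratio exactly 1 are bit-identical to the input.
    """
    arr = validate_image(image)
    ratios = np.asarray(ratios, dtype=float)
    if ratios.ndim != 1 or ratios.shape[0] != arr.shape[1]:
        raise DomainError(
            f"ratios length {ratios.shape} does not match image width {arr.shape[1]}"
        )
    if not np.all(np.isfinite(ratios)) or np.any(ratios <= 0):
        raise DomainError("all ratios must be finite and > 0")
    scaled = arr.astype(float) * ratios[np.newaxis, :, np.newaxis]
    return np.clip(round_half_away(scaled), 0, 255).astype(np.uint8)


ReferencePolicy = Union[str, Tuple[str, float]]


def _resolve_reference(targets: np.ndarray, policy: ReferencePolicy) -> float:
    if isinstance(policy, tuple):
        name, value = policy
        if name != "fixed":
            raise DomainError(f"unknown reference policy {policy!r}")
        if not (np.isfinite(value) and value > 0):
            raise DomainError("fixed reference must be finite and > 0")
        return float(value)
    if policy == "brightest-column":
        ref = float(np.max(targets))
    elif policy == "mean-column":
        ref = float(np.mean(targets))
    else:
        raise DomainError(
            f"unknown reference policy {policy!r}; expected 'brightest-column', "
            "'mean-column' or ('fixed', value)"
        )
    if not (np.isfinite(ref) and ref > 0):
        raise DomainError(
            f"reference policy {policy!r} produced a nonpositive reference "
            f"({ref}); the predicted profile cannot anchor a compensation"
        )
    return ref


def icnet_enhance(
    image: np.ndarray,
    coeffs: PolyCoefficients,
    stage: StageParams,
    reference_policy: ReferencePolicy = "brightest-column",
    clamp_lo: float = DEFAULT_CLAMP[0],
    clamp_hi: float = DEFAULT_CLAMP[1],
    l_min: float = DEFAULT_L_RANGE[0],
    l_max: float = DEFAULT_L_RANGE[1],
) -> Tuple[np.ndarray, ColumnIlluminationProfile]:
    """Full column-wise compensation: positions -> targets -> ratios -> image.

    Returns the enhanced image and the audit profile.  With the default
    brightest-column reference every ratio is >= 1 up to the clamp.

    Columns whose predicted illuminance is nonpositive (the empirical
    quadratic can dip below zero when extrapolated hard into the shaded
    edge) are treated as maximally dark: their ratio is the clamp ceiling,
    the continuity limit of reference/target as the target approaches
    zero from above.  The emitted ratios therefore always lie in
    ``[clamp_lo, clamp_hi]`` regardless of the coefficient vector.
    """
    arr = validate_image(image)
    positions = column_positions(arr.shape[1], l_min, l_max)
    targets = np.asarray(
        predict_intensity(
            coeffs, stage.height_difference_cm, stage.solar_elevation_deg, positions
        ),
        dtype=float,
    )
    reference = _resolve_reference(targets, reference_policy)
    if not clamp_lo < clamp_hi:
        raise DomainError("clamp_lo must be < clamp_hi")
    positive = targets > 0
    ratios = np.full_like(targets, clamp_hi)
    ratios[positive] = np.clip(reference / targets[positive], clamp_lo, clamp_hi)
    enhanced = apply_compensation(arr, ratios)
    profile = ColumnIlluminationProfile(
        positions_cm=positions, targets=targets, reference=reference, ratios=ratios
    )
    return enhanced, profile
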