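"""Image-quality metrics and channel profiles.

Covers the full evaluation stack used to compare enhancers: mean squared
error and PSNR between image pairs, RGB/HLS series sampled along the
horizontal centerline, and per-channel standard deviations over the
central 80% of columns (the outer tenths border the tall-crop strips and
are excluded).

HLS convention (fixed so numbers are comparable across runs): hue H in
degrees on [0, 360) with undefined hue (S = 0) reported as 0; lightness L
and saturation S rescaled from [0, 1] to [0, 255].  Conversion follows
the standard hexcone model and is vectorized here; it agrees with the
stdlib ``colorsys`` per-pixel formulas.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict

import numpy as np

from .errors import DomainError
from .icnet import validate_image

#: Returned by :func:`psnr` for a zero-MSE (identical) pair.
PSNR_IDENTICAL = math.inf


@dataclass(frozen=True)
class ChannelProfile:
    """Channel series sampled along the image's horizontal centerline."""

    column_index: np.ndarray
    series: Dict[str, np.ndarray]
    smoothing_window: int = 1


@dataclass(frozen=True)
class EvaluationReport:
    """Distortion metrics plus color statistics for one processed image."""

    mse: float
    psnr_db: float
    channel_std: Dict[str, float]
    profiles: Dict[str, ChannelProfile]


def mse(image_a: np.ndarray, image_b: np.ndarray) -> float:
    """Mean squared error over all pixels and channels, in float64."""
    a = validate_image(image_a)
    b = validate_image(image_b)
    if a.shape != b.shape:
        raise DomainError(f"image shapes differ: {a.shape} vs {b.shape}")
    diff = a.astype(np.int64) - b.astype(np.int64)
    return float(np.mean(diff * diff))


def psnr(image_a: np.ndarray, image_b: np.ndarray, max_value: float = 255.0) -> float:
    """Peak signal-to-noise ratio, 10*log10(max^2 / MSE), in dB.

    Identical images have zero MSE; the function then returns
    :data:`PSNR_IDENTICAL` (positive infinity).
    """
    err = mse(image_a, image_b)
    if err == 0.0:
        return PSNR_IDENTICAL
    return 10.0 * math.log10(max_value * max_value / err)


def rgb_to_hls_channels(rgb: np.ndarray):
    """Vectorized hexcone RGB -> (H, L, S).

    Input is any array with a trailing axis of 3 holding 8-bit RGB.
    Returns float arrays: H in degrees [0, 360), L and S on [0, 255].
    """
    arr = np.asarray(rgb, dtype=float) / 255.0
    r, g, b = arr[..., 0], arr[..., 1], arr[..., 2]
    maxc = np.max(arr, axis=-1)
    minc = np.min(arr, axis=-1)
    L = (maxc + minc) / 2.0
    delta = maxc - minc
    chromatic = delta > 0

    S = np.zeros_like(L)
    denom_lo = maxc + minc
    denom_hi = 2.0 - maxc - minc
    lo = chromatic & (L <= 0.5)
    hi = chromatic & (L > 0.5)
    S[lo] = delta[lo] / denom_lo[lo]
    S[hi] = delta[hi] / denom_hi[hi]

    H = np.zeros_like(L)
    with np.errstate(invalid="ignore", divide="ignore"):
        rc = np.where(chromatic, (maxc - r) / delta, 0.0)
        gc = np.where(chromatic, (maxc - g) / delta, 0.0)
        bc = np.where(chromatic, (maxc - b) / delta, 0.0)
    h = np.where(
        maxc == r,
        bc - gc,
        np.where(maxc == g, 2.0 + rc - bc, 4.0 + gc - rc),
    )
    H = np.where(chromatic, (h / 6.0) % 1.0, 0.0) * 360.0
    return H, L * 255.0, S * 255.0


def hls_to_rgb(H: np.ndarray, L: np.ndarray, S: np.ndarray) -> np.ndarray:
    """Inverse hexcone map; inputs in the package convention, output float RGB on [0, 255]."""
    h = np.asarray(H, dtype=float) / 360.0
    l = np.asarray(L, dtype=float) / 255.0
    s = np.asarray(S, dtype=float) / 255.0
    m2 = np.where(l <= 0.5, l * (1.0 + s), l + s - l * s)
    m1 = 2.0 * l - m2

    def component(hue):
        hue = hue % 1.0
        out = np.where(
            hue < 1.0 / 6.0,
            m1 + (m2 - m1) * hue * 6.0,
            np.where(
                hue < 0.5,
                m2,
                np.where(hue < 2.0 / 3.0, m1 + (m2 - m1) * (2.0 / 3.0 - hue) * 6.0, m1),
            ),
        )
        return out

    rgb = np.stack(
        [component(h + 1.0 / 3.0), component(h), component(h - 1.0 / 3.0)], axis=-1
    )
    return rgb * 255.0


def _moving_average(series: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with edge truncation (shorter windows at borders)."""
    if window == 1:
        return series.astype(float)
    half = window // 2
    n = series.shape[0]
    out = np.empty(n, dtype=float)
    csum = np.concatenate([[0.0], np.cumsum(series, dtype=float)])
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, i + half + 1)
        out[i] = (csum[hi] - csum[lo]) / (hi - lo)
    return out


def centerline_profile(
    image: np.ndarray, colorspace: str = "RGB", smoothing_window: int = 1
) -> ChannelProfile:
    """Channel values along the horizontal centerline, left to right.

    The sampled row is ``floor(height / 2)``.  ``colorspace`` selects
    RGB (raw 8-bit values) or HLS (package convention).  An odd
    ``smoothing_window`` > 1 applies a centered moving average with edge
    truncation to each series.
    """
    arr = validate_image(image)
    w = arr.shape[1]
    if smoothing_window < 1 or smoothing_window % 2 == 0:
        raise DomainError("smoothing_window must be an odd integer >= 1")
    if smoothing_window > w:
        raise DomainError("smoothing_window exceeds image width")
    row = arr[arr.shape[0] // 2, :, :]
    if colorspace == "RGB":
        series = {name: row[:, i].astype(float) for i, name in enumerate("RGB")}
    elif colorspace == "HLS":
        H, L, S = rgb_to_hls_channels(row)
        series = {"H": H, "L": L, "S": S}
    else:
        raise DomainError(f"unknown colorspace {colorspace!r}; expected 'RGB' or 'HLS'")
    series = {k: _moving_average(v, smoothing_window) for k, v in series.items()}
    return ChannelProfile(
        column_index=np.arange(w), series=series, smoothing_window=smoothing_window
    )


def trimmed_channel_std(image: np.ndarray) -> Dict[str, float]:
    """Population std of R, G, B, H, L, S over the central columns.

    Drops ``floor(width / 10)`` columns from each side (the strip borders)
    and computes the population (ddof = 0) standard deviation of each RGB
    channel and each HLS channel over every remaining pixel.
    """
    arr = validate_image(image)
    w = arr.shape[1]
    if w < 10:
        raise DomainError("width must be >= 10 to trim 1/10 from each side")
    k = w // 10
    core = arr[:, k : w - k, :]
    out = {name: float(np.std(core[..., i].astype(float))) for i, name in enumerate("RGB")}
    H, L, S = rgb_to_hls_channels(core)
    out.update({"H": float(np.std(H)), "L": float(np.std(L)), "S": float(np.std(S))})
    return out


def evaluate_pair(
    reference: np.ndarray, processed: np.ndarray, smoothing_window: int = 1
) -> EvaluationReport:
    """Full report for a processed image against a reference.

    MSE/PSNR compare the pair; the channel standard deviations and the
    centerline profiles describe the processed image alone.
    """
    err = mse(reference, processed)
    return EvaluationReport(
        mse=err,
        psnr_db=psnr(reference, processed),
        channel_std=trimmed_channel_std(processed),
        profiles={
            "RGB": centerline_profile(processed, "RGB", smoothing_window),
            "HLS": centerline_profile(processed, "HLS", smoothing_window),
        },
    )
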