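"""Comparison enhancers: histogram equalization, multi-scale Retinex, gamma.

These are the three conventional methods the column-wise compensation is
benchmarked against.  All three operate per channel on 8-bit RGB rasters
and are deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import DomainError
from .icnet import round_half_away, validate_image


@dataclass(frozen=True)
class MsrParams:
    """Multi-scale Retinex parameters.

    ``sigmas`` are the Gaussian surround scales in pixels; ``weights``
    the per-scale mixing weights (must sum to 1); ``log_offset`` a small
    positive constant added before each logarithm so black pixels do not
    blow up.  Defaults are the conventional three scales {15, 80, 250}
    with equal weights.
    """

    sigmas: Sequence[float] = (15.0, 80.0, 250.0)
    weights: Sequence[float] = ()
    log_offset: float = 1.0

    def __post_init__(self):
        sigmas = tuple(float(s) for s in self.sigmas)
        if len(sigmas) < 1 or any(s < 0 for s in sigmas):
            raise DomainError("need >= 1 nonnegative sigma")
        weights = tuple(float(w) for w in self.weights) or tuple(
            1.0 / len(sigmas) for _ in sigmas
        )
        if len(weights) != len(sigmas):
            raise DomainError("weights and sigmas must have equal length")
        if any(w < 0 for w in weights) or abs(sum(weights) - 1.0) > 1e-9:
            raise DomainError("weights must be nonnegative and sum to 1")
        if not self.log_offset > 0:
            raise DomainError("log_offset must be > 0")
        object.__setattr__(self, "sigmas", sigmas)
        object.__setattr__(self, "weights", weights)


@dataclass(frozen=True)
class GammaParams:
    """Power-law brightness mapping ``out = C * in**gamma`` on [0, 1]."""

    gamma: float = 0.8
    constant: float = 1.0

    def __post_init__(self):
        if not self.gamma > 0:
            raise DomainError("gamma must be > 0")
        if not self.constant > 0:
            raise DomainError("constant must be > 0")


def histogram_equalize(image: np.ndarray) -> np.ndarray:
    """Classical CDF-based histogram equalization, per channel.

    Each channel is remapped by ``T(v) = round(255 * (cdf(v) - cdf_min)
    / (1 - cdf_min))`` with cdf normalized to [0, 1] and cdf_min the cdf
    at the lowest occupied level.  A single-level (constant) channel is
    left unchanged (the mapping is degenerate there).
    """
    arr = validate_image(image)
    out = np.empty_like(arr)
    for c in range(3):
        ch = arr[..., c]
        hist = np.bincount(ch.ravel(), minlength=256)
        cdf = np.cumsum(hist) / ch.size
        cdf_min = cdf[np.nonzero(hist)[0][0]]
        if cdf_min >= 1.0:
            out[..., c] = ch
            continue
        table = round_half_away(255.0 * (cdf - cdf_min) / (1.0 - cdf_min))
        out[..., c] = np.clip(table, 0, 255).astype(np.uint8)[ch]
    return out


def msr(image: np.ndarray, params: MsrParams = MsrParams()) -> np.ndarray:
    """Multi-scale Retinex: log-reflectance under Gaussian illumination.

    Per channel, ``R = sum_i w_i * (log(I + eps) - log(G_sigma_i * I + eps))``
    where ``G_sigma * I`` is convolution with a normalized Gaussian
    surround (nearest-edge padding).  R is then min–max rescaled per
    channel to [0, 255] for display; an all-equal R field maps to 0.
    Images smaller than the largest surround support still work (the
    kernel is effectively truncated at the border) but trigger a warning.
    """
    arr = validate_image(image)
    h, w = arr.shape[:2]
    support = 2 * int(4.0 * max(params.sigmas) + 0.5) + 1
    if min(h, w) < support:
        warnings.warn(
            f"image ({h}x{w}) smaller than the largest Gaussian support "
            f"({support}px); the surround is truncated at the border",
            UserWarning,
            stacklevel=2,
        )
    eps = params.log_offset
    out = np.empty_like(arr)
    for c in range(3):
        I = arr[..., c].astype(float)
        R = np.zeros_like(I)
        for sigma, wgt in zip(params.sigmas, params.weights):
            blurred = gaussian_filter(I, sigma, mode="nearest")
            R += wgt * (np.log(I + eps) - np.log(blurred + eps))
        lo, hi = R.min(), R.max()
        if hi - lo <= 0:
            out[..., c] = 0
        else:
            out[..., c] = round_half_away((R - lo) / (hi - lo) * 255.0).astype(np.uint8)
    return out


def gamma_correct(image: np.ndarray, params: GammaParams = GammaParams()) -> np.ndarray:
    """Power-law correction ``round(255 * C * (v/255)**gamma)``, clipped.

    gamma < 1 lifts dark regions (never darkens when C = 1); gamma > 1
    compresses highlights.
    """
    arr = validate_image(image)
    table = np.clip(
        round_half_away(255.0 * params.constant * (np.arange(256) / 255.0) ** params.gamma),
        0,
        255,
    ).astype(np.uint8)
    return table[arr]
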