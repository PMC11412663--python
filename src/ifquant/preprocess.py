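"""Background subtraction (rolling ball) and local contrast enhancement (CLAHE).

Fixed pipeline order: background subtraction first, then CLAHE, then —
for the segmentation channel only — the DoG filter (see
:mod:`ifquant.segmentation`).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

__all__ = [
    "RollingBallParams",
    "ClaheParams",
    "rolling_ball_background",
    "rolling_ball_subtract",
    "clahe",
    "preprocess_channel",
]


@dataclass
class RollingBallParams:
    """Rolling-ball background estimation radius, in pixels (default 50)."""

    radius_px: float = 50.0

    def __post_init__(self) -> None:
        if self.radius_px <= 0:
            raise ValueError(f"rolling ball radius must be > 0, got {self.radius_px}")


@dataclass
class ClaheParams:
    """CLAHE parameters: 30 px blocks, 256 histogram bins, max slope 3."""

    block_size_px: int = 30
    histogram_bins: int = 256
    max_slope: float = 3.0
    enabled: bool = True

    def __post_init__(self) -> None:
        if self.block_size_px < 2:
            raise ValueError("block_size_px must be >= 2")
        if self.histogram_bins < 2:
            raise ValueError("histogram_bins must be >= 2")
        if self.max_slope <= 0:
            raise ValueError("max_slope must be positive")


def _ball_element(radius: float) -> tuple[np.ndarray, np.ndarray]:
    """Heights and footprint of the ball structuring element."""
    r = int(np.ceil(radius))
    yy, xx = np.mgrid[-r:r + 1, -r:r + 1].astype(np.float64)
    d2 = yy ** 2 + xx ** 2
    footprint = d2 <= radius ** 2
    heights = np.zeros_like(d2)
    heights[footprint] = np.sqrt(radius ** 2 - d2[footprint])
    return heights, footprint


def _shrink_factor(radius_px: float) -> int:
    if radius_px <= 10:
        return 1
    if radius_px <= 30:
        return 2
    if radius_px <= 100:
        return 4
    return 8


def rolling_ball_background(
    channel: np.ndarray, radius_px: float, exact: bool = False
) -> np.ndarray:
    """Background estimate: grayscale opening by the non-flat ball element.

    The opening (erosion then dilation by the ball's height profile) is
    the upper envelope the ball traces while rolling under the intensity
    landscape; it removes flat offsets and slowly varying illumination
    while passing under features smaller than the ball.

    For radii above 10 px the opening runs on a min-pooled image at
    reduced scale (factor 2/4/8 with the radius scaled to match) and the
    result is upsampled — the customary large-radius speedup. Pass
    ``exact=True`` to force the full-resolution opening.
    """
    img = np.asarray(channel, dtype=np.float64)
    s = 1 if exact else _shrink_factor(radius_px)
    if s > 1:
        H, W = img.shape
        pad_h, pad_w = (-H) % s, (-W) % s
        padded = np.pad(img, ((0, pad_h), (0, pad_w)), mode="edge")
        pooled = padded.reshape(
            padded.shape[0] // s, s, padded.shape[1] // s, s).min(axis=(1, 3))
        bg_small = rolling_ball_background(pooled, radius_px / s, exact=True)
        bg = np.repeat(np.repeat(bg_small, s, axis=0), s, axis=1)[:H, :W]
        return np.minimum(bg, img)
    heights, footprint = _ball_element(radius_px)
    eroded = ndimage.grey_erosion(img, structure=heights, footprint=footprint,
                                  mode="nearest")
    return ndimage.grey_dilation(eroded, structure=heights, footprint=footprint,
                                 mode="nearest")


def rolling_ball_subtract(
    channel: np.ndarray, params: RollingBallParams | float = RollingBallParams()
) -> np.ndarray:
    """Subtract the rolling-ball background estimate, clipping at 0.

    Output dtype matches the input family (integer in -> same integer
    dtype out; float in -> float out).
    """
    if not isinstance(params, RollingBallParams):
        params = RollingBallParams(float(params))
    channel = np.asarray(channel)
    if channel.size == 0:
        raise ValueError("empty image")
    background = rolling_ball_background(channel, params.radius_px)
    if np.issubdtype(channel.dtype, np.integer):
        out = np.rint(channel.astype(np.float64) - background)
        info = np.iinfo(channel.dtype)
        return np.clip(out, 0, info.max).astype(channel.dtype)
    out = channel.astype(np.float64) - background
    return np.clip(out, 0.0, None)


def _value_range(img: np.ndarray) -> tuple[float, float]:
    if np.issubdtype(img.dtype, np.integer):
        info = np.iinfo(img.dtype)
        return float(info.min), float(info.max)
    lo, hi = float(img.min()), float(img.max())
    return (lo, hi if hi > lo else lo + 1.0)


def clahe(channel: np.ndarray, params: ClaheParams = ClaheParams()) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization (fast variant).

    The image is divided into ``block_size_px`` square blocks (mirrored at
    the borders so every block is full size). Each block's
    ``histogram_bins``-bin histogram is clipped at
    ``max_slope * block_pixels / histogram_bins`` with the clipped mass
    redistributed uniformly, then turned into an equalization mapping.
    Per-pixel output interpolates bilinearly between the mappings of the
    four nearest block centers. Blocks whose histogram occupies a single
    bin map identically (nothing to equalize), so constant images pass
    through unchanged.
    """
    channel = np.asarray(channel)
    if channel.size == 0:
        raise ValueError("empty image")
    if channel.ndim != 2:
        raise ValueError("clahe expects a 2D image")
    H, W = channel.shape
    B = params.block_size_px
    if B > min(H, W):
        B = min(H, W)
        logger.warning(
            "CLAHE block size %d exceeds image %dx%d; shrunk to %d",
            params.block_size_px, H, W, B,
        )
    nbins = params.histogram_bins
    vmin, vmax = _value_range(channel)
    vspan = vmax - vmin

    if float(channel.min()) == float(channel.max()):
        return channel.copy()

    n_br = math.ceil(H / B)
    n_bc = math.ceil(W / B)
    padded = np.pad(
        channel.astype(np.float64),
        ((0, n_br * B - H), (0, n_bc * B - W)),
        mode="symmetric",
    )

    # bin index per pixel of the original image
    scale = nbins / vspan
    bin_idx = np.clip(((channel.astype(np.float64) - vmin) * scale).astype(np.intp),
                      0, nbins - 1)

    block_pixels = B * B
    clip_limit = params.max_slope * block_pixels / nbins

    # per-block equalization LUTs, shape (n_br, n_bc, nbins)
    luts = np.empty((n_br, n_bc, nbins), dtype=np.float64)
    bin_edges_value = vmin + np.arange(nbins) * (vspan / nbins)
    for i in range(n_br):
        for j in range(n_bc):
            block = padded[i * B:(i + 1) * B, j * B:(j + 1) * B]
            bidx = np.clip(((block - vmin) * scale).astype(np.intp), 0, nbins - 1)
            hist = np.bincount(bidx.ravel(), minlength=nbins).astype(np.float64)
            if np.count_nonzero(hist) <= 1:
                luts[i, j] = bin_edges_value  # degenerate: identity at bin resolution
                continue
            if np.isfinite(clip_limit):
                excess = np.clip(hist - clip_limit, 0, None).sum()
                hist = np.minimum(hist, clip_limit) + excess / nbins
            cdf = np.cumsum(hist)
            cdf_min = cdf[np.nonzero(hist)[0][0]]
            denom = cdf[-1] - cdf_min
            if denom <= 0:
                luts[i, j] = bin_edges_value
            else:
                luts[i, j] = vmin + (cdf - cdf_min) / denom * vspan

    # bilinear interpolation between block-center mappings
    rows = np.arange(H, dtype=np.float64)
    cols = np.arange(W, dtype=np.float64)
    fr = np.clip(rows / B - 0.5, 0.0, n_br - 1.0)
    fc = np.clip(cols / B - 0.5, 0.0, n_bc - 1.0)
    r0 = np.floor(fr).astype(np.intp)
    c0 = np.floor(fc).astype(np.intp)
    r1 = np.minimum(r0 + 1, n_br - 1)
    c1 = np.minimum(c0 + 1, n_bc - 1)
    wr = (fr - r0)[:, None]
    wc = (fc - c0)[None, :]

    R0 = r0[:, None]
    R1 = r1[:, None]
    C0 = c0[None, :]
    C1 = c1[None, :]
    v00 = luts[R0, C0, bin_idx]
    v01 = luts[R0, C1, bin_idx]
    v10 = luts[R1, C0, bin_idx]
    v11 = luts[R1, C1, bin_idx]
    out = ((1 - wr) * ((1 - wc) * v00 + wc * v01)
           + wr * ((1 - wc) * v10 + wc * v11))

    out = np.clip(out, vmin, vmax)
    if np.issubdtype(channel.dtype, np.integer):
        return np.rint(out).astype(channel.dtype)
    return out


def preprocess_channel(
    channel: np.ndarray,
    rolling_ball_params: RollingBallParams = RollingBallParams(),
    clahe_params: ClaheParams = ClaheParams(),
) -> np.ndarray:
    """Background subtraction followed by (optional) CLAHE, in that order."""
    out = rolling_ball_subtract(channel, rolling_ball_params)
    if clahe_params.enabled:
        out = clahe(out, clahe_params)
    return out
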