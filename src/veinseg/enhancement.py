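"""Contrast enhancement and denoising.

Two preprocessing stages: contrast-limited adaptive histogram equalization
(CLAHE) to lift the low, spatially varying contrast of NIR forearm images,
and Gaussian smoothing to suppress the sensor noise (which is well modelled
as additive Gaussian).

CLAHE here follows the clip-and-redistribute formulation: the image is cut
into an M x N grid of non-overlapping tiles; each tile's 256-bin histogram is
clipped at ``L_C = clip_factor * Av``, where ``Av`` is the tile's average
pixel count per occupied gray level; the clipped mass ``S`` is first
redistributed uniformly over the occupied levels (``a_v = S / N_XY`` per
level) and the integer remainder is dealt one pixel at a time at gray-level
step ``L = L_G / S`` starting from level 0. Tile mappings are blended by
bilinear interpolation between tile centers to avoid block artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from veinseg.io import as_gray_u8

__all__ = [
    "ClaheParams",
    "GaussianKernelSpec",
    "clahe",
    "gaussian_kernel",
    "gaussian_filter",
    "gaussian_filter_float",
]

_NLEVELS = 256  # 8-bit gray-level range length L_G


@dataclass(frozen=True)
class ClaheParams:
    """CLAHE tiling and clip configuration.

    tiles_m : number of tile columns (horizontal sub-regions M)
    tiles_n : number of tile rows (vertical sub-regions N)
    clip_factor : multiple of the tile's average pixels-per-gray-level at
        which histogram bins are clipped; larger means less limiting, and
        for a single tile the limit ``clip_factor -> inf`` recovers plain
        histogram equalization.
    """

    tiles_m: int = 8
    tiles_n: int = 8
    clip_factor: float = 2.0

    def validate(self) -> None:
        if self.tiles_m < 1 or self.tiles_n < 1:
            raise ValueError("tile counts must be >= 1")
        if self.clip_factor <= 0:
            raise ValueError("clip_factor must be positive")


@dataclass(frozen=True)
class GaussianKernelSpec:
    """Square Gaussian convolution kernel: odd side length, sigma in pixels."""

    size: int = 3
    sigma: float = 1.5

    def validate(self) -> None:
        if self.size < 1 or self.size % 2 == 0:
            raise ValueError("kernel size must be odd and >= 1")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


def _tile_mapping(tile: np.ndarray, clip_factor: float) -> np.ndarray:
    """256-entry gray-level mapping for one tile (clip, redistribute, CDF)."""
    hist = np.bincount(tile.ravel(), minlength=_NLEVELS).astype(np.int64)
    npix = tile.size
    occupied = hist > 0
    n_levels = int(occupied.sum())  # N_XY: gray levels present in the tile
    av = npix / n_levels
    limit = max(1, int(round(clip_factor * av)))  # L_C = clip_factor * Av
    excess = hist - limit
    clipped = int(excess[excess > 0].sum())  # S: total clipped pixels
    hist = np.minimum(hist, limit)
    if clipped > 0:
        # uniform share a_v = S / N_XY over the occupied levels
        share, residual = divmod(clipped, n_levels)
        hist[occupied] += share
        if residual > 0:
            # deal the remainder one pixel per gray level at step L = L_G / S,
            # cycling from level 0
            step = max(1, int(round(_NLEVELS / clipped)))
            levels = (np.arange(residual) * step) % _NLEVELS
            np.add.at(hist, levels, 1)
    cdf = np.cumsum(hist)
    return np.rint((_NLEVELS - 1) * cdf / cdf[-1]).astype(np.uint8)


def clahe(img: np.ndarray, params: ClaheParams | None = None) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization.

    The image is split into ``tiles_n`` x ``tiles_m`` non-overlapping tiles
    (rows x cols); each tile's clipped-histogram equalization mapping is
    computed as described in the module docstring, and per-pixel outputs are
    bilinearly interpolated between the mappings of the four nearest tile
    centers (clamped at the borders).
    """
    params = params or ClaheParams()
    params.validate()
    a = as_gray_u8(img)
    h, w = a.shape
    m, n = params.tiles_m, params.tiles_n
    if w < m or h < n:
        raise ValueError(f"image {h}x{w} smaller than tile grid {n}x{m}")

    row_edges = np.linspace(0, h, n + 1).astype(int)
    col_edges = np.linspace(0, w, m + 1).astype(int)
    luts = np.empty((n, m, _NLEVELS), dtype=np.uint8)
    for i in range(n):
        for j in range(m):
            tile = a[row_edges[i] : row_edges[i + 1], col_edges[j] : col_edges[j + 1]]
            luts[i, j] = _tile_mapping(tile, params.clip_factor)

    row_centers = (row_edges[:-1] + row_edges[1:] - 1) / 2.0
    col_centers = (col_edges[:-1] + col_edges[1:] - 1) / 2.0
    wy = _axis_weights(h, row_centers)  # (n, H)
    wx = _axis_weights(w, col_centers)  # (m, W)

    out = np.zeros((h, w), dtype=np.float64)
    for i in range(n):
        if not wy[i].any():
            continue
        for j in range(m):
            if not wx[j].any():
                continue
            out += np.outer(wy[i], wx[j]) * luts[i, j][a]
    return np.rint(np.clip(out, 0, 255)).astype(np.uint8)


def _axis_weights(length: int, centers: np.ndarray) -> np.ndarray:
    """Per-tile triangular interpolation weights along one axis.

    Row k holds tile k's weight at each coordinate: 1 at its center,
    linearly decaying to 0 at the neighbouring centers, clamped to 1
    outside the outermost centers. Columns sum to 1.
    """
    coords = np.arange(length, dtype=np.float64)
    k = len(centers)
    weights = np.zeros((k, length))
    if k == 1:
        weights[0] = 1.0
        return weights
    idx = np.clip(np.searchsorted(centers, coords) - 1, 0, k - 2)
    lo, hi = centers[idx], centers[idx + 1]
    frac = np.clip((coords - lo) / (hi - lo), 0.0, 1.0)
    np.add.at(weights, (idx, np.arange(length)), 1.0 - frac)
    np.add.at(weights, (idx + 1, np.arange(length)), frac)
    return weights


def gaussian_kernel(spec: GaussianKernelSpec | None = None) -> np.ndarray:
    """Sample the 2-D Gaussian ``exp(-(x^2+y^2) / 2 sigma^2) / (2 pi sigma^2)``
    on the integer grid centered at 0 and normalize the weights to sum 1."""
    spec = spec or GaussianKernelSpec()
    spec.validate()
    r = spec.size // 2
    y, x = np.mgrid[-r : r + 1, -r : r + 1]
    k = np.exp(-(x * x + y * y) / (2.0 * spec.sigma**2)) / (2.0 * np.pi * spec.sigma**2)
    return k / k.sum()


def gaussian_filter_float(img: np.ndarray, spec: GaussianKernelSpec | None = None) -> np.ndarray:
    """Gaussian convolution without the final rounding/clipping (float output).

    Borders are edge-replicated. Exposed separately because linearity holds
    exactly only before quantization.
    """
    spec = spec or GaussianKernelSpec()
    kernel = gaussian_kernel(spec)
    return ndimage.correlate(np.asarray(img, dtype=np.float64), kernel, mode="nearest")


def gaussian_filter(img: np.ndarray, spec: GaussianKernelSpec | None = None) -> np.ndarray:
    """Smooth a grayscale image by convolution with a normalized Gaussian
    kernel (edge-replicated borders), rounded back to uint8."""
    out = gaussian_filter_float(as_gray_u8(img), spec)
    return np.rint(np.clip(out, 0, 255)).astype(np.uint8)
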