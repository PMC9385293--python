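"""Noise removal and geometric normalisation of multispectral stacks.

Two operations: the classical bilateral filter (a Gaussian kernel in the
spatial domain times a Gaussian kernel in the intensity/range domain, window
truncated at the image border with weight renormalisation), applied
independently per wavelength; and corner-aligned per-wavelength bilinear
resizing that brings stacks of non-uniform acquisition extent to a common
grid (e.g. 20 x 64 slices up to 64 x 64).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["BilateralParams", "bilateral_filter", "filter_stack", "resize_bilinear"]


@dataclass(frozen=True)
class BilateralParams:
    """Kernel scales of the bilateral filter.

    sigma_spatial : pixels; geometric-proximity Gaussian scale (> 0).
    sigma_range : intensity units; photometric-similarity Gaussian scale (> 0).
    window_radius : half-width of the truncated square window; default
        ``ceil(3 * sigma_spatial)``.
    """

    sigma_spatial: float = 2.0
    sigma_range: float = 0.1
    window_radius: int | None = None

    def __post_init__(self) -> None:
        if self.sigma_spatial <= 0:
            raise ValueError("sigma_spatial must be > 0")
        if self.sigma_range <= 0:
            raise ValueError("sigma_range must be > 0")
        if self.window_radius is not None and self.window_radius < 1:
            raise ValueError("window_radius must be >= 1")

    @property
    def radius(self) -> int:
        if self.window_radius is not None:
            return int(self.window_radius)
        return max(1, math.ceil(3.0 * self.sigma_spatial))


def bilateral_filter(image: np.ndarray, params: BilateralParams) -> np.ndarray:
    """Edge-preserving smoothing of a single H x W intensity image.

    ``out[p] = sum_q w(p,q) I(q) / sum_q w(p,q)`` over the truncated window,
    with ``w = exp(-||p-q||^2 / 2 sigma_s^2) * exp(-(I(p)-I(q))^2 / 2 sigma_r^2)``.
    Neighbours outside the image are simply absent from both sums (border
    renormalisation, no padding).  Output values are convex combinations of
    input values, hence bounded by the input range.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("bilateral_filter expects a 2-D image")
    if not np.all(np.isfinite(image)):
        raise ValueError("image intensities must be finite")
    h, w = image.shape
    r = params.radius
    inv2ss = 1.0 / (2.0 * params.sigma_spatial**2)
    inv2sr = 1.0 / (2.0 * params.sigma_range**2)

    num = np.zeros_like(image)
    den = np.zeros_like(image)
    for dy in range(-r, r + 1):
        for dx in range(-r, r + 1):
            ws = math.exp(-(dy * dy + dx * dx) * inv2ss)
            # p ranges over pixels whose neighbour q = p + (dy, dx) is in-bounds
            py = slice(max(0, -dy), h - max(0, dy))
            px = slice(max(0, -dx), w - max(0, dx))
            qy = slice(max(0, dy), h - max(0, -dy))
            qx = slice(max(0, dx), w - max(0, -dx))
            ip = image[py, px]
            iq = image[qy, qx]
            wgt = ws * np.exp(-((ip - iq) ** 2) * inv2sr)
            num[py, px] += wgt * iq
            den[py, px] += wgt
    return num / den


def filter_stack(stack: np.ndarray, params: BilateralParams) -> np.ndarray:
    """Apply :func:`bilateral_filter` independently to each wavelength slice."""
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3 or stack.shape[2] < 1 or stack.size == 0:
        raise ValueError("stack must be non-empty H x W x Lambda")
    out = np.empty_like(stack)
    for k in range(stack.shape[2]):
        out[:, :, k] = bilateral_filter(stack[:, :, k], params)
    return out


def resize_bilinear(stack: np.ndarray, target: tuple[int, int]) -> np.ndarray:
    """Corner-aligned per-wavelength bilinear resize of an H x W x Lambda stack.

    The output grid is ``linspace(0, H-1, H')`` x ``linspace(0, W-1, W')`` in
    input coordinates, so the four image corners map exactly onto the output
    corners and constant images are preserved.  A 2-D image is accepted and
    returned as 2-D.
    """
    stack = np.asarray(stack, dtype=float)
    squeeze = stack.ndim == 2
    if squeeze:
        stack = stack[:, :, None]
    if stack.ndim != 3:
        raise ValueError("stack must be H x W x Lambda (or a single H x W image)")
    h, w, _ = stack.shape
    if h < 2 or w < 2:
        raise ValueError("input spatial dims must be >= 2")
    th, tw = target
    if th < 1 or tw < 1:
        raise ValueError("target dims must be >= 1")
    if (th, tw) == (h, w):
        out = stack.copy()
        return out[:, :, 0] if squeeze else out

    rows = np.linspace(0.0, h - 1.0, th)
    cols = np.linspace(0.0, w - 1.0, tw)
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    coords = np.stack([rr.ravel(), cc.ravel()])
    out = np.empty((th, tw, stack.shape[2]), dtype=float)
    for k in range(stack.shape[2]):
        out[:, :, k] = ndimage.map_coordinates(
            stack[:, :, k], coords, order=1, mode="nearest"
        ).reshape(th, tw)
    return out[:, :, 0] if squeeze else out
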