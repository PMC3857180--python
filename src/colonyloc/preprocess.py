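"""Background removal and contrast conditioning ahead of colony segmentation.

Stages, in pipeline order:

1. :func:`remove_background` — grayscale top-hat with a rolling-ball
   structuring element (image minus its opening).
2. :func:`clahe` — contrast-limited adaptive histogram equalization.
3. :func:`enhance_borders` — above-threshold amplification followed by a
   normalized Gaussian blur.

All stages map intensities in [0, 255] back into [0, 255].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["PreprocessParams", "remove_background", "clahe", "enhance_borders",
           "run_preprocess"]

I_MIN, I_MAX = 0.0, 255.0


@dataclass
class PreprocessParams:
    #: objects (colonies/spots) darker than the background: invert before the
    #: top-hat so "structures of interest" are bright, which is what a top-hat
    #: residual preserves
    invert: bool = True
    ball_radius_px: float = 60.0
    ball_height: float = 40.0
    clahe_clip: float = 4.0
    clahe_tiles: tuple[int, int] = (8, 8)
    border_gauss_size_px: int = 9
    border_gauss_sigma: float = 2.0
    border_threshold: float = 180.0
    border_gain: float = 0.5

    def validate(self) -> None:
        if self.ball_radius_px <= 0:
            raise ValueError("ball_radius_px must be > 0")
        if self.border_gauss_size_px < 3 or self.border_gauss_size_px % 2 == 0:
            raise ValueError("border_gauss_size_px must be odd and >= 3")
        if self.border_gain < 0:
            raise ValueError("border_gain must be >= 0")
        if self.clahe_tiles[0] < 1 or self.clahe_tiles[1] < 1:
            raise ValueError("clahe_tiles must be >= (1, 1)")


def _ball_structure(radius: float, height: float) -> np.ndarray:
    """Grayscale rolling-ball structuring element (non-flat, spherical cap)."""
    r = int(np.floor(radius))
    dy, dx = np.mgrid[-r:r + 1, -r:r + 1]
    rho2 = (dx**2 + dy**2) / radius**2
    ball = np.full(dy.shape, -np.inf)
    inside = rho2 <= 1.0
    ball[inside] = height * np.sqrt(1.0 - rho2[inside])
    return ball


def remove_background(img: np.ndarray, ball_radius_px: float,
                      ball_height: float) -> np.ndarray:
    """Top-hat residual: image minus its grayscale opening by a rolling ball."""
    img = np.asarray(img, dtype=float)
    if ball_radius_px <= 0:
        raise ValueError("ball_radius_px must be > 0")
    if ball_radius_px > min(img.shape):
        raise ValueError(
            f"ball radius {ball_radius_px} exceeds the smallest image "
            f"dimension {min(img.shape)}")
    ball = _ball_structure(ball_radius_px, ball_height)
    footprint = np.isfinite(ball)
    structure = np.where(footprint, ball, 0.0)
    eroded = ndimage.grey_erosion(img, footprint=footprint, structure=structure,
                                  mode="reflect")
    opened = ndimage.grey_dilation(eroded, footprint=footprint,
                                   structure=structure, mode="reflect")
    return np.clip(img - opened, I_MIN, I_MAX)


def _tile_mapping(tile: np.ndarray, clip: float) -> np.ndarray:
    """256-entry intensity mapping for one tile (clipped histogram CDF)."""
    vals = np.clip(np.round(tile), 0, 255).astype(int)
    hist = np.bincount(vals.ravel(), minlength=256).astype(float)
    n = hist.sum()
    if np.count_nonzero(hist) <= 1:  # constant tile: nothing to equalize
        return np.arange(256, dtype=float)
    if np.isfinite(clip):
        limit = max(clip * n / 256.0, 1.0)
        excess = np.sum(np.maximum(hist - limit, 0.0))
        hist = np.minimum(hist, limit) + excess / 256.0
    cdf = np.cumsum(hist)
    nz = cdf[cdf > 0]
    cdf_min = nz[0] if nz.size else 0.0
    denom = cdf[-1] - cdf_min
    if denom <= 0:  # degenerate (constant) tile: identity mapping
        return np.arange(256, dtype=float)
    return (cdf - cdf_min) / denom * 255.0


def clahe(img: np.ndarray, clip: float = 4.0,
          tiles: tuple[int, int] = (8, 8)) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization.

    Tile-wise clipped-histogram equalization with bilinear interpolation of
    the tile mappings between tile centres.  ``clip`` is the histogram clip
    limit as a multiple of the uniform bin count (``np.inf`` disables
    clipping); with a single tile and no clipping this degenerates to plain
    global histogram equalization.
    """
    img = np.asarray(img, dtype=float)
    ty, tx = tiles
    if ty < 1 or tx < 1:
        raise ValueError("tiles must be >= (1, 1)")
    h, w = img.shape
    ty, tx = min(ty, h), min(tx, w)

    y_edges = np.linspace(0, h, ty + 1).astype(int)
    x_edges = np.linspace(0, w, tx + 1).astype(int)
    maps = np.empty((ty, tx, 256))
    y_centers = np.empty(ty)
    x_centers = np.empty(tx)
    for i in range(ty):
        for j in range(tx):
            tile = img[y_edges[i]:y_edges[i + 1], x_edges[j]:x_edges[j + 1]]
            maps[i, j] = _tile_mapping(tile, clip)
            y_centers[i] = 0.5 * (y_edges[i] + y_edges[i + 1] - 1)
            x_centers[j] = 0.5 * (x_edges[j] + x_edges[j + 1] - 1)

    vals = np.clip(np.round(img), 0, 255).astype(int)
    yy = np.arange(h, dtype=float)[:, None] * np.ones((1, w))
    xx = np.ones((h, 1)) * np.arange(w, dtype=float)[None, :]

    # fractional tile coordinates, clamped so border pixels use edge tiles
    fy = np.clip(np.interp(yy, y_centers, np.arange(ty)), 0, ty - 1) if ty > 1 \
        else np.zeros_like(yy)
    fx = np.clip(np.interp(xx, x_centers, np.arange(tx)), 0, tx - 1) if tx > 1 \
        else np.zeros_like(xx)
    i0 = np.minimum(np.floor(fy).astype(int), ty - 1)
    j0 = np.minimum(np.floor(fx).astype(int), tx - 1)
    i1 = np.minimum(i0 + 1, ty - 1)
    j1 = np.minimum(j0 + 1, tx - 1)
    wy = fy - i0
    wx = fx - j0

    out = ((1 - wy) * (1 - wx) * maps[i0, j0, vals]
           + (1 - wy) * wx * maps[i0, j1, vals]
           + wy * (1 - wx) * maps[i1, j0, vals]
           + wy * wx * maps[i1, j1, vals])
    return np.clip(out, I_MIN, I_MAX)


def _gaussian_kernel_1d(size: int, sigma: float) -> np.ndarray:
    half = size // 2
    x = np.arange(-half, half + 1, dtype=float)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def enhance_borders(img: np.ndarray, params: PreprocessParams) -> np.ndarray:
    """Amplify above-threshold pixels then blur with a unit-sum Gaussian.

    Computes G * (I + gain * I * H(I - t)) with reflect boundary handling,
    clipped to [0, 255].
    """
    params.validate()
    img = np.asarray(img, dtype=float)
    amplified = img * (1.0 + params.border_gain * (img > params.border_threshold))
    k = _gaussian_kernel_1d(params.border_gauss_size_px, params.border_gauss_sigma)
    blurred = ndimage.correlate1d(amplified, k, axis=0, mode="reflect")
    blurred = ndimage.correlate1d(blurred, k, axis=1, mode="reflect")
    return np.clip(blurred, I_MIN, I_MAX)


def run_preprocess(img: np.ndarray, params: PreprocessParams) -> np.ndarray:
    """Full conditioning chain: (invert) -> top-hat -> CLAHE -> border enhancement."""
    params.validate()
    out = np.asarray(img, dtype=float)
    if params.invert:
        out = I_MAX - out
    out = remove_background(out, params.ball_radius_px, params.ball_height)
    out = clahe(out, params.clahe_clip, params.clahe_tiles)
    return enhance_borders(out, params)
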