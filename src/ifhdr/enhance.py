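"""Post-processing chain for the rescaled merged image.

Three steps, applied in order on 12-bit integer grids:

(a) luminance adjustment by a mean-anchored gamma correction,
(b) contrast-limited adaptive histogram equalization (CLAHE),
(c) contrast enhancement from white-hat and black-hat morphology.

The CLAHE here is the classic tile-histogram algorithm: per-tile histograms
are clipped at a count limit (a multiple of the mean bin occupancy), the
excess is redistributed evenly, each tile's equalization map is min-max
normalized over its occupied bins, and per-pixel output is the bilinear blend
of the four surrounding tile maps.
"""

from __future__ import annotations

import numpy as np
from skimage.morphology import black_tophat, disk, white_tophat

from .imgio import MAX_12BIT

DEFAULT_TARGET_MEAN = 0.25
DEFAULT_CLIP_LIMIT = 2.0
DEFAULT_TILES = (8, 8)
DEFAULT_SE_RADIUS = 7


def gamma_adjust(
    image: np.ndarray, target_mean: float = DEFAULT_TARGET_MEAN
) -> np.ndarray:
    """Gamma-correct so the normalized image mean lands on ``target_mean``.

    With ``x = image / 4095`` and ``mu = clip(mean(x), 0.01, 0.99)``, the
    exponent is ``gamma = ln(target_mean) / ln(mu)``, which maps the mean
    of a uniform image exactly onto the target and leaves an image whose
    mean already equals the target unchanged.  Endpoints 0 and 4095 are
    fixed points for any gamma; the map is pointwise monotone.
    """
    if not 0 < target_mean < 1:
        raise ValueError("target_mean must be in (0, 1)")
    x = np.asarray(image, dtype=float) / MAX_12BIT
    mu = float(np.clip(x.mean(), 0.01, 0.99))
    gamma = 1.0 if mu == target_mean else np.log(target_mean) / np.log(mu)
    out = np.round(MAX_12BIT * np.power(x, gamma))
    return np.clip(out, 0, MAX_12BIT).astype(np.uint16)


def _tile_lut(hist: np.ndarray, clip_count: float, out_max: int) -> np.ndarray:
    npix = hist.sum()
    hist = hist.astype(float)
    excess = np.clip(hist - clip_count, 0, None).sum()
    if excess > 0:
        hist = np.minimum(hist, clip_count) + excess / hist.size
    cdf = np.cumsum(hist)
    cdf_mid = cdf - hist / 2.0
    occupied = np.flatnonzero(hist > 0)
    lo, hi = cdf_mid[occupied[0]], cdf_mid[occupied[-1]]
    if hi <= lo:  # single occupied bin: leave the tile's values in place
        return np.linspace(0.0, out_max, hist.size)
    return np.clip((cdf_mid - lo) / (hi - lo), 0.0, 1.0) * out_max


def clahe(
    image: np.ndarray,
    clip_limit: float = DEFAULT_CLIP_LIMIT,
    tiles: tuple[int, int] = DEFAULT_TILES,
    nbins: int = 256,
) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization on a 12-bit grid.

    ``clip_limit`` is expressed as a multiple of the mean histogram bin
    count of a tile (so 1.0 clips to a flat histogram and large values
    disable clipping); a constant image is returned unchanged.
    """
    if clip_limit <= 0:
        raise ValueError("clip_limit must be positive")
    img = np.asarray(image)
    rows, cols = img.shape
    ty, tx = tiles
    if ty < 1 or tx < 1 or ty > rows or tx > cols:
        raise ValueError("tile grid must fit inside the image")
    if img.max() == img.min():
        return img.copy()

    th, tw = -(-rows // ty), -(-cols // tx)  # ceil
    pad = ((0, ty * th - rows), (0, tx * tw - cols))
    work = np.pad(img, pad, mode="edge")
    bins = (work.astype(np.int64) * nbins) // (MAX_12BIT + 1)

    clip_count = max(clip_limit * (th * tw) / nbins, 1.0)
    luts = np.empty((ty, tx, nbins))
    for i in range(ty):
        for j in range(tx):
            tile = bins[i * th : (i + 1) * th, j * tw : (j + 1) * tw]
            hist = np.bincount(tile.ravel(), minlength=nbins)
            luts[i, j] = _tile_lut(hist, clip_count, MAX_12BIT)

    yy = np.clip((np.arange(ty * th) + 0.5) / th - 0.5, 0, ty - 1)
    xx = np.clip((np.arange(tx * tw) + 0.5) / tw - 0.5, 0, tx - 1)
    y0 = np.minimum(np.floor(yy).astype(int), ty - 1)
    x0 = np.minimum(np.floor(xx).astype(int), tx - 1)
    y1 = np.minimum(y0 + 1, ty - 1)
    x1 = np.minimum(x0 + 1, tx - 1)
    wy = (yy - y0)[:, None]
    wx = (xx - x0)[None, :]

    b = bins
    g00 = luts[y0[:, None], x0[None, :], b]
    g01 = luts[y0[:, None], x1[None, :], b]
    g10 = luts[y1[:, None], x0[None, :], b]
    g11 = luts[y1[:, None], x1[None, :], b]
    out = (
        (1 - wy) * ((1 - wx) * g00 + wx * g01)
        + wy * ((1 - wx) * g10 + wx * g11)
    )
    out = np.clip(np.round(out), 0, MAX_12BIT).astype(np.uint16)
    return out[:rows, :cols]


def tophat_contrast(image: np.ndarray, se_radius: int = DEFAULT_SE_RADIUS) -> np.ndarray:
    """Boost bright details and suppress dark ones via top-hat morphology.

    ``out = clip(image + whitehat - blackhat, 0, 4095)`` with grayscale
    opening/closing by a disc of ``se_radius``.
    """
    if se_radius < 1:
        raise ValueError("se_radius must be >= 1")
    img = np.asarray(image).astype(np.int32)
    se = disk(se_radius)
    wth = white_tophat(img, footprint=se)
    bth = black_tophat(img, footprint=se)
    return np.clip(img + wth - bth, 0, MAX_12BIT).astype(np.uint16)


def enhance_chain(
    image: np.ndarray,
    target_mean: float = DEFAULT_TARGET_MEAN,
    clip_limit: float = DEFAULT_CLIP_LIMIT,
    tiles: tuple[int, int] = DEFAULT_TILES,
    se_radius: int = DEFAULT_SE_RADIUS,
) -> np.ndarray:
    """Apply gamma -> CLAHE -> top-hat in order."""
    out = gamma_adjust(image, target_mean=target_mean)
    out = clahe(out, clip_limit=clip_limit, tiles=tiles)
    return tophat_contrast(out, se_radius=se_radius)
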