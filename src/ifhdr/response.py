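"""Camera response-curve recovery from a multi-exposure stack.

The model is the classic log-exposure identity ``g(Z_ij) = ln E_i + ln dt_j``
for pixel value ``Z_ij`` of scene point ``i`` under exposure time ``dt_j``:
``g`` is recovered by regularized linear least squares over quantized
intensity levels, with a triangular ("hat") confidence weight that vanishes at
the clipped extremes and a second-difference smoothness penalty.

The sampling rule is specialized for immunofluorescence: instead of sampling
the field uniformly, candidate pixels are restricted to a band around
segmented nuclei whose PD-L1 intensity at the medium exposure is high — the
pixels that actually carry membranous signal — so the system is fitted where
the biology lives rather than on empty background.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, sparse
from scipy.sparse.linalg import spsolve
from skimage.filters import threshold_otsu
from skimage.morphology import disk

from .imgio import Channel, ExposureImage, ExposureStack, quantize_levels

logger = logging.getLogger(__name__)

DEFAULT_LEVELS = 4096
DEFAULT_LAMBDA = 10.0
DEFAULT_DILATION_RADIUS = 5
DEFAULT_INTENSITY_PERCENTILE = 50.0
DEFAULT_N_SAMPLES = 2048
DEFAULT_MIN_NUCLEUS_AREA = 10


@dataclass(frozen=True)
class SampleSet:
    """Pixel positions used to constrain the response fit."""

    coords: np.ndarray  # (n, 2) int array of (row, col)

    def __post_init__(self) -> None:
        c = np.asarray(self.coords, dtype=int).reshape(-1, 2)
        if len(np.unique(c, axis=0)) != len(c):
            raise ValueError("duplicate sample coordinates")
        object.__setattr__(self, "coords", c)

    @property
    def n(self) -> int:
        return len(self.coords)


@dataclass(frozen=True)
class ResponseCurve:
    """Recovered log-exposure response ``g`` over quantized levels.

    ``g[mid] = 0`` with ``mid = levels // 2`` (gauge fix); levels that
    received no samples are filled by linear interpolation from their
    neighbors.
    """

    g: np.ndarray
    levels: int
    lambda_smooth: float

    def __post_init__(self) -> None:
        g = np.asarray(self.g, dtype=float)
        if g.shape != (self.levels,):
            raise ValueError("g length must equal levels")
        object.__setattr__(self, "g", g)

    @property
    def mid(self) -> int:
        return self.levels // 2


def hat_weights(levels: int) -> np.ndarray:
    """Triangular confidence weights over quantized levels.

    ``w(z) = z - z_min`` for ``z <= mid`` and ``z_max - z`` above; zero at
    both clipped extremes, maximal at the middle of the range.
    """
    z = np.arange(levels)
    mid = levels // 2
    return np.where(z <= mid, z, (levels - 1) - z).astype(float)


def segment_nuclei(
    nuclei_image: ExposureImage, min_area: int = DEFAULT_MIN_NUCLEUS_AREA
) -> np.ndarray:
    """Otsu-threshold the counterstain channel and drop tiny components."""
    if nuclei_image.channel is not Channel.NUCLEI:
        raise ValueError("segment_nuclei requires a NUCLEI-channel image")
    px = nuclei_image.pixels
    if px.max() == px.min():
        raise ValueError("degenerate nuclei channel: constant image")
    mask = px > threshold_otsu(px)
    labels, n = ndimage.label(mask)
    if n:
        areas = np.bincount(labels.ravel())
        small = np.flatnonzero(areas < min_area)
        mask &= ~np.isin(labels, small[small > 0])
    return mask


def _medium_exposure_image(stack: ExposureStack) -> ExposureImage:
    originals = stack.pdl1_images(virtual=False)
    order = np.argsort([im.exposure_ms for im in originals])
    return originals[order[len(order) // 2]]


def select_samples(
    stack: ExposureStack,
    nuclei_mask: np.ndarray,
    dilation_radius: int = DEFAULT_DILATION_RADIUS,
    intensity_percentile: float = DEFAULT_INTENSITY_PERCENTILE,
    n_samples: int = DEFAULT_N_SAMPLES,
    seed: int = 0,
    levels: int = DEFAULT_LEVELS,
) -> SampleSet:
    """Pick fitting pixels near nuclei with significant PD-L1 expression.

    Candidates are pixels inside the nuclei mask dilated by a disc of
    ``dilation_radius`` whose medium-exposure PD-L1 intensity reaches the
    ``intensity_percentile``-th percentile of that band.  ``n_samples`` are
    drawn without replacement, stratified over a 4x4 spatial grid.  If the
    band is empty the sampler falls back to a uniform grid over the image.
    """
    if not 0 < intensity_percentile < 100:
        raise ValueError("intensity_percentile must be in (0, 100)")
    n_images = len(stack.pdl1_images())
    if n_images >= 2 and n_samples < levels / (n_images - 1):
        raise ValueError(
            f"under-determined system: need >= {levels / (n_images - 1):.0f} "
            f"samples for {levels} levels and {n_images} images"
        )
    med = _medium_exposure_image(stack)
    band = ndimage.binary_dilation(
        np.asarray(nuclei_mask, bool), structure=disk(dilation_radius)
    )
    rng = np.random.default_rng(seed)
    if band.any():
        cutoff = np.percentile(med.pixels[band], intensity_percentile)
        candidates = band & (med.pixels >= cutoff)
    else:
        candidates = np.zeros_like(band)
    if not candidates.any():
        logger.warning("no nuclei-proximal candidates; uniform-grid fallback")
        rows, cols = med.shape
        side = int(np.ceil(np.sqrt(n_samples)))
        rr = np.linspace(0, rows - 1, side).round().astype(int)
        cc = np.linspace(0, cols - 1, side).round().astype(int)
        coords = np.array([(r, c) for r in rr for c in cc])[:n_samples]
        return SampleSet(coords=coords)

    coords = np.argwhere(candidates)
    if len(coords) <= n_samples:
        if len(coords) < n_samples:
            logger.warning(
                "only %d candidates for %d requested samples", len(coords), n_samples
            )
        return SampleSet(coords=coords)

    # spatial stratification over a 4x4 grid
    rows, cols = med.shape
    cell = (coords[:, 0] * 4 // rows) * 4 + (coords[:, 1] * 4 // cols)
    picked: list[np.ndarray] = []
    per_cell = n_samples // 16
    remaining = []
    for c in range(16):
        idx = np.flatnonzero(cell == c)
        rng.shuffle(idx)
        picked.append(idx[:per_cell])
        remaining.append(idx[per_cell:])
    chosen = np.concatenate(picked)
    short = n_samples - len(chosen)
    if short > 0:
        pool = np.concatenate(remaining)
        chosen = np.concatenate([chosen, rng.choice(pool, short, replace=False)])
    return SampleSet(coords=coords[np.sort(chosen)])


def fit_response(
    stack: ExposureStack,
    samples: SampleSet,
    lambda_smooth: float = DEFAULT_LAMBDA,
    levels: int = DEFAULT_LEVELS,
) -> ResponseCurve:
    """Solve the regularized least-squares system for the response curve.

    Minimizes ``sum_ij w(Z_ij) [g(Z_ij) - ln E_i - ln dt_j]^2
    + lambda * sum_z w(z) g''(z)^2`` subject to ``g(mid) = 0``.  Virtual
    (erosion/blur-derived) frames participate with the exposure time of
    their source frame.  The per-sample ``ln E_i`` estimates are discarded.
    """
    pdl1 = stack.pdl1_images()
    times = sorted({im.exposure_ms for im in pdl1})
    if len(times) < 2:
        raise ValueError("needs >=2 exposures with distinct times")
    if samples.n == 0:
        raise ValueError("empty sample set")

    # virtual (eroded/blurred) frames see a locally modified scene, so each
    # sample gets a separate irradiance unknown for its virtual observations
    groups = sorted({im.virtual for im in pdl1})
    w = hat_weights(levels)
    mid = levels // 2
    rr, cc = samples.coords[:, 0], samples.coords[:, 1]

    obs_z = np.stack(
        [quantize_levels(im.pixels[rr, cc], levels) for im in pdl1]
    )  # (frames, n)
    obs_w = w[obs_z]
    # drop samples clipped (zero weight) in every frame: they constrain nothing
    live = obs_w.sum(axis=0) > 0
    if not live.any():
        raise ValueError(
            f"singular system: all {samples.n} samples are clipped in every frame"
        )
    if not live.all():
        logger.debug("dropping %d fully clipped samples", int((~live).sum()))
    obs_z, obs_w = obs_z[:, live], obs_w[:, live]
    n_s = int(live.sum())

    n_unknowns = levels + n_s * len(groups)
    rows, cols, vals, b = [], [], [], []
    row = 0
    for f, im in enumerate(pdl1):
        offset = levels + groups.index(im.virtual) * n_s
        for i in range(n_s):
            wij = obs_w[f, i]
            if wij == 0:
                continue
            rows += [row, row]
            cols += [int(obs_z[f, i]), offset + i]
            vals += [wij, -wij]
            b.append(wij * np.log(im.exposure_ms))
            row += 1
    # smoothness on second differences, weighted by the hat function
    for z in range(1, levels - 1):
        s = lambda_smooth * w[z]
        rows += [row] * 3
        cols += [z - 1, z, z + 1]
        vals += [s, -2 * s, s]
        b.append(0.0)
        row += 1
    rows.append(row)
    cols.append(mid)
    vals.append(1.0)  # gauge
    b.append(0.0)
    row += 1

    a = sparse.csr_matrix(
        (vals, (rows, cols)), shape=(row, n_unknowns), dtype=float
    )
    bvec = np.asarray(b)
    # normal equations with a tiny ridge; the system is sparse and well scaled
    n_mat = (a.T @ a).tocsc() + 1e-9 * sparse.identity(n_unknowns, format="csc")
    sol = spsolve(n_mat, a.T @ bvec)
    g = sol[:levels]
    g = g - g[mid]  # enforce the gauge exactly

    # fill levels never observed (with nonzero weight) by linear interpolation
    sampled = np.zeros(levels, dtype=bool)
    sampled[obs_z[obs_w > 0]] = True
    if not sampled.all():
        known = np.flatnonzero(sampled)
        g = np.interp(np.arange(levels), known, g[known])
        g = g - g[mid]
    return ResponseCurve(g=g, levels=levels, lambda_smooth=lambda_smooth)


def sample_coverage(
    stack: ExposureStack, samples: SampleSet, levels: int = DEFAULT_LEVELS
) -> np.ndarray:
    """Number of informative (nonzero-weight) observations per level.

    Observations at the clipped extremes carry zero hat weight and do not
    constrain the fit, so they are not counted.
    """
    counts = np.zeros(levels, dtype=int)
    w = hat_weights(levels)
    rr, cc = samples.coords[:, 0], samples.coords[:, 1]
    for im in stack.pdl1_images():
        z = quantize_levels(im.pixels[rr, cc], levels)
        z = z[w[z] > 0]
        counts += np.bincount(z, minlength=levels)
    return counts
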