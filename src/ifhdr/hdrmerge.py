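"""Virtual-exposure augmentation, radiance merging, and the full HDR pipeline.

Merging follows the weighted-average estimator
``ln E(p) = sum_j w(Z_j) [g(Z_j) - ln dt_j] / sum_j w(Z_j)`` over all frames
(originals plus their erosion/blur-derived virtual counterparts, which carry
the same exposure times).  Pixels clipped in every frame get a fallback
estimate from the least-clipped exposure so the radiance map stays finite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import disk, erosion

from . import enhance, response
from .imgio import MAX_12BIT, Channel, ExposureImage, ExposureStack, quantize_levels
from .response import ResponseCurve

logger = logging.getLogger(__name__)

DEFAULT_EROSION_RADIUS = 3
DEFAULT_GAUSSIAN_SIGMA = 2.0


@dataclass(frozen=True)
class RadianceMap:
    """Per-pixel relative log-irradiance and merge weight sums.

    ``weight_sum == 0`` marks pixels that were clipped (or empty) in every
    input frame; their ``log_irradiance`` comes from the fallback rule.
    """

    log_irradiance: np.ndarray
    weight_sum: np.ndarray


@dataclass(frozen=True)
class HDRParams:
    """Every knob of the end-to-end pipeline, with the package defaults."""

    levels: int = response.DEFAULT_LEVELS
    lambda_smooth: float = response.DEFAULT_LAMBDA
    dilation_radius: int = response.DEFAULT_DILATION_RADIUS
    intensity_percentile: float = response.DEFAULT_INTENSITY_PERCENTILE
    n_samples: int = response.DEFAULT_N_SAMPLES
    erosion_radius: int = DEFAULT_EROSION_RADIUS
    gaussian_sigma: float = DEFAULT_GAUSSIAN_SIGMA
    virtual_in_merge: bool = True
    target_mean: float = enhance.DEFAULT_TARGET_MEAN
    clip_limit: float = enhance.DEFAULT_CLIP_LIMIT
    tiles: tuple[int, int] = enhance.DEFAULT_TILES
    se_radius: int = enhance.DEFAULT_SE_RADIUS
    seed: int = 0


def make_virtual_exposures(
    stack: ExposureStack,
    erosion_radius: int = DEFAULT_EROSION_RADIUS,
    gaussian_sigma: float = DEFAULT_GAUSSIAN_SIGMA,
) -> ExposureStack:
    """Append an eroded-and-blurred virtual copy of each original PD-L1 frame.

    The virtual frame keeps its source's exposure time and is flagged
    ``virtual=True``; nuclei frames pass through untouched.
    """
    if erosion_radius < 0 or gaussian_sigma < 0:
        raise ValueError("erosion_radius and gaussian_sigma must be >= 0")
    if stack.has_virtual:
        raise ValueError("already augmented")
    out = list(stack.images)
    for im in stack.pdl1_images(virtual=False):
        px = im.pixels.astype(float)
        if erosion_radius > 0:
            px = erosion(px, footprint=disk(erosion_radius))
        if gaussian_sigma > 0:
            px = ndimage.gaussian_filter(px, sigma=gaussian_sigma)
        out.append(
            ExposureImage(
                pixels=np.clip(np.round(px), 0, MAX_12BIT).astype(np.uint16),
                exposure_ms=im.exposure_ms,
                channel=Channel.PDL1,
                virtual=True,
            )
        )
    return ExposureStack(images=out)


def estimate_noise_floor(pixels: np.ndarray, n_mad: float = 3.0) -> float:
    """Robust background ceiling of a fluorescence frame.

    Histogram mode plus ``n_mad`` robust standard deviations
    (1.4826 * median absolute deviation about the mode).  In a
    darkfield image the mode is the background level; values at or below
    the returned floor are statistically indistinguishable from it.
    """
    v = np.asarray(pixels).ravel()
    mode = int(np.bincount(v).argmax())
    sigma = 1.4826 * float(np.median(np.abs(v.astype(float) - mode)))
    return mode + n_mad * max(sigma, 1.0)


def merge_radiance(
    stack: ExposureStack,
    curve: ResponseCurve,
    use_virtual: bool = True,
    noise_floor: float | str | None = "auto",
) -> RadianceMap:
    """Merge the stack into a relative log-irradiance map.

    Observations at or below ``noise_floor`` (``"auto"``: mode + 3 MAD of
    the longest original frame, the background detection limit) carry no
    weight.  Pixels with zero total weight are filled by a fallback:
    bright-clipped pixels from the shortest exposure at its clipped level,
    dark pixels at the floor radiance of the longest exposure — the merge
    does not pretend to resolve irradiance below the detection limit of
    its longest constituent frame.
    """
    frames = stack.pdl1_images() if use_virtual else stack.pdl1_images(virtual=False)
    if not frames:
        raise ValueError("empty stack")
    originals = stack.pdl1_images(virtual=False) or frames
    shortest = min(originals, key=lambda im: im.exposure_ms)
    longest = max(originals, key=lambda im: im.exposure_ms)
    if noise_floor == "auto":
        floor = estimate_noise_floor(longest.pixels)
    else:
        floor = float(noise_floor or 0.0)

    w = response.hat_weights(curve.levels)
    num = np.zeros(stack.shape, dtype=float)
    den = np.zeros(stack.shape, dtype=float)
    for im in frames:
        z = quantize_levels(im.pixels, curve.levels)
        wij = np.where(im.pixels <= floor, 0.0, w[z])
        num += wij * (curve.g[z] - np.log(im.exposure_ms))
        den += wij
    log_e = np.divide(num, den, out=np.zeros_like(num), where=den > 0)

    bad = den == 0
    if bad.any():
        z_short = quantize_levels(shortest.pixels, curve.levels)
        bright = bad & (z_short > curve.mid)
        dark = bad & ~bright
        log_e[bright] = curve.g[z_short[bright]] - np.log(shortest.exposure_ms)
        z_floor = quantize_levels(
            np.full((), min(int(np.ceil(floor)), MAX_12BIT)), curve.levels
        )
        log_e[dark] = curve.g[z_floor] - np.log(longest.exposure_ms)
    return RadianceMap(log_irradiance=log_e, weight_sum=den)


def rescale_linear(
    radiance: RadianceMap, originals: ExposureStack
) -> np.ndarray:
    """Affinely map ``exp(log_irradiance)`` onto the originals' value range.

    The minimum of the linear radiance maps to the minimum pixel value over
    all original PD-L1 frames, the maximum to the maximum; a constant
    radiance map yields a constant image at the minimum.
    """
    pdl1 = originals.pdl1_images(virtual=False)
    if not pdl1:
        raise ValueError("originals must contain a non-virtual PDL1 image")
    i_min = min(int(im.pixels.min()) for im in pdl1)
    i_max = max(int(im.pixels.max()) for im in pdl1)
    e = np.exp(radiance.log_irradiance)
    e_min, e_max = float(e.min()), float(e.max())
    if e_max == e_min:
        return np.full(e.shape, i_min, dtype=np.uint16)
    out = i_min + (e - e_min) * (i_max - i_min) / (e_max - e_min)
    return np.clip(np.round(out), 0, MAX_12BIT).astype(np.uint16)


def compute_radiance(
    stack: ExposureStack, params: HDRParams = HDRParams()
) -> tuple[RadianceMap, ResponseCurve]:
    """Front half of the pipeline: segmentation through radiance merge."""
    nuclei = stack.nuclei_images()
    if not nuclei:
        raise ValueError("stack has no nuclei channel")
    nuclei_mask = response.segment_nuclei(nuclei[0])
    samples = response.select_samples(
        stack,
        nuclei_mask,
        dilation_radius=params.dilation_radius,
        intensity_percentile=params.intensity_percentile,
        n_samples=params.n_samples,
        seed=params.seed,
        levels=params.levels,
    )
    augmented = make_virtual_exposures(
        stack,
        erosion_radius=params.erosion_radius,
        gaussian_sigma=params.gaussian_sigma,
    )
    curve = response.fit_response(
        augmented, samples, lambda_smooth=params.lambda_smooth, levels=params.levels
    )
    radiance = merge_radiance(augmented, curve, use_virtual=params.virtual_in_merge)
    return radiance, curve


def hdr_pipeline(
    stack: ExposureStack, params: HDRParams = HDRParams()
) -> np.ndarray:
    """Run the full chain on one layer and return the enhanced 12-bit image.

    Stages: nuclei segmentation -> nuclei-proximal sampling -> virtual
    exposure augmentation -> response fit -> radiance merge -> linear
    rescale -> gamma -> CLAHE -> top-hat.
    """
    logger.info("hdr_pipeline parameters: %s", params)
    radiance, _ = compute_radiance(stack, params)
    merged = rescale_linear(radiance, stack)
    return enhance.enhance_chain(
        merged,
        target_mean=params.target_mean,
        clip_limit=params.clip_limit,
        tiles=params.tiles,
        se_radius=params.se_radius,
    )


def process_zstack(
    stacks: list[ExposureStack], params: HDRParams = HDRParams()
) -> list[np.ndarray]:
    """Apply :func:`hdr_pipeline` independently to each z-layer, in order."""
    if stacks:
        shapes = {s.shape for s in stacks}
        if len(shapes) > 1:
            raise ValueError(f"inconsistent shapes across layers: {sorted(shapes)}")
    return [hdr_pipeline(s, params) for s in stacks]
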