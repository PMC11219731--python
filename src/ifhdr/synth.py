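"""Seeded phantom generator for end-to-end testing of the HDR pipeline.

The phantom emulates a PD-L1 immunofluorescence field of view: disc-shaped
nuclei, a configurable fraction of which carry a membranous PD-L1 ring
(annulus), with per-ring irradiances spanning several decades so that a single
12-bit exposure cannot capture every ring — dim rings drown in read noise at
short exposures while bright rings clip at long ones.  The same ground truth
renders a brightfield IHC counterpart through Beer–Lambert two-stain
(hematoxylin + DAB) absorption, which exercises the Macenko deconvolution
path.

Every operation takes an explicit seed and draws from its own
``numpy.random.Generator``; there is no global RNG state.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .imgio import MAX_12BIT, Channel, ExposureImage, ExposureStack

#: Default exposure times (ms) of the acquisition protocol.
DEFAULT_EXPOSURES_MS = (6.5, 25.0, 55.0)

#: Default additive read noise, in camera counts (standard deviation).
DEFAULT_READ_NOISE_SD = 2.0


@dataclass(frozen=True)
class CameraResponse:
    """Smooth monotone camera response ``f(x) = 4095 * (x / x_sat) ** gamma``.

    ``x`` is the exposure (irradiance times exposure time, relative units)
    and ``x_sat`` the full-well exposure at which the 12-bit output clips.
    ``gamma=1, saturation_exposure=4095`` gives the identity response
    ``f(x) = x``.
    """

    gamma: float = 0.8
    saturation_exposure: float = 4095.0

    def __call__(self, x: np.ndarray | float) -> np.ndarray:
        x = np.clip(np.asarray(x, dtype=float), 0.0, None)
        return np.clip(
            MAX_12BIT * (x / self.saturation_exposure) ** self.gamma,
            0.0,
            float(MAX_12BIT),
        )

    def inverse(self, p: np.ndarray | float) -> np.ndarray:
        """Ideal inverse on the unclipped range (p in (0, 4095))."""
        p = np.asarray(p, dtype=float)
        return self.saturation_exposure * (p / MAX_12BIT) ** (1.0 / self.gamma)

    def log_exposure_for_levels(self, levels: int = 256) -> np.ndarray:
        """True log-exposure at each quantized level's bin center.

        Level ``z`` covers pixel values ``[z*s, (z+1)*s)`` with
        ``s = 4096 / levels``; the returned value is ``ln x`` at the bin
        center, the quantity the recovered response curve estimates up to
        its gauge constant.
        """
        step = (MAX_12BIT + 1) / levels
        centers = (np.arange(levels) + 0.5) * step
        return np.log(self.inverse(np.clip(centers, 1e-9, MAX_12BIT)))


IDENTITY_RESPONSE = CameraResponse(gamma=1.0, saturation_exposure=float(MAX_12BIT))


@dataclass
class PhantomTruth:
    """Ground truth of one synthetic field of view."""

    irradiance: np.ndarray
    nuclei_mask: np.ndarray
    membrane_mask: np.ndarray
    true_response: CameraResponse
    stain_basis_true: np.ndarray  # 3x2 OD matrix, columns (H, DAB)
    seed: int
    background_irradiance: float = 0.55

    @property
    def shape(self) -> tuple[int, int]:
        return self.irradiance.shape

    @property
    def membrane_dynamic_range(self) -> float:
        """max/min irradiance over membrane pixels."""
        vals = self.irradiance[self.membrane_mask]
        return float(vals.max() / vals.min())


def _default_stain_basis() -> np.ndarray:
    # Ruifrok-style hematoxylin / DAB OD vectors, unit-normalized columns
    h = np.array([0.65, 0.70, 0.29])
    d = np.array([0.27, 0.57, 0.78])
    basis = np.stack([h / np.linalg.norm(h), d / np.linalg.norm(d)], axis=1)
    return basis


def make_phantom(
    rows: int = 512,
    cols: int = 512,
    n_nuclei: int = 60,
    dynamic_range_decades: float = 3.0,
    seed: int = 0,
    ring_fraction: float = 0.8,
    nucleus_radius: tuple[int, int] = (6, 10),
    ring_width: int = 3,
    background_irradiance: float = 0.55,
    saturation_ms: float = 50.0,
    max_attempts_per_nucleus: int = 200,
) -> PhantomTruth:
    """Generate a ground-truth scene with nuclei and membrane rings.

    Nuclei are discs at rejection-sampled non-overlapping centers; a
    ``ring_fraction`` of them carry a PD-L1 membrane annulus of width
    ``ring_width`` just outside the nuclear disc.  Ring irradiances are a
    seeded permutation of values evenly spaced in log10 across
    ``dynamic_range_decades`` (stratified log-uniform), so the membrane
    max/min ratio equals ``10 ** decades`` by construction.  The dimmest
    ring has irradiance 1 (relative units); background is a low constant
    autofluorescence level just beneath it.

    The camera's full-well point is set so the brightest ring clips at
    exposures of ``saturation_ms`` and above: the long (55 ms) frame
    overexposes the top of the membrane range while the dim decade falls
    to within read noise of the background in the short (6.5 ms) frame —
    the dynamic-range failure modes the HDR merge exists to fix.
    """
    if rows < 64 or cols < 64:
        raise ValueError("rows and cols must be >= 64")
    if n_nuclei < 1:
        raise ValueError("n_nuclei must be >= 1")
    if dynamic_range_decades < 0:
        raise ValueError("dynamic_range_decades must be >= 0")
    rng = np.random.default_rng(seed)

    r_lo, r_hi = nucleus_radius
    margin = r_hi + ring_width + 2
    centers: list[tuple[int, int]] = []
    radii: list[int] = []
    attempts_left = max_attempts_per_nucleus * n_nuclei
    while len(centers) < n_nuclei:
        if attempts_left <= 0:
            raise RuntimeError(
                f"placement failed: could not fit {n_nuclei} nuclei in a "
                f"{rows}x{cols} field"
            )
        attempts_left -= 1
        r = int(rng.integers(r_lo, r_hi + 1))
        cy = int(rng.integers(margin, rows - margin))
        cx = int(rng.integers(margin, cols - margin))
        ok = all(
            (cy - y) ** 2 + (cx - x) ** 2
            >= (r + rr + 2 * ring_width + 2) ** 2
            for (y, x), rr in zip(centers, radii)
        )
        if ok:
            centers.append((cy, cx))
            radii.append(r)

    n_rings = int(round(ring_fraction * n_nuclei))
    if ring_fraction > 0:
        n_rings = max(1, n_rings)
    ring_idx = rng.choice(n_nuclei, size=n_rings, replace=False)
    # stratified log-uniform: permuted even spacing guarantees the full span
    log_e = rng.permutation(np.linspace(0.0, dynamic_range_decades, max(n_rings, 1)))

    yy, xx = np.mgrid[0:rows, 0:cols]
    nuclei_mask = np.zeros((rows, cols), dtype=bool)
    membrane_mask = np.zeros((rows, cols), dtype=bool)
    irradiance = np.full((rows, cols), background_irradiance, dtype=float)

    ring_e = dict(zip(ring_idx.tolist(), (10.0 ** log_e).tolist()))
    for i, ((cy, cx), r) in enumerate(zip(centers, radii)):
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        nuclei_mask |= d2 <= r * r
        if i in ring_e:
            ring = (d2 > r * r) & (d2 <= (r + ring_width) ** 2)
            membrane_mask |= ring
            irradiance[ring] = ring_e[i]

    e_max = 10.0 ** dynamic_range_decades
    response = CameraResponse(gamma=0.8, saturation_exposure=e_max * saturation_ms)
    return PhantomTruth(
        irradiance=irradiance,
        nuclei_mask=nuclei_mask,
        membrane_mask=membrane_mask,
        true_response=response,
        stain_basis_true=_default_stain_basis(),
        seed=seed,
        background_irradiance=background_irradiance,
    )


def render_exposures(
    truth: PhantomTruth,
    exposures_ms: Sequence[float] = DEFAULT_EXPOSURES_MS,
    read_noise_sd: float = DEFAULT_READ_NOISE_SD,
    seed: int = 0,
    response: CameraResponse | None = None,
    nuclei_level: int = 3000,
) -> ExposureStack:
    """Render the phantom through the camera at each exposure time.

    ``pixel = clip(round(f(E * dt) + eps), 0, 4095)`` with Gaussian read
    noise ``eps``.  A NUCLEI-channel frame is appended, rendering the
    nuclei mask at a fixed mid-range intensity.  Deterministic given seed.
    """
    if read_noise_sd < 0:
        raise ValueError("negative read_noise_sd")
    if any(t <= 0 for t in exposures_ms):
        raise ValueError("nonpositive exposure")
    f = response if response is not None else truth.true_response
    rng = np.random.default_rng(seed)
    images = []
    for dt in exposures_ms:
        clean = f(truth.irradiance * dt)
        noise = rng.normal(0.0, read_noise_sd, clean.shape) if read_noise_sd else 0.0
        px = np.clip(np.round(clean + noise), 0, MAX_12BIT).astype(np.uint16)
        images.append(
            ExposureImage(pixels=px, exposure_ms=float(dt), channel=Channel.PDL1)
        )
    nuc = np.where(truth.nuclei_mask, nuclei_level, 100).astype(float)
    if read_noise_sd:
        nuc = nuc + rng.normal(0.0, read_noise_sd, nuc.shape)
    nuc_px = np.clip(np.round(nuc), 0, MAX_12BIT).astype(np.uint16)
    images.append(
        ExposureImage(pixels=nuc_px, exposure_ms=5.0, channel=Channel.NUCLEI)
    )
    return ExposureStack(images=images)


def detection_threshold(
    truth: PhantomTruth,
    exposure_ms: float = DEFAULT_EXPOSURES_MS[1],
    read_noise_sd: float = DEFAULT_READ_NOISE_SD,
    n_sigma: float = 5.0,
) -> float:
    """Fixed count threshold of the imaging protocol.

    The detection threshold is calibrated once, on the properly exposed
    (medium) frame: the camera value of the background plus ``n_sigma``
    read-noise standard deviations.  Applied unchanged to every exposure —
    which is what makes the long exposure's elevated background bleed into
    the positive class (the overexposure artifact) while the short
    exposure's dim membranes drop below it (the lost-signal artifact).
    """
    bg = float(truth.true_response(truth.background_irradiance * exposure_ms))
    return bg + n_sigma * read_noise_sd


def level_log_exposure(
    truth: PhantomTruth, stack: ExposureStack, levels: int = 256
) -> np.ndarray:
    """Ground-truth log exposure attributed to each quantized level.

    For every original PD-L1 frame, each pixel contributes its true
    ``ln(E * dt)`` to the level its rendered value quantizes to; the
    returned vector is the per-level population mean (NaN where no pixel
    lands).  This is the value an ideal estimator would assign to the
    level, the natural reference for a recovered response curve: on 12-bit
    data the lowest of 256 bins spans a wide log-exposure range, so a
    bin-center convention would measure quantization geometry rather than
    recovery error.
    """
    from .imgio import quantize_levels

    s = np.zeros(levels)
    n = np.zeros(levels)
    for im in stack.pdl1_images(virtual=False):
        z = quantize_levels(im.pixels, levels).ravel()
        lx = np.log(truth.irradiance.ravel() * im.exposure_ms)
        s += np.bincount(z, weights=lx, minlength=levels)
        n += np.bincount(z, minlength=levels)
    with np.errstate(invalid="ignore"):
        return np.where(n > 0, s / np.maximum(n, 1), np.nan)


def true_concentrations(
    truth: PhantomTruth,
    hematoxylin_level: float = 0.8,
    dab_scale: float = 0.3,
    dab_offset: float = 0.2,
) -> tuple[np.ndarray, np.ndarray]:
    """Ground-truth stain concentration maps for the IHC rendering.

    Hematoxylin marks nuclei at a constant level; DAB marks membranes with a
    concentration affine in log10 irradiance (brighter fluorescent rings
    correspond to stronger chromogenic deposits).
    """
    c_h = np.where(truth.nuclei_mask, hematoxylin_level, 0.0)
    c_d = np.zeros(truth.shape, dtype=float)
    mem = truth.membrane_mask
    c_d[mem] = dab_offset + dab_scale * np.log10(truth.irradiance[mem])
    return c_h, c_d


def render_ihc(
    truth: PhantomTruth,
    stain_basis: np.ndarray | None = None,
    i0: float = 255.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Render a brightfield IHC image by Beer–Lambert absorption.

    Per RGB channel ``c``: ``I_c = I0 * 10 ** -(C_H * s_H,c + C_D * s_D,c)``
    plus optional Gaussian noise, clipped to [0, 255] and returned as uint8.
    """
    basis = truth.stain_basis_true if stain_basis is None else np.asarray(stain_basis)
    if basis.shape != (3, 2):
        raise ValueError("stain basis must be 3x2 (columns H, DAB)")
    if (basis < 0).any() or not np.allclose(np.linalg.norm(basis, axis=0), 1.0):
        raise ValueError("stain vectors must be unit-norm with nonnegative entries")
    c_h, c_d = true_concentrations(truth)
    od = (
        c_h[..., None] * basis[:, 0][None, None, :]
        + c_d[..., None] * basis[:, 1][None, None, :]
    )
    img = i0 * 10.0 ** (-od)
    if noise_sd:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise_sd, img.shape)
    return np.clip(np.round(img), 0, 255).astype(np.uint8)
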