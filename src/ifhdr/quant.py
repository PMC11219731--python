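"""PD-L1 expression-area quantification for IHC and IF images.

For brightfield IHC, the DAB signal is isolated by Macenko stain
deconvolution: pixels are mapped to optical density (Beer–Lambert), the
two-stain plane is found by PCA, and the stain vectors are the extreme
projection angles of the OD cloud.  The area proportion of PD-L1 expression
is the fraction of annotated-tumor pixels above a threshold (Otsu within the
annotation by default), with the physical area from the micrometer-per-pixel
pitch.  The proportion approximates, but is deliberately not called, the
pathologist tumor proportion score (TPS); TPS categories and the <100
tumor-cell exclusion rule are provided separately.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from skimage.filters import threshold_otsu

from .imgio import TumorAnnotation

#: Physical pixel pitch of the study's scanners, micrometers per pixel.
MPP_IHC = 0.465
MPP_IF = 0.334

TPS_CATEGORIES = ("<1%", "1-49%", ">=50%")
EXCLUDED = "excluded"

#: Minimum number of tumor cells for a case to be scoreable.
MIN_TUMOR_CELLS = 100


@dataclass(frozen=True)
class StainBasis:
    """Two unit OD stain vectors, hematoxylin first, DAB second (3x2)."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 2):
            raise ValueError("stain basis must be 3x2")
        if (m < -1e-12).any():
            raise ValueError("stain vectors must be nonnegative")
        if not np.allclose(np.linalg.norm(m, axis=0), 1.0, atol=1e-8):
            raise ValueError("stain vectors must be unit-norm")
        object.__setattr__(self, "matrix", m)

    @property
    def hematoxylin(self) -> np.ndarray:
        return self.matrix[:, 0]

    @property
    def dab(self) -> np.ndarray:
        return self.matrix[:, 1]


@dataclass(frozen=True)
class ConcentrationMaps:
    """Per-stain concentration images, order matching the basis."""

    hematoxylin: np.ndarray
    dab: np.ndarray


@dataclass(frozen=True)
class AreaProportionResult:
    """Thresholded positive-area summary inside a tumor annotation."""

    proportion: float
    positive_pixels: int
    total_pixels: int
    threshold_used: float
    area_um2: float

    def as_dict(self) -> dict:
        return {
            "proportion": self.proportion,
            "positive_pixels": self.positive_pixels,
            "total_pixels": self.total_pixels,
            "threshold_used": self.threshold_used,
            "area_um2": self.area_um2,
        }


def od_transform(rgb: np.ndarray, i0: float = 255.0) -> np.ndarray:
    """Per-pixel optical density: ``OD_c = -log10((pixel_c + 1) / I0)``.

    The +1 keeps the logarithm finite at pixel value 0.
    """
    if i0 <= 0:
        raise ValueError("I0 must be positive")
    rgb = np.asarray(rgb, dtype=float)
    return -np.log10((rgb + 1.0) / i0)


def macenko_stains(
    od: np.ndarray, beta: float = 0.15, alpha: float = 1.0
) -> StainBasis:
    """Estimate H and DAB OD vectors from the OD cloud (Macenko).

    Pixels with any OD component <= ``beta`` are discarded; the retained
    vectors are projected onto their top-2 principal plane and the stain
    vectors are taken at the ``alpha``-th and (100-alpha)-th percentile
    projection angles.  The more blue-absorbing vector is labeled
    hematoxylin.
    """
    flat = od.reshape(-1, 3)
    keep = flat[(flat > beta).all(axis=1)]
    if len(keep) < 100:
        raise ValueError("insufficient stained tissue: too few above-floor pixels")
    # PCA of the uncentered OD cloud: stains mix additively from the origin
    cov = keep.T @ keep / len(keep)
    evals, evecs = np.linalg.eigh(cov)
    if evals[-2] < 1e-8 * evals[-1]:
        raise ValueError("degenerate stain plane: OD cloud is effectively rank 1")
    plane = evecs[:, [-1, -2]]  # columns: dominant direction, then second
    if plane[:, 0].sum() < 0:  # point the dominant axis into the positive octant
        plane[:, 0] *= -1
    proj = keep @ plane
    phi = np.arctan2(proj[:, 1], proj[:, 0])
    lo, hi = np.percentile(phi, [alpha, 100.0 - alpha])
    vectors = []
    for angle in (lo, hi):
        v = plane @ np.array([np.cos(angle), np.sin(angle)])
        if v.sum() < 0:
            v = -v
        v = np.clip(v, 0.0, None)
        vectors.append(v / np.linalg.norm(v))
    # hematoxylin (blue stain) absorbs blue light least, DAB (brown) most:
    # the vector with the smaller blue OD component is hematoxylin
    vectors.sort(key=lambda v: v[2])
    return StainBasis(matrix=np.stack(vectors, axis=1))


def deconvolve(od: np.ndarray, basis: StainBasis) -> ConcentrationMaps:
    """Least-squares per-pixel stain concentrations, clipped nonnegative."""
    pinv = np.linalg.pinv(basis.matrix)  # 2x3
    flat = od.reshape(-1, 3) @ pinv.T
    conc = np.clip(flat, 0.0, None).reshape(od.shape[:-1] + (2,))
    return ConcentrationMaps(hematoxylin=conc[..., 0], dab=conc[..., 1])


def area_proportion(
    channel: np.ndarray,
    annotation: TumorAnnotation,
    threshold_rule: Literal["otsu"] | float = "otsu",
) -> AreaProportionResult:
    """Fraction of annotated pixels strictly above a threshold.

    ``threshold_rule`` is either ``"otsu"`` (computed over the pixels inside
    the annotation) or a fixed numeric threshold.  Pixels exactly at the
    threshold count as negative.  The physical positive area uses the
    annotation's micrometer-per-pixel pitch.
    """
    mask = annotation.mask
    if not mask.any():
        raise ValueError("empty annotation")
    values = np.asarray(channel)[mask]
    if threshold_rule == "otsu":
        threshold = float(threshold_otsu(values))
    else:
        threshold = float(threshold_rule)
    positive = int((values > threshold).sum())
    total = int(mask.sum())
    return AreaProportionResult(
        proportion=positive / total,
        positive_pixels=positive,
        total_pixels=total,
        threshold_used=threshold,
        area_um2=positive * annotation.mpp**2,
    )


def tps_category(proportion_percent: float) -> str:
    """Clinical TPS bin: <1%, 1-49%, or >=50% (boundaries per the labels)."""
    p = float(proportion_percent)
    if not 0 <= p <= 100:
        raise ValueError("proportion_percent must be in [0, 100]")
    if p < 1:
        return TPS_CATEGORIES[0]
    if p < 50:
        return TPS_CATEGORIES[1]
    return TPS_CATEGORIES[2]


def case_summary(proportion_percent: float, tumor_cell_count: int) -> str:
    """TPS category, or ``"excluded"`` when fewer than 100 tumor cells."""
    if tumor_cell_count < 0:
        raise ValueError("negative tumor cell count")
    if tumor_cell_count < MIN_TUMOR_CELLS:
        return EXCLUDED
    return tps_category(proportion_percent)
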