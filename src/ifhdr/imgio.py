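"""I/O and the exposure-stack data model.

Multi-exposure fluorescence acquisitions travel as multi-page 16-bit grayscale
TIFFs holding 12-bit data, with a JSON or YAML sidecar manifest listing one
entry per page (``pages: [{exposure_ms, channel}]``).  Tumor annotations are
8-bit binary PNG masks (0/255).  Pixel grids are row-major with the origin at
the top-left and 0-based indices throughout the package.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile
import yaml

logger = logging.getLogger(__name__)

#: Maximum representable value of the 12-bit camera.
MAX_12BIT = 4095


class Channel(str, Enum):
    """Role of a channel in the acquisition."""

    PDL1 = "PDL1"
    NUCLEI = "NUCLEI"


@dataclass(frozen=True)
class ExposureImage:
    """A single co-registered frame with its exposure time and channel role.

    Parameters
    ----------
    pixels
        2-D non-negative integer array; 12-bit values in a 16-bit container.
    exposure_ms
        Exposure time in milliseconds, strictly positive.
    channel
        :class:`Channel` role (PD-L1 signal or nuclear counterstain).
    virtual
        True for frames derived by erosion/blur augmentation rather than
        acquired by the camera.
    """

    pixels: np.ndarray
    exposure_ms: float
    channel: Channel = Channel.PDL1
    virtual: bool = False

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError(f"pixels must be 2-D, got shape {px.shape}")
        if not np.issubdtype(px.dtype, np.integer):
            raise ValueError("pixels must be an integer array")
        if px.size and px.min() < 0:
            raise ValueError("negative pixel value in 12-bit image")
        if px.size and px.max() > MAX_12BIT:
            raise ValueError(
                f"pixel value {int(px.max())} exceeds the 12-bit maximum "
                f"{MAX_12BIT}; values above 4095 indicate an acquisition error"
            )
        if not self.exposure_ms > 0:
            raise ValueError("nonpositive exposure")
        object.__setattr__(self, "pixels", px)
        object.__setattr__(self, "channel", Channel(self.channel))

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class ExposureStack:
    """An ordered collection of co-registered :class:`ExposureImage` frames."""

    images: list[ExposureImage] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.images:
            raise ValueError("empty stack")
        shapes = {im.shape for im in self.images}
        if len(shapes) > 1:
            raise ValueError(f"shape mismatch across pages: {sorted(shapes)}")
        if not self.pdl1_images():
            raise ValueError("stack contains no PDL1 image")
        orig = [im.exposure_ms for im in self.pdl1_images(virtual=False)]
        if any(b <= a for a, b in zip(orig, orig[1:])):
            raise ValueError(
                "original PDL1 exposure times must be strictly increasing"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.images[0].shape

    def pdl1_images(self, virtual: bool | None = None) -> list[ExposureImage]:
        """PD-L1 frames, optionally restricted by the ``virtual`` flag."""
        out = [im for im in self.images if im.channel is Channel.PDL1]
        if virtual is not None:
            out = [im for im in out if im.virtual == virtual]
        return out

    def nuclei_images(self) -> list[ExposureImage]:
        return [im for im in self.images if im.channel is Channel.NUCLEI]

    @property
    def has_virtual(self) -> bool:
        return any(im.virtual for im in self.images)


@dataclass(frozen=True)
class TumorAnnotation:
    """Boolean tumor mask plus the physical pixel pitch (micrometers/pixel)."""

    mask: np.ndarray
    mpp: float

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        if m.ndim != 2:
            raise ValueError("mask must be 2-D")
        if not self.mpp > 0:
            raise ValueError("mpp must be positive")
        object.__setattr__(self, "mask", m)


def _load_manifest(manifest_path: str | Path) -> list[dict]:
    path = Path(manifest_path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        doc = json.loads(text)
    else:
        doc = yaml.safe_load(text)
    if not isinstance(doc, dict) or "pages" not in doc:
        raise ValueError("manifest must be a mapping with a 'pages' key")
    extra = set(doc) - {"pages"}
    if extra:
        logger.warning("ignoring unknown manifest keys: %s", sorted(extra))
    pages = doc["pages"]
    if not isinstance(pages, list) or not pages:
        raise ValueError("manifest 'pages' must be a nonempty list")
    return pages


def read_exposure_stack(
    image_path: str | Path, manifest_path: str | Path
) -> ExposureStack:
    """Read a multi-page TIFF plus manifest into a validated stack.

    The manifest order defines the stack order; every page is flagged as an
    original (non-virtual) frame.
    """
    pages = _load_manifest(manifest_path)
    with tifffile.TiffFile(image_path) as tif:
        arrays = [p.asarray() for p in tif.pages]
    if len(arrays) != len(pages):
        raise ValueError(
            f"page/manifest count mismatch: TIFF has {len(arrays)} pages, "
            f"manifest lists {len(pages)}"
        )
    images = []
    for arr, meta in zip(arrays, pages):
        images.append(
            ExposureImage(
                pixels=np.asarray(arr).astype(np.uint16),
                exposure_ms=float(meta["exposure_ms"]),
                channel=Channel(meta["channel"]),
                virtual=False,
            )
        )
    return ExposureStack(images=images)


def write_exposure_stack(
    stack: ExposureStack, image_path: str | Path, manifest_path: str | Path
) -> None:
    """Write a stack as a multi-page 16-bit TIFF plus a manifest sidecar."""
    data = np.stack([im.pixels.astype(np.uint16) for im in stack.images])
    tifffile.imwrite(image_path, data, photometric="minisblack")
    manifest = {
        "pages": [
            {
                "exposure_ms": float(im.exposure_ms),
                "channel": im.channel.value,
            }
            for im in stack.images
        ]
    }
    path = Path(manifest_path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(manifest, indent=2))
    else:
        path.write_text(yaml.safe_dump(manifest))


def read_mask(path: str | Path) -> np.ndarray:
    """Read an 8-bit binary PNG mask; 255 maps to True, 0 to False."""
    arr = np.asarray(iio.imread(path))
    if arr.ndim == 3:  # grayscale saved with redundant channels
        if not (arr == arr[..., :1]).all():
            raise ValueError("non-binary mask: multi-channel PNG")
        arr = arr[..., 0]
    values = np.unique(arr)
    if not np.isin(values, (0, 255)).all():
        raise ValueError(f"non-binary mask: found values {values[:10]}")
    return arr == 255


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    iio.imwrite(path, (np.asarray(mask, bool) * 255).astype(np.uint8))


def quantize_levels(pixels: np.ndarray, levels: int = 256) -> np.ndarray:
    """Map 12-bit values onto ``levels`` bins: ``v -> floor(v*levels/4096)``.

    The mapping is monotone non-decreasing; 0 maps to 0 and 4095 to
    ``levels - 1``.  Used to keep the response-curve least-squares system
    small relative to the native 12-bit domain.
    """
    if levels < 2:
        raise ValueError("levels must be >= 2")
    px = np.asarray(pixels)
    return (px.astype(np.int64) * levels) // (MAX_12BIT + 1)
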