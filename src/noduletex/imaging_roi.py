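"""Image patches, ROI masks, NIfTI I/O and the semi-automatic segmentation surrogate.

The segmentation stand-in (rectangle seed -> within-rectangle bimodal threshold ->
largest connected component -> hole filling) replaces an undocumented commercial
algorithm; externally supplied masks are accepted everywhere a mask is needed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence, Tuple

import nibabel as nib
import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

HU_MIN = -1024.0
HU_MAX = 3071.0

#: default HU threshold separating ground-glass from solid attenuation
SOLID_HU_THRESHOLD = -300.0

#: 8-connectivity structuring element
_EIGHT = np.ones((3, 3), dtype=bool)


class Rect(NamedTuple):
    """Half-open axis-aligned rectangle [row0, row1) x [col0, col1)."""

    row0: int
    col0: int
    row1: int
    col1: int

    @property
    def area(self) -> int:
        return (self.row1 - self.row0) * (self.col1 - self.col0)


@dataclass(frozen=True)
class ImagePatch:
    """A 2D grid of Hounsfield-unit values with pixel spacing in mm.

    Spacing is stored at float32 precision so that a NIfTI round trip is exact.
    """

    pixels: np.ndarray
    spacing: Tuple[float, float] = (1.0, 1.0)
    origin: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2:
            raise ValueError(f"pixels must be 2D, got shape {px.shape}")
        if px.shape[0] < 16 or px.shape[1] < 16:
            raise ValueError(f"both dimensions must be >= 16, got {px.shape}")
        if not np.all(np.isfinite(px)):
            raise ValueError("pixel values must be finite")
        if px.min() < HU_MIN or px.max() > HU_MAX:
            raise ValueError(
                f"HU values must lie in [{HU_MIN}, {HU_MAX}], "
                f"got range [{px.min()}, {px.max()}]"
            )
        sp = tuple(float(np.float32(s)) for s in self.spacing)
        if len(sp) != 2 or any(s <= 0 for s in sp):
            raise ValueError(f"spacing must be two positive values, got {self.spacing}")
        object.__setattr__(self, "pixels", px)
        object.__setattr__(self, "spacing", sp)

    @property
    def shape(self) -> Tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class RoiMask:
    """Binary mask congruent with an :class:`ImagePatch`.

    Foreground must be a single 8-connected region of at least 16 pixels.
    """

    mask: np.ndarray
    reader_id: str = ""

    def __post_init__(self) -> None:
        m = np.asarray(self.mask).astype(bool)
        if m.ndim != 2:
            raise ValueError(f"mask must be 2D, got shape {m.shape}")
        n_fg = int(m.sum())
        if n_fg < 16:
            raise ValueError(f"mask must have >= 16 foreground pixels, got {n_fg}")
        _, n_comp = ndimage.label(m, structure=_EIGHT)
        if n_comp != 1:
            raise ValueError(
                f"mask foreground must be one 8-connected region, got {n_comp}"
            )
        object.__setattr__(self, "mask", m)

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


# ---------------------------------------------------------------------------
# segmentation surrogate
# ---------------------------------------------------------------------------

def segment_nodule(
    image: ImagePatch,
    rect: Rect,
    reader_id: str = "auto",
    min_contrast: float = 150.0,
) -> RoiMask:
    """Segment the nodule inside ``rect`` by bimodal-histogram thresholding.

    The intensity threshold is chosen automatically (Otsu split of the
    within-rectangle histogram); the largest 8-connected above-threshold
    component is kept and its holes are filled. ``min_contrast`` guards
    against rectangles containing no bimodal structure (pure background).
    """
    rect = Rect(*(int(v) for v in rect))
    nrow, ncol = image.shape
    if not (0 <= rect.row0 < rect.row1 <= nrow and 0 <= rect.col0 < rect.col1 <= ncol):
        raise ValueError(f"rectangle {rect} not within image of shape {image.shape}")
    if rect.area < 16:
        raise ValueError(f"rectangle area must be >= 16 pixels, got {rect.area}")

    window = image.pixels[rect.row0 : rect.row1, rect.col0 : rect.col1]
    if window.max() - window.min() < min_contrast:
        raise ValueError("empty segmentation: no foreground above threshold in rectangle")
    thr = threshold_otsu(window)
    fg = window > thr
    if not fg.any():
        raise ValueError("empty segmentation: no foreground above threshold in rectangle")

    labels, n_comp = ndimage.label(fg, structure=_EIGHT)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n_comp + 1))
    keep = int(np.argmax(sizes)) + 1
    comp = ndimage.binary_fill_holes(labels == keep)

    full = np.zeros(image.shape, dtype=bool)
    full[rect.row0 : rect.row1, rect.col0 : rect.col1] = comp
    return RoiMask(mask=full, reader_id=reader_id)


def apply_manual_override(auto: RoiMask, manual: Optional[RoiMask] = None) -> RoiMask:
    """Return ``manual`` when provided (validating it), else ``auto`` unchanged."""
    if manual is None:
        return auto
    if manual.mask.shape != auto.mask.shape:
        raise ValueError(
            f"manual mask shape {manual.mask.shape} differs from auto {auto.mask.shape}"
        )
    # construction re-validates connectivity/size invariants
    return RoiMask(mask=manual.mask, reader_id=manual.reader_id)


def select_max_solid_slice(
    stack: Sequence[Tuple[ImagePatch, RoiMask]],
    solid_threshold: float = SOLID_HU_THRESHOLD,
) -> int:
    """Index of the slice whose ROI holds the most solid (above-threshold) pixels.

    Falls back to the largest total ROI area when no pixel in any slice
    exceeds the solid threshold.
    """
    if len(stack) == 0:
        raise ValueError("empty slice stack")
    solid_counts = []
    areas = []
    for image, roi in stack:
        if image.shape != roi.mask.shape:
            raise ValueError("image and mask shapes differ within the stack")
        vals = image.pixels[roi.mask]
        solid_counts.append(int((vals > solid_threshold).sum()))
        areas.append(int(roi.mask.sum()))
    if max(solid_counts) > 0:
        return int(np.argmax(solid_counts))
    return int(np.argmax(areas))


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def _affine(spacing: Tuple[float, float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0] = spacing[0]
    aff[1, 1] = spacing[1]
    return aff


def write_image(image: ImagePatch, path) -> None:
    data = image.pixels[:, :, np.newaxis].astype(np.float64)
    img = nib.Nifti1Image(data, _affine(image.spacing))
    img.header.set_zooms((image.spacing[0], image.spacing[1], 1.0))
    nib.save(img, str(path))


def read_image(path, origin: str = "") -> ImagePatch:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim == 3:
        if data.shape[2] != 1:
            raise ValueError(f"expected a single slice, got shape {data.shape}")
        data = data[:, :, 0]
    zooms = img.header.get_zooms()[:2]
    return ImagePatch(pixels=data, spacing=(float(zooms[0]), float(zooms[1])),
                      origin=origin or str(path))


def write_mask(roi: RoiMask, spacing: Tuple[float, float], path) -> None:
    data = roi.mask[:, :, np.newaxis].astype(np.uint8)
    img = nib.Nifti1Image(data, _affine(spacing))
    img.header.set_zooms((spacing[0], spacing[1], 1.0))
    nib.save(img, str(path))


def read_mask(path, reader_id: str = "") -> RoiMask:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim == 3:
        data = data[:, :, 0]
    return RoiMask(mask=data > 0, reader_id=reader_id or str(path))
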