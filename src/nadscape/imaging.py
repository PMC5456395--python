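"""Immunofluorescence quantification in nuclear sub-compartments.

Quantifies how a stain (e.g. H3K9me3) distributes between the nuclear
periphery and the perinucleolar space.  Shell regions of interest are
bands of fixed physical depth (default 240 nm) measured inward from the
nucleus border or outward from the nucleolus border on the pixel grid
(default 80.25 nm/pixel).  Per-ROI metrics: fraction of total nuclear
intensity, coefficient of variation (sd/mean), and the share of the
brightest nuclear pixels falling in the ROI.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.measure import label as cc_label

LAMINA = "lamina"
PERINUCLEOLAR = "perinucleolar"

DEFAULT_PIXEL_SIZE_NM = 80.25
DEFAULT_SHELL_DEPTH_NM = 240.0


@dataclass
class NucleusImage:
    """Intensity grid with nucleus / nucleolus masks.

    2D single optical sections by default; 3D stacks are supported for
    object counting and volume measurements.  ``pixel_size_xy`` in nm;
    ``z_step`` (nm) applies to 3D stacks only.
    """

    intensity: np.ndarray
    nucleus_mask: np.ndarray
    nucleolus_mask: np.ndarray
    pixel_size_xy: float = DEFAULT_PIXEL_SIZE_NM
    z_step: float = 500.0

    def __post_init__(self) -> None:
        if self.nucleus_mask.shape != self.intensity.shape:
            raise ValueError("nucleus mask shape differs from intensity grid")
        if self.nucleolus_mask.shape != self.intensity.shape:
            raise ValueError("nucleolus mask shape differs from intensity grid")
        if np.any(self.nucleolus_mask & ~self.nucleus_mask):
            raise ValueError("nucleolus mask must lie inside the nucleus mask")
        if self.pixel_size_xy <= 0:
            raise ValueError("pixel size must be positive")


@dataclass
class ShellROI:
    """Boolean shell region at a fixed physical depth from a border."""

    mask: np.ndarray
    origin: str  # LAMINA | PERINUCLEOLAR
    depth_nm: float


@dataclass
class RoiMetrics:
    intensity_fraction: float
    cv: float  # NaN when the ROI mean is zero / ROI empty
    bright_fraction: float  # NaN when no bright pixel exists
    n_pixels: int


def depth_in_pixels(depth_nm: float, pixel_size_nm: float) -> int:
    """Physical shell depth converted to whole pixels (nearest)."""
    return int(round(depth_nm / pixel_size_nm))


def shell_roi(
    image: NucleusImage, origin: str, depth_nm: float = DEFAULT_SHELL_DEPTH_NM
) -> ShellROI:
    """Build a lamina or perinucleolar shell ROI.

    The lamina shell contains nucleus pixels whose Euclidean distance to
    the nucleus boundary is at most ``depth_nm`` (inward); the
    perinucleolar shell contains nucleus pixels outside the nucleolus
    within ``depth_nm`` of the nucleolus boundary (outward).  Depth is
    rounded to whole pixels: 240 nm at 80.25 nm pixels gives 3 pixels.
    """
    depth_px = depth_in_pixels(depth_nm, image.pixel_size_xy)
    if origin == LAMINA:
        base = image.nucleus_mask
        if not base.any():
            warnings.warn("empty nucleus mask: empty shell", stacklevel=2)
            return ShellROI(np.zeros_like(base), origin, depth_nm)
        if depth_px <= 0:
            return ShellROI(np.zeros_like(base), origin, depth_nm)
        dist = ndimage.distance_transform_edt(base)
        mask = base & (dist <= depth_px)
    elif origin == PERINUCLEOLAR:
        if not image.nucleolus_mask.any():
            warnings.warn("empty nucleolus mask: empty shell", stacklevel=2)
            return ShellROI(np.zeros_like(image.nucleolus_mask), origin, depth_nm)
        if depth_px <= 0:
            return ShellROI(np.zeros_like(image.nucleolus_mask), origin, depth_nm)
        dist = ndimage.distance_transform_edt(~image.nucleolus_mask)
        mask = image.nucleus_mask & ~image.nucleolus_mask & (dist <= depth_px)
    else:
        raise ValueError(f"unknown shell origin {origin!r}")
    return ShellROI(mask, origin, depth_nm)


def roi_intensity_stats(
    image: NucleusImage, roi: ShellROI, bright_mode: str = "threshold90"
) -> RoiMetrics:
    """Intensity fraction, C.V. and bright-pixel share for one ROI.

    ``bright_mode``:

    - ``"threshold90"``: bright = nuclear pixels at or above 90% of the
      maximal nuclear intensity;
    - ``"decile"``: bright = the top 10% of nuclear pixels by rank.

    The two rules differ on real images; both are provided.
    """
    if np.any(roi.mask & ~image.nucleus_mask):
        raise ValueError("ROI extends outside the nucleus mask")
    nuc = image.intensity[image.nucleus_mask]
    total = float(nuc.sum())
    roi_vals = image.intensity[roi.mask]
    fraction = float(roi_vals.sum()) / total if total > 0 else math.nan

    if roi_vals.size == 0 or roi_vals.mean() == 0:
        cv = math.nan
    else:
        cv = float(roi_vals.std(ddof=0) / roi_vals.mean())

    if bright_mode == "threshold90":
        cutoff = 0.9 * float(nuc.max())
        bright = image.nucleus_mask & (image.intensity >= cutoff)
    elif bright_mode == "decile":
        k = max(int(math.ceil(0.1 * nuc.size)), 1)
        cutoff = float(np.partition(nuc, nuc.size - k)[nuc.size - k])
        bright = image.nucleus_mask & (image.intensity >= cutoff)
    else:
        raise ValueError(f"unknown bright_mode {bright_mode!r}")
    n_bright = int(bright.sum())
    bright_fraction = (
        float((bright & roi.mask).sum()) / n_bright if n_bright else math.nan
    )
    return RoiMetrics(
        intensity_fraction=fraction,
        cv=cv,
        bright_fraction=bright_fraction,
        n_pixels=int(roi.mask.sum()),
    )


def whole_nucleus_cv(image: NucleusImage) -> float:
    """C.V. of the stain over the whole nucleus mask."""
    vals = image.intensity[image.nucleus_mask]
    if vals.size == 0 or vals.mean() == 0:
        return math.nan
    return float(vals.std(ddof=0) / vals.mean())


def count_objects_and_volumes(
    mask: np.ndarray, voxel_dims_um: tuple[float, ...]
) -> dict:
    """Connected-component count and volumes of a boolean mask.

    3D masks use 26-connectivity, 2D use 8-connectivity.  ``voxel_dims_um``
    are the physical voxel edge lengths in µm (matching mask.ndim);
    volume per object = voxel count × voxel volume (µm³ for 3D stacks,
    µm² area for 2D sections).
    """
    if mask.ndim != len(voxel_dims_um):
        raise ValueError("voxel_dims_um must match mask dimensionality")
    if any(d <= 0 for d in voxel_dims_um):
        raise ValueError("voxel dimensions must be positive")
    if not mask.any():
        return {"count": 0, "voxel_counts": [], "volumes_um3": []}
    labels, n = cc_label(mask, connectivity=mask.ndim, return_num=True)
    counts = np.bincount(labels.ravel())[1:]
    voxel_volume = float(np.prod(voxel_dims_um))
    return {
        "count": int(n),
        "voxel_counts": counts.astype(int).tolist(),
        "volumes_um3": (counts * voxel_volume).tolist(),
    }


def volume_ratio(nucleolus_mask: np.ndarray, nucleus_mask: np.ndarray) -> float:
    """Nucleolar / nuclear volume ratio from voxel counts."""
    n_nuc = int(nucleus_mask.sum())
    if n_nuc == 0:
        return math.nan
    return float(nucleolus_mask.sum()) / n_nuc
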