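"""PERCIST-style tumor segmentation on isotropically resampled SUV volumes.

The segmentation threshold follows the PET response criteria convention:
``T = 1.5 x mean liver SUV + 2 SD``, with the liver statistics taken over a
3-cm spherical volume of interest. Voxels at or above T, minus user-supplied
organ exclusion masks (brain, kidneys, bladder, ...), grouped by
26-connectivity, form the tumor burden mask.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "SuvVolume",
    "LiverReference",
    "SegmentationResult",
    "resample_isotropic",
    "resample_mask",
    "liver_reference",
    "percist_threshold",
    "segment_lesions",
    "read_nifti",
    "write_nifti",
]

#: 3x3x3 structuring element defining 26-connectivity in 3D.
CONNECTIVITY_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True)
class SuvVolume:
    """A 3D grid of standardized uptake values with physical voxel spacing.

    Axes are indexed (i, j, k); voxel (i, j, k) has its *center* at
    ``origin + index * spacing`` (mm). SUV is unitless (body-weight
    normalization) and must be finite and non-negative.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 3:
            raise ValueError(f"SUV volume must be 3D, got ndim={data.ndim}")
        if data.size == 0:
            raise ValueError("SUV volume is empty")
        if not np.all(np.isfinite(data)):
            raise ValueError("SUV volume contains non-finite values")
        if data.min() < 0:
            raise ValueError("SUV values must be >= 0")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be 3 positive floats, got {self.spacing}")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    def physical_extent(self) -> tuple[tuple[float, float], ...]:
        """Per-axis (low, high) physical coordinates of voxel centers (mm)."""
        return tuple(
            (o, o + (n - 1) * s)
            for o, n, s in zip(self.origin, self.shape, self.spacing)
        )


@dataclass(frozen=True)
class LiverReference:
    """Liver background statistics from a spherical VOI (default 3 cm)."""

    center: tuple[float, float, float]
    mean: float
    sd: float
    n_voxels: int
    diameter: float = 30.0

    def __post_init__(self):
        if self.n_voxels <= 0:
            raise ValueError("liver VOI contains no voxels")
        if self.sd < 0:
            raise ValueError("liver SD must be >= 0")


@dataclass
class SegmentationResult:
    """Binary tumor mask plus per-component bookkeeping."""

    mask: np.ndarray
    threshold: float
    component_sizes: dict[int, int] = field(default_factory=dict)
    labels: np.ndarray | None = None
    n_exclusions: int = 0

    @property
    def n_components(self) -> int:
        return len(self.component_sizes)

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


# ---------------------------------------------------------------------------
# NIfTI I/O

def read_nifti(path) -> SuvVolume:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    zooms = img.header.get_zooms()[:3]
    return SuvVolume(data, tuple(float(z) for z in zooms))


def write_nifti(volume: SuvVolume | np.ndarray, path, spacing=None) -> None:
    if isinstance(volume, SuvVolume):
        data, spacing = volume.data, volume.spacing
    else:
        data = np.asarray(volume, dtype=float)
        if spacing is None:
            spacing = (1.0, 1.0, 1.0)
    affine = np.diag(list(spacing) + [1.0])
    nib.save(nib.Nifti1Image(data, affine), str(path))


# ---------------------------------------------------------------------------
# Operations

def _resample_grid(shape, spacing, target):
    """New shape and per-axis sample coordinates (in old voxel units)."""
    new_shape, coords = [], []
    for n, s in zip(shape, spacing):
        m = int(np.floor((n - 1) * s / target)) + 1
        new_shape.append(m)
        coords.append(np.arange(m) * (target / s))
    return tuple(new_shape), coords


def resample_isotropic(volume: SuvVolume, target: float = 1.0) -> SuvVolume:
    """Trilinearly resample a volume to isotropic voxels of ``target`` mm.

    The output grid shares the input origin; new voxel centers are placed
    every ``target`` mm and interpolated from the old voxel centers, so a
    volume already at the target spacing is returned unchanged.
    """
    if target <= 0:
        raise ValueError("target spacing must be > 0")
    if all(abs(s - target) < 1e-12 for s in volume.spacing):
        return SuvVolume(volume.data.copy(), volume.spacing, volume.origin)
    new_shape, coords = _resample_grid(volume.shape, volume.spacing, target)
    grid = np.meshgrid(*coords, indexing="ij")
    out = ndimage.map_coordinates(
        volume.data, np.stack(grid), order=1, mode="nearest"
    ).reshape(new_shape)
    # trilinear interpolation of non-negative data can produce -1e-17 noise
    np.clip(out, 0.0, None, out=out)
    return SuvVolume(out, (target,) * 3, volume.origin)


def resample_mask(mask: np.ndarray, spacing, target: float = 1.0) -> np.ndarray:
    """Nearest-neighbor resampling of a binary mask to isotropic voxels."""
    mask = np.asarray(mask)
    if all(abs(s - target) < 1e-12 for s in spacing):
        return mask.astype(bool).copy()
    new_shape, coords = _resample_grid(mask.shape, spacing, target)
    grid = np.meshgrid(*coords, indexing="ij")
    out = ndimage.map_coordinates(
        mask.astype(np.uint8), np.stack(grid), order=0, mode="nearest"
    ).reshape(new_shape)
    return out.astype(bool)


def sphere_mask(shape, spacing, center, radius, origin=(0.0, 0.0, 0.0)) -> np.ndarray:
    """Boolean mask of voxels whose centers lie within ``radius`` mm of
    ``center`` (inclusive: distance <= radius)."""
    axes = [o + np.arange(n) * s for o, n, s in zip(origin, shape, spacing)]
    zz, yy, xx = np.meshgrid(*axes, indexing="ij")
    d2 = (zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2
    return d2 <= radius**2 + 1e-9


def liver_reference(
    volume: SuvVolume, center, diameter: float = 30.0
) -> LiverReference:
    """Mean and population SD of SUV in a spherical liver VOI.

    ``center`` is in mm. A voxel belongs to the sphere when its center lies
    within ``diameter / 2`` mm of the sphere center (inclusive).
    """
    radius = diameter / 2.0
    for (lo, hi), c in zip(volume.physical_extent(), center):
        if c - radius < lo - 1e-9 or c + radius > hi + 1e-9:
            raise ValueError(
                f"liver VOI (center {tuple(center)}, radius {radius} mm) "
                "extends outside the volume"
            )
    voi = sphere_mask(volume.shape, volume.spacing, center, radius, volume.origin)
    values = volume.data[voi]
    return LiverReference(
        center=tuple(float(c) for c in center),
        mean=float(values.mean()),
        sd=float(values.std(ddof=0)),
        n_voxels=int(values.size),
        diameter=float(diameter),
    )


def percist_threshold(ref: LiverReference) -> float:
    """Segmentation threshold T = 1.5 * mean liver SUV + 2 * SD."""
    return 1.5 * ref.mean + 2.0 * ref.sd


def segment_lesions(
    volume: SuvVolume,
    threshold: float,
    exclusions: list[np.ndarray] | None = None,
    min_component_size: int = 64,
) -> SegmentationResult:
    """Threshold the volume at ``threshold`` (inclusive, SUV >= T), remove
    exclusion-mask voxels, and keep 26-connected components of at least
    ``min_component_size`` voxels.

    An empty result (no voxel above threshold, or everything excluded or too
    small) is returned with a warning rather than raised.
    """
    mask = volume.data >= threshold
    exclusions = list(exclusions or [])
    for excl in exclusions:
        excl = np.asarray(excl, dtype=bool)
        if excl.shape != mask.shape:
            raise ValueError(
                f"exclusion mask shape {excl.shape} != volume shape {mask.shape}"
            )
        mask &= ~excl
    labels, n = ndimage.label(mask, structure=CONNECTIVITY_26)
    sizes = np.bincount(labels.ravel())
    component_sizes = {}
    for lab in range(1, n + 1):
        if sizes[lab] >= min_component_size:
            component_sizes[lab] = int(sizes[lab])
        else:
            keep = labels == lab
            mask[keep] = False
            labels[keep] = 0
    if not component_sizes:
        warnings.warn(
            f"no lesion voxels at threshold {threshold:.3g} "
            f"(min component size {min_component_size})",
            stacklevel=2,
        )
    return SegmentationResult(
        mask=mask,
        threshold=float(threshold),
        component_sizes=component_sizes,
        labels=labels,
        n_exclusions=len(exclusions),
    )
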