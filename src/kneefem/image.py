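"""Voxel image and label mask containers.

Conventions used throughout the package (stated once, here):

* arrays are indexed ``values[ix, iy, iz]``; axis 2 (+z) is the superior
  direction of the joint,
* voxel spacing is isotropic and carried in micrometres,
* the physical coordinate (mm) of the centre of voxel ``(i, j, k)`` is
  ``origin_mm + spacing_mm * (i, j, k)``, with 0-based indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "VoxelImage",
    "LabelMask",
    "TISSUES",
    "save_nifti",
    "load_nifti",
    "save_tiff",
    "load_tiff",
]

#: tissue names a :class:`LabelMask` may carry
TISSUES = (
    "femur_bone",
    "tibia_bone",
    "femur_cartilage",
    "tibia_cartilage",
    "calcified_meniscus",
    "soft_meniscus",
)

_GRID_ATOL_MM = 1e-9


@dataclass
class VoxelImage:
    """3D scalar image with isotropic physical spacing.

    Parameters
    ----------
    values
        3D float array, indexed ``[ix, iy, iz]``.
    spacing_um
        Isotropic voxel edge length in micrometres.
    origin_mm
        Physical coordinate (mm) of the centre of voxel ``(0, 0, 0)``.
    """

    values: np.ndarray
    spacing_um: float
    origin_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError("VoxelImage requires a 3D array")
        if not self.spacing_um > 0:
            raise ValueError("spacing must be positive")
        self.origin_mm = np.asarray(self.origin_mm, dtype=float).reshape(3)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("image contains non-finite values")

    # -- grid helpers -------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def spacing_mm(self) -> float:
        return self.spacing_um * 1e-3

    @property
    def voxel_volume_mm3(self) -> float:
        return self.spacing_mm**3

    def same_grid(self, other: "VoxelImage | LabelMask") -> bool:
        return (
            self.shape == other.shape
            and abs(self.spacing_um - other.spacing_um) * 1e-3 < _GRID_ATOL_MM
            and np.allclose(self.origin_mm, other.origin_mm, atol=_GRID_ATOL_MM)
        )

    def axis_coords_mm(self, axis: int) -> np.ndarray:
        """Physical coordinates (mm) of voxel centres along one axis."""
        n = self.shape[axis]
        return self.origin_mm[axis] + self.spacing_mm * np.arange(n)

    def coordinate_grids_mm(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Broadcastable physical-coordinate arrays (mm) for all voxels."""
        cx = self.axis_coords_mm(0)[:, None, None]
        cy = self.axis_coords_mm(1)[None, :, None]
        cz = self.axis_coords_mm(2)[None, None, :]
        return cx, cy, cz

    def with_values(self, values: np.ndarray) -> "VoxelImage":
        return replace(self, values=values)


@dataclass
class LabelMask:
    """Boolean tissue mask sharing the grid of a :class:`VoxelImage`."""

    values: np.ndarray
    spacing_um: float
    origin_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))
    tissue: str = "femur_bone"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values).astype(bool)
        if self.values.ndim != 3:
            raise ValueError("LabelMask requires a 3D array")
        if not self.spacing_um > 0:
            raise ValueError("spacing must be positive")
        self.origin_mm = np.asarray(self.origin_mm, dtype=float).reshape(3)

    shape = VoxelImage.shape
    spacing_mm = VoxelImage.spacing_mm
    voxel_volume_mm3 = VoxelImage.voxel_volume_mm3
    same_grid = VoxelImage.same_grid
    axis_coords_mm = VoxelImage.axis_coords_mm
    coordinate_grids_mm = VoxelImage.coordinate_grids_mm

    @property
    def count(self) -> int:
        return int(self.values.sum())

    @property
    def volume_mm3(self) -> float:
        return self.count * self.voxel_volume_mm3

    def with_values(self, values: np.ndarray, tissue: str | None = None) -> "LabelMask":
        return replace(
            self, values=np.asarray(values).astype(bool),
            tissue=self.tissue if tissue is None else tissue,
        )

    def as_image(self) -> VoxelImage:
        return VoxelImage(self.values.astype(float), self.spacing_um, self.origin_mm)


# -- I/O ---------------------------------------------------------------


def _affine(img: VoxelImage | LabelMask) -> np.ndarray:
    aff = np.diag([img.spacing_mm] * 3 + [1.0])
    aff[:3, 3] = img.origin_mm
    return aff


def save_nifti(img: VoxelImage | LabelMask, path) -> None:
    import nibabel as nib

    data = img.values.astype(np.uint8) if isinstance(img, LabelMask) else np.asarray(
        img.values, dtype=np.float32
    )
    nib.save(nib.Nifti1Image(data, _affine(img)), str(path))


def load_nifti(path, mask: bool = False, tissue: str = "femur_bone"):
    import nibabel as nib

    ni = nib.load(str(path))
    aff = ni.affine
    spacing_mm = float(aff[0, 0])
    origin = np.asarray(aff[:3, 3], dtype=float)
    data = np.asarray(ni.dataobj)
    if mask:
        return LabelMask(data > 0, spacing_mm * 1e3, origin, tissue)
    return VoxelImage(np.asarray(data, dtype=float), spacing_mm * 1e3, origin)


def save_tiff(img: VoxelImage | LabelMask, path) -> None:
    """Write a multipage TIFF; pages run along z (superior last page)."""
    import tifffile

    data = img.values.astype(np.uint8) if isinstance(img, LabelMask) else np.asarray(
        img.values, dtype=np.float32
    )
    # tifffile expects (pages, height, width) = (z, y, x)
    tifffile.imwrite(str(path), np.transpose(data, (2, 1, 0)))


def load_tiff(path, spacing_um: float, origin_mm=(0.0, 0.0, 0.0),
              mask: bool = False, tissue: str = "femur_bone"):
    import tifffile

    data = np.transpose(tifffile.imread(str(path)), (2, 1, 0))
    if mask:
        return LabelMask(data > 0, spacing_um, np.asarray(origin_mm), tissue)
    return VoxelImage(np.asarray(data, dtype=float), spacing_um, np.asarray(origin_mm))
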