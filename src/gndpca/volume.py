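"""Volume container and file I/O (NIfTI and MetaImage).

A :class:`Volume` is a 3D scalar grid with voxel spacing and a physical
origin; axes are ordered (x, y, z) and voxel indices are 0-based.  The
physical position of voxel (i, j, k) is ``origin + (i, j, k) * spacing``.

NIfTI files are handled with nibabel, MetaImage (.mha / .mhd) with SimpleITK.
Only axis-aligned geometries are produced or expected; direction matrices
other than the identity are rejected rather than silently reinterpreted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["Volume", "read_volume", "write_volume"]

_NIFTI_EXT = (".nii", ".nii.gz")
_META_EXT = (".mha", ".mhd")


@dataclass
class Volume:
    """3D scalar image with geometry.

    Attributes
    ----------
    data : ndarray, shape (nx, ny, nz)
        Voxel intensities (float64).
    spacing : ndarray, shape (3,)
        Voxel size along each axis, in mm.
    origin : ndarray, shape (3,)
        Physical coordinates of voxel (0, 0, 0), in mm.
    """

    data: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.data.ndim}")
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if np.any(self.spacing <= 0):
            raise ValueError(f"spacing must be positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def extent(self) -> np.ndarray:
        """Physical size of the grid: (shape - 1) * spacing."""
        return (np.asarray(self.shape) - 1) * self.spacing

    @property
    def center(self) -> np.ndarray:
        """Physical center of the grid."""
        return self.origin + 0.5 * self.extent

    def physical_to_voxel(self, pts: np.ndarray) -> np.ndarray:
        """Map physical coordinates (…, 3) to fractional voxel indices."""
        return (np.asarray(pts, dtype=float) - self.origin) / self.spacing

    def voxel_to_physical(self, idx: np.ndarray) -> np.ndarray:
        """Map (fractional) voxel indices (…, 3) to physical coordinates."""
        return np.asarray(idx, dtype=float) * self.spacing + self.origin

    def like(self, data: np.ndarray) -> "Volume":
        """A new Volume with the same geometry and different intensities."""
        return Volume(np.asarray(data, dtype=float), self.spacing.copy(), self.origin.copy())


def _ext_of(path: Path) -> str:
    name = path.name.lower()
    if name.endswith(".nii.gz"):
        return ".nii.gz"
    return path.suffix.lower()


def read_volume(path) -> Volume:
    """Read a NIfTI (.nii/.nii.gz) or MetaImage (.mha/.mhd) volume."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume file not found: {path}")
    ext = _ext_of(path)
    if ext in _NIFTI_EXT:
        import nibabel as nib

        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=float)
        if data.ndim != 3:
            raise ValueError(f"{path}: expected a 3D volume, got shape {data.shape}")
        affine = img.affine
        rot = affine[:3, :3]
        spacing = np.sqrt((rot**2).sum(axis=0))
        if not np.allclose(rot, np.diag(spacing), atol=1e-6):
            raise ValueError(f"{path}: only axis-aligned NIfTI volumes are supported")
        return Volume(data, spacing, affine[:3, 3])
    if ext in _META_EXT:
        import SimpleITK as sitk

        img = sitk.ReadImage(str(path))
        if img.GetDimension() != 3:
            raise ValueError(f"{path}: expected a 3D volume")
        if not np.allclose(np.asarray(img.GetDirection()).reshape(3, 3), np.eye(3)):
            raise ValueError(f"{path}: only identity-direction MetaImage volumes are supported")
        # SimpleITK arrays are indexed (z, y, x)
        data = sitk.GetArrayFromImage(img).astype(float).transpose(2, 1, 0)
        return Volume(data, np.asarray(img.GetSpacing()), np.asarray(img.GetOrigin()))
    raise ValueError(
        f"unsupported volume format {ext!r} for {path}; "
        f"supported extensions: {', '.join(_NIFTI_EXT + _META_EXT)}"
    )


def write_volume(v: Volume, path) -> None:
    """Write a volume as NIfTI or MetaImage, chosen by extension."""
    path = Path(path)
    ext = _ext_of(path)
    if ext in _NIFTI_EXT:
        import nibabel as nib

        affine = np.eye(4)
        affine[:3, :3] = np.diag(v.spacing)
        affine[:3, 3] = v.origin
        nib.save(nib.Nifti1Image(v.data.astype(np.float64), affine), str(path))
        return
    if ext in _META_EXT:
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(v.data.astype(np.float64).transpose(2, 1, 0))
        img.SetSpacing(tuple(float(s) for s in v.spacing))
        img.SetOrigin(tuple(float(o) for o in v.origin))
        sitk.WriteImage(img, str(path))
        return
    raise ValueError(
        f"unsupported volume format {ext!r} for {path}; "
        f"supported extensions: {', '.join(_NIFTI_EXT + _META_EXT)}"
    )
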