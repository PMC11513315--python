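"""In-memory containers for scalar and tensor voxel volumes, with NIfTI-1 I/O.

A :class:`VoxelVolume` is a 3D scalar field (T1 intensities, masks, bias
fields) with physical voxel spacing carried in a NIfTI affine.  A
:class:`TensorVolume` stores one symmetric diffusion tensor per voxel as six
components in ``(xx, xy, xz, yy, yz, zz)`` order, units mm²/s, with the x/y/z
axes fixed as left-right / anterior-posterior / superior-inferior.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

#: component order of the 4th axis of a TensorVolume / tensor NIfTI file
TENSOR_COMPONENTS = ("xx", "xy", "xz", "yy", "yz", "zz")


def _affine_from_spacing(spacing_mm) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = np.asarray(spacing_mm, dtype=float)
    return aff


@dataclass
class VoxelVolume:
    """3D scalar field with physical geometry.

    Parameters
    ----------
    values
        3D array of voxel values.
    affine
        4x4 voxel-to-mm affine (NIfTI convention).  Use
        :meth:`from_spacing` for axis-aligned grids.
    """

    values: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3D array, got shape {self.values.shape}")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if np.any(self.spacing_mm <= 0):
            raise ValueError("voxel spacing must be strictly positive")

    @classmethod
    def from_spacing(cls, values: np.ndarray, spacing_mm=(1.0, 1.0, 1.0)) -> "VoxelVolume":
        return cls(np.asarray(values), _affine_from_spacing(spacing_mm))

    @property
    def shape(self) -> tuple:
        return self.values.shape

    @property
    def spacing_mm(self) -> np.ndarray:
        """Per-axis voxel size in mm (column norms of the affine)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def like(self, values: np.ndarray) -> "VoxelVolume":
        """New volume with the same geometry but different values."""
        if np.asarray(values).shape != self.shape:
            raise ValueError("shape mismatch")
        return VoxelVolume(np.asarray(values), self.affine.copy())

    def voxel_centers_mm(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Physical (mm) coordinates of every voxel center, one array per axis."""
        idx = np.indices(self.shape, dtype=float)
        hom = np.stack([idx[0], idx[1], idx[2], np.ones(self.shape)])
        out = np.einsum("ij,j...->i...", self.affine, hom)
        return out[0], out[1], out[2]


@dataclass
class TensorVolume:
    """Per-voxel symmetric diffusion tensors (mm²/s).

    ``components`` has shape ``grid + (6,)`` in :data:`TENSOR_COMPONENTS`
    order.
    """

    components: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.components = np.asarray(self.components, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.components.ndim != 4 or self.components.shape[-1] != 6:
            raise ValueError("tensor components must have shape (nx, ny, nz, 6)")

    @classmethod
    def from_spacing(cls, components, spacing_mm=(1.0, 1.0, 1.0)) -> "TensorVolume":
        return cls(np.asarray(components), _affine_from_spacing(spacing_mm))

    @property
    def shape(self) -> tuple:
        return self.components.shape[:3]

    @property
    def spacing_mm(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def as_matrices(self) -> np.ndarray:
        """Dense (..., 3, 3) symmetric matrices."""
        c = self.components
        m = np.empty(c.shape[:-1] + (3, 3))
        m[..., 0, 0] = c[..., 0]
        m[..., 0, 1] = m[..., 1, 0] = c[..., 1]
        m[..., 0, 2] = m[..., 2, 0] = c[..., 2]
        m[..., 1, 1] = c[..., 3]
        m[..., 1, 2] = m[..., 2, 1] = c[..., 4]
        m[..., 2, 2] = c[..., 5]
        return m

    def geometry(self) -> VoxelVolume:
        """Scalar-volume view of the grid geometry (values all zero)."""
        return VoxelVolume(np.zeros(self.shape), self.affine.copy())


def read_volume(path) -> VoxelVolume:
    """Read a 3D scalar NIfTI-1 volume."""
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several format errors
        raise ValueError(f"{path}: not a readable NIfTI file ({exc})") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got shape {data.shape}")
    return VoxelVolume(data, img.affine)


def write_volume(vol: VoxelVolume, path) -> None:
    """Write a scalar volume as NIfTI-1; masks should be uint8 {0,1}."""
    img = nib.Nifti1Image(vol.values, vol.affine)
    nib.save(img, str(path))


def read_tensor_volume(path) -> TensorVolume:
    """Read a tensor NIfTI: 4D with 6 components in (xx,xy,xz,yy,yz,zz) order."""
    try:
        img = nib.load(str(path))
    except Exception as exc:
        raise ValueError(f"{path}: not a readable NIfTI file ({exc})") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4 or data.shape[-1] != 6:
        raise ValueError(f"{path}: expected a 4D x6-component tensor volume, got shape {data.shape}")
    return TensorVolume(data, img.affine)


def write_tensor_volume(tv: TensorVolume, path) -> None:
    img = nib.Nifti1Image(tv.components, tv.affine)
    img.header["descrip"] = b"tensor components: xx,xy,xz,yy,yz,zz (mm^2/s)"
    nib.save(img, str(path))


def check_aligned(a: VoxelVolume, b: VoxelVolume, names=("first", "second")) -> None:
    """Raise if two volumes disagree in shape or affine."""
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch between {names[0]} {a.shape} and {names[1]} {b.shape}")
    if not np.allclose(a.affine, b.affine, atol=1e-6):
        raise ValueError(f"affine mismatch between {names[0]} and {names[1]}")
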