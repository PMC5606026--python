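"""Core spatial types: image grids, label masks, deformation fields, rigid transforms.

All geometry is expressed in world millimeters through the image affine
(voxel index -> world position). No cross-grid arithmetic is ever done in
index space: sagittal spine acquisitions have strongly anisotropic voxels
(about 1.25 x 1.25 mm in plane, 4.4 mm between slice centers), so a rigid
motion in index space would not be rigid in the scanner frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = [
    "VolumeGrid",
    "LabelMask",
    "DeformationField",
    "RigidTransform",
    "GridMismatchError",
]


class GridMismatchError(ValueError):
    """Two objects expected on the same voxel grid are not."""


def _check_affine(affine: np.ndarray) -> np.ndarray:
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4):
        raise ValueError(f"affine must be 4x4, got {affine.shape}")
    if not np.allclose(affine[3], [0, 0, 0, 1]):
        raise ValueError("affine last row must be [0, 0, 0, 1]")
    return affine


def world_from_voxel(affine: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Map voxel indices (..., 3) to world coordinates in mm."""
    idx = np.asarray(idx, dtype=float)
    return idx @ affine[:3, :3].T + affine[:3, 3]


def voxel_from_world(affine: np.ndarray, pts: np.ndarray) -> np.ndarray:
    """Map world coordinates (..., 3) to fractional voxel indices."""
    inv = np.linalg.inv(affine)
    pts = np.asarray(pts, dtype=float)
    return pts @ inv[:3, :3].T + inv[:3, 3]


@dataclass
class _Grid:
    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.data.ndim}")
        self.affine = _check_affine(self.affine)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def spacing(self) -> np.ndarray:
        """Per-axis voxel pitch in mm (column norms of the affine)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def same_grid(self, other: "_Grid | DeformationField") -> bool:
        return self.shape == other.shape and np.allclose(self.affine, other.affine)

    def require_same_grid(self, other: "_Grid | DeformationField", what: str = "operand") -> None:
        if not self.same_grid(other):
            raise GridMismatchError(
                f"{what}: grids differ (shape {self.shape} vs {other.shape})"
            )

    def world_coords(self, idx: np.ndarray) -> np.ndarray:
        return world_from_voxel(self.affine, idx)

    def voxel_coords(self, pts: np.ndarray) -> np.ndarray:
        return voxel_from_world(self.affine, pts)

    def all_voxel_centers(self) -> np.ndarray:
        """World coordinates of every voxel center, shape (*grid, 3)."""
        idx = np.stack(
            np.meshgrid(*[np.arange(s) for s in self.shape], indexing="ij"), axis=-1
        )
        return self.world_coords(idx)


@dataclass
class VolumeGrid(_Grid):
    """A 3D scalar image with world geometry."""

    def __post_init__(self) -> None:
        super().__post_init__()
        self.data = self.data.astype(np.float64, copy=False)

    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(self.data.astype(np.float32), self.affine)

    def save(self, path) -> None:
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def load(cls, path) -> "VolumeGrid":
        img = nib.load(str(path))
        return cls(np.asanyarray(img.dataobj, dtype=np.float64), img.affine)


@dataclass
class LabelMask(_Grid):
    """Integer mask: 0 = background, 1..24 = vertebral bodies C2..S1."""

    def __post_init__(self) -> None:
        super().__post_init__()
        self.data = np.rint(np.asarray(self.data)).astype(np.int16)
        if self.data.min() < 0:
            raise ValueError("label mask must be non-negative")

    @property
    def labels(self) -> np.ndarray:
        """Sorted nonzero labels present in the mask."""
        u = np.unique(self.data)
        return u[u != 0]

    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(self.data.astype(np.int16), self.affine)

    def save(self, path) -> None:
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def load(cls, path) -> "LabelMask":
        img = nib.load(str(path))
        return cls(np.asanyarray(img.dataobj), img.affine)


@dataclass
class DeformationField:
    """Dense displacement field on the fixed-image grid.

    ``displacement[i, j, k]`` is the world-frame mm displacement taking the
    fixed-image (TP1) position of voxel (i, j, k) to its corresponding
    position in the moving image (TP2).
    """

    displacement: np.ndarray  # (*grid, 3), mm
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.displacement = np.asarray(self.displacement, dtype=np.float64)
        if self.displacement.ndim != 4 or self.displacement.shape[-1] != 3:
            raise ValueError(
                f"displacement must have shape (*grid, 3), got {self.displacement.shape}"
            )
        self.affine = _check_affine(self.affine)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.displacement.shape[:3]  # type: ignore[return-value]

    @property
    def spacing(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def world_coords(self, idx: np.ndarray) -> np.ndarray:
        return world_from_voxel(self.affine, idx)

    def mapped_positions(self) -> np.ndarray:
        """World position each fixed voxel maps to, shape (*grid, 3)."""
        idx = np.stack(
            np.meshgrid(*[np.arange(s) for s in self.shape], indexing="ij"), axis=-1
        )
        return world_from_voxel(self.affine, idx) + self.displacement

    def to_nifti(self) -> nib.Nifti1Image:
        img = nib.Nifti1Image(self.displacement.astype(np.float32), self.affine)
        img.header.set_intent("vector")
        return img

    def save(self, path) -> None:
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def load(cls, path) -> "DeformationField":
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj, dtype=np.float64)
        if data.ndim == 5:  # (x, y, z, 1, 3) NIfTI vector convention
            data = data[:, :, :, 0, :]
        return cls(data, img.affine)


_ORTHO_TOL = 1e-10


@dataclass
class RigidTransform:
    """Proper rigid transform in world coordinates: p -> R p + t (mm)."""

    rotation: np.ndarray
    translation: np.ndarray
    rms_residual_mm: float = 0.0

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=np.float64)
        self.translation = np.asarray(self.translation, dtype=np.float64).reshape(3)
        if self.rotation.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        err = np.abs(self.rotation.T @ self.rotation - np.eye(3)).max()
        if err > _ORTHO_TOL:
            raise ValueError(f"rotation not orthonormal (max deviation {err:.2e})")
        if np.linalg.det(self.rotation) < 0:
            raise ValueError("rotation must be proper (det = +1)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        return pts @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation, self.rms_residual_mm)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return self o other (apply ``other`` first)."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    @property
    def angle_deg(self) -> float:
        """Rotation angle about the transform's axis, in degrees."""
        c = np.clip((np.trace(self.rotation) - 1.0) / 2.0, -1.0, 1.0)
        return float(np.degrees(np.arccos(c)))

    def to_matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    @classmethod
    def from_matrix(cls, m: np.ndarray, rms_residual_mm: float = 0.0) -> "RigidTransform":
        m = np.asarray(m, dtype=float)
        return cls(m[:3, :3], m[:3, 3], rms_residual_mm)

    @classmethod
    def about_center(
        cls, rotation: np.ndarray, center: np.ndarray, translation: np.ndarray
    ) -> "RigidTransform":
        """Rotation about ``center`` followed by ``translation``, as a world-frame transform."""
        rotation = np.asarray(rotation, dtype=float)
        center = np.asarray(center, dtype=float)
        t = center - rotation @ center + np.asarray(translation, dtype=float)
        return cls(rotation, t)


def rotation_about_axis(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rodrigues rotation matrix for a unit axis and angle."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    k = np.array(
        [
            [0, -axis[2], axis[1]],
            [axis[2], 0, -axis[0]],
            [-axis[1], axis[0], 0],
        ]
    )
    return np.eye(3) + np.sin(angle_rad) * k + (1 - np.cos(angle_rad)) * (k @ k)
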