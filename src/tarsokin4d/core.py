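"""Core containers: axis-aligned intensity volumes and rigid transforms.

All physical coordinates are millimetres in a fixed world frame; volumes are
axis-aligned (no oblique direction cosines), so the world coordinate of voxel
(i, j, k) is ``origin + (i, j, k) * spacing``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "VoxelGrid",
    "RigidTransform",
    "TarsokinError",
    "FormatError",
    "SizingError",
    "OutOfFieldError",
]


class TarsokinError(Exception):
    """Base class for pipeline errors."""


class FormatError(TarsokinError):
    """Malformed file or non-rigid matrix on read."""


class SizingError(TarsokinError):
    """Grid too small to contain the requested phantom geometry."""


class OutOfFieldError(TarsokinError):
    """A transform moves a bone (partly) outside the volume."""


_ORTHO_TOL = 1e-9


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion ``x -> R x + t`` (rotation matrix + mm translation).

    The rotation must be orthonormal with determinant +1 to within 1e-9;
    composition and inversion stay closed under those invariants.
    """

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
            raise ValueError("rotation is not orthonormal")
        if not abs(np.linalg.det(R) - 1.0) < 1e-8:
            raise ValueError("rotation determinant is not +1 (improper rotation)")
        # re-orthonormalise via SVD so chained compositions do not drift
        u, _, vt = np.linalg.svd(R)
        R = u @ vt
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        self.rotation.setflags(write=False)
        self.translation.setflags(write=False)

    # -- constructors ------------------------------------------------------
    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_matrix(cls, m: np.ndarray) -> "RigidTransform":
        """Build from a 4x4 homogeneous matrix (validates rigidity)."""
        m = np.asarray(m, dtype=float)
        if m.shape != (4, 4):
            raise FormatError(f"expected a 4x4 homogeneous matrix, got shape {m.shape}")
        if not np.allclose(m[3], [0.0, 0.0, 0.0, 1.0], atol=1e-6):
            raise FormatError("bottom row of homogeneous matrix is not [0,0,0,1]")
        R = m[:3, :3]
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-6):
            raise FormatError("matrix rotation block is not orthonormal")
        if np.linalg.det(R) < 0:
            raise FormatError("matrix has negative determinant (reflection, not rigid)")
        return cls(R, m[:3, 3])

    @classmethod
    def from_euler_zyx(
        cls, x_deg: float, y_deg: float, z_deg: float, translation=(0.0, 0.0, 0.0)
    ) -> "RigidTransform":
        """Rotation composed as ``Rz(z) @ Ry(y) @ Rx(x)`` (ZYX Cardan)."""
        return cls(rotation_zyx(x_deg, y_deg, z_deg), np.asarray(translation, float))

    @classmethod
    def rotation_about_point(
        cls, rotation: np.ndarray, center, extra_translation=(0.0, 0.0, 0.0)
    ) -> "RigidTransform":
        """Rotate about ``center`` then translate by ``extra_translation``."""
        c = np.asarray(center, float)
        R = np.asarray(rotation, float)
        return cls(R, c - R @ c + np.asarray(extra_translation, float))

    # -- algebra -----------------------------------------------------------
    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map mm point(s); accepts shape (3,) or (N, 3)."""
        p = np.asarray(points, dtype=float)
        return p @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return ``self ∘ other`` (apply *other* first)."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        return self.compose(other)

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)

    def as_matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    def is_identity(self, atol: float = 1e-12) -> bool:
        return np.allclose(self.rotation, np.eye(3), atol=atol) and np.allclose(
            self.translation, 0.0, atol=atol
        )


def rotation_zyx(x_deg: float, y_deg: float, z_deg: float) -> np.ndarray:
    """Rotation matrix ``Rz(z) @ Ry(y) @ Rx(x)`` with angles in degrees."""
    ax, ay, az = np.deg2rad([x_deg, y_deg, z_deg])
    cx, sx = np.cos(ax), np.sin(ax)
    cy, sy = np.cos(ay), np.sin(ay)
    cz, sz = np.cos(az), np.sin(az)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return rz @ ry @ rx


@dataclass
class VoxelGrid:
    """A 3D scalar intensity volume with physical spacing and origin (mm).

    ``intensities`` is indexed (i, j, k) along the world (X, Y, Z) axes.
    """

    intensities: np.ndarray
    spacing: tuple = (1.0, 1.0, 1.0)
    origin: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 3:
            raise ValueError("intensities must be a 3D array")
        if min(self.intensities.shape) < 1:
            raise ValueError("dims components must be >= 1")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing components must be positive")

    @property
    def dims(self) -> tuple:
        return self.intensities.shape

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        """Continuous voxel indices for mm point(s)."""
        p = np.asarray(points, dtype=float)
        return (p - np.asarray(self.origin)) / np.asarray(self.spacing)

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        i = np.asarray(idx, dtype=float)
        return np.asarray(self.origin) + i * np.asarray(self.spacing)

    @property
    def physical_extent(self) -> np.ndarray:
        """(2, 3) array of min/max world coordinates of voxel centers."""
        lo = np.asarray(self.origin)
        hi = lo + (np.asarray(self.dims) - 1) * np.asarray(self.spacing)
        return np.vstack([lo, hi])

    def contains_points(self, points: np.ndarray) -> np.ndarray:
        idx = self.world_to_index(points)
        dims = np.asarray(self.dims)
        return np.all((idx >= 0) & (idx <= dims - 1), axis=-1)

    def same_geometry(self, other: "VoxelGrid", atol: float = 1e-9) -> bool:
        return (
            self.dims == other.dims
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )

    def copy(self) -> "VoxelGrid":
        return VoxelGrid(self.intensities.copy(), self.spacing, self.origin)
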