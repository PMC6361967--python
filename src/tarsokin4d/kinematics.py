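"""Talocrural kinematic parameters from per-frame rigid transforms.

Three quantities describe the motion of the talus relative to the tibia:

1. ZYX Cardan angles ``R = Rz(z) @ Ry(y) @ Rx(x)`` — x: dorsi-/plantar-
   flexion, y: pronation/supination, z: ab-/adduction;
2. displacement of the centre of the trochlea tali — transformed coordinates
   minus the time-point-0 coordinates;
3. the finite helical axis (FHA) of the displacement, extracted in the
   Spoor–Veldpaus least-squares form: the unique screw axis such that the
   motion is a rotation about, plus a translation along, one line in space.

Axis orientations are reported as lines (sign-ambiguous); for summaries the
direction is canonicalized so its X-component is <= 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import RigidTransform, rotation_zyx

__all__ = [
    "CardanAngles",
    "HelicalAxis",
    "KinematicTrack",
    "AxisSummary",
    "DegenerateRotationError",
    "cardan_zyx",
    "landmark_displacement",
    "finite_helical_axis",
    "axis_plane_intersection",
    "projected_axis_angle",
    "track_from_transforms",
    "axis_summary",
]


class DegenerateRotationError(ValueError):
    """Rotation angle too small for a defined helical axis."""


@dataclass(frozen=True)
class CardanAngles:
    """ZYX Cardan angles in degrees; ``y`` lies in [-90, 90] by convention.

    ``degenerate`` flags gimbal lock (|cos y| ~ 0), where z has been fixed to
    zero and x absorbs the free degree of freedom.
    """

    x: float
    y: float
    z: float
    degenerate: bool = False

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


@dataclass(frozen=True)
class HelicalAxis:
    """Finite helical axis: unit direction, rotation angle (deg, in [0, 180]),
    translation along the axis (mm) and the axis point closest to the origin."""

    direction: np.ndarray
    angle_deg: float
    axial_translation: float
    axis_point: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, float)
        object.__setattr__(self, "direction", d / np.linalg.norm(d))
        object.__setattr__(self, "axis_point", np.asarray(self.axis_point, float))

    def to_transform(self) -> RigidTransform:
        """Reconstruct the screw motion (inverse of :func:`finite_helical_axis`)."""
        n = self.direction
        theta = np.deg2rad(self.angle_deg)
        K = np.array([[0, -n[2], n[1]], [n[2], 0, -n[0]], [-n[1], n[0], 0]])
        R = np.eye(3) + np.sin(theta) * K + (1 - np.cos(theta)) * (K @ K)
        t = (np.eye(3) - R) @ self.axis_point + self.axial_translation * n
        return RigidTransform(R, t)

    def point_at(self, lam: float) -> np.ndarray:
        return self.axis_point + lam * self.direction


@dataclass
class KinematicTrack:
    """Per-frame Cardan angles and trochlea-center displacement for one
    repetition, plus the total (frame 0 → final) helical axis."""

    angles_deg: np.ndarray  # (n_frames, 3): x, y, z
    displacement_mm: np.ndarray  # (n_frames, 3)
    total_fha: HelicalAxis = None  # None when the total rotation is degenerate
    trochlea_center: np.ndarray = None

    @property
    def n_frames(self) -> int:
        return len(self.angles_deg)

    @property
    def end_range_rotation(self) -> np.ndarray:
        return self.angles_deg[-1]

    @property
    def end_range_translation(self) -> np.ndarray:
        return self.displacement_mm[-1]


@dataclass
class AxisSummary:
    """Reporting view of a helical axis: canonicalized orientation (X <= 0)
    and its intersection with a sagittal plane at fixed X (mm)."""

    orientation: np.ndarray
    plane_x: float
    intercept_yz: tuple
    angle_deg: float = None
    axial_translation: float = None


def cardan_zyx(transform: RigidTransform, gimbal_tol: float = 1e-8) -> CardanAngles:
    """Decompose the rotation as ``Rz(z) @ Ry(y) @ Rx(x)`` (angles in deg).

    Near gimbal lock (|cos y| < ``gimbal_tol``) z is set to 0, x absorbs the
    remaining rotation, and the result is flagged degenerate.
    """
    R = transform.rotation
    sy = -R[2, 0]
    sy = float(np.clip(sy, -1.0, 1.0))
    cy = np.hypot(R[2, 1], R[2, 2])
    if cy < gimbal_tol:
        y = 90.0 if sy > 0 else -90.0
        if sy > 0:
            x = np.degrees(np.arctan2(R[0, 1], R[0, 2]))
        else:
            x = np.degrees(np.arctan2(-R[0, 1], -R[0, 2]))
        return CardanAngles(x, y, 0.0, degenerate=True)
    x = np.degrees(np.arctan2(R[2, 1], R[2, 2]))
    y = np.degrees(np.arcsin(sy))
    z = np.degrees(np.arctan2(R[1, 0], R[0, 0]))
    return CardanAngles(x, y, z)


def landmark_displacement(transform: RigidTransform, point0) -> np.ndarray:
    """Displacement ``transform(point0) - point0`` in mm."""
    p = np.asarray(point0, float)
    return transform.apply(p) - p


def finite_helical_axis(
    transform: RigidTransform, angle_min_deg: float = 0.1
) -> HelicalAxis:
    """Finite helical axis of a rigid displacement (Spoor–Veldpaus form).

    The direction and rotation angle come from the skew-symmetric part of the
    rotation; near 180 deg, where the sine extraction degenerates, the
    direction is recovered from the symmetric part instead.  The axis point
    returned is the point on the axis closest to the origin.

    Raises :class:`DegenerateRotationError` below ``angle_min_deg`` (an axis
    direction is not defined for a near-pure translation).
    """
    R = transform.rotation
    v = transform.translation
    w = 0.5 * np.array([R[2, 1] - R[1, 2], R[0, 2] - R[2, 0], R[1, 0] - R[0, 1]])
    sin_t = np.linalg.norm(w)
    cos_t = 0.5 * (np.trace(R) - 1.0)
    theta = np.arctan2(sin_t, cos_t)
    if np.degrees(theta) < angle_min_deg:
        raise DegenerateRotationError(
            f"rotation angle {np.degrees(theta):.4g} deg below "
            f"{angle_min_deg} deg; helical axis undefined"
        )
    if theta < 0.75 * np.pi:  # sine extraction is stable away from 180 deg
        n = w / sin_t
    else:
        # symmetric-part extraction, robust near 180 deg
        B = 0.5 * (R + R.T) - cos_t * np.eye(3)  # = (1 - cos) n n^T
        i = int(np.argmax(np.diag(B)))
        n = B[:, i] / np.sqrt(B[i, i] * (1.0 - cos_t))
        if n @ w < 0 and sin_t > 1e-12:  # align with the skew part's sign
            n = -n
    n = n / np.linalg.norm(n)

    d = float(n @ v)  # translation along the axis
    # axis point s with s . n = 0 solving (I - R) s = v - d n
    A = np.vstack([np.eye(3) - R, n[None, :]])
    b = np.concatenate([v - d * n, [0.0]])
    s, *_ = np.linalg.lstsq(A, b, rcond=None)
    return HelicalAxis(n, float(np.degrees(theta)), d, s)


def axis_plane_intersection(axis: HelicalAxis, plane_x: float) -> tuple:
    """(Y, Z) mm where the axis crosses the plane X = ``plane_x``.

    Raises ValueError when the axis is (numerically) parallel to the plane.
    """
    dx = axis.direction[0]
    if abs(dx) < 1e-8:
        raise ValueError("axis is parallel to the YZ plane; no intersection")
    lam = (plane_x - axis.axis_point[0]) / dx
    p = axis.point_at(lam)
    return float(p[1]), float(p[2])


_PLANE_KEEP = {"YZ": (1, 2), "XY": (0, 1), "XZ": (0, 2)}


def projected_axis_angle(a, b, plane: str) -> float:
    """Unsigned angle (deg, in [0, 90]) between the *lines* spanned by two
    axis vectors after projection onto a coordinate plane.

    Line angles (not vector angles) because an axis direction is
    sign-ambiguous; the result is invariant to flipping either input.
    """
    try:
        keep = _PLANE_KEEP[plane.upper()]
    except KeyError:
        raise ValueError(f"plane must be one of {sorted(_PLANE_KEEP)}") from None
    pa = np.asarray(a, float)[list(keep)]
    pb = np.asarray(b, float)[list(keep)]
    na, nb = np.linalg.norm(pa), np.linalg.norm(pb)
    if na < 1e-8 or nb < 1e-8:
        raise ValueError(f"degenerate projection onto the {plane} plane")
    c = abs(pa @ pb) / (na * nb)
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def canonical_direction(direction) -> np.ndarray:
    """Flip an axis direction so its X-component is <= 0 (reporting convention)."""
    d = np.asarray(direction, float)
    return -d if d[0] > 0 else d.copy()


def track_from_transforms(
    transforms, trochlea0, angle_min_deg: float = 0.1
) -> KinematicTrack:
    """Kinematic track from per-frame transforms (frame 0 = identity prepended
    when absent): per-frame Cardan angles and trochlea displacement, plus the
    total FHA of the final frame's transform (None when degenerate)."""
    transforms = list(transforms)
    if not transforms or not transforms[0].is_identity(atol=1e-9):
        transforms = [RigidTransform.identity()] + transforms
    if len(transforms) < 2:
        raise ValueError("need at least 2 frames")
    trochlea0 = np.asarray(trochlea0, float)
    angles = np.array([cardan_zyx(t).as_array() for t in transforms])
    disp = np.array([landmark_displacement(t, trochlea0) for t in transforms])
    try:
        fha = finite_helical_axis(transforms[-1], angle_min_deg=angle_min_deg)
    except DegenerateRotationError:
        fha = None
    return KinematicTrack(angles, disp, total_fha=fha, trochlea_center=trochlea0)


def transform_difference(a: RigidTransform, b: RigidTransform, point) -> tuple:
    """(max per-axis Cardan angle difference in deg, displacement difference
    at ``point`` in mm) between two rigid transforms — the natural error
    measure when comparing a recovered transform against ground truth."""
    da = np.abs(cardan_zyx(a).as_array() - cardan_zyx(b).as_array())
    da = np.minimum(da, 360.0 - da)
    dt = np.linalg.norm(a.apply(point) - b.apply(point))
    return float(da.max()), float(dt)


def axis_summary(fha: HelicalAxis, plane_x: float) -> AxisSummary:
    """Reporting summary: canonicalized orientation and sagittal-plane
    intersection at X = ``plane_x``."""
    return AxisSummary(
        orientation=canonical_direction(fha.direction),
        plane_x=float(plane_x),
        intercept_yz=axis_plane_intersection(fha, plane_x),
        angle_deg=fha.angle_deg,
        axial_translation=fha.axial_translation,
    )
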