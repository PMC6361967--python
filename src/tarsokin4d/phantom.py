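"""Synthetic 4D bone-motion phantoms.

Generates a two-bone digital phantom — a tibia shaft elongated along Z and a
compact talus below it — on a low-intensity background, plus ground-truth
rigid motion of the talus (tibia static) rendered into an image sequence.
The phantom emulates the geometry of a dynamic ankle CT acquisition: one
reference frame at maximum dorsiflexion and a set of moving frames spanning
the motion to full inversion.

Bones carry smooth internal intensity texture (on top of the plateau) so that
rotations are identifiable by an intensity-based similarity metric; edges are
Gaussian-blurred.  No CT physics is modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import (
    OutOfFieldError,
    RigidTransform,
    SizingError,
    VoxelGrid,
    rotation_zyx,
)
from .scenarios import ScenarioSpec

__all__ = [
    "LandmarkSet",
    "BonePhantom",
    "MotionProfile",
    "FrameSequence",
    "make_bone_phantom",
    "make_motion_profile",
    "render_sequence",
    "smoothstep",
]

BACKGROUND = 50.0
BONE_BASE = 600.0
BONE_TEXTURE = 500.0
EDGE_BLUR_SIGMA_MM = 0.7
TIBIA_LABEL = 1
TALUS_LABEL = 2
MIN_EXTENT_MM = 31.0  # each axis must span at least this to fit both bones


@dataclass
class LandmarkSet:
    """Named anatomical points (mm) plus per-bone correspondence points.

    ``tre_points`` maps bone name ("tibia"/"talus") to an (N, 3) array of
    points inside that bone, used for target-registration-error evaluation.
    """

    trochlea_center: np.ndarray
    tibial_tuberosity: np.ndarray
    medial_malleolus: np.ndarray
    tre_points: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.trochlea_center = np.asarray(self.trochlea_center, float)
        self.tibial_tuberosity = np.asarray(self.tibial_tuberosity, float)
        self.medial_malleolus = np.asarray(self.medial_malleolus, float)
        self.tre_points = {k: np.asarray(v, float) for k, v in self.tre_points.items()}


@dataclass
class BonePhantom:
    """Reference volume + integer labels (0 bg, 1 tibia, 2 talus) + landmarks.

    ``base`` (background + static tibia) and ``talus_delta`` (talus intensity
    above background) are kept separately so the talus can be re-rendered
    rigidly moved without disturbing the tibia.
    """

    volume: VoxelGrid
    labels: np.ndarray
    landmarks: LandmarkSet
    base: np.ndarray = None
    talus_delta: np.ndarray = None

    def __iter__(self):
        return iter((self.volume, self.labels, self.landmarks))


@dataclass
class MotionProfile:
    """Ground-truth talus motion: one rigid transform per frame.

    Transforms map reference-frame points to their moved position; frame 0 is
    the identity.  Rotation is about ``center`` (normally the trochlea
    center), so the trochlea-center displacement equals the interpolated
    translation schedule exactly.
    """

    transforms: list
    angles_deg: np.ndarray
    translations_mm: np.ndarray
    center: np.ndarray

    @property
    def n_frames(self) -> int:
        return len(self.transforms)


@dataclass
class FrameSequence:
    """One reference frame plus moving frames sharing its geometry."""

    reference: VoxelGrid
    frames: list
    landmarks: LandmarkSet
    ground_truth: MotionProfile = None

    @property
    def n_frames(self) -> int:
        return len(self.frames) + 1


def smoothstep(u: np.ndarray) -> np.ndarray:
    """Monotone C1 schedule 3u^2 - 2u^3 on [0, 1], endpoint-exact."""
    u = np.clip(np.asarray(u, float), 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def _capsule_mask(coords, p0, p1, radius):
    """Voxels within ``radius`` of segment p0-p1 (a rounded cylinder)."""
    x, y, z = coords
    p0 = np.asarray(p0, float)
    p1 = np.asarray(p1, float)
    d = p1 - p0
    L2 = float(d @ d)
    t = ((x - p0[0]) * d[0] + (y - p0[1]) * d[1] + (z - p0[2]) * d[2]) / L2
    t = np.clip(t, 0.0, 1.0)
    dist2 = (
        (x - p0[0] - t * d[0]) ** 2
        + (y - p0[1] - t * d[1]) ** 2
        + (z - p0[2] - t * d[2]) ** 2
    )
    return dist2 <= radius**2


def make_bone_phantom(
    dims=(64, 64, 96),
    spacing=(1.0, 1.0, 1.0),
    seed: int = 0,
    n_tre_points: int = 12,
) -> BonePhantom:
    """Build the two-bone phantom with landmarks, deterministically from the seed.

    Raises :class:`SizingError` when the physical extent cannot contain both
    bodies (each axis must span at least ~31 mm).
    """
    dims = tuple(int(d) for d in dims)
    spacing = tuple(float(s) for s in spacing)
    extent = np.array([(d - 1) * s for d, s in zip(dims, spacing)])
    if np.any(extent < MIN_EXTENT_MM):
        raise SizingError(
            f"physical extent {tuple(extent)} mm too small; each axis must span "
            f">= {MIN_EXTENT_MM} mm to contain tibia and talus"
        )

    idx = np.indices(dims, dtype=float)
    coords = [idx[a] * spacing[a] for a in range(3)]  # world mm, origin 0
    Lx, Ly, Lz = extent

    # tibia: rounded vertical shaft in the upper part of the volume
    tibia_r = 0.13 * min(Lx, Ly)
    tibia_top = np.array([0.5 * Lx, 0.5 * Ly, 0.95 * Lz])
    tibia_bot = np.array([0.5 * Lx, 0.5 * Ly, 0.54 * Lz])
    tibia = _capsule_mask(coords, tibia_bot, tibia_top, tibia_r)

    # talus: compact ellipsoid body below the tibia plus an offset head lobe
    # (the head breaks the 180-degree symmetry of a bare ellipsoid, so the
    # pose is identifiable even at coarse pyramid levels)
    tc = np.array([0.5 * Lx, 0.52 * Ly, 0.33 * Lz])
    semi = np.array([0.19 * Lx, 0.155 * Ly, 0.085 * Lz])
    body = (
        ((coords[0] - tc[0]) / semi[0]) ** 2
        + ((coords[1] - tc[1]) / semi[1]) ** 2
        + ((coords[2] - tc[2]) / semi[2]) ** 2
    ) <= 1.0
    hc = tc + np.array([0.0, 0.85 * semi[1], -0.25 * semi[2]])
    hsemi = np.array([0.45 * semi[0], 0.55 * semi[1], 0.6 * semi[2]])
    head = (
        ((coords[0] - hc[0]) / hsemi[0]) ** 2
        + ((coords[1] - hc[1]) / hsemi[1]) ** 2
        + ((coords[2] - hc[2]) / hsemi[2]) ** 2
    ) <= 1.0
    talus = body | head

    labels = np.zeros(dims, dtype=np.int16)
    labels[tibia] = TIBIA_LABEL
    labels[talus] = TALUS_LABEL

    # smooth internal texture makes rotations identifiable under MI
    rng = np.random.default_rng(seed)
    phase = rng.uniform(0, 2 * np.pi, size=3)
    tex = (
        0.5
        + 0.22 * np.sin(2 * np.pi * coords[0] / (0.9 * Lx) + phase[0])
        + 0.18 * np.cos(2 * np.pi * (coords[1] + coords[2]) / (0.8 * Ly) + phase[1])
        + 0.10 * np.sin(2 * np.pi * coords[2] / (0.5 * Lz) + phase[2])
    )
    bone_intensity = BONE_BASE + BONE_TEXTURE * np.clip(tex, 0.0, 1.0)

    sigma_vox = [EDGE_BLUR_SIGMA_MM / s for s in spacing]
    tibia_delta = ndimage.gaussian_filter(np.where(tibia, bone_intensity - BACKGROUND, 0.0), sigma_vox)
    talus_delta = ndimage.gaussian_filter(np.where(talus, bone_intensity - BACKGROUND, 0.0), sigma_vox)
    base = BACKGROUND + tibia_delta
    volume = VoxelGrid(base + talus_delta, spacing=spacing, origin=(0.0, 0.0, 0.0))

    trochlea_center = tc + np.array([0.0, 0.0, 0.55 * semi[2]])
    tibial_tuberosity = tibia_top.copy()
    medial_malleolus = tibia_bot + np.array([tibia_r, 0.0, 0.0])

    tre = {}
    for name, mask, c, half in (
        ("tibia", tibia, 0.5 * (tibia_bot + tibia_top), np.array([tibia_r, tibia_r, 0.5 * np.linalg.norm(tibia_top - tibia_bot) + tibia_r])),
        ("talus", talus, tc, semi),
    ):
        pts = []
        while len(pts) < n_tre_points:
            cand = c + (2 * rng.random(3) - 1) * 0.85 * half
            ci = np.round(cand / np.asarray(spacing)).astype(int)
            if np.all(ci >= 0) and np.all(ci < dims) and mask[tuple(ci)]:
                pts.append(cand)
        tre[name] = np.array(pts)

    landmarks = LandmarkSet(trochlea_center, tibial_tuberosity, medial_malleolus, tre)
    return BonePhantom(volume, labels, landmarks, base=base, talus_delta=talus_delta)


def make_motion_profile(spec: ScenarioSpec, center=(0.0, 0.0, 0.0)) -> MotionProfile:
    """Ground-truth motion for one repetition of a scenario.

    Per-frame ZYX Cardan angles and translations follow a smoothstep schedule
    from zero to the (noise-perturbed) end range; the rotation is taken about
    ``center`` and the translation applied on top, so ``center`` (the trochlea
    center in the full pipeline) is displaced by exactly the translation
    schedule.  Repetition noise is a single zero-mean Gaussian draw on the end
    range per repetition, seeded by ``spec.seed``.
    """
    center = np.asarray(center, float)
    end_rot = np.asarray(spec.end_range_rotation, float).copy()
    end_tra = np.asarray(spec.end_range_translation, float).copy()
    if spec.repetition_noise_deg > 0 or spec.repetition_noise_mm > 0:
        rng = np.random.default_rng(spec.seed)
        end_rot = end_rot + spec.repetition_noise_deg * rng.standard_normal(3)
        end_tra = end_tra + spec.repetition_noise_mm * rng.standard_normal(3)

    u = np.arange(spec.n_frames) / (spec.n_frames - 1)
    s = smoothstep(u)
    angles = np.outer(s, end_rot)
    translations = np.outer(s, end_tra)
    transforms = [
        RigidTransform.rotation_about_point(rotation_zyx(*a), center, extra_translation=t)
        for a, t in zip(angles, translations)
    ]
    return MotionProfile(transforms, angles, translations, center)


def _warp_rigid(delta: np.ndarray, grid: VoxelGrid, motion: RigidTransform) -> np.ndarray:
    """Resample ``delta`` so the object appears moved by ``motion``.

    Output voxel value at world point w is the input value at motion^-1(w)
    (linear interpolation, zero fill).
    """
    S = np.diag(grid.spacing)
    Sinv = np.diag([1.0 / s for s in grid.spacing])
    Rt = motion.rotation.T
    origin = np.asarray(grid.origin)
    matrix = Sinv @ Rt @ S
    offset = Sinv @ (Rt @ (origin - motion.translation) - origin)
    return ndimage.affine_transform(delta, matrix, offset=offset, order=1, mode="constant", cval=0.0)


def render_sequence(
    phantom: BonePhantom,
    profile: MotionProfile,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> FrameSequence:
    """Render the moving-talus image sequence for one repetition.

    Frame t is the reference with the talus rigidly moved by
    ``profile.transforms[t]`` (tibia static), linear interpolation, plus
    optional additive Gaussian intensity noise.  Frame 0 of the profile must
    be (numerically) the identity; with zero noise it reproduces the
    reference voxel-for-voxel.  Raises :class:`OutOfFieldError` when a
    transform moves talus surface voxels outside the volume.
    """
    grid = phantom.volume
    if phantom.base is None or phantom.talus_delta is None:
        raise ValueError("phantom lacks cached base/talus_delta channels")

    talus_mask = phantom.labels == TALUS_LABEL
    surface = talus_mask & ~ndimage.binary_erosion(talus_mask)
    surf_world = grid.index_to_world(np.argwhere(surface))

    rng = np.random.default_rng(seed)
    images = []
    for t, tf in enumerate(profile.transforms):
        moved = tf.apply(surf_world)
        if not np.all(grid.contains_points(moved)):
            raise OutOfFieldError(f"frame {t}: transform moves the talus outside the volume")
        arr = phantom.base + _warp_rigid(phantom.talus_delta, grid, tf)
        if noise_sd > 0:
            arr = arr + rng.normal(0.0, noise_sd, size=arr.shape)
        images.append(VoxelGrid(arr, grid.spacing, grid.origin))

    return FrameSequence(
        reference=images[0],
        frames=images[1:],
        landmarks=phantom.landmarks,
        ground_truth=profile,
    )
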