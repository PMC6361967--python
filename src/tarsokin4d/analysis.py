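"""Statistical layer: repeatability across repetitions, between-scenario
maximum differences over the time course, and helical-axis shifts.

All comparisons operate on kinematic tracks (per-frame Cardan angles and
trochlea-center displacements).  Scenario curves are summarized by the mean
of the (typically four) repetitions at each time point; repeatability is the
maximum pairwise difference of end-range values between repetitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import RigidTransform, rotation_zyx
from .kinematics import (
    AxisSummary,
    KinematicTrack,
    finite_helical_axis,
    projected_axis_angle,
)

__all__ = [
    "RepetitionSet",
    "MeanTrack",
    "RepeatabilityReport",
    "ComparisonReport",
    "AxisShift",
    "mean_track",
    "repeatability",
    "compare_scenarios",
    "axis_shift",
]

COMPONENTS = ("x", "y", "z")
PERCENT_FLOOR = 1e-6


@dataclass
class RepetitionSet:
    """All repetitions of one scenario (tracks must share frame counts)."""

    scenario_id: int
    tracks: list
    axis_summaries: list = field(default_factory=list)

    def __post_init__(self) -> None:
        counts = {t.n_frames for t in self.tracks}
        if len(counts) > 1:
            raise ValueError(f"tracks have mismatched frame counts: {sorted(counts)}")

    @property
    def n_reps(self) -> int:
        return len(self.tracks)


@dataclass
class MeanTrack:
    """Component-wise per-frame mean and sample SD over repetitions.

    ``single_repetition`` flags n=1 (SD reported as zero), mirroring a
    scenario with only one usable acquisition.
    """

    track: KinematicTrack
    angles_sd: np.ndarray
    displacement_sd: np.ndarray
    n_reps: int
    single_repetition: bool


def mean_track(reps: RepetitionSet) -> MeanTrack:
    """Mean kinematic track (+ per-frame sample SD) of a repetition set.

    The mean track's total FHA is rebuilt from the mean end-range angles and
    displacement (rotation about the shared trochlea center), so scenario
    axes can be compared on mean curves.
    """
    if reps.n_reps < 1:
        raise ValueError("need at least one track")
    ang = np.stack([t.angles_deg for t in reps.tracks])
    disp = np.stack([t.displacement_mm for t in reps.tracks])
    single = reps.n_reps == 1
    ddof = 0 if single else 1
    ang_m, disp_m = ang.mean(axis=0), disp.mean(axis=0)
    ang_sd = np.zeros_like(ang_m) if single else ang.std(axis=0, ddof=ddof)
    disp_sd = np.zeros_like(disp_m) if single else disp.std(axis=0, ddof=ddof)

    center = reps.tracks[0].trochlea_center
    fha = None
    if center is not None:
        end_tf = RigidTransform.rotation_about_point(
            rotation_zyx(*ang_m[-1]), center, extra_translation=disp_m[-1]
        )
        try:
            fha = finite_helical_axis(end_tf)
        except ValueError:
            fha = None
    mean_kt = KinematicTrack(ang_m, disp_m, total_fha=fha, trochlea_center=center)
    return MeanTrack(mean_kt, ang_sd, disp_sd, reps.n_reps, single)


@dataclass
class RepeatabilityReport:
    """Max pairwise end-range differences across repetitions (per component)
    plus the per-frame spread (max - min) curves."""

    rotation_max_diff_deg: np.ndarray
    translation_max_diff_mm: np.ndarray
    rotation_spread_deg: np.ndarray
    translation_spread_mm: np.ndarray


def repeatability(reps: RepetitionSet) -> RepeatabilityReport:
    """Repeatability of the setup: per component, the maximum over repetition
    pairs of the absolute end-range (final frame) difference; the per-frame
    spread is max - min across repetitions at each time point."""
    if reps.n_reps < 2:
        raise ValueError("repeatability needs at least 2 repetitions")
    ang = np.stack([t.angles_deg for t in reps.tracks])  # (reps, frames, 3)
    disp = np.stack([t.displacement_mm for t in reps.tracks])
    # max pairwise |difference| over reps == range (max - min)
    rot_end = ang[:, -1, :]
    tra_end = disp[:, -1, :]
    return RepeatabilityReport(
        rotation_max_diff_deg=rot_end.max(axis=0) - rot_end.min(axis=0),
        translation_max_diff_mm=tra_end.max(axis=0) - tra_end.min(axis=0),
        rotation_spread_deg=ang.max(axis=0) - ang.min(axis=0),
        translation_spread_mm=disp.max(axis=0) - disp.min(axis=0),
    )


@dataclass
class ComparisonReport:
    """Signed maximum differences between two scenarios' mean curves.

    Per component: the signed (other - reference) difference at the frame
    where |difference| peaks, the frame index, and the percent change
    relative to the reference scenario's peak absolute value over the time
    course (None when the reference amplitude is below the floor).
    """

    rotation_delta_deg: np.ndarray
    rotation_percent: list
    rotation_argmax: np.ndarray
    translation_delta_mm: np.ndarray
    translation_percent: list
    translation_argmax: np.ndarray


def _max_diff(ref: np.ndarray, other: np.ndarray):
    diff = other - ref  # (frames, 3)
    arg = np.abs(diff).argmax(axis=0)
    delta = diff[arg, np.arange(diff.shape[1])]
    amp = np.abs(ref).max(axis=0)
    pct = [
        float(100.0 * d / a) if a >= PERCENT_FLOOR else None
        for d, a in zip(delta, amp)
    ]
    return delta, pct, arg


def compare_scenarios(reference: KinematicTrack, other: KinematicTrack) -> ComparisonReport:
    """Between-scenario maximum differences over the course of the movement.

    Note the maxima are searched over the whole time course, not just the end
    point — differences commonly peak mid-motion.
    """
    if reference.n_frames != other.n_frames:
        raise ValueError("tracks have different frame counts")
    rd, rp, ra = _max_diff(reference.angles_deg, other.angles_deg)
    td, tp, ta = _max_diff(reference.displacement_mm, other.displacement_mm)
    return ComparisonReport(rd, rp, ra, td, tp, ta)


def percent_change(delta: float, reference_amplitude: float) -> float:
    """Percent change of a maximum difference relative to the reference
    scenario's peak absolute value (the convention used in scenario tables)."""
    if abs(reference_amplitude) < PERCENT_FLOOR:
        raise ValueError("reference amplitude below the percent floor")
    return 100.0 * delta / abs(reference_amplitude)


@dataclass
class AxisShift:
    """Orientation change (projected line angles, deg) and sagittal-plane
    intersection displacement (mm) between two scenarios' helical axes."""

    alpha_yz_deg: float
    beta_xy_deg: float
    gamma_xz_deg: float
    displacement_mm: float
    direction: str  # e.g. "postero-cranial": +Y posterior, +Z cranial


def axis_shift(ref_axis: AxisSummary, other_axis: AxisSummary) -> AxisShift:
    """Shift of the axis of rotation between two scenarios.

    Both summaries must be computed at the same sagittal plane; displacement
    is the Euclidean distance between the two (Y, Z) intersections, with a
    coarse anatomical direction descriptor from the signs of the change.
    """
    if abs(ref_axis.plane_x - other_axis.plane_x) > 1e-9:
        raise ValueError("axis summaries were computed at different planes")
    alpha = projected_axis_angle(ref_axis.orientation, other_axis.orientation, "YZ")
    beta = projected_axis_angle(ref_axis.orientation, other_axis.orientation, "XY")
    gamma = projected_axis_angle(ref_axis.orientation, other_axis.orientation, "XZ")
    dy = other_axis.intercept_yz[0] - ref_axis.intercept_yz[0]
    dz = other_axis.intercept_yz[1] - ref_axis.intercept_yz[1]
    direction = ("postero" if dy >= 0 else "antero") + "-" + ("cranial" if dz >= 0 else "caudal")
    return AxisShift(alpha, beta, gamma, float(np.hypot(dy, dz)), direction)
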