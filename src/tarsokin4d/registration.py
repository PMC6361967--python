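"""Mask-guided rigid registration by mutual-information maximization.

Each bone of the reference frame is registered to every moving frame by
solving, over the six rigid parameters mu (three ZYX Euler angles about the
region centroid + three translations),

    mu_hat = arg min_mu  -MI( f(x), g(T_mu(x)) ),   x in the bone region,

with a multi-resolution pyramid and a derivative-free Powell optimizer.  MI
is estimated from the joint intensity histogram of region voxels, pairing
fixed values with linearly interpolated moving values; voxels mapping outside
the moving volume are excluded.  The recovered transform maps reference-frame
coordinates into the moving frame.

Accuracy is quantified by target registration error (TRE): the distance
between corresponding points after applying the estimated transform.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage, optimize

from .core import RigidTransform, TarsokinError, VoxelGrid, rotation_zyx
from .kinematics import cardan_zyx
from .phantom import FrameSequence
from .segmentation import BONE_LABELS, BoneMask, mask_to_region

__all__ = [
    "MetricUndefinedError",
    "RegistrationConfig",
    "RegistrationResult",
    "TREReport",
    "mutual_information",
    "register_rigid",
    "register_sequence",
    "relative_motion",
    "target_registration_error",
]


class MetricUndefinedError(TarsokinError):
    """Empty region, or every region voxel mapped outside the moving volume."""


@dataclass(frozen=True)
class RegistrationConfig:
    """Optimizer/metric settings (conventional choices, all overridable).

    ``pyramid`` lists downsampling factors coarse→fine; histogram bins shrink
    with the factor so coarse levels keep enough samples per bin.  The
    coarse rotation search evaluates a +-search_range grid at the coarsest
    level and starts the optimizer from the best cell — this is what gives
    the method its capture range at large inversion angles.
    """

    bins: int = 32
    pyramid: tuple = (2, 1)
    max_iterations: int = 60
    xtol: float = 1e-3  # deg / mm parameter step tolerance at the finest level
    region_dilation_mm: float = 2.0
    fine_smoothing_vox: float = 0.5  # Gaussian sigma at the full-resolution level
    fine_samples_per_voxel: int = 4  # jittered samples per voxel at full resolution
    max_samples: int = 28_000  # cap on total metric samples (voxels subsampled above it)
    fine_passes: int = 1  # Powell runs at the finest level (restarts refresh directions)
    coarse_search: bool = True
    coarse_search_range_deg: float = 40.0
    coarse_search_step_deg: float = 20.0
    prealign_threshold: float = None  # default: Otsu-like midpoint


@dataclass
class RegistrationResult:
    """Outcome of one rigid registration.

    ``final_metric`` is the minimized cost (negated MI, nats);
    ``metric_history`` holds, per pyramid level, the best cost after each
    accepted improvement — non-increasing within a level by construction
    (levels are not comparable: they sample different resolutions).
    """

    transform: RigidTransform
    final_metric: float
    iterations: int
    converged: bool
    metric_history: list = field(default_factory=list)

    def __post_init__(self) -> None:
        for level in self.metric_history:
            if not all(b <= a + 1e-12 for a, b in zip(level, level[1:])):
                raise AssertionError("best-metric history must be non-increasing within a level")


@dataclass
class TREReport:
    """Per-point registration errors (mm) with summary statistics."""

    errors: np.ndarray
    mean: float
    min: float
    max: float

    @classmethod
    def from_errors(cls, errors: np.ndarray) -> "TREReport":
        e = np.asarray(errors, float)
        return cls(e, float(e.mean()), float(e.min()), float(e.max()))


# ---------------------------------------------------------------------------
# mutual information


def _entropy_mi(joint: np.ndarray) -> float:
    p = joint / joint.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float(np.sum(p[nz] * np.log(p[nz] / (px @ py)[nz])))


def _bin_indices(values: np.ndarray, lo: float, hi: float, bins: int) -> np.ndarray:
    if hi - lo < 1e-12:
        return np.zeros(values.shape, dtype=np.intp)
    idx = ((values - lo) / (hi - lo) * bins).astype(np.intp)
    return np.clip(idx, 0, bins - 1)


def mutual_information(
    fixed: VoxelGrid,
    moving: VoxelGrid,
    transform: RigidTransform,
    region: np.ndarray,
    bins: int = 32,
) -> float:
    """MI (nats, >= 0) between fixed and transformed-moving intensities over
    the region.

    Pairs f(x) with g(T(x)) (linear interpolation) for region voxels x;
    voxels mapping outside the moving volume are excluded.  Histogram edges
    span each sample set's own min/max, so MI(f, f | identity) equals the
    marginal entropy of f over the region.
    """
    region = np.asarray(region, bool)
    if region.shape != fixed.dims:
        raise ValueError("region shape must match the fixed volume")
    if not region.any():
        raise MetricUndefinedError("empty registration region")
    if bins < 8:
        raise ValueError("bins must be >= 8")

    coords = fixed.index_to_world(np.argwhere(region))
    fvals = fixed.intensities[region]
    mapped = transform.apply(coords)
    idx = moving.world_to_index(mapped)
    dims = np.asarray(moving.dims)
    valid = np.all((idx >= 0) & (idx <= dims - 1), axis=1)
    if not valid.any():
        raise MetricUndefinedError("all region voxels map outside the moving volume")
    gvals = ndimage.map_coordinates(moving.intensities, idx[valid].T, order=1)
    fv = fvals[valid]
    fb = _bin_indices(fv, fv.min(), fv.max(), bins)
    gb = _bin_indices(gvals, gvals.min(), gvals.max(), bins)
    joint = np.bincount(fb * bins + gb, minlength=bins * bins).reshape(bins, bins)
    return max(0.0, _entropy_mi(joint))


class _LevelSampler:
    """Cached MI evaluator for one pyramid level.

    Fixed-value binning is precomputed over the whole region and moving-value
    edges come from the moving volume's global range, so the cost landscape
    is smooth in the transform parameters (per-call edges would make it
    jump).  Returns 0.0 when every voxel maps out of field.
    """

    def __init__(
        self,
        fixed: VoxelGrid,
        moving: VoxelGrid,
        region: np.ndarray,
        bins: int,
        samples_per_voxel: int = 1,
        max_samples: int = None,
    ):
        self.bins = bins
        # sample at sub-voxel jittered positions (fixed seed): both images are
        # then linearly interpolated everywhere, so exact-grid alignment is not
        # artificially favoured (on-grid sampling keeps full noise variance
        # while off-grid sampling smooths it, which would bias MI).  Several
        # jittered samples per voxel lower the MI-estimator noise floor, which
        # limits accuracy on weakly-constrained parameters; above
        # ``max_samples`` total samples, region voxels are subsampled (seeded).
        spv = max(1, samples_per_voxel)
        vox = np.argwhere(region).astype(float)
        if max_samples is not None and len(vox) * spv > max_samples:
            keep = np.random.default_rng(1).choice(
                len(vox), size=max_samples // spv, replace=False
            )
            vox = vox[keep]
        idx = np.tile(vox, (spv, 1))
        jitter = np.random.default_rng(0).uniform(-0.5, 0.5, size=idx.shape)
        idx = np.clip(idx + jitter, 0, np.asarray(fixed.dims) - 1.0)
        self.coords = fixed.index_to_world(idx)
        fv = ndimage.map_coordinates(fixed.intensities, idx.T, order=1)
        self.fbin = _bin_indices(fv, float(fv.min()), float(fv.max()), bins)
        self.moving = moving.intensities
        self.m_origin = np.asarray(moving.origin)
        self.m_spacing = np.asarray(moving.spacing)
        self.m_dims = np.asarray(moving.dims)
        self.g_lo = float(moving.intensities.min())
        self.g_hi = float(moving.intensities.max())

    def mi(self, transform: RigidTransform) -> float:
        mapped = self.coords @ transform.rotation.T + transform.translation
        idx = (mapped - self.m_origin) / self.m_spacing
        valid = np.all((idx >= 0) & (idx <= self.m_dims - 1), axis=1)
        n = int(valid.sum())
        if n == 0:
            return 0.0
        gvals = ndimage.map_coordinates(self.moving, idx[valid].T, order=1)
        # partial-volume binning of the moving value: weight split between the
        # two neighbouring bins keeps the cost smooth in the parameters
        scale = self.g_hi - self.g_lo
        if scale < 1e-12:
            gpos = np.zeros(n)
        else:
            gpos = np.clip((gvals - self.g_lo) / scale * self.bins - 0.5, 0.0, self.bins - 1.0)
        g0 = np.floor(gpos).astype(np.intp)
        g1 = np.minimum(g0 + 1, self.bins - 1)
        w1 = gpos - g0
        fb = self.fbin[valid]
        nb = self.bins * self.bins
        joint = np.bincount(fb * self.bins + g0, weights=1.0 - w1, minlength=nb)
        joint += np.bincount(fb * self.bins + g1, weights=w1, minlength=nb)
        return _entropy_mi(joint.reshape(self.bins, self.bins))


# ---------------------------------------------------------------------------
# rigid optimization


def _downsample(grid: VoxelGrid, factor: int, fine_sigma_vox: float = 0.0) -> VoxelGrid:
    """Pyramid level: Gaussian smoothing (sigma = factor/2 voxels) + decimation.

    The full-resolution level gets light smoothing too (``fine_sigma_vox``):
    it suppresses intensity noise in the metric, which otherwise limits the
    accuracy of weakly-constrained parameters such as rotation about a long
    bone's axis.
    """
    if factor == 1:
        if fine_sigma_vox <= 0:
            return grid
        arr = ndimage.gaussian_filter(grid.intensities, fine_sigma_vox)
        return VoxelGrid(arr, spacing=grid.spacing, origin=grid.origin)
    sigma = [0.5 * factor] * 3
    arr = ndimage.gaussian_filter(grid.intensities, sigma)[::factor, ::factor, ::factor]
    return VoxelGrid(
        arr, spacing=tuple(s * factor for s in grid.spacing), origin=grid.origin
    )


def _params_to_transform(p: np.ndarray, center: np.ndarray) -> RigidTransform:
    R = rotation_zyx(p[0], p[1], p[2])
    return RigidTransform.rotation_about_point(R, center, extra_translation=p[3:6])


def _transform_to_params(t: RigidTransform, center: np.ndarray) -> np.ndarray:
    ang = cardan_zyx(t).as_array()
    tau = t.apply(center) - center
    return np.concatenate([ang, tau])


def centroid_prealign(
    fixed: VoxelGrid, moving: VoxelGrid, region: np.ndarray, threshold: float = None
) -> RigidTransform:
    """Coarse translation init: shift by the difference between the
    above-threshold intensity centroid of the moving volume (searched in a
    generously dilated region) and that of the fixed region."""
    if threshold is None:
        lo, hi = float(fixed.intensities.min()), float(fixed.intensities.max())
        threshold = lo + 0.5 * (hi - lo)
    search = ndimage.binary_dilation(region, iterations=12)
    f_sel = region & (fixed.intensities > threshold)
    m_sel = search & (moving.intensities > threshold)
    if not f_sel.any() or not m_sel.any():
        return RigidTransform.identity()
    fc = fixed.index_to_world(np.argwhere(f_sel)).mean(axis=0)
    mc = moving.index_to_world(np.argwhere(m_sel)).mean(axis=0)
    return RigidTransform(np.eye(3), mc - fc)


def register_rigid(
    fixed: VoxelGrid,
    moving: VoxelGrid,
    region: np.ndarray,
    init: RigidTransform = None,
    config: RegistrationConfig = RegistrationConfig(),
) -> RegistrationResult:
    """Recover the rigid transform (reference→moving) maximizing MI over the
    region, via a coarse-to-fine pyramid and Powell optimization.

    Raises :class:`MetricUndefinedError` when the metric is undefined at the
    initial transform.  Non-convergence at the iteration cap returns a result
    with ``converged=False`` rather than raising.
    """
    region = np.asarray(region, bool)
    if not region.any():
        raise MetricUndefinedError("empty registration region")
    if init is None:
        init = RigidTransform.identity()
    # validates the metric at init (raises if undefined)
    mutual_information(fixed, moving, init, region, bins=max(8, config.bins))

    center = fixed.index_to_world(np.argwhere(region)).mean(axis=0)

    history: list = []
    total_evals = 0
    converged = True
    final_cost = np.inf

    # candidate starting points; distinct MI basins can score alike at
    # coarse resolution, so runners-up are carried through the pyramid and
    # the finest level decides
    candidates = [(_transform_to_params(init, center), np.inf)]

    for li, factor in enumerate(config.pyramid):
        f_lv = _downsample(fixed, factor, config.fine_smoothing_vox)
        m_lv = _downsample(moving, factor, config.fine_smoothing_vox)
        reg_lv = region[::factor, ::factor, ::factor]
        if not reg_lv.any():
            continue
        bins = max(8, config.bins // factor)
        spv = config.fine_samples_per_voxel if factor == 1 else 1
        sampler = _LevelSampler(
            f_lv, m_lv, reg_lv, bins, samples_per_voxel=spv, max_samples=config.max_samples
        )

        def cost(q):
            return -sampler.mi(_params_to_transform(q, center))

        best = [np.inf]
        level_history: list = []
        history.append(level_history)

        def tracked(q):
            nonlocal total_evals
            total_evals += 1
            c = cost(q)
            if c < best[0]:
                best[0] = c
                level_history.append(c)
            return c

        xtol = config.xtol if factor == 1 else max(config.xtol, 0.01 * factor)
        opts = {"xtol": xtol, "ftol": 1e-10, "maxiter": config.max_iterations, "disp": False}

        starts = [q for q, _ in candidates]
        if li == 0 and config.coarse_search and config.coarse_search_range_deg > 0:
            starts = _coarse_rotation_search(cost, starts[0], config)

        refined = []
        for q0 in starts:
            res = optimize.minimize(tracked, q0, method="Powell", options=opts)
            refined.append((res.x, float(res.fun), res))
        refined.sort(key=lambda t: t[1])
        keep = 2 if (len(refined) > 1 and factor > 1) else 1
        candidates = [(q, c) for q, c, _ in refined[:keep]]

        if factor == 1:
            for _ in range(max(0, config.fine_passes - 1)):
                # extra passes with a fresh direction set guard against
                # Powell's search directions degenerating mid-run
                res = optimize.minimize(tracked, candidates[0][0], method="Powell", options=opts)
                candidates = [(res.x, float(res.fun))]
            converged = bool(res.success) or res.nit < config.max_iterations
        final_cost = candidates[0][1]

    return RegistrationResult(
        transform=_params_to_transform(candidates[0][0], center),
        final_metric=final_cost,
        iterations=total_evals,
        converged=converged,
        metric_history=history,
    )


def _coarse_rotation_search(cost, p0: np.ndarray, config: RegistrationConfig, k: int = 3) -> list:
    """Grid search over rotation offsets at the coarsest level.

    Returns the ``k`` most promising starting points (the unperturbed start
    is always among the candidates considered): several basins can look
    alike on the raw grid at coarse resolution, so the caller refines each
    candidate before committing to one.
    """
    rng_deg = config.coarse_search_range_deg
    step = config.coarse_search_step_deg
    offsets = np.arange(-rng_deg, rng_deg + 0.5 * step, step)
    cands = [(cost(p0), 0.0, p0.copy())]
    for dx in offsets:
        for dy in offsets:
            for dz in offsets:
                if dx == dy == dz == 0.0:
                    continue
                q = p0.copy()
                q[:3] += (dx, dy, dz)
                # tie-break towards the smaller rotation offset
                cands.append((cost(q), float(np.hypot(np.hypot(dx, dy), dz)), q))
    cands.sort(key=lambda t: (t[0], t[1]))
    return [c[2] for c in cands[:k]]


@dataclass
class SequenceRegistration:
    """Per-bone registered transforms (reference→moving, one per moving
    frame) with per-frame diagnostics."""

    transforms: dict
    results: dict

    def all_converged(self, bone: str) -> bool:
        return all(r.converged for r in self.results[bone])


def register_sequence(
    seq: FrameSequence,
    mask: BoneMask,
    config: RegistrationConfig = RegistrationConfig(),
    bones=("tibia", "talus"),
) -> SequenceRegistration:
    """Register each bone of the reference frame to every moving frame.

    Frame 1 starts from a centroid pre-alignment; each later frame is
    initialized from the previous frame's solution (frame chaining), which
    keeps per-frame steps small at large inversion angles.  Non-converged
    frames are flagged in the result and the pipeline continues.
    """
    if mask.dims != seq.reference.dims:
        raise ValueError("mask and sequence geometry differ")
    transforms: dict = {}
    results: dict = {}
    for bone in bones:
        region = mask_to_region(mask, bone, dilation_mm=config.region_dilation_mm)
        prev = None
        chained = replace(config, coarse_search=False)  # init is already close
        bone_tf, bone_res = [], []
        for frame in seq.frames:
            if prev is None:
                init = centroid_prealign(seq.reference, frame, region, config.prealign_threshold)
                cfg = config
            else:
                init, cfg = prev, chained
            res = register_rigid(seq.reference, frame, region, init=init, config=cfg)
            prev = res.transform
            bone_tf.append(res.transform)
            bone_res.append(res)
        transforms[bone] = bone_tf
        results[bone] = bone_res
    return SequenceRegistration(transforms, results)


def relative_motion(talus_tf: RigidTransform, tibia_tf: RigidTransform) -> RigidTransform:
    """Talus motion expressed in the tibia frame: ``tibia_tf^-1 ∘ talus_tf``.

    With a perfectly static tibia this equals ``talus_tf``.
    """
    return tibia_tf.inverse().compose(talus_tf)


def target_registration_error(points_ref, points_moving, transform: RigidTransform) -> TREReport:
    """Euclidean distances between transformed reference points and their
    known moving-frame correspondences."""
    pr = np.atleast_2d(np.asarray(points_ref, float))
    pm = np.atleast_2d(np.asarray(points_moving, float))
    if pr.shape != pm.shape or pr.shape[0] < 1:
        raise ValueError(f"point lists must match and be non-empty (got {pr.shape} vs {pm.shape})")
    errors = np.linalg.norm(transform.apply(pr) - pm, axis=1)
    return TREReport.from_errors(errors)
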