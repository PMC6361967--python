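"""Semi-automatic segmentation of the reference frame into per-bone masks.

Thresholding, morphological cleanup and seed-driven connected-component
labelling produce a tibia/talus label map; "manual refinement" is modelled as
a replayable list of spherical paint/erase edits, so the whole step is
scriptable and deterministic.  The masks serve as registration regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import TarsokinError, VoxelGrid

__all__ = [
    "BoneMask",
    "MaskEdit",
    "SeedError",
    "AmbiguityError",
    "segment_reference",
    "refine_mask",
    "mask_to_region",
]

# 26-connectivity: standard for 3D bone blobs
_STRUCT26 = np.ones((3, 3, 3), dtype=bool)

BONE_LABELS = {"tibia": 1, "talus": 2}


class SeedError(TarsokinError):
    """A seed point falls in background after thresholding."""


class AmbiguityError(TarsokinError):
    """Two seeds landed in the same connected component."""


@dataclass
class BoneMask:
    """Integer label volume (0 background, 1 tibia, 2 talus) with the source
    geometry of the segmented volume."""

    labels: np.ndarray
    spacing: tuple
    origin: tuple

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def dims(self) -> tuple:
        return self.labels.shape

    def present_labels(self) -> set:
        return set(np.unique(self.labels)) - {0}

    def component_count(self, label: int) -> int:
        _, n = ndimage.label(self.labels == label, structure=_STRUCT26)
        return n

    def check_connectivity(self) -> dict:
        """Map label -> 26-connected component count (1 means intact)."""
        return {int(l): self.component_count(int(l)) for l in sorted(self.present_labels())}


@dataclass(frozen=True)
class MaskEdit:
    """One spherical paint ('add') or erase ('remove') edit at a mm point."""

    point: tuple
    radius_mm: float
    mode: str  # "add" | "remove"
    label: int


def _world_to_index(points, spacing, origin):
    return (np.atleast_2d(np.asarray(points, float)) - np.asarray(origin)) / np.asarray(spacing)


def segment_reference(
    volume: VoxelGrid,
    threshold: float,
    seeds: dict,
    min_component_voxels: int = 50,
    closing_radius_vox: int = 1,
) -> BoneMask:
    """Threshold + morphology + seeded component labelling.

    ``seeds`` maps bone name ("tibia"/"talus") to one mm point inside that
    bone.  After binarization at ``threshold``, a morphological closing then
    opening (ball radius ``closing_radius_vox``) cleans the mask; each bone
    becomes the 26-connected component containing its seed, provided it holds
    at least ``min_component_voxels`` voxels.  The label follows the seed:
    swapped seeds produce swapped labels.
    """
    arr = volume.intensities
    if not (arr.min() <= threshold <= arr.max()):
        raise ValueError(
            f"threshold {threshold} outside intensity range [{arr.min():.3g}, {arr.max():.3g}]"
        )
    unknown = set(seeds) - set(BONE_LABELS)
    if unknown:
        raise ValueError(f"unknown bone names in seeds: {sorted(unknown)}")

    binary = arr > threshold
    if closing_radius_vox > 0:
        ball = _ball(closing_radius_vox)
        binary = ndimage.binary_closing(binary, structure=ball)
        binary = ndimage.binary_opening(binary, structure=ball)
    comp, _ = ndimage.label(binary, structure=_STRUCT26)

    labels = np.zeros(arr.shape, dtype=np.int16)
    taken: dict = {}
    for name, point in seeds.items():
        idx = np.round(_world_to_index(point, volume.spacing, volume.origin)[0]).astype(int)
        if np.any(idx < 0) or np.any(idx >= np.asarray(arr.shape)):
            raise SeedError(f"{name} seed {tuple(point)} lies outside the volume")
        cid = comp[tuple(idx)]
        if cid == 0:
            raise SeedError(f"{name} seed {tuple(point)} falls in background after thresholding")
        if cid in taken:
            raise AmbiguityError(f"seeds for {taken[cid]!r} and {name!r} share one component")
        size = int(np.sum(comp == cid))
        if size < min_component_voxels:
            raise SeedError(
                f"{name} component has {size} voxels (< min_component_voxels={min_component_voxels})"
            )
        taken[cid] = name
        labels[comp == cid] = BONE_LABELS[name]

    return BoneMask(labels, volume.spacing, volume.origin)


def _ball(radius_vox: int) -> np.ndarray:
    r = int(radius_vox)
    g = np.indices((2 * r + 1,) * 3) - r
    return (g**2).sum(axis=0) <= r**2


def refine_mask(mask: BoneMask, edits) -> tuple:
    """Apply spherical paint/erase edits in order; returns (new mask, report).

    The report maps label -> component count after editing; a count other
    than 1 is an invariant violation that is reported, never silently fixed.
    Points must fall inside the grid.
    """
    labels = mask.labels.copy()
    dims = np.asarray(labels.shape)
    spacing = np.asarray(mask.spacing)
    for e in edits:
        idx = _world_to_index(e.point, mask.spacing, mask.origin)[0]
        if np.any(idx < 0) or np.any(idx > dims - 1):
            raise ValueError(f"edit point {tuple(e.point)} outside the grid")
        if e.mode not in ("add", "remove"):
            raise ValueError(f"edit mode must be 'add' or 'remove', got {e.mode!r}")
        # sphere in mm, evaluated on the voxel lattice
        lo = np.maximum(0, np.floor(idx - e.radius_mm / spacing - 1).astype(int))
        hi = np.minimum(dims, np.ceil(idx + e.radius_mm / spacing + 2).astype(int))
        sub = np.indices(tuple(hi - lo)).reshape(3, -1).T + lo
        d2 = (((sub - idx) * spacing) ** 2).sum(axis=1)
        sel = tuple(sub[d2 <= e.radius_mm**2].T)
        if e.mode == "add":
            labels[sel] = e.label
        else:
            region = labels[sel]
            region[region == e.label] = 0
            labels[sel] = region
    new = BoneMask(labels, mask.spacing, mask.origin)
    return new, new.check_connectivity()


def mask_to_region(mask: BoneMask, label, dilation_mm: float = 2.0) -> np.ndarray:
    """Binary registration region: one bone dilated by ``dilation_mm`` to
    include edge context; congruent with the source volume."""
    if isinstance(label, str):
        label = BONE_LABELS[label]
    if label not in mask.present_labels():
        raise KeyError(f"label {label} not present in mask (has {sorted(mask.present_labels())})")
    region = mask.labels == label
    if dilation_mm > 0:
        # isotropic dilation via EDT threshold (handles anisotropic spacing)
        dist = ndimage.distance_transform_edt(~region, sampling=mask.spacing)
        region = dist <= dilation_mm
    return region
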