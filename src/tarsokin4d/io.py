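"""Volume, transform and landmark I/O.

Volumes round-trip through NIfTI-1 (.nii/.nii.gz) and MetaImage (.mha/.mhd)
preserving dims, spacing, origin and intensities (axis-aligned geometry
only).  Rigid transforms are serialized as JSON lists of 4x4 row-major
homogeneous matrices in mm; landmarks as a JSON name→[x, y, z] mapping.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import SimpleITK as sitk

from .core import FormatError, RigidTransform, VoxelGrid
from .phantom import LandmarkSet

__all__ = [
    "read_volume",
    "write_volume",
    "read_transforms",
    "write_transforms",
    "read_landmarks",
    "write_landmarks",
]

_VOLUME_SUFFIXES = (".nii", ".nii.gz", ".mha", ".mhd")

#: convention recorded in every transform JSON we write
TRANSFORM_CONVENTION = "reference_to_moving"


def _check_suffix(path: Path) -> None:
    name = path.name.lower()
    if not any(name.endswith(s) for s in _VOLUME_SUFFIXES):
        raise FormatError(
            f"unknown volume extension on {path.name!r}; "
            f"supported: {', '.join(_VOLUME_SUFFIXES)}"
        )


def read_volume(path) -> VoxelGrid:
    """Read a NIfTI or MetaImage volume into a :class:`VoxelGrid`."""
    path = Path(path)
    _check_suffix(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as exc:  # malformed header etc.
        raise FormatError(f"cannot read {path}: {exc}") from exc
    if img.GetDimension() != 3:
        raise FormatError(f"{path} is not a 3D volume")
    direction = np.array(img.GetDirection()).reshape(3, 3)
    if not np.allclose(direction, np.eye(3), atol=1e-6):
        raise FormatError(f"{path}: oblique direction cosines are not supported")
    # SimpleITK arrays are (z, y, x); VoxelGrid stores (x, y, z)
    arr = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    return VoxelGrid(arr.astype(float), spacing=img.GetSpacing(), origin=img.GetOrigin())


def write_volume(grid: VoxelGrid, path) -> None:
    path = Path(path)
    _check_suffix(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"parent directory {path.parent} does not exist")
    img = sitk.GetImageFromArray(np.ascontiguousarray(grid.intensities.transpose(2, 1, 0)))
    img.SetSpacing(tuple(grid.spacing))
    img.SetOrigin(tuple(grid.origin))
    sitk.WriteImage(img, str(path))


def write_transforms(transforms, path, convention: str = TRANSFORM_CONVENTION) -> None:
    """Serialize rigid transforms as JSON 4x4 row-major matrices (mm)."""
    payload = {
        "convention": convention,
        "units": "mm",
        "matrices": [np.asarray(t.as_matrix()).tolist() for t in transforms],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_transforms(path) -> list:
    """Read a transform JSON; rejects non-rigid matrices (orthonormality
    violated beyond 1e-6, or reflections)."""
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: not valid JSON ({exc})") from exc
    if isinstance(payload, list):  # bare list of matrices also accepted
        matrices = payload
    else:
        matrices = payload.get("matrices")
        if matrices is None:
            raise FormatError(f"{path}: missing 'matrices' key")
    return [RigidTransform.from_matrix(np.asarray(m, dtype=float)) for m in matrices]


def write_landmarks(landmarks: LandmarkSet, path) -> None:
    payload = {
        "trochlea_center": landmarks.trochlea_center.tolist(),
        "tibial_tuberosity": landmarks.tibial_tuberosity.tolist(),
        "medial_malleolus": landmarks.medial_malleolus.tolist(),
        "tre_points": {k: v.tolist() for k, v in landmarks.tre_points.items()},
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_landmarks(path) -> LandmarkSet:
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: not valid JSON ({exc})") from exc
    try:
        return LandmarkSet(
            trochlea_center=payload["trochlea_center"],
            tibial_tuberosity=payload["tibial_tuberosity"],
            medial_malleolus=payload["medial_malleolus"],
            tre_points=payload.get("tre_points", {}),
        )
    except KeyError as exc:
        raise FormatError(f"{path}: missing landmark {exc}") from exc
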