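"""Scenario presets for the four ligament-integrity states.

The synthetic scenarios emulate a cadaver 4DCT experiment in which an ankle
was driven from maximum dorsiflexion to full inversion under four ligament
states: intact (scenario 1), then sequential sectioning of the anterior
talo-fibular (2), calcaneo-fibular (3) and posterior talo-fibular (4)
ligaments.  Sectioning progressively enlarges the talocrural range of motion,
so scenarios 2-4 are amplitude presets on top of scenario 1.

Axis conventions (right-handed anatomical frame): X points lateral→medial
(rotation = dorsi-/plantar-flexion), Y completes the frame (rotation =
pronation/supination, translation = antero-posterior), Z runs cranially along
the tibia (rotation = ab-/adduction, translation = cranio-caudal).

``SCENARIO1_REFERENCE`` holds the measured end-range values of the four
intact-state repetitions of the reference cadaver experiment; they anchor the
generator defaults and double as worked-example inputs for the repeatability
and percent-change arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ScenarioSpec",
    "SCENARIO1_REFERENCE",
    "SCENARIO_DELTAS",
    "SCENARIO_AXIS_REFERENCE",
    "scenario_spec",
]

# Measured end-range values for the intact scenario, one row per repetition.
# Rotations are ZYX Cardan angles (deg) of the talus relative to the tibia at
# full inversion; translations are the trochlea-center displacement (mm).
SCENARIO1_REFERENCE = {
    "rotation_deg": np.array(
        [
            [37.81, -1.97, 12.36],
            [37.81, -1.80, 12.18],
            [37.78, -1.88, 12.19],
            [37.00, -1.60, 11.47],
        ]
    ),
    "translation_mm": np.array(
        [
            [0.10, -11.08, -5.94],
            [-0.14, -11.28, -5.92],
            [-0.06, -11.22, -5.86],
            [-0.17, -10.62, -5.87],
        ]
    ),
    # helical axis per repetition: axial displacement (mm), total rotation
    # (deg), orientation vector (printed as rounded components; not unit norm)
    "axis_displacement_mm": np.array([0.40, 0.39, 0.44, 0.38]),
    "axis_rotation_deg": np.array([43.23, 43.40, 43.62, 43.53]),
    "axis_vector": np.array([-0.77, 0.15, -0.23]),
}

# Signed maximum differences of each sectioned scenario relative to the
# intact scenario over the motion course (rotation deg, translation mm).
SCENARIO_DELTAS = {
    1: {"rotation_deg": np.zeros(3), "translation_mm": np.zeros(3)},
    2: {
        "rotation_deg": np.array([6.07, 5.12, 4.88]),
        "translation_mm": np.array([0.56, 1.54, 2.61]),
    },
    3: {
        "rotation_deg": np.array([5.46, 8.82, 5.47]),
        "translation_mm": np.array([0.78, -2.37, 2.41]),
    },
    4: {
        "rotation_deg": np.array([9.83, 10.01, 6.93]),
        "translation_mm": np.array([0.21, -2.73, 3.85]),
    },
}

# Mean helical-axis orientation (rounded components) and intersection with the
# sagittal plane X = 11.46 mm through the trochlea center, per scenario.
SCENARIO_AXIS_REFERENCE = {
    "plane_x_mm": 11.46,
    1: {"orientation": np.array([-0.77, 0.15, -0.23]), "intercept_yz": (10.08, -148.00)},
    2: {"orientation": np.array([-0.72, 0.24, -0.28]), "intercept_yz": (10.46, -147.08)},
    3: {"orientation": np.array([-0.72, 0.31, -0.23]), "intercept_yz": (11.58, -144.87)},
    4: {"orientation": np.array([-0.71, 0.33, -0.24]), "intercept_yz": (11.62, -144.16)},
}

#: Scenario 1 end range = mean of the four reference repetitions.
_S1_ROT = SCENARIO1_REFERENCE["rotation_deg"].mean(axis=0)
_S1_TRA = SCENARIO1_REFERENCE["translation_mm"].mean(axis=0)

#: Default repetition noise: zero-mean Gaussian perturbation of the end range,
#: one draw per repetition.  0.2 deg / 0.1 mm keeps the max pairwise
#: end-range difference of four repetitions well below 1 deg / 1 mm.
DEFAULT_NOISE_DEG = 0.2
DEFAULT_NOISE_MM = 0.1


@dataclass(frozen=True)
class ScenarioSpec:
    """Parametric description of one scenario's ground-truth motion.

    ``end_range_rotation`` are ZYX Cardan angles (deg) and
    ``end_range_translation`` the trochlea-center displacement (mm) reached at
    the final frame; intermediate frames follow a smoothstep schedule.
    """

    scenario_id: int
    end_range_rotation: tuple
    end_range_translation: tuple
    n_frames: int = 18
    repetition_noise_deg: float = DEFAULT_NOISE_DEG
    repetition_noise_mm: float = DEFAULT_NOISE_MM
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= int(self.scenario_id) <= 4:
            raise ValueError("scenario_id must be 1..4")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.repetition_noise_deg < 0 or self.repetition_noise_mm < 0:
            raise ValueError("repetition noise must be >= 0")
        object.__setattr__(self, "end_range_rotation", tuple(float(v) for v in self.end_range_rotation))
        object.__setattr__(self, "end_range_translation", tuple(float(v) for v in self.end_range_translation))


def scenario_spec(
    scenario_id: int,
    n_frames: int = 18,
    repetition_noise_deg: float = DEFAULT_NOISE_DEG,
    repetition_noise_mm: float = DEFAULT_NOISE_MM,
    seed: int = 0,
) -> ScenarioSpec:
    """Default spec for a scenario: intact-state mean end range plus, for
    scenarios 2-4, the signed between-scenario maximum differences."""
    if scenario_id not in SCENARIO_DELTAS:
        raise ValueError("scenario_id must be 1..4")
    rot = _S1_ROT + SCENARIO_DELTAS[scenario_id]["rotation_deg"]
    tra = _S1_TRA + SCENARIO_DELTAS[scenario_id]["translation_mm"]
    return ScenarioSpec(
        scenario_id=scenario_id,
        end_range_rotation=tuple(rot),
        end_range_translation=tuple(tra),
        n_frames=n_frames,
        repetition_noise_deg=repetition_noise_deg,
        repetition_noise_mm=repetition_noise_mm,
        seed=seed,
    )
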