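import numpy as np
import pytest

import tarsokin4d as tk


@pytest.fixture(scope="session")
def phantom():
    """Default-size phantom (64x64x96 @ 1 mm), shared read-only."""
    return tk.make_bone_phantom(seed=1)


@pytest.fixture(scope="session")
def noiseless_end_seq(phantom):
    """Two-frame noiseless scenario-1 sequence: reference + full end-range frame."""
    spec = tk.scenario_spec(1, n_frames=2, repetition_noise_deg=0, repetition_noise_mm=0)
    profile = tk.make_motion_profile(spec, center=phantom.landmarks.trochlea_center)
    seq = tk.render_sequence(phantom, profile, noise_sd=0.0, seed=1)
    return seq, profile


@pytest.fixture(scope="session")
def reference_mask(phantom, noiseless_end_seq):
    seq, _ = noiseless_end_seq
    arr = seq.reference.intensities
    thr = 0.5 * (arr.min() + arr.max())
    return tk.segment_reference(
        seq.reference,
        thr,
        seeds={
            "tibia": phantom.landmarks.tibial_tuberosity,
            "talus": phantom.landmarks.trochlea_center,
        },
    )


def default_threshold(grid):
    arr = grid.intensities
    lo, hi = np.percentile(arr, [1.0, 99.5])
    return 0.5 * (lo + hi)
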