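"""Segment the reference frame into tibia/talus masks.

Thresholding at the midpoint of the intensity range, morphological cleanup,
then seeded connected components: each bone becomes the component containing
its seed landmark.  The Dice overlap against the generator's true labels
shows how faithful the semi-automatic step is.
"""

import numpy as np

import tarsokin4d as tk

phantom = tk.make_bone_phantom(seed=7)
spec = tk.scenario_spec(1, n_frames=2, repetition_noise_deg=0, repetition_noise_mm=0)
profile = tk.make_motion_profile(spec, center=phantom.landmarks.trochlea_center)
seq = tk.render_sequence(phantom, profile, noise_sd=20.0, seed=1)

arr = seq.reference.intensities
threshold = 0.5 * (np.percentile(arr, 1) + np.percentile(arr, 99.5))
mask = tk.segment_reference(
    seq.reference,
    threshold,
    seeds={"tibia": phantom.landmarks.tibial_tuberosity,
           "talus": phantom.landmarks.trochlea_center},
)
print("threshold:", round(threshold, 1), "components:", mask.check_connectivity())

for name, label in (("tibia", 1), ("talus", 2)):
    a = phantom.labels == label
    b = mask.labels == label
    dice = 2 * np.sum(a & b) / (a.sum() + b.sum())
    print(f"{name}: {b.sum()} voxels, Dice vs ground truth = {dice:.3f}")
# Dice ~0.97-0.99 per bone: the threshold+morphology step recovers the bones
# almost exactly on this noise level.

region = tk.mask_to_region(mask, "talus", dilation_mm=2.0)
print("talus registration region (2 mm context):", int(region.sum()), "voxels")
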