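"""Kinematic parameters from rigid transforms: Cardan angles, trochlea
displacement and the finite helical axis.

A talocrural displacement is summarized three ways: ZYX Cardan angles
(R = Rz Ry Rx; x = dorsi-/plantar-flexion, y = pronation/supination,
z = ab-/adduction), the mm displacement of the trochlea tali center, and the
finite helical axis — the single screw (line + rotation about it + slide
along it) equivalent to the displacement.
"""

import numpy as np

import tarsokin4d as tk

# end-range pose of the first intact-scenario repetition (measured values)
rot = tk.rotation_zyx(37.81, -1.97, 12.36)
trochlea = np.array([11.46, 10.0, 30.0])
tf = tk.RigidTransform.rotation_about_point(rot, trochlea,
                                            extra_translation=(0.10, -11.08, -5.94))

angles = tk.cardan_zyx(tf)
print("Cardan ZYX (deg): x=%.2f  y=%.2f  z=%.2f" % (angles.x, angles.y, angles.z))

disp = tk.landmark_displacement(tf, trochlea)
print("trochlea displacement (mm):", np.round(disp, 2))

fha = tk.finite_helical_axis(tf)
print("helical axis direction:", np.round(fha.direction, 3))
print("helical rotation: %.2f deg, axial slide: %.2f mm" % (fha.angle_deg, fha.axial_translation))
# The helical angle (~40 deg) exceeds every single Cardan component: the screw
# axis combines the three rotations into one oblique rotation axis.

summary = tk.axis_summary(fha, plane_x=trochlea[0])
print("canonical orientation (X <= 0):", np.round(summary.orientation, 3))
print("sagittal-plane intersection (Y, Z mm):", np.round(summary.intercept_yz, 2))

# round trip: the four helical fields reconstruct the original transform
err = np.abs(fha.to_transform().as_matrix() - tf.as_matrix()).max()
print("screw reconstruction error:", f"{err:.2e}")
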