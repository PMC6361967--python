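"""Mutual information metric, rigid recovery and TRE."""

import numpy as np
import pytest

import tarsokin4d as tk
from tarsokin4d.registration import RegistrationConfig, centroid_prealign

from conftest import default_threshold


@pytest.fixture(scope="module")
def talus_region(reference_mask):
    return tk.mask_to_region(reference_mask, "talus", dilation_mm=2.0)


class TestMutualInformation:
    def test_self_information_equals_entropy(self, noiseless_end_seq, talus_region):
        """MI(f, f | identity) = H(f) over the region."""
        seq, _ = noiseless_end_seq
        f = seq.reference
        mi = tk.mutual_information(f, f, tk.RigidTransform.identity(), talus_region, bins=32)
        vals = f.intensities[talus_region]
        edges = np.linspace(vals.min(), vals.max(), 33)
        hist, _ = np.histogram(vals, bins=edges)
        p = hist / hist.sum()
        h = -np.sum(p[p > 0] * np.log(p[p > 0]))
        assert np.isclose(mi, h, atol=1e-9)

    def test_independent_noise_has_near_zero_mi(self):
        rng = np.random.default_rng(0)
        f = tk.VoxelGrid(rng.random((47, 47, 47)))
        g = tk.VoxelGrid(rng.random((47, 47, 47)))
        region = np.ones(f.dims, dtype=bool)  # ~1e5 voxels
        mi = tk.mutual_information(f, g, tk.RigidTransform.identity(), region, bins=32)
        assert 0.0 <= mi <= 0.05

    def test_constant_fixed_image_gives_zero(self):
        f = tk.VoxelGrid(np.full((20, 20, 20), 7.0))
        g = tk.VoxelGrid(np.random.default_rng(1).random((20, 20, 20)))
        mi = tk.mutual_information(f, g, tk.RigidTransform.identity(), np.ones(f.dims, bool))
        assert np.isclose(mi, 0.0, atol=1e-12)

    def test_symmetry_at_identity(self, noiseless_end_seq, talus_region):
        seq, _ = noiseless_end_seq
        f, g = seq.reference, seq.frames[0]
        ident = tk.RigidTransform.identity()
        a = tk.mutual_information(f, g, ident, talus_region)
        b = tk.mutual_information(g, f, ident, talus_region)
        assert np.isclose(a, b, atol=0.02)  # histogram-discretization tolerance

    def test_empty_region_and_out_of_field(self, noiseless_end_seq, talus_region):
        seq, _ = noiseless_end_seq
        f = seq.reference
        with pytest.raises(tk.MetricUndefinedError):
            tk.mutual_information(f, f, tk.RigidTransform.identity(), np.zeros(f.dims, bool))
        far = tk.RigidTransform(np.eye(3), (1e4, 0, 0))
        with pytest.raises(tk.MetricUndefinedError):
            tk.mutual_information(f, f, far, talus_region)


class TestRegisterRigid:
    def test_self_registration_is_identity(self, noiseless_end_seq, talus_region):
        seq, _ = noiseless_end_seq
        f = seq.reference
        res = tk.register_rigid(f, f, talus_region, config=RegistrationConfig(coarse_search=False))
        ang, tra = tk.transform_difference(res.transform, tk.RigidTransform.identity(),
                                           np.array([32.0, 32.0, 32.0]))
        assert ang <= 0.05 and tra <= 0.05
        assert res.converged

    def test_recovers_known_end_range_motion(self, phantom, noiseless_end_seq, talus_region):
        """Full end-range frame (rotations to ~38 deg) recovered within 0.5 deg / 0.5 mm
        from identity init plus centroid pre-alignment."""
        seq, profile = noiseless_end_seq
        init = centroid_prealign(seq.reference, seq.frames[0], talus_region)
        res = tk.register_rigid(seq.reference, seq.frames[0], talus_region, init=init)
        ang, tra = tk.transform_difference(
            res.transform, profile.transforms[-1], phantom.landmarks.trochlea_center
        )
        assert ang <= 0.5 and tra <= 0.5
        assert res.converged

    def test_metric_history_monotone_within_levels(self, noiseless_end_seq, talus_region):
        seq, _ = noiseless_end_seq
        res = tk.register_rigid(seq.reference, seq.frames[0], talus_region,
                                init=centroid_prealign(seq.reference, seq.frames[0], talus_region))
        for level in res.metric_history:
            assert all(b <= a + 1e-12 for a, b in zip(level, level[1:]))

    def test_equivariance_under_known_perturbation(self, phantom):
        """Shifting the ground-truth motion by P shifts the recovered transform by P."""
        tc = phantom.landmarks.trochlea_center
        spec = tk.ScenarioSpec(1, (8.0, -3.0, 5.0), (1.0, -2.0, -1.5), n_frames=2,
                               repetition_noise_deg=0, repetition_noise_mm=0)
        prof = tk.make_motion_profile(spec, center=tc)
        P = tk.RigidTransform.rotation_about_point(tk.rotation_zyx(4.0, 0, 0), tc,
                                                   extra_translation=(0, 1.0, 0))
        perturbed = tk.phantom.MotionProfile(
            [prof.transforms[0], P @ prof.transforms[1]], prof.angles_deg,
            prof.translations_mm, prof.center)
        seq_a = tk.render_sequence(phantom, prof, noise_sd=0.0, seed=0)
        seq_b = tk.render_sequence(phantom, perturbed, noise_sd=0.0, seed=0)
        mask = tk.segment_reference(
            seq_a.reference, default_threshold(seq_a.reference),
            {"tibia": phantom.landmarks.tibial_tuberosity, "talus": tc})
        region = tk.mask_to_region(mask, "talus")
        cfg = RegistrationConfig(coarse_search=False)
        ra = tk.register_rigid(seq_a.reference, seq_a.frames[0], region, config=cfg)
        rb = tk.register_rigid(seq_b.reference, seq_b.frames[0], region, config=cfg)
        ang, tra = tk.transform_difference(rb.transform, P @ ra.transform, tc)
        assert ang <= 0.3 and tra <= 0.3

    def test_empty_region_raises(self, noiseless_end_seq):
        seq, _ = noiseless_end_seq
        with pytest.raises(tk.MetricUndefinedError):
            tk.register_rigid(seq.reference, seq.frames[0], np.zeros(seq.reference.dims, bool))


class TestRegisterSequence:
    def test_two_frame_sequence_gives_one_transform(self, phantom, noiseless_end_seq, reference_mask):
        seq, profile = noiseless_end_seq
        reg = tk.register_sequence(seq, reference_mask)
        assert len(reg.transforms["talus"]) == 1
        assert len(reg.transforms["tibia"]) == 1
        assert reg.all_converged("talus")
        # static tibia registers to identity
        ang, tra = tk.transform_difference(
            reg.transforms["tibia"][0], tk.RigidTransform.identity(),
            phantom.landmarks.trochlea_center)
        assert ang <= 0.1 and tra <= 0.1
        # moving talus matches the ground truth
        ang, tra = tk.transform_difference(
            reg.transforms["talus"][0], profile.transforms[-1],
            phantom.landmarks.trochlea_center)
        assert ang <= 0.5 and tra <= 0.5

    def test_geometry_mismatch_rejected(self, noiseless_end_seq):
        seq, _ = noiseless_end_seq
        bad = tk.BoneMask(np.zeros((10, 10, 10), np.int16), (1, 1, 1), (0, 0, 0))
        with pytest.raises(ValueError):
            tk.register_sequence(seq, bad)


class TestRelativeMotion:
    def test_closed_forms(self):
        ident = tk.RigidTransform.identity()
        T = tk.RigidTransform.from_euler_zyx(10, 5, -3, (1, 2, 3))
        assert tk.relative_motion(ident, ident).is_identity(atol=1e-12)
        assert np.allclose(tk.relative_motion(T, ident).as_matrix(), T.as_matrix())
        assert tk.relative_motion(T, T).is_identity(atol=1e-9)


class TestTargetRegistrationError:
    def test_exact_correspondence_gives_zero(self):
        pts = np.random.default_rng(0).normal(0, 20, (15, 3))
        T = tk.RigidTransform.from_euler_zyx(20, -5, 10, (1, -2, 3))
        rep = tk.target_registration_error(pts, T.apply(pts), T)
        assert np.allclose(rep.errors, 0, atol=1e-12)
        assert rep.min <= rep.mean <= rep.max

    def test_three_four_five(self):
        rep = tk.target_registration_error([[0, 0, 0]], [[3, 4, 0]], tk.RigidTransform.identity())
        assert np.isclose(rep.mean, 5.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            tk.target_registration_error([[0, 0, 0]], [[1, 1, 1], [2, 2, 2]],
                                         tk.RigidTransform.identity())

    def test_end_to_end_tre_below_1mm(self, phantom, noiseless_end_seq, reference_mask):
        """Registered transform keeps correspondence error well below 1 mm."""
        seq, profile = noiseless_end_seq
        reg = tk.register_sequence(seq, reference_mask, bones=("talus",))
        pts = phantom.landmarks.tre_points["talus"]
        rep = tk.target_registration_error(
            pts, profile.transforms[-1].apply(pts), reg.transforms["talus"][0])
        assert rep.mean <= 1.0
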