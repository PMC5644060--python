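"""Posing, contact detection and impingement-limited motion search."""

import numpy as np
import pytest
import trimesh

from hiprom.frames import Frame, SphereFit, _axis_angle_matrix
from hiprom.rom import (CollisionConfig, ContactChecker, Pose, check_exclusion,
                        classify_region, detect_contact, max_flexion,
                        max_internal_rotation_at_flexion, pose_femur,
                        pose_rotation, sweep_limit)
from hiprom.synthetic import FemurParams, generate_hip_case

CFG = CollisionConfig()


def _identity_frames():
    pelvic = Frame(origin=np.zeros(3), axes=np.eye(3))
    femoral = Frame(origin=np.zeros(3), axes=np.eye(3))
    return pelvic, femoral


class TestPose:
    def test_neutral_pose_is_identity(self):
        pelvic, femoral = _identity_frames()
        assert np.allclose(pose_rotation(pelvic, femoral, Pose(0, 0)), np.eye(3))

    def test_matches_composition_of_rotation_matrices(self):
        """Flexion about the pelvic x axis followed by internal rotation
        about the flexed long axis equals the explicit matrix product."""
        pelvic, femoral = _identity_frames()
        R = pose_rotation(pelvic, femoral, Pose(90.0, 30.0))
        r_flex = _axis_angle_matrix(np.array([1.0, 0, 0]), np.pi / 2)
        flexed_axis = r_flex @ np.array([0.0, 0, -1.0])
        r_ir = _axis_angle_matrix(flexed_axis, -np.radians(30.0))
        assert np.allclose(R, r_ir @ r_flex, atol=1e-12)
        marker = np.array([10.0, 5.0, -30.0])
        assert np.allclose(R @ marker, r_ir @ (r_flex @ marker))

    def test_inverse_composition_returns_marker(self):
        pelvic, femoral = _identity_frames()
        R = pose_rotation(pelvic, femoral, Pose(40.0, 25.0))
        marker = np.array([7.0, -3.0, -20.0])
        assert np.allclose(R.T @ (R @ marker), marker, atol=1e-12)

    def test_pose_femur_rotates_about_head_center(self, demo_case):
        case, fit, femoral, pelvic = demo_case
        posed = pose_femur(case.femur_mesh, pelvic, femoral, Pose(30.0, 0.0))
        d0 = np.linalg.norm(case.femur_mesh.vertices - fit.center, axis=1)
        d1 = np.linalg.norm(posed.vertices - fit.center, axis=1)
        assert np.allclose(d0, d1, atol=1e-9)  # pure rotation, no translation

    def test_pose_validation(self):
        with pytest.raises(ValueError):
            Pose(flexion=-5.0)
        with pytest.raises(ValueError):
            Pose(flexion=90.0, internal_rotation=120.0)


class TestDetectContact:
    def _spheres(self, dist):
        a = trimesh.creation.icosphere(subdivisions=3, radius=1.0)
        b = trimesh.creation.icosphere(subdivisions=3, radius=1.0)
        b.vertices = b.vertices + np.array([dist, 0.0, 0.0])
        return a, b

    def test_separated_spheres_do_not_touch(self):
        a, b = self._spheres(3.0)
        hit, _ = detect_contact(a, b, CFG)
        assert not hit

    def test_overlapping_spheres_touch(self):
        a, b = self._spheres(1.5)
        hit, witness = detect_contact(a, b, CFG)
        assert hit and witness is not None

    def test_near_tangency_witness_at_gap_midpoint(self):
        gap = CFG.contact_tolerance / 2
        a, b = self._spheres(2.0 + gap)
        hit, witness = detect_contact(a, b, CFG)
        assert hit
        assert np.linalg.norm(witness - [1.0 + gap / 2, 0, 0]) < 0.1

    def test_non_watertight_input_warns(self):
        a, _ = self._spheres(3.0)
        open_box = trimesh.Trimesh(
            vertices=[[5, 0, 0], [6, 0, 0], [5, 1, 0], [6, 1, 0]],
            faces=[[0, 1, 2], [1, 3, 2]], process=False)
        with pytest.warns(UserWarning, match="distance-only"):
            hit, _ = detect_contact(a, open_box, CFG)
        assert not hit


class TestMotionLimits:
    def test_bisection_matches_exhaustive_sweep(self, demo_case):
        """The bisection limit equals an ascending 0.05-degree sweep limit
        within the angular resolution (light version; the acceptance suite
        covers 20 cases)."""
        case, fit, femoral, pelvic = demo_case
        checker = ContactChecker(case.pelvis_mesh, case.femur_mesh,
                                 fit.center, CFG)
        ir = max_internal_rotation_at_flexion(case.pelvis_mesh, case.femur_mesh,
                                              pelvic, femoral, 90.0, CFG,
                                              checker=checker)
        swept = sweep_limit(checker, pelvic, femoral, "internal_rotation",
                            step=0.05)
        assert ir.limit_angle == pytest.approx(swept, abs=0.1)

    def test_limits_invariant_under_rigid_motion(self, demo_case, rng):
        """Rotating pelvis + femur + frames together leaves both motion
        limits unchanged within the search resolution."""
        case, fit, femoral, pelvic = demo_case
        checker = ContactChecker(case.pelvis_mesh, case.femur_mesh,
                                 fit.center, CFG)
        ir0 = max_internal_rotation_at_flexion(None, None, pelvic, femoral,
                                               90.0, CFG, checker=checker)
        fx0 = max_flexion(None, None, pelvic, femoral, CFG, checker=checker)

        q = rng.normal(size=4)
        q /= np.linalg.norm(q)
        w, x, y, z = q
        R = np.array([
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)]])
        t = np.array([10.0, -5.0, 20.0])

        def move(mesh):
            return trimesh.Trimesh(vertices=np.asarray(mesh.vertices) @ R.T + t,
                                   faces=mesh.faces, process=False)

        pel_m = Frame(origin=R @ pelvic.origin + t, axes=pelvic.axes @ R.T)
        fem_m = Frame(origin=R @ femoral.origin + t, axes=femoral.axes @ R.T)
        checker_m = ContactChecker(move(case.pelvis_mesh), move(case.femur_mesh),
                                   fem_m.origin, CFG)
        ir1 = max_internal_rotation_at_flexion(None, None, pel_m, fem_m, 90.0,
                                               CFG, checker=checker_m)
        fx1 = max_flexion(None, None, pel_m, fem_m, CFG, checker=checker_m)
        assert ir1.limit_angle == pytest.approx(ir0.limit_angle, abs=0.25)
        assert fx1.limit_angle == pytest.approx(fx0.limit_angle, abs=0.25)

    def test_larger_tolerance_never_raises_a_limit(self, demo_case):
        case, fit, femoral, pelvic = demo_case
        limits = []
        for tol in (0.05, 0.1, 0.3):
            cfg = CollisionConfig(contact_tolerance=tol)
            checker = ContactChecker(case.pelvis_mesh, case.femur_mesh,
                                     fit.center, cfg)
            limits.append(max_internal_rotation_at_flexion(
                None, None, pelvic, femoral, 90.0, cfg,
                checker=checker).limit_angle)
        assert limits[0] >= limits[1] - 0.1 >= limits[2] - 0.2

    def test_growing_cam_never_raises_the_rotation_limit(self):
        from hiprom.frames import build_femoral_frame, build_pelvic_frame, fit_sphere
        from hiprom.synthetic import (LandmarkSet, PelvisParams, generate_femur,
                                      generate_pelvis)
        pelvis, plm, _ = generate_pelvis(PelvisParams(), target_ce=22.0)
        limits = []
        for amp in (1.0, 3.0, 5.0):
            femur, flm, _ = generate_femur(FemurParams(cam_amplitude=amp))
            lm = LandmarkSet(**plm, **flm)
            fit = fit_sphere(lm.head_reference_points)
            femoral = build_femoral_frame(fit.center, lm.medial_epicondyle,
                                          lm.lateral_epicondyle)
            pelvic = build_pelvic_frame(lm, side="right")
            checker = ContactChecker(pelvis, femur, fit.center, CFG)
            limits.append(max_internal_rotation_at_flexion(
                None, None, pelvic, femoral, 90.0, CFG,
                checker=checker).limit_angle)
        assert limits[0] >= limits[1] >= limits[2]

    def test_contact_at_start_pose_is_an_error(self):
        a = trimesh.creation.icosphere(subdivisions=2, radius=10.0)
        b = trimesh.creation.icosphere(subdivisions=2, radius=10.0)
        b.vertices = b.vertices + np.array([5.0, 0, 0])  # overlapping at neutral
        pelvic, femoral = _identity_frames()
        checker = ContactChecker(a, b, np.zeros(3), CFG)
        with pytest.raises(ValueError, match="malformed"):
            max_flexion(None, None, pelvic, femoral, CFG, checker=checker)


class TestExclusionAndRegion:
    @pytest.mark.parametrize("limit, capped, excluded", [
        (85.0, False, True),    # impingement below 90 deg of flexion
        (113.1, False, False),  # typical cam-FAI flexion limit
        (150.0, True, False),   # cap reached, never impinged
    ])
    def test_exclusion_rule(self, limit, capped, excluded):
        from hiprom.rom import ROMResult
        res = ROMResult(limit_angle=limit,
                        contact_point=None if capped else np.zeros(3),
                        region="none" if capped else "unassigned",
                        reached_cap=capped)
        assert check_exclusion(res) is excluded

    def test_region_split_and_tie_break(self):
        fit = SphereFit(center=np.zeros(3), radius=24.0, rms_residual=0.0)
        axis = np.array([0.0, 0.0, 1.0])
        rn = 16.5
        boundary = np.sqrt(24.0**2 - rn**2)
        on_head = [5.0, 0.0, boundary - 5.0]
        on_neck = [5.0, 0.0, boundary + 5.0]
        on_plane = [rn, 0.0, boundary]
        assert classify_region(on_head, fit, axis, rn) == "proximal"
        assert classify_region(on_neck, fit, axis, rn) == "distal"
        assert classify_region(on_plane, fit, axis, rn) == "proximal"  # tie

    def test_far_retracted_rim_reaches_flexion_cap(self):
        """A cup with a large clearance never blocks flexion: the search
        stops at the 150-degree cap with no contact point."""
        from hiprom.frames import build_femoral_frame, build_pelvic_frame, fit_sphere
        from hiprom.synthetic import (LandmarkSet, PelvisParams, generate_femur,
                                      generate_pelvis)
        pelvis, plm, _ = generate_pelvis(PelvisParams(cup_radius=45.0,
                                                      rim_thickness=3.0))
        femur, flm, _ = generate_femur(FemurParams())
        lm = LandmarkSet(**plm, **flm)
        fit = fit_sphere(lm.head_reference_points)
        femoral = build_femoral_frame(fit.center, lm.medial_epicondyle,
                                      lm.lateral_epicondyle)
        pelvic = build_pelvic_frame(lm, side="right")
        checker = ContactChecker(pelvis, femur, fit.center, CFG)
        res = max_flexion(None, None, pelvic, femoral, CFG, checker=checker)
        assert res.reached_cap and res.limit_angle == CFG.flexion_cap
        assert res.contact_point is None and res.region == "none"
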