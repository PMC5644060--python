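"""Virtual osteochondroplasty: trough placement, carving and contracts."""

import numpy as np
import pytest

from hiprom.frames import build_femoral_frame, build_pelvic_frame, fit_sphere
from hiprom.resection import (RESECTION_MODELS, ResectionSpec, apply_resection,
                              compute_improvement, jitter_center,
                              make_resection_spec)
from hiprom.rom import (CollisionConfig, ContactChecker,
                        max_internal_rotation_at_flexion)
from hiprom.synthetic import (FemurParams, LandmarkSet, PelvisParams,
                              generate_femur, generate_pelvis)

CFG = CollisionConfig()


def half_ellipsoid_volume(model: str) -> float:
    d, w, length = RESECTION_MODELS[model]
    return (2.0 / 3.0) * np.pi * (w / 2.0) * d * (length / 2.0)


@pytest.fixture(scope="module")
def cam_setup():
    """Calibrated cam hip with its pre-op internal-rotation result."""
    femur, flm, fp = generate_femur(FemurParams(), target_alpha=66.0)
    pelvis, plm, _ = generate_pelvis(PelvisParams(), target_ce=22.0)
    lm = LandmarkSet(**plm, **flm)
    fit = fit_sphere(lm.head_reference_points)
    femoral = build_femoral_frame(fit.center, lm.medial_epicondyle,
                                  lm.lateral_epicondyle)
    pelvic = build_pelvic_frame(lm, side="right")
    checker = ContactChecker(pelvis, femur, fit.center, CFG)
    ir0 = max_internal_rotation_at_flexion(None, None, pelvic, femoral, 90.0,
                                           CFG, checker=checker)
    return dict(femur=femur, pelvis=pelvis, fit=fit, femoral=femoral,
                pelvic=pelvic, ir0=ir0)


class TestSpecPlacement:
    @pytest.mark.parametrize("model, dims", [("slight", (4.0, 8.0, 15.0)),
                                             ("sufficient", (8.0, 16.0, 15.0))])
    def test_standardized_dimensions(self, cam_setup, model, dims):
        spec = make_resection_spec(model, cam_setup["ir0"].contact_point,
                                   cam_setup["femoral"], cam_setup["femur"])
        assert (spec.depth, spec.width, spec.length) == dims
        # orthonormal local frame: depth, width and length directions
        for a, b in [(spec.normal, spec.width_dir), (spec.normal, spec.length_dir),
                     (spec.width_dir, spec.length_dir)]:
            assert abs(a @ b) < 1e-9

    def test_unknown_model_fails(self, cam_setup):
        with pytest.raises(ValueError, match="huge"):
            make_resection_spec("huge", cam_setup["ir0"].contact_point,
                                cam_setup["femoral"], cam_setup["femur"])
        with pytest.raises(ValueError):
            ResectionSpec(model="slight", depth=8.0, width=8.0, length=15.0,
                          center=np.zeros(3), normal=[0, 0, 1],
                          width_dir=[1, 0, 0], length_dir=[0, 1, 0])

    def test_far_off_surface_center_rejected(self, cam_setup):
        with pytest.raises(ValueError, match="mm from the femoral"):
            make_resection_spec("slight", [0.0, 60.0, 0.0],
                                cam_setup["femoral"], cam_setup["femur"])


class TestApplyResection:
    def test_non_intersecting_solid_leaves_mesh_unchanged(self, cam_setup):
        femur = cam_setup["femur"]
        spec = ResectionSpec(model="slight", depth=4.0, width=8.0, length=15.0,
                             center=[0.0, 80.0, 0.0], normal=[0.0, 1.0, 0.0],
                             width_dir=[1.0, 0.0, 0.0], length_dir=[0.0, 0.0, 1.0])
        out = apply_resection(femur, spec)
        assert out.removed_volume == pytest.approx(0.0, abs=1e-6)
        assert np.array_equal(out.post_mesh.vertices, femur.vertices)

    @pytest.mark.parametrize("model", ["slight", "sufficient"])
    def test_removed_volume_bounded_by_half_ellipsoid(self, cam_setup, model):
        spec = make_resection_spec(model, cam_setup["ir0"].contact_point,
                                   cam_setup["femoral"], cam_setup["femur"])
        out = apply_resection(cam_setup["femur"], spec)
        assert 0.0 < out.removed_volume <= half_ellipsoid_volume(model)
        assert out.post_mesh.is_watertight

    @pytest.mark.parametrize("model", ["slight", "sufficient"])
    def test_surface_beyond_modified_region_is_bit_identical(self, cam_setup, model):
        femur = cam_setup["femur"]
        spec = make_resection_spec(model, cam_setup["ir0"].contact_point,
                                   cam_setup["femoral"], femur)
        out = apply_resection(femur, spec)
        far = (np.linalg.norm(np.asarray(femur.vertices) - spec.center, axis=1)
               > out.modified_region_radius)
        assert far.sum() > 0
        assert np.array_equal(np.asarray(out.post_mesh.vertices)[far],
                              np.asarray(femur.vertices)[far])
        assert np.array_equal(out.post_mesh.faces, femur.faces)

    def test_resection_never_reduces_rotation(self, cam_setup):
        """Removing material cannot create obstruction, and the deeper model
        gains at least as much as the shallow one."""
        gains = {}
        for model in ("slight", "sufficient"):
            spec = make_resection_spec(model, cam_setup["ir0"].contact_point,
                                       cam_setup["femoral"], cam_setup["femur"])
            out = apply_resection(cam_setup["femur"], spec)
            checker = ContactChecker(cam_setup["pelvis"], out.post_mesh,
                                     cam_setup["fit"].center, CFG)
            post = max_internal_rotation_at_flexion(
                None, None, cam_setup["pelvic"], cam_setup["femoral"], 90.0,
                CFG, checker=checker)
            gains[model] = post.limit_angle - cam_setup["ir0"].limit_angle
        assert gains["slight"] >= -CFG.angular_resolution
        assert gains["sufficient"] >= gains["slight"] - CFG.angular_resolution

    def test_zero_cam_femur_gains_little_from_slight_resection(self):
        """On a cam-free femur the trough at the impingement point frees
        less than 3 degrees of rotation (the no-cam analogue of the
        smallest group effect)."""
        femur, flm, _ = generate_femur(FemurParams())
        pelvis, plm, _ = generate_pelvis(PelvisParams(), target_ce=22.0)
        lm = LandmarkSet(**plm, **flm)
        fit = fit_sphere(lm.head_reference_points)
        femoral = build_femoral_frame(fit.center, lm.medial_epicondyle,
                                      lm.lateral_epicondyle)
        pelvic = build_pelvic_frame(lm, side="right")
        checker = ContactChecker(pelvis, femur, fit.center, CFG)
        ir0 = max_internal_rotation_at_flexion(None, None, pelvic, femoral,
                                               90.0, CFG, checker=checker)
        spec = make_resection_spec("slight", ir0.contact_point, femoral, femur)
        out = apply_resection(femur, spec)
        checker1 = ContactChecker(pelvis, out.post_mesh, fit.center, CFG)
        ir1 = max_internal_rotation_at_flexion(None, None, pelvic, femoral,
                                               90.0, CFG, checker=checker1)
        assert ir1.limit_angle - ir0.limit_angle < 3.0


class TestImprovement:
    @pytest.mark.parametrize("pre, post, expected", [
        (49.0, 65.0, 16.0),  # sufficient resection of the worked-case right hip
        (49.0, 53.0, 4.0),   # slight resection of the same hip
        (49.0, 52.0, 3.0),   # sufficient resection of the cam-free left hip
    ])
    def test_post_minus_pre(self, pre, post, expected):
        assert compute_improvement(pre, post) == expected

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            compute_improvement(np.nan, 10.0)


def test_jitter_center_stays_on_surface(cam_setup, rng):
    femur = cam_setup["femur"]
    c0 = np.asarray(cam_setup["ir0"].contact_point)
    moved = jitter_center(c0, femur, sigma=1.0, rng=rng)
    spec = make_resection_spec("slight", moved, cam_setup["femoral"], femur)
    assert np.linalg.norm(spec.center - moved) < 0.5
    assert np.linalg.norm(moved - c0) < 6.0  # a few sigma at most
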