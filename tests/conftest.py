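"""Shared fixtures.

Mesh generation and motion-limit searches are the expensive parts of the
suite, so the canonical objects — a default zero-cam femur, the thin-neck
geometry used for closed-form checks, a calibrated demonstration hip and
the full default-seed study — are built once per session.
"""

from __future__ import annotations

import numpy as np
import pytest

from hiprom.cohort import StudyConfig, run_case, run_study
from hiprom.frames import build_femoral_frame, build_pelvic_frame, fit_sphere
from hiprom.synthetic import (FemurParams, PelvisParams, default_cohort_spec,
                              generate_cohort, generate_femur,
                              generate_hip_case, generate_pelvis)


@pytest.fixture(scope="session")
def default_femur():
    """Zero-cam femur at default anatomy: (mesh, landmarks dict, params)."""
    return generate_femur(FemurParams())


@pytest.fixture(scope="session")
def thin_neck_femur():
    """Sphere-and-thin-cylinder geometry (head 24 mm, neck 12 mm) whose
    cam-free alpha has the closed form arcsin(12/24) = 30 deg."""
    return generate_femur(FemurParams(neck_radius=12.0))


@pytest.fixture(scope="session")
def demo_case():
    """One calibrated cam hip (alpha 67 deg, CE 21 deg) with its frames."""
    case = generate_hip_case("demo", None, 67.0, 21.0, seed=11)
    lm = case.landmarks
    fit = fit_sphere(lm.head_reference_points)
    femoral = build_femoral_frame(fit.center, lm.medial_epicondyle,
                                  lm.lateral_epicondyle)
    pelvic = build_pelvic_frame(lm, side="right")
    return case, fit, femoral, pelvic


@pytest.fixture(scope="session")
def default_study():
    """The full default-seed cohort study: (hips, results, StudyResult)."""
    spec = default_cohort_spec(master_seed=0)
    hips = generate_cohort(spec)
    config = StudyConfig()
    results = [run_case(h, config) for h in hips]
    from hiprom.cohort import StudyResult, summarize_groups
    import pandas as pd
    study = StudyResult(
        cases=pd.DataFrame([r.to_row() for r in results]),
        group_summaries=summarize_groups(results),
        stats_report={},
        case_results=results,
    )
    return hips, results, study


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
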