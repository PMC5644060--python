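"""End-to-end study orchestration over a synthetic cohort.

``run_case`` drives the whole per-hip pipeline — reference frames,
radiographic measurement, diagnostic classification, the below-90-deg
flexion exclusion check, pre-operative motion limits, both standardized
resections (each carved independently from the pre-operative femur), and
post-operative limits — and ``run_study`` aggregates the three
diagnostic groups and runs the statistical battery: per-outcome one-way
ANOVA with post-hoc pairwise tests, a Fisher exact comparison of the
impingement-region distribution between the two cam-bearing groups, and
(optionally) ICC repeatability of the improvement under jittered
resection centers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .frames import SphereFit, build_femoral_frame, build_pelvic_frame, fit_sphere
from .radiographic import (GroupLabel, STUDY_GROUPS, classify_hip,
                           estimate_neck_axis, measure_alpha, measure_ce)
from .resection import (apply_resection, compute_improvement, jitter_center,
                        make_resection_spec)
from .rom import (CollisionConfig, ContactChecker, check_exclusion,
                  classify_region, max_flexion,
                  max_internal_rotation_at_flexion)
from .stats import anova_oneway, fisher_exact_2x2, icc_repeatability, posthoc_pairwise
from .synthetic import CohortSpec, HipCase, default_cohort_spec, generate_cohort

__all__ = [
    "StudyConfig",
    "CaseResult",
    "StudyResult",
    "run_case",
    "summarize_groups",
    "run_icc_experiment",
    "run_study",
]

ANGLE_OUTCOMES = (
    "alpha", "ce", "preop_max_flexion", "preop_max_ir",
    "postop_max_ir_slight", "postop_max_ir_sufficient",
    "postop_max_flexion_slight", "postop_max_flexion_sufficient",
    "improvement_ir_slight", "improvement_ir_sufficient",
    "improvement_flexion_slight", "improvement_flexion_sufficient",
)


@dataclass(frozen=True)
class StudyConfig:
    collision: CollisionConfig = field(default_factory=CollisionConfig)
    resection_models: tuple[str, ...] = ("slight", "sufficient")
    posthoc_method: str = "tukey"
    icc_jitter_sigma: float = 1.0  # mm, investigator placement variability
    icc_repeats: int = 2
    side: str = "right"


@dataclass
class CaseResult:
    """All per-hip quantities of the study design (angles in degrees)."""

    case_id: str
    group: GroupLabel
    alpha: float = np.nan
    ce: float = np.nan
    preop_max_flexion: float = np.nan
    preop_max_ir: float = np.nan
    postop_max_ir_slight: float = np.nan
    postop_max_ir_sufficient: float = np.nan
    postop_max_flexion_slight: float = np.nan
    postop_max_flexion_sufficient: float = np.nan
    improvement_ir_slight: float = np.nan
    improvement_ir_sufficient: float = np.nan
    improvement_flexion_slight: float = np.nan
    improvement_flexion_sufficient: float = np.nan
    region: str = "none"
    contact_point: tuple | None = None
    flexion_capped: bool = False
    excluded: bool = False
    note: str = ""

    def to_row(self) -> dict:
        d = asdict(self)
        d["group"] = self.group.value
        if self.contact_point is not None:
            d["contact_x"], d["contact_y"], d["contact_z"] = self.contact_point
        d.pop("contact_point")
        return d


@dataclass
class StudyResult:
    cases: pd.DataFrame
    group_summaries: pd.DataFrame
    stats_report: dict
    case_results: list[CaseResult]


def run_case(hip: HipCase, config: StudyConfig | None = None) -> CaseResult:
    """Run the full simulation pipeline for one hip.

    Stage failures are recorded on the result (excluded, with a note)
    rather than raised, so a cohort run is never aborted by one case.
    """
    config = config or StudyConfig()
    lm = hip.landmarks
    result = CaseResult(case_id=hip.case_id, group=GroupLabel.excluded_other)
    try:
        head_fit = fit_sphere(lm.head_reference_points)
        pelvic = build_pelvic_frame(lm, side=config.side)
        femoral = build_femoral_frame(head_fit.center, lm.medial_epicondyle,
                                      lm.lateral_epicondyle)
        result.alpha = measure_alpha(hip.femur_mesh, femoral, head_fit)
        result.ce = measure_ce(hip.pelvis_mesh, head_fit.center, pelvic)
        result.group = classify_hip(result.alpha, result.ce)
        if result.group not in STUDY_GROUPS:
            result.excluded = True
            result.note = f"diagnostic exclusion: {result.group.value}"
            return result

        checker = ContactChecker(hip.pelvis_mesh, hip.femur_mesh,
                                 head_fit.center, config.collision)
        flex = max_flexion(hip.pelvis_mesh, hip.femur_mesh, pelvic, femoral,
                           config.collision, checker=checker)
        result.preop_max_flexion = flex.limit_angle
        result.flexion_capped = flex.reached_cap
        if check_exclusion(flex):
            result.excluded = True
            result.note = "impingement below 90 deg of flexion"
            return result

        ir = max_internal_rotation_at_flexion(
            hip.pelvis_mesh, hip.femur_mesh, pelvic, femoral, 90.0,
            config.collision, checker=checker)
        result.preop_max_ir = ir.limit_angle
        if ir.reached_cap:
            result.region = "none"
            result.note = "no impingement up to the rotation cap"
            return result

        neck_axis, neck_radius = estimate_neck_axis(hip.femur_mesh, head_fit)
        result.region = classify_region(ir.contact_point, head_fit,
                                        neck_axis, neck_radius)
        result.contact_point = tuple(np.round(ir.contact_point, 6))

        for model in config.resection_models:
            spec = make_resection_spec(model, ir.contact_point, femoral,
                                       hip.femur_mesh)
            outcome = apply_resection(hip.femur_mesh, spec)
            post_checker = ContactChecker(hip.pelvis_mesh, outcome.post_mesh,
                                          head_fit.center, config.collision)
            post_ir = max_internal_rotation_at_flexion(
                hip.pelvis_mesh, outcome.post_mesh, pelvic, femoral, 90.0,
                config.collision, checker=post_checker)
            post_flex = max_flexion(hip.pelvis_mesh, outcome.post_mesh, pelvic,
                                    femoral, config.collision, checker=post_checker)
            setattr(result, f"postop_max_ir_{model}", post_ir.limit_angle)
            setattr(result, f"postop_max_flexion_{model}", post_flex.limit_angle)
            setattr(result, f"improvement_ir_{model}",
                    compute_improvement(result.preop_max_ir, post_ir.limit_angle))
            setattr(result, f"improvement_flexion_{model}",
                    compute_improvement(result.preop_max_flexion,
                                        post_flex.limit_angle))
    except (ValueError, RuntimeError) as err:
        result.excluded = True
        result.group = GroupLabel.excluded_other
        result.note = f"pipeline failure: {err}"
    return result


def summarize_groups(results: list[CaseResult]) -> pd.DataFrame:
    """Mean and sample SD (n-1 denominator) of every angle outcome per
    diagnostic group, over included cases.  A single-case group reports
    the mean with an absent (NaN) SD; empty groups are omitted."""
    rows = []
    for group in STUDY_GROUPS:
        sub = [r for r in results if r.group == group and not r.excluded]
        if not sub:
            continue
        row: dict = {"group": group.value, "n": len(sub)}
        for name in ANGLE_OUTCOMES:
            vals = np.array([getattr(r, name) for r in sub], dtype=float)
            vals = vals[np.isfinite(vals)]
            row[f"{name}_mean"] = vals.mean() if len(vals) else np.nan
            row[f"{name}_sd"] = vals.std(ddof=1) if len(vals) > 1 else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def run_icc_experiment(hips: list[HipCase], results: list[CaseResult],
                       config: StudyConfig | None = None,
                       seed: int = 0) -> dict:
    """Repeatability of the simulated improvement.

    For every included case with an impingement point, the resection is
    re-placed with a tangentially jittered center (Gaussian, sigma =
    ``config.icc_jitter_sigma`` mm — the investigator's placement
    variability) and the post-operative internal-rotation limit is
    re-measured; ICC(1,1) is computed per resection model over the
    subjects x repeats improvement matrix.
    """
    config = config or StudyConfig()
    by_id = {h.case_id: h for h in hips}
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7001]))
    usable = [r for r in results
              if not r.excluded and r.contact_point is not None]
    out: dict = {}
    for model in config.resection_models:
        matrix = []
        for r in usable:
            hip = by_id[r.case_id]
            head_fit = fit_sphere(hip.landmarks.head_reference_points)
            pelvic = build_pelvic_frame(hip.landmarks, side=config.side)
            femoral = build_femoral_frame(head_fit.center,
                                          hip.landmarks.medial_epicondyle,
                                          hip.landmarks.lateral_epicondyle)
            repeats = []
            for _ in range(config.icc_repeats):
                center = jitter_center(np.asarray(r.contact_point),
                                       hip.femur_mesh,
                                       config.icc_jitter_sigma, rng)
                spec = make_resection_spec(model, center, femoral, hip.femur_mesh)
                outcome = apply_resection(hip.femur_mesh, spec)
                checker = ContactChecker(hip.pelvis_mesh, outcome.post_mesh,
                                         head_fit.center, config.collision)
                post = max_internal_rotation_at_flexion(
                    hip.pelvis_mesh, outcome.post_mesh, pelvic, femoral, 90.0,
                    config.collision, checker=checker)
                repeats.append(compute_improvement(r.preop_max_ir,
                                                   post.limit_angle))
            matrix.append(repeats)
        icc = icc_repeatability(np.asarray(matrix))
        out[model] = {"icc": icc.estimate, "ci_low": icc.ci_low,
                      "ci_high": icc.ci_high, "n_subjects": icc.n_subjects,
                      "n_repeats": icc.n_repeats}
    return out


def _region_counts(results: list[CaseResult], group: GroupLabel) -> tuple[int, int]:
    sub = [r for r in results if r.group == group and not r.excluded]
    return (sum(r.region == "proximal" for r in sub),
            sum(r.region == "distal" for r in sub))


def run_study(spec: CohortSpec | None = None,
              config: StudyConfig | None = None,
              include_icc: bool = False) -> StudyResult:
    """Generate the cohort of ``spec`` and reproduce the study design.

    Deterministic: the spec's master seed fixes every output.  The
    statistics report carries, per outcome, the one-way ANOVA and the
    post-hoc pairwise p-values across the three groups; the Fisher exact
    p for the proximal/distal impingement-region distribution between
    the two cam-bearing groups; and, when ``include_icc`` is set, the
    ICC repeatability block.
    """
    spec = spec or default_cohort_spec()
    config = config or StudyConfig()
    hips = generate_cohort(spec)
    results = [run_case(h, config) for h in hips]

    report: dict = {"n_cases": len(results),
                    "n_excluded": sum(r.excluded for r in results),
                    "anova": {}, "posthoc": {}}
    outcomes = ("preop_max_flexion", "preop_max_ir",
                "improvement_ir_slight", "improvement_ir_sufficient",
                "improvement_flexion_slight", "improvement_flexion_sufficient")
    labels = [g.value for g in STUDY_GROUPS]
    for outcome in outcomes:
        groups = []
        for g in STUDY_GROUPS:
            vals = np.array([getattr(r, outcome) for r in results
                             if r.group == g and not r.excluded], dtype=float)
            groups.append(vals[np.isfinite(vals)])
        if any(len(g) < 2 for g in groups):
            continue
        a = anova_oneway(groups)
        report["anova"][outcome] = {"F": a.f_statistic, "p": a.p_value}
        ph = posthoc_pairwise(groups, method=config.posthoc_method, labels=labels)
        report["posthoc"][outcome] = {f"{i} vs {j}": p for (i, j), p in ph.items()}

    cam_counts = _region_counts(results, GroupLabel.cam_FAI)
    ddh_counts = _region_counts(results, GroupLabel.DDH_with_cam)
    report["region_counts"] = {"cam_FAI": {"proximal": cam_counts[0],
                                           "distal": cam_counts[1]},
                               "DDH_with_cam": {"proximal": ddh_counts[0],
                                                "distal": ddh_counts[1]}}
    try:
        report["region_fisher_p"] = fisher_exact_2x2(*cam_counts, *ddh_counts)
    except ValueError as err:
        report["region_fisher_p"] = None
        report["region_fisher_note"] = str(err)

    if include_icc:
        report["icc"] = run_icc_experiment(hips, results, config,
                                           seed=spec.master_seed)

    cases_df = pd.DataFrame([r.to_row() for r in results])
    return StudyResult(cases=cases_df, group_summaries=summarize_groups(results),
                       stats_report=report, case_results=results)
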