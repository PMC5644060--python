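"""The study's statistical battery.

Group comparisons use classical one-way ANOVA with configurable post-hoc
pairwise tests (the default is Tukey's HSD); the impingement-region
distribution is compared with a two-sided Fisher exact test; and
repeatability of the simulated improvement is summarized with the
one-way random-effects intraclass correlation ICC(1,1) and its F-based
95% confidence interval.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats as sps

__all__ = [
    "AnovaResult",
    "ICCResult",
    "anova_oneway",
    "posthoc_pairwise",
    "fisher_exact_2x2",
    "icc_repeatability",
]


@dataclass(frozen=True)
class AnovaResult:
    f_statistic: float
    p_value: float
    df_between: int
    df_within: int
    degenerate: bool = False


@dataclass(frozen=True)
class ICCResult:
    estimate: float
    ci_low: float
    ci_high: float
    n_subjects: int
    n_repeats: int
    undefined: bool = False


def _as_groups(groups) -> list[np.ndarray]:
    out = [np.asarray(g, dtype=float).ravel() for g in groups]
    if any(not np.all(np.isfinite(g)) for g in out):
        raise ValueError("non-finite values in ANOVA input")
    return out


def anova_oneway(groups) -> AnovaResult:
    """Classical one-way (fixed-effects) analysis of variance.

    ``groups`` is an iterable of >= 2 samples, each with n >= 2.  The
    fully degenerate case (zero between- and within-group variance)
    returns F = 0, p = 1 with the ``degenerate`` flag set.
    """
    gs = _as_groups(groups)
    if len(gs) < 2 or any(len(g) < 2 for g in gs):
        raise ValueError("one-way ANOVA needs >= 2 groups with n >= 2 each")
    ns = np.array([len(g) for g in gs])
    means = np.array([g.mean() for g in gs])
    grand = np.concatenate(gs).mean()
    ss_between = float((ns * (means - grand) ** 2).sum())
    ss_within = float(sum(((g - m) ** 2).sum() for g, m in zip(gs, means)))
    df_b = len(gs) - 1
    df_w = int(ns.sum()) - len(gs)
    if ss_within == 0.0:
        if ss_between == 0.0:
            return AnovaResult(0.0, 1.0, df_b, df_w, degenerate=True)
        return AnovaResult(np.inf, 0.0, df_b, df_w, degenerate=True)
    f = (ss_between / df_b) / (ss_within / df_w)
    p = float(sps.f.sf(f, df_b, df_w))
    return AnovaResult(float(f), p, df_b, df_w)


def posthoc_pairwise(groups, method: str = "tukey",
                     labels=None) -> dict[tuple, float]:
    """Pairwise p-values following a one-way ANOVA.

    ``method`` is one of ``tukey`` (studentized-range HSD, default),
    ``bonferroni-t`` (pairwise t tests with Bonferroni correction) or
    ``unadjusted-t``.  Returns ``{(label_i, label_j): p}``.
    """
    gs = _as_groups(groups)
    if len(gs) < 2 or any(len(g) < 2 for g in gs):
        raise ValueError("post-hoc tests need >= 2 groups with n >= 2 each")
    labels = list(labels) if labels is not None else list(range(len(gs)))
    if len(labels) != len(gs):
        raise ValueError("labels length must match the number of groups")
    pairs = list(combinations(range(len(gs)), 2))
    out: dict[tuple, float] = {}
    if method == "tukey":
        if all(np.ptp(g) == 0 for g in gs) and len({g[0] for g in gs}) == 1:
            return {(labels[i], labels[j]): 1.0 for i, j in pairs}
        res = sps.tukey_hsd(*gs)
        for i, j in pairs:
            out[(labels[i], labels[j])] = float(res.pvalue[i, j])
    elif method in ("bonferroni-t", "unadjusted-t"):
        m = len(pairs)
        for i, j in pairs:
            p = float(sps.ttest_ind(gs[i], gs[j]).pvalue)
            if np.isnan(p):  # identical constant groups
                p = 1.0
            if method == "bonferroni-t":
                p = min(1.0, p * m)
            out[(labels[i], labels[j])] = p
    else:
        raise ValueError(f"unknown post-hoc method {method!r}")
    return out


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the table [[a, b], [c, d]].

    The two-sided p is the sum of hypergeometric probabilities of all
    tables (with the observed margins) no more likely than the observed
    one.
    """
    cells = (a, b, c, d)
    if any(int(x) != x or x < 0 for x in cells):
        raise ValueError("cell counts must be non-negative integers")
    a, b, c, d = (int(x) for x in cells)
    if min(a + b, c + d, a + c, b + d) == 0:
        raise ValueError("Fisher exact test needs positive margins")
    return float(sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def icc_repeatability(measurements, confidence: float = 0.95) -> ICCResult:
    """One-way random-effects intraclass correlation ICC(1,1).

    ``measurements`` is an (n_subjects, n_repeats) array of repeated
    measurements of the same quantity (here: the simulated improvement
    re-measured with jittered resection centers).  The estimate is

        ICC = (MSB - MSW) / (MSB + (k - 1) MSW)

    from the one-way ANOVA decomposition over subjects, with the
    standard F-based confidence interval.  Zero total variance leaves
    the ICC undefined (flagged, NaN estimate).
    """
    x = np.asarray(measurements, dtype=float)
    if x.ndim != 2 or x.shape[0] < 5 or x.shape[1] < 2:
        raise ValueError("need >= 5 subjects with >= 2 repeats each")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite measurement")
    n, k = x.shape
    subj_means = x.mean(axis=1)
    grand = x.mean()
    msb = k * ((subj_means - grand) ** 2).sum() / (n - 1)
    msw = ((x - subj_means[:, None]) ** 2).sum() / (n * (k - 1))
    if msb == 0.0 and msw == 0.0:
        return ICCResult(np.nan, np.nan, np.nan, n, k, undefined=True)
    if msw == 0.0:
        return ICCResult(1.0, 1.0, 1.0, n, k)
    icc = (msb - msw) / (msb + (k - 1) * msw)
    alpha = 1.0 - confidence
    f_obs = msb / msw
    df1, df2 = n - 1, n * (k - 1)
    f_low = f_obs / sps.f.ppf(1 - alpha / 2, df1, df2)
    f_high = f_obs * sps.f.ppf(1 - alpha / 2, df2, df1)
    ci_low = (f_low - 1) / (f_low + k - 1)
    ci_high = (f_high - 1) / (f_high + k - 1)
    return ICCResult(float(icc), float(ci_low), float(ci_high), n, k)
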