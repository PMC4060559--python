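"""Group-level statistics: CISS scoring, t-tests, and brain-behavior regression.

Subjects are stratified into three groups -- binocularly normal controls
(BNC), convergence-insufficiency patients before training (CI pre), and the
same patients after training (CI post).  BNC vs CI-pre comparisons use an
unpaired (pooled-variance) t-test; pre vs post comparisons are paired.  The
brain-behavior link is a linear regression of subject-mean convergence peak
velocity on ROI percent signal change (left/right hemispheres averaged),
pooling all subject-condition rows.

No multiple-comparison correction is applied by default (matching the small-
cohort design); two-sided p-values are reported throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

CISS_N_ITEMS = 15
CISS_ITEM_MAX = 4
CISS_SYMPTOMATIC_CUTOFF = 21

#: clinical measures and the direction of improvement after vergence training
CLINICAL_IMPROVEMENT = {
    "npc_cm": "decrease",  # near point of convergence recedes less
    "bo_range_pd": "increase",  # base-out fusional range grows
    "near_phoria_pd": "decrease",  # exophoria (exo positive) shrinks
    "ciss_total": "decrease",  # symptoms lessen
}


@dataclass(frozen=True)
class CissRecord:
    items: tuple[int, ...]
    total: int
    symptomatic: bool


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float
    mean_difference: float
    paired: bool
    n: int
    note: str = ""


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r: float
    p: float
    n: int

    def __post_init__(self) -> None:
        if abs(self.r) > 1 + 1e-12:
            raise ValueError("|r| must be <= 1")
        if self.n < 3:
            raise ValueError("regression needs n >= 3")


def score_ciss(items) -> CissRecord:
    """Sum the 15 symptom items (each 0-4); total >= 21 is symptomatic."""
    items = tuple(int(i) for i in items)
    if len(items) != CISS_N_ITEMS:
        raise ValueError(f"CISS has exactly {CISS_N_ITEMS} items, got {len(items)}")
    if any(not 0 <= i <= CISS_ITEM_MAX for i in items):
        raise ValueError("each CISS item must be an integer in 0..4")
    total = sum(items)
    return CissRecord(items, total, total >= CISS_SYMPTOMATIC_CUTOFF)


def unpaired_ttest(a, b, equal_var: bool = True) -> TTestResult:
    """Two-sample t-test (pooled-variance by default) with df = n_a + n_b - 2."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    t, p = float(res.statistic), float(res.pvalue)
    df = int(res.df) if equal_var else float(res.df)
    if np.isnan(t):  # both groups constant and equal
        t, p = 0.0, 1.0
    return TTestResult(t, df, p, float(a.mean() - b.mean()), False, a.size + b.size)


def paired_ttest(pre, post, ids_pre=None, ids_post=None) -> TTestResult:
    """One-sample t-test on post - pre differences, df = n - 1.

    If subject ids are supplied the pairing is checked; mismatched ids raise.
    Zero variance with zero mean difference is reported as "no difference"
    (t = 0, p = 1) rather than NaN.
    """
    pre = np.asarray(pre, float)
    post = np.asarray(post, float)
    if pre.size != post.size:
        raise ValueError("paired samples must have equal length")
    if pre.size < 2:
        raise ValueError("paired test needs n >= 2")
    if ids_pre is not None or ids_post is not None:
        if list(ids_pre) != list(ids_post):
            raise ValueError("pre/post subject ids do not pair up")
    diff = post - pre
    if np.allclose(diff.std(ddof=1), 0.0):
        if np.allclose(diff.mean(), 0.0):
            return TTestResult(
                0.0, pre.size - 1, 1.0, 0.0, True, pre.size, note="no difference"
            )
        # constant nonzero shift: t is formally infinite
        return TTestResult(
            float(np.inf) * np.sign(diff.mean()), pre.size - 1, 0.0,
            float(diff.mean()), True, pre.size, note="zero-variance shift",
        )
    res = stats.ttest_rel(post, pre)
    return TTestResult(
        float(res.statistic), pre.size - 1, float(res.pvalue),
        float(diff.mean()), True, pre.size,
    )


def _roi_pair_psc(cohort: pd.DataFrame, roi: str) -> pd.Series:
    """Averaged left/right PSC for a paired ROI; the single value for CV."""
    left, right = f"psc_{roi}_L", f"psc_{roi}_R"
    if left in cohort.columns and right in cohort.columns:
        return (cohort[left] + cohort[right]) / 2.0
    single = f"psc_{roi}"
    if single in cohort.columns:
        return cohort[single]
    raise KeyError(f"cohort table has no PSC columns for ROI {roi!r}")


def behavior_bold_regression(cohort: pd.DataFrame, roi: str) -> RegressionResult:
    """Linear regression of peak velocity on ROI percent signal change.

    x = left/right-averaged PSC for the ROI (CV has a single midline value),
    y = subject-mean convergence peak velocity; all subject-condition rows
    (BNC, CI pre, CI post) are pooled into one fit.
    """
    x = _roi_pair_psc(cohort, roi)
    y = cohort["peak_velocity"]
    keep = x.notna() & y.notna()
    if keep.sum() < len(cohort):
        logger.warning(
            "regression for %s drops %d rows with missing values",
            roi, int(len(cohort) - keep.sum()),
        )
    x, y = x[keep].to_numpy(), y[keep].to_numpy()
    if x.size < 3:
        raise ValueError("regression needs n >= 3 complete rows")
    fit = stats.linregress(x, y)
    return RegressionResult(
        float(fit.slope), float(fit.intercept), float(fit.rvalue),
        float(fit.pvalue), x.size,
    )


def _paired_frames(cohort: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    ci = cohort[cohort["group"] == "CI"]
    pre = ci[ci["condition"] == "pre"].set_index("subject_id").sort_index()
    post = ci[ci["condition"] == "post"].set_index("subject_id").sort_index()
    if not pre.index.equals(post.index):
        raise ValueError("CI pre/post rows are not paired by subject_id")
    return pre, post


def clinical_comparison(cohort: pd.DataFrame) -> dict[str, TTestResult]:
    """Paired pre/post t-tests for the clinical measures.

    Measures: NPC (cm), base-out fusional range (prism diopters), near
    dissociated phoria (prism diopters, exophoria positive), and CISS total.
    Pairs with a missing value are excluded from that measure's test with a
    logged warning.  Each result's note annotates whether the observed change
    is in the improving direction.
    """
    pre, post = _paired_frames(cohort)
    out: dict[str, TTestResult] = {}
    for measure, direction in CLINICAL_IMPROVEMENT.items():
        if measure not in cohort.columns:
            continue
        a, b = pre[measure], post[measure]
        keep = a.notna() & b.notna()
        if keep.sum() < len(a):
            logger.warning(
                "%s: dropping %d unpaired/missing subjects", measure,
                int(len(a) - keep.sum()),
            )
        res = paired_ttest(a[keep].to_numpy(), b[keep].to_numpy())
        improved = (res.mean_difference < 0) == (direction == "decrease")
        note = ("improved" if improved else "worsened") if res.mean_difference else res.note
        out[measure] = TTestResult(
            res.t, res.df, res.p, res.mean_difference, True, res.n, note
        )
    return out


def group_comparisons(cohort: pd.DataFrame, rois=("FEF", "PPC", "CV", "Broca")) -> dict:
    """The study's group-level comparison battery.

    Unpaired BNC vs CI-pre tests on peak velocity and per-ROI PSC; paired CI
    pre vs post tests on the same measures; paired clinical tests; and the
    pooled brain-behavior regressions per ROI.
    """
    bnc = cohort[cohort["group"] == "BNC"]
    pre_rows = cohort[(cohort["group"] == "CI") & (cohort["condition"] == "pre")]
    pre, post = _paired_frames(cohort)

    out: dict = {"unpaired_bnc_vs_ci_pre": {}, "paired_pre_vs_post": {}}
    out["unpaired_bnc_vs_ci_pre"]["peak_velocity"] = unpaired_ttest(
        bnc["peak_velocity"], pre_rows["peak_velocity"]
    )
    out["paired_pre_vs_post"]["peak_velocity"] = paired_ttest(
        pre["peak_velocity"], post["peak_velocity"]
    )
    for roi in rois:
        x_bnc = _roi_pair_psc(bnc, roi)
        x_pre = _roi_pair_psc(pre_rows, roi)
        out["unpaired_bnc_vs_ci_pre"][f"psc_{roi}"] = unpaired_ttest(x_bnc, x_pre)
        out["paired_pre_vs_post"][f"psc_{roi}"] = paired_ttest(
            _roi_pair_psc(pre.reset_index(), roi),
            _roi_pair_psc(post.reset_index(), roi),
        )
    out["clinical"] = clinical_comparison(cohort)
    out["regression"] = {roi: behavior_bold_regression(cohort, roi) for roi in rois}
    return out
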