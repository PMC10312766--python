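"""Volume-normalized counting and cell-type contribution estimators.

Per-ROI vesicle counts are normalized to the raw biofluid volume incubated
on the coverslip (EV/μL). Two complementary estimators turn paired cohorts
into a cell-type contribution fraction:

* **stain-based** — vesicles captured on the reference (anti-mouse CD81)
  coverslip that stain positively with the tracer antibody, divided by those
  staining with the pan-exosome panel. Positivity requires a full cluster
  (≥ M localizations ≈ 3 detected markers), so dim tracer carriers are
  missed: a lower bound in practice.
* **capture-based** — vesicles captured on the tracer-specific coverslip
  divided by those captured on the reference coverslip, both stained with
  the pan-exosome panel. A single surface tracer copy suffices for capture,
  so this estimator avoids the positivity floor.

Both are ratios of cohort means of EV/μL (not means of per-ROI ratios),
background-corrected by subtracting the same ratio measured in a
tracer-negative control cohort, with nonparametric bootstrap confidence
intervals over ROIs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .config import ConfigurationError

log = logging.getLogger(__name__)


class UndefinedFractionError(ZeroDivisionError):
    pass


@dataclass
class RoiCount:
    roi_id: str
    n_ev: int
    ev_per_ul: float


@dataclass
class CohortSummary:
    """Per-condition EV/μL statistics across ROIs."""

    condition: str
    n_roi: int
    mean: float
    median: float
    sem: float
    cv: float

    @classmethod
    def from_stats(
        cls, condition: str, mean: float, median: float, sem: float, cv: float, n_roi: int = 0
    ) -> "CohortSummary":
        """Build a summary from already-tabulated statistics."""
        return cls(condition, n_roi, mean, median, sem, cv)


@dataclass
class ContributionEstimate:
    f_stain: float | None = None
    f_capture: float | None = None
    f_background: float | None = None
    f_corrected: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    n_roi: int = 0


def count_rois(
    clusters_per_roi: dict[str, int], volume_raw_ul: float
) -> list[RoiCount]:
    """Normalize per-ROI cluster counts to the incubated raw volume."""
    if volume_raw_ul <= 0:
        raise ConfigurationError("volume_raw_ul: must be > 0")
    return [
        RoiCount(roi_id, n, n / volume_raw_ul)
        for roi_id, n in clusters_per_roi.items()
    ]


def summarize_cohort(counts: list[RoiCount], condition: str = "") -> CohortSummary:
    """Mean/median/SEM/CV of EV/μL over the ROIs of one condition.

    SEM uses the sample sd (n−1 denominator); CV = sample sd / mean. Both
    are NaN (with a warning) for a single ROI, and CV is NaN when the mean
    is zero.
    """
    if not counts:
        raise ValueError("empty cohort")
    v = np.array([c.ev_per_ul for c in counts], dtype=float)
    n = len(v)
    mean = float(v.mean())
    if n < 2:
        warnings.warn("SEM/CV undefined for a single ROI", stacklevel=2)
        return CohortSummary(condition, n, mean, mean, float("nan"), float("nan"))
    sd = float(v.std(ddof=1))
    cv = sd / mean if mean != 0 else float("nan")
    if mean == 0:
        warnings.warn("CV undefined for zero mean", stacklevel=2)
    return CohortSummary(condition, n, mean, float(np.median(v)), sd / np.sqrt(n), cv)


def implied_n_roi(summary: CohortSummary) -> float:
    """Replicate count implied by the identity n = (sd/SEM)² = (cv·mean/sem)²."""
    return (summary.cv * summary.mean / summary.sem) ** 2


def _mean_ratio(test: CohortSummary, denom: CohortSummary) -> float:
    if denom.mean == 0:
        raise UndefinedFractionError(f"denominator cohort {denom.condition!r} has zero mean")
    return test.mean / denom.mean


def contribution_stain(test: CohortSummary, denom: CohortSummary) -> float:
    """Stain-based fraction: tracer-stained / panel-stained on the reference
    capture coverslip."""
    return _mean_ratio(test, denom)


def contribution_capture(test: CohortSummary, denom: CohortSummary) -> float:
    """Capture-based fraction: tracer-captured / reference-captured, both
    panel-stained."""
    return _mean_ratio(test, denom)


def background_and_correct(
    f: float,
    test_num: list[RoiCount] | None = None,
    test_den: list[RoiCount] | None = None,
    ctrl_num: list[RoiCount] | None = None,
    ctrl_den: list[RoiCount] | None = None,
    n_boot: int = 2000,
    rng: np.random.Generator | int | None = None,
    kind: str = "capture",
) -> ContributionEstimate:
    """Background-correct a contribution fraction and attach bootstrap CIs.

    ``f`` is the raw test-cohort fraction. The background is the identical
    mean-ratio estimator evaluated on the control cohort; the corrected
    fraction is ``max(0, f − f_background)``. When per-ROI counts are given,
    a 95% percentile bootstrap (ROIs resampled with replacement, all four
    cohorts independently) is attached to the corrected fraction. Without a
    control cohort the estimate is returned uncorrected with a warning.
    """
    est = ContributionEstimate()
    if kind == "stain":
        est.f_stain = f
    else:
        est.f_capture = f
    if ctrl_num is not None and ctrl_den is not None:
        ctrl_num_v = np.array([c.ev_per_ul for c in ctrl_num])
        ctrl_den_v = np.array([c.ev_per_ul for c in ctrl_den])
        if ctrl_den_v.mean() == 0:
            raise UndefinedFractionError("control denominator cohort has zero mean")
        est.f_background = float(ctrl_num_v.mean() / ctrl_den_v.mean())
        est.f_corrected = max(0.0, f - est.f_background)
    else:
        warnings.warn("no control cohort: background left absent", stacklevel=2)
        est.f_corrected = f

    if test_num is not None and test_den is not None:
        rng = np.random.default_rng(rng)
        num_v = np.array([c.ev_per_ul for c in test_num])
        den_v = np.array([c.ev_per_ul for c in test_den])
        est.n_roi = len(num_v)
        reps = np.empty(n_boot)
        have_ctrl = est.f_background is not None
        for b in range(n_boot):
            nm = rng.choice(num_v, len(num_v)).mean()
            dn = rng.choice(den_v, len(den_v)).mean()
            if dn == 0:
                reps[b] = np.nan
                continue
            fb = 0.0
            if have_ctrl:
                cd = rng.choice(ctrl_den_v, len(ctrl_den_v)).mean()
                cn = rng.choice(ctrl_num_v, len(ctrl_num_v)).mean()
                fb = cn / cd if cd != 0 else np.nan
            reps[b] = max(0.0, nm / dn - fb)
        reps = reps[np.isfinite(reps)]
        if len(reps):
            est.ci_low = float(np.percentile(reps, 2.5))
            est.ci_high = float(np.percentile(reps, 97.5))
    return est


def compare_log(*groups: np.ndarray) -> float:
    """P-value for group differences after natural-log transformation.

    Diameters and per-vesicle marker counts are right-skewed; the comparison
    is done on logs (zeros excluded with a logged count): Welch's two-sample
    t-test for two groups, one-way ANOVA for more.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    logs = []
    for g in groups:
        g = np.asarray(g, dtype=float)
        n_zero = int((g <= 0).sum())
        if n_zero:
            log.info("compare_log: excluded %d non-positive values", n_zero)
            g = g[g > 0]
        if len(g) < 2:
            raise ValueError("each group needs at least 2 positive values")
        logs.append(np.log(g))
    if len(logs) == 2:
        res = stats.ttest_ind(logs[0], logs[1], equal_var=False)
    else:
        res = stats.f_oneway(*logs)
    p = float(res.pvalue)
    if np.isnan(p):  # zero variance in both groups (identical values)
        p = 1.0
    return p
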