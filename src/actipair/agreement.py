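"""Between-device agreement statistics.

The validation battery compares the phone against the reference device at
two granularities:

* **minute level** ("coinciding time periods"): pooled vertical-axis
  correlation/regression over all participants' jointly worn minutes, plus
  per-participant summaries (active-time %, mean MET intensity) compared by
  Lin's concordance correlation coefficient (CCC) and Bland-Altman analysis,
  and a within-class intensity comparison over minutes the reference device
  assigns to each class;
* **day level** ("coinciding valid days"): per-day class durations on days
  valid (>= 10 h wear) on both devices, without restricting to coinciding
  minutes — the sensitivity analysis for wearing-time discrepancies.

CCC is computed with n-denominator moments,

    ccc = 2 cov(x,y) / (var x + var y + (mean x - mean y)^2),

and can be read as the ratio of between-subject variance to total variance;
1 - CCC is the share of disagreement attributable to the method.  Confidence
intervals use Lin's Fisher-z asymptotic variance.  Bland-Altman reports the
mean difference, 1.96-SD limits of agreement and a proportional-bias
regression of differences on pair means; the bias is significant when the
slope's 95% CI excludes zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .alignment import adjusted_r2
from .energy import ACTIVITY_CLASSES, IntensityClass
from .exceptions import UndefinedStatisticError


def _clean_pairs(x, y, min_n):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < min_n:
        raise UndefinedStatisticError(f"need >= {min_n} complete pairs, got {len(x)}")
    return x, y


@dataclass
class CCCResult:
    ccc: float
    ci_low: float
    ci_high: float
    n: int


def ccc(x, y, alpha: float = 0.05) -> CCCResult:
    """Lin's concordance correlation coefficient with Fisher-z CI.

    Penalizes both correlation loss and location/scale shifts between the
    two measures; equals the Pearson correlation only when means and
    variances agree.

    Raises
    ------
    UndefinedStatisticError
        With fewer than 3 complete pairs, or when both sequences are
        constant (agreement undefined).
    """
    x, y = _clean_pairs(x, y, 3)
    n = len(x)
    mx, my = x.mean(), y.mean()
    sx2 = np.mean((x - mx) ** 2)  # n-denominator moments
    sy2 = np.mean((y - my) ** 2)
    sxy = np.mean((x - mx) * (y - my))
    denom = sx2 + sy2 + (mx - my) ** 2
    if denom == 0:
        raise UndefinedStatisticError("CCC undefined: both sequences constant and equal")
    rho_c = 2 * sxy / denom

    # Lin's asymptotic variance of atanh(ccc)
    if sx2 > 0 and sy2 > 0 and abs(rho_c) < 1:
        r = sxy / math.sqrt(sx2 * sy2)
        if r == 0:
            se_z = math.sqrt(1.0 / (n - 2))  # degenerate guard; CI still finite
        else:
            u = (mx - my) / (sx2 * sy2) ** 0.25
            num = (
                (1 - r * r) * rho_c * rho_c / (r * r)
                + 2 * rho_c**3 * (1 - rho_c) * u * u / r
                - rho_c**4 * u**4 / (2 * r * r)
            )
            se_z = math.sqrt(max(num, 0.0) / ((1 - rho_c * rho_c) ** 2 * (n - 2)))
        z = math.atanh(max(min(rho_c, 1 - 1e-15), -1 + 1e-15))
        zcrit = stats.norm.ppf(1 - alpha / 2)
        lo, hi = math.tanh(z - zcrit * se_z), math.tanh(z + zcrit * se_z)
    else:
        lo = hi = rho_c
    return CCCResult(ccc=float(rho_c), ci_low=float(lo), ci_high=float(hi), n=n)


@dataclass
class SpearmanResult:
    rho: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int


def spearman_with_ci(x, y, alpha: float = 0.05) -> SpearmanResult:
    """Spearman rank correlation (average ranks for ties) with Fisher-z CI.

    The CI uses ``atanh(rho)`` with variance ``1/(n-3)``.

    Raises
    ------
    UndefinedStatisticError
        With fewer than 4 pairs or a constant input.
    """
    x, y = _clean_pairs(x, y, 4)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedStatisticError("Spearman undefined for constant input")
    rho, p = stats.spearmanr(x, y)
    n = len(x)
    zcrit = stats.norm.ppf(1 - alpha / 2)
    se = 1.0 / math.sqrt(n - 3)
    z = math.atanh(max(min(float(rho), 1 - 1e-15), -1 + 1e-15))
    return SpearmanResult(
        rho=float(rho),
        ci_low=math.tanh(z - zcrit * se),
        ci_high=math.tanh(z + zcrit * se),
        p_value=float(p),
        n=n,
    )


@dataclass
class BlandAltmanResult:
    """Bland-Altman agreement summary for differences ``d = x - y``.

    ``table`` carries the plot-ready ``(mean, diff)`` pairs;
    ``bias_significant`` is True when the proportional-bias slope's CI
    excludes zero.
    """

    n: int
    mean_diff: float
    mean_diff_ci: tuple[float, float]
    sd_diff: float
    loa_low: float
    loa_high: float
    bias_slope: float
    bias_slope_ci: tuple[float, float]
    bias_intercept: float
    bias_p_value: float
    bias_significant: bool
    table: pd.DataFrame = field(repr=False, default=None)

    def annotations(self) -> dict:
        """Scalar values a plotting front end overlays on the scatter."""
        return {
            "mean_diff": self.mean_diff,
            "loa_low": self.loa_low,
            "loa_high": self.loa_high,
            "bias_slope": self.bias_slope,
            "bias_intercept": self.bias_intercept,
        }


def bland_altman(x, y, alpha: float = 0.05) -> BlandAltmanResult:
    """Bland-Altman analysis of ``x`` (test) against ``y`` (reference).

    Differences ``d = x - y`` are summarized by their mean (with a t-based
    CI), the ``mean ± 1.96 SD`` limits of agreement, and an OLS regression
    of ``d`` on the pair means ``(x + y)/2`` whose slope CI decides
    proportional bias.

    Raises
    ------
    UndefinedStatisticError
        With fewer than 3 complete pairs.
    """
    x, y = _clean_pairs(x, y, 3)
    d = x - y
    m = (x + y) / 2.0
    n = len(d)
    mean_d = float(d.mean())
    sd_d = float(d.std(ddof=1))
    tcrit = stats.t.ppf(1 - alpha / 2, n - 1)
    se_mean = sd_d / math.sqrt(n)
    zcrit = 1.96

    if np.ptp(m) == 0 or sd_d == 0:
        # degenerate: constant differences or constant means — no bias line
        slope, slope_ci, intercept, pval = 0.0, (0.0, 0.0), mean_d, 1.0
    else:
        res = sm.OLS(d, sm.add_constant(m)).fit()
        ci = res.conf_int(alpha)
        slope = float(res.params[1])
        intercept = float(res.params[0])
        slope_ci = (float(ci[1][0]), float(ci[1][1]))
        pval = float(res.pvalues[1])
    return BlandAltmanResult(
        n=n,
        mean_diff=mean_d,
        mean_diff_ci=(mean_d - tcrit * se_mean, mean_d + tcrit * se_mean),
        sd_diff=sd_d,
        loa_low=mean_d - zcrit * sd_d,
        loa_high=mean_d + zcrit * sd_d,
        bias_slope=slope,
        bias_slope_ci=slope_ci,
        bias_intercept=intercept,
        bias_p_value=pval,
        bias_significant=not (slope_ci[0] <= 0.0 <= slope_ci[1]),
        table=pd.DataFrame({"mean": m, "diff": d}),
    )


def _safe_ccc(x, y) -> CCCResult | None:
    """CCC, taking the limiting value 1 for identical constant sequences."""
    try:
        return ccc(x, y)
    except UndefinedStatisticError:
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        if len(x) and np.array_equal(x, y):
            return CCCResult(ccc=1.0, ci_low=1.0, ci_high=1.0, n=len(x))
        return None


@dataclass
class AgreementReport:
    """One comparison's agreement battery, JSON-serializable via :meth:`as_dict`."""

    measure: str
    comparison_level: str  # "minute" | "day"
    n: int
    spearman: SpearmanResult | None = None
    adjusted_r2: float | None = None
    ccc: CCCResult | None = None
    bland_altman: BlandAltmanResult | None = None
    empty: bool = False

    def as_dict(self) -> dict:
        out = {
            "measure": self.measure,
            "comparison_level": self.comparison_level,
            "n": self.n,
            "empty": self.empty,
            "adjusted_r2": self.adjusted_r2,
        }
        if self.spearman:
            out["spearman"] = asdict(self.spearman)
        if self.ccc:
            out["ccc"] = asdict(self.ccc)
        if self.bland_altman:
            ba = {k: v for k, v in asdict(self.bland_altman).items() if k != "table"}
            out["bland_altman"] = ba
        return out


@dataclass
class ParticipantMinutes:
    """One participant's paired minute-level data over jointly worn minutes."""

    participant_id: str
    phone_vt: np.ndarray
    ref_vt: np.ndarray
    phone_mets: np.ndarray
    ref_mets: np.ndarray

    @property
    def n(self) -> int:
        return len(self.phone_vt)


@dataclass
class ClassIntensityComparison:
    """Device MET means within each reference-assigned intensity class.

    One row per class the reference device identified: each device's mean and
    SD over those minutes and a two-sided Welch t-test p-value for the
    difference in mean intensity.
    """

    table: pd.DataFrame

    def as_dict(self) -> dict:
        return self.table.reset_index().to_dict(orient="records")


@dataclass
class MinuteComparison:
    vt: AgreementReport
    active_pct: AgreementReport
    mean_met: AgreementReport
    class_durations: dict[str, AgreementReport]
    class_intensity: ClassIntensityComparison
    excluded: list[tuple[str, str]]  # (participant_id, reason)


def _participant_summaries(participants, active_threshold, active_inclusive):
    rows = []
    for p in participants:
        phone_active = (
            p.phone_mets >= active_threshold
            if active_inclusive
            else p.phone_mets > active_threshold
        )
        ref_active = (
            p.ref_mets >= active_threshold
            if active_inclusive
            else p.ref_mets > active_threshold
        )
        row = {
            "participant_id": p.participant_id,
            "n": p.n,
            "phone_active_pct": 100.0 * phone_active.mean(),
            "ref_active_pct": 100.0 * ref_active.mean(),
            "phone_mean_met": float(p.phone_mets.mean()),
            "ref_mean_met": float(p.ref_mets.mean()),
        }
        bounds = np.array([1.5, 3.0, 6.0])
        for dev, mets in (("phone", p.phone_mets), ("ref", p.ref_mets)):
            idx = np.digitize(mets, bounds)
            for k, cls in enumerate(ACTIVITY_CLASSES):
                row[f"{dev}_{cls}_pct"] = 100.0 * float((idx == k).mean())
        rows.append(row)
    return pd.DataFrame(rows)


def compare_minutes(
    participants: list[ParticipantMinutes],
    active_threshold: float = 1.5,
    active_inclusive: bool = True,
) -> MinuteComparison:
    """Minute-level ("coinciding time periods") agreement battery.

    Vertical-axis measures are pooled across participants (the huge-n
    correlation/regression); active-time % , mean MET intensity and per-class
    duration % are summarized per participant, then compared with CCC and
    Bland-Altman.  The within-class intensity table uses the reference
    device's minute classification.  Participants with zero joint minutes
    are excluded and listed, not fatal.
    """
    kept, excluded = [], []
    for p in participants:
        if p.n == 0:
            excluded.append((p.participant_id, "no_joint_minutes"))
        else:
            kept.append(p)
    if not kept:
        empty = AgreementReport("vt", "minute", 0, empty=True)
        return MinuteComparison(
            vt=empty,
            active_pct=AgreementReport("active_pct", "minute", 0, empty=True),
            mean_met=AgreementReport("mean_met", "minute", 0, empty=True),
            class_durations={},
            class_intensity=ClassIntensityComparison(pd.DataFrame()),
            excluded=excluded,
        )

    phone_vt = np.concatenate([p.phone_vt for p in kept])
    ref_vt = np.concatenate([p.ref_vt for p in kept])
    vt_report = AgreementReport(
        measure="vt",
        comparison_level="minute",
        n=len(phone_vt),
        spearman=spearman_with_ci(phone_vt, ref_vt),
        adjusted_r2=adjusted_r2(phone_vt, ref_vt),
    )

    per = _participant_summaries(kept, active_threshold, active_inclusive)

    def paired_report(measure, xcol, ycol):
        x = per[xcol].to_numpy()
        y = per[ycol].to_numpy()
        if len(x) < 3:
            return AgreementReport(measure, "minute", len(x), empty=True)
        return AgreementReport(
            measure=measure,
            comparison_level="minute",
            n=len(per),
            ccc=_safe_ccc(x, y),
            bland_altman=bland_altman(x, y),
        )

    active_report = paired_report("active_pct", "phone_active_pct", "ref_active_pct")
    met_report = paired_report("mean_met", "phone_mean_met", "ref_mean_met")
    class_reports = {
        cls: paired_report(f"{cls}_pct", f"phone_{cls}_pct", f"ref_{cls}_pct")
        for cls in ("light", "moderate", "vigorous")
    }

    # within-class intensity: minutes pooled, classes per the reference device
    phone_mets = np.concatenate([p.phone_mets for p in kept])
    ref_mets = np.concatenate([p.ref_mets for p in kept])
    ref_class = np.digitize(ref_mets, np.array([1.5, 3.0, 6.0]))
    rows = []
    for k, cls in enumerate(ACTIVITY_CLASSES):
        if cls == IntensityClass.SEDENTARY.value:
            continue
        sel = ref_class == k
        n_cls = int(sel.sum())
        if n_cls == 0:
            rows.append({"ref_class": cls, "n": 0})
            continue
        pm, rm = phone_mets[sel], ref_mets[sel]
        if n_cls >= 2 and (np.ptp(pm) > 0 or np.ptp(rm) > 0):
            p_val = float(stats.ttest_ind(pm, rm, equal_var=False).pvalue)
        else:
            p_val = float("nan") if n_cls < 2 else 1.0
        rows.append(
            {
                "ref_class": cls,
                "n": n_cls,
                "phone_mean": float(pm.mean()),
                "phone_sd": float(pm.std(ddof=1)) if n_cls > 1 else 0.0,
                "ref_mean": float(rm.mean()),
                "ref_sd": float(rm.std(ddof=1)) if n_cls > 1 else 0.0,
                "p_value": p_val,
            }
        )
    cic = ClassIntensityComparison(pd.DataFrame(rows).set_index("ref_class"))
    return MinuteComparison(
        vt=vt_report,
        active_pct=active_report,
        mean_met=met_report,
        class_durations=class_reports,
        class_intensity=cic,
        excluded=excluded,
    )


@dataclass
class DayComparison:
    reports: dict[str, AgreementReport]
    n_days: int
    empty: bool


DAY_MEASURES = ("light_minutes", "moderate_minutes", "vigorous_minutes",
                "active_minutes", "mean_met")


def compare_days(phone_days: pd.DataFrame, ref_days: pd.DataFrame) -> DayComparison:
    """Day-level ("coinciding valid days") sensitivity battery.

    Inputs are per participant-day activity tables (index: participant, day;
    columns as :meth:`actipair.energy.ActivitySummary.as_row` plus boolean
    ``valid``).  Only days valid on *both* devices enter; each class
    duration (min/day) and the mean intensity are compared with CCC and
    Bland-Altman.  Zero coinciding valid days yields an empty-flagged report.
    """
    joined = phone_days.join(ref_days, how="inner", lsuffix="_phone", rsuffix="_ref")
    if "valid_phone" in joined.columns:
        joined = joined[joined["valid_phone"] & joined["valid_ref"]]
    if joined.empty:
        return DayComparison(reports={}, n_days=0, empty=True)

    reports = {}
    for measure in DAY_MEASURES:
        xcol, ycol = f"{measure}_phone", f"{measure}_ref"
        if xcol not in joined.columns:
            continue
        x = joined[xcol].to_numpy(dtype=float)
        y = joined[ycol].to_numpy(dtype=float)
        c = _safe_ccc(x, y)
        reports[measure] = AgreementReport(
            measure=measure,
            comparison_level="day",
            n=len(joined),
            ccc=c,
            bland_altman=bland_altman(x, y),
        )
    return DayComparison(reports=reports, n_days=len(joined), empty=False)
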