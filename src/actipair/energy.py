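"""Energy expenditure (MET) estimation and intensity classification.

Both devices' vertical-axis measures are mapped to metabolic equivalents
(METs) through Freedson-style linear equations so the two instruments can be
compared on a common physiological scale:

* reference accelerometer:  METs = 1.439008 + 0.000795 · VT counts/min
* phone (adapted):          METs = 1.2907087 + 0.4141791 · VT g/min

The phone coefficients arise from composing a fitted linear unit calibration
(counts/min as a function of g/min) with the reference equation;
:func:`fit_unit_calibration` re-derives such a calibration from any aligned
pair, so study-specific coefficients can replace the shipped ones.

Intensity classes partition the MET axis with lower-inclusive boundaries:
sedentary [0, 1.5), light [1.5, 3), moderate [3, 6), vigorous [6, inf).
"Active" time is any minute at or above 1.5 METs (a strict-inequality
variant is available for sensitivity analysis).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .alignment import AlignedPair
from .epochs import UNIT_COUNTS, UNIT_G
from .exceptions import DomainError, FitError
from .wear import WearMask


@dataclass(frozen=True)
class CalibrationModel:
    """A linear map ``intercept + slope * x`` with provenance tag.

    ``source`` is ``actigraph_freedson`` / ``calfit_adapted`` for the two
    shipped MET equations (then ``unit`` names the expected VT unit) or
    ``fitted`` for a unit calibration estimated from data (then the map is
    g/min → counts/min and stderr/r2 are populated).
    """

    intercept: float
    slope: float
    source: str
    unit: str | None = None
    stderr_intercept: float | None = None
    stderr_slope: float | None = None
    r2: float | None = None

    def __post_init__(self):
        if not np.isfinite(self.slope) or not np.isfinite(self.intercept):
            raise DomainError("calibration coefficients must be finite")

    def predict(self, x):
        return self.intercept + self.slope * np.asarray(x, dtype=float)


#: Reference-device Freedson MET equation (VT in counts/min).
ACTIGRAPH_FREEDSON = CalibrationModel(
    intercept=1.439008, slope=0.000795, source="actigraph_freedson", unit=UNIT_COUNTS
)
#: Phone-adapted Freedson MET equation (VT in g/min).
CALFIT_ADAPTED = CalibrationModel(
    intercept=1.2907087, slope=0.4141791, source="calfit_adapted", unit=UNIT_G
)

MET_MODELS = {"actigraph": ACTIGRAPH_FREEDSON, "calfit": CALFIT_ADAPTED}


def predict_mets(model: CalibrationModel, vt):
    """Evaluate a MET equation at vertical-axis intensity ``vt`` (scalar or array).

    Missing values propagate; negative intensities are outside the domain.
    """
    arr = np.asarray(vt, dtype=float)
    if np.any(arr[np.isfinite(arr)] < 0):
        raise DomainError("vertical-axis intensity must be >= 0")
    out = model.predict(arr)
    if np.isscalar(vt) or arr.ndim == 0:
        return float(out)
    if isinstance(vt, pd.Series):
        return pd.Series(out, index=vt.index)
    return out


def fit_unit_calibration(pair: AlignedPair) -> CalibrationModel:
    """OLS fit of reference counts/min on phone g/min over jointly valid minutes.

    Uses the pair's joint mask (both recorded, and both worn once the mask
    has been wear-restricted).  Returns a ``fitted`` CalibrationModel with
    coefficient standard errors and R².

    Raises
    ------
    FitError
        With fewer than 3 joint minutes or zero variance in the phone measure.
    """
    d = pair.data.loc[pair.joint_mask, ["phone_vt", "ref_vt"]].dropna()
    if len(d) < 3:
        raise FitError(f"unit calibration needs >= 3 joint minutes, got {len(d)}")
    g = d["phone_vt"].to_numpy()
    counts = d["ref_vt"].to_numpy()
    if np.ptp(g) == 0:
        raise FitError("unit calibration undefined: phone measure has zero variance")
    # accelerometer noise grows with signal level, so use
    # heteroscedasticity-robust coefficient standard errors
    res = sm.OLS(counts, sm.add_constant(g)).fit(cov_type="HC1")
    return CalibrationModel(
        intercept=float(res.params[0]),
        slope=float(res.params[1]),
        source="fitted",
        unit=UNIT_G,
        stderr_intercept=float(res.bse[0]),
        stderr_slope=float(res.bse[1]),
        r2=float(res.rsquared),
    )


class IntensityClass(str, Enum):
    SEDENTARY = "sedentary"
    LIGHT = "light"
    MODERATE = "moderate"
    VIGOROUS = "vigorous"


ACTIVITY_CLASSES = [c.value for c in IntensityClass]
#: Lower-inclusive MET boundaries of light / moderate / vigorous.
CLASS_BOUNDS = (1.5, 3.0, 6.0)


def classify_intensity(mets, bounds=CLASS_BOUNDS):
    """Map MET value(s) to intensity class(es).

    Boundaries are lower-inclusive: 1.5 → light, 3.0 → moderate,
    6.0 → vigorous.  Scalars return an :class:`IntensityClass`; arrays and
    Series return label arrays/Series.  NaN propagates as None/NaN.
    """
    arr = np.asarray(mets, dtype=float)
    if np.any(arr[np.isfinite(arr)] < 0):
        raise DomainError("MET values must be >= 0")
    idx = np.digitize(arr, bounds)  # 0..3
    labels = np.array(ACTIVITY_CLASSES, dtype=object)[idx]
    labels = np.where(np.isfinite(arr), labels, None)
    if np.isscalar(mets) or arr.ndim == 0:
        return IntensityClass(str(labels[()]))
    if isinstance(mets, pd.Series):
        return pd.Series(labels, index=mets.index, dtype=object)
    return labels


@dataclass
class ActivitySummary:
    """Class-by-class activity accounting over a stated minute set.

    ``minutes``/``pct`` map each intensity class to its duration in minutes
    and share of the set; ``active_minutes`` counts minutes at or above the
    active threshold (1.5 METs by default).  ``empty`` flags a zero-minute
    set; all other fields are then zero/NaN.
    """

    n_minutes: int
    minutes: dict = field(default_factory=dict)
    pct: dict = field(default_factory=dict)
    active_minutes: int = 0
    active_pct: float = float("nan")
    mean_met: float = float("nan")
    empty: bool = False

    def as_row(self) -> dict:
        row = {"n_minutes": self.n_minutes, "active_minutes": self.active_minutes,
               "active_pct": self.active_pct, "mean_met": self.mean_met}
        for c in ACTIVITY_CLASSES:
            row[f"{c}_minutes"] = self.minutes.get(c, 0)
            row[f"{c}_pct"] = self.pct.get(c, float("nan"))
        return row


def summarize_activity(
    mets: pd.Series,
    mask: WearMask | None = None,
    minute_set: pd.Series | pd.Index | None = None,
    active_threshold: float = 1.5,
    active_inclusive: bool = True,
    bounds=CLASS_BOUNDS,
) -> ActivitySummary:
    """Summarize a per-minute MET series over an explicit minute set.

    ``minute_set`` selects the minutes to account for (boolean Series on the
    MET index, or an index of timestamps); when omitted it defaults to the
    mask's worn minutes, or to all non-missing minutes if no mask is given.
    An empty set yields a flagged empty summary, not an error.
    """
    if minute_set is None:
        if mask is not None:
            sel = mask.worn.reindex(mets.index).fillna(False).astype(bool)
        else:
            sel = mets.notna()
    elif isinstance(minute_set, (pd.Index, pd.DatetimeIndex)):
        sel = pd.Series(False, index=mets.index)
        sel.loc[mets.index.intersection(minute_set)] = True
    else:
        sel = minute_set.reindex(mets.index).fillna(False).astype(bool)

    vals = mets[sel].dropna()
    n = len(vals)
    if n == 0:
        return ActivitySummary(
            n_minutes=0,
            minutes={c: 0 for c in ACTIVITY_CLASSES},
            pct={c: float("nan") for c in ACTIVITY_CLASSES},
            empty=True,
        )
    labels = classify_intensity(vals, bounds=bounds)
    counts = labels.value_counts()
    minutes = {c: int(counts.get(c, 0)) for c in ACTIVITY_CLASSES}
    pct = {c: 100.0 * m / n for c, m in minutes.items()}
    arr = vals.to_numpy()
    active = int((arr >= active_threshold).sum() if active_inclusive else (arr > active_threshold).sum())
    return ActivitySummary(
        n_minutes=n,
        minutes=minutes,
        pct=pct,
        active_minutes=active,
        active_pct=100.0 * active / n,
        mean_met=float(arr.mean()),
    )
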