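"""Nonwear detection, wear-time accounting and usability measures.

A waist-worn device that is taken off keeps recording near-zero signal, so
nonwear is inferred from sustained near-zero runs: at least ``min_run``
(default 40) consecutive *recorded* minutes at or below the device's
zero threshold — exactly 0 for counts/min series, below 0.3 g for g/min
series (a threshold calibrated on overnight phone recordings).  A single
supra-threshold minute breaks a run; minutes the device did not record
break runs too and are classified ``not_recorded``.

Usability here means the operational ease of obtaining a valid
physical-activity assessment: days recorded, recorded time, wear fraction
and valid-day counts per participant, compared across devices with the
Kruskal-Wallis rank-sum test.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .epochs import UNIT_COUNTS, UNIT_G, EpochSeries
from .exceptions import ConfigurationError

WORN = "worn"
NONWEAR = "nonwear"
NOT_RECORDED = "not_recorded"

#: Default near-zero thresholds by unit: counts are exactly zero; the phone's
#: g/min measure sits below 0.3 g when the device lies still.
DEFAULT_THRESHOLDS = {UNIT_COUNTS: 0.0, UNIT_G: 0.3}


@dataclass
class WearEpisode:
    start: pd.Timestamp
    length: int  # minutes
    state: str


@dataclass
class WearMask:
    """Per-minute wear classification plus the maximal-episode list.

    ``states`` is a string Series (``worn`` / ``nonwear`` / ``not_recorded``)
    on the same minute index as the source series; ``episodes`` lists every
    maximal same-state run.
    """

    states: pd.Series
    episodes: list[WearEpisode]

    @property
    def worn(self) -> pd.Series:
        return self.states == WORN

    def minutes(self, state: str) -> int:
        return int((self.states == state).sum())

    def nonwear_episodes(self) -> list[WearEpisode]:
        return [e for e in self.episodes if e.state == NONWEAR]


def _episodes_from_states(states: pd.Series) -> list[WearEpisode]:
    if states.empty:
        return []
    arr = states.to_numpy()
    change = np.flatnonzero(arr[1:] != arr[:-1]) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [len(arr)]])
    return [
        WearEpisode(start=states.index[s], length=int(e - s), state=str(arr[s]))
        for s, e in zip(starts, ends)
    ]


def detect_nonwear(
    series: EpochSeries,
    zero_threshold: float | None = None,
    min_run: int = 40,
) -> WearMask:
    """Classify every minute of ``series`` as worn / nonwear / not_recorded.

    A maximal run of at least ``min_run`` consecutive recorded minutes with
    near-zero intensity (``<= threshold`` for counts/min, ``< threshold``
    for g/min) is nonwear; every other recorded minute is worn.

    Raises
    ------
    ConfigurationError
        If the threshold is negative or is a fractional value applied to a
        counts/min series (a g-threshold on the wrong unit).
    """
    if zero_threshold is None:
        zero_threshold = DEFAULT_THRESHOLDS[series.unit]
    if zero_threshold < 0:
        raise ConfigurationError(f"zero_threshold must be >= 0, got {zero_threshold}")
    if series.unit == UNIT_COUNTS and 0 < zero_threshold < 1:
        raise ConfigurationError(
            f"threshold {zero_threshold} looks like a g-force value but the "
            f"series is in {UNIT_COUNTS}"
        )

    vals = series.values
    recorded = vals.notna().to_numpy()
    if series.unit == UNIT_G:
        below = (vals < zero_threshold).to_numpy() & recorded
    else:
        below = (vals <= zero_threshold).to_numpy() & recorded

    states = np.where(recorded, WORN, NOT_RECORDED).astype(object)
    # maximal runs of below-threshold recorded minutes
    padded = np.concatenate([[False], below, [False]])
    starts = np.flatnonzero(padded[1:].astype(int) - padded[:-1].astype(int) == 1)
    ends = np.flatnonzero(padded[1:].astype(int) - padded[:-1].astype(int) == -1)
    for s, e in zip(starts, ends):
        if e - s >= min_run:
            states[s:e] = NONWEAR

    state_series = pd.Series(states, index=vals.index, dtype=object)
    return WearMask(states=state_series, episodes=_episodes_from_states(state_series))


@dataclass
class UsabilitySummary:
    """Per participant-device usability bookkeeping.

    ``recorded_hours_per_recorded_day`` and the wear fraction are means over
    recorded days (days with >= 1 recorded minute); a valid day has at least
    ``valid_day_minutes`` wearing (or recorded, per configuration) minutes,
    and a valid assessment requires at least ``valid_days_required`` of them.
    """

    participant_id: str
    device_id: str
    days_recorded: int
    recorded_minutes: int
    worn_minutes: int
    recorded_hours_per_recorded_day: float
    worn_hours_per_recorded_day: float
    pct_worn_of_recorded: float
    n_valid_days: int
    valid_assessment: bool

    def as_dict(self) -> dict:
        return asdict(self)


#: Metrics compared across devices by :func:`compare_usability`.
USABILITY_METRICS = (
    "days_recorded",
    "recorded_minutes",
    "worn_minutes",
    "recorded_hours_per_recorded_day",
    "worn_hours_per_recorded_day",
    "pct_worn_of_recorded",
    "n_valid_days",
)


def usability_summary(
    series: EpochSeries,
    mask: WearMask,
    participant_id: str = "",
    valid_day_minutes: int = 600,
    valid_days_required: int = 3,
    valid_day_basis: str = "worn",
) -> UsabilitySummary:
    """Compute the usability measures for one participant-device series.

    Calendar days are midnight-to-midnight on the device's local clock.  The
    valid-day criterion counts wearing minutes by default
    (``valid_day_basis="worn"``); set ``"recorded"`` for the recorded-time
    variant of the >=10-hour rule.
    """
    if valid_day_basis not in ("worn", "recorded"):
        raise ConfigurationError(f"valid_day_basis must be worn|recorded, got {valid_day_basis!r}")
    if len(mask.states) == 0:
        return UsabilitySummary(participant_id, series.device_id, 0, 0, 0, 0.0, 0.0, 0.0, 0, False)

    day = mask.states.index.floor("D")
    rec = pd.Series((mask.states != NOT_RECORDED).to_numpy(), index=day)
    worn = pd.Series((mask.states == WORN).to_numpy(), index=day)
    rec_per_day = rec.groupby(level=0).sum()
    worn_per_day = worn.groupby(level=0).sum()

    recorded_days = rec_per_day[rec_per_day >= 1]
    n_days = len(recorded_days)
    recorded_minutes = int(rec_per_day.sum())
    worn_minutes = int(worn_per_day.sum())

    basis = worn_per_day if valid_day_basis == "worn" else rec_per_day
    n_valid = int((basis >= valid_day_minutes).sum())

    if n_days:
        rec_hours = float(recorded_days.mean() / 60.0)
        worn_hours = float(worn_per_day.reindex(recorded_days.index).mean() / 60.0)
    else:
        rec_hours = worn_hours = 0.0
    pct = 100.0 * worn_minutes / recorded_minutes if recorded_minutes else 0.0
    return UsabilitySummary(
        participant_id=participant_id,
        device_id=series.device_id,
        days_recorded=n_days,
        recorded_minutes=recorded_minutes,
        worn_minutes=worn_minutes,
        recorded_hours_per_recorded_day=rec_hours,
        worn_hours_per_recorded_day=worn_hours,
        pct_worn_of_recorded=pct,
        n_valid_days=n_valid,
        valid_assessment=n_valid >= valid_days_required,
    )


def compare_usability(*groups, labels=None, metrics=USABILITY_METRICS) -> pd.DataFrame:
    """Kruskal-Wallis comparison of usability metrics across device groups.

    Each positional argument is a list of :class:`UsabilitySummary` for one
    device.  Returns one row per metric with the tie-corrected H statistic,
    its chi-square p-value and each group's median and IQR.  When every value
    ties across all groups the test is degenerate and ``H=0, p=1`` is
    reported rather than raised.  Any number of groups >= 2 is accepted.
    """
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ConfigurationError("compare_usability needs >= 2 nonempty groups")
    if labels is None:
        labels = [g[0].device_id or f"group{i}" for i, g in enumerate(groups)]

    rows = []
    for metric in metrics:
        samples = [np.array([getattr(s, metric) for s in g], dtype=float) for g in groups]
        pooled = np.concatenate(samples)
        if np.ptp(pooled) == 0:
            # every value ties across all groups: H degenerates to 0
            h, p = 0.0, 1.0
        else:
            try:
                h, p = stats.kruskal(*samples)
            except ValueError:
                h, p = 0.0, 1.0
        row = {"metric": metric, "H": float(h), "p_value": float(p)}
        for lab, vals in zip(labels, samples):
            row[f"{lab}_median"] = float(np.median(vals))
            q1, q3 = np.percentile(vals, [25, 75])
            row[f"{lab}_iqr_low"] = float(q1)
            row[f"{lab}_iqr_high"] = float(q3)
        rows.append(row)
    return pd.DataFrame(rows).set_index("metric")
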