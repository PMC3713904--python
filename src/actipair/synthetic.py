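"""Synthetic paired-device cohorts with exact ground truth.

No public dataset pairs a waist-worn phone with a research accelerometer at
the minute level, so every pipeline stage is exercised on simulated cohorts
that emulate the validation-study design: ``n_participants`` wearing both
devices for ``protocol_days`` days, with device-specific units and noise, a
phone clock offset of up to ±5 minutes, nonwear episodes (shared overnight
ones, and phone-only charging episodes), and recording gaps or whole missing
days per device.

The generative model is minute-resolution:

1. each day starts with a sleep episode (both devices off-body), followed by
   a waking period of sedentary baseline interrupted by piecewise-constant
   activity bouts of light/moderate/vigorous intensity with within-bout MET
   jitter clipped to the bout's class interval — so per-class daily minutes
   are exact ground truth, not a target;
2. the true MET trajectory is inverted through each device's Freedson-style
   equation to that device's vertical-axis unit (counts/min and g/min,
   floored at zero), then multiplicative and additive gaussian device noise
   is applied;
3. nonwear minutes read exactly 0 counts on the reference device and a small
   sub-0.3 g residue on the phone; gaps and missing days are missing-coded;
   the phone's clock is shifted by the participant's true offset.

Sedentary waking minutes come in two kinds: "quiet movement" minutes with a
MET level just above both equations' intercepts (a waist sensor sees
incidental trunk motion, so counts stay nonzero and sedentary wear time is
not mistaken for nonwear), and completely "still" minutes that read zero on
both instruments.  Still minutes sit below both intercepts, where the linear
equations floor at their intercepts — a real limitation of count-based MET
prediction at rest; :meth:`CohortConfig.noiseless` removes them (with all
noise, offsets and gaps) because the identity it supports is exact
invertibility of the linear maps.

All randomness flows from one seed via spawned per-participant generators,
so cohorts are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace, asdict

import numpy as np
import pandas as pd

from .energy import ACTIGRAPH_FREEDSON, CALFIT_ADAPTED
from .epochs import UNIT_COUNTS, UNIT_G, EpochSeries, RawStream
from .exceptions import ConfigurationError

MINUTES_PER_DAY = 1440

SLEEP = "sleep_nonwear"
EXTRA_NONWEAR = "extra_nonwear"
PHONE_NONWEAR = "phone_nonwear"


@dataclass(frozen=True)
class CohortConfig:
    """Study-design parameters for one simulated cohort.

    Defaults mirror the validation study's deployment: 36 participants for 5
    protocol days, phone clock offsets within ±5 minutes, roughly 7.5 h of
    overnight off-body time plus occasional daytime nonwear (device wear
    around 55-60% of recorded time), about 10% of phone days and 4% of
    reference days lost to power/battery problems, and mean daily activity of
    150/45/15 light/moderate/vigorous minutes.
    """

    n_participants: int = 36
    protocol_days: int = 5
    seed: int = 0
    start: str = "2013-03-04"

    # clock
    clock_offset_range: tuple[int, int] = (-5, 5)

    # daily structure (minutes)
    sleep_minutes_mean: float = 450.0
    sleep_minutes_sd: float = 30.0
    extra_nonwear_per_day: float = 2.0  # mean count of shared daytime episodes
    extra_nonwear_minutes: tuple[int, int] = (40, 100)
    phone_nonwear_prob: float = 0.8  # charging episode per day
    phone_nonwear_minutes: tuple[int, int] = (45, 90)

    # recording losses
    phone_missing_day_prob: float = 0.10
    ref_missing_day_prob: float = 0.04
    phone_gap_prob: float = 0.25
    phone_gap_minutes: tuple[int, int] = (60, 240)

    # activity schedule (mean daily minutes per class, mean bout length)
    light_minutes: float = 150.0
    moderate_minutes: float = 45.0
    vigorous_minutes: float = 15.0
    bout_length: dict = field(
        default_factory=lambda: {"light": 20, "moderate": 15, "vigorous": 10}
    )
    # MET levels: (level_low, level_high) bout levels, jitter sd, class clip
    met_levels: dict = field(
        default_factory=lambda: {
            "light": (1.7, 2.8, 0.15, (1.5, 2.999)),
            "moderate": (3.2, 5.5, 0.2, (3.0, 5.999)),
            "vigorous": (6.2, 8.5, 0.2, (6.0, 9.0)),
        }
    )
    sedentary_met_range: tuple[float, float] = (1.44, 1.495)
    sedentary_still_prob: float = 0.25
    still_met_range: tuple[float, float] = (1.0, 1.3)
    sleep_met: float = 0.95

    # device noise
    phone_mult_noise: float = 0.05
    phone_add_noise: float = 0.01  # g
    phone_nonwear_g_sd: float = 0.05  # residue while off-body, clipped < 0.3
    ref_mult_noise: float = 0.03
    ref_add_noise: float = 10.0  # counts, applied to nonzero signal only

    def __post_init__(self):
        if self.n_participants < 1 or self.protocol_days < 1:
            raise ConfigurationError("need >= 1 participant and >= 1 protocol day")
        lo, hi = self.clock_offset_range
        if lo > hi:
            raise ConfigurationError("clock_offset_range must be (low, high)")
        for name in (
            "extra_nonwear_per_day", "phone_nonwear_prob", "phone_missing_day_prob",
            "ref_missing_day_prob", "phone_gap_prob", "light_minutes",
            "moderate_minutes", "vigorous_minutes", "phone_mult_noise",
            "phone_add_noise", "ref_mult_noise", "ref_add_noise",
        ):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        budget = self.light_minutes + self.moderate_minutes + self.vigorous_minutes
        wake = MINUTES_PER_DAY - (self.sleep_minutes_mean + 3 * self.sleep_minutes_sd)
        if budget > wake:
            raise ConfigurationError(
                f"activity schedule infeasible: {budget:.0f} bout minutes exceed "
                f"{wake:.0f} available waking minutes"
            )

    @classmethod
    def noiseless(cls, **overrides) -> "CohortConfig":
        """Degenerate identity configuration: no noise, no offset, no losses.

        Still minutes are removed too, so every worn minute's MET sits above
        both equation intercepts and the vt→MET maps invert exactly.
        """
        base = dict(
            clock_offset_range=(0, 0),
            phone_missing_day_prob=0.0,
            ref_missing_day_prob=0.0,
            phone_gap_prob=0.0,
            sedentary_still_prob=0.0,
            phone_mult_noise=0.0,
            phone_add_noise=0.0,
            phone_nonwear_g_sd=0.0,
            ref_mult_noise=0.0,
            ref_add_noise=0.0,
        )
        base.update(overrides)
        return cls(**base)

    def with_(self, **overrides) -> "CohortConfig":
        return replace(self, **overrides)


@dataclass
class ParticipantTruth:
    """Exact per-minute bookkeeping for one simulated participant.

    ``frame`` is indexed by true-clock minutes with columns:
    ``met`` (true MET), ``klass`` (sedentary/light/moderate/vigorous or a
    nonwear label), ``phone_worn``, ``ref_worn``, ``phone_recorded``,
    ``ref_recorded``, ``phone_g`` and ``ref_counts`` (noise-free signals).
    """

    participant_id: str
    offset: int
    frame: pd.DataFrame

    @property
    def joint_worn(self) -> pd.Series:
        f = self.frame
        return f.phone_worn & f.ref_worn & f.phone_recorded & f.ref_recorded

    def class_minutes_per_day(self, joint: bool = True) -> pd.DataFrame:
        """True activity-class minutes per calendar day (joint-worn minutes by default)."""
        f = self.frame
        sel = self.joint_worn if joint else pd.Series(True, index=f.index)
        sub = f.loc[sel & f.klass.isin(["sedentary", "light", "moderate", "vigorous"])]
        tab = (
            sub.groupby([sub.index.floor("D"), "klass"], observed=False)
            .size()
            .unstack(fill_value=0)
        )
        for c in ("sedentary", "light", "moderate", "vigorous"):
            if c not in tab.columns:
                tab[c] = 0
        return tab[["sedentary", "light", "moderate", "vigorous"]]

    def wear_pct(self, device: str) -> float:
        f = self.frame
        rec = f[f"{device}_recorded"]
        worn = f[f"{device}_worn"] & rec
        return 100.0 * worn.sum() / rec.sum() if rec.sum() else float("nan")

    def nonwear_episodes(self, device: str) -> list[tuple[pd.Timestamp, int]]:
        f = self.frame
        off = (~f[f"{device}_worn"]).to_numpy()
        out = []
        i = 0
        while i < len(off):
            if off[i]:
                j = i
                while j < len(off) and off[j]:
                    j += 1
                out.append((f.index[i], j - i))
                i = j
            else:
                i += 1
        return out


@dataclass
class SimulatedCohort:
    config: CohortConfig
    truth: dict[str, ParticipantTruth]
    pairs: dict[str, tuple[EpochSeries, EpochSeries]]  # (phone, ref)

    @property
    def participant_ids(self) -> list[str]:
        return list(self.truth)


def _place_bouts(rng, free: np.ndarray, total: int, mean_len: int):
    """Mark ``total`` minutes of bouts in the boolean free mask; returns bout slices."""
    bouts = []
    remaining = total
    while remaining > 0:
        if remaining < 5:
            length = remaining
        else:
            length = int(np.clip(round(rng.normal(mean_len, mean_len / 3)), 5, remaining))
        # maximal free runs
        padded = np.concatenate([[False], free, [False]])
        d = padded[1:].astype(int) - padded[:-1].astype(int)
        starts = np.flatnonzero(d == 1)
        ends = np.flatnonzero(d == -1)
        fits = [(s, e) for s, e in zip(starts, ends) if e - s >= length]
        if not fits:
            runs = [(s, e) for s, e in zip(starts, ends)]
            if not runs:
                break
            s, e = runs[int(rng.integers(len(runs)))]
            length = e - s
        else:
            weights = np.array([e - s - length + 1 for s, e in fits], dtype=float)
            k = int(rng.choice(len(fits), p=weights / weights.sum()))
            s, e = fits[k]
            s = int(s + rng.integers(e - s - length + 1))
        free[s : s + length] = False
        bouts.append((s, s + length))
        remaining -= length
    return bouts


def _simulate_participant(pid: str, cfg: CohortConfig, rng: np.random.Generator):
    n_min = cfg.protocol_days * MINUTES_PER_DAY
    index = pd.date_range(cfg.start, periods=n_min, freq="min")
    met = np.empty(n_min)
    klass = np.empty(n_min, dtype=object)
    phone_worn = np.ones(n_min, dtype=bool)
    ref_worn = np.ones(n_min, dtype=bool)
    phone_rec = np.ones(n_min, dtype=bool)
    ref_rec = np.ones(n_min, dtype=bool)

    lo, hi = cfg.clock_offset_range
    offset = int(rng.integers(lo, hi + 1))

    for day in range(cfg.protocol_days):
        d0 = day * MINUTES_PER_DAY
        sl = int(np.clip(round(rng.normal(cfg.sleep_minutes_mean, cfg.sleep_minutes_sd)), 300, 600))
        day_klass = np.full(MINUTES_PER_DAY, "sedentary", dtype=object)
        day_klass[:sl] = SLEEP

        # shared daytime nonwear episodes (shower, sports locker...)
        n_extra = rng.poisson(cfg.extra_nonwear_per_day)
        free = day_klass == "sedentary"
        for _ in range(n_extra):
            length = int(rng.integers(*cfg.extra_nonwear_minutes))
            starts = np.flatnonzero(free[: MINUTES_PER_DAY - length])
            if len(starts) == 0:
                break
            s = int(rng.choice(starts))
            day_klass[s : s + length] = EXTRA_NONWEAR
            free[s : s + length] = False

        # phone-only nonwear (charging); person may still be active
        phone_off = np.zeros(MINUTES_PER_DAY, dtype=bool)
        if rng.random() < cfg.phone_nonwear_prob:
            length = int(rng.integers(*cfg.phone_nonwear_minutes))
            starts = np.flatnonzero(free[: MINUTES_PER_DAY - length])
            if len(starts):
                s = int(rng.choice(starts))
                phone_off[s : s + length] = True

        # activity bouts over waking, on-body-person minutes
        bout_free = (day_klass == "sedentary").copy()
        for cls in ("vigorous", "moderate", "light"):
            target = float(getattr(cfg, f"{cls}_minutes"))
            total = int(max(0, round(rng.normal(target, 0.15 * target))))
            lvl_lo, lvl_hi, jit, clip = cfg.met_levels[cls]
            for s, e in _place_bouts(rng, bout_free, total, cfg.bout_length[cls]):
                level = rng.uniform(lvl_lo, lvl_hi)
                vals = np.clip(level + rng.normal(0, jit, e - s), clip[0], clip[1])
                met[d0 + s : d0 + e] = vals
                day_klass[s:e] = cls

        # sedentary / still / sleep METs
        sed = day_klass == "sedentary"
        still = sed & (rng.random(MINUTES_PER_DAY) < cfg.sedentary_still_prob)
        quiet = sed & ~still
        met[d0 : d0 + MINUTES_PER_DAY][quiet] = rng.uniform(
            *cfg.sedentary_met_range, int(quiet.sum())
        )
        met[d0 : d0 + MINUTES_PER_DAY][still] = rng.uniform(
            *cfg.still_met_range, int(still.sum())
        )
        nonwear_min = (day_klass == SLEEP) | (day_klass == EXTRA_NONWEAR)
        met[d0 : d0 + MINUTES_PER_DAY][nonwear_min] = cfg.sleep_met

        klass[d0 : d0 + MINUTES_PER_DAY] = day_klass
        phone_worn[d0 : d0 + MINUTES_PER_DAY] = ~(nonwear_min | phone_off)
        ref_worn[d0 : d0 + MINUTES_PER_DAY] = ~nonwear_min

        # recording losses
        if rng.random() < cfg.phone_missing_day_prob:
            phone_rec[d0 : d0 + MINUTES_PER_DAY] = False
        elif rng.random() < cfg.phone_gap_prob:
            length = int(rng.integers(*cfg.phone_gap_minutes))
            s = int(rng.integers(0, MINUTES_PER_DAY - length))
            phone_rec[d0 + s : d0 + s + length] = False
        if rng.random() < cfg.ref_missing_day_prob:
            ref_rec[d0 : d0 + MINUTES_PER_DAY] = False

    # noise-free device signals from the true METs
    g_true = np.maximum(0.0, (met - CALFIT_ADAPTED.intercept) / CALFIT_ADAPTED.slope)
    c_true = np.maximum(0.0, (met - ACTIGRAPH_FREEDSON.intercept) / ACTIGRAPH_FREEDSON.slope)
    g_true = np.where(phone_worn, g_true, 0.0)
    c_true = np.where(ref_worn, c_true, 0.0)

    frame = pd.DataFrame(
        {
            "met": met,
            "klass": klass,
            "phone_worn": phone_worn,
            "ref_worn": ref_worn,
            "phone_recorded": phone_rec,
            "ref_recorded": ref_rec,
            "phone_g": g_true,
            "ref_counts": c_true,
        },
        index=index,
    )
    truth = ParticipantTruth(participant_id=pid, offset=offset, frame=frame)

    # observed phone g/min
    g_obs = g_true.copy()
    worn_pos = phone_worn & phone_rec
    eps_m = rng.normal(0.0, cfg.phone_mult_noise, n_min)
    eps_a = rng.normal(0.0, cfg.phone_add_noise, n_min)
    g_obs = np.where(worn_pos, np.maximum(0.0, g_true * (1 + eps_m) + eps_a), g_obs)
    off_body = ~phone_worn & phone_rec
    if cfg.phone_nonwear_g_sd > 0:
        residue = np.minimum(np.abs(rng.normal(0.0, cfg.phone_nonwear_g_sd, n_min)), 0.29)
    else:
        residue = np.zeros(n_min)
    g_obs = np.where(off_body, residue, g_obs)
    g_obs = np.where(phone_rec, g_obs, np.nan)

    # observed reference counts/min (exact zeros stay exact zeros)
    c_obs = c_true.copy()
    eps_m = rng.normal(0.0, cfg.ref_mult_noise, n_min)
    eps_a = rng.normal(0.0, cfg.ref_add_noise, n_min)
    pos = (c_true > 0) & ref_worn & ref_rec
    c_obs = np.where(pos, np.maximum(0.0, c_true * (1 + eps_m) + eps_a), c_obs)
    c_obs = np.where(~ref_worn & ref_rec, 0.0, c_obs)
    c_obs = np.where(ref_rec, c_obs, np.nan)

    phone = EpochSeries(
        device_id=f"{pid}-phone",
        unit=UNIT_G,
        values=pd.Series(g_obs, index=index + pd.Timedelta(minutes=offset)),
    )
    ref = EpochSeries(
        device_id=f"{pid}-ref",
        unit=UNIT_COUNTS,
        values=pd.Series(c_obs, index=index),
    )
    return truth, (phone, ref)


def simulate_cohort(config: CohortConfig) -> SimulatedCohort:
    """Simulate a full cohort; reproducible bit-for-bit under a fixed seed."""
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_participants)
    truth: dict[str, ParticipantTruth] = {}
    pairs: dict[str, tuple[EpochSeries, EpochSeries]] = {}
    for i, child in enumerate(children):
        pid = f"P{i + 1:02d}"
        rng = np.random.default_rng(child)
        t, pair = _simulate_participant(pid, config, rng)
        truth[pid] = t
        pairs[pid] = pair
    return SimulatedCohort(config=config, truth=truth, pairs=pairs)


def simulate_raw(
    cohort: SimulatedCohort,
    participant: str,
    sample_rate: float = 10.0,
    minutes: int | None = None,
    gravity: float = 1.0,
    freq_hz: float = 1.0,
) -> RawStream:
    """Emit a raw tri-axial stream whose epoching reproduces a phone trajectory.

    Each recorded minute carries a vertical sinusoid at ``freq_hz`` whose
    amplitude is chosen so the per-minute mean absolute deviation from the
    median equals that minute's observed g/min value; missing minutes emit no
    samples.  ``minutes`` truncates the stream (useful for tests).

    Raises
    ------
    ConfigurationError
        If ``sample_rate`` is not positive.
    KeyError
        If the participant is unknown.
    """
    if sample_rate <= 0:
        raise ConfigurationError(f"sample_rate must be > 0, got {sample_rate}")
    phone, _ = cohort.pairs[participant]
    series = phone.values if minutes is None else phone.values.iloc[:minutes]

    n = int(round(60 * sample_rate))
    t_rel = np.arange(n) / sample_rate
    pattern = np.sin(2 * np.pi * freq_hz * t_rel)
    med = np.median(pattern)
    mad = np.abs(pattern - med).mean()

    chunks = []
    for ts, g in series.items():
        if not np.isfinite(g):
            continue
        amp = g / mad if mad > 0 else 0.0
        ay = gravity + amp * pattern
        idx = ts + pd.to_timedelta(t_rel, unit="s")
        chunks.append(pd.DataFrame({"ax": 0.0, "ay": ay, "az": 0.05}, index=idx))
    if not chunks:
        raise ConfigurationError(f"participant {participant} has no recorded minutes")
    samples = pd.concat(chunks)
    return RawStream(
        device_id=f"{participant}-phone-raw",
        sample_rate=sample_rate,
        samples=samples,
    )


def config_fingerprint(config: CohortConfig) -> str:
    """Stable short hash of the config, stamped into emitted files."""
    import hashlib
    import json

    blob = json.dumps(asdict(config), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
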