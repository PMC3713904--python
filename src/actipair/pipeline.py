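"""End-to-end study orchestration: manifest in, report bundle out.

``run_study`` drives epoch reading → clock alignment → wear detection →
MET estimation → the agreement battery for every participant in a
:class:`StudyManifest`, isolating per-participant failures with
machine-readable exclusion codes (the usability findings of a deployment are
largely exclusion accounting, so the log is a first-class output).

Outputs written by :func:`write_bundle`:

* ``usability.csv`` — per participant-device usability rows plus the
  Kruskal-Wallis comparison table (``usability_tests.csv``);
* ``agreement_minute.json`` — pooled VT correlation/regression and the
  per-participant duration/intensity CCC + Bland-Altman reports;
* ``agreement_day.json`` — coinciding-valid-days sensitivity reports;
* ``class_intensity.csv`` — device MET means within reference-assigned
  intensity classes;
* ``bland_altman_<measure>.csv`` — plot-ready (mean, diff) tables;
* ``run.log`` — every exclusion with its reason code.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import agreement, energy, wear
from .alignment import align
from .epochs import UNIT_COUNTS, UNIT_G, EpochSeries, read_epoch_csv
from .exceptions import ActipairError, AlignmentError, ConfigurationError

EXCL_READ_ERROR = "read_error"
EXCL_EMPTY = "empty_series"
EXCL_ALIGNMENT = "alignment_failed"
EXCL_NO_JOINT = "no_joint_minutes"


@dataclass
class StudyOptions:
    """Every tunable threshold of the analysis, defaulting to the protocol values."""

    active_threshold: float = 1.5
    moderate_threshold: float = 3.0
    vigorous_threshold: float = 6.0
    g_nonwear_threshold: float = 0.3
    counts_nonwear_threshold: float = 0.0
    nonwear_min_run: int = 40
    valid_day_minutes: int = 600  # 10 hours
    valid_days_required: int = 3
    valid_day_basis: str = "worn"  # or "recorded"
    active_inclusive: bool = True
    max_offset: int = 5
    min_align_overlap: int = 30
    protocol_days: int = 5

    @property
    def class_bounds(self):
        return (self.active_threshold, self.moderate_threshold, self.vigorous_threshold)


@dataclass
class ParticipantEntry:
    participant_id: str
    phone_path: str | None = None
    ref_path: str | None = None
    # in-memory alternative to file paths (used by synthetic studies)
    phone_series: EpochSeries | None = field(default=None, repr=False)
    ref_series: EpochSeries | None = field(default=None, repr=False)


@dataclass
class StudyManifest:
    participants: list[ParticipantEntry]
    options: StudyOptions = field(default_factory=StudyOptions)

    def __post_init__(self):
        ids = [p.participant_id for p in self.participants]
        if len(set(ids)) != len(ids):
            raise ConfigurationError("participant ids must be unique")


def load_manifest(path) -> StudyManifest:
    """Load a YAML manifest: ``participants: [{id, phone, ref}, ...]`` + ``options``."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not doc or "participants" not in doc:
        raise ConfigurationError(f"{path}: manifest must list participants")
    base = Path(path).parent
    entries = []
    for p in doc["participants"]:
        entries.append(
            ParticipantEntry(
                participant_id=str(p["id"]),
                phone_path=str(base / p["phone"]),
                ref_path=str(base / p["ref"]),
            )
        )
    opts = StudyOptions(**(doc.get("options") or {}))
    return StudyManifest(participants=entries, options=opts)


def manifest_from_cohort(cohort, options: StudyOptions | None = None) -> StudyManifest:
    """Build an in-memory manifest directly from a simulated cohort."""
    entries = [
        ParticipantEntry(
            participant_id=pid,
            phone_series=pair[0],
            ref_series=pair[1],
        )
        for pid, pair in cohort.pairs.items()
    ]
    return StudyManifest(participants=entries, options=options or StudyOptions())


@dataclass
class ParticipantResult:
    participant_id: str
    scan: object
    pair: object
    phone_mask: wear.WearMask
    ref_mask: wear.WearMask
    phone_usability: wear.UsabilitySummary
    ref_usability: wear.UsabilitySummary
    phone_days: pd.DataFrame
    ref_days: pd.DataFrame
    minutes: agreement.ParticipantMinutes


@dataclass
class StudyResult:
    """Everything :func:`run_study` computed, before any file is written."""

    n_enrolled: int
    analyzed: list[ParticipantResult]
    exclusions: list[tuple[str, str, str]]  # (participant, code, detail)
    usability_table: pd.DataFrame
    usability_tests: pd.DataFrame | None
    minute_comparison: agreement.MinuteComparison | None
    day_comparison: agreement.DayComparison | None
    log: list[str]

    @property
    def n_analyzed(self) -> int:
        return len(self.analyzed)


def _per_day_activity(mets: pd.Series, mask: wear.WearMask, opts: StudyOptions) -> pd.DataFrame:
    """Per calendar day activity summary over worn minutes, with validity flag."""
    worn = mask.worn.reindex(mets.index).fillna(False).astype(bool)
    day_of = mets.index.floor("D")
    rows = {}
    for day in sorted(set(day_of)):
        sel = worn & (day_of == day)
        summ = energy.summarize_activity(
            mets,
            minute_set=sel,
            active_threshold=opts.active_threshold,
            active_inclusive=opts.active_inclusive,
            bounds=opts.class_bounds,
        )
        row = summ.as_row()
        row["worn_minutes"] = int(sel.sum())
        row["valid"] = row["worn_minutes"] >= opts.valid_day_minutes
        rows[day] = row
    return pd.DataFrame.from_dict(rows, orient="index")


def _analyze_participant(entry: ParticipantEntry, opts: StudyOptions) -> ParticipantResult:
    if entry.phone_series is not None:
        phone, ref = entry.phone_series, entry.ref_series
    else:
        phone = read_epoch_csv(entry.phone_path, unit=UNIT_G)
        ref = read_epoch_csv(entry.ref_path, unit=UNIT_COUNTS)
    if phone.n_recorded == 0 or ref.n_recorded == 0:
        raise ActipairError(EXCL_EMPTY)

    phone_mask = wear.detect_nonwear(
        phone, zero_threshold=opts.g_nonwear_threshold, min_run=opts.nonwear_min_run
    )
    ref_mask = wear.detect_nonwear(
        ref, zero_threshold=opts.counts_nonwear_threshold, min_run=opts.nonwear_min_run
    )
    kw = dict(
        valid_day_minutes=opts.valid_day_minutes,
        valid_days_required=opts.valid_days_required,
        valid_day_basis=opts.valid_day_basis,
    )
    phone_usab = wear.usability_summary(phone, phone_mask, entry.participant_id, **kw)
    ref_usab = wear.usability_summary(ref, ref_mask, entry.participant_id, **kw)

    scan, pair = align(phone, ref, max_offset=opts.max_offset, min_overlap=opts.min_align_overlap)
    # joint mask: both recorded and both worn (phone wear shifted onto ref clock)
    phone_worn = phone_mask.worn.copy()
    phone_worn.index = phone_worn.index + pd.Timedelta(minutes=pair.offset)
    pair.restrict_mask(phone_worn)
    pair.restrict_mask(ref_mask.worn)

    phone_mets_aligned = energy.predict_mets(energy.CALFIT_ADAPTED, pair.phone_vt.dropna())
    ref_mets_aligned = energy.predict_mets(energy.ACTIGRAPH_FREEDSON, pair.ref_vt.dropna())

    joint = pair.data.index[pair.joint_mask]
    if len(joint) == 0:
        raise ActipairError(EXCL_NO_JOINT)
    minutes = agreement.ParticipantMinutes(
        participant_id=entry.participant_id,
        phone_vt=pair.phone_vt.loc[joint].to_numpy(),
        ref_vt=pair.ref_vt.loc[joint].to_numpy(),
        phone_mets=phone_mets_aligned.reindex(joint).to_numpy(),
        ref_mets=ref_mets_aligned.reindex(joint).to_numpy(),
    )

    # day-level summaries on the aligned (reference) clock, each device's own wear
    phone_mask_aligned = wear.WearMask(
        states=phone_mask.states.set_axis(
            phone_mask.states.index + pd.Timedelta(minutes=pair.offset)
        ),
        episodes=phone_mask.episodes,
    )
    phone_days = _per_day_activity(phone_mets_aligned, phone_mask_aligned, opts)
    ref_days = _per_day_activity(ref_mets_aligned, ref_mask, opts)

    return ParticipantResult(
        participant_id=entry.participant_id,
        scan=scan,
        pair=pair,
        phone_mask=phone_mask,
        ref_mask=ref_mask,
        phone_usability=phone_usab,
        ref_usability=ref_usab,
        phone_days=phone_days,
        ref_days=ref_days,
        minutes=minutes,
    )


def run_study(manifest: StudyManifest) -> StudyResult:
    """Execute the full between-device analysis for every manifest participant.

    Per-participant failures are isolated and logged with a reason code;
    a cohort where every participant fails aborts with a diagnostic.
    Results are independent of participant ordering in the manifest.
    """
    opts = manifest.options
    analyzed: list[ParticipantResult] = []
    exclusions: list[tuple[str, str, str]] = []
    log: list[str] = []

    for entry in sorted(manifest.participants, key=lambda e: e.participant_id):
        try:
            analyzed.append(_analyze_participant(entry, opts))
            log.append(f"analyzed {entry.participant_id}")
        except AlignmentError as exc:
            exclusions.append((entry.participant_id, EXCL_ALIGNMENT, str(exc)))
            log.append(f"excluded {entry.participant_id}: {EXCL_ALIGNMENT}: {exc}")
        except ActipairError as exc:
            code = str(exc) if str(exc) in (EXCL_EMPTY, EXCL_NO_JOINT) else EXCL_READ_ERROR
            exclusions.append((entry.participant_id, code, str(exc)))
            log.append(f"excluded {entry.participant_id}: {code}: {exc}")
        except (OSError, ValueError) as exc:
            exclusions.append((entry.participant_id, EXCL_READ_ERROR, str(exc)))
            log.append(f"excluded {entry.participant_id}: {EXCL_READ_ERROR}: {exc}")

    if not analyzed:
        raise ActipairError(
            f"all {len(manifest.participants)} participants failed; "
            f"exclusions: {exclusions}"
        )

    usab_rows = []
    for r in analyzed:
        for dev, summ in (("phone", r.phone_usability), ("reference", r.ref_usability)):
            row = summ.as_dict()
            row["device"] = dev
            usab_rows.append(row)
    usability_table = pd.DataFrame(usab_rows)
    usability_tests = None
    if len(analyzed) >= 2:
        usability_tests = wear.compare_usability(
            [r.phone_usability for r in analyzed],
            [r.ref_usability for r in analyzed],
            labels=("phone", "reference"),
        )

    minute_cmp = agreement.compare_minutes(
        [r.minutes for r in analyzed],
        active_threshold=opts.active_threshold,
        active_inclusive=opts.active_inclusive,
    )
    for pid, reason in minute_cmp.excluded:
        exclusions.append((pid, EXCL_NO_JOINT, reason))
        log.append(f"excluded {pid} from minute comparison: {reason}")

    phone_day_tab = pd.concat(
        {r.participant_id: r.phone_days for r in analyzed}, names=["participant", "day"]
    )
    ref_day_tab = pd.concat(
        {r.participant_id: r.ref_days for r in analyzed}, names=["participant", "day"]
    )
    day_cmp = agreement.compare_days(phone_day_tab, ref_day_tab)

    return StudyResult(
        n_enrolled=len(manifest.participants),
        analyzed=analyzed,
        exclusions=exclusions,
        usability_table=usability_table,
        usability_tests=usability_tests,
        minute_comparison=minute_cmp,
        day_comparison=day_cmp,
        log=log,
    )


def write_bundle(result: StudyResult, out_dir) -> None:
    """Write the report bundle for a completed study run."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    result.usability_table.to_csv(out / "usability.csv", index=False)
    if result.usability_tests is not None:
        result.usability_tests.to_csv(out / "usability_tests.csv")

    mc = result.minute_comparison
    minute_doc = {
        "vt": mc.vt.as_dict(),
        "active_pct": mc.active_pct.as_dict(),
        "mean_met": mc.mean_met.as_dict(),
        "class_durations": {k: v.as_dict() for k, v in mc.class_durations.items()},
    }
    (out / "agreement_minute.json").write_text(json.dumps(minute_doc, indent=2))

    dc = result.day_comparison
    day_doc = {
        "empty": dc.empty,
        "n_days": dc.n_days,
        "reports": {k: v.as_dict() for k, v in dc.reports.items()},
    }
    (out / "agreement_day.json").write_text(json.dumps(day_doc, indent=2))

    if len(mc.class_intensity.table):
        mc.class_intensity.table.to_csv(out / "class_intensity.csv")

    for name, report in [("active_pct", mc.active_pct), ("mean_met", mc.mean_met)] + [
        (f"{k}_pct", v) for k, v in mc.class_durations.items()
    ]:
        if report.bland_altman is not None and report.bland_altman.table is not None:
            report.bland_altman.table.to_csv(out / f"bland_altman_{name}.csv", index=False)

    lines = [f"enrolled={result.n_enrolled} analyzed={result.n_analyzed} "
             f"excluded={len(result.exclusions)}"]
    lines += result.log
    (out / "run.log").write_text("\n".join(lines) + "\n")
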