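"""Raw acceleration streams and 1-minute epoch series.

The two devices compared by this package report vertical-axis activity in
different units: the reference accelerometer emits manufacturer "counts" per
minute, the phone per-minute mean gravity-removed vertical acceleration in g.
This module holds both representations: :class:`RawStream` for timestamped
tri-axial samples and :class:`EpochSeries` for the per-minute series every
downstream stage (alignment, wear detection, energy expenditure) consumes.

Epoch conventions
-----------------
* Epochs are calendar minutes, half-open ``[t, t+60 s)``.
* An :class:`EpochSeries` is always contiguous at 1-minute spacing; minutes
  with no recording are coded ``NaN`` in memory and ``NA`` in files, never
  silently dropped — wear/usability logic must distinguish "not recorded"
  from "zero movement".
* Gravity is removed per minute by subtracting the minute's median vertical
  acceleration; the epoch value is the mean absolute deviation from that
  median, in g.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, DataError, EmptyInputError

EPOCH = pd.Timedelta(minutes=1)

#: Recognised intensity units for an EpochSeries.
UNIT_COUNTS = "counts/min"
UNIT_G = "g/min"
VALID_UNITS = (UNIT_COUNTS, UNIT_G)

_AXIS_COLUMNS = {"x": "ax", "y": "ay", "z": "az"}

#: Default column mapping for delimited raw files.  ``vertical`` names the
#: axis worn vertically (a deployment property, not inferable from data).
DEFAULT_DIALECT = {
    "timestamp": "timestamp",
    "x": "ax",
    "y": "ay",
    "z": "az",
    "vertical": "y",
    "delimiter": ",",
}


@dataclass
class RawStream:
    """Timestamped tri-axial acceleration samples from one device.

    Parameters
    ----------
    device_id : str
        Label of the emitting device.
    sample_rate : float
        Nominal sampling rate in Hz; must be positive.
    samples : pandas.DataFrame
        Indexed by ``DatetimeIndex`` (strictly increasing), columns
        ``ax, ay, az`` in g, all finite.
    n_bad_rows : int
        Rows dropped by the reader because a field failed to parse.
    """

    device_id: str
    sample_rate: float
    samples: pd.DataFrame
    n_bad_rows: int = 0

    def __post_init__(self):
        if self.sample_rate <= 0:
            raise ConfigurationError(f"sample_rate must be > 0, got {self.sample_rate}")
        missing = [c for c in ("ax", "ay", "az") if c not in self.samples.columns]
        if missing:
            raise ConfigurationError(f"samples missing axis columns: {missing}")
        idx = self.samples.index
        if len(idx) > 1:
            diffs = np.diff(idx.asi8)
            if (diffs <= 0).any():
                row = int(np.argmax(diffs <= 0)) + 1
                raise DataError(
                    f"timestamps not strictly increasing at row {row} "
                    f"(t={idx[row]})"
                )
        vals = self.samples[["ax", "ay", "az"]].to_numpy()
        if len(vals) and not np.isfinite(vals).all():
            raise DataError("acceleration samples contain non-finite values")

    def __len__(self):
        return len(self.samples)

    def vertical(self, axis: str = "y") -> pd.Series:
        """Return the vertical-axis series for the declared vertical axis."""
        try:
            return self.samples[_AXIS_COLUMNS[axis]]
        except KeyError:
            raise ConfigurationError(f"unknown vertical axis {axis!r}") from None


@dataclass
class EpochSeries:
    """Per-minute vertical-axis intensity values with a device unit tag.

    ``values`` is a float Series on a contiguous 1-minute ``DatetimeIndex``;
    ``NaN`` marks minutes the device did not record.  All recorded values are
    non-negative.
    """

    device_id: str
    unit: str
    values: pd.Series
    sample_counts: pd.Series | None = field(default=None, repr=False)

    def __post_init__(self):
        if self.unit not in VALID_UNITS:
            raise ConfigurationError(
                f"unit must be one of {VALID_UNITS}, got {self.unit!r}"
            )
        v = self.values
        if not isinstance(v.index, pd.DatetimeIndex):
            raise ConfigurationError("EpochSeries requires a DatetimeIndex")
        if len(v) > 1:
            deltas = np.diff(v.index.asi8)
            if not (deltas == EPOCH.value).all():
                raise DataError("epochs must be contiguous at exactly 1-minute spacing")
        finite = v.dropna()
        if len(finite) and (finite.to_numpy() < 0).any():
            raise DataError("epoch intensity values must be >= 0")
        self.values = v.astype(float)

    def __len__(self):
        return len(self.values)

    @property
    def start(self) -> pd.Timestamp:
        return self.values.index[0]

    @property
    def recorded(self) -> pd.Series:
        """Boolean per-minute indicator that the device recorded this minute."""
        return self.values.notna()

    @property
    def n_recorded(self) -> int:
        return int(self.values.notna().sum())

    def shift_minutes(self, offset: int) -> "EpochSeries":
        """Return a copy with every timestamp shifted by ``offset`` whole minutes."""
        shifted = self.values.copy()
        shifted.index = shifted.index + offset * EPOCH
        return EpochSeries(self.device_id, self.unit, shifted)


def _parse_timestamps(raw: pd.Series) -> pd.Series:
    """Parse ISO-8601 strings or epoch-seconds numbers to Timestamps (NaT on failure)."""
    numeric = pd.to_numeric(raw, errors="coerce")
    if numeric.notna().mean() > 0.5:
        return pd.to_datetime(numeric, unit="s", errors="coerce")
    return pd.to_datetime(raw, errors="coerce", format="ISO8601")


def read_raw_stream(path, dialect: dict | None = None) -> RawStream:
    """Read a delimited raw acceleration file into a :class:`RawStream`.

    ``dialect`` maps logical fields to column names (see
    :data:`DEFAULT_DIALECT`); it must name the timestamp column and the three
    axis columns.  Rows whose timestamp or any axis value fails to parse are
    dropped and counted in ``RawStream.n_bad_rows``.

    Raises
    ------
    ConfigurationError
        If a required column mapping is absent or the column is missing
        from the file.
    DataError
        If timestamps are not strictly increasing (the offending row is
        named) or the file has no parseable rows.
    """
    cfg = dict(DEFAULT_DIALECT)
    cfg.update(dialect or {})
    for key in ("timestamp", "x", "y", "z"):
        if key not in cfg or not cfg[key]:
            raise ConfigurationError(f"dialect must name the {key!r} column")
    df = pd.read_csv(path, sep=cfg.get("delimiter", ","))
    missing = [cfg[k] for k in ("timestamp", "x", "y", "z") if cfg[k] not in df.columns]
    if missing:
        raise ConfigurationError(f"{path}: required columns absent: {missing}")

    ts = _parse_timestamps(df[cfg["timestamp"]]).rename(None)
    axes = {
        _AXIS_COLUMNS[k]: pd.to_numeric(df[cfg[k]], errors="coerce")
        for k in ("x", "y", "z")
    }
    parsed = pd.DataFrame(axes)
    parsed.index = ts
    ok = ts.notna().to_numpy() & parsed.notna().all(axis=1).to_numpy()
    n_bad = int((~ok).sum())
    parsed = parsed.loc[ok]
    if parsed.empty:
        raise DataError(f"{path}: no parseable rows")

    rate = cfg.get("sample_rate")
    if rate is None:
        # infer from median inter-sample interval
        dt = np.median(np.diff(parsed.index.asi8)) / 1e9 if len(parsed) > 1 else 1.0
        rate = 1.0 / dt if dt > 0 else 1.0
    return RawStream(
        device_id=str(cfg.get("device_id", "unknown")),
        sample_rate=float(rate),
        samples=parsed,
        n_bad_rows=n_bad,
    )


def write_raw_stream(stream: RawStream, path, dialect: dict | None = None) -> None:
    """Write a RawStream back to delimited text (inverse of :func:`read_raw_stream`)."""
    cfg = dict(DEFAULT_DIALECT)
    cfg.update(dialect or {})
    out = pd.DataFrame(
        {
            cfg["timestamp"]: stream.samples.index.strftime("%Y-%m-%dT%H:%M:%S.%f"),
            cfg["x"]: stream.samples["ax"].to_numpy(),
            cfg["y"]: stream.samples["ay"].to_numpy(),
            cfg["z"]: stream.samples["az"].to_numpy(),
        }
    )
    out.to_csv(path, index=False, sep=cfg.get("delimiter", ","))


def summarize_to_epochs(stream: RawStream, vertical: str = "y") -> EpochSeries:
    """Summarize a raw stream to 1-minute vertical-axis epochs in g/min.

    Each calendar minute touched by the stream yields one value: the mean
    over that minute's samples of ``|v - median(v)|`` where ``v`` is the
    vertical acceleration — the per-minute median stands in for gravity, so a
    motionless device scores 0 regardless of orientation.  Minutes inside the
    stream's span with no samples are missing-coded.

    Raises
    ------
    EmptyInputError
        If the stream holds no samples.
    """
    if len(stream) == 0:
        raise EmptyInputError("cannot summarize an empty stream")
    v = stream.vertical(vertical)
    minute = v.index.floor("min")
    dev = (v - v.groupby(minute).transform("median")).abs()
    per_min = dev.groupby(minute).mean()
    counts = v.groupby(minute).size()

    full = pd.date_range(minute[0], minute[-1], freq="min")
    values = per_min.reindex(full)
    sample_counts = counts.reindex(full, fill_value=0).astype(int)
    return EpochSeries(stream.device_id, UNIT_G, values, sample_counts=sample_counts)


MISSING_SENTINEL = "NA"


def write_epoch_csv(series: EpochSeries, path) -> None:
    """Write an EpochSeries as CSV with columns ``timestamp,vt,unit,device``.

    Missing minutes are written with the ``NA`` sentinel so the round trip is
    lossless.
    """
    df = pd.DataFrame(
        {
            "timestamp": series.values.index.strftime("%Y-%m-%dT%H:%M:%S"),
            "vt": series.values.to_numpy(),
            "unit": series.unit,
            "device": series.device_id,
        }
    )
    df.to_csv(path, index=False, na_rep=MISSING_SENTINEL)


def read_epoch_csv(path, unit: str | None = None) -> EpochSeries:
    """Read an epoch CSV written by :func:`write_epoch_csv`.

    ``unit`` overrides or supplies the unit tag when the file lacks a
    ``unit`` column.  Negative intensities raise :class:`DataError`;
    non-contiguous timestamps are reindexed onto the full minute range with
    the gap minutes missing-coded.
    """
    df = pd.read_csv(path, na_values=[MISSING_SENTINEL], keep_default_na=True)
    for col in ("timestamp", "vt"):
        if col not in df.columns:
            raise ConfigurationError(f"{path}: epoch CSV missing column {col!r}")
    ts = pd.to_datetime(df["timestamp"], format="ISO8601")
    vt = pd.to_numeric(df["vt"], errors="coerce")
    bad = df["vt"].notna() & vt.isna()
    if bad.any():
        raise DataError(f"{path}: unparseable vt at row {int(np.argmax(bad.to_numpy()))}")
    if (vt.dropna() < 0).any():
        row = int(np.argmax((vt < 0).to_numpy()))
        raise DataError(f"{path}: negative intensity value at row {row}")

    file_unit = None
    if "unit" in df.columns and df["unit"].notna().any():
        units = df["unit"].dropna().unique()
        if len(units) > 1:
            raise DataError(f"{path}: mixed units {list(units)}")
        file_unit = units[0]
    resolved = unit or file_unit
    if resolved is None:
        raise ConfigurationError(f"{path}: no unit column; pass unit= explicitly")
    if unit and file_unit and unit != file_unit:
        raise ConfigurationError(
            f"{path}: requested unit {unit!r} but file says {file_unit!r}"
        )
    device = "unknown"
    if "device" in df.columns and df["device"].notna().any():
        device = str(df["device"].dropna().iloc[0])

    values = pd.Series(vt.to_numpy(), index=pd.DatetimeIndex(ts))
    values = values[~values.index.duplicated()]
    full = pd.date_range(values.index.min(), values.index.max(), freq="min")
    return EpochSeries(device, resolved, values.reindex(full))
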