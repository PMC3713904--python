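"""Clock alignment between the two devices' epoch series.

Consumer phones and research accelerometers are set by different clocks, so
before any minute-by-minute comparison the phone series must be shifted onto
the reference timeline.  Device clocks in the target deployment disagree by
at most a few minutes, so the search runs over integer-minute offsets in
``[-max_offset, +max_offset]`` (default ±5) and keeps the offset whose
simple linear regression between the two vertical-axis measures attains the
highest adjusted R² over jointly recorded minutes.

Sign convention: ``offset`` is the shift *applied to the phone series* so
that it matches the reference.  A phone clock running ``k`` minutes ahead of
the reference is therefore recovered as ``offset = -k``; the scan also
reports ``clock_shift = -offset``, the estimated phone clock error, which is
usually what a study log wants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .epochs import EPOCH, EpochSeries
from .exceptions import AlignmentError, UndefinedStatisticError


def adjusted_r2(x, y) -> float:
    """Adjusted R² of the simple linear regression of ``y`` on ``x``.

    Pairs with a missing value in either sequence are dropped first.  With
    ``n`` complete pairs and one regressor the adjustment is
    ``1 - (1 - R²)(n - 1)/(n - 2)``.

    Raises
    ------
    UndefinedStatisticError
        If fewer than 3 complete pairs remain or ``x`` has zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        raise UndefinedStatisticError(f"adjusted R² needs n >= 3 complete pairs, got {n}")
    sxx = np.sum((x - x.mean()) ** 2)
    syy = np.sum((y - y.mean()) ** 2)
    if sxx == 0:
        raise UndefinedStatisticError("adjusted R² undefined: x has zero variance")
    if syy == 0:
        # regression reproduces the constant y exactly
        return 1.0
    sxy = np.sum((x - x.mean()) * (y - y.mean()))
    r2 = sxy * sxy / (sxx * syy)
    return 1.0 - (1.0 - r2) * (n - 1) / (n - 2)


@dataclass
class OffsetScan:
    """Result of the offset search: adjusted R² per candidate, and the winner."""

    scores: dict[int, float]
    overlap: dict[int, int]
    chosen: int
    boundary_attained: bool

    @property
    def clock_shift(self) -> int:
        """Estimated phone clock error in minutes (positive = phone ahead)."""
        return -self.chosen


@dataclass
class AlignedPair:
    """Two devices' epoch values merged on the reference timeline.

    ``data`` is indexed by reference-clock minutes with float columns
    ``phone_vt`` (g/min) and ``ref_vt`` (counts/min) and boolean
    ``joint_mask``.  At construction the mask marks minutes both devices
    recorded; the pipeline refines it to "both recorded and both worn" once
    wear masks exist (:meth:`restrict_mask`).
    """

    offset: int
    data: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        for col in ("phone_vt", "ref_vt", "joint_mask"):
            if col not in self.data.columns:
                raise ValueError(f"AlignedPair data missing column {col!r}")

    @property
    def phone_vt(self) -> pd.Series:
        return self.data["phone_vt"]

    @property
    def ref_vt(self) -> pd.Series:
        return self.data["ref_vt"]

    @property
    def joint_mask(self) -> pd.Series:
        return self.data["joint_mask"]

    @property
    def n_joint(self) -> int:
        return int(self.data["joint_mask"].sum())

    def restrict_mask(self, keep: pd.Series) -> None:
        """AND the joint mask with ``keep`` (reindexed, missing→False)."""
        aligned = keep.reindex(self.data.index).fillna(False).astype(bool)
        self.data["joint_mask"] &= aligned


def _tie_break_key(offset: int):
    # smallest |offset| first, then the negative of a ±pair
    return (abs(offset), offset)


def align(
    phone: EpochSeries,
    ref: EpochSeries,
    max_offset: int = 5,
    min_overlap: int = 30,
) -> tuple[OffsetScan, AlignedPair]:
    """Find the integer-minute offset merging ``phone`` onto ``ref``'s clock.

    Every offset in ``[-max_offset, +max_offset]`` is scored by the adjusted
    R² between the two vertical-axis measures over jointly recorded,
    non-missing minutes; the pair is merged at the argmax.  Ties prefer the
    smallest absolute offset, then the negative one.  If the winner sits on
    the window edge the scan is flagged ``boundary_attained`` — the true
    shift may lie outside the search window.

    Raises
    ------
    AlignmentError
        If any candidate offset has fewer than ``min_overlap`` jointly
        recorded minutes; the per-offset overlap counts ride on the error.
    """
    offsets = list(range(-max_offset, max_offset + 1))
    ref_vals = ref.values
    scores: dict[int, float] = {}
    overlap: dict[int, int] = {}
    for o in offsets:
        shifted = phone.values.copy()
        shifted.index = shifted.index + o * EPOCH
        joined = pd.concat(
            {"phone_vt": shifted, "ref_vt": ref_vals}, axis=1, join="inner"
        ).dropna()
        overlap[o] = len(joined)
        if len(joined) >= 3:
            try:
                scores[o] = adjusted_r2(joined["phone_vt"], joined["ref_vt"])
            except UndefinedStatisticError:
                scores[o] = float("-inf")
        else:
            scores[o] = float("-inf")

    short = {o: n for o, n in overlap.items() if n < min_overlap}
    if short:
        raise AlignmentError(
            f"insufficient overlap (<{min_overlap} joint minutes) at offsets "
            f"{sorted(short)}",
            overlap_per_offset=overlap,
        )

    best = max(scores.values())
    if not np.isfinite(best):
        raise AlignmentError(
            "adjusted R² undefined at every candidate offset", overlap_per_offset=overlap
        )
    winners = [o for o, s in scores.items() if s == best]
    chosen = min(winners, key=_tie_break_key)
    scan = OffsetScan(
        scores=scores,
        overlap=overlap,
        chosen=chosen,
        boundary_attained=abs(chosen) == max_offset,
    )

    shifted = phone.values.copy()
    shifted.index = shifted.index + chosen * EPOCH
    merged = pd.concat({"phone_vt": shifted, "ref_vt": ref_vals}, axis=1, join="outer")
    full = pd.date_range(merged.index.min(), merged.index.max(), freq="min")
    merged = merged.reindex(full)
    merged["joint_mask"] = merged["phone_vt"].notna() & merged["ref_vt"].notna()
    return scan, AlignedPair(offset=chosen, data=merged)
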