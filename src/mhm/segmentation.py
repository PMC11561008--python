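"""Cycle segmentation and per-cycle evidence extraction.

Converts an :class:`~mhm.model.ObservationLog` into :class:`Cycle` records:
a new cycle starts at every *bleed onset* -- a bleed day with no bleed on
the previous calendar day -- and ends the day before the next onset.  The
final cycle is open (unknown length).

Conventions (declared once, used everywhere):

* cycle days are 1-based; day 1 is the first bleed day of the cycle;
* luteal length counts the LH-positive day itself through the last day
  before the next onset, ``length_days - lh_positive_day + 1``, so the
  printed "< 14 days" short-luteal criterion is testable with one rule;
* the mid-luteal serum progesterone of a cycle is the first value recorded
  4-11 days after the positive LH test (the scheduled draw is +7).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from datetime import date, timedelta
from typing import Mapping, Optional, Sequence

from .model import Event, EventKind, ObservationLog

__all__ = [
    "Cycle",
    "SegmentationResult",
    "AnnualBleeds",
    "InsufficientDataError",
    "segment_cycles",
    "bleeds_per_year",
    "luteal_length",
    "detect_bbt_shift",
    "BBT_RISE_C",
    "BBT_BASELINE_WINDOW",
    "BBT_RUN_LENGTH",
]

# Biphasic-shift detection rule ("three over six"): the first run of
# BBT_RUN_LENGTH consecutive days all at least BBT_RISE_C above the maximum
# of the previous BBT_BASELINE_WINDOW recorded temperatures.
BBT_RISE_C = 0.2
BBT_BASELINE_WINDOW = 6
BBT_RUN_LENGTH = 3

# Mid-luteal window relative to the LH-positive day (target draw is +7,
# acceptable +7..+9; the wider read window tolerates off-schedule draws).
MIDLUTEAL_READ_WINDOW = (4, 11)


class InsufficientDataError(ValueError):
    """Raised when too few values exist for the requested computation."""


@dataclass(frozen=True)
class Cycle:
    """One menstrual cycle and the evidence recorded within it."""

    index: int  # ordinal from 1
    onset: date
    length_days: Optional[int]  # None for the final, open cycle
    bleed_days: tuple[int, ...] = ()
    lh_positive_day: Optional[int] = None
    lh_tests_done: int = 0
    luteal_length_days: Optional[int] = None
    midluteal_p4_nmol_l: Optional[float] = None
    p4_values: tuple[float, ...] = ()
    bbt_shift_day: Optional[int] = None
    blood_loss_ml: Optional[float] = None
    events: tuple[Event, ...] = ()

    @property
    def closed(self) -> bool:
        return self.length_days is not None

    def day_of(self, d: date) -> int:
        """1-based cycle day of a calendar date."""
        return (d - self.onset).days + 1


@dataclass(frozen=True)
class SegmentationResult:
    cycles: tuple[Cycle, ...]
    no_bleeds: bool = False

    @property
    def closed_cycles(self) -> tuple[Cycle, ...]:
        return tuple(c for c in self.cycles if c.closed)


@dataclass(frozen=True)
class AnnualBleeds:
    """Bleed onsets in the 365-day window ending at ``as_of``.

    ``count`` is annualized (count * 365 / observed span) and flagged
    ``extrapolated`` when the log covers less than the full window.
    """

    count: float
    coverage: float
    extrapolated: bool
    observed_onsets: int


def _bleed_onsets(log: ObservationLog) -> list[date]:
    bleed_dates = sorted({e.date for e in log.events_of(EventKind.BLEED)})
    bleed_set = set(bleed_dates)
    return [d for d in bleed_dates if (d - timedelta(days=1)) not in bleed_set]


def luteal_length(cycle: Cycle) -> Optional[int]:
    """Days from the LH-positive day through the day before the next onset,
    inclusive of the LH-positive day; None when either piece is unknown."""
    if cycle.length_days is None or cycle.lh_positive_day is None:
        return None
    return cycle.length_days - cycle.lh_positive_day + 1


def detect_bbt_shift(
    temps: Mapping[int, float],
    *,
    rise_c: float = BBT_RISE_C,
    baseline_window: int = BBT_BASELINE_WINDOW,
    run_length: int = BBT_RUN_LENGTH,
) -> Optional[int]:
    """First cycle day ``d`` such that the temperatures on days
    ``d .. d+run_length-1`` (all recorded, consecutive calendar days) each
    exceed the maximum of the previous ``baseline_window`` recorded
    temperatures by at least ``rise_c``; None if no such day exists.

    Advisory evidence only -- a detected shift never substitutes for LH or
    progesterone evidence in the classification trees.

    Raises :class:`InsufficientDataError` with fewer than
    ``baseline_window + run_length`` recorded values.
    """
    if len(temps) < baseline_window + run_length:
        raise InsufficientDataError(
            f"need >= {baseline_window + run_length} BBT values, got {len(temps)}"
        )
    days = sorted(temps)
    for i, d in enumerate(days):
        if i < baseline_window:
            continue
        run = [d + k for k in range(run_length)]
        if not all(day in temps for day in run):
            continue
        baseline_max = max(temps[days[j]] for j in range(i - baseline_window, i))
        if all(temps[day] >= baseline_max + rise_c for day in run):
            return d
    return None


def segment_cycles(log: ObservationLog) -> SegmentationResult:
    """Partition the log into cycles at bleed onsets.

    Every event dated within ``[onset, next onset)`` is attached to that
    cycle; events before the first onset belong to no cycle.  Returns an
    empty result flagged ``no_bleeds`` when the log has no bleed events
    (needed for the amenorrhea paths, which are not an error).
    """
    onsets = _bleed_onsets(log)
    if not onsets:
        return SegmentationResult(cycles=(), no_bleeds=True)

    cycles: list[Cycle] = []
    for i, onset in enumerate(onsets):
        nxt = onsets[i + 1] if i + 1 < len(onsets) else None
        length = (nxt - onset).days if nxt else None
        in_cycle = tuple(
            e
            for e in log.events
            if e.date >= onset and (nxt is None or e.date < nxt)
        )
        day = lambda d: (d - onset).days + 1  # noqa: E731

        bleed_days = tuple(
            sorted(day(e.date) for e in in_cycle if e.kind == EventKind.BLEED)
        )
        lh_tests = [e for e in in_cycle if e.kind == EventKind.LH_TEST]
        lh_positive_day = next(
            (day(e.date) for e in lh_tests if e.value), None
        )

        p4_values = tuple(
            float(e.value) for e in in_cycle if e.kind == EventKind.SERUM_P4
        )
        midluteal = None
        if lh_positive_day is not None:
            lo, hi = MIDLUTEAL_READ_WINDOW
            for e in in_cycle:
                if e.kind == EventKind.SERUM_P4 and lo <= day(e.date) - lh_positive_day <= hi:
                    midluteal = float(e.value)
                    break

        temps = {
            day(e.date): float(e.value)
            for e in in_cycle
            if e.kind == EventKind.BBT
        }
        try:
            bbt_shift = detect_bbt_shift(temps)
        except InsufficientDataError:
            bbt_shift = None

        loss = next(
            (
                float(e.value)
                for e in in_cycle
                if e.kind == EventKind.BLOOD_LOSS_ESTIMATE
            ),
            None,
        )

        cycle = Cycle(
            index=i + 1,
            onset=onset,
            length_days=length,
            bleed_days=bleed_days,
            lh_positive_day=lh_positive_day,
            lh_tests_done=len(lh_tests),
            luteal_length_days=None,
            midluteal_p4_nmol_l=midluteal,
            p4_values=p4_values,
            bbt_shift_day=bbt_shift,
            blood_loss_ml=loss,
            events=in_cycle,
        )
        cycle = dataclasses.replace(cycle, luteal_length_days=luteal_length(cycle))
        cycles.append(cycle)
    return SegmentationResult(cycles=tuple(cycles), no_bleeds=False)


def bleeds_per_year(log: ObservationLog, as_of: date) -> AnnualBleeds:
    """Bleed-onset count in the 365-day window ending at ``as_of``.

    Coverage is the fraction of that window the log observes (from its
    first event).  With partial coverage the count is annualized
    (count * 365 / observed days) and marked extrapolated; the classifier
    never lets an extrapolated low count trigger the oligomenorrheic leaf
    on its own.
    """
    window_start = as_of - timedelta(days=364)
    onsets = [d for d in _bleed_onsets(log) if window_start <= d <= as_of]
    first = log.first_date
    if first is None or first > as_of:
        return AnnualBleeds(count=0.0, coverage=0.0, extrapolated=True, observed_onsets=0)
    span = (as_of - max(window_start, first)).days + 1
    coverage = span / 365.0
    if coverage >= 1.0:
        return AnnualBleeds(
            count=float(len(onsets)),
            coverage=1.0,
            extrapolated=False,
            observed_onsets=len(onsets),
        )
    count = len(onsets) * 365.0 / span if span > 0 else 0.0
    return AnnualBleeds(
        count=count, coverage=coverage, extrapolated=True, observed_onsets=len(onsets)
    )
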