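"""Domain types and event-log parsing, validation, and file I/O.

An :class:`ObservationLog` is the sole input to everything downstream: one
individual's metadata plus a time-ordered list of dated self-monitoring
events (bleed days, urinary LH tests, basal body temperature, serum
progesterone, cervical mucus ratings, symptom surveys, contraception
records, and per-menses blood-loss estimates).

Parsing is strict and auditable: every fatal problem raises a
:class:`LogError` that names the offending row; nothing is silently
coerced or dropped.  Non-fatal issues (tracking gaps, orphan blood tests)
are surfaced by :func:`validate_log` as structured warnings.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field, replace
from datetime import date, timedelta
from pathlib import Path
from typing import Any, Iterable, Mapping, Optional, Sequence, Union

__all__ = [
    "EventKind",
    "ContraceptionCategory",
    "Regimen",
    "ContraceptionRecord",
    "Event",
    "IndividualMeta",
    "ObservationLog",
    "LogError",
    "LogWarningRecord",
    "EVENT_TIER",
    "PILL_CATEGORIES",
    "BBT_MIN_C",
    "BBT_MAX_C",
    "parse_event_log",
    "validate_log",
    "log_to_rows",
    "write_csv",
    "read_csv",
    "log_to_dict",
    "log_from_dict",
    "write_json",
    "read_json",
]

# Plausible-measurement bounds for basal body temperature, degrees Celsius.
BBT_MIN_C = 30.0
BBT_MAX_C = 45.0

# Gaps longer than this in otherwise daily tracking raise a GAP warning.
GAP_WARNING_DAYS = 60


class EventKind(str, enum.Enum):
    BLEED = "BLEED"
    LH_TEST = "LH_TEST"
    BBT = "BBT"
    SERUM_P4 = "SERUM_P4"
    CERVICAL_MUCUS = "CERVICAL_MUCUS"
    SYMPTOM = "SYMPTOM"
    CONTRACEPTION = "CONTRACEPTION"
    BLOOD_LOSS_ESTIMATE = "BLOOD_LOSS_ESTIMATE"


# Monitoring tier of each event kind.  Tier 0 is bleed dates (and the
# contraception context needed to route the basic tree); tier 1 adds
# symptoms, BBT, mucus and loss ratings; tier 2 adds urinary LH tests;
# tier 3 adds serum progesterone.  Classification at a capped tier never
# reads evidence above the cap.
EVENT_TIER: dict[EventKind, int] = {
    EventKind.BLEED: 0,
    EventKind.CONTRACEPTION: 0,
    EventKind.SYMPTOM: 1,
    EventKind.BBT: 1,
    EventKind.CERVICAL_MUCUS: 1,
    EventKind.BLOOD_LOSS_ESTIMATE: 1,
    EventKind.LH_TEST: 2,
    EventKind.SERUM_P4: 3,
}

# Kinds for which a duplicate (date, kind) pair is a hard error.
UNIQUE_PER_DAY = frozenset(
    {EventKind.BLEED, EventKind.LH_TEST, EventKind.BBT, EventKind.SERUM_P4}
)


class ContraceptionCategory(str, enum.Enum):
    NONE = "NONE"
    OCP_COMBINED_MONO = "OCP_COMBINED_MONO"
    OCP_COMBINED_BI = "OCP_COMBINED_BI"
    OCP_COMBINED_TRI = "OCP_COMBINED_TRI"
    OCP_PROGESTIN_ONLY = "OCP_PROGESTIN_ONLY"
    IUD_HORMONAL = "IUD_HORMONAL"
    IMPLANT = "IMPLANT"
    VAGINAL_RING = "VAGINAL_RING"
    INJECTION = "INJECTION"
    IUD_COPPER = "IUD_COPPER"


PILL_CATEGORIES = frozenset(
    {
        ContraceptionCategory.OCP_COMBINED_MONO,
        ContraceptionCategory.OCP_COMBINED_BI,
        ContraceptionCategory.OCP_COMBINED_TRI,
        ContraceptionCategory.OCP_PROGESTIN_ONLY,
    }
)

# Hormonal categories: active use routes the basic tree to the
# contraception handoff.  The copper IUD is non-hormonal and its users
# remain on the naturally-menstruating path.
HORMONAL_CATEGORIES = frozenset(
    {
        ContraceptionCategory.OCP_COMBINED_MONO,
        ContraceptionCategory.OCP_COMBINED_BI,
        ContraceptionCategory.OCP_COMBINED_TRI,
        ContraceptionCategory.OCP_PROGESTIN_ONLY,
        ContraceptionCategory.IUD_HORMONAL,
        ContraceptionCategory.IMPLANT,
        ContraceptionCategory.VAGINAL_RING,
        ContraceptionCategory.INJECTION,
    }
)


class LogError(ValueError):
    """Fatal event-log problem.  ``code`` is machine-readable; ``row``
    is the zero-based index of the offending input row when known."""

    def __init__(self, code: str, message: str, row: Optional[int] = None):
        self.code = code
        self.row = row
        prefix = f"[{code}]" if row is None else f"[{code}] row {row}:"
        super().__init__(f"{prefix} {message}")


@dataclass(frozen=True)
class LogWarningRecord:
    """Non-fatal validation finding."""

    kind: str
    message: str
    start: Optional[date] = None
    end: Optional[date] = None

    def to_dict(self) -> dict[str, Any]:
        return {
            "kind": self.kind,
            "message": self.message,
            "start": self.start.isoformat() if self.start else None,
            "end": self.end.isoformat() if self.end else None,
        }


@dataclass(frozen=True)
class Regimen:
    """Pill regimen: active-pill count and hormone-free count per cycle."""

    active_days: int
    hormone_free_days: int

    def __post_init__(self) -> None:
        if self.active_days < 1 or self.hormone_free_days < 0:
            raise ValueError("regimen day counts out of range")


@dataclass(frozen=True)
class ContraceptionRecord:
    category: ContraceptionCategory
    start_date: Optional[date] = None
    regimen: Optional[Regimen] = None
    extended_use_repeats: int = 0
    brand_note: str = ""

    def __post_init__(self) -> None:
        if self.regimen is not None and self.category not in PILL_CATEGORIES:
            raise ValueError(
                f"regimen only applies to pill categories, not {self.category.value}"
            )
        if self.extended_use_repeats < 0:
            raise ValueError("extended_use_repeats must be non-negative")

    @property
    def hormonal(self) -> bool:
        return self.category in HORMONAL_CATEGORIES

    def to_dict(self) -> dict[str, Any]:
        return {
            "category": self.category.value,
            "start_date": self.start_date.isoformat() if self.start_date else None,
            "regimen": (
                {
                    "active_days": self.regimen.active_days,
                    "hormone_free_days": self.regimen.hormone_free_days,
                }
                if self.regimen
                else None
            ),
            "extended_use_repeats": self.extended_use_repeats,
            "brand_note": self.brand_note,
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "ContraceptionRecord":
        regimen = None
        if d.get("regimen"):
            regimen = Regimen(
                int(d["regimen"]["active_days"]),
                int(d["regimen"]["hormone_free_days"]),
            )
        start = d.get("start_date")
        return cls(
            category=ContraceptionCategory(d["category"]),
            start_date=date.fromisoformat(start) if start else None,
            regimen=regimen,
            extended_use_repeats=int(d.get("extended_use_repeats", 0)),
            brand_note=str(d.get("brand_note", "") or ""),
        )


@dataclass(frozen=True)
class Event:
    """One dated observation.  ``value`` is kind-specific:

    ========================  =============================================
    BLEED                     optional ordinal volume rating (int) or None
    LH_TEST                   bool (True = positive)
    BBT                       float, degrees C (30-45)
    SERUM_P4                  float, nmol/L (>= 0)
    CERVICAL_MUCUS            int ordinal consistency score (>= 0)
    SYMPTOM                   mapping name -> numeric score
    CONTRACEPTION             :class:`ContraceptionRecord`
    BLOOD_LOSS_ESTIMATE       float, ml per menses (>= 0), attached to the
                              first day of the menses
    ========================  =============================================
    """

    date: date
    kind: EventKind
    value: Any = None

    @property
    def tier(self) -> int:
        return EVENT_TIER[self.kind]


@dataclass(frozen=True)
class IndividualMeta:
    individual_id: str
    age_years: Optional[float] = None
    menarche_reached: Optional[bool] = None  # None = unknown
    sex_assignment_note: str = ""
    secondary_sex_characteristics_present: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.age_years is not None and self.age_years < 0:
            raise ValueError("age_years must be non-negative")

    def to_dict(self) -> dict[str, Any]:
        return {
            "individual_id": self.individual_id,
            "age_years": self.age_years,
            "menarche_reached": self.menarche_reached,
            "sex_assignment_note": self.sex_assignment_note,
            "secondary_sex_characteristics_present": self.secondary_sex_characteristics_present,
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "IndividualMeta":
        return cls(
            individual_id=str(d["individual_id"]),
            age_years=(None if d.get("age_years") is None else float(d["age_years"])),
            menarche_reached=d.get("menarche_reached"),
            sex_assignment_note=str(d.get("sex_assignment_note", "") or ""),
            secondary_sex_characteristics_present=d.get(
                "secondary_sex_characteristics_present"
            ),
        )


def _canonical_value(value: Any) -> str:
    """Deterministic serialization of a payload, used both for CSV output
    and as the final tie-break in event ordering."""
    if isinstance(value, ContraceptionRecord):
        return json.dumps(value.to_dict(), sort_keys=True)
    return json.dumps(value, sort_keys=True)


def _event_sort_key(e: Event) -> tuple:
    return (e.date, e.kind.name, _canonical_value(e.value))


@dataclass(frozen=True)
class ObservationLog:
    """An individual's metadata plus time-ordered dated events.

    Events are sorted ascending by date, ties broken by kind name then by
    canonical payload serialization; no duplicate (date, kind) pair exists
    for the per-day-unique measurement kinds.
    """

    meta: IndividualMeta
    events: tuple[Event, ...] = ()

    def __post_init__(self) -> None:
        events = tuple(sorted(self.events, key=_event_sort_key))
        object.__setattr__(self, "events", events)
        seen: set[tuple[date, EventKind]] = set()
        for e in events:
            key = (e.date, e.kind)
            if e.kind in UNIQUE_PER_DAY:
                if key in seen:
                    raise LogError(
                        "BAD_PAYLOAD",
                        f"duplicate {e.kind.value} event on {e.date.isoformat()}",
                    )
                seen.add(key)

    def events_of(self, kind: EventKind) -> tuple[Event, ...]:
        return tuple(e for e in self.events if e.kind == kind)

    def capped(self, tier: int) -> "ObservationLog":
        """A copy containing only events readable at ``tier`` or below."""
        return ObservationLog(
            meta=self.meta, events=tuple(e for e in self.events if e.tier <= tier)
        )

    @property
    def first_date(self) -> Optional[date]:
        return self.events[0].date if self.events else None

    @property
    def last_date(self) -> Optional[date]:
        return self.events[-1].date if self.events else None


# ---------------------------------------------------------------------------
# Payload coercion


def _as_bool(raw: Any) -> bool:
    if isinstance(raw, bool):
        return raw
    if isinstance(raw, (int, float)) and raw in (0, 1):
        return bool(raw)
    if isinstance(raw, str):
        s = raw.strip().lower()
        if s in {"positive", "pos", "true", "yes", "1"}:
            return True
        if s in {"negative", "neg", "false", "no", "0"}:
            return False
    raise ValueError(f"cannot interpret {raw!r} as a test result")


def _coerce_payload(kind: EventKind, raw: Any) -> Any:
    if kind == EventKind.BLEED:
        if raw is None or raw == "":
            return None
        v = int(raw)
        if v < 0:
            raise ValueError("bleed volume rating must be non-negative")
        return v
    if kind == EventKind.LH_TEST:
        return _as_bool(raw)
    if kind == EventKind.BBT:
        v = float(raw)
        if not (BBT_MIN_C <= v <= BBT_MAX_C):
            raise ValueError(
                f"BBT {v} degC outside plausible range {BBT_MIN_C}-{BBT_MAX_C}"
            )
        return v
    if kind == EventKind.SERUM_P4:
        v = float(raw)
        if v < 0:
            raise ValueError("serum progesterone must be >= 0 nmol/L")
        return v
    if kind == EventKind.CERVICAL_MUCUS:
        v = int(raw)
        if v < 0:
            raise ValueError("cervical mucus score must be a non-negative ordinal")
        return v
    if kind == EventKind.SYMPTOM:
        if not isinstance(raw, Mapping):
            raise ValueError("symptom payload must be a name->score mapping")
        return {str(k): float(v) for k, v in raw.items()}
    if kind == EventKind.CONTRACEPTION:
        if isinstance(raw, ContraceptionRecord):
            return raw
        if isinstance(raw, Mapping):
            return ContraceptionRecord.from_dict(raw)
        raise ValueError("contraception payload must be a record mapping")
    if kind == EventKind.BLOOD_LOSS_ESTIMATE:
        v = float(raw)
        if v < 0:
            raise ValueError("blood loss must be >= 0 ml")
        return v
    raise ValueError(f"unhandled kind {kind}")  # pragma: no cover


def _decode_raw_value(raw: Any) -> Any:
    """CSV cells hold JSON-encoded payloads; tolerate bare strings."""
    if isinstance(raw, str):
        s = raw.strip()
        if s == "":
            return None
        try:
            return json.loads(s)
        except json.JSONDecodeError:
            return s
    if raw is None:
        return None
    try:  # pandas NaN
        if isinstance(raw, float) and raw != raw:
            return None
    except Exception:  # pragma: no cover
        pass
    return raw


# ---------------------------------------------------------------------------
# Parsing


def parse_event_log(
    rows: Union[Sequence[Mapping[str, Any]], "Any"],
    meta: Optional[IndividualMeta] = None,
) -> ObservationLog:
    """Parse tabular records with columns ``individual_id,date,kind,value``
    into a sorted, validated :class:`ObservationLog`.

    ``rows`` may be a sequence of mappings or a pandas DataFrame.  If
    ``meta`` is omitted a minimal one is built from the (single)
    individual_id found in the rows.

    Raises :class:`LogError` with code ``MIXED_INDIVIDUALS``, ``BAD_DATE``
    or ``BAD_PAYLOAD``, each naming the offending row index.
    """
    if hasattr(rows, "to_dict") and hasattr(rows, "columns"):  # DataFrame
        rows = rows.to_dict("records")
    rows = list(rows)
    if not rows:
        raise LogError("BAD_PAYLOAD", "no rows supplied")

    ids = {str(r.get("individual_id", "")) for r in rows}
    if len(ids) > 1:
        bad = next(
            i
            for i, r in enumerate(rows)
            if str(r.get("individual_id", "")) != str(rows[0].get("individual_id", ""))
        )
        raise LogError(
            "MIXED_INDIVIDUALS",
            f"rows mix individual ids {sorted(ids)}",
            row=bad,
        )
    individual_id = ids.pop()
    if meta is not None and meta.individual_id != individual_id:
        raise LogError(
            "MIXED_INDIVIDUALS",
            f"rows are for {individual_id!r} but meta is for {meta.individual_id!r}",
        )
    if meta is None:
        meta = IndividualMeta(individual_id=individual_id)

    events: list[Event] = []
    for i, r in enumerate(rows):
        raw_date = r.get("date")
        if isinstance(raw_date, date):
            d = raw_date
        else:
            try:
                d = date.fromisoformat(str(raw_date).strip())
            except (TypeError, ValueError):
                raise LogError(
                    "BAD_DATE", f"{raw_date!r} is not an ISO-8601 calendar date", row=i
                ) from None
        raw_kind = str(r.get("kind", "")).strip().upper()
        try:
            kind = EventKind(raw_kind)
        except ValueError:
            raise LogError(
                "BAD_PAYLOAD", f"unknown event kind {raw_kind!r}", row=i
            ) from None
        try:
            value = _coerce_payload(kind, _decode_raw_value(r.get("value")))
        except (ValueError, TypeError, KeyError) as exc:
            raise LogError("BAD_PAYLOAD", str(exc), row=i) from None
        events.append(Event(date=d, kind=kind, value=value))

    # Duplicate detection naming the row: ObservationLog re-checks, but
    # there it cannot say which input row collided.
    seen: dict[tuple[date, EventKind], int] = {}
    for i, e in enumerate(events):
        key = (e.date, e.kind)
        if e.kind in UNIQUE_PER_DAY:
            if key in seen:
                raise LogError(
                    "BAD_PAYLOAD",
                    f"duplicate {e.kind.value} event on {e.date.isoformat()} "
                    f"(first at row {seen[key]})",
                    row=i,
                )
            seen[key] = i

    return ObservationLog(meta=meta, events=tuple(events))


def validate_log(log: ObservationLog) -> list[LogWarningRecord]:
    """Non-fatal issues as structured warnings; the log is unchanged.

    Emitted warning kinds:

    * ``GAP`` -- more than 60 days between consecutive recorded events.
    * ``ORPHAN_P4`` -- a serum progesterone value with no positive urinary
      LH test on any earlier date (a mid-luteal blood draw is only
      interpretable 7-9 days after a positive surge test).
    """
    warnings: list[LogWarningRecord] = []
    dates = sorted({e.date for e in log.events})
    for a, b in zip(dates, dates[1:]):
        if (b - a).days > GAP_WARNING_DAYS:
            warnings.append(
                LogWarningRecord(
                    kind="GAP",
                    message=f"{(b - a).days}-day gap in tracking",
                    start=a,
                    end=b,
                )
            )
    positives = [e.date for e in log.events_of(EventKind.LH_TEST) if e.value]
    for e in log.events_of(EventKind.SERUM_P4):
        if not any(p < e.date for p in positives):
            warnings.append(
                LogWarningRecord(
                    kind="ORPHAN_P4",
                    message=(
                        "serum progesterone recorded with no preceding positive "
                        "urinary LH test"
                    ),
                    start=e.date,
                    end=e.date,
                )
            )
    return warnings


# ---------------------------------------------------------------------------
# File I/O

_META_PREFIX = "#meta "


def log_to_rows(log: ObservationLog) -> list[dict[str, str]]:
    return [
        {
            "individual_id": log.meta.individual_id,
            "date": e.date.isoformat(),
            "kind": e.kind.value,
            "value": _canonical_value(e.value),
        }
        for e in log.events
    ]


def write_csv(log: ObservationLog, path: Union[str, Path]) -> None:
    """Write the interchange CSV: a ``#meta`` JSON comment line, a header
    ``individual_id,date,kind,value``, then one JSON-valued row per event."""
    import csv

    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        fh.write(_META_PREFIX + json.dumps(log.meta.to_dict(), sort_keys=True) + "\n")
        writer = csv.DictWriter(fh, fieldnames=["individual_id", "date", "kind", "value"])
        writer.writeheader()
        writer.writerows(log_to_rows(log))


def read_csv(path: Union[str, Path]) -> ObservationLog:
    import csv

    path = Path(path)
    meta: Optional[IndividualMeta] = None
    with path.open("r", newline="", encoding="utf-8") as fh:
        first = fh.readline()
        if first.startswith(_META_PREFIX):
            meta = IndividualMeta.from_dict(json.loads(first[len(_META_PREFIX):]))
        else:
            fh.seek(0)
        rows = list(csv.DictReader(fh))
    return parse_event_log(rows, meta=meta)


def log_to_dict(log: ObservationLog) -> dict[str, Any]:
    return {
        "meta": log.meta.to_dict(),
        "events": [
            {
                "date": e.date.isoformat(),
                "kind": e.kind.value,
                "value": (
                    e.value.to_dict()
                    if isinstance(e.value, ContraceptionRecord)
                    else e.value
                ),
            }
            for e in log.events
        ],
    }


def log_from_dict(d: Mapping[str, Any]) -> ObservationLog:
    meta = IndividualMeta.from_dict(d["meta"])
    rows = [
        {
            "individual_id": meta.individual_id,
            "date": ev["date"],
            "kind": ev["kind"],
            "value": ev["value"],
        }
        for ev in d["events"]
    ]
    if not rows:
        return ObservationLog(meta=meta)
    return parse_event_log(rows, meta=meta)


def write_json(log: ObservationLog, path: Union[str, Path]) -> None:
    Path(path).write_text(
        json.dumps(log_to_dict(log), sort_keys=True, indent=1), encoding="utf-8"
    )


def read_json(path: Union[str, Path]) -> ObservationLog:
    return log_from_dict(json.loads(Path(path).read_text(encoding="utf-8")))
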