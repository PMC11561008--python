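"""Hormonal contraception taxonomy, regimen schedules, and monitoring
method compatibility.

Maps a :class:`~mhm.model.ContraceptionRecord` to one terminal code of the
contraception tree (O1.1-O2 pills, H1-H4 devices, B1.1 copper IUD), models
each method's schedule (active/hormone-free pill tiling, injection redose
interval, device replacement milestone), and reports which monitoring
methods remain usable for each method group.

Withdrawal bleeds -- bleeding during a hormone-free pill window -- are
annotated as *expected*, never counted as menstrual bleeds: the user has
not ovulated, the bleed follows the metabolism of the synthetic hormones.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace
from datetime import date, timedelta
from typing import Optional, Union

from .model import ContraceptionCategory, ContraceptionRecord, Regimen

__all__ = [
    "ContraceptionLeafCode",
    "OvulationSuppression",
    "DoseLevel",
    "Phase",
    "ScheduleModel",
    "ContraceptionLeaf",
    "DayType",
    "ScheduleDay",
    "ScheduleExpansion",
    "ContraceptionError",
    "NoScheduleError",
    "MonitoringMethod",
    "NATURAL",
    "classify_contraception",
    "expand_schedule",
    "compatible_methods",
    "EXTENDED_USE_REVIEW_REPEATS",
]

#: Extended active-pill use beyond this many repeats prompts medical review.
EXTENDED_USE_REVIEW_REPEATS = 3

#: Sentinel for a naturally menstruating individual in compatibility queries.
NATURAL = "NATURAL"


class ContraceptionError(ValueError):
    def __init__(self, code: str, message: str):
        self.code = code
        super().__init__(f"[{code}] {message}")


class NoScheduleError(ContraceptionError):
    def __init__(self, message: str):
        super().__init__("NO_SCHEDULE", message)


class ContraceptionLeafCode(str, enum.Enum):
    O1_1 = "O1.1"  # monophasic combined pill
    O1_2 = "O1.2"  # biphasic combined pill
    O1_3 = "O1.3"  # triphasic combined pill
    O2 = "O2"  # progestin-only "mini-pill"
    H1 = "H1"  # hormonal IUD
    H2 = "H2"  # hormonal implant
    H3 = "H3"  # vaginal ring
    H4 = "H4"  # injection
    B1_1 = "B1.1"  # copper IUD (non-hormonal)


class OvulationSuppression(str, enum.Enum):
    YES = "YES"
    LIKELY = "LIKELY"
    DECREASES_OVER_TIME = "DECREASES_OVER_TIME"
    NO = "NO"


class DoseLevel(str, enum.Enum):
    """Ordinal dose labels: published descriptions name no concentrations,
    only whether a dose is constant or steps up across the pill cycle."""

    CONSTANT = "constant"
    STEP_UP = "step-up"


@dataclass(frozen=True)
class Phase:
    span_days: int
    estrogen: DoseLevel
    progestin: DoseLevel


@dataclass(frozen=True)
class ScheduleModel:
    active_days: int
    hormone_free_days: int
    phase_structure: tuple[Phase, ...] = ()
    repeat_extended: int = 0  # hormone-free windows skipped per super-cycle
    redose_interval_weeks: Optional[int] = None
    wear_pattern: Optional[str] = None
    optional_pill_free: bool = False

    @property
    def regimen_days(self) -> int:
        return self.active_days + self.hormone_free_days


@dataclass(frozen=True)
class ContraceptionLeaf:
    code: ContraceptionLeafCode
    description: str
    ovulation_suppressed: OvulationSuppression
    schedule: Optional[ScheduleModel] = None
    replacement_years: Optional[int] = None


def _combined_phases(n: int) -> tuple[Phase, ...]:
    if n == 1:
        return (Phase(21, DoseLevel.CONSTANT, DoseLevel.CONSTANT),)
    if n == 2:
        # Progestin increases in the second half of the 21 hormone pills.
        return (
            Phase(11, DoseLevel.CONSTANT, DoseLevel.CONSTANT),
            Phase(10, DoseLevel.CONSTANT, DoseLevel.STEP_UP),
        )
    # Triphasic: progestin steps up every 7 days.
    return (
        Phase(7, DoseLevel.CONSTANT, DoseLevel.CONSTANT),
        Phase(7, DoseLevel.CONSTANT, DoseLevel.STEP_UP),
        Phase(7, DoseLevel.CONSTANT, DoseLevel.STEP_UP),
    )


_LEAVES: dict[ContraceptionLeafCode, ContraceptionLeaf] = {
    ContraceptionLeafCode.O1_1: ContraceptionLeaf(
        ContraceptionLeafCode.O1_1,
        description=(
            "Monophasic combined oral contraceptive pill: low doses of both "
            "ethinylestradiol and progestin, the dose staying the same "
            "throughout the 21 days of hormone pills; 7 hormone-free pills "
            "complete the cycle."
        ),
        ovulation_suppressed=OvulationSuppression.YES,
        schedule=ScheduleModel(21, 7, _combined_phases(1)),
    ),
    ContraceptionLeafCode.O1_2: ContraceptionLeaf(
        ContraceptionLeafCode.O1_2,
        description=(
            "Biphasic combined oral contraceptive pill: ethinylestradiol stays "
            "constant over the 21 hormone pills while the progestin dose "
            "increases in the second half of the pill cycle."
        ),
        ovulation_suppressed=OvulationSuppression.YES,
        schedule=ScheduleModel(21, 7, _combined_phases(2)),
    ),
    ContraceptionLeafCode.O1_3: ContraceptionLeaf(
        ContraceptionLeafCode.O1_3,
        description=(
            "Triphasic combined oral contraceptive pill: ethinylestradiol "
            "stays constant over the 21 hormone pills while progestin levels "
            "increase every 7 days."
        ),
        ovulation_suppressed=OvulationSuppression.YES,
        schedule=ScheduleModel(21, 7, _combined_phases(3)),
    ),
    ContraceptionLeafCode.O2: ContraceptionLeaf(
        ContraceptionLeafCode.O2,
        description=(
            "Progestin-only 'mini-pill': low doses of progestin for 28 days, "
            "unless the individual completes an optional 7-day pill-free "
            "period."
        ),
        ovulation_suppressed=OvulationSuppression.YES,
        schedule=ScheduleModel(
            28, 0, (Phase(28, DoseLevel.CONSTANT, DoseLevel.CONSTANT),),
            optional_pill_free=True,
        ),
    ),
    ContraceptionLeafCode.H1: ContraceptionLeaf(
        ContraceptionLeafCode.H1,
        description=(
            "Hormonal intrauterine device: slow-release progestin inside the "
            "uterus, typically lasting 5 years. The progestin dose decreases "
            "over time, so ovulation may start to occur more readily in the "
            "later years of the device's life."
        ),
        ovulation_suppressed=OvulationSuppression.DECREASES_OVER_TIME,
        replacement_years=5,
    ),
    ContraceptionLeafCode.H2: ContraceptionLeaf(
        ContraceptionLeafCode.H2,
        description=(
            "Hormonal implant: slow-release progestin rods under the skin of "
            "the upper arm, typically lasting 5 years; ovulation is likely to "
            "be suppressed for the duration of use."
        ),
        ovulation_suppressed=OvulationSuppression.LIKELY,
        replacement_years=5,
    ),
    ContraceptionLeafCode.H3: ContraceptionLeaf(
        ContraceptionLeafCode.H3,
        description=(
            "Vaginal ring: low doses of ethinylestradiol and progestin, "
            "typically worn 3 out of 4 weeks but wearable continuously."
        ),
        ovulation_suppressed=OvulationSuppression.YES,
        schedule=ScheduleModel(
            21, 7, (Phase(21, DoseLevel.CONSTANT, DoseLevel.CONSTANT),),
            wear_pattern="3 of 4 weeks",
        ),
    ),
    ContraceptionLeafCode.H4: ContraceptionLeaf(
        ContraceptionLeafCode.H4,
        description=(
            "Contraceptive injection: moderate doses of progestin requiring "
            "regular doses every 13 weeks."
        ),
        ovulation_suppressed=OvulationSuppression.YES,
        schedule=ScheduleModel(91, 0, (), redose_interval_weeks=13),
    ),
    ContraceptionLeafCode.B1_1: ContraceptionLeaf(
        ContraceptionLeafCode.B1_1,
        description=(
            "Copper intrauterine device: contains no synthetic hormones and "
            "does not stop ovulation; depending on the type it lasts 3, 5 or "
            "10 years. Users keep regular menstrual bleeds and are classified "
            "as naturally menstruating -- re-enter the natural-cycle tree."
        ),
        ovulation_suppressed=OvulationSuppression.NO,
        replacement_years=5,  # configurable: devices last 3, 5 or 10 years
    ),
}

_CATEGORY_TO_LEAF: dict[ContraceptionCategory, ContraceptionLeafCode] = {
    ContraceptionCategory.OCP_COMBINED_MONO: ContraceptionLeafCode.O1_1,
    ContraceptionCategory.OCP_COMBINED_BI: ContraceptionLeafCode.O1_2,
    ContraceptionCategory.OCP_COMBINED_TRI: ContraceptionLeafCode.O1_3,
    ContraceptionCategory.OCP_PROGESTIN_ONLY: ContraceptionLeafCode.O2,
    ContraceptionCategory.IUD_HORMONAL: ContraceptionLeafCode.H1,
    ContraceptionCategory.IMPLANT: ContraceptionLeafCode.H2,
    ContraceptionCategory.VAGINAL_RING: ContraceptionLeafCode.H3,
    ContraceptionCategory.INJECTION: ContraceptionLeafCode.H4,
    ContraceptionCategory.IUD_COPPER: ContraceptionLeafCode.B1_1,
}

OCP_LEAVES = frozenset(
    {
        ContraceptionLeafCode.O1_1,
        ContraceptionLeafCode.O1_2,
        ContraceptionLeafCode.O1_3,
        ContraceptionLeafCode.O2,
    }
)


def classify_contraception(rec: ContraceptionRecord) -> ContraceptionLeaf:
    """Deterministic mapping of a contraception record to its leaf.

    Pill subtypes are resolved by hormone content (combined vs
    progestin-only) and phase structure (mono/bi/tri); a copper IUD maps to
    B1.1 with the instruction to re-enter the naturally-menstruating path.
    A record's own regimen (active/hormone-free counts) and extended-use
    repeats override the standard schedule.
    """
    if rec.category == ContraceptionCategory.NONE:
        raise ContraceptionError(
            "UNKNOWN_CATEGORY", "no contraception in use; nothing to classify"
        )
    try:
        leaf = _LEAVES[_CATEGORY_TO_LEAF[rec.category]]
    except KeyError:
        raise ContraceptionError(
            "UNKNOWN_CATEGORY", f"unknown category {rec.category!r}"
        ) from None
    if leaf.schedule is not None and (rec.regimen or rec.extended_use_repeats):
        sched = leaf.schedule
        if rec.regimen is not None:
            sched = replace(
                sched,
                active_days=rec.regimen.active_days,
                hormone_free_days=rec.regimen.hormone_free_days,
            )
        if rec.extended_use_repeats:
            sched = replace(sched, repeat_extended=rec.extended_use_repeats)
        leaf = replace(leaf, schedule=sched)
    return leaf


# ---------------------------------------------------------------------------
# Schedule expansion


class DayType(str, enum.Enum):
    ACTIVE = "active"
    HORMONE_FREE = "hormone-free"
    REDOSE = "redose"
    REPLACEMENT = "replacement"


@dataclass(frozen=True)
class ScheduleDay:
    date: date
    day_index: int  # 1-based from the schedule start
    day_type: DayType
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class ScheduleExpansion:
    leaf: ContraceptionLeafCode
    days: tuple[ScheduleDay, ...]
    flags: frozenset[str]


#: Offsets (1-based) within a hormone-free window on which a withdrawal
#: bleed is expected: it typically begins 2-3 days after the last active
#: pill as the synthetic hormones are metabolized.
WITHDRAWAL_BLEED_WINDOW_OFFSETS = (2, 3, 4)


def expand_schedule(
    leaf: ContraceptionLeaf, start: date, horizon_days: int
) -> ScheduleExpansion:
    """Tile the leaf's regimen over ``horizon_days`` from ``start``.

    Extended use (``repeat_extended = k``) runs k+1 active blocks
    back-to-back before each hormone-free window; more than 3 repeats adds
    the EXTENDED_USE_REVIEW flag.  Expected-withdrawal-bleed marks fall
    only inside hormone-free windows.  Injections yield redose days at the
    13-week interval; devices (hormonal/copper IUD, implant) yield only
    their replacement milestone.
    """
    if horizon_days < 1:
        raise ValueError("horizon_days must be >= 1")
    flags: set[str] = set()
    days: list[ScheduleDay] = []

    sched = leaf.schedule
    if sched is None:
        if leaf.replacement_years is None:
            raise NoScheduleError(
                f"leaf {leaf.code.value} has neither a regimen nor a milestone"
            )
        milestone = start + timedelta(days=round(leaf.replacement_years * 365.25))
        if (milestone - start).days < horizon_days:
            days.append(
                ScheduleDay(
                    milestone,
                    (milestone - start).days + 1,
                    DayType.REPLACEMENT,
                    ("REPLACEMENT_DUE",),
                )
            )
        return ScheduleExpansion(leaf.code, tuple(days), frozenset(flags))

    if sched.repeat_extended > EXTENDED_USE_REVIEW_REPEATS:
        flags.add("EXTENDED_USE_REVIEW")

    if sched.redose_interval_weeks is not None:
        interval = sched.redose_interval_weeks * 7
        for i in range(horizon_days):
            d = start + timedelta(days=i)
            if i % interval == 0:
                days.append(ScheduleDay(d, i + 1, DayType.REDOSE, ("REDOSE_DUE",)))
            else:
                days.append(ScheduleDay(d, i + 1, DayType.ACTIVE))
        return ScheduleExpansion(leaf.code, tuple(days), frozenset(flags))

    active_block = sched.active_days * (sched.repeat_extended + 1)
    free = sched.hormone_free_days
    super_cycle = active_block + free
    for i in range(horizon_days):
        d = start + timedelta(days=i)
        pos = i % super_cycle
        if pos < active_block or free == 0:
            days.append(ScheduleDay(d, i + 1, DayType.ACTIVE))
        else:
            offset = pos - active_block + 1  # 1-based within the free window
            day_flags = (
                ("EXPECTED_WITHDRAWAL_BLEED",)
                if offset in WITHDRAWAL_BLEED_WINDOW_OFFSETS
                else ()
            )
            days.append(ScheduleDay(d, i + 1, DayType.HORMONE_FREE, day_flags))
    return ScheduleExpansion(leaf.code, tuple(days), frozenset(flags))


# ---------------------------------------------------------------------------
# Monitoring-method compatibility


class MonitoringMethod(str, enum.Enum):
    BLEED_DATES = "BLEED_DATES"  # recording any bleeding: universal
    CYCLE_DURATION = "CYCLE_DURATION"
    SYMPTOMS = "SYMPTOMS"
    URINARY_LH = "URINARY_LH"
    BBT = "BBT"
    CERVICAL_MUCUS = "CERVICAL_MUCUS"
    BLOOD_P4 = "BLOOD_P4"
    OCP_SCHEDULE = "OCP_SCHEDULE"
    OCP_BRAND = "OCP_BRAND"
    BLEED_VOLUME = "BLEED_VOLUME"  # per-menses loss rating


_NATURAL_METHODS: dict[MonitoringMethod, str] = {
    MonitoringMethod.BLEED_DATES: "record menstrual bleed days",
    MonitoringMethod.CYCLE_DURATION: (
        "track cycle length to judge regularity (prolonged > 35 days, "
        "short < 21 days)"
    ),
    MonitoringMethod.SYMPTOMS: "daily symptom survey at a consistent time of day",
    MonitoringMethod.URINARY_LH: (
        "urinary ovulation test for the LH surge, starting cycle day 8 until "
        "a positive result"
    ),
    MonitoringMethod.BBT: (
        "morning basal body temperature before any activity; progesterone "
        "raises it in the second half of the cycle"
    ),
    MonitoringMethod.CERVICAL_MUCUS: (
        "mucus consistency rating; thickens under luteal progesterone"
    ),
    MonitoringMethod.BLOOD_P4: (
        "mid-luteal blood progesterone 7-9 days after a positive urinary test"
    ),
    MonitoringMethod.BLEED_VOLUME: "per-menses blood-loss volume rating",
}


def compatible_methods(
    leaf_or_natural: Union[ContraceptionLeaf, ContraceptionLeafCode, str],
) -> dict[MonitoringMethod, str]:
    """Monitoring methods usable by the given method group, with notes.

    Urinary LH and blood progesterone are excluded for every hormonal
    method: synthetic hormones prevent the natural fluctuations those
    tests read.  Copper-IUD users count as naturally menstruating.
    """
    if isinstance(leaf_or_natural, ContraceptionLeaf):
        code: Union[str, ContraceptionLeafCode] = leaf_or_natural.code
    else:
        code = leaf_or_natural
    if code == NATURAL or code == ContraceptionLeafCode.B1_1:
        return dict(_NATURAL_METHODS)
    code = ContraceptionLeafCode(code)

    methods: dict[MonitoringMethod, str] = {
        MonitoringMethod.BLEED_DATES: (
            "record any bleeding; bleeds in hormone-free windows are "
            "withdrawal bleeds, not menstrual bleeds"
        ),
        MonitoringMethod.SYMPTOMS: "daily symptom survey at a consistent time of day",
        MonitoringMethod.BLEED_VOLUME: "per-bleed volume rating",
    }
    if code in OCP_LEAVES:
        methods[MonitoringMethod.BBT] = (
            "natural temperature changes may still be present in OCP users"
        )
        methods[MonitoringMethod.OCP_SCHEDULE] = (
            "review the schedule of use (21/7, extended active-pill use); "
            "medical advice for extended use beyond 3 repeats"
        )
        methods[MonitoringMethod.OCP_BRAND] = (
            "brand and generation review; synthetic hormone concentrations "
            "vary between brands and generations"
        )
    if code in (ContraceptionLeafCode.H1, ContraceptionLeafCode.H2):
        methods[MonitoringMethod.CERVICAL_MUCUS] = (
            "thickening of cervical mucus is a noted effect of the low-dose "
            "synthetic progestin"
        )
    return methods
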