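"""Dated monitoring-plan generation.

Builds a :class:`MonitoringPlan` -- a dated schedule of monitoring actions
at the published frequencies (daily symptom/BBT tracking; urinary LH
testing from cycle day 8 for up to 12 days per cycle; a confirmatory
mid-luteal blood test 7-9 days after a positive LH test, at most quarterly;
monthly pill-schedule and quarterly brand reviews for pill users) --
restricted by the monitoring tier cap and by method-group compatibility.

Disorder monitoring profiles (endometriosis, PCOS, PMS/PMDD, heavy
menstrual bleeding) add their published per-cycle and quarterly items.
Life-cycle stages beyond the premenopausal trees (pregnancy, postpartum,
peri-menopause, menopause) are enumerated but not implemented.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from datetime import date, timedelta
from typing import Iterable, Optional, Sequence, Union

from .classifier import ClassificationResult, MonitoringTier
from .contraception import (
    NATURAL,
    ContraceptionLeaf,
    ContraceptionLeafCode,
    MonitoringMethod,
    OCP_LEAVES,
    compatible_methods,
)

__all__ = [
    "Profile",
    "LifeStage",
    "PlanItem",
    "MonitoringPlan",
    "PlannerError",
    "BloodTestWindow",
    "build_plan",
    "lh_test_days",
    "blood_test_day",
    "life_stage_plan",
    "LH_TEST_START_DAY",
    "LH_TEST_MAX_COUNT",
    "BLOOD_TEST_OFFSET_DAYS",
    "BLOOD_TEST_WINDOW_DAYS",
    "QUARTER_DAYS",
    "MONTH_DAYS",
]

# Frequency conventions: "quarterly" = every 91 days from plan start,
# "monthly" = every 30 days.
QUARTER_DAYS = 91
MONTH_DAYS = 30

# Urinary LH testing starts on cycle day 8 and continues until a positive
# result, for roughly 6-12 days depending on cycle length.
LH_TEST_START_DAY = 8
LH_TEST_MAX_COUNT = 12

# Confirmatory blood test: 7-9 days after the positive urinary test; the
# plan targets the earliest window day.
BLOOD_TEST_OFFSET_DAYS = 7
BLOOD_TEST_WINDOW_DAYS = 3


class Profile(str, enum.Enum):
    DEFAULT = "DEFAULT"
    ENDOMETRIOSIS = "ENDOMETRIOSIS"
    PCOS = "PCOS"
    PMS_PMDD = "PMS_PMDD"
    HMB = "HMB"


class LifeStage(str, enum.Enum):
    PREGNANCY = "PREGNANCY"
    POSTPARTUM = "POSTPARTUM"
    PERI_MENOPAUSE = "PERI_MENOPAUSE"
    MENOPAUSE = "MENOPAUSE"


def life_stage_plan(stage: LifeStage) -> None:
    """Planning for life-cycle stages outside the premenopausal trees is a
    recognized future extension; each stage is enumerated but raises."""
    stage = LifeStage(stage)
    raise NotImplementedError(
        f"NOT_IMPLEMENTED: monitoring plans for the {stage.value} life stage "
        "are not provided by the premenopausal decision trees"
    )


class PlannerError(ValueError):
    def __init__(self, code: str, message: str, conflicts: Sequence[tuple] = ()):
        self.code = code
        self.conflicts = list(conflicts)
        super().__init__(f"[{code}] {message}")


@dataclass(frozen=True)
class PlanItem:
    date: date
    method: MonitoringMethod
    note: str
    tier: int


@dataclass(frozen=True)
class MonitoringPlan:
    individual_id: str
    start: date
    end: date
    items: tuple[PlanItem, ...]
    profile: Profile
    tier_cap: int

    def items_of(self, method: MonitoringMethod) -> tuple[PlanItem, ...]:
        return tuple(i for i in self.items if i.method == method)


@dataclass(frozen=True)
class BloodTestWindow:
    target: date
    earliest: date
    latest: date


def lh_test_days(cycle_start: date, expected_length: int) -> list[date]:
    """Scheduled urinary LH test dates for one cycle.

    Testing runs from cycle day 8 through
    ``min(8 + 11, expected_length - 7)`` -- at most 12 tests, stopping a
    week before the expected next onset (by then a surge would no longer
    leave a usable luteal window).  Re-planning truncates at the first
    recorded positive.
    """
    if expected_length < 21:
        raise PlannerError(
            "BAD_CYCLE_LENGTH",
            f"expected_length must be >= 21 days, got {expected_length}",
        )
    last_day = min(LH_TEST_START_DAY + LH_TEST_MAX_COUNT - 1, expected_length - 7)
    return [
        cycle_start + timedelta(days=d - 1)
        for d in range(LH_TEST_START_DAY, last_day + 1)
    ]


def blood_test_day(lh_positive: date) -> BloodTestWindow:
    """Confirmatory mid-luteal blood test window after a positive urinary
    LH test: target +7 days, acceptable +7 to +9."""
    target = lh_positive + timedelta(days=BLOOD_TEST_OFFSET_DAYS)
    return BloodTestWindow(
        target=target,
        earliest=target,
        latest=target + timedelta(days=BLOOD_TEST_WINDOW_DAYS - 1),
    )


# Tier of each plan method (what class of personal data the item records).
_METHOD_TIER: dict[MonitoringMethod, int] = {
    MonitoringMethod.BLEED_DATES: 0,
    MonitoringMethod.CYCLE_DURATION: 0,
    MonitoringMethod.OCP_SCHEDULE: 0,
    MonitoringMethod.OCP_BRAND: 0,
    MonitoringMethod.SYMPTOMS: 1,
    MonitoringMethod.BBT: 1,
    MonitoringMethod.CERVICAL_MUCUS: 1,
    MonitoringMethod.BLEED_VOLUME: 1,
    MonitoringMethod.URINARY_LH: 2,
    MonitoringMethod.BLOOD_P4: 3,
}

# Methods each disorder profile requires; a profile is incompatible when a
# required method is excluded for the group or sits above the tier cap.
_PROFILE_REQUIRES: dict[Profile, tuple[MonitoringMethod, ...]] = {
    Profile.DEFAULT: (),
    Profile.ENDOMETRIOSIS: (MonitoringMethod.SYMPTOMS,),
    Profile.PCOS: (MonitoringMethod.BLEED_DATES,),
    Profile.PMS_PMDD: (MonitoringMethod.SYMPTOMS,),
    Profile.HMB: (MonitoringMethod.BLEED_VOLUME,),
}


def _expected_cycle_starts(
    start: date, horizon_days: int, expected_length: int
) -> list[date]:
    return [
        start + timedelta(days=off)
        for off in range(0, horizon_days, expected_length)
    ]


def build_plan(
    status: Optional[ClassificationResult] = None,
    contraception: Union[ContraceptionLeaf, ContraceptionLeafCode, str] = NATURAL,
    start: Optional[date] = None,
    horizon_days: int = 91,
    profile: Profile = Profile.DEFAULT,
    tier_cap: Union[int, MonitoringTier] = MonitoringTier.BLOOD_TESTS,
    expected_cycle_length: Optional[int] = None,
    lh_positives: Sequence[date] = (),
    individual_id: Optional[str] = None,
) -> MonitoringPlan:
    """Build a dated monitoring plan.

    * Daily: bleed-date recording (tier 0, all groups); symptom survey and,
      where compatible, BBT (tier 1).
    * Per expected cycle: a cervical-mucus window note where compatible
      (tier 1); urinary LH tests on the scheduled block (tier 2, natural
      cycles only), truncated at the first recorded positive.
    * Per recorded positive LH test: one mid-luteal blood-test item at +7
      days (window to +9), tier 3, at most one per quarter.
    * Pill users: monthly schedule-of-use review and quarterly
      brand/generation review.
    * Disorder profiles add their published items (e.g. the heavy-bleeding
      profile adds per-cycle loss ratings, monthly fitness measures and a
      quarterly iron-status note).

    Raises ``INCOMPATIBLE_PROFILE`` when the profile requires a method the
    group excludes or the tier cap forbids.
    """
    if horizon_days < 1:
        raise PlannerError("BAD_HORIZON", "horizon_days must be >= 1")
    if start is None:
        start = status.as_of if status is not None else date.today()
    tier_cap = int(tier_cap)
    profile = Profile(profile)

    compat = compatible_methods(contraception)
    is_natural = contraception == NATURAL or (
        getattr(contraception, "code", contraception) == ContraceptionLeafCode.B1_1
    )
    leaf_code = None
    if not is_natural:
        leaf_code = (
            contraception.code
            if isinstance(contraception, ContraceptionLeaf)
            else ContraceptionLeafCode(contraception)
        )

    if individual_id is None:
        individual_id = status.individual_id if status is not None else ""
    if expected_cycle_length is None:
        expected_cycle_length = 28

    conflicts = []
    for method in _PROFILE_REQUIRES[profile]:
        if method not in compat:
            conflicts.append((profile.value, method.value, "excluded for this group"))
        elif _METHOD_TIER[method] > tier_cap:
            conflicts.append(
                (profile.value, method.value, f"above tier cap {tier_cap}")
            )
    if conflicts:
        raise PlannerError(
            "INCOMPATIBLE_PROFILE",
            f"profile {profile.value} requires methods unavailable here: {conflicts}",
            conflicts=conflicts,
        )

    end = start + timedelta(days=horizon_days - 1)
    items: dict[tuple[date, MonitoringMethod], PlanItem] = {}

    def add(d: date, method: MonitoringMethod, note: str) -> None:
        tier = _METHOD_TIER[method]
        if tier > tier_cap or method not in compat or not (start <= d <= end):
            return
        items.setdefault((d, method), PlanItem(d, method, note, tier))

    all_days = [start + timedelta(days=i) for i in range(horizon_days)]
    cycle_starts = _expected_cycle_starts(start, horizon_days, expected_cycle_length)

    for d in all_days:
        add(d, MonitoringMethod.BLEED_DATES, compat[MonitoringMethod.BLEED_DATES])
        add(d, MonitoringMethod.SYMPTOMS, compat.get(MonitoringMethod.SYMPTOMS, ""))
        if MonitoringMethod.BBT in compat:
            add(d, MonitoringMethod.BBT, compat[MonitoringMethod.BBT])

    if MonitoringMethod.CERVICAL_MUCUS in compat:
        for cs in cycle_starts:
            add(
                cs,
                MonitoringMethod.CERVICAL_MUCUS,
                "rate mucus consistency on ~1-4 days of your choosing this cycle",
            )

    if MonitoringMethod.URINARY_LH in compat:
        positives = sorted(lh_positives)
        for cs in cycle_starts:
            cycle_end = cs + timedelta(days=expected_cycle_length - 1)
            cutoff = next((p for p in positives if cs <= p <= cycle_end), None)
            for d in lh_test_days(cs, expected_cycle_length):
                if cutoff is not None and d > cutoff:
                    break
                add(
                    d,
                    MonitoringMethod.URINARY_LH,
                    "urinary LH test; stop for this cycle at the first positive",
                )

    if MonitoringMethod.BLOOD_P4 in compat:
        last_blood: Optional[date] = None
        for p in sorted(lh_positives):
            window = blood_test_day(p)
            if last_blood is not None and (window.target - last_blood).days < QUARTER_DAYS:
                continue  # blood testing is capped at quarterly frequency
            add(
                window.target,
                MonitoringMethod.BLOOD_P4,
                (
                    "mid-luteal blood progesterone; acceptable window "
                    f"{window.earliest.isoformat()} to {window.latest.isoformat()}"
                ),
            )
            if start <= window.target <= end:
                last_blood = window.target

    if leaf_code in OCP_LEAVES:
        for off in range(0, horizon_days, MONTH_DAYS):
            add(
                start + timedelta(days=off),
                MonitoringMethod.OCP_SCHEDULE,
                compat[MonitoringMethod.OCP_SCHEDULE],
            )
        for off in range(0, horizon_days, QUARTER_DAYS):
            add(
                start + timedelta(days=off),
                MonitoringMethod.OCP_BRAND,
                compat[MonitoringMethod.OCP_BRAND],
            )

    if profile == Profile.HMB:
        for cs in cycle_starts:
            add(
                cs,
                MonitoringMethod.BLEED_VOLUME,
                "rate volume lost per day during this menses; note duration",
            )
        for d in all_days:
            add(d, MonitoringMethod.SYMPTOMS, "wellness, readiness, sleep, fatigue")
        for off in range(0, horizon_days, MONTH_DAYS):
            add(
                start + timedelta(days=off),
                MonitoringMethod.BLEED_DATES,
                "fitness and exercise performance measures this month",
            )
        for off in range(0, horizon_days, QUARTER_DAYS):
            add(
                start + timedelta(days=off),
                MonitoringMethod.BLEED_VOLUME,
                "health biometrics review (specifically iron status)",
            )
    elif profile == Profile.ENDOMETRIOSIS:
        for cs in cycle_starts:
            add(
                cs,
                MonitoringMethod.SYMPTOMS,
                "per cycle: pain, fatigue, dose and frequency of pain medication",
            )
        for off in range(0, horizon_days, QUARTER_DAYS):
            add(
                start + timedelta(days=off),
                MonitoringMethod.SYMPTOMS,
                "quarterly nutrition and exercise programme review",
            )
    elif profile == Profile.PCOS:
        for cs in cycle_starts:
            add(
                cs,
                MonitoringMethod.BLEED_DATES,
                "per cycle: days and presence of menstrual bleeding",
            )
        for off in range(0, horizon_days, QUARTER_DAYS):
            add(
                start + timedelta(days=off),
                MonitoringMethod.BLEED_DATES,
                (
                    "quarterly nutrition, body composition, and health "
                    "biometrics (iron, inflammation, diabetic and CVD "
                    "parameters)"
                ),
            )
    elif profile == Profile.PMS_PMDD:
        for cs in cycle_starts:
            add(
                cs,
                MonitoringMethod.SYMPTOMS,
                (
                    "symptom window: expect augmented symptoms 1-5 days before "
                    "and 1-3 days during menstruation"
                ),
            )

    ordered = tuple(
        sorted(items.values(), key=lambda i: (i.date, i.tier, i.method.value))
    )
    return MonitoringPlan(
        individual_id=individual_id,
        start=start,
        end=end,
        items=ordered,
        profile=profile,
        tier_cap=tier_cap,
    )
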