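"""Menstrual cycle status classification.

Implements the basic status tree (menarche / primary amenorrhea /
contraception handoff / secondary amenorrhea) and the naturally
menstruating per-cycle tree, with:

* printed clinical thresholds collected in one overridable
  :class:`Thresholds` record;
* a *tier cap* privacy contract -- evidence above the requested monitoring
  tier is never read, so users can stop at a conservative node;
* an ordered node path (the evidence trail) in every result, which is a
  valid root-to-leaf walk in the declared tree adjacency;
* non-diagnostic review flags, each carrying the instruction
  "medical review required".

The tree adjacency lives in ``data/trees.yaml`` so alternative question
orders can be audited without touching this module.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field, fields, replace
from datetime import date, timedelta
from importlib import resources
from pathlib import Path
from typing import Any, Mapping, Optional, Union

import yaml

from .model import (
    EventKind,
    HORMONAL_CATEGORIES,
    ContraceptionCategory,
    ContraceptionRecord,
    ObservationLog,
)
from .segmentation import (
    AnnualBleeds,
    Cycle,
    SegmentationResult,
    bleeds_per_year,
    segment_cycles,
)

__all__ = [
    "LeafCode",
    "OvulationStatus",
    "ReviewFlag",
    "MonitoringTier",
    "Thresholds",
    "CycleCall",
    "ClassificationResult",
    "ClassifierError",
    "classify",
    "classify_natural_cycle",
    "review_flags",
    "leaf_info",
    "LeafInfo",
    "load_tree",
    "MEDICAL_REVIEW_INSTRUCTION",
    "MEDICAL_REVIEW_LEAVES",
]

MEDICAL_REVIEW_INSTRUCTION = "medical review required"


class LeafCode(str, enum.Enum):
    A1 = "A1"  # pre-menarche, under 15
    A2 = "A2"  # primary amenorrhea, medical review
    FHA = "FHA"  # functional hypothalamic / secondary amenorrhea
    B1 = "B1"  # naturally menstruating, ovulation untested
    B1_PROBABLE_OV = "B1_PROBABLE_OV"  # LH surge seen, no confirming blood test
    C1 = "C1"  # eumenorrheic: biphasic, confirmed ovulation
    D1 = "D1"  # luteal phase defect: low mid-luteal progesterone
    D2 = "D2"  # luteal phase defect: short cycle / short luteal phase
    E = "E"  # anovulatory cycle
    F = "F"  # oligomenorrheic / prolonged cycle
    HC = "HC"  # hormonal contraception handoff


class OvulationStatus(str, enum.Enum):
    UNKNOWN = "UNKNOWN"
    ABSENT = "ABSENT"
    PROBABLE = "PROBABLE"
    CONFIRMED = "CONFIRMED"


class ReviewFlag(str, enum.Enum):
    MEDICAL_REVIEW = "MEDICAL_REVIEW"
    HMB = "HMB"
    HMB_PERSISTENT = "HMB_PERSISTENT"
    SHORT_LUTEAL = "SHORT_LUTEAL"
    LOW_P4 = "LOW_P4"
    OLIGO = "OLIGO"
    AMENORRHEA = "AMENORRHEA"
    EXTRAPOLATED_COUNT = "EXTRAPOLATED_COUNT"


#: Leaves whose assignment always carries the medical-review flag.
MEDICAL_REVIEW_LEAVES = frozenset(
    {LeafCode.A2, LeafCode.FHA, LeafCode.D1, LeafCode.D2, LeafCode.F}
)


class MonitoringTier(enum.IntEnum):
    """Deepest class of personal data the classifier may read.

    0 = bleed dates only; 1 = + symptoms/BBT/mucus/loss ratings;
    2 = + urinary LH tests; 3 = + serum progesterone.
    """

    BLEED_DATES = 0
    SYMPTOMS = 1
    LH_TESTS = 2
    BLOOD_TESTS = 3


class ClassifierError(ValueError):
    def __init__(self, code: str, message: str):
        self.code = code
        super().__init__(f"[{code}] {message}")


@dataclass(frozen=True)
class Thresholds:
    """Printed clinical thresholds; defaults are the published values.

    Boundary semantics: the regular range 21-35 days is inclusive;
    prolonged is strictly > 35 days; the regular annual count is strictly
    > 9 bleeds (oligo at <= 9); eumenorrheic progesterone strictly
    > 16 nmol/L; short luteal strictly < 14 days; heavy menstrual bleeding
    strictly > 80 ml, persistent beyond (strictly more than) 7 cycles.
    """

    regular_min_days: int = 21
    regular_max_days: int = 35
    min_annual_bleeds_exclusive: int = 9
    short_luteal_exclusive_days: int = 14
    p4_confirm_exclusive_nmol_l: float = 16.0
    amenorrhea_months: int = 3
    primary_amenorrhea_age_years: float = 15
    primary_amenorrhea_age_no_secondary_years: float = 14
    hmb_exclusive_ml: float = 80.0
    hmb_complaint_cycles: int = 7

    def __post_init__(self) -> None:
        numeric = {f.name: getattr(self, f.name) for f in fields(self)}
        if any(v <= 0 for v in numeric.values()):
            raise ValueError("all thresholds must be positive")
        if self.regular_min_days >= self.regular_max_days:
            raise ValueError("regular_min_days must be < regular_max_days")

    @property
    def amenorrhea_days(self) -> int:
        # "3 months or more" operationalized as 30-day months.
        return self.amenorrhea_months * 30

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "Thresholds":
        """Load overrides from a YAML mapping; absent keys keep defaults."""
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown threshold keys: {sorted(unknown)}")
        return cls(**data)


DEFAULT_THRESHOLDS = Thresholds()


# ---------------------------------------------------------------------------
# Tree adjacency (data, not code)


def load_tree(path: Optional[Union[str, Path]] = None) -> dict[str, Any]:
    """Load the tree adjacency (the packaged default, or an override file)
    and validate that every edge targets a node, a known leaf, or the
    natural-subtree link."""
    if path is None:
        text = (
            resources.files("mhm").joinpath("data/trees.yaml").read_text("utf-8")
        )
    else:
        text = Path(path).read_text(encoding="utf-8")
    tree = yaml.safe_load(text)
    leaves = {c.value for c in LeafCode}
    for part in ("basic", "natural"):
        nodes = tree[part]["nodes"]
        if tree[part]["root"] not in nodes:
            raise ValueError(f"{part} tree root missing")
        for name, node in nodes.items():
            for ans in ("yes", "no"):
                target = node[ans]
                ok = target in nodes or target in leaves or target == "natural"
                if not ok:
                    raise ValueError(f"node {name}/{ans} targets unknown {target!r}")
    return tree


_DEFAULT_TREE = load_tree()


# ---------------------------------------------------------------------------
# Leaf descriptions

@dataclass(frozen=True)
class LeafInfo:
    code: LeafCode
    clinical: str
    non_clinical: str
    characteristics: str
    profile_id: str
    medical_review: bool


_LEAF_INFO: dict[LeafCode, LeafInfo] = {
    LeafCode.A1: LeafInfo(
        LeafCode.A1,
        clinical="Pre-menarche",
        non_clinical="First period has not happened yet",
        characteristics=(
            "Less than 15 years of age. Pre-commencement of the menstrual cycle."
        ),
        profile_id="pre-menarche-quiescent",
        medical_review=False,
    ),
    LeafCode.A2: LeafInfo(
        LeafCode.A2,
        clinical="Primary amenorrhea",
        non_clinical="No first menstrual bleed by the age of 15 years",
        characteristics=(
            "Absence of the first menstrual bleed by the age of 15 years despite "
            "secondary sex characteristics being present, or by the age of 14 "
            "years with no secondary sex characteristics present. Medical "
            "support is required for review of the absent menstrual cycle."
        ),
        profile_id="amenorrheic-flat",
        medical_review=True,
    ),
    LeafCode.FHA: LeafInfo(
        LeafCode.FHA,
        clinical="Functional hypothalamic amenorrhea / secondary amenorrhea",
        non_clinical="Menstrual bleeding has stopped for 3 months or more",
        characteristics=(
            "Absence of menstrual bleeding despite menarche having occurred, "
            "possibly resulting from psychological, nutritional or physical "
            "stressors. All other medical causes of amenorrhea must be excluded, "
            "and no medication or contraception explains the absence."
        ),
        profile_id="suppressed-flat",
        medical_review=True,
    ),
    LeafCode.B1: LeafInfo(
        LeafCode.B1,
        clinical="Naturally menstruating female",
        non_clinical=(
            "Regular menstrual bleeds without hormonal contraception; ovulation "
            "not yet tested"
        ),
        characteristics=(
            "Regular menstrual bleeds, typically within a 21-35 day cycle and "
            "more than 9 menstrual bleeds a year. Cannot be classified as "
            "eumenorrheic, luteal phase defect, or anovulatory because urinary "
            "ovulation (LH surge) tests and blood tests have not been completed."
        ),
        profile_id="presumed-biphasic-untested",
        medical_review=False,
    ),
    LeafCode.B1_PROBABLE_OV: LeafInfo(
        LeafCode.B1_PROBABLE_OV,
        clinical="Naturally menstruating, probable ovulation",
        non_clinical=(
            "Regular bleeds and a positive ovulation test; the confirming blood "
            "test has not been completed"
        ),
        characteristics=(
            "A positive urinary ovulation test makes ovulation probable. To "
            "confirm ovulation a progesterone blood test must be completed 7-9 "
            "days after the positive urinary test; without it the status stays "
            "at the naturally-menstruating node annotated probable."
        ),
        profile_id="probable-biphasic",
        medical_review=False,
    ),
    LeafCode.C1: LeafInfo(
        LeafCode.C1,
        clinical="Eumenorrheic biphasic cycle",
        non_clinical=(
            "Naturally menstruating with confirmed ovulation and confirmed "
            "hormone levels in both halves of the cycle"
        ),
        characteristics=(
            "Regular menstrual bleeds within a 21-35 day cycle; positive urine "
            "ovulation tests confirm the LH surge; the luteal phase is ~14 days "
            "and mid-luteal blood progesterone is > 16 nmol/L, confirming "
            "ovulation and two distinct hormonal phases (eumenorrheic)."
        ),
        profile_id="biphasic-ovulatory",
        medical_review=False,
    ),
    LeafCode.D1: LeafInfo(
        LeafCode.D1,
        clinical="Luteal phase defect: low mid-luteal progesterone",
        non_clinical=(
            "Ovulation confirmed but hormone levels in the second half of the "
            "cycle are inadequate"
        ),
        characteristics=(
            "21-35 day cycles, 9 or more cycles a year and positive urinary "
            "ovulation tests, but mid-luteal blood progesterone below 16 nmol/L. "
            "The presence of progesterone, even at low levels, confirms "
            "ovulation occurred. Medical review required."
        ),
        profile_id="biphasic-low-luteal-p4",
        medical_review=True,
    ),
    LeafCode.D2: LeafInfo(
        LeafCode.D2,
        clinical="Luteal phase defect: short luteal phase / short cycle",
        non_clinical=(
            "Short cycle: the next bleed starts fewer than 14 days after a "
            "positive ovulation test"
        ),
        characteristics=(
            "The onset of the subsequent menstrual bleed occurs < 14 days after "
            "a positive urinary ovulation test (LH surge occurred), or the whole "
            "cycle is shorter than 21 days. Probable ovulation; a blood test in "
            "the second half of the cycle and medical review are required. Often "
            "missed because cycle length may not change."
        ),
        profile_id="short-luteal-biphasic",
        medical_review=True,
    ),
    LeafCode.E: LeafInfo(
        LeafCode.E,
        clinical="Anovulatory cycle",
        non_clinical="Cycle without ovulation: no positive ovulation tests",
        characteristics=(
            "Regular menstrual bleeds (every 21-35 days, 9 or more cycles a "
            "year) but urinary ovulation tests are negative -- no LH surge "
            "detected. Lack of ovulation is confirmed by low mid-luteal blood "
            "progesterone."
        ),
        profile_id="monophasic-anovulatory",
        medical_review=False,
    ),
    LeafCode.F: LeafInfo(
        LeafCode.F,
        clinical="Oligomenorrheic",
        non_clinical="Extended cycle length; 9 or fewer menstrual bleeds per year",
        characteristics=(
            "Menstrual bleeds occur less regularly, every 35 days or more, with "
            "9 or fewer bleeds in a year. These cycles can be anovulatory or "
            "ovulatory; distinguishing them requires urinary ovulation testing "
            "and phase-specific blood tests. Medical review required."
        ),
        profile_id="prolonged-irregular",
        medical_review=True,
    ),
    LeafCode.HC: LeafInfo(
        LeafCode.HC,
        clinical="Hormonal contraception user",
        non_clinical="Using hormonal contraception",
        characteristics=(
            "Exogenous reproductive hormones suppress endogenous hormone levels "
            "and may inhibit ovulation for the duration of use. Continue with "
            "the contraception classification to identify the method and its "
            "schedule; bleeding in hormone-free windows is a withdrawal bleed, "
            "not a menstrual bleed."
        ),
        profile_id="exogenous-hormone",
        medical_review=False,
    ),
}


def leaf_info(code: Union[LeafCode, str]) -> LeafInfo:
    """Description record for a leaf code; raises ``UNKNOWN_CODE`` for
    anything outside the taxonomy."""
    try:
        code = LeafCode(code)
    except ValueError:
        raise ClassifierError("UNKNOWN_CODE", f"{code!r} is not a leaf code") from None
    return _LEAF_INFO[code]


# ---------------------------------------------------------------------------
# Results


@dataclass(frozen=True)
class CycleCall:
    cycle_index: int
    leaf: LeafCode
    ovulation_status: OvulationStatus
    path: tuple[tuple[str, str], ...]


@dataclass(frozen=True)
class ClassificationResult:
    leaf: LeafCode
    ovulation_status: OvulationStatus
    node_path: tuple[tuple[str, str], ...]
    review_flags: frozenset[ReviewFlag]
    per_cycle: tuple[CycleCall, ...]
    tier_used: int
    as_of: date
    individual_id: str
    contraception_category: Optional[ContraceptionCategory] = None
    flag_instructions: Mapping[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        return {
            "individual_id": self.individual_id,
            "as_of": self.as_of.isoformat(),
            "leaf": self.leaf.value,
            "ovulation_status": self.ovulation_status.value,
            "node_path": [list(step) for step in self.node_path],
            "review_flags": sorted(f.value for f in self.review_flags),
            "flag_instructions": {
                k: v for k, v in sorted(self.flag_instructions.items())
            },
            "per_cycle": [
                {
                    "cycle_index": c.cycle_index,
                    "leaf": c.leaf.value,
                    "ovulation_status": c.ovulation_status.value,
                }
                for c in self.per_cycle
            ],
            "tier_used": self.tier_used,
            "contraception_category": (
                self.contraception_category.value
                if self.contraception_category
                else None
            ),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)


# ---------------------------------------------------------------------------
# Per-cycle tree walk


def classify_natural_cycle(
    cycle: Cycle,
    annual: AnnualBleeds,
    cap: Union[int, MonitoringTier] = MonitoringTier.BLOOD_TESTS,
    th: Thresholds = DEFAULT_THRESHOLDS,
) -> CycleCall:
    """Walk the naturally-menstruating tree for one closed cycle.

    Evidence above the tier cap is treated as absent: urinary LH results
    are readable only at tier >= 2 and serum progesterone only at tier 3.
    An extrapolated (partial-coverage) annual count never answers the
    prolonged-cycle question.
    """
    if cycle.length_days is None:
        raise ClassifierError("OPEN_CYCLE", "cannot classify an open cycle")
    cap = int(cap)
    length = cycle.length_days
    path: list[tuple[str, str]] = []

    lh_readable = cap >= MonitoringTier.LH_TESTS and cycle.lh_tests_done > 0
    lh_positive = lh_readable and cycle.lh_positive_day is not None
    p4_mid = cycle.midluteal_p4_nmol_l if cap >= MonitoringTier.BLOOD_TESTS else None
    p4_any = (
        bool(cycle.p4_values) and cap >= MonitoringTier.BLOOD_TESTS
    )

    prolonged = length > th.regular_max_days or (
        not annual.extrapolated and annual.count <= th.min_annual_bleeds_exclusive
    )
    path.append(("q_prolonged", "yes" if prolonged else "no"))
    if prolonged:
        return CycleCall(cycle.index, LeafCode.F, OvulationStatus.UNKNOWN, tuple(path))

    short = length < th.regular_min_days
    path.append(("q_short", "yes" if short else "no"))
    if short:
        status = OvulationStatus.PROBABLE if lh_positive else OvulationStatus.UNKNOWN
        return CycleCall(cycle.index, LeafCode.D2, status, tuple(path))

    path.append(("q_lh_done", "yes" if lh_readable else "no"))
    if not lh_readable:
        return CycleCall(cycle.index, LeafCode.B1, OvulationStatus.UNKNOWN, tuple(path))

    path.append(("q_lh_pos", "yes" if lh_positive else "no"))
    if not lh_positive:
        return CycleCall(cycle.index, LeafCode.E, OvulationStatus.ABSENT, tuple(path))

    luteal = length - cycle.lh_positive_day + 1
    short_luteal = luteal < th.short_luteal_exclusive_days
    path.append(("q_luteal", "yes" if short_luteal else "no"))
    if short_luteal:
        confirmed = p4_any and any(v > 0 for v in cycle.p4_values)
        status = (
            OvulationStatus.CONFIRMED if confirmed else OvulationStatus.PROBABLE
        )
        return CycleCall(cycle.index, LeafCode.D2, status, tuple(path))

    p4_readable = p4_mid is not None
    path.append(("q_p4_done", "yes" if p4_readable else "no"))
    if not p4_readable:
        return CycleCall(
            cycle.index, LeafCode.B1_PROBABLE_OV, OvulationStatus.PROBABLE, tuple(path)
        )

    high = p4_mid > th.p4_confirm_exclusive_nmol_l
    path.append(("q_p4_high", "yes" if high else "no"))
    leaf = LeafCode.C1 if high else LeafCode.D1
    return CycleCall(cycle.index, leaf, OvulationStatus.CONFIRMED, tuple(path))


# ---------------------------------------------------------------------------
# Review flags (non-diagnostic)


def review_flags(
    log: ObservationLog,
    cycles: SegmentationResult,
    th: Thresholds = DEFAULT_THRESHOLDS,
) -> set[ReviewFlag]:
    """Evidence-level review flags from segmented cycles.

    Heavy menstrual bleeding: any menses with loss strictly over 80 ml
    raises ``HMB``; losses over the threshold in strictly more than 7
    cycles escalate to ``HMB_PERSISTENT``.  Short-luteal and low-P4
    evidence mirror the corresponding leaf criteria.  Flags are review
    prompts, never diagnoses.
    """
    flags: set[ReviewFlag] = set()
    heavy = [
        c
        for c in cycles.cycles
        if c.blood_loss_ml is not None and c.blood_loss_ml > th.hmb_exclusive_ml
    ]
    if heavy:
        flags.add(ReviewFlag.HMB)
    if len(heavy) > th.hmb_complaint_cycles:
        flags.add(ReviewFlag.HMB_PERSISTENT)
    for c in cycles.closed_cycles:
        if (
            c.luteal_length_days is not None
            and c.luteal_length_days < th.short_luteal_exclusive_days
        ):
            flags.add(ReviewFlag.SHORT_LUTEAL)
        if (
            c.midluteal_p4_nmol_l is not None
            and c.lh_positive_day is not None
            and c.midluteal_p4_nmol_l <= th.p4_confirm_exclusive_nmol_l
        ):
            flags.add(ReviewFlag.LOW_P4)
    return flags


# ---------------------------------------------------------------------------
# Individual-level classification


def _active_contraception(
    log: ObservationLog, as_of: date
) -> Optional[ContraceptionRecord]:
    records = [
        e
        for e in log.events_of(EventKind.CONTRACEPTION)
        if e.date <= as_of
    ]
    if not records:
        return None
    latest = records[-1].value
    if latest.category == ContraceptionCategory.NONE:
        return None
    return latest


def classify(
    log: ObservationLog,
    cap: Union[int, MonitoringTier] = MonitoringTier.BLOOD_TESTS,
    as_of: Optional[date] = None,
    th: Thresholds = DEFAULT_THRESHOLDS,
) -> ClassificationResult:
    """Classify an individual's menstrual cycle status as of a date.

    Walks the basic tree: pre-menarche by age (A1/A2); hormonal
    contraception handoff (HC); secondary amenorrhea when no bleed occurred
    within the amenorrhea window (FHA); otherwise the naturally
    menstruating per-cycle tree.  The individual-level leaf is the most
    recent closed cycle's leaf, except that the oligomenorrheic leaf F is
    decided on the 365-day window: it stands only when the fully observed
    annual bleed count is at or below the threshold; a single prolonged
    cycle with an adequate annual count is held at the conservative B1
    node (with the OLIGO flag retained as a review prompt).

    Evidence above ``cap`` is deleted before anything is computed, so
    classifying a capped log and classifying a log with the above-cap
    events removed are identical by construction.
    """
    cap = int(cap)
    filtered = log.capped(cap)
    if as_of is None:
        as_of = filtered.last_date
        if as_of is None:
            raise ClassifierError("EMPTY_LOG", "no events and no as_of date")
    meta = filtered.meta
    path: list[tuple[str, str]] = []
    flags: set[ReviewFlag] = set()

    has_bleeds = bool(filtered.events_of(EventKind.BLEED))
    menarche = meta.menarche_reached
    if menarche is None:
        menarche = has_bleeds

    tier_used = max((e.tier for e in filtered.events), default=0)

    def _result(
        leaf: LeafCode,
        status: OvulationStatus,
        per_cycle: tuple[CycleCall, ...] = (),
        contraception: Optional[ContraceptionCategory] = None,
    ) -> ClassificationResult:
        if leaf in MEDICAL_REVIEW_LEAVES:
            flags.add(ReviewFlag.MEDICAL_REVIEW)
        if flags & {ReviewFlag.HMB, ReviewFlag.HMB_PERSISTENT}:
            flags.add(ReviewFlag.MEDICAL_REVIEW)
        instructions = {f.value: MEDICAL_REVIEW_INSTRUCTION for f in flags}
        return ClassificationResult(
            leaf=leaf,
            ovulation_status=status,
            node_path=tuple(path),
            review_flags=frozenset(flags),
            per_cycle=per_cycle,
            tier_used=tier_used,
            as_of=as_of,
            individual_id=meta.individual_id,
            contraception_category=contraception,
            flag_instructions=instructions,
        )

    path.append(("q_menarche", "yes" if menarche else "no"))
    if not menarche:
        if meta.age_years is None:
            raise ClassifierError(
                "MISSING_AGE",
                "age is required to classify an individual without menarche",
            )
        primary = meta.age_years >= th.primary_amenorrhea_age_years or (
            meta.age_years >= th.primary_amenorrhea_age_no_secondary_years
            and meta.secondary_sex_characteristics_present is False
        )
        path.append(("q_age", "yes" if primary else "no"))
        if primary:
            flags.add(ReviewFlag.AMENORRHEA)
            return _result(LeafCode.A2, OvulationStatus.UNKNOWN)
        return _result(LeafCode.A1, OvulationStatus.UNKNOWN)

    contraception = _active_contraception(filtered, as_of)
    hormonal = contraception is not None and contraception.hormonal
    path.append(("q_contraception", "yes" if hormonal else "no"))
    if hormonal:
        return _result(
            LeafCode.HC, OvulationStatus.UNKNOWN, contraception=contraception.category
        )
    copper = contraception.category if contraception is not None else None

    bleed_dates = [e.date for e in filtered.events_of(EventKind.BLEED)]
    last_bleed = max(bleed_dates) if bleed_dates else None
    recent = last_bleed is not None and (as_of - last_bleed).days < th.amenorrhea_days
    path.append(("q_recent_bleed", "yes" if recent else "no"))
    if not recent:
        flags.add(ReviewFlag.AMENORRHEA)
        return _result(LeafCode.FHA, OvulationStatus.UNKNOWN, contraception=copper)

    seg = segment_cycles(filtered)
    annual = bleeds_per_year(filtered, as_of)
    flags |= review_flags(filtered, seg, th)

    per_cycle = tuple(
        classify_natural_cycle(c, annual, cap, th) for c in seg.closed_cycles
    )

    oligo_by_count = (
        not annual.extrapolated and annual.count <= th.min_annual_bleeds_exclusive
    )
    if annual.extrapolated and annual.count <= th.min_annual_bleeds_exclusive:
        flags.add(ReviewFlag.EXTRAPOLATED_COUNT)

    if not per_cycle:
        # Only an open cycle exists: hold at the conservative node.
        path.extend([("q_prolonged", "no"), ("q_short", "no"), ("q_lh_done", "no")])
        return _result(
            LeafCode.B1, OvulationStatus.UNKNOWN, per_cycle, contraception=copper
        )

    recent_call = per_cycle[-1]
    leaf, status = recent_call.leaf, recent_call.ovulation_status
    if any(
        c.length_days is not None and c.length_days > th.regular_max_days
        for c in seg.closed_cycles
    ) or oligo_by_count:
        flags.add(ReviewFlag.OLIGO)
    if leaf == LeafCode.F and not oligo_by_count:
        # A prolonged cycle without an oligomenorrheic annual pattern:
        # hold the individual at the conservative node.  The per-cycle
        # call keeps its F.
        path.extend([("q_prolonged", "no"), ("q_short", "no"), ("q_lh_done", "no")])
        return _result(
            LeafCode.B1, OvulationStatus.UNKNOWN, per_cycle, contraception=copper
        )
    path.extend(recent_call.path)
    return _result(leaf, status, per_cycle, contraception=copper)
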