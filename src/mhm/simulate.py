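"""Synthetic cycle simulator with ground truth.

Generates :class:`~mhm.model.ObservationLog` instances for every hormonal
phenotype on the published continuum (eumenorrheic, the two luteal-phase
defects, anovulatory, oligomenorrheic, functional hypothalamic amenorrhea,
primary amenorrhea) and for hormonal-contraception regimens, together with
a :class:`GroundTruth` record of the latent state (onsets, ovulation days,
the intended status leaf per cycle).  Every decision path of the
classification trees is therefore testable without any real health data.

Hormone curves are arbitrary-unit piecewise shapes: the published profiles
are qualitative, so only the ordinal relations are contractual -- the
follicular estrogen metabolite (E1G) peaks just before ovulation, the LH
spike marks ovulation day, and the progesterone metabolite (PdG) and serum
progesterone peak about 7 days after ovulation, with the serum plateau on
the true nmol/L scale (above 16 for eumenorrheic, below for the low-P4
defect, baseline for anovulatory).

Randomness is fully explicit: one global integer seed, with per-individual
streams derived from (seed, individual index).
"""

from __future__ import annotations

import enum
import hashlib
import json
from dataclasses import dataclass, field, replace
from datetime import date, timedelta
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .classifier import LeafCode, MonitoringTier, classify
from .contraception import classify_contraception, expand_schedule
from .model import (
    ContraceptionCategory,
    ContraceptionRecord,
    Event,
    EventKind,
    IndividualMeta,
    ObservationLog,
    Regimen,
)
from .planner import BLOOD_TEST_OFFSET_DAYS, lh_test_days

__all__ = [
    "Phenotype",
    "PhenotypeProfile",
    "DailyHormoneState",
    "NoiseSpec",
    "GroundTruth",
    "SimulationError",
    "PHENOTYPES",
    "NATURAL_PHENOTYPES",
    "LH_POSITIVE_THRESHOLD",
    "hormone_profile",
    "simulate_individual",
    "recovery_experiment",
    "RecoveryResult",
    "regular_history_log",
    "evenly_spaced_onsets_log",
    "amenorrhea_gap_log",
    "DEFAULT_START",
]

DEFAULT_START = date(2024, 1, 1)

# Urinary LH positivity threshold in the simulator's arbitrary units: the
# 1-day surge renders at 100 and baseline at 5, so threshold 50 keeps the
# spike positive and baseline negative with a >= 10x margin.
LH_POSITIVE_THRESHOLD = 50.0
LH_BASELINE = 5.0
LH_SURGE = 100.0

BBT_BASELINE_C = 36.4
SERUM_P4_BASELINE = 1.0


class SimulationError(ValueError):
    def __init__(self, code: str, message: str):
        self.code = code
        super().__init__(f"[{code}] {message}")


class Phenotype(str, enum.Enum):
    EUMENORRHEIC = "EUMENORRHEIC"
    LPD_LOW_P4 = "LPD_LOW_P4"
    LPD_SHORT = "LPD_SHORT"
    ANOVULATORY = "ANOVULATORY"
    OLIGO = "OLIGO"
    FHA = "FHA"
    PRIMARY_AMENORRHEA = "PRIMARY_AMENORRHEA"
    OCP_USER = "OCP_USER"
    HORMONAL_IUD_USER = "HORMONAL_IUD_USER"


@dataclass(frozen=True)
class PhenotypeProfile:
    """Generator parameters for one phenotype.

    ``cycle_length_dist`` is (mean, sd, min, max) in days, truncated to its
    support; ``ovulation_day_dist`` is (mean, sd), truncated so the luteal
    phase stays in the phenotype's intended range; ``luteal_days_target``
    pins the luteal length instead (short-luteal phenotype);
    ``luteal_p4_level`` is the mid-luteal serum plateau in nmol/L.
    """

    name: Phenotype
    intended_leaf: LeafCode
    cycle_length_dist: tuple[float, float, int, int] = (28.0, 2.0, 26, 32)
    ovulation_day_dist: Optional[tuple[float, float]] = (14.0, 1.5)
    luteal_days_target: Optional[tuple[int, int]] = None  # inclusive range
    luteal_p4_level: float = 30.0
    bbt_shift_c: float = 0.35
    bleed_duration_days: int = 5
    loss_ml_dist: tuple[float, float] = (40.0, 10.0)
    contraception: Optional[ContraceptionCategory] = None
    age_years: float = 28.0
    menarche_reached: bool = True
    bleeds: bool = True
    default_n_cycles: int = 6


PHENOTYPES: dict[Phenotype, PhenotypeProfile] = {
    Phenotype.EUMENORRHEIC: PhenotypeProfile(
        name=Phenotype.EUMENORRHEIC,
        intended_leaf=LeafCode.C1,
        luteal_p4_level=30.0,
    ),
    Phenotype.LPD_LOW_P4: PhenotypeProfile(
        name=Phenotype.LPD_LOW_P4,
        intended_leaf=LeafCode.D1,
        luteal_p4_level=10.0,
    ),
    Phenotype.LPD_SHORT: PhenotypeProfile(
        name=Phenotype.LPD_SHORT,
        intended_leaf=LeafCode.D2,
        cycle_length_dist=(27.0, 1.5, 26, 30),
        ovulation_day_dist=None,
        luteal_days_target=(11, 13),
        luteal_p4_level=18.0,
    ),
    Phenotype.ANOVULATORY: PhenotypeProfile(
        name=Phenotype.ANOVULATORY,
        intended_leaf=LeafCode.E,
        ovulation_day_dist=None,
        luteal_p4_level=0.0,
        bbt_shift_c=0.0,
    ),
    Phenotype.OLIGO: PhenotypeProfile(
        name=Phenotype.OLIGO,
        intended_leaf=LeafCode.F,
        cycle_length_dist=(45.0, 5.0, 42, 60),
        ovulation_day_dist=None,
        luteal_p4_level=0.0,
        bbt_shift_c=0.0,
        default_n_cycles=10,  # spans a full 365-day window
    ),
    Phenotype.FHA: PhenotypeProfile(
        name=Phenotype.FHA,
        intended_leaf=LeafCode.FHA,
        ovulation_day_dist=None,
        luteal_p4_level=0.0,
        bbt_shift_c=0.0,
        bleeds=False,
    ),
    Phenotype.PRIMARY_AMENORRHEA: PhenotypeProfile(
        name=Phenotype.PRIMARY_AMENORRHEA,
        intended_leaf=LeafCode.A2,
        ovulation_day_dist=None,
        luteal_p4_level=0.0,
        bbt_shift_c=0.0,
        bleeds=False,
        age_years=16.0,
        menarche_reached=False,
    ),
    Phenotype.OCP_USER: PhenotypeProfile(
        name=Phenotype.OCP_USER,
        intended_leaf=LeafCode.HC,
        ovulation_day_dist=None,
        luteal_p4_level=0.0,
        bbt_shift_c=0.0,
        contraception=ContraceptionCategory.OCP_COMBINED_MONO,
    ),
    Phenotype.HORMONAL_IUD_USER: PhenotypeProfile(
        name=Phenotype.HORMONAL_IUD_USER,
        intended_leaf=LeafCode.HC,
        ovulation_day_dist=None,
        luteal_p4_level=0.0,
        bbt_shift_c=0.0,
        bleeds=False,
        contraception=ContraceptionCategory.IUD_HORMONAL,
    ),
}

#: The natural phenotypes used in recovery experiments (one per leaf of the
#: naturally-menstruating tree reachable at full monitoring).
NATURAL_PHENOTYPES: tuple[Phenotype, ...] = (
    Phenotype.EUMENORRHEIC,
    Phenotype.LPD_LOW_P4,
    Phenotype.LPD_SHORT,
    Phenotype.ANOVULATORY,
    Phenotype.OLIGO,
    Phenotype.FHA,
    Phenotype.PRIMARY_AMENORRHEA,
)


@dataclass(frozen=True)
class NoiseSpec:
    """Observation-noise model.

    ``miss_rate`` drops each scheduled observation independently (survey
    fatigue); LH false rates flip individual test results; measurement
    noise is Gaussian.
    """

    bbt_sigma_c: float = 0.05
    p4_sigma_nmol_l: float = 0.5
    lh_false_positive: float = 0.02
    lh_false_negative: float = 0.02
    miss_rate: float = 0.10

    @classmethod
    def none(cls) -> "NoiseSpec":
        return cls(0.0, 0.0, 0.0, 0.0, 0.0)


@dataclass(frozen=True)
class DailyHormoneState:
    day: int  # 1-based cycle day
    e1g: float  # urinary estrogen metabolite, arbitrary units
    pdg: float  # urinary progesterone metabolite, arbitrary units
    lh: float  # arbitrary units
    fsh: float  # arbitrary units
    serum_p4_nmol_l: float  # latent serum progesterone


@dataclass(frozen=True)
class GroundTruth:
    phenotype: Phenotype
    intended_leaf: LeafCode
    onsets: tuple[date, ...]
    cycle_lengths: tuple[int, ...]  # closed cycles only
    ovulation_days: tuple[Optional[int], ...]  # per closed cycle
    luteal_days: tuple[Optional[int], ...]
    intended_cycle_leaves: tuple[LeafCode, ...]


def _rng_for(seed: int, individual_index: int) -> np.random.Generator:
    # Stable per-individual stream derived from (seed, index).
    return np.random.default_rng([int(seed), int(individual_index)])


def _trunc_normal_int(
    rng: np.random.Generator, mean: float, sd: float, lo: int, hi: int
) -> int:
    for _ in range(100):
        v = int(round(rng.normal(mean, sd)))
        if lo <= v <= hi:
            return v
    return int(np.clip(round(mean), lo, hi))


def hormone_profile(
    phenotype: Union[Phenotype, PhenotypeProfile],
    cycle_length: int,
    ovulation_day: Optional[int],
) -> list[DailyHormoneState]:
    """Latent daily hormone state over one cycle.

    Piecewise parametric shapes: follicular E1G rises to a pre-ovulatory
    peak (day before ovulation), LH spikes for one day at ovulation, and
    the luteal PdG / serum progesterone bell is centred near ovulation + 7
    with plateau ``luteal_p4_level`` (the short-luteal phenotype narrows
    and advances the bell so the phase ends early).  Anovulatory profiles
    stay at baseline with no LH surge.
    """
    profile = (
        phenotype
        if isinstance(phenotype, PhenotypeProfile)
        else PHENOTYPES[Phenotype(phenotype)]
    )
    lo, hi = profile.cycle_length_dist[2], profile.cycle_length_dist[3]
    if not (lo <= cycle_length <= hi):
        raise SimulationError(
            "BAD_PHENOTYPE",
            f"cycle length {cycle_length} outside {profile.name.value} support "
            f"[{lo}, {hi}]",
        )
    ovulatory = profile.ovulation_day_dist is not None or profile.luteal_days_target
    if ovulation_day is None and ovulatory:
        raise SimulationError(
            "BAD_PHENOTYPE", f"{profile.name.value} requires an ovulation day"
        )
    if ovulation_day is not None and not ovulatory:
        raise SimulationError(
            "BAD_PHENOTYPE",
            f"{profile.name.value} is anovulatory; ovulation_day must be None",
        )
    if ovulation_day is not None and not (2 <= ovulation_day <= cycle_length):
        raise SimulationError("BAD_PHENOTYPE", "ovulation day outside the cycle")

    short_luteal = profile.luteal_days_target is not None
    states = []
    for d in range(1, cycle_length + 1):
        if ovulation_day is not None:
            # E1G: follicular rise to a peak the day before ovulation, then
            # a fall and a modest luteal shoulder.
            if d < ovulation_day:
                e1g = 20.0 + 80.0 * d / max(ovulation_day - 1, 1)
            else:
                e1g = 30.0 + 20.0 * np.exp(
                    -((d - (ovulation_day + 7)) ** 2) / (2 * 4.0**2)
                )
            lh = LH_SURGE if d == ovulation_day else LH_BASELINE
            center = ovulation_day + (5 if short_luteal else 7)
            width = 2.5 if short_luteal else 4.0
            bell = float(np.exp(-((d - center) ** 2) / (2 * width**2)))
            plateau = profile.luteal_p4_level
            # Flat-topped bell: full plateau within ~2 days of the centre.
            p4 = SERUM_P4_BASELINE + max(plateau - SERUM_P4_BASELINE, 0.0) * (
                1.0 if abs(d - center) <= 2 else bell
            )
            p4 = p4 if d > ovulation_day else SERUM_P4_BASELINE
            pdg = p4 * 1.5  # urinary metabolite tracks serum with a gain
        else:
            e1g = 20.0 + 10.0 * np.sin(np.pi * d / cycle_length)
            lh = LH_BASELINE
            p4 = SERUM_P4_BASELINE
            pdg = p4 * 1.5
        fsh = 15.0 if d <= 4 else 8.0
        states.append(
            DailyHormoneState(
                day=d, e1g=float(e1g), pdg=float(pdg), lh=float(lh),
                fsh=float(fsh), serum_p4_nmol_l=float(p4),
            )
        )
    return states


def _draw_cycle(
    profile: PhenotypeProfile, rng: np.random.Generator
) -> tuple[int, Optional[int]]:
    mean, sd, lo, hi = profile.cycle_length_dist
    length = _trunc_normal_int(rng, mean, sd, lo, hi)
    if profile.luteal_days_target is not None:
        llo, lhi = profile.luteal_days_target
        # Keep the surge inside the scheduled urinary-test window (the
        # last scheduled test is cycle day 19), as for the other
        # ovulatory phenotypes: ovulation = length - luteal + 1 <= 19.
        llo = max(llo, length - 18)
        luteal = int(rng.integers(llo, lhi + 1))
        return length, length - luteal + 1
    if profile.ovulation_day_dist is None:
        return length, None
    om, osd = profile.ovulation_day_dist
    # Keep the luteal phase >= 14 days and the surge within the scheduled
    # urinary-test window.
    hi_ov = min(length - 14 + 1, 19)
    ov = _trunc_normal_int(rng, om, osd, 10, hi_ov)
    return length, ov


def simulate_individual(
    phenotype: Union[Phenotype, str],
    n_cycles: Optional[int] = None,
    noise: NoiseSpec = NoiseSpec(),
    seed: int = 0,
    individual_index: int = 0,
    start: date = DEFAULT_START,
    individual_id: Optional[str] = None,
) -> tuple[ObservationLog, GroundTruth]:
    """Simulate one individual's observation log plus its ground truth.

    ``n_cycles`` closed cycles are generated (plus the final open onset);
    latent hormones are rendered per cycle and then *observed*: urinary LH
    tests follow the planner's schedule (positive iff the latent LH is at
    or above the positivity threshold, flipped at the noise spec's false
    rates, stopping at the first recorded positive); a serum progesterone
    draw follows 7 days after a recorded positive; BBT is daily with the
    phenotype's post-ovulatory shift; bleeds run from each onset with a
    per-menses loss estimate attached to the first day.  Each scheduled
    observation is dropped independently with probability ``miss_rate``.
    """
    phenotype = Phenotype(phenotype)
    profile = PHENOTYPES[phenotype]
    if n_cycles is None:
        n_cycles = profile.default_n_cycles
    rng = _rng_for(seed, individual_index)
    if individual_id is None:
        individual_id = f"sim-{phenotype.value.lower()}-{seed}-{individual_index}"
    meta = IndividualMeta(
        individual_id=individual_id,
        age_years=profile.age_years,
        menarche_reached=profile.menarche_reached,
        secondary_sex_characteristics_present=True,
    )

    events: list[Event] = []

    def keep() -> bool:
        return noise.miss_rate <= 0 or rng.random() >= noise.miss_rate

    if profile.contraception is not None:
        return _simulate_contraception_user(
            profile, n_cycles, noise, rng, start, meta
        )

    if not profile.bleeds:
        # Amenorrheic phenotypes: daily BBT and weekly symptoms, no bleeds.
        horizon = 120
        for i in range(horizon):
            d = start + timedelta(days=i)
            if keep():
                events.append(
                    Event(d, EventKind.BBT,
                          float(np.clip(BBT_BASELINE_C + rng.normal(0, noise.bbt_sigma_c), 30, 45)))
                )
            if i % 7 == 0 and keep():
                events.append(
                    Event(d, EventKind.SYMPTOM, {"wellness": float(round(rng.uniform(3, 8), 1))})
                )
        log = ObservationLog(meta=meta, events=tuple(events))
        truth = GroundTruth(
            phenotype=phenotype,
            intended_leaf=profile.intended_leaf,
            onsets=(), cycle_lengths=(), ovulation_days=(), luteal_days=(),
            intended_cycle_leaves=(),
        )
        return log, truth

    lengths: list[int] = []
    ovulations: list[Optional[int]] = []
    for _ in range(n_cycles):
        length, ov = _draw_cycle(profile, rng)
        lengths.append(length)
        ovulations.append(ov)

    onsets: list[date] = []
    cursor = start
    for length in lengths:
        onsets.append(cursor)
        cursor += timedelta(days=length)
    final_onset = cursor
    onsets_all = onsets + [final_onset]
    expected_length = int(round(profile.cycle_length_dist[0]))

    for ci, (onset, length, ov) in enumerate(zip(onsets, lengths, ovulations)):
        hormones = hormone_profile(profile, length, ov)
        by_day = {h.day: h for h in hormones}

        for b in range(profile.bleed_duration_days):
            d = onset + timedelta(days=b)
            if d < onset + timedelta(days=length):
                events.append(Event(d, EventKind.BLEED, None))
        loss = float(
            np.clip(rng.normal(*profile.loss_ml_dist), 5.0, 500.0)
        )
        if keep():
            events.append(
                Event(onset, EventKind.BLOOD_LOSS_ESTIMATE, round(loss, 1))
            )

        for i in range(length):
            d = onset + timedelta(days=i)
            if not keep():
                continue
            day = i + 1
            shift = (
                profile.bbt_shift_c if (ov is not None and day > ov) else 0.0
            )
            temp = BBT_BASELINE_C + shift + rng.normal(0, noise.bbt_sigma_c)
            events.append(Event(d, EventKind.BBT, float(np.clip(round(temp, 2), 30, 45))))

        recorded_positive: Optional[date] = None
        for d in lh_test_days(onset, expected_length):
            if d >= onset + timedelta(days=length):
                break
            if recorded_positive is not None:
                break
            if not keep():
                continue
            day = (d - onset).days + 1
            latent_pos = by_day[day].lh >= LH_POSITIVE_THRESHOLD
            result = latent_pos
            if latent_pos and noise.lh_false_negative > 0:
                if rng.random() < noise.lh_false_negative:
                    result = False
            elif not latent_pos and noise.lh_false_positive > 0:
                if rng.random() < noise.lh_false_positive:
                    result = True
            events.append(Event(d, EventKind.LH_TEST, bool(result)))
            if result:
                recorded_positive = d

        if recorded_positive is not None:
            draw = recorded_positive + timedelta(days=BLOOD_TEST_OFFSET_DAYS)
            if draw < onset + timedelta(days=length) and keep():
                day = (draw - onset).days + 1
                value = by_day[day].serum_p4_nmol_l + rng.normal(
                    0, noise.p4_sigma_nmol_l
                )
                events.append(
                    Event(draw, EventKind.SERUM_P4, float(max(round(value, 1), 0.0)))
                )

    # Final open cycle: the closing onset's bleed days.
    for b in range(profile.bleed_duration_days):
        events.append(Event(final_onset + timedelta(days=b), EventKind.BLEED, None))

    log = ObservationLog(meta=meta, events=tuple(events))
    luteals = [
        (l - o + 1) if o is not None else None for l, o in zip(lengths, ovulations)
    ]
    truth = GroundTruth(
        phenotype=phenotype,
        intended_leaf=profile.intended_leaf,
        onsets=tuple(onsets_all),
        cycle_lengths=tuple(lengths),
        ovulation_days=tuple(ovulations),
        luteal_days=tuple(luteals),
        intended_cycle_leaves=tuple(profile.intended_leaf for _ in lengths),
    )
    return log, truth


def _simulate_contraception_user(
    profile: PhenotypeProfile,
    n_regimens: int,
    noise: NoiseSpec,
    rng: np.random.Generator,
    start: date,
    meta: IndividualMeta,
) -> tuple[ObservationLog, GroundTruth]:
    category = profile.contraception
    assert category is not None
    regimen = (
        Regimen(21, 7)
        if category == ContraceptionCategory.OCP_COMBINED_MONO
        else None
    )
    record = ContraceptionRecord(
        category=category, start_date=start, regimen=regimen
    )
    events: list[Event] = [Event(start, EventKind.CONTRACEPTION, record)]

    def keep() -> bool:
        return noise.miss_rate <= 0 or rng.random() >= noise.miss_rate

    leaf = classify_contraception(record)
    horizon = (
        n_regimens * leaf.schedule.regimen_days if leaf.schedule else n_regimens * 28
    )
    if leaf.schedule is not None:
        expansion = expand_schedule(leaf, start, horizon)
        for sd in expansion.days:
            if "EXPECTED_WITHDRAWAL_BLEED" in sd.flags and profile.bleeds:
                events.append(Event(sd.date, EventKind.BLEED, None))
    for i in range(horizon):
        d = start + timedelta(days=i)
        if keep():
            temp = BBT_BASELINE_C + rng.normal(0, noise.bbt_sigma_c)
            events.append(Event(d, EventKind.BBT, float(np.clip(round(temp, 2), 30, 45))))
        if i % 7 == 0 and keep():
            events.append(
                Event(d, EventKind.SYMPTOM, {"wellness": float(round(rng.uniform(3, 8), 1))})
            )
    log = ObservationLog(meta=meta, events=tuple(events))
    truth = GroundTruth(
        phenotype=profile.name,
        intended_leaf=profile.intended_leaf,
        onsets=(), cycle_lengths=(), ovulation_days=(), luteal_days=(),
        intended_cycle_leaves=(),
    )
    return log, truth


# ---------------------------------------------------------------------------
# Recovery experiments


@dataclass(frozen=True)
class RecoveryResult:
    confusion: pd.DataFrame  # intended (rows) x assigned (columns)
    recovery_rate: dict[str, float]
    n_per_phenotype: int

    @property
    def diagonal(self) -> bool:
        return all(rate == 1.0 for rate in self.recovery_rate.values())


def recovery_experiment(
    n_per_phenotype: int,
    noise: NoiseSpec = NoiseSpec.none(),
    cap: Union[int, MonitoringTier] = MonitoringTier.BLOOD_TESTS,
    seed: int = 0,
    phenotypes: Sequence[Phenotype] = NATURAL_PHENOTYPES,
    n_cycles: Optional[int] = None,
) -> RecoveryResult:
    """Simulate, classify, and cross-tabulate intended vs assigned leaf.

    Returns the confusion matrix (rows = intended leaf by phenotype,
    columns = assigned leaf) and the per-phenotype recovery rate, i.e. the
    fraction of simulated individuals assigned their intended leaf.
    """
    if n_per_phenotype < 1:
        raise ValueError("n_per_phenotype must be >= 1")
    rows = []
    idx = 0
    for ph in phenotypes:
        ph = Phenotype(ph)
        profile = PHENOTYPES[ph]
        for _ in range(n_per_phenotype):
            log, truth = simulate_individual(
                ph,
                n_cycles=n_cycles,
                noise=noise,
                seed=seed,
                individual_index=idx,
            )
            result = classify(log, cap=cap, as_of=log.last_date)
            rows.append(
                {
                    "phenotype": ph.value,
                    "intended": truth.intended_leaf.value,
                    "assigned": result.leaf.value,
                }
            )
            idx += 1
    frame = pd.DataFrame(rows)
    confusion = pd.crosstab(frame["intended"], frame["assigned"])
    recovery = {
        ph: float((sub["intended"] == sub["assigned"]).mean())
        for ph, sub in frame.groupby("phenotype")
    }
    return RecoveryResult(
        confusion=confusion, recovery_rate=recovery, n_per_phenotype=n_per_phenotype
    )


# ---------------------------------------------------------------------------
# Deterministic crafted logs (boundary sweeps and worked examples)


def _bleed_events(onset: date, n_days: int = 1) -> list[Event]:
    return [Event(onset + timedelta(days=i), EventKind.BLEED, None) for i in range(n_days)]


def regular_history_log(
    final_length: int,
    *,
    lh_day: Optional[int] = None,
    p4: Optional[float] = None,
    loss_ml: Optional[float] = None,
    prefix_cycles: int = 13,
    prefix_length: int = 28,
    start: date = date(2023, 1, 2),
    individual_id: str = "sweep",
) -> tuple[ObservationLog, date]:
    """A year of regular cycles followed by one closed cycle of
    ``final_length`` days carrying the requested evidence.

    The swept cycle can carry a positive urinary LH test on cycle day
    ``lh_day``, a serum progesterone value drawn 7 days later, and a
    per-menses loss estimate.  Returns the log and the as-of date (the
    final closing onset).
    """
    meta = IndividualMeta(
        individual_id=individual_id, age_years=30.0, menarche_reached=True
    )
    events: list[Event] = []
    for i in range(prefix_cycles):
        events += _bleed_events(start + timedelta(days=i * prefix_length))
    swept_onset = start + timedelta(days=prefix_cycles * prefix_length)
    events += _bleed_events(swept_onset)
    if lh_day is not None:
        lh_date = swept_onset + timedelta(days=lh_day - 1)
        events.append(Event(lh_date, EventKind.LH_TEST, True))
        if p4 is not None:
            events.append(
                Event(lh_date + timedelta(days=7), EventKind.SERUM_P4, float(p4))
            )
    if loss_ml is not None:
        events.append(
            Event(swept_onset, EventKind.BLOOD_LOSS_ESTIMATE, float(loss_ml))
        )
    closing = swept_onset + timedelta(days=final_length)
    events += _bleed_events(closing)
    return ObservationLog(meta=meta, events=tuple(events)), closing


def evenly_spaced_onsets_log(
    k: int,
    *,
    window_days: int = 365,
    start: date = date(2023, 1, 2),
    individual_id: str = "annual-sweep",
) -> tuple[ObservationLog, date]:
    """A fully observed window with ``k`` evenly spaced bleed onsets;
    returns the log and the as-of date (the window's last day)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    spacing = window_days // k
    meta = IndividualMeta(
        individual_id=individual_id, age_years=30.0, menarche_reached=True
    )
    events: list[Event] = [
        Event(start, EventKind.SYMPTOM, {"note": 1.0})  # anchors full coverage
    ]
    for i in range(k):
        events += _bleed_events(start + timedelta(days=i * spacing))
    as_of = start + timedelta(days=window_days - 1)
    return ObservationLog(meta=meta, events=tuple(events)), as_of


def amenorrhea_gap_log(
    gap_days: int,
    *,
    prefix_cycles: int = 6,
    prefix_length: int = 28,
    start: date = date(2023, 6, 5),
    individual_id: str = "gap-sweep",
) -> tuple[ObservationLog, date]:
    """Regular single-day bleeds followed by a terminal bleed-free gap of
    exactly ``gap_days`` before the as-of date."""
    meta = IndividualMeta(
        individual_id=individual_id, age_years=30.0, menarche_reached=True
    )
    events: list[Event] = []
    for i in range(prefix_cycles + 1):
        events += _bleed_events(start + timedelta(days=i * prefix_length))
    last_bleed = start + timedelta(days=prefix_cycles * prefix_length)
    as_of = last_bleed + timedelta(days=gap_days)
    return ObservationLog(meta=meta, events=tuple(events)), as_of
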