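"""Decision-tree classification: leaves, flags, paths, tier caps."""

from __future__ import annotations

from datetime import date, timedelta

import pytest

from mhm.classifier import (
    ClassifierError,
    LeafCode,
    MonitoringTier,
    OvulationStatus,
    ReviewFlag,
    Thresholds,
    classify,
    classify_natural_cycle,
    leaf_info,
    load_tree,
    review_flags,
)
from mhm.model import (
    ContraceptionCategory,
    ContraceptionRecord,
    Event,
    EventKind,
    IndividualMeta,
    ObservationLog,
)
from mhm.segmentation import AnnualBleeds, SegmentationResult, segment_cycles
from mhm.simulate import (
    NoiseSpec,
    Phenotype,
    amenorrhea_gap_log,
    regular_history_log,
    simulate_individual,
)

from conftest import bleed_run, make_cycle

FULL_YEAR = AnnualBleeds(count=13, coverage=1.0, extrapolated=False, observed_onsets=13)


def meta_no_menarche(age, secondary=True):
    return IndividualMeta(
        individual_id="x",
        age_years=age,
        menarche_reached=False,
        secondary_sex_characteristics_present=secondary,
    )


class TestBasicTree:
    def test_pre_menarche_under_15_is_a1(self):
        log = ObservationLog(meta=meta_no_menarche(13))
        result = classify(log, cap=0, as_of=date(2024, 1, 1))
        assert result.leaf == LeafCode.A1
        assert ReviewFlag.MEDICAL_REVIEW not in result.review_flags

    def test_no_menarche_at_16_is_primary_amenorrhea(self):
        log = ObservationLog(meta=meta_no_menarche(16))
        result = classify(log, cap=0, as_of=date(2024, 1, 1))
        assert result.leaf == LeafCode.A2
        assert ReviewFlag.MEDICAL_REVIEW in result.review_flags

    def test_age_14_without_secondary_characteristics_is_a2(self):
        log = ObservationLog(meta=meta_no_menarche(14, secondary=False))
        assert classify(log, cap=0, as_of=date(2024, 1, 1)).leaf == LeafCode.A2
        log2 = ObservationLog(meta=meta_no_menarche(14, secondary=True))
        assert classify(log2, cap=0, as_of=date(2024, 1, 1)).leaf == LeafCode.A1

    def test_missing_age_without_menarche_raises(self):
        log = ObservationLog(
            meta=IndividualMeta(individual_id="x", menarche_reached=False)
        )
        with pytest.raises(ClassifierError) as exc:
            classify(log, cap=0, as_of=date(2024, 1, 1))
        assert exc.value.code == "MISSING_AGE"

    def test_120_day_bleed_gap_is_secondary_amenorrhea(self):
        log, as_of = amenorrhea_gap_log(120)
        result = classify(log, cap=0, as_of=as_of)
        assert result.leaf == LeafCode.FHA
        assert {ReviewFlag.MEDICAL_REVIEW, ReviewFlag.AMENORRHEA} <= result.review_flags

    def test_hormonal_contraception_hands_off_to_hc(self, adult_meta):
        rec = ContraceptionRecord(
            category=ContraceptionCategory.OCP_COMBINED_MONO,
            start_date=date(2024, 1, 1),
        )
        log = ObservationLog(
            meta=adult_meta,
            events=(Event(date(2024, 1, 1), EventKind.CONTRACEPTION, rec),),
        )
        result = classify(log, cap=0, as_of=date(2024, 3, 1))
        assert result.leaf == LeafCode.HC
        assert result.contraception_category == ContraceptionCategory.OCP_COMBINED_MONO

    def test_copper_iud_user_stays_naturally_menstruating(self, adult_meta):
        d0 = date(2023, 1, 2)
        events = [
            Event(
                d0,
                EventKind.CONTRACEPTION,
                ContraceptionRecord(
                    category=ContraceptionCategory.IUD_COPPER, start_date=d0
                ),
            )
        ]
        for i in range(14):
            events += bleed_run(d0 + timedelta(days=28 * i), 1)
        log = ObservationLog(meta=adult_meta, events=tuple(events))
        result = classify(log, cap=0, as_of=d0 + timedelta(days=13 * 28))
        assert result.leaf == LeafCode.B1

    def test_empty_log_without_as_of_raises(self, adult_meta):
        with pytest.raises(ClassifierError) as exc:
            classify(ObservationLog(meta=adult_meta))
        assert exc.value.code == "EMPTY_LOG"


class TestNaturalCycleTree:
    @pytest.mark.parametrize(
        "kwargs, cap, expected_leaf, expected_status",
        [
            (dict(length=28, lh_day=14, p4=20.0), 3, LeafCode.C1, OvulationStatus.CONFIRMED),
            (dict(length=28, lh_day=14, p4=12.0), 3, LeafCode.D1, OvulationStatus.CONFIRMED),
            (dict(length=28, n_lh_tests=10), 3, LeafCode.E, OvulationStatus.ABSENT),
            (dict(length=40), 0, LeafCode.F, OvulationStatus.UNKNOWN),
            (dict(length=40), 3, LeafCode.F, OvulationStatus.UNKNOWN),
            (dict(length=28, lh_day=14), 2, LeafCode.B1_PROBABLE_OV, OvulationStatus.PROBABLE),
            (dict(length=28), 0, LeafCode.B1, OvulationStatus.UNKNOWN),
            (dict(length=19), 3, LeafCode.D2, OvulationStatus.UNKNOWN),
            (dict(length=24, lh_day=16, p4=18.0), 3, LeafCode.D2, OvulationStatus.CONFIRMED),
            (dict(length=24, lh_day=16), 2, LeafCode.D2, OvulationStatus.PROBABLE),
        ],
    )
    def test_leaf_assignments(self, kwargs, cap, expected_leaf, expected_status):
        call = classify_natural_cycle(make_cycle(**kwargs), FULL_YEAR, cap=cap)
        assert (call.leaf, call.ovulation_status) == (expected_leaf, expected_status)

    def test_annual_oligo_triggers_f_even_for_regular_length(self):
        sparse = AnnualBleeds(count=8, coverage=1.0, extrapolated=False, observed_onsets=8)
        call = classify_natural_cycle(make_cycle(30), sparse, cap=0)
        assert call.leaf == LeafCode.F

    def test_extrapolated_low_count_never_triggers_f(self):
        partial = AnnualBleeds(count=8.5, coverage=0.4, extrapolated=True, observed_onsets=3)
        call = classify_natural_cycle(make_cycle(30), partial, cap=0)
        assert call.leaf == LeafCode.B1


class TestIndividualAggregation:
    def test_single_prolonged_cycle_with_adequate_annual_count_holds_at_b1(self):
        # One 40-day cycle inside a year of regular bleeds: the per-cycle
        # call is prolonged but the individual is not oligomenorrheic.
        log, as_of = regular_history_log(40)
        result = classify(log, cap=0, as_of=as_of)
        assert result.per_cycle[-1].leaf == LeafCode.F
        assert result.leaf == LeafCode.B1
        assert ReviewFlag.OLIGO in result.review_flags

    def test_open_cycle_only_is_conservative_b1(self, adult_meta):
        d0 = date(2024, 1, 1)
        log = ObservationLog(meta=adult_meta, events=tuple(bleed_run(d0, 3)))
        result = classify(log, cap=3, as_of=d0 + timedelta(days=10))
        assert result.leaf == LeafCode.B1
        assert result.per_cycle == ()


class TestReviewFlags:
    def _seg(self, *cycles):
        return SegmentationResult(cycles=tuple(cycles), no_bleeds=False)

    def test_hmb_is_strictly_over_80_ml(self, adult_meta):
        log = ObservationLog(meta=adult_meta)
        at_80 = self._seg(make_cycle(28, loss=80.0))
        over = self._seg(make_cycle(28, loss=95.0))
        assert review_flags(log, at_80) == set()
        assert review_flags(log, over) == {ReviewFlag.HMB}

    def test_hmb_persistent_needs_more_than_7_cycles(self, adult_meta):
        log = ObservationLog(meta=adult_meta)
        seven = self._seg(
            *(make_cycle(28, index=i + 1, loss=90.0) for i in range(7))
        )
        eight = self._seg(
            *(make_cycle(28, index=i + 1, loss=90.0) for i in range(8))
        )
        assert review_flags(log, seven) == {ReviewFlag.HMB}
        assert review_flags(log, eight) == {ReviewFlag.HMB, ReviewFlag.HMB_PERSISTENT}

    def test_short_luteal_and_low_p4_mirror_leaf_evidence(self, adult_meta):
        log = ObservationLog(meta=adult_meta)
        seg = self._seg(
            make_cycle(24, index=1, lh_day=16, p4=18.0),  # luteal 9 < 14
            make_cycle(28, index=2, lh_day=14, p4=10.0),  # p4 <= 16
        )
        flags = review_flags(log, seg)
        assert {ReviewFlag.SHORT_LUTEAL, ReviewFlag.LOW_P4} <= flags

    def test_every_flag_carries_the_review_instruction(self):
        log, as_of = regular_history_log(28, loss_ml=95.0)
        result = classify(log, cap=3, as_of=as_of)
        assert ReviewFlag.HMB in result.review_flags
        assert set(result.flag_instructions.values()) == {"medical review required"}


class TestLeafInfo:
    def test_c1_is_eumenorrheic_biphasic(self):
        info = leaf_info("C1")
        assert "eumenorrheic" in (info.clinical + info.characteristics).lower()
        assert info.profile_id == "biphasic-ovulatory"

    def test_f_requires_medical_review(self):
        info = leaf_info(LeafCode.F)
        assert "Oligomenorrheic" in info.clinical
        assert info.medical_review

    def test_unknown_code_rejected(self):
        with pytest.raises(ClassifierError) as exc:
            leaf_info("Z9")
        assert exc.value.code == "UNKNOWN_CODE"

    def test_every_leaf_has_info_and_profile(self):
        seen = {leaf_info(code).profile_id for code in LeafCode}
        assert len(seen) == len(LeafCode)  # profile ids are distinct


class TestContracts:
    def test_classification_is_deterministic_and_serializable(self):
        log, _ = simulate_individual(Phenotype.EUMENORRHEIC, noise=NoiseSpec(), seed=13)
        a = classify(log, cap=3, as_of=log.last_date)
        b = classify(log, cap=3, as_of=log.last_date)
        assert a.to_json() == b.to_json()

    @pytest.mark.parametrize("phenotype", list(Phenotype))
    @pytest.mark.parametrize("cap", [0, 1, 2, 3])
    def test_node_path_is_a_valid_tree_walk(self, phenotype, cap):
        tree = load_tree()
        nodes = {**tree["basic"]["nodes"], **tree["natural"]["nodes"]}
        log, _ = simulate_individual(phenotype, noise=NoiseSpec.none(), seed=5)
        result = classify(log, cap=cap, as_of=log.last_date)
        position = tree["basic"]["root"]
        for question, answer in result.node_path:
            assert question == position
            position = nodes[question][answer]
            if position == "natural":
                position = tree["natural"]["root"]
        assert position == result.leaf.value

    def test_thresholds_yaml_overrides(self, tmp_path):
        path = tmp_path / "th.yaml"
        path.write_text("regular_max_days: 40\n", encoding="utf-8")
        th = Thresholds.from_yaml(path)
        assert th.regular_max_days == 40
        assert th.regular_min_days == 21  # untouched default
        bad = tmp_path / "bad.yaml"
        bad.write_text("not_a_key: 1\n", encoding="utf-8")
        with pytest.raises(ValueError):
            Thresholds.from_yaml(bad)
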