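"""Contraception taxonomy, schedule models and method compatibility."""

from __future__ import annotations

from datetime import date, timedelta

import pytest

from mhm.contraception import (
    ContraceptionError,
    ContraceptionLeafCode,
    DayType,
    DoseLevel,
    MonitoringMethod,
    NATURAL,
    OvulationSuppression,
    classify_contraception,
    compatible_methods,
    expand_schedule,
)
from mhm.model import ContraceptionCategory, ContraceptionRecord, Regimen

START = date(2024, 1, 1)


def record(category, **kwargs):
    return ContraceptionRecord(category=category, start_date=START, **kwargs)


class TestClassifyContraception:
    def test_total_and_injective_on_categories(self):
        cats = [c for c in ContraceptionCategory if c != ContraceptionCategory.NONE]
        leaves = [classify_contraception(record(c)).code for c in cats]
        assert len(set(leaves)) == len(cats)

    def test_none_category_rejected(self):
        with pytest.raises(ContraceptionError) as exc:
            classify_contraception(record(ContraceptionCategory.NONE))
        assert exc.value.code == "UNKNOWN_CATEGORY"

    def test_triphasic_has_three_weekly_progestin_steps(self):
        leaf = classify_contraception(record(ContraceptionCategory.OCP_COMBINED_TRI))
        assert leaf.code == ContraceptionLeafCode.O1_3
        phases = leaf.schedule.phase_structure
        assert [p.span_days for p in phases] == [7, 7, 7]
        assert [p.progestin for p in phases[1:]] == [DoseLevel.STEP_UP] * 2
        assert all(p.estrogen == DoseLevel.CONSTANT for p in phases)

    def test_copper_iud_routes_back_to_natural(self):
        leaf = classify_contraception(record(ContraceptionCategory.IUD_COPPER))
        assert leaf.code == ContraceptionLeafCode.B1_1
        assert leaf.ovulation_suppressed == OvulationSuppression.NO

    def test_injection_redoses_every_13_weeks(self):
        leaf = classify_contraception(record(ContraceptionCategory.INJECTION))
        assert leaf.code == ContraceptionLeafCode.H4
        assert leaf.schedule.redose_interval_weeks == 13

    def test_hormonal_iud_suppression_decreases_over_time(self):
        leaf = classify_contraception(record(ContraceptionCategory.IUD_HORMONAL))
        assert leaf.ovulation_suppressed == OvulationSuppression.DECREASES_OVER_TIME

    def test_standard_combined_pill_is_21_active_7_free(self):
        leaf = classify_contraception(record(ContraceptionCategory.OCP_COMBINED_MONO))
        assert (leaf.schedule.active_days, leaf.schedule.hormone_free_days) == (21, 7)

    def test_record_regimen_and_extended_use_override_defaults(self):
        leaf = classify_contraception(
            record(
                ContraceptionCategory.OCP_COMBINED_MONO,
                regimen=Regimen(24, 4),
                extended_use_repeats=2,
            )
        )
        assert (leaf.schedule.active_days, leaf.schedule.hormone_free_days) == (24, 4)
        assert leaf.schedule.repeat_extended == 2


class TestExpandSchedule:
    def _mono(self, **kwargs):
        return classify_contraception(
            record(ContraceptionCategory.OCP_COMBINED_MONO, **kwargs)
        )

    def test_standard_tiling_over_two_regimens(self):
        days = expand_schedule(self._mono(), START, 56).days
        kinds = [d.day_type for d in days]
        assert kinds[:21] == [DayType.ACTIVE] * 21
        assert kinds[21:28] == [DayType.HORMONE_FREE] * 7
        assert kinds[28:49] == [DayType.ACTIVE] * 21
        assert kinds[49:56] == [DayType.HORMONE_FREE] * 7

    def test_extended_use_skips_hormone_free_windows(self):
        # Two extra active-block repeats: the first hormone-free day is
        # day 64 (after 3 x 21 active days).
        expansion = expand_schedule(self._mono(extended_use_repeats=2), START, 84)
        first_free = next(
            d.day_index for d in expansion.days if d.day_type == DayType.HORMONE_FREE
        )
        assert first_free == 64
        assert "EXTENDED_USE_REVIEW" not in expansion.flags

    def test_more_than_three_repeats_flags_review(self):
        expansion = expand_schedule(self._mono(extended_use_repeats=4), START, 120)
        assert "EXTENDED_USE_REVIEW" in expansion.flags

    def test_tiling_conserves_days_over_whole_regimens(self):
        for repeats in range(0, 4):
            leaf = self._mono(extended_use_repeats=repeats or 0)
            regimen = 21 * (repeats + 1) + 7
            for reps in (1, 3):
                days = expand_schedule(leaf, START, regimen * reps).days
                active = sum(1 for d in days if d.day_type == DayType.ACTIVE)
                free = sum(1 for d in days if d.day_type == DayType.HORMONE_FREE)
                assert active == 21 * (repeats + 1) * reps
                assert free == 7 * reps

    @pytest.mark.parametrize(
        "category",
        [
            ContraceptionCategory.OCP_COMBINED_MONO,
            ContraceptionCategory.OCP_COMBINED_BI,
            ContraceptionCategory.OCP_COMBINED_TRI,
            ContraceptionCategory.OCP_PROGESTIN_ONLY,
            ContraceptionCategory.VAGINAL_RING,
            ContraceptionCategory.INJECTION,
        ],
    )
    @pytest.mark.parametrize("horizon", [28, 365, 730])
    @pytest.mark.parametrize("repeats", [0, 2, 6])
    def test_withdrawal_marks_only_in_hormone_free_windows(
        self, category, horizon, repeats
    ):
        kwargs = {"extended_use_repeats": repeats} if category in (
            ContraceptionCategory.OCP_COMBINED_MONO,
            ContraceptionCategory.OCP_COMBINED_BI,
            ContraceptionCategory.OCP_COMBINED_TRI,
        ) else {}
        leaf = classify_contraception(record(category, **kwargs))
        days = expand_schedule(leaf, START, horizon).days
        for d in days:
            if "EXPECTED_WITHDRAWAL_BLEED" in d.flags:
                assert d.day_type == DayType.HORMONE_FREE

    def test_progestin_only_default_has_no_free_window(self):
        leaf = classify_contraception(record(ContraceptionCategory.OCP_PROGESTIN_ONLY))
        days = expand_schedule(leaf, START, 56).days
        assert all(d.day_type == DayType.ACTIVE for d in days)

    def test_devices_yield_replacement_milestone_only(self):
        leaf = classify_contraception(record(ContraceptionCategory.IUD_HORMONAL))
        horizon = 6 * 365
        days = expand_schedule(leaf, START, horizon).days
        assert len(days) == 1
        assert days[0].day_type == DayType.REPLACEMENT
        assert abs((days[0].date - START).days - round(5 * 365.25)) == 0

    def test_injection_redose_days(self):
        leaf = classify_contraception(record(ContraceptionCategory.INJECTION))
        days = expand_schedule(leaf, START, 200).days
        redose = [d.day_index for d in days if d.day_type == DayType.REDOSE]
        assert redose == [1, 92, 183]  # every 13 weeks = 91 days


class TestCompatibleMethods:
    def test_natural_group_can_use_every_method(self):
        methods = compatible_methods(NATURAL)
        assert MonitoringMethod.URINARY_LH in methods
        assert MonitoringMethod.BLOOD_P4 in methods
        assert MonitoringMethod.CYCLE_DURATION in methods

    def test_copper_iud_counts_as_natural(self):
        assert compatible_methods(ContraceptionLeafCode.B1_1) == compatible_methods(
            NATURAL
        )

    def test_pill_users_lose_cycle_and_blood_methods_keep_symptoms(self):
        methods = compatible_methods(ContraceptionLeafCode.O1_1)
        assert MonitoringMethod.SYMPTOMS in methods
        assert MonitoringMethod.BBT in methods  # with a caveat note
        assert "natural temperature changes" in methods[MonitoringMethod.BBT]
        for excluded in (
            MonitoringMethod.CYCLE_DURATION,
            MonitoringMethod.URINARY_LH,
            MonitoringMethod.BLOOD_P4,
            MonitoringMethod.CERVICAL_MUCUS,
        ):
            assert excluded not in methods

    def test_hormonal_iud_and_implant_add_cervical_mucus(self):
        for code in (ContraceptionLeafCode.H1, ContraceptionLeafCode.H2):
            methods = compatible_methods(code)
            assert MonitoringMethod.CERVICAL_MUCUS in methods
            assert MonitoringMethod.URINARY_LH not in methods
            assert MonitoringMethod.BLOOD_P4 not in methods

    def test_no_hormonal_leaf_can_use_lh_or_blood_tests(self):
        for code in ContraceptionLeafCode:
            if code == ContraceptionLeafCode.B1_1:
                continue
            methods = compatible_methods(code)
            assert MonitoringMethod.URINARY_LH not in methods
            assert MonitoringMethod.BLOOD_P4 not in methods
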