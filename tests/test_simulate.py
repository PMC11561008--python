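"""Simulator: hormone curves, determinism, observation model, recovery."""

from __future__ import annotations

import hashlib

import numpy as np
import pytest

from mhm.classifier import LeafCode, classify
from mhm.model import EventKind, log_to_dict
from mhm.segmentation import segment_cycles
from mhm.simulate import (
    LH_POSITIVE_THRESHOLD,
    NATURAL_PHENOTYPES,
    NoiseSpec,
    Phenotype,
    SimulationError,
    hormone_profile,
    recovery_experiment,
    simulate_individual,
)

from oracle import flat_cycle_leaf


class TestHormoneProfile:
    def test_eumenorrheic_curve_shape(self):
        states = hormone_profile(Phenotype.EUMENORRHEIC, 28, 14)
        lh = [s.lh for s in states]
        assert int(np.argmax(lh)) + 1 == 14  # LH spike on ovulation day
        day21 = states[20]
        assert day21.serum_p4_nmol_l > 16  # mid-luteal plateau above threshold
        # PdG and serum P4 peak strictly after the LH peak.
        p4 = [s.serum_p4_nmol_l for s in states]
        assert int(np.argmax(p4)) + 1 > 14
        # E1G peaks before ovulation.
        e1g = [s.e1g for s in states]
        assert int(np.argmax(e1g)) + 1 < 14

    def test_anovulatory_profile_stays_at_baseline(self):
        states = hormone_profile(Phenotype.ANOVULATORY, 28, None)
        assert max(s.lh for s in states) < LH_POSITIVE_THRESHOLD
        assert len({s.serum_p4_nmol_l for s in states}) == 1  # flat baseline

    def test_low_p4_defect_plateau_is_under_threshold(self):
        states = hormone_profile(Phenotype.LPD_LOW_P4, 28, 14)
        plateau = max(s.serum_p4_nmol_l for s in states)
        assert 0 < plateau <= 16

    @pytest.mark.parametrize(
        "phenotype, length, ov",
        [
            (Phenotype.ANOVULATORY, 28, 14),  # ovulation day for anovulatory
            (Phenotype.EUMENORRHEIC, 28, None),  # missing ovulation day
            (Phenotype.EUMENORRHEIC, 99, 14),  # length outside support
        ],
    )
    def test_bad_phenotype_combinations_rejected(self, phenotype, length, ov):
        with pytest.raises(SimulationError) as exc:
            hormone_profile(phenotype, length, ov)
        assert exc.value.code == "BAD_PHENOTYPE"


class TestDeterminism:
    def test_same_seed_gives_byte_identical_logs(self):
        import json

        a, _ = simulate_individual(Phenotype.EUMENORRHEIC, noise=NoiseSpec(), seed=7)
        b, _ = simulate_individual(Phenotype.EUMENORRHEIC, noise=NoiseSpec(), seed=7)
        assert json.dumps(log_to_dict(a)) == json.dumps(log_to_dict(b))

    def test_distinct_seeds_give_distinct_logs(self):
        import json

        hashes = set()
        for seed in range(5):
            log, _ = simulate_individual(
                Phenotype.EUMENORRHEIC, noise=NoiseSpec(), seed=seed
            )
            hashes.add(hashlib.sha256(json.dumps(log_to_dict(log)).encode()).hexdigest())
        assert len(hashes) == 5


class TestObservationModel:
    def test_eumenorrheic_noise_free_recovers_c1_every_cycle(self):
        log, truth = simulate_individual(
            Phenotype.EUMENORRHEIC, n_cycles=6, noise=NoiseSpec.none(), seed=7
        )
        result = classify(log, cap=3, as_of=log.last_date)
        assert [c.leaf for c in result.per_cycle] == [LeafCode.C1] * 6
        assert result.leaf == LeafCode.C1

    def test_ocp_user_bleeds_only_in_hormone_free_windows(self):
        log, truth = simulate_individual(
            Phenotype.OCP_USER, n_cycles=3, noise=NoiseSpec.none(), seed=3
        )
        # Standard 21/7 regimen: bleed-like events only on hormone-free days.
        start = log.events_of(EventKind.CONTRACEPTION)[0].date
        for e in log.events_of(EventKind.BLEED):
            offset = (e.date - start).days % 28
            assert 21 <= offset <= 27
        assert classify(log, cap=0, as_of=log.last_date).leaf == LeafCode.HC
        assert truth.intended_leaf == LeafCode.HC

    def test_no_excluded_event_kinds_for_hormonal_users(self):
        for phenotype in (Phenotype.OCP_USER, Phenotype.HORMONAL_IUD_USER):
            log, _ = simulate_individual(phenotype, noise=NoiseSpec(), seed=8)
            assert not log.events_of(EventKind.LH_TEST)
            assert not log.events_of(EventKind.SERUM_P4)

    def test_ground_truth_agrees_with_flat_predicate_oracle(self):
        # Two-oracle validation of the generator's intent: evidence derived
        # from the latent truth must map to the intended leaf under the
        # independent flat predicates before it is used to judge the tree.
        for phenotype in (
            Phenotype.EUMENORRHEIC,
            Phenotype.LPD_LOW_P4,
            Phenotype.LPD_SHORT,
            Phenotype.ANOVULATORY,
            Phenotype.OLIGO,
        ):
            log, truth = simulate_individual(
                phenotype, noise=NoiseSpec.none(), seed=17
            )
            seg = segment_cycles(log)
            annual_oligo = phenotype == Phenotype.OLIGO
            for cycle, intended in zip(seg.closed_cycles, truth.intended_cycle_leaves):
                leaf, _ = flat_cycle_leaf(
                    length=cycle.length_days,
                    annual_count=5 if annual_oligo else 13,
                    annual_extrapolated=False,
                    cap=3,
                    n_lh_tests=cycle.lh_tests_done,
                    lh_positive_day=cycle.lh_positive_day,
                    p4=cycle.midluteal_p4_nmol_l,
                )
                assert leaf == intended.value


class TestRecoveryExperiment:
    def test_noise_free_small_run_is_diagonal(self):
        result = recovery_experiment(
            n_per_phenotype=5, noise=NoiseSpec.none(), cap=3, seed=2
        )
        assert result.diagonal
        assert set(result.recovery_rate) == {p.value for p in NATURAL_PHENOTYPES}

    def test_cap_zero_eumenorrheic_is_conservatively_b1(self):
        result = recovery_experiment(
            n_per_phenotype=8,
            noise=NoiseSpec.none(),
            cap=0,
            seed=2,
            phenotypes=(Phenotype.EUMENORRHEIC,),
        )
        assert list(result.confusion.columns) == ["B1"]

    def test_missingness_degrades_confirmed_calls_monotonically(self):
        # With rising miss rates the share of confirmed eumenorrheic calls
        # falls monotonically; at moderate missingness the conservative
        # B1/B1_PROBABLE_OV share rises (at extreme missingness the missed
        # surge-day test converts cycles to apparently-anovulatory calls).
        rates = []
        conservative = []
        for miss in (0.0, 0.15, 0.3, 0.6):
            res = recovery_experiment(
                n_per_phenotype=40,
                noise=NoiseSpec(0.05, 0.5, 0.0, 0.0, miss),
                cap=3,
                seed=5,
                phenotypes=(Phenotype.EUMENORRHEIC,),
            )
            rates.append(res.recovery_rate["EUMENORRHEIC"])
            conf = res.confusion
            total = conf.to_numpy().sum()
            cons = sum(
                int(conf[c].iloc[0])
                for c in conf.columns
                if c in ("B1", "B1_PROBABLE_OV")
            )
            conservative.append(cons / total)
        assert rates == sorted(rates, reverse=True)
        assert rates[0] == 1.0 and rates[-1] < 0.5
        assert conservative[1] > conservative[0]
        assert conservative[2] > conservative[0]
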