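"""Outcome accounting: overdiagnosis, utilities, percent convention, paired runs."""

import copy
import math
from dataclasses import replace

import numpy as np
import pytest

from psa_mri_sim import config as cfgmod
from psa_mri_sim.demography import Person
from psa_mri_sim.natural_history import LifeHistory
from psa_mri_sim.outcomes import (
    UtilityConfigError,
    UtilityEntry,
    UtilityTable,
    classify_overdiagnosed,
    compute_utility_loss,
    derive_comparison,
    percent_change,
    run_paired_simulation,
)
from psa_mri_sim.reference_values import PUBLISHED_PER_1000
from psa_mri_sim.screening import ScreenOutcome
from psa_mri_sim.states import parse_state
from psa_mri_sim.synthetic import default_config


def history(dx_age, death_age):
    st = parse_state("T2_EQ7_M0")
    return LifeHistory(
        person=Person(0, death_age), onset_age=50.0, trajectory=[(st, 50.0)],
        clinical_dx_age=dx_age, state_at_clinical_dx=st if dx_age else None,
    )


def outcome(mode, age=None):
    return ScreenOutcome(detected=mode != "none", mode=mode, detection_age=age)


class TestOverdiagnosis:
    def test_dx_after_death_is_overdiagnosed(self):
        assert classify_overdiagnosed(history(70.0, 65.0), outcome("screen", 60.0))

    def test_dx_within_lifetime_is_not(self):
        assert not classify_overdiagnosed(history(63.0, 80.0), outcome("screen", 60.0))

    def test_never_diagnosed_counterfactual_is_overdiagnosed(self):
        assert classify_overdiagnosed(history(None, 80.0), outcome("screen", 60.0))

    def test_clinical_detection_never_overdiagnosed(self):
        assert not classify_overdiagnosed(history(70.0, 65.0), outcome("clinical", 70.0))


class TestUtilityLoss:
    def table(self):
        return UtilityTable(
            [
                UtilityEntry("mpmri", 0.96, 1 / 52),
                UtilityEntry("trusgb_biopsy", 0.90, 3 / 52),
                UtilityEntry("diagnosis", 0.80, 1 / 12),
            ]
        )

    def test_single_mpmri_event(self):
        loss = compute_utility_loss([("mpmri", 60.0)], self.table(), "mri")
        assert loss == pytest.approx(0.04 / 52)

    def test_mrigb_disutility_is_half_trusgb(self):
        t = self.table()
        loss_mri = compute_utility_loss([("screen_biopsy", 60.0)], t, "mri")
        loss_reg = compute_utility_loss([("screen_biopsy", 60.0)], t, "regular")
        assert loss_reg == pytest.approx(0.10 * 3 / 52)
        assert loss_mri == pytest.approx(0.5 * loss_reg)

    def test_empty_event_list(self):
        assert compute_utility_loss([], self.table(), "regular") == 0.0

    def test_truncation_at_death(self):
        # half the diagnosis state is lived
        loss = compute_utility_loss(
            [("diagnosis", 60.0)], self.table(), "regular", death_age=60.0 + 1 / 24
        )
        assert loss == pytest.approx(0.20 / 24)
        assert compute_utility_loss(
            [("diagnosis", 60.0)], self.table(), "regular", death_age=60.0) == 0.0

    def test_unmatched_label_is_configuration_error(self):
        with pytest.raises(UtilityConfigError, match="hospitalisation"):
            compute_utility_loss([("hospitalisation", 60.0)], self.table(), "regular")


class TestPercentConvention:
    @pytest.mark.parametrize(
        "regular, mri, expected",
        [
            (396.0, 278.0, -29.8),
            (36.0, 51.3, 29.8),
            (80.8, 58.9, -27.1),
            (15.6, 8.9, -42.9),
            (8.53, 8.77, 2.7),
            (1.8, 1.0, -44.4),
            (5.0, 5.0, 0.0),
        ],
    )
    def test_printed_convention(self, regular, mri, expected):
        assert percent_change(regular, mri) == pytest.approx(expected, abs=0.05)

    def test_both_zero(self):
        assert percent_change(0.0, 0.0) == 0.0


@pytest.fixture(scope="module")
def summary():
    return derive_comparison(PUBLISHED_PER_1000)


class TestDerivedArithmetic:
    """The published comparison's derived rows recomputed from its inputs."""

    def test_harm_benefit_ratios(self, summary):
        assert round(summary.harm_benefit_regular, 1) == 1.8
        assert round(summary.harm_benefit_mri, 1) == 1.0

    def test_biopsy_difference_and_percent(self, summary):
        row = summary.rows["men_biopsied"]
        assert row["difference"] == pytest.approx(118.0)
        assert round(row["percent_change"]) == -30

    def test_overdiagnosis_reduction(self, summary):
        assert round(summary.rows["overdiagnosed"]["percent_change"]) == -43

    def test_significant_cancer_increase(self, summary):
        assert summary.rows["significant_detected"]["percent_change"] == pytest.approx(
            29.8, abs=0.05
        )

    def test_deaths_averted_difference(self, summary):
        assert summary.rows["deaths_averted"]["difference"] == pytest.approx(0.24)

    def test_per_death_averted_ratios(self, summary):
        assert summary.rows["ly_gained_per_death_averted"]["regular"] == pytest.approx(
            9.57, abs=0.005
        )
        assert summary.rows["qaly_gained_per_death_averted"]["mri"] == pytest.approx(
            9.14, abs=0.005
        )

    def test_qaly_gained_difference(self, summary):
        assert summary.rows["qalys_gained"]["difference"] == pytest.approx(3.2)

    def test_undefined_ratio_sentinel_not_exception(self):
        vals = copy.deepcopy(PUBLISHED_PER_1000)
        vals["deaths_averted"] = {"regular": 0.0, "mri": 0.0}
        s = derive_comparison(vals)
        assert math.isnan(s.harm_benefit_regular) and math.isnan(s.harm_benefit_mri)


class TestPairedSimulation:
    def small_cfg(self, **raw_overrides):
        raw = default_config()
        raw.update(raw_overrides)
        return cfgmod.resolve_config(raw)

    def test_determinism_bit_identical(self):
        cfg = self.small_cfg()
        a = run_paired_simulation(2000, cfg, seed=5)
        b = run_paired_simulation(2000, cfg, seed=5)
        for arm_a, arm_b in zip(a[:3], b[:3]):
            assert arm_a == arm_b

    def test_zero_attendance_reduces_to_no_screening(self):
        raw = default_config()
        raw["screening"]["attendance"] = 0.0
        cfg = cfgmod.resolve_config(raw)
        ns, reg, mri, _, _ = run_paired_simulation(3000, cfg, seed=6)
        for arm in (reg, mri):
            assert arm.screen_detected == 0.0
            assert arm.pca_deaths == ns.pca_deaths
            assert arm.life_years == ns.life_years
            assert arm.overdiagnosed == 0.0

    def test_pathway_equivalence_identity(self):
        raw = default_config()
        raw["tests"].update(
            mpmri_sens_low=1.0, mpmri_sens_high=1.0,
            mrigb_sens_low=raw["tests"]["trusgb_sens"],
            mrigb_sens_high=raw["tests"]["trusgb_sens"],
            misclass_mrigb=raw["tests"]["misclass_regular"],
            ppv_mri=raw["tests"]["ppv_screen_regular"],
        )
        cfg = cfgmod.resolve_config(raw)
        _, reg, mri, records, _ = run_paired_simulation(4000, cfg, seed=7)
        for rec in records:
            a, b = rec.arms["regular"], rec.arms["mri"]
            assert (a.mode, a.detection_age, a.recorded_grade, a.death_age) == (
                b.mode, b.detection_age, b.recorded_grade, b.death_age)
        # MRIGB disutility still differs; everything else is identical
        assert reg.men_biopsied == mri.men_biopsied
        assert reg.significant_detected == mri.significant_detected
        assert reg.overdiagnosed == mri.overdiagnosed
        assert reg.pca_deaths == mri.pca_deaths
        assert reg.life_years == mri.life_years

    def test_qaly_accounting_identity(self):
        cfg = self.small_cfg()
        ns, reg, mri, _, summary = run_paired_simulation(3000, cfg, seed=8)
        for arm in (reg, mri):
            lyg = arm.life_years - ns.life_years
            qalyg = lyg - (arm.utility_loss - ns.utility_loss)
            assert arm.qalys - ns.qalys == pytest.approx(qalyg, abs=1e-9)
        assert summary.rows["qalys_gained"]["regular"] == pytest.approx(
            reg.qalys - ns.qalys, abs=1e-9)

    def test_overdiagnosed_bounded_by_screen_detected(self):
        cfg = self.small_cfg()
        for seed in (1, 2, 3):
            _, reg, mri, _, _ = run_paired_simulation(2000, cfg, seed=seed)
            for arm in (reg, mri):
                assert arm.overdiagnosed <= arm.screen_detected
                assert arm.insignificant_detected + arm.significant_detected >= 0


class TestDirectionChecks:
    """Qualitative findings at default test parameters on the synthetic cohort."""

    def test_mri_pathway_directions(self, paired_run_100k):
        _, reg, mri, _, summary = paired_run_100k
        assert mri.men_biopsied < reg.men_biopsied
        assert mri.insignificant_detected < reg.insignificant_detected
        assert mri.significant_detected > reg.significant_detected
        assert summary.harm_benefit_mri < summary.harm_benefit_regular

    def test_some_overdiagnosis_and_deaths_averted(self, paired_run_100k):
        _, reg, mri, _, summary = paired_run_100k
        for arm in (reg, mri):
            assert arm.overdiagnosed > 0
        assert summary.deaths_averted_regular > 0
        assert summary.deaths_averted_mri > 0

    def test_matched_significant_missed_fraction(self, paired_run_100k):
        *_, summary = paired_run_100k
        assert 0.0 < summary.pct_significant_missed < 100.0


class TestMonotoneCoupling:
    def test_raising_high_grade_sensitivity_raises_significant_detected(self):
        raw = default_config()
        cfg = cfgmod.resolve_config(raw)
        base = run_paired_simulation(30_000, cfg, seed=9)
        raised = run_paired_simulation(
            30_000, replace(cfg, tests=cfg.tests.with_updates(mpmri_sens_high=0.99)),
            seed=9,
        )
        assert raised[2].significant_detected >= base[2].significant_detected
        base_da = base[4].deaths_averted_mri
        raised_da = raised[4].deaths_averted_mri
        assert raised_da >= base_da
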