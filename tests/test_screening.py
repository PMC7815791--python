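"""Screening-pathway mechanics: schedules, episodes, misclassification, biopsies."""

import math

import numpy as np
import pytest

from psa_mri_sim.demography import Person
from psa_mri_sim.natural_history import LifeHistory
from psa_mri_sim.screening import (
    EpisodeDraws,
    ScreeningConfigError,
    ScreeningProtocol,
    TestParams,
    expected_biopsies,
    misclassify,
    screen_ages,
    screen_episode_detects,
    simulate_screening,
)
from psa_mri_sim.states import parse_state

HIGH = parse_state("T1_EQ7_M0")
LOW = parse_state("T1_LT7_M0")


def default_tests(**overrides):
    base = dict(psa_pos_prob={s: 0.6 for s in ("T1_EQ7_M0", "T1_LT7_M0")})
    base.update(overrides)
    return TestParams(**base)


def history_with(onset, state_label, dx_age, death_age, person_id=0):
    return LifeHistory(
        person=Person(person_id, death_age),
        onset_age=onset,
        trajectory=[(parse_state(state_label), onset)],
        clinical_dx_age=dx_age,
        state_at_clinical_dx=parse_state(state_label) if dx_age is not None else None,
    )


def run_screening(history, protocol, tests, seed=0, u_mis_clinical=0.99):
    rng = np.random.default_rng(seed)
    k = len(screen_ages(protocol))
    return simulate_screening(
        history,
        protocol,
        tests,
        u_attend=rng.uniform(size=k),
        u_psa=rng.uniform(size=k),
        u_mri=rng.uniform(size=k),
        u_comp=rng.uniform(size=k),
        u_bx=rng.uniform(size=k),
        u_mis_screen=rng.uniform(size=k),
        u_mis_clinical=u_mis_clinical,
    )


class TestScreenAges:
    @pytest.mark.parametrize(
        "start, stop, interval, expected",
        [
            (55, 64, 3, [55, 58, 61, 64]),
            (55, 55, 3, [55]),
            (55, 64, 20, [55]),
            (50, 60, 5, [50, 55, 60]),
        ],
    )
    def test_arithmetic_sequence(self, start, stop, interval, expected):
        proto = ScreeningProtocol(start_age=start, stop_age=stop, interval=interval)
        assert screen_ages(proto) == expected

    def test_invalid_protocol_rejected(self):
        with pytest.raises(ScreeningConfigError):
            ScreeningProtocol(start_age=64, stop_age=55)
        with pytest.raises(ScreeningConfigError, match="attendance"):
            ScreeningProtocol(attendance=2.0)


class TestEpisode:
    def test_certain_detection_with_perfect_tests(self):
        tests = default_tests(
            psa_pos_prob={HIGH.label: 1.0},
            trusgb_sens=1.0, biopsy_compliance=1.0,
            mpmri_sens_high=1.0, mrigb_sens_high=1.0,
        )
        draws = EpisodeDraws(0.5, 0.5, 0.5, 0.5)
        assert screen_episode_detects(HIGH, "regular", tests, draws)
        assert screen_episode_detects(HIGH, "mri", tests, draws)

    def test_zero_low_grade_mpmri_filters_all_low_grade(self):
        tests = default_tests(mpmri_sens_low=0.0)
        rng = np.random.default_rng(1)
        assert not any(
            screen_episode_detects(
                LOW, "mri", tests, EpisodeDraws(*rng.uniform(size=4))
            )
            for _ in range(2000)
        )

    def test_detection_probability_is_bernoulli_product(self):
        # high-grade state at defaults: psa*0.9*0.9 regular, psa*0.94*0.9*0.91 MRI
        tests = default_tests()
        psa = tests.psa_prob(HIGH)
        n = 100_000
        rng = np.random.default_rng(2)
        u = rng.uniform(size=(n, 4))
        reg = mri = 0
        for row in u:
            d = EpisodeDraws(*row)
            reg += screen_episode_detects(HIGH, "regular", tests, d)
            mri += screen_episode_detects(HIGH, "mri", tests, d)
        for emp, p in ((reg / n, psa * 0.9 * 0.9), (mri / n, psa * 0.94 * 0.9 * 0.91)):
            assert abs(emp - p) < 4 * math.sqrt(p * (1 - p) / n)


class TestMisclassify:
    def test_low_grade_never_upgraded(self):
        for u in (0.0, 0.1, 0.9):
            assert misclassify("low", 0.363, u) == "low"

    def test_high_grade_downgraded_below_rate(self):
        assert misclassify("high", 0.087, 0.05) == "low"
        assert misclassify("high", 0.087, 0.10) == "high"

    def test_zero_rate_preserves_grade(self):
        assert misclassify("high", 0.0, 0.0001) == "high"


class TestSimulateScreening:
    def proto(self, pathway="regular", attendance=1.0):
        return ScreeningProtocol(attendance=attendance, pathway=pathway)

    def certain_tests(self):
        return default_tests(
            psa_pos_prob={HIGH.label: 1.0, LOW.label: 1.0},
            trusgb_sens=1.0, biopsy_compliance=1.0,
            mpmri_sens_low=1.0, mpmri_sens_high=1.0,
            mrigb_sens_low=1.0, mrigb_sens_high=1.0,
            misclass_regular=0.0, misclass_mrigb=0.0,
        )

    def test_no_onset_yields_no_detection(self):
        h = LifeHistory(person=Person(0, 80.0))
        out = run_screening(h, self.proto(), default_tests())
        assert not out.detected and out.mode == "none"

    def test_first_eligible_screen_detects(self):
        h = history_with(56.0, HIGH.label, None, 90.0)
        out = run_screening(h, self.proto(), self.certain_tests())
        assert out.mode == "screen" and out.detection_age == 58.0
        assert out.lead_time == math.inf  # no counterfactual clinical dx

    def test_lead_time_is_dx_minus_detection(self):
        h = history_with(56.0, HIGH.label, 60.0, 90.0)
        out = run_screening(h, self.proto(), self.certain_tests())
        assert out.mode == "screen" and out.detection_age == 58.0
        assert out.lead_time == pytest.approx(2.0)

    def test_no_screens_at_or_after_clinical_dx_or_death(self):
        # dx at 58 exactly: the age-58 screen must not happen
        h = history_with(56.0, HIGH.label, 58.0, 57.5)
        out = run_screening(h, self.proto(), self.certain_tests())
        assert out.mode != "screen"

    def test_clinical_detection_when_dx_before_death(self):
        h = history_with(50.0, HIGH.label, 70.0, 90.0)
        out = run_screening(h, self.proto(attendance=0.0), self.certain_tests())
        assert out.mode == "clinical" and out.detection_age == 70.0
        assert out.lead_time == 0.0

    def test_clinical_route_uses_trusgb_misclassification(self):
        tests = self.certain_tests().with_updates(misclass_regular=1.0)
        h = history_with(50.0, HIGH.label, 70.0, 90.0)
        for pathway in ("regular", "mri"):
            out = run_screening(h, self.proto(pathway, attendance=0.0), tests,
                                u_mis_clinical=0.5)
            assert out.mode == "clinical" and out.recorded_grade == "low"

    def test_overdue_clinical_dx_not_detected(self):
        h = history_with(50.0, HIGH.label, 95.0, 90.0)
        out = run_screening(h, self.proto(attendance=0.0), self.certain_tests())
        assert not out.detected and out.mode == "none"

    def test_pathway_equivalence_under_common_draws(self):
        # equalised parameters + shared uniforms => identical outcomes
        tests = default_tests(
            psa_pos_prob={HIGH.label: 0.7, LOW.label: 0.5},
            mpmri_sens_low=1.0, mpmri_sens_high=1.0,
            mrigb_sens_low=0.9, mrigb_sens_high=0.9, trusgb_sens=0.9,
            misclass_mrigb=0.363, misclass_regular=0.363,
            ppv_mri=0.227, ppv_screen_regular=0.227,
        )
        rng = np.random.default_rng(7)
        for trial in range(200):
            h = history_with(54.0, HIGH.label if trial % 2 else LOW.label, 75.0, 85.0)
            k = 4
            kw = dict(
                u_attend=rng.uniform(size=k), u_psa=rng.uniform(size=k),
                u_mri=rng.uniform(size=k), u_comp=rng.uniform(size=k),
                u_bx=rng.uniform(size=k), u_mis_screen=rng.uniform(size=k),
                u_mis_clinical=rng.uniform(),
            )
            out_r = simulate_screening(h, self.proto("regular", 0.8), tests, **kw)
            out_m = simulate_screening(h, self.proto("mri", 0.8), tests, **kw)
            assert (out_r.mode, out_r.detection_age, out_r.recorded_grade) == (
                out_m.mode, out_m.detection_age, out_m.recorded_grade)

    def test_per_screen_recorded_significant_rates_at_defaults(self):
        # attended screen, high-grade state, PSA positive:
        # P(recorded significant) = 0.9*0.9*(1-0.363) regular
        #                         = 0.94*0.9*0.91*(1-0.087) MRI
        tests = default_tests(psa_pos_prob={HIGH.label: 1.0})
        n = 100_000
        rng = np.random.default_rng(11)
        counts = {"regular": 0, "mri": 0}
        for _ in range(n):
            k = 1
            kw = dict(
                u_attend=np.zeros(k), u_psa=rng.uniform(size=k),
                u_mri=rng.uniform(size=k), u_comp=rng.uniform(size=k),
                u_bx=rng.uniform(size=k), u_mis_screen=rng.uniform(size=k),
                u_mis_clinical=rng.uniform(),
            )
            h = history_with(50.0, HIGH.label, None, 90.0)
            for pathway in counts:
                proto = ScreeningProtocol(start_age=60, stop_age=60, attendance=1.0,
                                          pathway=pathway)
                out = simulate_screening(h, proto, tests, **kw)
                counts[pathway] += out.mode == "screen" and out.recorded_grade == "high"
        for pathway, p in (("regular", 0.9 * 0.9 * (1 - 0.363)),
                           ("mri", 0.94 * 0.9 * 0.91 * (1 - 0.087))):
            emp = counts[pathway] / n
            assert abs(emp - p) < 4 * math.sqrt(p * (1 - p) / n), (pathway, emp, p)


class TestExpectedBiopsies:
    def test_zero_counts(self):
        bc = expected_biopsies(0, 0, default_tests(), "regular")
        assert bc.total == 0.0

    def test_published_ppv_arithmetic(self):
        tests = default_tests()
        assert expected_biopsies(58, 0, tests, "mri").screen_biopsies == pytest.approx(100.0)
        assert expected_biopsies(22.7, 0, tests, "regular").screen_biopsies == pytest.approx(100.0)
        assert expected_biopsies(0, 35.8, tests, "mri").clinical_biopsies == pytest.approx(100.0)

    def test_total_is_sum_and_fractions_not_rounded(self):
        bc = expected_biopsies(10, 7, default_tests(), "regular")
        assert bc.total == pytest.approx(bc.screen_biopsies + bc.clinical_biopsies)
        assert bc.screen_biopsies == pytest.approx(10 / 0.227)

    def test_zero_ppv_is_configuration_error(self):
        tests = default_tests(ppv_mri=0.0)
        with pytest.raises(ScreeningConfigError):
            expected_biopsies(5, 0, tests, "mri")
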