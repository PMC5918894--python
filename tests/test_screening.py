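"""Screening overlay: schedules, FIT, colonoscopy, surveillance, outcomes."""
import math
import random

import pytest
from hypothesis import given, settings, strategies as st

from crcsim import (Findings, NaturalHistoryParams, ParticipationModel,
                    ProgramConfig, ScreeningStreams, SurveillanceRules,
                    TestCharacteristics, build_invitation_schedule,
                    next_disposition, perform_colonoscopy, perform_fit,
                    run_natural_history, run_screened_history,
                    unscreened_outcome)

from conftest import make_individual


def streams(seed=0):
    return ScreeningStreams(random.Random(seed), random.Random(seed + 1),
                            random.Random(seed + 2))


class TestInvitationSchedule:
    def test_biennial_enumeration_born_1950(self):
        ind = make_individual(birth_year=1950, death_age=95.0,
                              first_invitation_year=2009)
        sched = build_invitation_schedule(ind, ProgramConfig())
        assert [a for _y, a in sched] == [59, 61, 63, 65, 67, 69]
        assert [y for y, _a in sched] == [2009, 2011, 2013, 2015, 2017, 2019]

    def test_never_invited_gives_empty_schedule(self):
        ind = make_individual(birth_year=1939, death_age=95.0,
                              first_invitation_year=None)
        assert build_invitation_schedule(ind, ProgramConfig()) == []

    def test_truncated_by_death(self):
        ind = make_individual(birth_year=1950, death_age=60.0,
                              first_invitation_year=2009)
        sched = build_invitation_schedule(ind, ProgramConfig())
        assert [a for _y, a in sched] == [59]


class TestFit:
    def test_all_sensitivities_zero_always_negative(self):
        chars = TestCharacteristics(
            fit_sensitivity_small=0, fit_sensitivity_medium=0,
            fit_sensitivity_large=0, fit_sensitivity_crc=0,
            fit_specificity=1.0)
        rng = random.Random(1)
        lesions = [("large", False), ("crc", False)]
        assert not any(perform_fit(lesions, chars, rng) for _ in range(500))

    def test_false_positive_rate_matches_specificity(self):
        chars = TestCharacteristics(fit_specificity=0.95)
        rng = random.Random(2)
        n = 10_000
        hits = sum(perform_fit([], chars, rng) for _ in range(n))
        se = math.sqrt(0.05 * 0.95 / n)
        assert abs(hits / n - 0.05) < 3 * se

    def test_systematically_missed_lesion_never_triggers(self):
        chars = TestCharacteristics(fit_sensitivity_large=1.0,
                                    fit_specificity=1.0)
        rng = random.Random(3)
        lesions = [("large", True)]  # flagged undetectable
        assert not any(perform_fit(lesions, chars, rng) for _ in range(500))


class TestColonoscopy:
    def test_no_lesions_no_findings(self):
        chars = TestCharacteristics()
        det_a, det_c, f = perform_colonoscopy([], chars, random.Random(4))
        assert det_a == [] and det_c == []
        assert not f.polypectomy and not f.crc_detected

    def test_perfect_sensitivity_excises_all(self):
        chars = TestCharacteristics(colo_sensitivity_small=1.0,
                                    colo_sensitivity_medium=1.0,
                                    colo_sensitivity_large=1.0)
        lesions = [(0, "small", False), (1, "medium", False),
                   (2, "large", False)]
        det_a, _det_c, f = perform_colonoscopy(
            lesions, chars, random.Random(5), sizes_mm={0: 3, 1: 7, 2: 14})
        assert det_a == [0, 1, 2]
        assert f.polypectomy
        assert sorted(f.adenoma_sizes_mm) == [3, 7, 14]

    def test_complication_rate_given_polypectomy(self):
        p = 0.1
        chars = TestCharacteristics(colo_sensitivity_small=1.0,
                                    complication_prob=p)
        rng = random.Random(6)
        n = 10_000
        hits = 0
        for _ in range(n):
            _a, _c, f = perform_colonoscopy([(0, "small", False)], chars, rng,
                                            sizes_mm={0: 3.0})
            assert f.polypectomy
            hits += f.complication
        se = math.sqrt(p * (1 - p) / n)
        assert abs(hits / n - p) < 3 * se


class TestDisposition:
    @pytest.mark.parametrize("sizes,expected", [
        ([22.0], "colonoscopy_in_1y"),
        ([4.0] * 5, "colonoscopy_in_1y"),
        ([12.0], "colonoscopy_in_3y"),
        ([4.0, 5.0, 6.0], "colonoscopy_in_3y"),
        ([4.0, 4.0], "fit_in_5y"),
        ([9.9], "fit_in_5y"),
        ([], "routine_biennial_fit"),
    ])
    def test_rule_examples(self, sizes, expected):
        f = Findings(adenoma_sizes_mm=list(sizes))
        assert next_disposition(f, SurveillanceRules()) == expected

    def test_crc_goes_to_treatment_not_surveillance(self):
        f = Findings(adenoma_sizes_mm=[4.0], crc_detected=True)
        with pytest.raises(ValueError, match="treatment"):
            next_disposition(f, SurveillanceRules())

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(sizes=st.lists(st.floats(1.0, 60.0), max_size=8))
    def test_exactly_one_disposition_and_priority(self, sizes):
        rules = SurveillanceRules()
        d = next_disposition(Findings(adenoma_sizes_mm=sizes), rules)
        # independent re-derivation of the rule partition
        if not sizes:
            expected = "routine_biennial_fit"
        elif max(sizes) > 20 or len(sizes) >= 5:
            expected = "colonoscopy_in_1y"
        elif max(sizes) > 10 or len(sizes) >= 3:
            expected = "colonoscopy_in_3y"
        else:
            expected = "fit_in_5y"
        assert d == expected


def default_setup(**char_kwargs):
    return (ProgramConfig(), ParticipationModel(),
            TestCharacteristics(**char_kwargs), SurveillanceRules())


class TestScreenedHistory:
    def test_null_programme_matches_counterfactual(self, default_params):
        prog = ProgramConfig()
        part = ParticipationModel(p_first=(0.0,) * 4, p_successive=(0.0,) * 4)
        chars, rules = TestCharacteristics(), SurveillanceRules()
        for i in range(50):
            ind = make_individual(pid=i, birth_year=1950, death_age=95.0,
                                  first_invitation_year=2009)
            life = run_natural_history(ind, default_params, random.Random(i))
            out = run_screened_history(life, prog, part, chars, rules,
                                       streams(i), default_params)
            base = unscreened_outcome(life)
            assert out.death_age == base.death_age
            assert out.dx_records == base.dx_records
            assert all(e[1] == "invitation" for e in out.events
                       if e[1] not in ("colonoscopy",))
            # the only colonoscopies are the clinical work-ups of the
            # counterfactual diagnoses
            assert ([e for e in out.events if e[1] == "colonoscopy"]
                    == [e for e in base.events if e[1] == "colonoscopy"])

    def test_perfect_first_round_clears_all_precursors(self):
        # onset confined to <50; perfect tests and participation:
        # every diagnosis in the screened arm happens at or before the
        # first invitation (nothing can arise afterwards)
        params = NaturalHistoryParams(
            onset_age_breaks=(20.0, 50.0),
            onset_rates_male=(0.15, 0.0), onset_rates_female=(0.15, 0.0),
            transform_hazard_small=0.01, transform_hazard_medium=0.02,
            transform_hazard_large=0.05)
        prog = ProgramConfig()
        part = ParticipationModel(p_first=(1.0,) * 4, p_successive=(1.0,) * 4,
                                  colonoscopy_compliance=1.0)
        chars = TestCharacteristics(
            fit_sensitivity_small=1.0, fit_sensitivity_medium=1.0,
            fit_sensitivity_large=1.0, fit_sensitivity_crc=1.0,
            fit_specificity=1.0, colo_sensitivity_small=1.0,
            colo_sensitivity_medium=1.0, colo_sensitivity_large=1.0,
            colo_sensitivity_crc=1.0)
        rules = SurveillanceRules()
        for i in range(300):
            ind = make_individual(pid=i, birth_year=1955, death_age=95.0,
                                  first_invitation_year=2009)
            first_age = 2009 - 1955
            life = run_natural_history(ind, params, random.Random(i))
            out = run_screened_history(life, prog, part, chars, rules,
                                       streams(i), params)
            if any(dx <= first_age for dx, *_ in out.dx_records):
                continue  # diagnosed before the programme: never screened
            for dx_age, _s, _l, _screen in out.dx_records:
                assert dx_age <= first_age + 1e-9

    def test_screened_survival_never_worse_per_person(self, default_params):
        # common random numbers + the no-harm survival floor: excision and
        # stage anticipation can only preserve or extend each person's life
        prog, part, chars, rules = default_setup()
        for i in range(400):
            ind = make_individual(pid=i, birth_year=1950, death_age=95.0,
                                  risk=3.0, first_invitation_year=2009)
            life = run_natural_history(ind, default_params, random.Random(i))
            out = run_screened_history(life, prog, part, chars, rules,
                                       streams(i), default_params)
            assert out.death_age >= life.death_age - 1e-9
            assert ind.death_age_other == 95.0  # never touched

    def test_event_ages_within_life_and_screen_window(self, default_params):
        prog, part, chars, rules = default_setup()
        for i in range(300):
            ind = make_individual(pid=i, birth_year=1950, death_age=95.0,
                                  risk=3.0, first_invitation_year=2009)
            life = run_natural_history(ind, default_params, random.Random(i))
            out = run_screened_history(life, prog, part, chars, rules,
                                       streams(i), default_params)
            for age, etype, detail in out.events:
                assert 0 <= age <= out.death_age + 1e-9
                if etype in ("invitation", "fit", "fit_positive"):
                    assert prog.age_min <= age <= prog.age_max
                if etype == "colonoscopy" and detail[0] == "diagnostic":
                    assert prog.age_min <= age <= prog.age_max

    def test_determinism_and_cost_decoupling(self, default_params):
        prog, part, chars, rules = default_setup()
        ind = make_individual(pid=5, birth_year=1952, death_age=93.0,
                              risk=2.0, first_invitation_year=2009)
        life = run_natural_history(ind, default_params, random.Random(5))
        o1 = run_screened_history(life, prog, part, chars, rules, streams(5),
                                  default_params)
        o2 = run_screened_history(life, prog, part, chars, rules, streams(5),
                                  default_params)
        assert o1.events == o2.events
        assert o1.dx_records == o2.dx_records
        assert o1.death_age == o2.death_age

    def test_correlated_scenario_deterministic_miss(self, default_params):
        # a person whose only lesion is flagged missed tests negative at
        # every round (systematic_fn_fraction = 1 flags every adenoma)
        prog, part, chars, rules = default_setup(systematic_fn_fraction=1.0,
                                                 fit_specificity=1.0)
        part = ParticipationModel(p_first=(1.0,) * 4, p_successive=(1.0,) * 4,
                                  colonoscopy_compliance=1.0)
        params = default_params.with_updates(
            transform_hazard_small=0.0, transform_hazard_medium=0.0,
            transform_hazard_large=0.0)
        for i in range(100):
            ind = make_individual(pid=i, birth_year=1950, death_age=95.0,
                                  risk=5.0, first_invitation_year=2009)
            life = run_natural_history(ind, params, random.Random(i))
            out = run_screened_history(life, prog, part, chars, rules,
                                       streams(i), params)
            assert out.count("fit_positive") == 0
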