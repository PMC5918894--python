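"""Natural-history samplers against analytic oracles."""
import math
import random

import numpy as np
import pytest

from crcsim import (NaturalHistoryParams, run_natural_history,
                    sample_adenoma_onsets, simulate_adenoma_progression,
                    simulate_cancer_course, summarize_epidemiology)
from crcsim.tables import STAGES, default_age_bands

from conftest import make_individual


def flat_params(**kwargs):
    base = dict(onset_age_breaks=(0.0,), onset_rates_male=(0.02,),
                onset_rates_female=(0.02,))
    base.update(kwargs)
    return NaturalHistoryParams(**base)


class TestOnsets:
    def test_zero_baseline_gives_no_adenomas(self):
        params = flat_params(onset_rates_male=(0.0,), onset_rates_female=(0.0,))
        ind = make_individual(death_age=80.0)
        assert sample_adenoma_onsets(ind, params, random.Random(1)) == []

    def test_poisson_mean_oracle(self):
        # lam=0.02/yr over 50 years -> Poisson mean 1.0
        params = flat_params()
        rng = random.Random(2)
        n = 10_000
        counts = []
        for i in range(n):
            ind = make_individual(pid=i, death_age=50.0)
            counts.append(len(sample_adenoma_onsets(ind, params, rng)))
        mean = np.mean(counts)
        se = math.sqrt(1.0 / n)  # Poisson variance = mean = 1
        assert abs(mean - 1.0) < 3 * se

    def test_frailty_overdispersion(self):
        # mixed Poisson: Var = m + v m^2 > m
        params = flat_params(frailty_variance=1.0)
        n = 10_000
        counts = []
        rng_frailty = random.Random(42)
        rng = random.Random(3)
        for i in range(n):
            risk = rng_frailty.gammavariate(1.0, 1.0)
            ind = make_individual(pid=i, death_age=50.0, risk=risk)
            counts.append(len(sample_adenoma_onsets(ind, params, rng)))
        m, v = np.mean(counts), np.var(counts)
        assert v > 1.5 * m  # expected Var/mean = 1 + m = 2

    def test_onsets_truncated_at_death(self):
        params = flat_params(onset_rates_male=(0.5,))
        ind = make_individual(death_age=40.0)
        onsets = sample_adenoma_onsets(ind, params, random.Random(4))
        assert all(a < 40.0 for a, _loc in onsets)


class TestProgression:
    def test_zero_transformation_never_malignant(self):
        params = flat_params(transform_hazard_small=0.0,
                             transform_hazard_medium=0.0,
                             transform_hazard_large=0.0)
        rng = random.Random(5)
        for _ in range(200):
            ad = simulate_adenoma_progression(40.0, "colon", params, "male", rng)
            assert ad.malignant_age is None
            assert ad.cancer is None

    def test_competing_risk_transform_probability(self):
        # in the small state: P(transform before growth) = m / (m + g)
        g, m = 0.05, 0.02
        params = flat_params(dwell_mean_small_to_medium=1.0 / g,
                             transform_hazard_small=m)
        rng = random.Random(6)
        n = 10_000
        hits = 0
        for _ in range(n):
            ad = simulate_adenoma_progression(40.0, "colon", params, "male", rng)
            if ad.malignant_age is not None and ad.age_to_medium is None:
                hits += 1
        p = m / (m + g)
        se = math.sqrt(p * (1 - p) / n)
        assert abs(hits / n - p) < 3 * se

    def test_size_path_monotone(self, default_params):
        rng = random.Random(7)
        for _ in range(500):
            ad = simulate_adenoma_progression(30.0, "rectum", default_params,
                                              "female", rng)
            if ad.age_to_medium is not None:
                assert ad.onset_age < ad.age_to_medium
            if ad.age_to_large is not None:
                assert ad.age_to_medium < ad.age_to_large
            # state sequence at sampled ages never regresses
            order = {"small": 0, "medium": 1, "large": 2}
            last = -1
            stop = ad.malignant_age or 110.0
            for age in np.linspace(ad.onset_age, stop - 1e-6, 20):
                s = ad.size_state_at(age)
                assert s is not None and order[s] >= last
                last = order[s]


class TestCancerCourse:
    def test_symptomatic_only_in_stage_iv_when_forced(self, default_params):
        params = default_params.with_updates(
            sym_dx_hazards=(0.0, 0.0, 0.0, 1.0))
        rng = random.Random(8)
        for _ in range(200):
            c = simulate_cancer_course(50.0, "colon", params, "male", rng)
            assert c.dx_stage == 3

    def test_full_cure_fraction_never_kills(self, default_params):
        params = default_params.with_updates(
            cure_fractions=(1.0, 1.0, 1.0, 1.0))
        rng = random.Random(9)
        for _ in range(200):
            c = simulate_cancer_course(50.0, "colon", params, "male", rng)
            assert c.crc_death_age is None

    def test_exponential_sojourn_mean(self, default_params):
        # one-stage toy: progression off, dx hazard d -> mean sojourn 1/d
        d = 0.4
        params = default_params.with_updates(
            sojourn_mean_I_II=1e12, sym_dx_hazards=(d, d, d, d))
        rng = random.Random(10)
        n = 10_000
        sojourns = []
        for _ in range(n):
            c = simulate_cancer_course(50.0, "colon", params, "male", rng)
            assert c.dx_stage == 0
            sojourns.append(c.symptomatic_dx_age - 50.0)
        se = (1 / d) / math.sqrt(n)  # exponential: sd = mean
        assert abs(np.mean(sojourns) - 1 / d) < 3 * se

    def test_stage_entry_ages_strictly_increasing(self, default_params):
        rng = random.Random(11)
        for _ in range(300):
            c = simulate_cancer_course(45.0, "rectum", default_params,
                                       "female", rng)
            ages = [a for a in c.stage_entry_ages if a is not None]
            assert all(x < y for x, y in zip(ages, ages[1:]))


class TestLifeHistory:
    def test_truncation_no_adenomas_after_death(self, default_params):
        ind = make_individual(death_age=40.0)
        params = default_params.with_updates(
            onset_age_breaks=(45.0,), onset_rates_male=(5.0,),
            onset_rates_female=(5.0,))
        h = run_natural_history(ind, params, random.Random(12))
        assert h.adenomas == []
        assert h.cause_of_death == "other"

    def test_zero_onset_death_always_other(self, default_params):
        params = default_params.with_updates(
            onset_rates_male=(0.0,) * 6, onset_rates_female=(0.0,) * 6)
        for i in range(100):
            ind = make_individual(pid=i, death_age=70.0 + i / 10)
            h = run_natural_history(ind, params, random.Random(i))
            assert h.cause_of_death == "other"
            assert h.death_age == ind.death_age_other

    def test_determinism_under_seed(self, default_params, person):
        h1 = run_natural_history(person, default_params, random.Random(13))
        h2 = run_natural_history(person, default_params, random.Random(13))
        assert len(h1.adenomas) == len(h2.adenomas)
        for a, b in zip(h1.adenomas, h2.adenomas):
            assert (a.onset_age, a.malignant_age, a.location) == \
                   (b.onset_age, b.malignant_age, b.location)
        assert h1.death_age == h2.death_age

    def test_no_cancer_without_adenoma_pathway(self, default_params):
        # zero transformation hazards: incidence must be exactly zero
        params = default_params.with_updates(
            transform_hazard_small=0.0, transform_hazard_medium=0.0,
            transform_hazard_large=0.0)
        histories = [run_natural_history(make_individual(pid=i, death_age=90.0),
                                         params, random.Random(i))
                     for i in range(500)]
        t = summarize_epidemiology(histories, default_age_bands())
        assert (t.incidence["rate_per_100k"] == 0).all()

    def test_death_age_is_min_of_causes(self, default_params, person):
        h = run_natural_history(person, default_params, random.Random(99))
        assert h.death_age <= person.death_age_other
        if h.cause_of_death == "other":
            assert h.death_age == person.death_age_other


class TestSummarize:
    def test_hand_built_prevalence(self, default_params):
        # 4 people alive at 62.5; exactly 2 carry an adenoma then
        import random as _r
        people = [make_individual(pid=i, death_age=90.0) for i in range(4)]
        histories = []
        for i, p in enumerate(people):
            params = default_params.with_updates(
                onset_age_breaks=(55.0,),
                onset_rates_male=(3.0,) if i < 2 else (0.0,),
                onset_rates_female=(3.0,) if i < 2 else (0.0,),
                transform_hazard_small=0.0, transform_hazard_medium=0.0,
                transform_hazard_large=0.0)
            h = run_natural_history(p, params, _r.Random(i + 1))
            histories.append(h)
        assert sum(bool(h.adenomas) for h in histories) == 2
        t = summarize_epidemiology(histories, [(60, 64)])
        male = t.prevalence[t.prevalence.sex == "male"]
        assert male["prevalence"].iloc[0] == pytest.approx(0.5)

    def test_agreement_with_naive_tally(self, default_params):
        # independent brute-force recount of the same histories
        histories = [run_natural_history(make_individual(pid=i, death_age=85.0),
                                         default_params, random.Random(i))
                     for i in range(2000)]
        bands = default_age_bands()
        t = summarize_epidemiology(histories, bands)

        for _, row in t.prevalence[t.prevalence.sex == "male"].iterrows():
            mid = row.age_lo + (min(row.age_hi, 99) - row.age_lo + 1) / 2
            den = num = 0
            for h in histories:
                if h.death_age <= mid:
                    continue
                den += 1
                carrying = False
                for a in h.adenomas:
                    if a.onset_age <= mid and (a.malignant_age is None
                                               or mid < a.malignant_age):
                        carrying = True
                num += carrying
            assert den == row.n
            assert num / den == pytest.approx(row.prevalence) if den else row.prevalence == 0

        # naive incidence recount for one band
        lo, hi = 60, 64
        n_cases = 0
        py = 0.0
        for h in histories:
            py += max(0.0, min(h.death_age, hi + 1.0) - lo)
            for c in h.diagnosed_cancers():
                if lo <= c.symptomatic_dx_age <= hi:
                    n_cases += 1
        band = t.incidence[(t.incidence.sex == "male")
                           & (t.incidence.age_lo == lo)]
        assert band["person_years"].iloc[0] == pytest.approx(py)
        total_rate = band["rate_per_100k"].sum()
        assert total_rate == pytest.approx(1e5 * n_cases / py)
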