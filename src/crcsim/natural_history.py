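"""Adenoma-carcinoma natural history in continuous time.

Each person accrues adenomas from a non-homogeneous Poisson process whose
intensity is a piecewise-constant baseline (by age and sex) multiplied by a
personal gamma frailty.  Every adenoma independently walks the size states
(small <=5 mm, medium 6-9 mm, large >=10 mm) with competing exponential
transitions: growth to the next size versus malignant transformation to
preclinical stage I colorectal cancer.  A preclinical cancer walks stages
I->IV, in each stage racing exponential progression against symptomatic
diagnosis; stage IV cannot progress further and has a strictly positive
diagnosis hazard, so every cancer is eventually diagnosed unless the person
dies first.  Survival after diagnosis is a stage-specific cure fraction plus
an exponential time to cancer death for the non-cured.

All dwell and sojourn distributions are exponential by default, keeping the
model Markovian and every unit-test oracle analytic; the hazards are the
calibration surface.  The uniform draws behind cure and survival are stored
on the cancer so that a screening overlay can re-evaluate survival at an
earlier detected stage with the same randomness (common random numbers).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .tables import CalibrationTargets, LOCATIONS, SEXES, STAGES, TERMINAL_AGE

SIZE_STATES = ("small", "medium", "large")

# representative lesion diameters (mm) drawn at entry into each size state;
# only used to apply the mm-based surveillance rules to the class-based model
_SIZE_MM_RANGE = {"small": (1.0, 5.0), "medium": (6.0, 9.0)}
_LARGE_MM_MIN, _LARGE_MM_EXP_MEAN, _LARGE_MM_MAX = 10.0, 7.0, 60.0


@dataclass
class NaturalHistoryParams:
    """Hazard parameterisation of the adenoma-carcinoma sequence.

    All hazards are per year.  ``onset_rates_*`` apply on the age intervals
    defined by ``onset_age_breaks`` (last rate extends to the terminal age);
    intensity is zero before the first break, so lesions cannot predate
    adulthood.  Stage-indexed tuples are ordered (I, II, III, IV).
    """

    onset_age_breaks: tuple[float, ...] = (20.0, 30.0, 40.0, 50.0, 60.0, 70.0)
    onset_rates_male: tuple[float, ...] = (0.010, 0.020, 0.035, 0.050, 0.060, 0.060)
    onset_rates_female: tuple[float, ...] = (0.006, 0.012, 0.021, 0.030, 0.036, 0.036)
    onset_scale_male: float = 1.0       # calibration handle
    onset_scale_female: float = 1.0     # calibration handle
    frailty_variance: float = 1.0       # gamma frailty, mean 1

    dwell_mean_small_to_medium: float = 20.0   # years
    dwell_mean_medium_to_large: float = 18.0
    transform_hazard_small: float = 0.0004
    transform_hazard_medium: float = 0.0015
    transform_hazard_large: float = 0.015

    sojourn_mean_I_II: float = 2.5      # preclinical stage sojourn means
    sojourn_mean_II_III: float = 2.0
    sojourn_mean_III_IV: float = 1.5
    sym_dx_hazards: tuple[float, float, float, float] = (0.05, 0.20, 0.45, 0.90)

    cure_fractions: tuple[float, float, float, float] = (0.90, 0.75, 0.50, 0.05)
    survival_means: tuple[float, float, float, float] = (5.0, 4.0, 3.0, 1.5)

    p_colon: float = 0.65
    max_age: float = float(TERMINAL_AGE)

    def validate(self) -> None:
        rates = self.onset_rates_male + self.onset_rates_female
        if any(r < 0 for r in rates):
            raise ValueError("onset rates must be non-negative")
        if len(self.onset_rates_male) != len(self.onset_age_breaks):
            raise ValueError("one onset rate per age break required")
        if self.dwell_mean_small_to_medium <= 0 or self.dwell_mean_medium_to_large <= 0:
            raise ValueError("dwell means must be positive")
        if any(h < 0 for h in (self.transform_hazard_small,
                               self.transform_hazard_medium,
                               self.transform_hazard_large)):
            raise ValueError("transformation hazards must be non-negative")
        if any(not (0 <= c <= 1) for c in self.cure_fractions):
            raise ValueError("cure fractions must lie in [0, 1]")
        if self.sym_dx_hazards[3] <= 0:
            raise ValueError("stage IV symptomatic diagnosis hazard must be positive")
        if self.frailty_variance < 0:
            raise ValueError("frailty variance must be non-negative")

    def onset_rates(self, sex: str) -> tuple[float, ...]:
        if sex == "male":
            s = self.onset_scale_male
            return tuple(r * s for r in self.onset_rates_male)
        s = self.onset_scale_female
        return tuple(r * s for r in self.onset_rates_female)

    def with_updates(self, **kwargs) -> "NaturalHistoryParams":
        return replace(self, **kwargs)


class Adenoma:
    """One adenoma's full counterfactual trajectory."""

    __slots__ = (
        "onset_age", "location", "age_to_medium", "age_to_large",
        "malignant_age", "size_mm", "u_missed", "cancer",
    )

    def __init__(self, onset_age, location, age_to_medium, age_to_large,
                 malignant_age, size_mm, u_missed, cancer):
        self.onset_age = onset_age
        self.location = location
        self.age_to_medium = age_to_medium      # None if never reached
        self.age_to_large = age_to_large
        self.malignant_age = malignant_age      # None if never transforms
        self.size_mm = size_mm                  # dict state -> representative mm
        self.u_missed = u_missed                # uniform for systematic-miss flag
        self.cancer = cancer                    # CancerCourse or None

    def size_state_at(self, age: float) -> str | None:
        """Size state while still an adenoma at ``age`` (None if not present)."""
        if age < self.onset_age:
            return None
        if self.malignant_age is not None and age >= self.malignant_age:
            return None
        if self.age_to_large is not None and age >= self.age_to_large:
            return "large"
        if self.age_to_medium is not None and age >= self.age_to_medium:
            return "medium"
        return "small"

    def size_mm_at(self, age: float) -> float:
        return self.size_mm[self.size_state_at(age)]


class CancerCourse:
    """Counterfactual course of one preclinical cancer.

    ``stage_entry_ages`` holds the ages of entry into stages I..IV (None for
    stages never reached).  ``u_cure`` and ``u_surv`` are the uniforms behind
    the post-diagnosis survival draw; a screening overlay reuses them when
    re-evaluating survival at an earlier detected stage.
    """

    __slots__ = (
        "location", "onset_age", "stage_entry_ages", "symptomatic_dx_age",
        "dx_stage", "u_cure", "u_surv", "survival_time", "crc_death_age",
    )

    def __init__(self, location, onset_age, stage_entry_ages, symptomatic_dx_age,
                 dx_stage, u_cure, u_surv, survival_time, crc_death_age):
        self.location = location
        self.onset_age = onset_age
        self.stage_entry_ages = stage_entry_ages
        self.symptomatic_dx_age = symptomatic_dx_age
        self.dx_stage = dx_stage
        self.u_cure = u_cure
        self.u_surv = u_surv
        self.survival_time = survival_time      # None if cured
        self.crc_death_age = crc_death_age      # None if cured

    def stage_at(self, age: float) -> int:
        """Preclinical stage index (0..3) occupied at ``age``."""
        stage = 0
        for s in (1, 2, 3):
            a = self.stage_entry_ages[s]
            if a is not None and age >= a:
                stage = s
        return stage


class LifeHistory:
    """A person's complete counterfactual (no-screening) timeline."""

    __slots__ = ("individual", "adenomas", "death_age", "cause_of_death")

    def __init__(self, individual, adenomas, death_age, cause_of_death):
        self.individual = individual
        self.adenomas = adenomas
        self.death_age = death_age
        self.cause_of_death = cause_of_death

    def cancers(self):
        return [a.cancer for a in self.adenomas if a.cancer is not None]

    def diagnosed_cancers(self):
        """Cancers symptomatically diagnosed before death, in dx order."""
        out = [c for c in self.cancers()
               if c.symptomatic_dx_age is not None
               and c.symptomatic_dx_age < self.death_age]
        out.sort(key=lambda c: c.symptomatic_dx_age)
        return out


def _poisson(rng, lam: float) -> int:
    """Knuth sampler; onset interval means are small so this is fast."""
    if lam <= 0:
        return 0
    limit = math.exp(-lam)
    k, p = 0, 1.0
    while True:
        p *= rng.random()
        if p <= limit:
            return k
        k += 1


def sample_adenoma_onsets(individual, params: NaturalHistoryParams, rng
                          ) -> list[tuple[float, str]]:
    """Adenoma onset ages and locations for one person.

    Non-homogeneous Poisson process with intensity
    risk_index x baseline(age, sex), truncated at the other-cause death age.
    """
    horizon = min(individual.death_age_other, params.max_age)
    rates = params.onset_rates(individual.sex)
    breaks = params.onset_age_breaks
    risk = individual.risk_index
    onsets: list[tuple[float, str]] = []
    for i, lo in enumerate(breaks):
        hi = breaks[i + 1] if i + 1 < len(breaks) else params.max_age
        hi = min(hi, horizon)
        if hi <= lo:
            break
        lam = risk * rates[i] * (hi - lo)
        for _ in range(_poisson(rng, lam)):
            age = lo + rng.random() * (hi - lo)
            loc = "colon" if rng.random() < params.p_colon else "rectum"
            onsets.append((age, loc))
    onsets.sort(key=lambda t: t[0])
    return onsets


def _draw_large_mm(rng) -> float:
    return min(_LARGE_MM_MIN + rng.expovariate(1.0 / _LARGE_MM_EXP_MEAN),
               _LARGE_MM_MAX)


def simulate_adenoma_progression(onset_age: float, location: str,
                                 params: NaturalHistoryParams, sex: str, rng
                                 ) -> Adenoma:
    """Walk one adenoma through the size states with competing transformation."""
    growth = (1.0 / params.dwell_mean_small_to_medium,
              1.0 / params.dwell_mean_medium_to_large,
              0.0)
    transform = (params.transform_hazard_small,
                 params.transform_hazard_medium,
                 params.transform_hazard_large)
    size_mm = {
        "small": rng.uniform(*_SIZE_MM_RANGE["small"]),
        "medium": rng.uniform(*_SIZE_MM_RANGE["medium"]),
        "large": _draw_large_mm(rng),
    }
    age = onset_age
    age_to_medium = age_to_large = malignant_age = None
    for state in range(3):
        g, m = growth[state], transform[state]
        total = g + m
        if total <= 0:
            break  # inert in this state forever
        age += rng.expovariate(total)
        if rng.random() < m / total:
            malignant_age = age
            break
        if state == 0:
            age_to_medium = age
        else:
            age_to_large = age
    cancer = None
    if malignant_age is not None:
        cancer = simulate_cancer_course(malignant_age, location, params, sex, rng)
    return Adenoma(onset_age, location, age_to_medium, age_to_large,
                   malignant_age, size_mm, rng.random(), cancer)


def simulate_cancer_course(preclinical_onset_age: float, location: str,
                           params: NaturalHistoryParams, sex: str, rng
                           ) -> CancerCourse:
    """Stage walk I->IV with competing symptomatic diagnosis, then survival."""
    prog = (1.0 / params.sojourn_mean_I_II,
            1.0 / params.sojourn_mean_II_III,
            1.0 / params.sojourn_mean_III_IV,
            0.0)
    dx_haz = params.sym_dx_hazards
    entry: list[float | None] = [preclinical_onset_age, None, None, None]
    age = preclinical_onset_age
    stage = 0
    dx_age = None
    while True:
        p, d = prog[stage], dx_haz[stage]
        total = p + d
        if total <= 0:
            break  # undiagnosable and non-progressing; dies undetected
        age += rng.expovariate(total)
        if rng.random() < d / total:
            dx_age = age
            break
        stage += 1
        entry[stage] = age
    u_cure = rng.random()
    u_surv = rng.random()
    survival_time = crc_death_age = None
    if dx_age is not None:
        cured = u_cure < params.cure_fractions[stage]
        if not cured:
            survival_time = -params.survival_means[stage] * math.log(max(u_surv, 1e-300))
            crc_death_age = dx_age + survival_time
    return CancerCourse(location, preclinical_onset_age, entry, dx_age,
                        stage, u_cure, u_surv, survival_time, crc_death_age)


def redraw_survival(cancer: CancerCourse, detected_stage: int, dx_age: float,
                    params: NaturalHistoryParams
                    ) -> tuple[float | None, float | None]:
    """Survival at an earlier detected stage using the cancer's stored uniforms.

    Returns (survival_time, crc_death_age), both None when cured.  The death
    age is floored at the counterfactual one (stage anticipation can only
    preserve or improve an individual's survival).
    """
    if cancer.u_cure < params.cure_fractions[detected_stage]:
        return None, None
    t = -params.survival_means[detected_stage] * math.log(max(cancer.u_surv, 1e-300))
    death = dx_age + t
    if cancer.crc_death_age is not None:
        death = max(death, cancer.crc_death_age)
    return death - dx_age, death


def _resolve_death(death_age_other: float, fates: Iterable[tuple[float | None, float | None]]
                   ) -> tuple[float, str]:
    """Effective death age and cause from other-cause death and cancer fates.

    ``fates`` are (dx_age, crc_death_age) pairs; a cancer only kills if its
    diagnosis precedes the current effective death age.
    """
    death, cause = death_age_other, "other"
    for dx, cd in sorted((f for f in fates if f[0] is not None),
                         key=lambda f: f[0]):
        if dx < death and cd is not None and cd < death:
            death, cause = cd, "crc"
    return death, cause


def run_natural_history(individual, params: NaturalHistoryParams, rng) -> LifeHistory:
    """Compose onset, progression and cancer-course samplers for one person."""
    adenomas = [
        simulate_adenoma_progression(age, loc, params, individual.sex, rng)
        for age, loc in sample_adenoma_onsets(individual, params, rng)
    ]
    fates = [(a.cancer.symptomatic_dx_age, a.cancer.crc_death_age)
             for a in adenomas if a.cancer is not None]
    death, cause = _resolve_death(individual.death_age_other, fates)
    return LifeHistory(individual, adenomas, death, cause)


def summarize_epidemiology(histories: Sequence[LifeHistory],
                           age_bands: Sequence[tuple[int, int]],
                           observation_years: tuple[int, int] | None = None,
                           ) -> CalibrationTargets:
    """Empirical adenoma prevalence and CRC incidence tables from histories.

    Prevalence in a band is the share of people alive at the band midpoint who
    carry at least one non-malignant adenoma then (excised lesions never enter
    counterfactual histories).  Incidence is symptomatically diagnosed CRC per
    100,000 person-years lived inside the band, split by stage and location.
    When ``observation_years`` is given, diagnoses and person-years are
    restricted to that calendar window (requires individuals with birth years).
    """
    mids = [lo + (min(hi, 99) - lo + 1) / 2.0 for lo, hi in age_bands]
    prev_num = {s: [0] * len(age_bands) for s in SEXES}
    prev_den = {s: [0] * len(age_bands) for s in SEXES}
    py = {s: [0.0] * len(age_bands) for s in SEXES}
    cases = {}  # (sex, band_idx, location, stage) -> count

    for h in histories:
        sex = h.individual.sex
        death = h.death_age
        if observation_years is not None:
            by = h.individual.birth_year
            a_lo = observation_years[0] - by
            a_hi = observation_years[1] + 1 - by
        else:
            a_lo, a_hi = 0.0, float("inf")
        for b, (lo, hi) in enumerate(age_bands):
            m = mids[b]
            if m < death and a_lo <= m < a_hi:
                prev_den[sex][b] += 1
                if any(a.size_state_at(m) is not None for a in h.adenomas):
                    prev_num[sex][b] += 1
            overlap = (min(death, hi + 1.0, a_hi) - max(float(lo), a_lo))
            if overlap > 0:
                py[sex][b] += overlap
        for c in h.diagnosed_cancers():
            dx = c.symptomatic_dx_age
            if not (a_lo <= dx < a_hi):
                continue
            for b, (lo, hi) in enumerate(age_bands):
                if lo <= dx <= hi:
                    key = (sex, b, c.location, STAGES[c.dx_stage])
                    cases[key] = cases.get(key, 0) + 1
                    break

    prev_rows = []
    for sex in SEXES:
        for b, (lo, hi) in enumerate(age_bands):
            n = prev_den[sex][b]
            prev_rows.append({
                "sex": sex, "age_lo": lo, "age_hi": hi,
                "prevalence": prev_num[sex][b] / n if n else 0.0,
                "n": n,
            })
    inc_rows = []
    for sex in SEXES:
        for b, (lo, hi) in enumerate(age_bands):
            pys = py[sex][b]
            for loc in LOCATIONS:
                for st in STAGES:
                    k = cases.get((sex, b, loc, st), 0)
                    inc_rows.append({
                        "sex": sex, "age_lo": lo, "age_hi": hi,
                        "location": loc, "stage": st,
                        "rate_per_100k": 1e5 * k / pys if pys > 0 else 0.0,
                        "person_years": pys,
                    })
    return CalibrationTargets(pd.DataFrame(prev_rows), pd.DataFrame(inc_rows))
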