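"""Simulated multi-cohort population with phased programme roll-out.

Individuals are sampled from a demography pyramid at the 2008 reference year,
assigned an other-cause death age from the sex-specific life table
(conditional on being alive at their 2008 age), a gamma frailty multiplier on
adenoma onset, and a first-invitation calendar year under the 2009->2013
linear roll-out of the organised screening programme.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import rng as rngmod
from .tables import DemographyPyramid, LifeTable, TERMINAL_AGE


@dataclass
class ProgramConfig:
    """Organised biennial FIT programme, ages 50-69, rolled out 2009-2013."""

    start_year: int = 2009
    full_implementation_year: int = 2013
    last_new_cohort_year: int = 2038
    age_min: int = 50
    age_max: int = 69
    screening_interval: int = 2
    discount_rate: float = 0.03
    surveillance_after_69: bool = True

    def __post_init__(self) -> None:
        if self.age_min >= self.age_max:
            raise ValueError("age_min must be below age_max")
        if self.screening_interval <= 0:
            raise ValueError("screening interval must be positive")
        if not (0 <= self.discount_rate < 1):
            raise ValueError("discount rate must lie in [0, 1)")

    @property
    def rollout_fractions(self) -> list[tuple[int, float]]:
        """Cumulative share of initially eligible strata active per year."""
        years = range(self.start_year, self.full_implementation_year + 1)
        n = self.full_implementation_year - self.start_year + 1
        return [(y, (i + 1) / n) for i, y in enumerate(years)]


class Individual:
    __slots__ = ("id", "sex", "birth_year", "death_age_other", "risk_index",
                 "first_invitation_year")

    def __init__(self, id, sex, birth_year, death_age_other, risk_index,
                 first_invitation_year):
        self.id = id
        self.sex = sex
        self.birth_year = birth_year
        self.death_age_other = death_age_other
        self.risk_index = risk_index
        self.first_invitation_year = first_invitation_year

    def age_in(self, year: int) -> int:
        return year - self.birth_year


def sample_other_cause_death_age(current_age: int, sex: str,
                                 life_table: LifeTable, rng) -> float:
    """Draw a continuous other-cause death age conditional on being alive.

    Walks the discrete annual probabilities from ``current_age``; death is
    placed uniformly within the death year.  The terminal age has q = 1 so the
    walk always ends.
    """
    q = life_table.q
    age = int(current_age)
    while age < TERMINAL_AGE and rng.random() >= q[age]:
        age += 1
    return age + rng.random()


def first_invitation_year(age_2009: int, program: ProgramConfig,
                          u_stratum: float) -> int | None:
    """Calendar year of a person's first programme invitation, or None.

    People aged ``age_max + 1`` or older at programme start are never invited.
    Initially eligible strata activate linearly over the roll-out years; a
    uniform draw places the person in a stratum.  People reaching ``age_min``
    later join in the year they become age-eligible (their stratum permitting)
    as long as that year is within the new-cohort horizon.
    """
    start = program.start_year
    if age_2009 > program.age_max:
        return None
    activation = None
    for year, frac in program.rollout_fractions:
        if u_stratum <= frac:
            activation = year
            break
    year_eligible = start + max(0, program.age_min - age_2009)
    first = max(activation, year_eligible)
    age_at_first = age_2009 + (first - start)
    if age_at_first > program.age_max:
        return None
    if first > program.last_new_cohort_year:
        return None
    return first


def build_population(pyramid: DemographyPyramid, life_tables: dict[str, LifeTable],
                     program: ProgramConfig, scale: float, seed: int,
                     frailty_variance: float = 1.0) -> list[Individual]:
    """Sample a scaled copy of the pyramid and equip each person for simulation.

    The number of individuals is round(total * scale), allocated across
    (sex, age) cells multinomially with the pyramid proportions.  All
    per-person draws come from the person's own population substream so the
    same seed reproduces the identical collection regardless of which
    screening scenario is later overlaid (common random numbers).
    """
    if not (0 < scale <= 1):
        raise ValueError("scale must lie in (0, 1]")
    total = pyramid.total
    if total <= 0:
        raise ValueError("no population")
    n = int(round(total * scale))
    if n < 1:
        raise ValueError("scaled population is empty")
    cells = pyramid.counts
    probs = cells["count"].to_numpy(dtype=float) / total
    master = np.random.default_rng(rngmod.substream_seed(seed, 240))
    alloc = master.multinomial(n, probs)

    frailty_var = frailty_variance
    people: list[Individual] = []
    pid = 0
    ref = pyramid.reference_year
    for (sex, age, _), k in zip(cells.itertuples(index=False), alloc):
        lt = life_tables[sex]
        for _ in range(int(k)):
            r = rngmod.substream(seed, pid, rngmod.POPULATION)
            death_age = sample_other_cause_death_age(int(age), sex, lt, r)
            risk = (r.gammavariate(1.0 / frailty_var, frailty_var)
                    if frailty_var > 0 else 1.0)
            age_2009 = int(age) + (program.start_year - ref)
            fiy = first_invitation_year(age_2009, program, r.random())
            people.append(Individual(pid, sex, ref - int(age), death_age,
                                     max(risk, 1e-12), fiy))
            pid += 1
    return people
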