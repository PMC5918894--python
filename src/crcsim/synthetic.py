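"""Synthetic inputs with known ground truth.

Every file the pipeline consumes can be generated here: Gompertz-Makeham
life tables standing in for 2008 European registry tables, a demography
pyramid with a baby-boom bulge (2.23 million people, 51 % women by default),
calibration target tables produced by simulating the natural history with
*known* parameters (so calibration can be tested as parameter recovery), and
the cost/utility tables pre-filled with the published unit costs.
"""
from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import rng as rngmod
from .economics import CostTable, UtilityTable
from .natural_history import (NaturalHistoryParams, run_natural_history,
                              summarize_epidemiology)
from .population import Individual, sample_other_cause_death_age
from .tables import (CalibrationTargets, DemographyPyramid, LifeTable,
                     SEXES, TERMINAL_AGE, default_age_bands)

DEFAULT_TOTAL = 2_230_000
DEFAULT_FEMALE_SHARE = 0.51
DEFAULT_REFERENCE_YEAR = 2008


@dataclass
class MakehamParams:
    """Gompertz-Makeham hazard h(x) = c + a * exp(b * x)."""

    a: float = 5e-5
    b: float = 0.095
    c: float = 5e-4


# modest female survival advantage, in the range of 2008 European tables
DEFAULT_MAKEHAM = {
    "male": MakehamParams(a=6.0e-5, b=0.096, c=7e-4),
    "female": MakehamParams(a=2.5e-5, b=0.100, c=4e-4),
}


def generate_life_table(sex: str, makeham_params: MakehamParams | None = None,
                        seed: int | None = None) -> LifeTable:
    """Deterministic life table from a Gompertz-Makeham hazard.

    Annual death probability is the exact hazard integral over each year of
    age, q(x) = 1 - exp(-H(x, x+1)); the terminal age is forced to q = 1.
    ``seed`` is accepted for signature symmetry but unused (no noise model).
    """
    p = makeham_params or MakehamParams()
    q = np.empty(TERMINAL_AGE + 1)
    clamped = False
    for x in range(TERMINAL_AGE):
        if p.b != 0:
            integral = p.c + p.a / p.b * (math.exp(p.b * (x + 1)) - math.exp(p.b * x))
        else:
            integral = p.c + p.a
        if integral < 0:
            raise ValueError("hazard parameters produce a negative hazard")
        if integral > 700:  # exp underflow: probability is numerically 1
            q[x] = 1.0
            clamped = True
        else:
            q[x] = 1.0 - math.exp(-integral)
            if q[x] >= 1.0:
                clamped = True
    q[TERMINAL_AGE] = 1.0
    if clamped:
        warnings.warn("death probability reached 1 before the terminal age; "
                      "clamped", stacklevel=2)
    return LifeTable(sex, q)


def default_life_tables() -> dict[str, LifeTable]:
    return {sex: generate_life_table(sex, DEFAULT_MAKEHAM[sex])
            for sex in SEXES}


def babyboom_age_profile(ages: np.ndarray | None = None) -> np.ndarray:
    """Piecewise-linear age weights with a bulge around the cohorts born in
    the late 1950s-1970s (aged roughly 30-50 in 2008), so an unscreened
    projection reproduces aging-driven cost growth."""
    if ages is None:
        ages = np.arange(100)
    knots_x = np.array([0, 20, 30, 40, 50, 65, 80, 99])
    knots_y = np.array([0.85, 0.95, 1.20, 1.40, 1.25, 0.90, 0.45, 0.05])
    return np.interp(ages, knots_x, knots_y)


def _largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Integer allocation proportional to weights summing exactly to total."""
    w = np.asarray(weights, dtype=float)
    if w.sum() <= 0:
        raise ValueError("age profile must have positive mass")
    exact = w / w.sum() * total
    base = np.floor(exact).astype(int)
    short = total - base.sum()
    order = np.argsort(-(exact - base))
    base[order[:short]] += 1
    return base


def generate_demography(total_count: int = DEFAULT_TOTAL,
                        female_share: float = DEFAULT_FEMALE_SHARE,
                        age_profile: np.ndarray | None = None,
                        reference_year: int = DEFAULT_REFERENCE_YEAR
                        ) -> DemographyPyramid:
    """Demography pyramid whose counts sum to ``total_count`` exactly.

    The female total is round(total * female_share); within each sex the age
    distribution follows ``age_profile`` (default: baby-boom bulge over ages
    0-99) via largest-remainder rounding, so conservation is exact.
    """
    if total_count <= 0:
        raise ValueError("total_count must be positive")
    if not (0 < female_share < 1):
        raise ValueError("female_share must lie strictly between 0 and 1")
    profile = babyboom_age_profile() if age_profile is None else np.asarray(age_profile, float)
    ages = np.arange(len(profile))
    n_female = int(round(total_count * female_share))
    n_male = total_count - n_female
    rows = []
    for sex, n in (("male", n_male), ("female", n_female)):
        counts = _largest_remainder(profile, n)
        rows += [{"sex": sex, "age": int(a), "count": int(c)}
                 for a, c in zip(ages, counts)]
    return DemographyPyramid(reference_year, pd.DataFrame(rows))


def simulate_cohort(nh_params: NaturalHistoryParams,
                    life_tables: dict[str, LifeTable], n_individuals: int,
                    seed: int, female_share: float = 0.5) -> list:
    """Simulate ``n_individuals`` natural histories from birth.

    The cohort is the target sizes' ground-truth generator for calibration:
    each person gets a life-table death age, a gamma frailty and a full
    adenoma-carcinoma history, all from per-person substreams of ``seed``.
    """
    if n_individuals < 1:
        raise ValueError("n_individuals must be at least 1")
    nh_params.validate()
    fv = nh_params.frailty_variance
    n_female = int(round(n_individuals * female_share))
    histories = []
    for pid in range(n_individuals):
        sex = "female" if pid < n_female else "male"
        r = rngmod.substream(seed, pid, rngmod.POPULATION)
        death = sample_other_cause_death_age(0, sex, life_tables[sex], r)
        risk = r.gammavariate(1.0 / fv, fv) if fv > 0 else 1.0
        ind = Individual(pid, sex, 0, death, max(risk, 1e-12), None)
        r_nh = rngmod.substream(seed, pid, rngmod.NATURAL_HISTORY)
        histories.append(run_natural_history(ind, nh_params, r_nh))
    return histories


def generate_calibration_targets(true_nh_params: NaturalHistoryParams,
                                 life_tables: dict[str, LifeTable],
                                 n_individuals: int, seed: int,
                                 age_bands=None) -> CalibrationTargets:
    """Empirical target tables from a simulation with known parameters.

    Reproducible under a fixed seed; bands that no simulated person reaches
    are reported with n (or person-years) zero, flagging them as
    uninformative rather than dropping them.
    """
    bands = age_bands or default_age_bands()
    histories = simulate_cohort(true_nh_params, life_tables, n_individuals, seed)
    return summarize_epidemiology(histories, bands)


def default_cost_utility_tables() -> tuple[CostTable, UtilityTable]:
    """Cost and utility tables pre-filled with the published unit values."""
    return CostTable(), UtilityTable()


def write_cost_utility_tables(costs: CostTable, utilities: UtilityTable,
                              costs_path, utilities_path) -> None:
    with open(costs_path, "w") as f:
        json.dump(costs.to_dict(), f, indent=2)
    with open(utilities_path, "w") as f:
        json.dump(utilities.to_dict(), f, indent=2)


def read_cost_utility_tables(costs_path, utilities_path
                             ) -> tuple[CostTable, UtilityTable]:
    with open(costs_path) as f:
        costs = CostTable.from_dict(json.load(f))
    with open(utilities_path) as f:
        utilities = UtilityTable.from_dict(json.load(f))
    return costs, utilities
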