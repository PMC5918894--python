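"""Health-economics layer: costing, QALYs, cost-effectiveness, budget impact.

Costs are booked in the calendar year of the event from the Basque Health
Service unit costs (2012 euros): invitation 6.06, FIT analysis 0.99, positive
consult 78.00, colonoscopy 461.30 with / 281.30 without polypectomy,
complication 5157.00, initial treatment 6968 / 12765 / 13075 for stages
I-III, 404 per follow-up year (stages I-III, capped), 24255 per year alive
with stage-IV disease.  QALYs are discounted life-years minus event
disutilities (2 days per colonoscopy, 14 days per complication, converted at
365 days/QALY) minus annual utility losses while living with diagnosed CRC.

Pricing is strictly decoupled from dynamics: arms are first reduced to event
*counts* per calendar year, then priced, so re-pricing the same logs with a
different cost table can never change counts, QALYs or colonoscopy
projections.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable

import pandas as pd

from .screening import PersonOutcome
from .tables import STAGES

BASE_YEAR = 2009
DISCOUNT_RATE = 0.03
DAYS_PER_YEAR = 365

COMPONENT_GROUPS = {
    "invitation": "screening",
    "fit_analysis": "screening",
    "consult": "screening",
    "colonoscopy_with_polypectomy": "diagnosis",
    "colonoscopy_without_polypectomy": "diagnosis",
    "complication": "diagnosis",
    "treatment_initial": "treatment",
    "treatment_followup": "treatment",
    "treatment_stage_iv": "treatment",
}


def days_to_qaly(days: float, decimals: int = 4) -> float:
    """Convert whole days of life lost into QALYs at 365 days/year."""
    return round(days / DAYS_PER_YEAR, decimals)


@dataclass
class CostTable:
    """Unit costs in 2012 euros.  Stage IV has no separate initial cost."""

    invitation: float = 6.06
    fit_analysis: float = 0.99
    primary_care_consult_positive: float = 78.00
    colonoscopy_with_polypectomy: float = 461.30
    colonoscopy_without_polypectomy: float = 281.30
    complication: float = 5157.00
    treatment_initial: tuple[float, float, float, float] = (6968.0, 12765.0, 13075.0, 0.0)
    followup_annual_stage_I_III: float = 404.0
    stage_IV_annual: float = 24255.0
    followup_years_cap: int = 5

    def __post_init__(self) -> None:
        vals = [self.invitation, self.fit_analysis,
                self.primary_care_consult_positive,
                self.colonoscopy_with_polypectomy,
                self.colonoscopy_without_polypectomy, self.complication,
                *self.treatment_initial, self.followup_annual_stage_I_III,
                self.stage_IV_annual]
        if any(v < 0 for v in vals):
            raise ValueError("unit costs must be non-negative")
        if self.treatment_initial[3] != 0.0:
            raise ValueError("stage IV carries no separate initial "
                             "treatment cost")

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["treatment_initial"] = list(self.treatment_initial)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CostTable":
        d = dict(d)
        d["treatment_initial"] = tuple(d["treatment_initial"])
        return cls(**d)


@dataclass
class UtilityTable:
    """Disutilities in QALYs.  The per-stage annual losses while living with
    diagnosed CRC are configurable surrogates."""

    disutility_colonoscopy: float = days_to_qaly(2)      # 0.0055
    disutility_complication: float = days_to_qaly(14)    # 0.0384
    annual_loss_by_stage: tuple[float, float, float, float] = (0.05, 0.10, 0.15, 0.30)
    care_years_cap: int = 5   # stages I-III; stage IV until death

    def __post_init__(self) -> None:
        if self.disutility_colonoscopy < 0 or self.disutility_complication < 0:
            raise ValueError("disutilities must be non-negative")
        if any(not (0 <= u <= 1) for u in self.annual_loss_by_stage):
            raise ValueError("annual utility losses must lie in [0, 1]")

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["annual_loss_by_stage"] = list(self.annual_loss_by_stage)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "UtilityTable":
        d = dict(d)
        d["annual_loss_by_stage"] = tuple(d["annual_loss_by_stage"])
        return cls(**d)


@dataclass
class DiscountConfig:
    base_year: int = BASE_YEAR
    rate: float = DISCOUNT_RATE

    def factor(self, year: int) -> float:
        return 1.0 / (1.0 + self.rate) ** (year - self.base_year)


def discount_value(amount: float, event_year: int, base_year: int = BASE_YEAR,
                   rate: float = DISCOUNT_RATE) -> float:
    """Present value at ``base_year`` with annual compounding."""
    if event_year < base_year:
        raise ValueError("event_year must not precede the base year")
    return amount / (1.0 + rate) ** (event_year - base_year)


def _count_items(outcome: PersonOutcome) -> Iterable[tuple[int, str]]:
    """(calendar_year, cost category) pairs, one per costable unit."""
    by = outcome.individual.birth_year
    for age, etype, detail in outcome.events:
        year = by + int(age)
        if etype == "invitation":
            yield year, "invitation"
        elif etype == "fit":
            yield year, "fit_analysis"
        elif etype == "fit_positive":
            yield year, "consult"
        elif etype == "colonoscopy":
            _purpose, polyp = detail
            yield year, ("colonoscopy_with_polypectomy" if polyp
                         else "colonoscopy_without_polypectomy")
        elif etype == "complication":
            yield year, "complication"
    for dx_age, stage, _loc, _screen in outcome.dx_records:
        dx_year = by + int(dx_age)
        surv_years = outcome.death_age - dx_age
        if stage < 3:
            yield dx_year, ("treatment_initial", stage)
            n_fu = int(surv_years)  # completed survival years
            for k in range(1, n_fu + 1):
                yield dx_year + k, ("treatment_followup", k)
        else:
            n_s4 = max(1, math.ceil(surv_years - 1e-9))  # started years
            for k in range(n_s4):
                yield dx_year + k, "treatment_stage_iv"


def _price(key, costs: CostTable) -> tuple[str, float]:
    """Map a count key to its (category, unit cost).

    Follow-up years beyond the configured cap price to zero, which keeps the
    count ledger pricing-agnostic while the cap remains a costing rule.
    """
    if isinstance(key, tuple):
        kind, idx = key
        if kind == "treatment_initial":
            return "treatment_initial", costs.treatment_initial[idx]
        if kind == "treatment_followup":
            amount = (costs.followup_annual_stage_I_III
                      if idx <= costs.followup_years_cap else 0.0)
            return "treatment_followup", amount
        raise KeyError(key)
    if key == "invitation":
        return key, costs.invitation
    if key == "fit_analysis":
        return key, costs.fit_analysis
    if key == "consult":
        return key, costs.primary_care_consult_positive
    if key == "colonoscopy_with_polypectomy":
        return key, costs.colonoscopy_with_polypectomy
    if key == "colonoscopy_without_polypectomy":
        return key, costs.colonoscopy_without_polypectomy
    if key == "complication":
        return key, costs.complication
    if key == "treatment_stage_iv":
        return key, costs.stage_IV_annual
    raise KeyError(key)


def tally_costs(outcome: PersonOutcome, costs: CostTable
                ) -> dict[int, dict[str, float]]:
    """Per-calendar-year cost ledger by category for one person, undiscounted.

    Stage I-III follow-up accrues for completed survival years up to the
    configured cap; stage IV accrues the flat annual amount for every started
    year alive with the disease.
    """
    ledger: dict[int, dict[str, float]] = {}
    for year, key in _count_items(outcome):
        cat, amount = _price(key, costs)
        if amount == 0.0:
            continue
        ledger.setdefault(year, {})
        ledger[year][cat] = ledger[year].get(cat, 0.0) + amount
    return ledger


def tally_qalys(outcome: PersonOutcome, utilities: UtilityTable,
                discount: DiscountConfig = DiscountConfig()) -> float:
    """Discounted QALYs for one person from the base year onwards.

    Life-years accrue continuously and are discounted by the factor of the
    calendar year containing them; colonoscopy and complication disutilities
    are booked at their event year; annual CRC-care utility losses accrue for
    each (possibly partial) year lived with diagnosed CRC, capped for stages
    I-III, until death for stage IV.
    """
    by = outcome.individual.birth_year
    base = discount.base_year
    death = outcome.death_age
    qaly = 0.0
    y = max(base, by)
    last_year = by + int(death) if death > int(death) else by + int(death) - 1
    while y <= last_year:
        lived = min(death, y + 1 - by) - max(0.0, y - by)
        if lived > 0:
            qaly += lived * discount.factor(y)
        y += 1
    for age, etype, _detail in outcome.events:
        year = max(base, by + int(age))
        if etype == "colonoscopy":
            qaly -= utilities.disutility_colonoscopy * discount.factor(year)
        elif etype == "complication":
            qaly -= utilities.disutility_complication * discount.factor(year)
    for dx_age, stage, _loc, _screen in outcome.dx_records:
        loss = utilities.annual_loss_by_stage[stage]
        years_with_care = death - dx_age
        if stage < 3:
            years_with_care = min(years_with_care, utilities.care_years_cap)
        k = 0
        dx_year = by + int(dx_age)
        while years_with_care > 1e-12:
            frac = min(1.0, years_with_care)
            qaly -= loss * frac * discount.factor(max(base, dx_year + k))
            years_with_care -= frac
            k += 1
    return qaly


class ArmAggregate:
    """Streaming accumulator for one simulation arm.

    Reduces person outcomes to per-year event counts (pricing-agnostic),
    discounted QALYs, colonoscopy counts by purpose and headline
    epidemiological tallies.
    """

    def __init__(self, utilities: UtilityTable,
                 discount: DiscountConfig = DiscountConfig()):
        self.utilities = utilities
        self.discount = discount
        self.counts: dict[tuple[int, object], int] = {}
        self.colonoscopies: dict[tuple[int, str], int] = {}
        self.qalys = 0.0
        self.life_years_from_base = 0.0
        self.n_people = 0
        self.n_invitations = 0
        self.n_fits = 0
        self.n_positive_fits = 0
        self.n_dx = 0
        self.n_dx_by_stage = [0, 0, 0, 0]
        self.n_screen_dx = 0
        self.n_crc_deaths = 0

    def add(self, outcome: PersonOutcome) -> None:
        self.n_people += 1
        by = outcome.individual.birth_year
        for year, key in _count_items(outcome):
            self.counts[(year, key)] = self.counts.get((year, key), 0) + 1
        for age, etype, detail in outcome.events:
            if etype == "colonoscopy":
                k = (by + int(age), detail[0])
                self.colonoscopies[k] = self.colonoscopies.get(k, 0) + 1
            elif etype == "invitation":
                self.n_invitations += 1
            elif etype == "fit":
                self.n_fits += 1
            elif etype == "fit_positive":
                self.n_positive_fits += 1
        self.qalys += tally_qalys(outcome, self.utilities, self.discount)
        self.life_years_from_base += max(
            0.0, outcome.death_age - (self.discount.base_year - by))
        for _a, stage, _l, screen in outcome.dx_records:
            self.n_dx += 1
            self.n_dx_by_stage[stage] += 1
            if screen:
                self.n_screen_dx += 1
        if outcome.cause_of_death == "crc":
            self.n_crc_deaths += 1

    def priced_ledger(self, costs: CostTable) -> dict[int, dict[str, float]]:
        """Undiscounted per-year cost ledger by category for the whole arm."""
        ledger: dict[int, dict[str, float]] = {}
        for (year, key), n in self.counts.items():
            cat, amount = _price(key, costs)
            if amount == 0.0:
                continue
            ledger.setdefault(year, {})
            ledger[year][cat] = ledger[year].get(cat, 0.0) + n * amount
        return ledger

    def total_cost(self, costs: CostTable, discounted: bool = True,
                   group: str | None = None) -> float:
        total = 0.0
        for year, cats in self.priced_ledger(costs).items():
            f = self.discount.factor(max(year, self.discount.base_year)) if discounted else 1.0
            for cat, amount in cats.items():
                if group is None or COMPONENT_GROUPS[cat] == group:
                    total += amount * f
        return total


@dataclass
class CEAResult:
    """Incremental cost-effectiveness of screening versus no screening."""

    cost_screened: float
    cost_unscreened: float
    treatment_cost_screened: float
    treatment_cost_unscreened: float
    qalys_screened: float
    qalys_unscreened: float

    @property
    def delta_cost(self) -> float:
        return self.cost_screened - self.cost_unscreened

    @property
    def delta_qalys(self) -> float:
        return self.qalys_screened - self.qalys_unscreened

    @property
    def verdict(self):
        return cea_verdict(self.delta_cost, self.delta_qalys)

    @property
    def icer(self) -> float | None:
        v = self.verdict
        return None if isinstance(v, str) else v

    def summary(self) -> dict:
        v = self.verdict
        return {
            "cost_screened": self.cost_screened,
            "cost_unscreened": self.cost_unscreened,
            "treatment_cost_screened": self.treatment_cost_screened,
            "treatment_cost_unscreened": self.treatment_cost_unscreened,
            "qalys_screened": self.qalys_screened,
            "qalys_unscreened": self.qalys_unscreened,
            "delta_cost": self.delta_cost,
            "delta_qalys": self.delta_qalys,
            "verdict": v if isinstance(v, str) else "icer",
            "icer": None if isinstance(v, str) else v,
        }


def cea_verdict(delta_cost: float, delta_qalys: float):
    """'dominant' iff cheaper and more effective, 'dominated' iff the
    opposite, else the numeric ICER (delta cost per QALY gained)."""
    if delta_cost < 0 and delta_qalys > 0:
        return "dominant"
    if delta_cost > 0 and delta_qalys < 0:
        return "dominated"
    if delta_qalys == 0:
        if delta_cost == 0:
            return 0.0
        return math.inf if delta_cost > 0 else -math.inf
    return delta_cost / delta_qalys


def compute_cea(screened: ArmAggregate, unscreened: ArmAggregate,
                costs: CostTable, scale_factor: float = 1.0) -> CEAResult:
    """Discounted lifetime CEA from two aggregates built on identical
    individuals (common random numbers)."""
    return CEAResult(
        cost_screened=screened.total_cost(costs) * scale_factor,
        cost_unscreened=unscreened.total_cost(costs) * scale_factor,
        treatment_cost_screened=screened.total_cost(costs, group="treatment") * scale_factor,
        treatment_cost_unscreened=unscreened.total_cost(costs, group="treatment") * scale_factor,
        qalys_screened=screened.qalys * scale_factor,
        qalys_unscreened=unscreened.qalys * scale_factor,
    )


@dataclass
class BIAResult:
    """Undiscounted annual financial streams per arm plus colonoscopy
    projections by purpose."""

    stream: pd.DataFrame        # year, arm, component, cost
    colonoscopies: pd.DataFrame  # year, purpose, count

    def incremental(self) -> pd.DataFrame:
        wide = (self.stream.groupby(["year", "arm"])["cost"].sum()
                .unstack("arm").fillna(0.0))
        for arm in ("screened", "unscreened"):
            if arm not in wide:
                wide[arm] = 0.0
        wide["incremental"] = wide["screened"] - wide["unscreened"]
        return wide.reset_index()


def compute_bia(screened: ArmAggregate, unscreened: ArmAggregate,
                costs: CostTable, scale_factor: float = 1.0,
                years: tuple[int, int] | None = (2009, 2038)) -> BIAResult:
    """Year-by-year undiscounted cost streams and colonoscopy counts.

    ``years=None`` keeps the full horizon (used for conservation checks);
    the default truncates the report to the 2009-2038 evaluation window.
    """
    rows = []
    for arm_name, agg in (("screened", screened), ("unscreened", unscreened)):
        for year, cats in agg.priced_ledger(costs).items():
            if years is not None and not (years[0] <= year <= years[1]):
                continue
            by_group: dict[str, float] = {}
            for cat, amount in cats.items():
                g = COMPONENT_GROUPS[cat]
                by_group[g] = by_group.get(g, 0.0) + amount
            for g, amount in by_group.items():
                rows.append({"year": year, "arm": arm_name, "component": g,
                             "cost": amount * scale_factor})
    crows = []
    for arm_name, agg in (("screened", screened), ("unscreened", unscreened)):
        for (year, purpose), n in agg.colonoscopies.items():
            if years is not None and not (years[0] <= year <= years[1]):
                continue
            crows.append({"year": year, "arm": arm_name, "purpose": purpose,
                          "count": n * scale_factor})
    stream = pd.DataFrame(rows, columns=["year", "arm", "component", "cost"])
    colos = pd.DataFrame(crows, columns=["year", "arm", "purpose", "count"])
    return BIAResult(stream.sort_values(["year", "arm", "component"])
                     .reset_index(drop=True),
                     colos.sort_values(["year", "arm", "purpose"])
                     .reset_index(drop=True))


def invitation_cost_sweep(screened: ArmAggregate, unscreened: ArmAggregate,
                          costs: CostTable, unit_costs: Iterable[float],
                          scale_factor: float = 1.0) -> pd.DataFrame:
    """Re-price the same event logs at each invitation unit cost.

    Dynamics are independent of unit costs, so incremental QALYs are
    identical across rows; only the incremental cost and verdict move.
    """
    rows = []
    for c in unit_costs:
        priced = replace(costs, invitation=float(c))
        cea = compute_cea(screened, unscreened, priced, scale_factor)
        v = cea.verdict
        rows.append({
            "invitation_cost": float(c),
            "delta_cost": cea.delta_cost,
            "delta_qalys": cea.delta_qalys,
            "verdict": v if isinstance(v, str) else "icer",
            "icer": None if isinstance(v, str) else v,
        })
    return pd.DataFrame(rows)
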