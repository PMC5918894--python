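"""End-to-end scenario orchestration with paired arms.

A scenario builds the population once, simulates every person's natural
history, overlays the screening programme on the *same* histories (common
random numbers), and reduces both arms to cost-effectiveness, budget-impact
and colonoscopy-projection outputs plus a manifest sufficient to reproduce
the run bit-identically.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__ as _version
from . import rng as rngmod
from .economics import (ArmAggregate, BIAResult, CEAResult, CostTable,
                        DiscountConfig, UtilityTable, compute_bia,
                        compute_cea, invitation_cost_sweep)
from .natural_history import NaturalHistoryParams, run_natural_history
from .population import ProgramConfig, build_population
from .screening import (ParticipationModel, ScreeningStreams,
                        SurveillanceRules, TestCharacteristics,
                        run_screened_history, unscreened_outcome)
from .synthetic import (DEFAULT_FEMALE_SHARE, DEFAULT_REFERENCE_YEAR,
                        DEFAULT_TOTAL, default_life_tables,
                        generate_demography)


@dataclass
class PopulationConfig:
    total: int = DEFAULT_TOTAL
    female_share: float = DEFAULT_FEMALE_SHARE
    reference_year: int = DEFAULT_REFERENCE_YEAR
    scale: float = 0.01


@dataclass
class ScenarioConfig:
    """Full configuration of one paired-arm scenario.

    ``seed`` is mandatory and drives every random stream.  Scenario switches
    mirror the published sensitivity analyses: ``low_prevalence`` swaps in an
    alternative natural history, ``systematic_fn_fraction > 0`` activates the
    correlated false-negative FIT scenario, and ``invitation_cost_sweep``
    re-prices the base run at alternative invitation unit costs.
    """

    seed: int
    population: PopulationConfig = field(default_factory=PopulationConfig)
    program: ProgramConfig = field(default_factory=ProgramConfig)
    nh_params: NaturalHistoryParams = field(default_factory=NaturalHistoryParams)
    test_characteristics: TestCharacteristics = field(default_factory=TestCharacteristics)
    participation: ParticipationModel = field(default_factory=ParticipationModel)
    surveillance_rules: SurveillanceRules = field(default_factory=SurveillanceRules)
    costs: CostTable = field(default_factory=CostTable)
    utilities: UtilityTable = field(default_factory=UtilityTable)
    invitation_cost_sweep: tuple[float, ...] = ()

    def to_dict(self) -> dict:
        return _to_plain(dataclasses.asdict(self))

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        d = dict(d)
        if "seed" not in d:
            raise ValueError("seed is mandatory in a scenario configuration")
        kw = {"seed": int(d["seed"])}
        for name, sub in (("population", PopulationConfig),
                          ("program", ProgramConfig),
                          ("nh_params", NaturalHistoryParams),
                          ("test_characteristics", TestCharacteristics),
                          ("participation", ParticipationModel),
                          ("surveillance_rules", SurveillanceRules),
                          ("costs", CostTable),
                          ("utilities", UtilityTable)):
            if name in d:
                kw[name] = _build_dataclass(sub, d[name])
        if "invitation_cost_sweep" in d:
            kw["invitation_cost_sweep"] = tuple(d["invitation_cost_sweep"])
        return cls(**kw)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as f:
            return cls.from_dict(yaml.safe_load(f))

    def to_yaml(self, path) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(self.to_dict(), f, sort_keys=True)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def _to_plain(obj):
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    return obj


def _build_dataclass(cls, d):
    if isinstance(d, cls):
        return d
    kw = {}
    for f in dataclasses.fields(cls):
        if f.name in d:
            v = d[f.name]
            if isinstance(v, list):
                v = tuple(tuple(x) if isinstance(x, list) else x for x in v)
            kw[f.name] = v
    return cls(**kw)


@dataclass
class ScenarioResult:
    """Everything one scenario run produces."""

    cea: CEAResult
    bia: BIAResult
    colonoscopy_projection: pd.DataFrame
    sweep: pd.DataFrame | None
    manifest: dict
    screened: ArmAggregate
    unscreened: ArmAggregate
    scale_factor: float


def simulate_arms(population, nh_params: NaturalHistoryParams,
                  program: ProgramConfig, participation: ParticipationModel,
                  chars: TestCharacteristics, rules: SurveillanceRules,
                  utilities: UtilityTable, seed: int,
                  discount: DiscountConfig | None = None
                  ) -> tuple[ArmAggregate, ArmAggregate]:
    """Run the unscreened and screened arms over identical individuals."""
    discount = discount or DiscountConfig(base_year=program.start_year,
                                          rate=program.discount_rate)
    unscreened = ArmAggregate(utilities, discount)
    screened = ArmAggregate(utilities, discount)
    nh_params.validate()
    for ind in population:
        r_nh = rngmod.substream(seed, ind.id, rngmod.NATURAL_HISTORY)
        life = run_natural_history(ind, nh_params, r_nh)
        unscreened.add(unscreened_outcome(life))
        streams = ScreeningStreams(
            participation=rngmod.substream(seed, ind.id, rngmod.PARTICIPATION),
            fit=rngmod.substream(seed, ind.id, rngmod.FIT),
            colonoscopy=rngmod.substream(seed, ind.id, rngmod.COLONOSCOPY))
        outcome = run_screened_history(life, program, participation, chars,
                                       rules, streams, nh_params)
        screened.add(outcome)
    return screened, unscreened


def run_scenario(config: ScenarioConfig, out_dir=None) -> ScenarioResult:
    """Build the population once, run both arms, and reduce to CEA, BIA and
    colonoscopy projections scaled to the full population."""
    pyramid = generate_demography(config.population.total,
                                  config.population.female_share,
                                  reference_year=config.population.reference_year)
    life_tables = default_life_tables()
    population = build_population(
        pyramid, life_tables, config.program, config.population.scale,
        config.seed, frailty_variance=config.nh_params.frailty_variance)
    scale_factor = pyramid.total / len(population)

    screened, unscreened = simulate_arms(
        population, config.nh_params, config.program, config.participation,
        config.test_characteristics, config.surveillance_rules,
        config.utilities, config.seed)

    cea = compute_cea(screened, unscreened, config.costs, scale_factor)
    bia = compute_bia(screened, unscreened, config.costs, scale_factor,
                      years=(config.program.start_year,
                             config.program.last_new_cohort_year))
    colos = (bia.colonoscopies[bia.colonoscopies["arm"] == "screened"]
             .drop(columns="arm").reset_index(drop=True))
    sweep = None
    if config.invitation_cost_sweep:
        sweep = invitation_cost_sweep(screened, unscreened, config.costs,
                                      config.invitation_cost_sweep,
                                      scale_factor)
    manifest = {
        "seed": config.seed,
        "config_sha256": config.config_hash(),
        "crcsim_version": _version,
        "n_individuals": len(population),
        "scale_factor": scale_factor,
    }
    result = ScenarioResult(cea, bia, colos, sweep, manifest, screened,
                            unscreened, scale_factor)
    if out_dir is not None:
        _write_outputs(result, Path(out_dir))
    return result


def _write_outputs(result: ScenarioResult, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "cea_result.json", "w") as f:
        json.dump(result.cea.summary(), f, indent=2)
    result.bia.stream.to_csv(out / "bia_stream.csv", index=False)
    result.colonoscopy_projection.to_csv(out / "colonoscopies.csv", index=False)
    if result.sweep is not None:
        result.sweep.to_csv(out / "invitation_cost_sweep.csv", index=False)
    with open(out / "manifest.json", "w") as f:
        json.dump(result.manifest, f, indent=2)
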