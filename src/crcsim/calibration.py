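"""Calibration of natural-history parameters to prevalence/incidence targets.

The objective is a weighted Pearson chi-square-style deviance: squared
residuals scaled by the binomial standard error for adenoma prevalence cells
and by the Poisson standard error for incidence cells.  Every objective
evaluation simulates a cohort with the *same* seed (common random numbers),
making the surface deterministic so a derivative-free simplex search
(Nelder-Mead, optionally restarted) behaves.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize

from .natural_history import NaturalHistoryParams, summarize_epidemiology
from .synthetic import simulate_cohort
from .tables import CalibrationTargets

_DEFAULT_CELL_N = 1000.0       # fallback effective n when targets lack one
_REJECT = 1e12                 # sentinel for non-finite evaluations

_PREV_KEYS = ["sex", "age_lo", "age_hi"]
_INC_KEYS = ["sex", "age_lo", "age_hi", "location", "stage"]


def _prevalence_residuals(sim: pd.DataFrame, tgt: pd.DataFrame) -> np.ndarray:
    merged = tgt.merge(sim, on=_PREV_KEYS, suffixes=("_t", "_s"))
    n = merged["n_t"] if "n_t" in merged else pd.Series(
        _DEFAULT_CELL_N, index=merged.index)
    n = n.astype(float).where(n > 0, _DEFAULT_CELL_N)
    p = merged["prevalence_t"].astype(float)
    p_adj = p.clip(lower=0.5 / n, upper=1 - 0.5 / n)
    se = np.sqrt(p_adj * (1 - p_adj) / n)
    return ((merged["prevalence_s"] - p) / se).to_numpy()


def _incidence_residuals(sim: pd.DataFrame, tgt: pd.DataFrame) -> np.ndarray:
    merged = tgt.merge(sim, on=_INC_KEYS, suffixes=("_t", "_s"))
    py = merged["person_years_t"] if "person_years_t" in merged else pd.Series(
        1e5, index=merged.index)
    py = py.astype(float).where(py > 0, 1e5)
    rate = merged["rate_per_100k_t"].astype(float)
    counts = (rate * py / 1e5).clip(lower=0.5)
    se = np.sqrt(counts) / py * 1e5
    return ((merged["rate_per_100k_s"] - rate) / se).to_numpy()


def objective_deviance(simulated: CalibrationTargets,
                       targets: CalibrationTargets,
                       weights: dict[str, float] | None = None) -> float:
    """Weighted sum of squared Pearson residuals over all target cells.

    Zero iff every cell matches exactly; invariant to target row order.
    """
    w = {"prevalence": 1.0, "incidence": 1.0, **(weights or {})}
    rp = _prevalence_residuals(simulated.prevalence, targets.prevalence)
    ri = _incidence_residuals(simulated.incidence, targets.incidence)
    return float(w["prevalence"] * np.sum(rp ** 2)
                 + w["incidence"] * np.sum(ri ** 2))


@dataclass
class CalibrationResult:
    params: NaturalHistoryParams
    fitted: dict[str, float]
    objective: float
    initial_objective: float
    trace: list[tuple[dict[str, float], float]]
    converged: bool
    n_evaluations: int

    def residual_table(self) -> pd.DataFrame | None:
        return getattr(self, "_residuals", None)


def _bands_from_targets(targets: CalibrationTargets):
    bands = sorted({(int(lo), int(hi)) for lo, hi in
                    zip(targets.prevalence["age_lo"], targets.prevalence["age_hi"])})
    return bands


def calibrate_parameters(initial_params: NaturalHistoryParams,
                         free_parameters: list[str],
                         targets: CalibrationTargets,
                         life_tables: dict,
                         sim_budget: int = 50_000,
                         optimizer_config: dict | None = None,
                         seed: int = 0,
                         weights: dict[str, float] | None = None,
                         ) -> CalibrationResult:
    """Fit the named scalar fields of ``initial_params`` to the targets.

    Free parameters are searched on the log scale (all are positive hazards,
    scales or means).  Each objective evaluation simulates ``sim_budget``
    individuals with the same seed, so repeated evaluations at the same
    point are bit-identical.  Nelder-Mead by default, with
    ``optimizer_config = {"n_restarts": k}`` adding k randomly perturbed
    restarts; the best vector ever evaluated (including the initial one) is
    returned, so the final objective never exceeds the initial objective.
    """
    cfg = {"maxfev": 80, "xatol": 0.01, "fatol": 1e-3, "n_restarts": 0,
           "simplex_step": 0.3, **(optimizer_config or {})}
    if sim_budget < 1000:
        raise ValueError("sim_budget must be at least 1000 individuals "
                         "per evaluation")
    bands = _bands_from_targets(targets)
    trace: list[tuple[dict[str, float], float]] = []

    def build(values: dict[str, float]) -> NaturalHistoryParams:
        return replace(initial_params, **values)

    def evaluate(values: dict[str, float]) -> float:
        params = build(values)
        try:
            histories = simulate_cohort(params, life_tables, sim_budget, seed)
            sim = summarize_epidemiology(histories, bands)
            obj = objective_deviance(sim, targets, weights)
        except (ValueError, OverflowError):
            obj = _REJECT
        if not math.isfinite(obj):
            obj = _REJECT
        trace.append((dict(values), obj))
        return obj

    init_values = {name: float(getattr(initial_params, name))
                   for name in free_parameters}
    f0 = evaluate(init_values)

    if not free_parameters:
        result = CalibrationResult(initial_params, init_values, f0, f0,
                                   trace, True, len(trace))
        return result

    names = list(free_parameters)

    def vec_obj(x: np.ndarray) -> float:
        return evaluate({n: math.exp(v) for n, v in zip(names, x)})

    x0 = np.array([math.log(max(v, 1e-12)) for v in init_values.values()])
    starts = [x0]
    rng = np.random.default_rng(seed)
    for _ in range(int(cfg["n_restarts"])):
        starts.append(x0 + rng.normal(scale=0.5, size=x0.shape))

    converged = False
    for s in starts:
        # explicit simplex: scipy's default step collapses near x0 = 0
        simplex = [s] + [s + cfg["simplex_step"] * np.eye(len(s))[i]
                         for i in range(len(s))]
        res = optimize.minimize(
            vec_obj, s, method="Nelder-Mead",
            options={"maxfev": cfg["maxfev"], "xatol": cfg["xatol"],
                     "fatol": cfg["fatol"],
                     "initial_simplex": np.array(simplex)})
        converged = converged or bool(res.success)

    best_values, best_obj = min(trace, key=lambda t: t[1])
    return CalibrationResult(build(best_values), best_values, best_obj, f0,
                             trace, converged, len(trace))


def validate_fit(params: NaturalHistoryParams, targets: CalibrationTargets,
                 life_tables: dict, n: int = 50_000, seed: int = 12345,
                 flag_threshold: float = 3.0) -> pd.DataFrame:
    """Goodness-of-fit report: one row per target cell with its Pearson
    residual against a fresh-seed simulation, flagged when |residual|
    exceeds ``flag_threshold``."""
    bands = _bands_from_targets(targets)
    histories = simulate_cohort(params, life_tables, n, seed)
    sim = summarize_epidemiology(histories, bands)

    rows = []
    res_p = _prevalence_residuals(sim.prevalence, targets.prevalence)
    merged = targets.prevalence.merge(sim.prevalence, on=_PREV_KEYS,
                                      suffixes=("_t", "_s"))
    for (_, row), r in zip(merged.iterrows(), res_p):
        rows.append({"kind": "prevalence", "sex": row["sex"],
                     "age_lo": row["age_lo"], "age_hi": row["age_hi"],
                     "location": None, "stage": None,
                     "target": row["prevalence_t"],
                     "simulated": row["prevalence_s"], "residual": r,
                     "flagged": abs(r) > flag_threshold})
    res_i = _incidence_residuals(sim.incidence, targets.incidence)
    merged = targets.incidence.merge(sim.incidence, on=_INC_KEYS,
                                     suffixes=("_t", "_s"))
    for (_, row), r in zip(merged.iterrows(), res_i):
        rows.append({"kind": "incidence", "sex": row["sex"],
                     "age_lo": row["age_lo"], "age_hi": row["age_hi"],
                     "location": row["location"], "stage": row["stage"],
                     "target": row["rate_per_100k_t"],
                     "simulated": row["rate_per_100k_s"], "residual": r,
                     "flagged": abs(r) > flag_threshold})
    return pd.DataFrame(rows)
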