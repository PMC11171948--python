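"""Sensitivity, probabilistic, and scenario analyses.

* One-way deterministic sensitivity analysis (DSA): each uncertain
  parameter is moved to base x (1 +- delta) with everything else at base,
  the target ICER is recomputed by exact rollback, and the results are
  presented as tornado entries sorted by bar width.
* Probabilistic sensitivity analysis (PSA): joint parameter draws from the
  fitted beta/gamma distributions; every strategy is evaluated on the same
  draw.  The default evaluation is expected-value rollback per draw (one
  level of Monte Carlo); ``mode="microsim"`` additionally simulates
  individuals within each draw (two-level, much slower).
* Cost-effectiveness acceptability curves (CEAC): at each willingness-to-pay
  value, each strategy's acceptance probability is the fraction of PSA
  iterations in which it attains the maximum net monetary benefit, ties
  split equally.
* Scenario analyses: referral-rate overrides and treatment-cost increases,
  re-running the base-case evaluation per scenario.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import cea
from .model import PRENATAL, ROUTINE, STRATEGIES, build_strategy_trees
from .params import ParameterError, ParameterSet, perturb, sample_parameter_arrays
from .tree import microsimulate, rollback

#: cost components scaled by the treatment-cost scenarios (treatment-related
#: services: diagnosis, medication, psychotherapy)
DEFAULT_SCALED_COSTS = ("c_diag", "c_med", "c_psychother")


def evaluate_strategies(
    pset: ParameterSet,
    trees=None,
    evaluator: str = "rollback",
    n: int | None = None,
    seed: int = 0,
) -> dict[str, tuple[float, float]]:
    """Per-strategy (expected cost, expected effect) under one realization.

    ``evaluator="rollback"`` is exact; ``"microsim"`` walks ``n``
    individuals per strategy with common random numbers across strategies
    (same seed, shared event labels).
    """
    trees = trees or build_strategy_trees()
    env = pset.env()
    if evaluator == "rollback":
        return {s: tuple(map(float, rollback(t, env))) for s, t in trees.items()}
    if evaluator == "microsim":
        if not n:
            raise ValueError("microsim evaluator needs a cohort size n")
        from .model import simulate_cohorts

        cohorts = simulate_cohorts(trees, env, n, seed)
        return {s: (r.mean_cost, r.mean_effect) for s, r in cohorts.items()}
    raise ValueError(f"unknown evaluator {evaluator!r}")


# -- one-way DSA -----------------------------------------------------------

@dataclass(frozen=True)
class TornadoEntry:
    parameter: str
    icer_low: float   # ICER at base x (1 - delta)
    icer_high: float  # ICER at base x (1 + delta)

    @property
    def width(self) -> float:
        return abs(self.icer_high - self.icer_low)


def _target_icer(results, target):
    alt, ref = target
    dc = results[alt][0] - results[ref][0]
    de = results[alt][1] - results[ref][1]
    if de == 0:
        return np.nan
    return dc / de


def one_way_dsa(
    pset: ParameterSet,
    delta: float = 0.2,
    target: tuple[str, str] = (PRENATAL, ROUTINE),
    parameters: list[str] | None = None,
) -> list[TornadoEntry]:
    """Tornado entries for the target ICER, sorted descending by width.

    Each uncertain parameter is perturbed to base x (1 +- delta) (clamped to
    its support) with all others at base; evaluation is deterministic
    rollback.  Parameters the trees never reference yield zero-width bars.
    """
    trees = build_strategy_trees()
    names = parameters if parameters is not None else pset.uncertain_names()
    entries = []
    for name in names:
        lo = _target_icer(evaluate_strategies(perturb(pset, name, 1.0 - delta), trees), target)
        hi = _target_icer(evaluate_strategies(perturb(pset, name, 1.0 + delta), trees), target)
        entries.append(TornadoEntry(name, float(lo), float(hi)))
    return sorted(entries, key=lambda t: t.width, reverse=True)


def tornado_frame(entries: list[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        [(t.parameter, t.icer_low, t.icer_high, t.width) for t in entries],
        columns=["parameter", "icer_low", "icer_high", "width"],
    )


# -- PSA -------------------------------------------------------------------

@dataclass
class PSAOutput:
    """Per-iteration (cost, effect) pairs for every strategy."""

    iterations: int
    seed: int
    costs: dict[str, np.ndarray] = field(repr=False)
    effects: dict[str, np.ndarray] = field(repr=False)

    def __post_init__(self):
        for d in (self.costs, self.effects):
            for s, arr in d.items():
                if len(arr) != self.iterations:
                    raise ValueError(f"{s}: array length != iterations")

    def scatter_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.costs:
            rows.append(pd.DataFrame({
                "iteration": np.arange(self.iterations),
                "strategy": s,
                "cost": self.costs[s],
                "effect": self.effects[s],
            }))
        return pd.concat(rows, ignore_index=True)


def run_psa(
    pset: ParameterSet,
    iterations: int,
    seed: int,
    mode: str = "expected-value",
    microsim_n: int = 1000,
) -> PSAOutput:
    """Probabilistic sensitivity analysis.

    Per iteration one joint parameter draw is applied to all three
    strategies.  ``expected-value`` mode rolls the trees back analytically
    under each draw (vectorized over iterations); ``microsim`` mode also
    simulates ``microsim_n`` individuals per draw.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    trees = build_strategy_trees()
    arrays = sample_parameter_arrays(pset, iterations, seed)
    costs, effects = {}, {}
    if mode == "expected-value":
        for s, tree in trees.items():
            c, e = rollback(tree, arrays)
            costs[s] = np.broadcast_to(np.asarray(c, dtype=float), (iterations,)).copy()
            effects[s] = np.broadcast_to(np.asarray(e, dtype=float), (iterations,)).copy()
    elif mode == "microsim":
        for s in trees:
            costs[s] = np.empty(iterations)
            effects[s] = np.empty(iterations)
        for i in range(iterations):
            env = {k: float(v[i]) for k, v in arrays.items()}
            for s, tree in trees.items():
                res = microsimulate(tree, env, microsim_n, seed + 1 + i)
                costs[s][i] = res.mean_cost
                effects[s][i] = res.mean_effect
    else:
        raise ValueError(f"unknown PSA mode {mode!r}")
    return PSAOutput(iterations, seed, costs, effects)


def ceac(psa: PSAOutput, wtp_grid) -> pd.DataFrame:
    """Cost-effectiveness acceptability curves over a WTP grid.

    Returns a DataFrame indexed by WTP with one acceptance-probability
    column per strategy; each row sums to 1 (ties split equally).
    """
    wtp_grid = np.asarray(list(wtp_grid), dtype=float)
    if wtp_grid.size == 0:
        raise ValueError("empty WTP grid")
    strategies = list(psa.costs)
    cost = np.column_stack([psa.costs[s] for s in strategies])     # (iters, S)
    effect = np.column_stack([psa.effects[s] for s in strategies])
    probs = np.empty((wtp_grid.size, len(strategies)))
    for j, w in enumerate(wtp_grid):
        nmb = w * effect - cost
        best = nmb.max(axis=1, keepdims=True)
        winners = (nmb == best)
        weights = winners / winners.sum(axis=1, keepdims=True)
        probs[j] = weights.mean(axis=0)
    out = pd.DataFrame(probs, columns=strategies)
    out.insert(0, "wtp", wtp_grid)
    return out


# -- scenarios -------------------------------------------------------------

@dataclass(frozen=True)
class ScenarioSpec:
    """A scenario: optional referral-rate override and/or cost multiplier.

    ``referral_rate`` replaces the probability of attending referral
    (``p_ref_high``); with ``override_self_referral=True`` the self-referral
    rates are replaced too.  ``cost_multiplier`` (>= 1: only service-cost
    increases are considered) scales ``scaled_costs``.
    """

    name: str
    referral_rate: float | None = None
    cost_multiplier: float = 1.0
    scaled_costs: tuple[str, ...] = DEFAULT_SCALED_COSTS
    override_self_referral: bool = False

    def __post_init__(self):
        if self.cost_multiplier < 1.0:
            raise ValueError("cost multiplier must be >= 1 (only increases are analyzed)")
        if self.referral_rate is not None and not (0.0 <= self.referral_rate <= 1.0):
            raise ValueError("referral rate must be a probability")

    def apply(self, pset: ParameterSet) -> ParameterSet:
        out = pset.at_base()
        if self.referral_rate is not None:
            out.values["p_ref_high"] = self.referral_rate
            if self.override_self_referral:
                out.values["p_selfref_low"] = self.referral_rate
                out.values["p_selfref_unscreened"] = self.referral_rate
        for name in self.scaled_costs if self.cost_multiplier != 1.0 else ():
            if name not in out.values:
                raise ParameterError(f"unknown cost field {name!r}")
            out.values[name] = out.values[name] * self.cost_multiplier
        return out


#: the published scenario grid: referral attendance levels and
#: treatment-cost increases
PAPER_SCENARIOS = (
    ScenarioSpec("referral_20", referral_rate=0.2),
    ScenarioSpec("referral_40", referral_rate=0.4),
    ScenarioSpec("referral_80", referral_rate=0.8),
    ScenarioSpec("referral_100", referral_rate=1.0),
    ScenarioSpec("costs_plus_50", cost_multiplier=1.5),
    ScenarioSpec("costs_plus_100", cost_multiplier=2.0),
)


def run_scenarios(
    pset: ParameterSet,
    scenarios=PAPER_SCENARIOS,
    evaluator: str = "rollback",
    n: int | None = None,
    seed: int = 0,
    reference: str = ROUTINE,
) -> dict[str, pd.DataFrame]:
    """Re-run the base-case evaluation under each scenario.

    Returns scenario name -> pairwise CEA table (vs ``reference``).
    """
    gdp = pset.constants.get("gdp_per_capita")
    out = {}
    for sc in scenarios:
        results = evaluate_strategies(sc.apply(pset), evaluator=evaluator, n=n, seed=seed)
        out[sc.name] = cea.icer_table(results, reference=reference, mode="pairwise",
                                      gdp_per_capita=gdp)
    return out
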