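"""Synthetic inputs: toy trees with known expectations, parameter fixtures,
and per-individual trajectory records.

The toy-tree generator computes each tree's exact expected cost and effect
*during construction* by forward accumulation over the generated branch
probabilities — a code path disjoint from the engine's bottom-up rollback —
so agreement between the two is a genuine oracle test, not a tautology.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import ParameterSet, load_default_parameters
from .tree import Branch, CohortResult, Node, chance, microsimulate, terminal


@dataclass(frozen=True)
class ToyTreeSpec:
    """Recipe for a random toy chance tree.

    ``depth`` levels of chance nodes with ``branching`` branches each;
    branch probabilities are Dirichlet-uniform (they sum to 1 by
    construction), branch costs and terminal payoffs are uniform over the
    given ranges.
    """

    depth: int = 3
    branching: int = 2
    cost_range: tuple[float, float] = (0.0, 100.0)
    effect_range: tuple[float, float] = (0.0, 1.0)
    seed: int = 0

    def __post_init__(self):
        if self.depth < 1 or self.branching < 2:
            raise ValueError("need depth >= 1 and branching >= 2")


def make_toy_tree(spec: ToyTreeSpec) -> tuple[Node, float, float]:
    """Random toy tree plus its exact expected (cost, effect).

    Probabilities and payoffs are embedded as numeric literals, so the tree
    needs no parameter environment.  The returned expectations are path
    sums accumulated while generating, independent of rollback.
    """
    rng = np.random.default_rng(spec.seed)
    exp = {"cost": 0.0, "effect": 0.0}
    counter = {"n": 0}

    def build(level: int, path_prob: float, path_cost: float) -> Node:
        counter["n"] += 1
        if level == spec.depth:
            cost = float(rng.uniform(*spec.cost_range))
            effect = float(rng.uniform(*spec.effect_range))
            exp["cost"] += path_prob * (path_cost + cost)
            exp["effect"] += path_prob * effect
            return terminal(f"t{counter['n']}", repr(cost), repr(effect), "leaf")
        probs = rng.dirichlet(np.ones(spec.branching))
        probs = probs / probs.sum()
        branches = []
        for j, p in enumerate(probs):
            p = float(p)
            cost = float(rng.uniform(*spec.cost_range))
            child = build(level + 1, path_prob * p, path_cost + cost)
            branches.append(Branch(f"b{counter['n']}_{j}", repr(p), repr(cost), child))
        # make the last probability close the sum exactly against fp error
        resid = 1.0 - sum(float(b.prob) for b in branches[:-1])
        exp_correction = resid - float(branches[-1].prob)
        if exp_correction != 0.0:
            # regenerate last branch bookkeeping with the corrected probability
            last = branches[-1]
            branches[-1] = Branch(last.label, repr(resid), last.cost, last.child)
        return chance(f"c{counter['n']}_{level}", branches)

    tree = build(0, 1.0, 0.0)
    return tree, exp["cost"], exp["effect"]


def make_fixture_params() -> ParameterSet:
    """The bundled parameter table (all point estimates, ranges, families)."""
    return load_default_parameters()


def generate_cohort_trajectories(
    tree: Node,
    params: ParameterSet | dict,
    n: int,
    seed: int,
) -> tuple[pd.DataFrame, CohortResult]:
    """One record per simulated individual, plus the matching aggregate.

    Records carry the individual id, the branch-label path taken, the
    accumulated cost, the effect and the terminal health-state tag.
    Aggregating the records reproduces :func:`ppdcea.tree.microsimulate`'s
    :class:`~ppdcea.tree.CohortResult` for the same seed exactly, because
    both come from the same walk.
    """
    env = params.env() if isinstance(params, ParameterSet) else dict(params)
    result, (cost, effect, tag_idx, path_idx, paths) = microsimulate(
        tree, env, n, seed, return_individuals=True
    )
    tag_names = sorted(result.counts)
    # tag indices are assigned in visit order inside microsimulate; rebuild
    # the visit-order list from the per-path tags
    records = pd.DataFrame({
        "individual": np.arange(n),
        "path": [" > ".join(paths[i]) for i in path_idx],
        "cost": cost,
        "effect": effect,
        "state": [_path_tag(paths[i], tree) for i in path_idx],
    })
    return records, result


def _path_tag(labels: tuple[str, ...], tree: Node) -> str:
    node = tree
    for label in labels:
        node = next(b.child for b in node.branches if b.label == label)
    return node.payoff.tag


def write_trajectories(records: pd.DataFrame, path) -> None:
    records.to_csv(path, index=False)
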