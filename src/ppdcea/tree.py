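"""Generic decision-tree machinery.

A tree is built from :class:`Node` objects (``decision``, ``chance`` or
``terminal``).  Chance-node branches carry *probability expressions* and
*incremental cost expressions* — plain arithmetic over parameter names —
so the clinical trees serialize to reviewable text and evaluate against any
:class:`~ppdcea.params.ParameterSet` realization (scalar or vectorized).

Evaluation routes:

``rollback``
    exact bottom-up expectation (no sampling);
``enumerate_paths``
    exhaustive root-to-terminal enumeration, the brute-force oracle that
    rollback must agree with to 1e-9;
``microsimulate``
    individual-level Monte Carlo: each simulated individual resolves every
    chance node against a pre-drawn uniform.

Uniforms are keyed by chance-node *label*: for a given seed, every
individual carries one uniform per event label, and trees that share event
labels (the three strategy arms share "ppd_onset", "cure", ...) resolve
them identically.  This common-random-numbers coupling makes incremental
costs and effects between arms far less noisy than independent streams
would, while keeping same-seed runs bit-for-bit reproducible.
"""

from __future__ import annotations

import ast
import warnings
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping

import numpy as np
import yaml

NODE_KINDS = ("decision", "chance", "terminal")

PROB_TOL = 1e-9


class TreeError(ValueError):
    """Raised for structurally invalid trees."""


# -- expressions -----------------------------------------------------------

_ALLOWED_NODES = (
    ast.Expression, ast.BinOp, ast.UnaryOp, ast.Constant, ast.Name, ast.Load,
    ast.Add, ast.Sub, ast.Mult, ast.Div, ast.USub, ast.UAdd,
)

_EXPR_CACHE: dict[str, Callable] = {}


def compile_expr(expr: str):
    """Compile an arithmetic expression over parameter names.

    Only +, -, *, /, unary signs, numbers and names are allowed; anything
    else raises :class:`TreeError`.  Compiled callables are cached.
    """
    fn = _EXPR_CACHE.get(expr)
    if fn is not None:
        return fn
    try:
        node = ast.parse(expr, mode="eval")
    except SyntaxError as exc:
        raise TreeError(f"bad expression {expr!r}: {exc}") from exc
    for sub in ast.walk(node):
        if not isinstance(sub, _ALLOWED_NODES):
            raise TreeError(f"disallowed construct {type(sub).__name__} in {expr!r}")
        if isinstance(sub, ast.Constant) and not isinstance(sub.value, (int, float)):
            raise TreeError(f"non-numeric constant in {expr!r}")
    code = compile(node, "<expr>", "eval")
    fn = lambda env: eval(code, {"__builtins__": {}}, env)  # noqa: S307 - AST whitelisted
    _EXPR_CACHE[expr] = fn
    return fn


def expr_names(expr: str) -> set[str]:
    """Parameter names referenced by an expression."""
    return {n.id for n in ast.walk(ast.parse(expr, mode="eval")) if isinstance(n, ast.Name)}


def evaluate(expr: str, env: Mapping[str, float]):
    try:
        return compile_expr(expr)(dict(env))
    except NameError as exc:
        raise TreeError(f"unknown name in expression {expr!r}: {exc}") from exc


# -- structure -------------------------------------------------------------

@dataclass
class Payoff:
    """Terminal payoff: cost and utility-weight expressions plus a state tag."""

    cost: str
    effect: str
    tag: str


@dataclass
class Branch:
    """An edge: probability expression, incremental cost expression, child."""

    label: str
    prob: str | None  # None only under a decision node
    cost: str
    child: "Node"


@dataclass
class Node:
    kind: str
    label: str
    branches: list[Branch] = field(default_factory=list)
    payoff: Payoff | None = None

    def is_terminal(self) -> bool:
        return self.kind == "terminal"


def terminal(label: str, cost: str, effect: str, tag: str) -> Node:
    return Node("terminal", label, payoff=Payoff(cost, effect, tag))


def chance(label: str, branches: Iterable[Branch]) -> Node:
    return Node("chance", label, branches=list(branches))


def decision(label: str, branches: Iterable[Branch]) -> Node:
    return Node("decision", label, branches=list(branches))


# -- validation ------------------------------------------------------------

@dataclass
class ValidationReport:
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def validate(tree: Node, env: Mapping[str, float] | None = None) -> ValidationReport:
    """Structural and probabilistic validation.

    Reports probability-sum violations and missing payoffs; flags branches
    whose probability evaluates to exactly 0 (unreachable) and chance labels
    repeated along a single path (which would reuse a uniform draw).  A
    cyclic structure is a hard error.
    """
    report = ValidationReport()
    env = dict(env or {})
    on_path: set[int] = set()

    def visit(node: Node, depth: int, labels_on_path: frozenset):
        if id(node) in on_path:
            raise TreeError(f"cycle detected at node {node.label!r}")
        if node.kind not in NODE_KINDS:
            report.errors.append(f"{node.label}: unknown node kind {node.kind!r}")
            return
        if node.kind == "terminal":
            if node.branches:
                report.errors.append(f"{node.label}: terminal node has branches")
            if node.payoff is None:
                report.errors.append(f"{node.label}: terminal node missing payoff")
            return
        if not node.branches:
            report.errors.append(f"{node.label}: {node.kind} node has no branches")
            return
        if node.kind == "decision" and depth > 0:
            report.errors.append(f"{node.label}: decision node below root")
        if node.kind == "chance":
            if node.label in labels_on_path:
                report.warnings.append(
                    f"{node.label}: chance label repeated along a path"
                )
            labels_on_path = labels_on_path | {node.label}
            try:
                probs = [evaluate(b.prob, env) for b in node.branches if b.prob is not None]
            except TreeError as exc:
                report.errors.append(str(exc))
                probs = None
            if probs is not None and len(probs) == len(node.branches):
                for b, p in zip(node.branches, probs):
                    if p < -PROB_TOL or p > 1 + PROB_TOL:
                        report.errors.append(
                            f"{node.label}/{b.label}: probability {p:.6g} outside [0, 1]"
                        )
                    elif p == 0.0:
                        report.warnings.append(
                            f"{node.label}/{b.label}: unreachable branch (probability 0)"
                        )
                total = float(sum(probs))
                if abs(total - 1.0) > PROB_TOL:
                    report.errors.append(
                        f"{node.label}: branch probabilities sum to {total!r}, not 1"
                    )
        on_path.add(id(node))
        try:
            for b in node.branches:
                if node.kind == "chance" and b.prob is None:
                    report.errors.append(f"{node.label}/{b.label}: missing probability")
                visit(b.child, depth + 1, labels_on_path)
        finally:
            on_path.discard(id(node))

    visit(tree, 0, frozenset())
    return report


# -- exact evaluation ------------------------------------------------------

def rollback(tree: Node, env: Mapping[str, float]) -> tuple[float, float]:
    """Bottom-up expected (cost, effect) of a chance/terminal tree.

    Terminal value = payoff; chance value = sum_i p_i * (child_i value +
    branch incremental cost).  Deterministic — no sampling.  Works on scalar
    or numpy-array environments (all names must broadcast together).
    """
    env = dict(env)

    def value(node: Node):
        if node.kind == "terminal":
            return evaluate(node.payoff.cost, env), evaluate(node.payoff.effect, env)
        if node.kind == "decision":
            raise TreeError(
                f"{node.label}: decision node in rollback; evaluate each strategy branch"
            )
        cost = 0.0
        effect = 0.0
        for b in node.branches:
            p = evaluate(b.prob, env)
            c, e = value(b.child)
            cost = cost + p * (evaluate(b.cost, env) + c)
            effect = effect + p * e
        return cost, effect

    return value(tree)


@dataclass
class PathRecord:
    prob: float
    cost: float
    effect: float
    tag: str
    labels: tuple[str, ...]


def enumerate_paths(tree: Node, env: Mapping[str, float]) -> list[PathRecord]:
    """Exhaustive root-to-terminal enumeration (the brute-force oracle).

    Path probabilities sum to 1 (within 1e-9) and the probability-weighted
    cost/effect sums equal :func:`rollback`.
    """
    env = dict(env)
    out: list[PathRecord] = []

    def walk(node: Node, prob: float, cost: float, labels: tuple[str, ...]):
        if node.kind == "terminal":
            out.append(
                PathRecord(
                    prob,
                    cost + evaluate(node.payoff.cost, env),
                    evaluate(node.payoff.effect, env),
                    node.payoff.tag,
                    labels,
                )
            )
            return
        if node.kind == "decision":
            raise TreeError(f"{node.label}: decision node in path enumeration")
        for b in node.branches:
            p = evaluate(b.prob, env)
            walk(b.child, prob * p, cost + evaluate(b.cost, env), labels + (b.label,))

    walk(tree, 1.0, 0.0, ())
    return out


# -- microsimulation -------------------------------------------------------

@dataclass
class CohortResult:
    """Aggregate of one microsimulated cohort."""

    n: int
    seed: int
    mean_cost: float
    mean_effect: float
    counts: dict[str, int]

    def __post_init__(self):
        if sum(self.counts.values()) != self.n:
            raise TreeError("terminal-state counts do not sum to cohort size")


def chance_labels(tree: Node) -> list[str]:
    """Sorted unique chance-node labels in a tree."""
    labels = set()

    def walk(node: Node):
        if node.kind == "chance":
            labels.add(node.label)
        for b in node.branches:
            walk(b.child)

    walk(tree)
    return sorted(labels)


def label_uniforms(labels: Iterable[str], n: int, seed: int) -> dict[str, np.ndarray]:
    """One uniform per individual per event label, derived from ``seed``.

    The stream for a label depends only on (seed, label), so two trees
    sharing a label see identical uniforms — the common-random-numbers
    contract.
    """
    out = {}
    for label in labels:
        key = zlib.crc32(label.encode()) & 0x7FFFFFFF
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), key]))
        out[label] = rng.random(n)
    return out


def sobol_label_uniforms(
    labels: Iterable[str], n: int, seed: int, order: Iterable[str] | None = None
) -> dict[str, np.ndarray]:
    """Scrambled-Sobol uniforms, one dimension per event label.

    A randomized quasi-Monte-Carlo alternative to :func:`label_uniforms`:
    individuals are rows of one scrambled Sobol matrix, so event
    combinations are near-equidistributed and cohort means converge much
    faster than with pseudo-random draws, while scrambling keeps the
    estimate unbiased and seed-reproducible.  Dimensions are assigned to
    labels in ``order`` (Sobol's leading dimensions have the best
    equidistribution, so put the labels whose interactions drive the
    quantity of interest first), remaining labels sorted; pass the union
    of labels when several trees are compared so arms share both the
    matrix and the assignment.
    """
    from scipy.stats import qmc

    labels = set(labels)
    ordered = [lab for lab in (order or ()) if lab in labels]
    labels = ordered + sorted(labels - set(ordered))
    sampler = qmc.Sobol(d=len(labels), scramble=True, seed=int(seed))
    with warnings.catch_warnings():
        # n need not be a power of two; the scramble keeps the estimate unbiased
        warnings.simplefilter("ignore", UserWarning)
        mat = sampler.random(n)
    return {label: np.ascontiguousarray(mat[:, i]) for i, label in enumerate(labels)}


def microsimulate(
    tree: Node,
    env: Mapping[str, float],
    n: int,
    seed: int,
    return_individuals: bool = False,
    uniforms: Mapping[str, np.ndarray] | None = None,
):
    """Simulate ``n`` independent individuals through the tree.

    Each individual walks root to terminal, resolving every chance node by
    comparing its uniform for that node's label against the cumulative
    branch probabilities (left-closed intervals).  Returns a
    :class:`CohortResult`; with ``return_individuals=True`` also returns
    per-individual arrays ``(cost, effect, tag_index, path_index)`` plus the
    list of path label-chains.  ``uniforms`` may supply pre-drawn
    per-label streams (used by :func:`microsimulate_strategies`).
    """
    if n < 1:
        raise TreeError("cohort size must be >= 1")
    env = dict(env)
    u = uniforms if uniforms is not None else label_uniforms(chance_labels(tree), n, seed)

    cost = np.zeros(n)
    effect = np.zeros(n)
    tags: list[str] = []
    tag_idx = np.full(n, -1, dtype=np.int64)
    path_idx = np.full(n, -1, dtype=np.int64)
    paths: list[tuple[str, ...]] = []

    def walk(node: Node, idx: np.ndarray, labels: tuple[str, ...]):
        if idx.size == 0 and node.kind != "terminal":
            # still recurse nowhere; terminal bookkeeping below handles size 0
            pass
        if node.kind == "terminal":
            cost[idx] += evaluate(node.payoff.cost, env)
            effect[idx] = evaluate(node.payoff.effect, env)
            tag = node.payoff.tag
            if tag not in tags:
                tags.append(tag)
            tag_idx[idx] = tags.index(tag)
            paths.append(labels)
            path_idx[idx] = len(paths) - 1
            return
        if node.kind == "decision":
            raise TreeError(f"{node.label}: decision node in microsimulation")
        probs = [float(evaluate(b.prob, env)) for b in node.branches]
        edges = np.cumsum(probs)
        edges[-1] = max(edges[-1], 1.0)  # absorb fp residue in the last interval
        draws = u[node.label][idx]
        lo = 0.0
        for b, hi in zip(node.branches, edges):
            mask = (draws >= lo) & (draws < hi)
            sub = idx[mask]
            if sub.size:
                cost[sub] += evaluate(b.cost, env)
                walk(b.child, sub, labels + (b.label,))
            elif b.child.kind == "terminal":
                walk(b.child, sub, labels + (b.label,))
            lo = hi

    walk(tree, np.arange(n), ())

    counts: dict[str, int] = {}
    binc = np.bincount(tag_idx[tag_idx >= 0], minlength=len(tags))
    for tag, c in zip(tags, binc):
        counts[tag] = counts.get(tag, 0) + int(c)
    result = CohortResult(
        n=n,
        seed=seed,
        mean_cost=float(cost.mean()),
        mean_effect=float(effect.mean()),
        counts=counts,
    )
    if return_individuals:
        return result, (cost, effect, tag_idx, path_idx, paths)
    return result


def microsimulate_strategies(
    trees: Mapping[str, Node],
    env: Mapping[str, float],
    n: int,
    seed: int,
    method: str = "qmc",
    label_order: Iterable[str] | None = None,
) -> dict[str, CohortResult]:
    """Microsimulate the same cohort through several strategy trees.

    All trees share one set of per-label uniforms built over the union of
    their event labels, so an individual resolves any event she encounters
    identically in every arm (common random numbers).  ``method="qmc"``
    draws the uniforms as one scrambled Sobol matrix, which sharply reduces
    Monte-Carlo noise in *incremental* quantities (the inputs to ICERs);
    ``method="pseudo"`` uses the independent per-label streams of
    :func:`label_uniforms`.
    """
    labels = sorted(set().union(*(chance_labels(t) for t in trees.values())))
    if method == "qmc":
        u = sobol_label_uniforms(labels, n, seed, order=label_order)
    elif method == "pseudo":
        u = label_uniforms(labels, n, seed)
    else:
        raise ValueError(f"unknown method {method!r}")
    return {
        s: microsimulate(tree, env, n, seed, uniforms=u)
        for s, tree in trees.items()
    }


# -- serialization ---------------------------------------------------------

def to_dict(tree: Node, _memo: dict | None = None) -> dict:
    # shared subtrees map to the same dict object, so YAML emits them once
    # as an anchor plus aliases and the file stays reviewably small
    memo = _memo if _memo is not None else {}
    cached = memo.get(id(tree))
    if cached is not None:
        return cached
    if tree.kind == "terminal":
        out = {
            "kind": "terminal",
            "label": tree.label,
            "payoff": {
                "cost": tree.payoff.cost,
                "effect": tree.payoff.effect,
                "tag": tree.payoff.tag,
            },
        }
    else:
        out = {
            "kind": tree.kind,
            "label": tree.label,
            "branches": [
                {
                    "label": b.label,
                    **({"prob": b.prob} if b.prob is not None else {}),
                    "cost": b.cost,
                    "child": to_dict(b.child, memo),
                }
                for b in tree.branches
            ],
        }
    memo[id(tree)] = out
    return out


def from_dict(doc: Mapping) -> Node:
    kind = doc["kind"]
    if kind == "terminal":
        p = doc["payoff"]
        return terminal(doc["label"], p["cost"], p["effect"], p["tag"])
    branches = [
        Branch(b["label"], b.get("prob"), b.get("cost", "0"), from_dict(b["child"]))
        for b in doc["branches"]
    ]
    return Node(kind, doc["label"], branches=branches)


def write_tree(tree: Node, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(to_dict(tree), fh, sort_keys=False)


def read_tree(path: str | Path) -> Node:
    with open(path) as fh:
        return from_dict(yaml.safe_load(fh))


def trees_equal(a: Node, b: Node) -> bool:
    """Structural equality (shared subtrees compare by content)."""
    return to_dict(a) == to_dict(b)
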