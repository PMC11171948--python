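"""Pipeline orchestration: configuration, full-run archives, manifests.

A :class:`RunConfig` fully determines a run.  ``run_base_case`` produces
the headline cost-effectiveness table and health-state counts;
``run_full_analysis`` executes every stage (base case, tornado, PSA, CEAC,
scenarios) with independently derived stage seeds and writes a manifest
that makes the archive reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import cea
from .model import (
    ROUTINE, STRATEGIES, build_strategy_trees, classify_cohort, simulate_cohorts,
)
from .params import ParameterSet, load_default_parameters, read_parameters
from .uncertainty import (
    PAPER_SCENARIOS, ceac, evaluate_strategies, one_way_dsa, run_psa,
    run_scenarios, tornado_frame,
)

logger = logging.getLogger("ppdcea")

# fixed offsets deriving stage seeds from the master seed, so stages are
# independently reproducible
SEED_OFFSETS = {"base": 1, "dsa": 2, "psa": 3, "scenarios": 4}
_SEED_MOD = 2**31 - 1


def stage_seed(master: int, stage: str) -> int:
    return (int(master) + SEED_OFFSETS[stage]) % _SEED_MOD


@dataclass
class RunConfig:
    """Everything a run needs; flags override file values upstream."""

    parameter_file: str | None = None   # None -> bundled fixture
    strategies: tuple[str, ...] = STRATEGIES
    cohort_n: int | None = None         # None -> parameter-file constant
    seed: int = 12345
    psa_iterations: int = 10000
    wtp_grid: tuple[float, ...] = tuple(np.arange(0, 30001, 250.0))
    scenarios: tuple = PAPER_SCENARIOS
    output_dir: str = "results"
    evaluation_mode: str = "microsim"   # microsim | rollback
    raw_qaly: bool = False              # report QALYs over the raw horizon

    def __post_init__(self):
        if self.cohort_n is not None and self.cohort_n < 1:
            raise ValueError("cohort size must be >= 1")
        if self.psa_iterations < 1:
            raise ValueError("PSA iterations must be >= 1")
        grid = list(self.wtp_grid)
        if any(b <= a for a, b in zip(grid, grid[1:])):
            raise ValueError("WTP grid must be strictly increasing")

    def load_parameters(self) -> ParameterSet:
        if self.parameter_file is None:
            return load_default_parameters()
        return read_parameters(self.parameter_file)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls(**doc)


def _disclose_calibrated(pset: ParameterSet) -> None:
    names = pset.calibrated_names()
    if names:
        logger.info(
            "calibrated (not literature-sourced) parameters in effect: %s",
            ", ".join(f"{n}={pset[n]:g}" for n in names),
        )


def run_base_case(config: RunConfig):
    """Base-case evaluation: CEA table plus per-strategy cohort results.

    Microsimulates ``cohort_n`` women per strategy with common random
    numbers (shared master seed), classifies terminal health states, and
    builds the pairwise CEA table against routine care.
    """
    pset = config.load_parameters()
    _disclose_calibrated(pset)
    n = config.cohort_n or int(pset.constants.get("cohort_n", 10000))
    seed = stage_seed(config.seed, "base")
    trees = {s: t for s, t in build_strategy_trees(pset).items() if s in config.strategies}
    scale = pset.constants.get("horizon_years", 1.0) if config.raw_qaly else 1.0

    cohorts = {}
    results = {}
    if config.evaluation_mode == "microsim":
        cohorts = simulate_cohorts(trees, pset, n, seed)
        results = {s: (r.mean_cost, r.mean_effect * scale) for s, r in cohorts.items()}
    else:
        for s, (c, e) in evaluate_strategies(pset, trees).items():
            results[s] = (c, e * scale)
    table = cea.icer_table(
        results, reference=ROUTINE, mode="pairwise",
        gdp_per_capita=pset.constants.get("gdp_per_capita"),
    )
    return table, cohorts


def health_state_table(cohorts) -> pd.DataFrame:
    rows = {s: classify_cohort(res) for s, res in cohorts.items()}
    return pd.DataFrame(rows).T.rename_axis("strategy")


def run_full_analysis(config: RunConfig) -> dict:
    """Execute all stages and write the archive; returns the manifest.

    Completed stages persist even if a later stage fails; the manifest
    records per-stage status, seeds and an input hash.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    pset = config.load_parameters()
    manifest: dict = {
        "package_version": __version__,
        "master_seed": int(config.seed),
        "stage_seeds": {k: stage_seed(config.seed, k) for k in SEED_OFFSETS},
        "parameter_file": config.parameter_file or "<bundled>",
        "parameter_hash": _params_hash(pset),
        "cohort_n": config.cohort_n or int(pset.constants.get("cohort_n", 10000)),
        "psa_iterations": int(config.psa_iterations),
        "stages": {},
        "outputs": [],
    }

    def stage(name, fn):
        try:
            fn()
            manifest["stages"][name] = "ok"
        except Exception as exc:  # noqa: BLE001 - partial-failure policy
            logger.exception("stage %s failed", name)
            manifest["stages"][name] = f"failed: {exc}"

    def base():
        table, cohorts = run_base_case(config)
        cea.write_cea_csv(table, outdir / "base_case_cea.csv")
        manifest["outputs"].append("base_case_cea.csv")
        if cohorts:
            health_state_table(cohorts).to_csv(outdir / "health_states.csv")
            manifest["outputs"].append("health_states.csv")

    def dsa():
        entries = one_way_dsa(pset)
        tornado_frame(entries).to_csv(outdir / "tornado.csv", index=False)
        manifest["outputs"].append("tornado.csv")

    def psa_stage():
        psa = run_psa(pset, config.psa_iterations, stage_seed(config.seed, "psa"))
        psa.scatter_frame().to_csv(outdir / "psa_scatter.csv", index=False)
        curves = ceac(psa, config.wtp_grid)
        curves.to_csv(outdir / "ceac.csv", index=False)
        manifest["outputs"] += ["psa_scatter.csv", "ceac.csv"]

    def scenarios():
        n = config.cohort_n or int(pset.constants.get("cohort_n", 10000))
        tables = run_scenarios(
            pset, config.scenarios,
            evaluator=config.evaluation_mode,
            n=n, seed=stage_seed(config.seed, "scenarios"),
        )
        for name, table in tables.items():
            fname = f"scenario_{name}.csv"
            cea.write_cea_csv(table, outdir / fname)
            manifest["outputs"].append(fname)

    stage("base", base)
    stage("dsa", dsa)
    stage("psa", psa_stage)
    stage("scenarios", scenarios)

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _params_hash(pset: ParameterSet) -> str:
    payload = json.dumps(
        {
            "params": {n: asdict(p) for n, p in sorted(pset.params.items())},
            "constants": dict(sorted(pset.constants.items())),
        },
        sort_keys=True,
    )
    return hashlib.sha256(payload.encode()).hexdigest()
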