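"""Model parameters and their second-order distributions.

Every uncertain quantity in the model carries a point estimate (``base``),
a plausible range ``(low, high)`` and a distribution family: ``gamma`` for
costs, ``beta`` for probabilities and utilities, ``fixed`` for analysis
constants.  Ranges are treated as central 95% intervals and fitted by method
of moments so that the distribution mean equals the point estimate — the
convention a probabilistic sensitivity analysis needs when only a point
estimate and a range are published.

The bundled fixture (``data/parameters.yaml``) holds the full parameter
table for the postpartum-depression model, including the two treatment cure
rates that are calibrated rather than sourced (flagged ``calibrated``).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import yaml

logger = logging.getLogger("ppdcea")

#: half-width of a central 95% normal interval, in standard deviations
_Z95_SPAN = 3.92

FAMILIES = ("beta", "gamma", "fixed")


class ParameterError(ValueError):
    """Raised for invalid parameter definitions or operations."""


@dataclass(frozen=True)
class DistSpec:
    """A fitted second-order distribution.

    ``kind`` is ``"beta"``, ``"gamma"`` or ``"point"``; ``args`` holds the
    native parameters ((a, b) for beta, (shape, rate) for gamma, (value,)
    for a point mass).  ``mean`` and ``sd`` are the analytic moments.
    """

    kind: str
    mean: float
    sd: float
    args: tuple[float, ...]

    def rvs(self, rng: np.random.Generator, size=None):
        if self.kind == "beta":
            a, b = self.args
            return rng.beta(a, b, size=size)
        if self.kind == "gamma":
            shape, rate = self.args
            return rng.gamma(shape, 1.0 / rate, size=size)
        value = self.args[0]
        if size is None:
            return value
        return np.full(size, value)


def fit_beta(base: float, low: float, high: float) -> DistSpec:
    """Fit a beta distribution with mean ``base`` from a 95% range.

    The spread comes from ``sd = (high - low) / 3.92``.  A range upper end
    above 1 is clamped to 1 (with a warning); if the implied variance is
    infeasible for a beta with that mean it is shrunk to 95% of the feasible
    maximum, again with a warning.  A zero-width range (or a boundary mean)
    degenerates to a point mass.
    """
    if high > 1.0:
        logger.warning("beta range upper end %.4g > 1; clamped to 1", high)
        high = 1.0
    if low < 0.0:
        raise ParameterError(f"beta range lower end {low} < 0")
    if not (low <= base <= high):
        raise ParameterError(f"base {base} outside range [{low}, {high}]")
    if base > 1.0:
        raise ParameterError(f"beta mean {base} > 1")
    if high == low or base in (0.0, 1.0):
        return DistSpec("point", base, 0.0, (base,))
    sd = (high - low) / _Z95_SPAN
    var = sd * sd
    vmax = base * (1.0 - base)
    if var >= vmax:
        logger.warning(
            "beta variance %.4g infeasible for mean %.4g; shrunk to feasible maximum",
            var, base,
        )
        var = 0.95 * vmax
    kappa = base * (1.0 - base) / var - 1.0
    a = base * kappa
    b = (1.0 - base) * kappa
    return DistSpec("beta", base, math.sqrt(var), (a, b))


def fit_gamma(base: float, low: float, high: float) -> DistSpec:
    """Fit a gamma distribution with mean ``base`` from a 95% range.

    shape = mean^2 / var, rate = mean / var with sd = (high - low) / 3.92.
    A zero-width range degenerates to a point mass; negative inputs are
    rejected.
    """
    if low < 0.0 or base < 0.0:
        raise ParameterError(f"gamma inputs must be non-negative (base={base}, low={low})")
    if not (low <= base <= high):
        raise ParameterError(f"base {base} outside range [{low}, {high}]")
    if high == low or base == 0.0:
        return DistSpec("point", base, 0.0, (base,))
    sd = (high - low) / _Z95_SPAN
    var = sd * sd
    shape = base * base / var
    rate = base / var
    return DistSpec("gamma", base, sd, (shape, rate))


@dataclass(frozen=True)
class Parameter:
    """One model quantity: point estimate, range, distribution family."""

    name: str
    base: float
    low: float
    high: float
    family: str
    description: str = ""
    calibrated: bool = False

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ParameterError(f"{self.name}: unknown family {self.family!r}")
        if self.family != "fixed" and not (self.low <= self.base <= self.high):
            raise ParameterError(
                f"{self.name}: base {self.base} outside range [{self.low}, {self.high}]"
            )

    @property
    def uncertain(self) -> bool:
        return self.family != "fixed"

    def dist(self) -> DistSpec:
        if self.family == "beta":
            return fit_beta(self.base, self.low, self.high)
        if self.family == "gamma":
            return fit_gamma(self.base, self.low, self.high)
        return DistSpec("point", self.base, 0.0, (self.base,))

    def support(self) -> tuple[float, float]:
        """Legal support for the parameter's value under its family."""
        if self.family == "beta":
            return (0.0, 1.0)
        if self.family == "gamma":
            return (0.0, math.inf)
        return (-math.inf, math.inf)


class ParameterSet:
    """A parameter table plus one concrete realization of its values.

    ``params`` maps name -> :class:`Parameter` (the second-order
    specification); ``values`` maps name -> the current realization, which
    defaults to the point estimates.  ``constants`` holds analysis-level
    scalars (willingness to pay, cohort size, horizon).
    """

    def __init__(
        self,
        params: Mapping[str, Parameter],
        values: Mapping[str, float] | None = None,
        constants: Mapping[str, float] | None = None,
    ):
        self.params: dict[str, Parameter] = dict(params)
        self.values: dict[str, float] = (
            dict(values) if values is not None else {n: p.base for n, p in self.params.items()}
        )
        self.constants: dict[str, float] = dict(constants or {})
        missing = set(self.params) - set(self.values)
        if missing:
            raise ParameterError(f"values missing for {sorted(missing)}")

    # -- mapping-ish access -------------------------------------------------
    def __getitem__(self, name: str) -> float:
        if name in self.values:
            return self.values[name]
        return self.constants[name]

    def __contains__(self, name: str) -> bool:
        return name in self.values or name in self.constants

    def __iter__(self) -> Iterator[str]:
        return iter(self.params)

    def env(self) -> dict[str, float]:
        """Evaluation environment for tree expressions."""
        out = dict(self.constants)
        out.update(self.values)
        return out

    def uncertain_names(self) -> list[str]:
        return [n for n, p in self.params.items() if p.uncertain]

    def calibrated_names(self) -> list[str]:
        return [n for n, p in self.params.items() if p.calibrated]

    def copy(self) -> "ParameterSet":
        return ParameterSet(self.params, self.values, self.constants)

    def at_base(self) -> "ParameterSet":
        return ParameterSet(self.params, None, self.constants)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, ParameterSet)
            and self.params == other.params
            and self.values == other.values
            and self.constants == other.constants
        )

    def __repr__(self) -> str:
        return f"ParameterSet({len(self.params)} parameters, {len(self.constants)} constants)"


def sample_parameters(pset: ParameterSet, seed: int) -> ParameterSet:
    """One independent draw of every uncertain parameter.

    Deterministic for a fixed seed; fixed parameters pass through unchanged.
    Draws are taken in sorted name order so the result does not depend on
    dict insertion order.
    """
    rng = np.random.default_rng(seed)
    values = dict(pset.values)
    for name in sorted(pset.params):
        p = pset.params[name]
        if p.uncertain:
            values[name] = float(p.dist().rvs(rng))
        else:
            values[name] = p.base
    return ParameterSet(pset.params, values, pset.constants)


def sample_parameter_arrays(
    pset: ParameterSet, iterations: int, seed: int
) -> dict[str, np.ndarray]:
    """Vectorized draws: name -> array of ``iterations`` values.

    Fixed parameters are broadcast.  The i-th entry of every array belongs to
    the same joint draw, which is what a probabilistic sensitivity analysis
    requires (the same parameter realization applied to every strategy).
    """
    rng = np.random.default_rng(seed)
    out: dict[str, np.ndarray] = {}
    for name in sorted(pset.params):
        p = pset.params[name]
        if p.uncertain:
            out[name] = np.asarray(p.dist().rvs(rng, size=iterations), dtype=float)
        else:
            out[name] = np.full(iterations, p.base)
    for name, value in pset.constants.items():
        out.setdefault(name, np.full(iterations, float(value)))
    return out


def perturb(pset: ParameterSet, name: str, factor: float) -> ParameterSet:
    """Copy of ``pset`` with one field set to base * factor (others at base).

    The result is clamped to the field's legal support (with a warning), the
    convention used by the one-way sensitivity analysis.
    """
    if name not in pset.params:
        raise ParameterError(f"unknown parameter {name!r}")
    p = pset.params[name]
    lo, hi = p.support()
    value = p.base * factor
    if value < lo or value > hi:
        clamped = min(max(value, lo), hi)
        logger.warning("%s: perturbed value %.4g clamped to %.4g", name, value, clamped)
        value = clamped
    out = pset.at_base()
    out.values[name] = value
    return out


# -- serialization ---------------------------------------------------------

def _parse_row(name: str, row: Mapping) -> Parameter:
    base = float(row["base"])
    rng = row.get("range")
    if rng is None:
        low = high = base
    else:
        a, b = float(rng[0]), float(rng[1])
        if a > b:
            logger.info("%s: range printed high~low (%g~%g); normalized", name, a, b)
        low, high = min(a, b), max(a, b)
    family = row.get("family", "fixed")
    if family in ("β", "Beta"):
        family = "beta"
    if family == "beta" and high > 1.0:
        logger.warning("%s: range upper end %.4g > 1; clamped to 1", name, high)
        high = 1.0
    return Parameter(
        name=name,
        base=base,
        low=low,
        high=high,
        family=family,
        description=str(row.get("description", "")),
        calibrated=bool(row.get("calibrated", False)),
    )


def read_parameters(path: str | Path) -> ParameterSet:
    """Read a parameter file (YAML: name -> {base, range, family, ...})."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return _from_doc(doc, source=str(path))


def _from_doc(doc: Mapping, source: str = "<doc>") -> ParameterSet:
    try:
        rows = doc["parameters"]
    except (KeyError, TypeError):
        raise ParameterError(f"{source}: missing 'parameters' section")
    params = {}
    for name, row in rows.items():
        try:
            params[name] = _parse_row(name, row)
        except (KeyError, TypeError, ValueError) as exc:
            raise ParameterError(f"{source}: bad parameter row {name!r}: {exc}") from exc
    constants = {k: float(v) for k, v in (doc.get("analysis") or {}).items()}
    return ParameterSet(params, None, constants)


def write_parameters(pset: ParameterSet, path: str | Path) -> None:
    """Write a parameter file that round-trips through :func:`read_parameters`."""
    rows = {}
    for name, p in pset.params.items():
        row: dict = {"base": p.base}
        if p.uncertain:
            row["range"] = [p.low, p.high]
        row["family"] = p.family
        if p.description:
            row["description"] = p.description
        if p.calibrated:
            row["calibrated"] = True
        rows[name] = row
    doc = {"parameters": rows, "analysis": dict(pset.constants)}
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_default_parameters() -> ParameterSet:
    """The bundled parameter table for the PPD model."""
    text = resources.files("ppdcea").joinpath("data/parameters.yaml").read_text()
    return _from_doc(yaml.safe_load(text), source="ppdcea/data/parameters.yaml")
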