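"""Incremental cost-effectiveness tables, dominance and WHO classification.

The incremental cost-effectiveness ratio (ICER) between two strategies is
Δcost / Δeffect, computed at full precision; display rounding to two
decimals happens only at output, so a printed table can legitimately show
increments whose quotient differs in the last digit from the printed ICER.

Two table modes are supported:

``pairwise``
    every strategy compared against a fixed reference (the mode used for
    the headline results, where both active strategies are compared to
    routine care);
``frontier``
    standard cost-effectiveness frontier with strict and extended
    dominance, ICERs referencing the previous non-dominated row.

WHO GDP-multiple classification: ICER < 1x GDP per capita is "very
cost-effective"; between 1x (inclusive) and 3x (inclusive) "cost-effective";
above 3x "not cost-effective".  A negative ICER from a cheaper-and-more-
effective comparison is dominant and flagged separately.
"""

from __future__ import annotations

import math
from typing import Mapping

import pandas as pd

COLUMNS = [
    "strategy", "cost", "effect",
    "incremental_cost", "incremental_effect", "icer",
    "dominance", "who_class",
]

VERY_CE = "very cost-effective"
CE = "cost-effective"
NOT_CE = "not cost-effective"
DOMINANT = "very cost-effective (dominant)"


def nmb(cost: float, effect: float, wtp: float) -> float:
    """Net monetary benefit, wtp * effect - cost (linear in both)."""
    if wtp < 0:
        raise ValueError("willingness to pay must be >= 0")
    return wtp * effect - cost


def who_class(icer: float, gdp_per_capita: float, dominant: bool = False) -> str:
    """WHO GDP-multiple classification of an ICER."""
    if gdp_per_capita <= 0:
        raise ValueError("GDP per capita must be positive")
    if dominant:
        return DOMINANT
    if icer < gdp_per_capita:
        return VERY_CE
    if icer <= 3 * gdp_per_capita:
        return CE
    return NOT_CE


def _row(strategy, cost, effect, ref_cost=None, ref_effect=None, gdp=None):
    row = {
        "strategy": strategy, "cost": cost, "effect": effect,
        "incremental_cost": math.nan, "incremental_effect": math.nan,
        "icer": math.nan, "dominance": "none", "who_class": "",
    }
    if ref_cost is None:
        return row
    dc = cost - ref_cost
    de = effect - ref_effect
    row["incremental_cost"] = dc
    row["incremental_effect"] = de
    if de <= 0 and dc > 0:
        # costs more, no health gain: dominated, ICER undefined
        row["dominance"] = "dominated"
    elif de == 0 and dc <= 0:
        row["dominance"] = "none"
    else:
        icer = dc / de
        row["icer"] = icer
        if gdp is not None:
            row["who_class"] = who_class(icer, gdp, dominant=(dc < 0 and de > 0))
    return row


def icer_table(
    results: Mapping[str, tuple[float, float]],
    reference: str | None = None,
    mode: str = "pairwise",
    gdp_per_capita: float | None = None,
) -> pd.DataFrame:
    """Incremental cost-effectiveness table from per-strategy (cost, effect).

    Rows are ordered by ascending cost (so the output is invariant to input
    order).  In ``pairwise`` mode increments reference ``reference``; in
    ``frontier`` mode they reference the previous non-dominated row and
    dominated / extended-dominated strategies are flagged.
    """
    if len(results) < 2:
        raise ValueError("need at least two strategies")
    ordered = sorted(results.items(), key=lambda kv: (kv[1][0], kv[0]))

    if mode == "pairwise":
        if reference is None or reference not in results:
            raise ValueError(f"reference strategy {reference!r} not in results")
        rc, re_ = results[reference]
        rows = []
        for s, (c, e) in ordered:
            if s == reference:
                rows.append(_row(s, c, e))
            else:
                rows.append(_row(s, c, e, rc, re_, gdp_per_capita))
        return pd.DataFrame(rows, columns=COLUMNS)

    if mode != "frontier":
        raise ValueError(f"unknown mode {mode!r}")

    # frontier: strict dominance, then extended dominance by increasing ICER
    names = [s for s, _ in ordered]
    dominated = {}
    for i, (s, (c, e)) in enumerate(ordered):
        for s2, (c2, e2) in ordered:
            if s2 != s and c2 <= c and e2 >= e and (c2 < c or e2 > e):
                dominated[s] = "dominated"
                break
    frontier = [s for s in names if s not in dominated]
    changed = True
    while changed:
        changed = False
        for i in range(1, len(frontier) - 1):
            prev, cur, nxt = frontier[i - 1], frontier[i], frontier[i + 1]
            ic1 = _icer(results[prev], results[cur])
            ic2 = _icer(results[cur], results[nxt])
            if ic1 is not None and ic2 is not None and ic1 >= ic2:
                dominated[cur] = "extended-dominated"
                frontier.pop(i)
                changed = True
                break

    rows = []
    prev = None
    for s, (c, e) in ordered:
        if s in dominated:
            row = _row(s, c, e)
            row["dominance"] = dominated[s]
            rows.append(row)
            continue
        if prev is None:
            rows.append(_row(s, c, e))
        else:
            rows.append(_row(s, c, e, *results[prev], gdp_per_capita))
        prev = s
    return pd.DataFrame(rows, columns=COLUMNS)


def _icer(ref: tuple[float, float], alt: tuple[float, float]) -> float | None:
    dc, de = alt[0] - ref[0], alt[1] - ref[1]
    if de == 0:
        return None
    return dc / de


def format_table(table: pd.DataFrame, decimals: int = 2) -> pd.DataFrame:
    """Display copy with numeric columns rounded; never feeds computation."""
    out = table.copy()
    for col in ("cost", "effect", "incremental_cost", "incremental_effect", "icer"):
        out[col] = out[col].round(decimals)
    return out


def write_cea_csv(table: pd.DataFrame, path, decimals: int = 2) -> None:
    format_table(table, decimals).to_csv(path, index=False)


def read_cea_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)
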