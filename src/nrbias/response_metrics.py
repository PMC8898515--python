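"""Response rates (AAPOR RR1) and homogeneity tests across study arms.

RR1 is the strictest standard response-rate definition: completed returns
divided by everything assigned to the condition. Homogeneity across arm
levels or across the twelve factorial cells is tested with a Pearson
chi-square on the level x returned contingency table (no continuity
correction by default; a flag exposes it).
"""

from __future__ import annotations

from typing import Mapping

import pandas as pd
from scipy import stats

from .factorial_design import FACTOR_LEVELS


class UndefinedRateError(ValueError):
    """Raised for a response rate over zero assigned subjects."""


def response_rate_rr1(returned: int, assigned: int) -> float:
    """AAPOR RR1 as a percentage: ``100 * returned / assigned``.

    Full precision; round to one decimal only when rendering reports.
    """
    if assigned <= 0:
        raise UndefinedRateError("assigned must be positive for RR1")
    if not (0 <= returned <= assigned):
        raise ValueError(f"returned={returned} outside [0, assigned={assigned}]")
    return 100.0 * returned / assigned


def omnibus_chi_square(
    counts: Mapping[str, tuple[int, int]], correction: bool = False
) -> dict[str, float]:
    """Pearson chi-square of a stratum x (returned, not_returned) table.

    ``counts`` maps stratum label -> (returned, not_returned). Returns
    ``{"statistic", "df", "p"}`` with df = strata - 1. ``correction``
    applies Yates' continuity correction (2x2 only; off by default, the
    convention under which the motivating trial's significance pattern
    reproduces).
    """
    if len(counts) < 2:
        raise ValueError("need at least 2 strata")
    table = []
    for label, (ret, not_ret) in counts.items():
        if ret + not_ret <= 0:
            raise UndefinedRateError(f"stratum {label!r} has zero assigned")
        if ret < 0 or not_ret < 0:
            raise ValueError(f"negative count in stratum {label!r}")
        table.append([ret, not_ret])
    res = stats.chi2_contingency(table, correction=correction)
    return {"statistic": float(res.statistic), "df": int(res.dof), "p": float(res.pvalue)}


def _merged(assignment: pd.DataFrame, responses: pd.DataFrame) -> pd.DataFrame:
    return assignment.merge(
        responses[["subject_id", "returned"]], on="subject_id", validate="1:1"
    )


def response_rate_table(
    assignment: pd.DataFrame, responses: pd.DataFrame
) -> pd.DataFrame:
    """Long-format response-rate table by block and arm manipulation.

    One row per (block, margin, level) with ``margin`` in
    {overall, content, source, incentive}; columns ``assigned``,
    ``returned``, ``rate_pct``. Overall rows sum the block; margin rows
    cover each factor level.
    """
    data = _merged(assignment, responses)
    rows = []
    for block, sub in data.groupby("block", sort=False):
        rows.append(
            {
                "block": block,
                "margin": "overall",
                "level": "overall",
                "assigned": len(sub),
                "returned": int(sub["returned"].sum()),
            }
        )
        for factor, levels in FACTOR_LEVELS.items():
            for level in levels:
                grp = sub[sub[factor] == level]
                rows.append(
                    {
                        "block": block,
                        "margin": factor,
                        "level": level,
                        "assigned": len(grp),
                        "returned": int(grp["returned"].sum()),
                    }
                )
    out = pd.DataFrame(rows)
    out["rate_pct"] = [
        response_rate_rr1(r, a) for r, a in zip(out["returned"], out["assigned"])
    ]
    return out


def margin_homogeneity_tests(
    assignment: pd.DataFrame, responses: pd.DataFrame, correction: bool = False
) -> pd.DataFrame:
    """Per-block chi-square tests: one per factor margin plus the 12-cell omnibus.

    Rows: (block, margin) with margin in {content, source, incentive,
    cells}; columns ``statistic``, ``df``, ``p``.
    """
    data = _merged(assignment, responses)
    rows = []
    for block, sub in data.groupby("block", sort=False):
        for factor, levels in FACTOR_LEVELS.items():
            counts = {}
            for level in levels:
                grp = sub[sub[factor] == level]
                counts[level] = (
                    int(grp["returned"].sum()),
                    int((1 - grp["returned"]).sum()),
                )
            rows.append({"block": block, "margin": factor, **omnibus_chi_square(counts, correction)})
        cell_counts = {}
        for (c, s, i), grp in sub.groupby(
            ["content", "source", "incentive"], sort=True
        ):
            cell_counts[f"{c}:{s}:{i}"] = (
                int(grp["returned"].sum()),
                int((1 - grp["returned"]).sum()),
            )
        rows.append(
            {"block": block, "margin": "cells", **omnibus_chi_square(cell_counts, correction)}
        )
    return pd.DataFrame(rows)
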