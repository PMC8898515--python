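"""Non-response bias and its factorial decomposition.

Bias for a binary administrative correlate is the respondent-pool
percentage minus the sampling-frame percentage, in signed percentage
points: negative means the characteristic is under-represented among
respondents. The variance in bias explained by each study-arm
manipulation is obtained from a three-factor ANOVA on respondent-level
frame-centered indicators (so that cell means equal cell biases), with
non-significant interaction terms pooled into error, and reported as
eta-squared = 100 * SS_factor / SS_total.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .factorial_design import FACTOR_LEVELS, manipulation_strata
from .synthetic_cohort import CORRELATES

FACTORS = tuple(FACTOR_LEVELS)


class EmptyCellError(ValueError):
    """A design cell has no respondents, so the factorial ANOVA is undefined."""


class EmptyStratumError(ValueError):
    """A stratum has no respondents, so its bias is undefined."""


def compute_bias(respondent_pct: float, frame_pct: float) -> float:
    """Signed non-response bias in percentage points.

    ``respondent_pct - frame_pct``, both on the 0-100 scale. Positive
    values mean over-representation of the characteristic among
    respondents, zero means no bias.
    """
    for name, value in (("respondent_pct", respondent_pct), ("frame_pct", frame_pct)):
        if not (0.0 <= value <= 100.0):
            raise ValueError(f"{name}={value} outside [0, 100]")
    return respondent_pct - frame_pct


def cohen_h(p1: float, p2: float) -> float:
    """Cohen's h effect size for two proportions.

    ``|2 arcsin(sqrt(p1)) - 2 arcsin(sqrt(p2))|``; ranges 0 (equal) to
    pi (0 vs 1). About 0.2 is conventionally small, 0.5 medium.
    """
    for name, p in (("p1", p1), ("p2", p2)):
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"{name}={p} outside [0, 1]")
    return abs(2.0 * math.asin(math.sqrt(p1)) - 2.0 * math.asin(math.sqrt(p2)))


def frame_prevalence_pct(frame: pd.DataFrame, correlate: str, block: str) -> float:
    sub = frame.loc[frame["block"] == block, correlate]
    return 100.0 * float(sub.mean())


def _analysis_table(
    frame: pd.DataFrame, assignment: pd.DataFrame, responses: pd.DataFrame
) -> pd.DataFrame:
    return frame.merge(
        assignment[["subject_id", "content", "source", "incentive"]],
        on="subject_id",
        validate="1:1",
    ).merge(responses[["subject_id", "returned"]], on="subject_id", validate="1:1")


def bias_by_arm(
    frame: pd.DataFrame,
    assignment: pd.DataFrame,
    responses: pd.DataFrame,
    correlate: str,
) -> pd.DataFrame:
    """Bias for one correlate, overall and within the 7 arm manipulations.

    For each block and stratum (overall plus each single-factor level),
    bias compares the stratum's respondents against the **full block**
    frame prevalence — randomization guarantees each stratum's frame
    composition matches the block in expectation. Strata without
    respondents get ``defined = False`` and NaN bias, never a silent 0.
    """
    data = _analysis_table(frame, assignment, responses)
    rows = []
    for block, sub in data.groupby("block", sort=False):
        frame_pct = 100.0 * float(sub[correlate].mean())
        strata = [("overall", "overall", pd.Series(True, index=sub.index))]
        strata += [
            (f, lvl, mask.loc[sub.index]) for f, lvl, mask in manipulation_strata(sub)
        ]
        for factor, level, mask in strata:
            resp = sub[mask & (sub["returned"] == 1)]
            row = {
                "block": block,
                "correlate": correlate,
                "margin": factor,
                "level": level,
                "n_respondents": len(resp),
                "frame_pct": frame_pct,
            }
            if len(resp) == 0:
                row.update(respondent_pct=np.nan, bias_pp=np.nan, defined=False)
            else:
                rpct = 100.0 * float(resp[correlate].mean())
                row.update(
                    respondent_pct=rpct,
                    bias_pp=compute_bias(rpct, frame_pct),
                    defined=True,
                )
            rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class AnovaPartition:
    """Sequential sum-of-squares partition of respondent-level bias.

    ``terms`` holds retained model terms in fit order, each with
    ``ss``, ``df``, ``F``, ``p``; interactions pooled into error are
    listed in ``pooled``. ``eta2_percent`` maps each main factor to
    100 * SS_factor / SS_total (0 when SS_total is 0).
    """

    terms: dict[str, dict[str, float]]
    ss_error: float
    df_error: int
    ss_total: float
    eta2_percent: dict[str, float]
    pooled: list[str] = field(default_factory=list)
    n: int = 0


def _check_cells(resp: pd.DataFrame, factors: tuple[str, ...]) -> None:
    from itertools import product as iproduct

    sizes = resp.groupby(list(factors), sort=True).size()
    for combo in iproduct(*(FACTOR_LEVELS[f] for f in factors)):
        key = combo if len(combo) > 1 else combo[0]
        if key not in sizes.index or sizes.loc[key] == 0:
            raise EmptyCellError(f"no respondents in cell {dict(zip(factors, combo))}")


def _anova_typ1(fit) -> pd.DataFrame:
    return sm.stats.anova_lm(fit, typ=1)


def factorial_anova_eta2(
    frame: pd.DataFrame,
    assignment: pd.DataFrame,
    responses: pd.DataFrame,
    correlate: str,
    block: str | None = None,
    factors: tuple[str, ...] = FACTORS,
    pool_interactions: bool = True,
    alpha: float = 0.05,
) -> AnovaPartition:
    """Factorial ANOVA of frame-centered bias with interaction pooling.

    The response is the respondent-level indicator minus the block frame
    prevalence, so each design cell's mean equals its bias. Sequential
    (Type I) sums of squares are used — they partition SS_total exactly
    even when respondent counts are unbalanced. Interactions are tested
    highest-order first; every interaction with p >= ``alpha`` is pooled
    into the error term (its df joins the error df) before eta-squared is
    read off the final model.
    """
    data = _analysis_table(frame, assignment, responses)
    if block is not None:
        data = data[data["block"] == block]
        if data.empty:
            raise ValueError(f"no subjects in block {block!r}")
    # Center within block so the pooled-block analysis removes block offsets.
    prev = data.groupby("block")[correlate].transform("mean")
    data = data.assign(d=data[correlate] - prev)
    resp = data[data["returned"] == 1].copy()
    if resp.empty:
        raise EmptyStratumError("no respondents")
    _check_cells(resp, factors)

    for f in factors:
        resp[f] = pd.Categorical(resp[f], categories=FACTOR_LEVELS[f])

    d = resp["d"].to_numpy(dtype=float)
    ss_total = float(((d - d.mean()) ** 2).sum())
    if ss_total < 1e-12:  # constant correlate: centering leaves nothing to partition
        return AnovaPartition(
            terms={f: {"ss": 0.0, "df": len(FACTOR_LEVELS[f]) - 1, "F": np.nan, "p": np.nan} for f in factors},
            ss_error=0.0,
            df_error=len(resp) - 1 - sum(len(FACTOR_LEVELS[f]) - 1 for f in factors),
            ss_total=0.0,
            eta2_percent={f: 0.0 for f in factors},
            n=len(resp),
        )

    mains = list(factors)
    pooled: list[str] = []
    from itertools import combinations

    interactions: list[str] = []
    for order in range(2, len(factors) + 1):
        interactions += [":".join(c) for c in combinations(factors, order)]

    retained = list(interactions)
    if pool_interactions and interactions:
        # Test highest-order interactions first; pool each non-significant
        # one into error (refitting between orders so lower-order tests use
        # the already-pooled error term).
        for order in range(len(factors), 1, -1):
            formula = "d ~ " + " + ".join(mains + retained)
            tab = _anova_typ1(smf.ols(formula, data=resp).fit())
            for term in [t for t in retained if t.count(":") == order - 1]:
                p = tab.loc[term, "PR(>F)"]
                if np.isnan(p) or p >= alpha:
                    retained.remove(term)
                    pooled.append(term)
    model_terms = mains + retained

    final = smf.ols("d ~ " + " + ".join(model_terms), data=resp).fit()
    tab = _anova_typ1(final)

    terms: dict[str, dict[str, float]] = {}
    for t in tab.index:
        if t == "Residual":
            continue
        terms[t] = {
            "ss": float(tab.loc[t, "sum_sq"]),
            "df": int(tab.loc[t, "df"]),
            "F": float(tab.loc[t, "F"]),
            "p": float(tab.loc[t, "PR(>F)"]),
        }
    ss_error = float(tab.loc["Residual", "sum_sq"])
    df_error = int(tab.loc["Residual", "df"])
    eta2 = {f: 100.0 * terms[f]["ss"] / ss_total for f in factors}
    return AnovaPartition(
        terms=terms,
        ss_error=ss_error,
        df_error=df_error,
        ss_total=ss_total,
        eta2_percent=eta2,
        pooled=pooled,
        n=len(resp),
    )


def overall_bias_test(
    frame: pd.DataFrame,
    assignment: pd.DataFrame,
    responses: pd.DataFrame,
    correlate: str,
    block: str,
) -> dict[str, float]:
    """One-sample t-test that the block's net bias is zero.

    Complements the factor-level F-tests: tests whether the mean
    frame-centered indicator among respondents differs from zero.
    """
    data = _analysis_table(frame, assignment, responses)
    data = data[data["block"] == block]
    d = data.loc[data["returned"] == 1, correlate] - data[correlate].mean()
    res = stats.ttest_1samp(d, 0.0)
    return {
        "bias_pp": 100.0 * float(d.mean()),
        "statistic": float(res.statistic),
        "p": float(res.pvalue),
        "n": int(len(d)),
    }


def eta2_table(
    frame: pd.DataFrame,
    assignment: pd.DataFrame,
    responses: pd.DataFrame,
    correlates: tuple[str, ...] = CORRELATES,
    **anova_kwargs,
) -> pd.DataFrame:
    """Eta-squared grid: correlates x main factors x blocks (report shape)."""
    rows = []
    for block in frame["block"].unique():
        for correlate in correlates:
            part = factorial_anova_eta2(
                frame, assignment, responses, correlate, block=block, **anova_kwargs
            )
            for factor in FACTORS:
                rows.append(
                    {
                        "block": block,
                        "correlate": correlate,
                        "factor": factor,
                        "eta2_percent": part.eta2_percent[factor],
                        "p": part.terms[factor]["p"],
                        "pooled_interactions": ";".join(part.pooled),
                    }
                )
    return pd.DataFrame(rows)


def characteristics_table(
    frame: pd.DataFrame,
    responses: pd.DataFrame,
    correlates: tuple[str, ...] = CORRELATES,
) -> pd.DataFrame:
    """Descriptive frame composition by block and response status.

    Per (block, correlate): overall, non-respondent and respondent
    percentages, with a chi-square p for respondent vs non-respondent.
    """
    data = frame.merge(
        responses[["subject_id", "returned"]], on="subject_id", validate="1:1"
    )
    rows = []
    for block, sub in data.groupby("block", sort=False):
        resp = sub[sub["returned"] == 1]
        nonresp = sub[sub["returned"] == 0]
        for c in correlates:
            tab = pd.crosstab(sub[c], sub["returned"])
            if tab.shape == (2, 2):
                p = float(stats.chi2_contingency(tab, correction=False).pvalue)
            else:
                p = np.nan  # degenerate (constant) correlate
            rows.append(
                {
                    "block": block,
                    "correlate": c,
                    "overall_pct": 100.0 * float(sub[c].mean()),
                    "nonrespondent_pct": 100.0 * float(nonresp[c].mean())
                    if len(nonresp)
                    else np.nan,
                    "respondent_pct": 100.0 * float(resp[c].mean())
                    if len(resp)
                    else np.nan,
                    "p": p,
                }
            )
    return pd.DataFrame(rows)
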