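"""Synthetic cohort generator for non-response bias studies.

Emulates a gender-blocked sampling frame of Veterans applying for PTSD
disability benefits, with eight binary administrative correlates per
subject, latent binary self-reports (combat exposure, military sexual
assault), and a response indicator generated from a selection model

    logit P(y = 1 | x)      = x' beta                (outcome model)
    logit P(r = 1 | x, y)   = x' alpha + gamma * y   (response model)

where ``x`` collects administrative covariates and study-arm indicators.
``gamma = 0`` makes missingness ignorable (MAR given x; MCAR when alpha
has only an intercept); ``gamma != 0`` makes it nonignorable (MNAR), so
the generator can score MNAR estimators against a known latent truth.

Administrative military sexual trauma (``mst_admin``, which also covers
severe physical sexual harassment) and self-reported military sexual
assault (``self_msa``) are distinct variables linked only through the
outcome model's coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit, ndtri

from .factorial_design import ARM_DUMMY_TERMS, arm_dummies

#: The eight administrative non-response correlates, frame-complete.
CORRELATES = (
    "age_lt30",
    "nonwhite",
    "combat_admin",
    "mst_admin",
    "smi",
    "charlson_gt0",
    "any_benefits",
    "ptsd_benefits",
)

#: Self-reported outcomes, observed only for responders.
OUTCOMES = ("self_combat", "self_msa")

#: Default per-block correlate prevalences (overall sampling-frame values
#: of the motivating trial's administrative data).
DEFAULT_COVARIATE_PREVALENCE: dict[str, dict[str, float]] = {
    "men": {
        "age_lt30": 0.304,
        "nonwhite": 0.419,
        "combat_admin": 0.671,
        "mst_admin": 0.021,
        "smi": 0.052,
        "charlson_gt0": 0.117,
        "any_benefits": 0.819,
        "ptsd_benefits": 0.563,
    },
    "women": {
        "age_lt30": 0.323,
        "nonwhite": 0.594,
        "combat_admin": 0.413,
        "mst_admin": 0.456,
        "smi": 0.082,
        "charlson_gt0": 0.100,
        "any_benefits": 0.773,
        "ptsd_benefits": 0.452,
    },
}


class SpecError(ValueError):
    """Invalid generator specification (probability or model mismatch)."""


def _default_prevalence() -> dict[str, dict[str, float]]:
    return {b: dict(p) for b, p in DEFAULT_COVARIATE_PREVALENCE.items()}


@dataclass
class FrameSpec:
    """Sampling-frame recipe: block sizes, prevalences, optional dependence.

    ``covariate_dependence`` gives pairwise latent correlations of a
    Gaussian-copula threshold construction, ``{(corr_a, corr_b): rho}``;
    the implied correlation matrix must be positive semi-definite (checked
    at generation time).
    """

    n_per_block: int = 480
    covariate_prevalence: Mapping[str, Mapping[str, float]] = field(
        default_factory=_default_prevalence
    )
    covariate_dependence: Mapping[tuple[str, str], float] | None = None

    def __post_init__(self) -> None:
        for block, prevs in self.covariate_prevalence.items():
            for name, p in prevs.items():
                if not (0.0 <= p <= 1.0):
                    raise SpecError(
                        f"prevalence of {name!r} in block {block!r} is {p}, "
                        "outside [0, 1]"
                    )
        if self.n_per_block <= 0:
            raise SpecError("n_per_block must be positive")

    def correlates(self, block: str) -> list[str]:
        return list(self.covariate_prevalence[block])

    def latent_correlation(self, block: str) -> np.ndarray:
        names = self.correlates(block)
        r = np.eye(len(names))
        if self.covariate_dependence:
            idx = {n: i for i, n in enumerate(names)}
            for (a, b), rho in self.covariate_dependence.items():
                if a not in idx or b not in idx:
                    raise SpecError(f"dependence names unknown correlate ({a}, {b})")
                if not (-1.0 < rho < 1.0):
                    raise SpecError(f"latent correlation {rho} outside (-1, 1)")
                r[idx[a], idx[b]] = r[idx[b], idx[a]] = rho
            if np.linalg.eigvalsh(r).min() < -1e-8:
                raise SpecError(
                    "covariate_dependence does not define a valid joint law "
                    "(latent correlation matrix not positive semi-definite)"
                )
        return r


@dataclass
class OutcomeModel:
    """Per-outcome logistic models for the latent self-reports.

    ``beta[outcome]`` maps term name -> coefficient; terms are
    ``"intercept"`` plus covariate column names of the frame.
    """

    beta: Mapping[str, Mapping[str, float]]

    def __post_init__(self) -> None:
        for outcome, coefs in self.beta.items():
            for term, value in coefs.items():
                if not np.isfinite(value):
                    raise SpecError(f"non-finite coefficient {term!r} for {outcome!r}")


@dataclass
class ResponseModel:
    """Selection model for the survey-return indicator.

    ``alpha`` maps term name -> coefficient (``"intercept"``, correlates,
    or arm dummy names from :data:`~nrbias.factorial_design.ARM_DUMMY_TERMS`);
    ``gamma`` maps outcome name -> coefficient on the latent self-report.
    ``gamma = {}`` reproduces MAR; an intercept-only ``alpha`` with empty
    ``gamma`` reproduces MCAR.
    """

    alpha: Mapping[str, float]
    gamma: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for term, value in {**dict(self.alpha), **dict(self.gamma)}.items():
            if not np.isfinite(value):
                raise SpecError(f"non-finite response coefficient {term!r}")


def _linear_predictor(
    data: pd.DataFrame, coefs: Mapping[str, float], context: str
) -> np.ndarray:
    eta = np.full(len(data), float(coefs.get("intercept", 0.0)))
    for term, value in coefs.items():
        if term == "intercept":
            continue
        if term not in data.columns:
            raise SpecError(f"{context}: unknown model term {term!r}")
        eta += value * data[term].to_numpy(dtype=float)
    return eta


def generate_frame(spec: FrameSpec, seed: int) -> pd.DataFrame:
    """Draw a sampling frame: ``n_per_block`` rows per block.

    Columns: ``subject_id``, ``block``, one 0/1 column per correlate.
    Empirical prevalences converge to the spec as n grows; identical seeds
    give identical frames.
    """
    rng = np.random.default_rng(seed)
    pieces = []
    for block, prevs in spec.covariate_prevalence.items():
        names = list(prevs)
        n = spec.n_per_block
        corr = spec.latent_correlation(block)
        # Gaussian copula: threshold correlated latent normals at the
        # per-correlate quantile. Identity correlation reduces to
        # independent Bernoullis through the same draw path.
        chol = np.linalg.cholesky(corr + 1e-12 * np.eye(len(names)))
        z = rng.standard_normal((n, len(names))) @ chol.T
        thresholds = ndtri(np.array([prevs[name] for name in names]))
        x = (z < thresholds[None, :]).astype(int)
        df = pd.DataFrame(x, columns=names)
        df.insert(0, "block", block)
        df.insert(0, "subject_id", [f"{block}_{i:05d}" for i in range(n)])
        pieces.append(df)
    return pd.concat(pieces, ignore_index=True)


def simulate_self_reports(
    frame: pd.DataFrame, model: OutcomeModel, seed: int
) -> pd.DataFrame:
    """Latent self-reports for every frame member (responders or not).

    One Bernoulli draw per subject and outcome with probability
    ``expit(x' beta)``. Latent values are the pre-masking ground truth an
    MNAR estimator is scored against.
    """
    rng = np.random.default_rng(seed)
    out = pd.DataFrame({"subject_id": frame["subject_id"]})
    for outcome, coefs in model.beta.items():
        p = expit(_linear_predictor(frame, coefs, f"outcome {outcome!r}"))
        out[outcome] = (rng.random(len(frame)) < p).astype(int)
    return out


def simulate_response(
    frame: pd.DataFrame,
    assignment: pd.DataFrame,
    latent: pd.DataFrame,
    model: ResponseModel,
    seed: int,
) -> pd.DataFrame:
    """Survey-return indicator and masked self-reports.

    ``returned ~ Bernoulli(expit(x' alpha + sum_o gamma_o y_o))``;
    self-reports are copied from the latent table for responders and set
    to missing (NaN) otherwise.
    """
    rng = np.random.default_rng(seed)
    data = (
        frame.merge(arm_dummies(assignment), on="subject_id", validate="1:1")
        .merge(latent, on="subject_id", validate="1:1")
        .sort_values("subject_id", kind="stable", ignore_index=True)
    )
    eta = _linear_predictor(data, model.alpha, "response model")
    for outcome, coef in model.gamma.items():
        if outcome not in latent.columns:
            raise SpecError(f"response model: gamma names unknown outcome {outcome!r}")
        eta += coef * data[outcome].to_numpy(dtype=float)
    returned = (rng.random(len(data)) < expit(eta)).astype(int)

    out = pd.DataFrame({"subject_id": data["subject_id"], "returned": returned})
    mask = returned == 1
    for outcome in latent.columns:
        if outcome == "subject_id":
            continue
        values = data[outcome].to_numpy(dtype=float)
        out[outcome] = np.where(mask, values, np.nan)
    return out


def mcar_response_model(response_rate: float) -> ResponseModel:
    """Intercept-only response model: missingness completely at random."""
    if not (0.0 < response_rate < 1.0):
        raise SpecError("response_rate must be in (0, 1)")
    logit = float(np.log(response_rate / (1.0 - response_rate)))
    return ResponseModel(alpha={"intercept": logit}, gamma={})
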