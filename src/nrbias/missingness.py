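"""Prevalence of a binary self-report under three missingness assumptions.

Given a frame-complete covariate set x and an outcome y observed only for
survey responders (r = 1), the prevalence of y is estimated three ways:

* **MCAR** — the complete-case mean of the observed values;
* **MAR** — multiple imputation: a responders-only logistic model of
  y on x, coefficient draws from its asymptotic normal, Bernoulli
  imputation of the missing outcomes, Rubin pooling across m copies;
* **MNAR** — a nonignorable selection model, fitted by EM, that couples a
  logistic outcome model ``logit P(y=1|x) = x'beta`` with a logistic
  response model ``logit P(r=1|x,y) = x'alpha + gamma*y``. The outcome
  enters its own missingness model, so information about nonresponders'
  y comes jointly from x and from the response pattern.

Numerically close estimates and a small variance across the three support
random missingness; divergence flags a nonignorable mechanism. The MNAR
estimate is identified only through the parametric form of the selection
model (there is no instrument), so it is an assumption-contingent
scenario, not a free lunch — reports carry a standing caveat.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .factorial_design import ARM_DUMMY_TERMS, arm_dummies
from .synthetic_cohort import CORRELATES

MNAR_CAVEAT = (
    "MNAR estimates are identified only through the parametric form of the "
    "selection model; treat them as an assumption-contingent scenario."
)


class CollinearityError(ValueError):
    """Design matrix is rank-deficient."""


class NoRespondersError(ValueError):
    """No observed outcomes to estimate from."""


# ---------------------------------------------------------------------------
# Weighted logistic regression (shared numerics for the MI and EM fits)
# ---------------------------------------------------------------------------


@dataclass
class LogisticFit:
    """Weighted logistic regression result.

    ``params`` are in the order of ``terms``; ``cov`` is the inverse
    observed information at the optimum (asymptotic covariance when
    weights are frequencies).
    """

    params: np.ndarray
    cov: np.ndarray
    terms: tuple[str, ...]
    converged: bool
    n_iter: int
    separation: bool = False


def weighted_logistic_loglik(
    beta: np.ndarray, X: np.ndarray, y: np.ndarray, w: np.ndarray
) -> float:
    """Weighted Bernoulli log-likelihood sum(w * [y log p + (1-y) log(1-p)])."""
    eta = X @ beta
    # log p = -log(1+e^-eta); log(1-p) = -log(1+e^eta)
    return float(np.sum(w * (y * eta - np.logaddexp(0.0, eta))))


def fit_weighted_logistic(
    X: np.ndarray,
    y: np.ndarray,
    w: np.ndarray | None = None,
    terms: Sequence[str] | None = None,
    start: np.ndarray | None = None,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> LogisticFit:
    """Maximize the weighted Bernoulli likelihood by Newton iteration (IRLS).

    Accepts fractional nonnegative weights (pseudo-observations from an
    EM E-step behave exactly like fractional frequencies). Deterministic
    for fixed input; supports warm starts. Quasi-complete separation is
    flagged (not fatal): iteration is bounded and the fit returned with
    ``separation=True`` plus a warning.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    if w is None:
        w = np.ones(n)
    w = np.asarray(w, dtype=float)
    if np.any(w < 0) or not np.all(np.isfinite(w)) or w.sum() <= 0:
        raise ValueError("weights must be finite, nonnegative, not all zero")
    active = w > 0
    if np.linalg.matrix_rank(X[active] * np.sqrt(w[active])[:, None]) < k:
        raise CollinearityError("design matrix is rank-deficient on weighted rows")

    beta = np.zeros(k) if start is None else np.asarray(start, dtype=float).copy()
    ll = weighted_logistic_loglik(beta, X, y, w)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = np.clip(X @ beta, -35.0, 35.0)
        mu = expit(eta)
        grad = X.T @ (w * (y - mu))
        wdiag = w * mu * (1.0 - mu)
        hess = X.T @ (X * wdiag[:, None])
        try:
            step = np.linalg.solve(hess + 1e-12 * np.eye(k), grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(hess, grad, rcond=None)[0]
        # step-halving keeps Newton monotone on flat/separated likelihoods
        for _ in range(30):
            cand = beta + step
            ll_new = weighted_logistic_loglik(cand, X, y, w)
            if ll_new >= ll - 1e-12:
                break
            step *= 0.5
        delta = float(np.max(np.abs(cand - beta)))
        beta, ll = cand, ll_new
        if delta < tol:
            converged = True
            break

    separation = bool(np.max(np.abs(beta)) > 15.0) or not converged
    if separation:
        warnings.warn(
            "possible quasi-complete separation in weighted logistic fit; "
            "coefficients bounded at the iteration limit",
            RuntimeWarning,
            stacklevel=2,
        )
    eta = np.clip(X @ beta, -35.0, 35.0)
    mu = expit(eta)
    wdiag = w * mu * (1.0 - mu)
    hess = X.T @ (X * wdiag[:, None])
    cov = np.linalg.pinv(hess)
    return LogisticFit(
        params=beta,
        cov=cov,
        terms=tuple(terms) if terms is not None else tuple(f"x{i}" for i in range(k)),
        converged=converged,
        n_iter=it,
        separation=separation,
    )


def _design(data: pd.DataFrame, covariates: Sequence[str]) -> tuple[np.ndarray, tuple[str, ...]]:
    terms = ("intercept", *covariates)
    X = np.column_stack(
        [np.ones(len(data))] + [data[c].to_numpy(dtype=float) for c in covariates]
    )
    return X, terms


# ---------------------------------------------------------------------------
# MCAR: complete-case estimate
# ---------------------------------------------------------------------------


def prevalence_mcar(responses: pd.DataFrame, outcome: str) -> float:
    """Complete-case prevalence (percent): mean of y among responders."""
    obs = responses.loc[responses["returned"] == 1, outcome]
    if len(obs) == 0:
        raise NoRespondersError("no responders with observed outcome")
    return 100.0 * float(obs.mean())


# ---------------------------------------------------------------------------
# MAR: multiple imputation with Rubin pooling
# ---------------------------------------------------------------------------


@dataclass
class MIResult:
    """Multiple-imputation prevalence with Rubin variance decomposition."""

    m: int
    estimates: list[float]  # per-imputation prevalence, percent
    pooled: float  # percent; mean of estimates
    within: float  # proportion-scale within-imputation variance
    between: float  # proportion-scale between-imputation variance
    total: float  # within + (1 + 1/m) * between
    separation_fallback: bool = False


def impute_mar(
    frame: pd.DataFrame,
    responses: pd.DataFrame,
    outcome: str,
    covariates: Sequence[str],
    m: int = 25,
    seed: int | None = None,
) -> MIResult:
    """MAR prevalence by multiple imputation of nonresponders' outcomes.

    A logistic model of the outcome on the frame-complete covariates is
    fitted to responders; each of the ``m`` imputations draws coefficients
    from the fit's asymptotic normal (a proper-imputation posterior-draw
    approximation), then draws Bernoulli outcomes for every nonresponder.
    The per-imputation estimate is the full-frame prevalence; Rubin's
    rules pool the mean and variance. On separation the responders-only
    model falls back to a lightly ridge-penalized fit (warned).
    """
    data = frame.merge(responses, on="subject_id", validate="1:1")
    resp = data[data["returned"] == 1]
    non = data[data["returned"] == 0]
    if len(resp) == 0:
        raise NoRespondersError("cannot impute with zero responders")
    X_resp, terms = _design(resp, covariates)
    y_resp = resp[outcome].to_numpy(dtype=float)

    fallback = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        fit = fit_weighted_logistic(X_resp, y_resp, terms=terms)
    if fit.separation:
        fallback = True
        fit = _ridge_logistic(X_resp, y_resp, terms)
        warnings.warn(
            "responders-only imputation model showed separation; "
            "using ridge-penalized fit for coefficient draws",
            RuntimeWarning,
            stacklevel=2,
        )
    else:
        for c in caught:
            warnings.warn_explicit(c.message, c.category, c.filename, c.lineno)

    rng = np.random.default_rng(seed)
    X_non, _ = _design(non, covariates)
    n_total = len(data)
    estimates = []
    withins = []
    # jitter keeps the Cholesky factor defined when cov is near-singular
    cov = fit.cov + 1e-12 * np.eye(len(fit.params))
    chol = np.linalg.cholesky(cov)
    for _ in range(m):
        beta_draw = fit.params + chol @ rng.standard_normal(len(fit.params))
        p_non = expit(np.clip(X_non @ beta_draw, -35.0, 35.0))
        y_imp = (rng.random(len(non)) < p_non).astype(float)
        prev = (y_resp.sum() + y_imp.sum()) / n_total
        estimates.append(100.0 * prev)
        withins.append(prev * (1.0 - prev) / n_total)

    pooled = float(np.mean(estimates))
    within = float(np.mean(withins))
    between = float(np.var(np.asarray(estimates) / 100.0, ddof=1)) if m > 1 else 0.0
    total = within + (1.0 + 1.0 / m) * between
    return MIResult(
        m=m,
        estimates=estimates,
        pooled=pooled,
        within=within,
        between=between,
        total=total,
        separation_fallback=fallback,
    )


def _ridge_logistic(
    X: np.ndarray, y: np.ndarray, terms: tuple[str, ...], lam: float = 1e-2
) -> LogisticFit:
    """L2-penalized Newton fit used as a separation fallback."""
    n, k = X.shape
    beta = np.zeros(k)
    for it in range(200):
        mu = expit(np.clip(X @ beta, -35.0, 35.0))
        grad = X.T @ (y - mu) - lam * beta
        hess = X.T @ (X * (mu * (1 - mu))[:, None]) + lam * np.eye(k)
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            break
    mu = expit(np.clip(X @ beta, -35.0, 35.0))
    hess = X.T @ (X * (mu * (1 - mu))[:, None]) + lam * np.eye(k)
    return LogisticFit(
        params=beta,
        cov=np.linalg.inv(hess),
        terms=terms,
        converged=True,
        n_iter=it + 1,
        separation=True,
    )


# ---------------------------------------------------------------------------
# MNAR: EM for the nonignorable selection model
# ---------------------------------------------------------------------------


@dataclass
class EMFit:
    """EM fit of the nonignorable selection model.

    ``beta`` parameterizes ``logit P(y=1|x)`` and ``(alpha, gamma)``
    parameterize ``logit P(r=1|x,y) = x'alpha + gamma*y``. ``weights``
    holds each nonresponder's posterior probability that y = 1
    (indexed by subject_id). ``loglik`` is the observed-data
    log-likelihood trajectory, one entry per EM iteration; ascent of this
    sequence is the standard EM correctness diagnostic.
    """

    beta: pd.Series
    alpha: pd.Series
    gamma: float
    loglik: list[float]
    n_iter: int
    converged: bool
    weights: pd.Series
    caveat: str = MNAR_CAVEAT


def _observed_loglik(
    beta: np.ndarray,
    ag: np.ndarray,
    Xy_resp: np.ndarray,
    y_resp: np.ndarray,
    Xy_non: np.ndarray,
    Xr_resp_base: np.ndarray,
    Xr_non_base: np.ndarray,
) -> float:
    """Observed-data log-likelihood of the selection model.

    Responders contribute log P(y|x) + log P(r=1|x,y); nonresponders the
    log of the mixture sum_y P(y|x) P(r=0|x,y).
    """
    alpha, gamma = ag[:-1], ag[-1]

    eta_y = Xy_resp @ beta
    ll = float(np.sum(y_resp * eta_y - np.logaddexp(0.0, eta_y)))
    eta_r = Xr_resp_base @ alpha + gamma * y_resp
    ll += float(np.sum(eta_r - np.logaddexp(0.0, eta_r)))  # log P(r=1)

    eta_y = Xy_non @ beta
    log_p1 = -np.logaddexp(0.0, -eta_y)
    log_p0 = -np.logaddexp(0.0, eta_y)
    eta_r0 = Xr_non_base @ alpha  # y = 0
    eta_r1 = eta_r0 + gamma  # y = 1
    log_q0 = -np.logaddexp(0.0, eta_r0)  # log P(r=0 | y=0)
    log_q1 = -np.logaddexp(0.0, eta_r1)
    ll += float(np.sum(np.logaddexp(log_p1 + log_q1, log_p0 + log_q0)))
    return ll


def fit_em_nonignorable(
    frame: pd.DataFrame,
    responses: pd.DataFrame,
    outcome: str,
    covariates: Sequence[str],
    init: tuple[np.ndarray, np.ndarray, float] | None = None,
    tol: float = 1e-6,
    max_iter: int = 500,
    n_starts: int = 1,
    seed: int | None = None,
) -> EMFit:
    """Maximum likelihood for the nonignorable selection model by EM.

    E-step: each nonresponder's missing outcome gets posterior weight
    ``w1 proportional to P(y=1|x) P(r=0|x,y=1)`` (normalized over y).
    M-step: two weighted logistic fits on the expanded table — responders
    with weight 1, each nonresponder as two pseudo-rows (y=0, y=1) with
    weights (w0, w1) — one fit for beta, one for (alpha, gamma). Stops at
    ``max |Delta parameter| < tol``, at a log-likelihood plateau below
    float resolution, or at ``max_iter`` (returned with
    ``converged=False`` and a warning). ``n_starts > 1`` adds randomly
    perturbed restarts and keeps the best likelihood.
    """
    data = frame.merge(responses, on="subject_id", validate="1:1")
    resp = data[data["returned"] == 1]
    non = data[data["returned"] == 0]
    if len(resp) == 0:
        raise NoRespondersError("selection model needs at least one responder")

    Xy_resp, y_terms = _design(resp, covariates)
    Xy_non, _ = _design(non, covariates)
    y_resp = resp[outcome].to_numpy(dtype=float)
    Xr_resp_base, r_terms_base = _design(resp, covariates)
    Xr_non_base, _ = _design(non, covariates)
    r_terms = (*r_terms_base, outcome)

    if len(non) == 0:
        # fully observed: the EM fixed point is the pair of ordinary fits
        beta_fit = fit_weighted_logistic(Xy_resp, y_resp, terms=y_terms)
        theta_ll = _observed_loglik(
            beta_fit.params,
            np.zeros(len(r_terms)),
            Xy_resp,
            y_resp,
            Xy_non,
            Xr_resp_base,
            Xr_non_base,
        )
        return EMFit(
            beta=pd.Series(beta_fit.params, index=list(y_terms)),
            alpha=pd.Series(np.zeros(len(r_terms_base)), index=list(r_terms_base)),
            gamma=0.0,
            loglik=[theta_ll],
            n_iter=0,
            converged=True,
            weights=pd.Series(dtype=float),
        )

    if init is None:
        beta0 = fit_weighted_logistic(Xy_resp, y_resp, terms=y_terms).params
        X_all, _ = _design(data, covariates)
        r_all = data["returned"].to_numpy(dtype=float)
        with warnings.catch_warnings():
            # an all-but-degenerate response pattern only affects the start
            warnings.simplefilter("ignore", RuntimeWarning)
            alpha0 = fit_weighted_logistic(X_all, r_all, terms=r_terms_base).params
        gamma0 = 0.0
    else:
        beta0, alpha0, gamma0 = (
            np.asarray(init[0], dtype=float),
            np.asarray(init[1], dtype=float),
            float(init[2]),
        )

    starts: list[tuple[np.ndarray, np.ndarray, float]] = [(beta0, alpha0, gamma0)]
    if n_starts > 1:
        rng = np.random.default_rng(seed)
        for _ in range(n_starts - 1):
            starts.append(
                (
                    beta0 + rng.normal(0.0, 0.5, beta0.shape),
                    alpha0 + rng.normal(0.0, 0.5, alpha0.shape),
                    gamma0 + rng.normal(0.0, 1.0),
                )
            )

    best: EMFit | None = None
    for beta_s, alpha_s, gamma_s in starts:
        fit = _em_single(
            beta_s,
            alpha_s,
            gamma_s,
            Xy_resp,
            Xy_non,
            y_resp,
            Xr_resp_base,
            Xr_non_base,
            y_terms,
            r_terms,
            non["subject_id"],
            tol,
            max_iter,
        )
        if best is None or fit.loglik[-1] > best.loglik[-1]:
            best = fit
    if not best.converged:
        warnings.warn(
            f"EM did not reach the parameter tolerance in {max_iter} iterations",
            RuntimeWarning,
            stacklevel=2,
        )
    return best


def _em_single(
    beta: np.ndarray,
    alpha: np.ndarray,
    gamma: float,
    Xy_resp: np.ndarray,
    Xy_non: np.ndarray,
    y_resp: np.ndarray,
    Xr_resp_base: np.ndarray,
    Xr_non_base: np.ndarray,
    y_terms: tuple[str, ...],
    r_terms: tuple[str, ...],
    non_ids: pd.Series,
    tol: float,
    max_iter: int,
) -> EMFit:
    """One EM run, accelerated with SQUAREM extrapolation.

    The plain EM map (E-step then the two weighted-logistic M-steps)
    converges only linearly, and very slowly when the selection model is
    weakly identified; each recorded iteration therefore takes a SQUAREM
    step built from two EM map applications, stabilized by a third, with
    a fallback to the plain double EM step whenever the extrapolated
    point would decrease the observed-data likelihood. Ascent of the
    recorded log-likelihood trajectory is thus preserved exactly.
    """
    n_resp, n_non = len(Xy_resp), len(Xy_non)
    kb = Xy_resp.shape[1]

    # expanded design matrices are fixed; only weights change per iteration
    Xy_exp = np.vstack([Xy_resp, Xy_non, Xy_non])
    y_exp = np.concatenate([y_resp, np.ones(n_non), np.zeros(n_non)])
    Xr_exp = np.column_stack(
        [np.vstack([Xr_resp_base, Xr_non_base, Xr_non_base]), y_exp]
    )
    r_exp = np.concatenate([np.ones(n_resp), np.zeros(2 * n_non)])

    def e_weights(theta: np.ndarray) -> np.ndarray:
        """Posterior P(y=1 | r=0, x) for each nonresponder."""
        b, a, g = theta[:kb], theta[kb:-1], theta[-1]
        p1 = expit(np.clip(Xy_non @ b, -35.0, 35.0))
        eta0 = np.clip(Xr_non_base @ a, -35.0, 35.0)
        q0 = 1.0 - expit(eta0)  # P(r=0 | y=0)
        q1 = 1.0 - expit(np.clip(eta0 + g, -35.0, 35.0))
        num = p1 * q1
        den = num + (1.0 - p1) * q0
        return np.where(den > 0, num / np.maximum(den, 1e-300), 0.5)

    def em_map(theta: np.ndarray) -> np.ndarray:
        w1 = e_weights(theta) if n_non else np.zeros(0)
        w_exp = np.concatenate([np.ones(n_resp), w1, 1.0 - w1])
        fit_b = fit_weighted_logistic(
            Xy_exp, y_exp, w_exp, terms=y_terms, start=theta[:kb]
        )
        fit_ag = fit_weighted_logistic(
            Xr_exp, r_exp, w_exp, terms=r_terms, start=theta[kb:]
        )
        return np.concatenate([fit_b.params, fit_ag.params])

    def ll(theta: np.ndarray) -> float:
        return _observed_loglik(
            theta[:kb], theta[kb:], Xy_resp, y_resp, Xy_non, Xr_resp_base, Xr_non_base
        )

    theta = np.concatenate([beta, alpha, [gamma]])
    loglik = [ll(theta)]
    converged = False
    n_maps = 0
    while n_maps < max_iter:
        theta1 = em_map(theta)
        n_maps += 1
        if float(np.max(np.abs(theta1 - theta))) < tol:
            theta = theta1
            loglik.append(ll(theta))
            converged = True
            break
        theta2 = em_map(theta1)
        n_maps += 1
        step1 = theta1 - theta
        curv = (theta2 - theta1) - step1
        curv_norm = float(np.sqrt(curv @ curv))
        if curv_norm < 1e-14:
            theta_new = theta2
        else:
            a = -float(np.sqrt((step1 @ step1)) / curv_norm)
            a = min(a, -1.0)  # never shorter than a plain double EM step
            cand = theta - 2.0 * a * step1 + (a * a) * curv
            theta_new = em_map(cand)  # stabilization step
            n_maps += 1
            if ll(theta_new) < loglik[-1] - 1e-10:
                theta_new = theta2  # monotone fallback: plain EM ascent
        loglik.append(ll(theta_new))
        if loglik[-1] - loglik[-2] < 1e-12 and len(loglik) > 2:
            # likelihood plateau below float resolution; the EM-map fixed
            # point residual decides convergence
            theta = theta_new
            resid = float(np.max(np.abs(em_map(theta) - theta)))
            n_maps += 1
            converged = resid < max(tol, 1e-5)
            break
        theta = theta_new

    beta = theta[:kb]
    ag = theta[kb:]
    w1 = e_weights(theta) if n_non else np.zeros(0)
    return EMFit(
        beta=pd.Series(beta, index=list(y_terms)),
        alpha=pd.Series(ag[:-1], index=list(r_terms[:-1])),
        gamma=float(ag[-1]),
        loglik=loglik,
        n_iter=n_maps,
        converged=converged,
        weights=pd.Series(w1, index=list(non_ids)),
    )


def prevalence_mnar(
    fit: EMFit,
    frame: pd.DataFrame,
    responses: pd.DataFrame,
    outcome: str,
    method: str = "posterior",
) -> float:
    """Prevalence (percent) implied by the fitted selection model.

    ``method="posterior"`` (default) averages observed outcomes for
    responders with posterior weights ``w_i1 = P(y=1 | r=0, x)`` for
    nonresponders; ``method="marginal"`` averages the outcome model's
    ``P(y=1|x)`` over the whole frame, ignoring the selection weighting.
    """
    data = frame.merge(responses, on="subject_id", validate="1:1")
    if method == "marginal":
        covs = [t for t in fit.beta.index if t != "intercept"]
        X, _ = _design(data, covs)
        return 100.0 * float(np.mean(expit(np.clip(X @ fit.beta.to_numpy(), -35, 35))))
    if method != "posterior":
        raise ValueError("method must be 'posterior' or 'marginal'")
    resp = data[data["returned"] == 1]
    non = data[data["returned"] == 0]
    total = float(resp[outcome].sum())
    if len(non):
        total += float(fit.weights.loc[non["subject_id"]].sum())
    return 100.0 * total / len(data)


# ---------------------------------------------------------------------------
# Cross-mechanism summary
# ---------------------------------------------------------------------------


@dataclass
class MechanismTriplet:
    """Prevalence under the three missingness assumptions, plus disagreement.

    Estimates are percents; ``variance_across`` is the sample variance
    (denominator 2) of the three estimates **on the proportion scale**,
    while ``range_across`` is max - min in percentage points — the mixed
    unit convention of the published tables this mirrors.
    """

    est_mcar: float
    est_mar: float
    est_mnar: float
    variance_across: float
    range_across: float

    @classmethod
    def from_estimates(
        cls, est_mcar: float, est_mar: float, est_mnar: float
    ) -> "MechanismTriplet":
        summary = summarize_mechanisms(est_mcar, est_mar, est_mnar)
        return cls(est_mcar, est_mar, est_mnar, **summary)


def summarize_mechanisms(
    est_mcar: float, est_mar: float, est_mnar: float
) -> dict[str, float]:
    """Cross-mechanism disagreement summary.

    ``variance_across``: sample variance (ddof=1) of the three estimates
    after conversion to proportions; ``range_across``: max - min in
    percentage points. Zero variance iff the three estimates coincide.
    """
    ests = np.array([est_mcar, est_mar, est_mnar], dtype=float)
    if np.any(ests < 0) or np.any(ests > 100):
        raise ValueError("estimates must be percents in [0, 100]")
    rng = float(ests.max() - ests.min())
    # exact zero for identical estimates (no float dust from the mean)
    var = 0.0 if rng == 0.0 else float(np.var(ests / 100.0, ddof=1))
    return {"variance_across": var, "range_across": rng}


DEFAULT_COVARIATES = (*CORRELATES, *ARM_DUMMY_TERMS)


def _usable_covariates(
    frame: pd.DataFrame, responses: pd.DataFrame, covariates: Sequence[str]
) -> list[str]:
    """Covariates that keep the responders-only design full rank.

    Stratum-level fits can see constant columns (an arm dummy inside its
    own stratum, a rare correlate absent among responders) or collinear
    combinations; a rank-revealing QR on the responders' design keeps a
    maximal independent subset, preserving covariate order.
    """
    from scipy.linalg import qr

    data = frame.merge(responses[["subject_id", "returned"]], on="subject_id")
    resp = data[data["returned"] == 1]
    candidates = [c for c in covariates if data[c].nunique() > 1 and resp[c].nunique() > 1]
    if not candidates:
        return []
    X = np.column_stack(
        [np.ones(len(resp))] + [resp[c].to_numpy(dtype=float) for c in candidates]
    )
    _, r, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    keep_rank = int(np.sum(diag > diag[0] * 1e-9))
    kept_cols = set(piv[:keep_rank])
    return [c for i, c in enumerate(candidates) if (i + 1) in kept_cols]


@dataclass
class MechanismResult:
    """Triplet plus the underlying MI and EM fits, for diagnostics."""

    triplet: MechanismTriplet
    mi: MIResult
    em: EMFit


def mechanism_triplet(
    frame: pd.DataFrame,
    assignment: pd.DataFrame,
    responses: pd.DataFrame,
    outcome: str,
    covariates: Sequence[str] | None = None,
    m: int = 25,
    seed: int | None = None,
    em_tol: float = 1e-6,
    em_max_iter: int = 500,
) -> MechanismResult:
    """One outcome's MCAR/MAR/MNAR estimates on a (sub)cohort.

    The default covariate set is the eight administrative correlates plus
    the treatment-coded arm indicators (all frame-complete by design).
    """
    if covariates is None:
        covariates = DEFAULT_COVARIATES
    aug = frame.merge(arm_dummies(assignment), on="subject_id", validate="1:1")
    usable = _usable_covariates(aug, responses, covariates)
    est_mcar = prevalence_mcar(responses, outcome)
    mi = impute_mar(aug, responses, outcome, usable, m=m, seed=seed)
    em = fit_em_nonignorable(
        aug, responses, outcome, usable, tol=em_tol, max_iter=em_max_iter
    )
    est_mnar = prevalence_mnar(em, aug, responses, outcome)
    triplet = MechanismTriplet.from_estimates(est_mcar, mi.pooled, est_mnar)
    return MechanismResult(triplet=triplet, mi=mi, em=em)


def mechanism_table(
    frame: pd.DataFrame,
    assignment: pd.DataFrame,
    responses: pd.DataFrame,
    outcome: str,
    covariates: Sequence[str] | None = None,
    m: int = 25,
    seed: int | None = None,
    em_tol: float = 1e-6,
    em_max_iter: int = 500,
) -> tuple[pd.DataFrame, dict[str, EMFit]]:
    """Mechanism triplets per block, overall and per arm manipulation.

    Returns a long-format table (block, stratum, estimates, variance,
    range) mirroring the published per-manipulation layout, plus the EM
    fits keyed by "block/stratum" for diagnostics. Covariates reduce to
    the correlates for single-factor strata (their own arm dummies are
    constant there and are dropped automatically).
    """
    from .factorial_design import manipulation_strata

    rows = []
    fits: dict[str, EMFit] = {}
    for block in frame["block"].unique():
        fmask = frame["block"] == block
        fsub = frame[fmask]
        asub = assignment[assignment["subject_id"].isin(fsub["subject_id"])]
        rsub = responses[responses["subject_id"].isin(fsub["subject_id"])]
        strata = [("overall", "overall", pd.Series(True, index=asub.index))]
        strata += manipulation_strata(asub)
        for factor, level, mask in strata:
            ids = asub.loc[mask, "subject_id"]
            res = mechanism_triplet(
                fsub[fsub["subject_id"].isin(ids)],
                asub[asub["subject_id"].isin(ids)],
                rsub[rsub["subject_id"].isin(ids)],
                outcome,
                covariates=covariates,
                m=m,
                seed=seed,
                em_tol=em_tol,
                em_max_iter=em_max_iter,
            )
            t = res.triplet
            rows.append(
                {
                    "block": block,
                    "outcome": outcome,
                    "margin": factor,
                    "level": level,
                    "n": len(ids),
                    "est_mcar": t.est_mcar,
                    "est_mar": t.est_mar,
                    "est_mnar": t.est_mnar,
                    "variance_across": t.variance_across,
                    "range_across": t.range_across,
                }
            )
            fits[f"{block}/{factor}={level}"] = res.em
    return pd.DataFrame(rows), fits
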