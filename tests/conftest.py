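import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings
from scipy.special import expit

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_selection_cohort(
    seed,
    n=5000,
    beta=(1.0, 2.5, -2.0),
    alpha=(1.0, 0.8, -0.8),
    gamma=-2.0,
):
    """Cohort drawn from the nonignorable selection model itself.

    Covariates: x1 ~ N(0,1), x2 ~ Bernoulli(0.4). Returns
    (frame, responses, latent y) with responses masked by r.
    """
    rng = np.random.default_rng(seed)
    x1 = rng.standard_normal(n)
    x2 = (rng.random(n) < 0.4).astype(int)
    X = np.column_stack([np.ones(n), x1, x2])
    y = (rng.random(n) < expit(X @ np.asarray(beta))).astype(int)
    r = (rng.random(n) < expit(X @ np.asarray(alpha) + gamma * y)).astype(int)
    frame = pd.DataFrame(
        {"subject_id": np.arange(n), "block": "men", "x1": x1, "x2": x2}
    )
    responses = pd.DataFrame(
        {
            "subject_id": np.arange(n),
            "returned": r,
            "y": np.where(r == 1, y.astype(float), np.nan),
        }
    )
    return frame, responses, y


def make_mar_cohort(
    seed,
    n=20000,
    beta=(0.3, 2.0, 1.5, 1.5),
    alpha=(0.5, 1.2, 0.5, 1.0),
):
    """Ignorable (gamma = 0) cohort: response depends on covariates that
    also predict the outcome, so the complete-case mean is biased but MAR
    methods recover the latent prevalence. Covariates x1, x3 ~ N(0,1),
    x2 ~ Bernoulli(0.4)."""
    rng = np.random.default_rng(seed)
    x1 = rng.standard_normal(n)
    x2 = (rng.random(n) < 0.4).astype(int)
    x3 = rng.standard_normal(n)
    X = np.column_stack([np.ones(n), x1, x2, x3])
    y = (rng.random(n) < expit(X @ np.asarray(beta))).astype(int)
    r = (rng.random(n) < expit(X @ np.asarray(alpha))).astype(int)
    frame = pd.DataFrame(
        {"subject_id": np.arange(n), "block": "men", "x1": x1, "x2": x2, "x3": x3}
    )
    responses = pd.DataFrame(
        {
            "subject_id": np.arange(n),
            "returned": r,
            "y": np.where(r == 1, y.astype(float), np.nan),
        }
    )
    return frame, responses, y


def make_mcar_cohort(seed, n=50000, response_rate=0.6, beta=(0.3, 2.0, 1.5, 1.5)):
    """Completely-at-random masking of the same outcome model."""
    rng = np.random.default_rng(seed)
    x1 = rng.standard_normal(n)
    x2 = (rng.random(n) < 0.4).astype(int)
    x3 = rng.standard_normal(n)
    X = np.column_stack([np.ones(n), x1, x2, x3])
    y = (rng.random(n) < expit(X @ np.asarray(beta))).astype(int)
    r = (rng.random(n) < response_rate).astype(int)
    frame = pd.DataFrame(
        {"subject_id": np.arange(n), "block": "men", "x1": x1, "x2": x2, "x3": x3}
    )
    responses = pd.DataFrame(
        {
            "subject_id": np.arange(n),
            "returned": r,
            "y": np.where(r == 1, y.astype(float), np.nan),
        }
    )
    return frame, responses, y


@pytest.fixture(scope="session")
def study_like_cohort():
    """One study-scale synthetic trial: 480 subjects per gender block."""
    import warnings

    from nrbias.pipeline import PipelineConfig, simulate_cohort

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        frame, assignment, latent, responses = simulate_cohort(PipelineConfig())
    return frame, assignment, latent, responses
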