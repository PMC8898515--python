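"""Simulate -> analyze -> report pipeline with a reproducible manifest.

``run_pipeline`` chains the synthetic cohort generator, the response-rate
and bias analyses, and the three-mechanism prevalence estimators, writing
the report tables as CSV, EM diagnostics as JSON, and a run manifest that
records every seed and configuration value. Re-running from a manifest
reproduces every stochastic output bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .bias_analysis import bias_by_arm, characteristics_table, eta2_table
from .factorial_design import randomize_blocked
from .io import write_table
from .missingness import MNAR_CAVEAT, mechanism_table
from .response_metrics import margin_homogeneity_tests, response_rate_table
from .synthetic_cohort import (
    CORRELATES,
    OUTCOMES,
    FrameSpec,
    OutcomeModel,
    ResponseModel,
    generate_frame,
    simulate_response,
    simulate_self_reports,
)

#: Rounding applied at render time only (decimals per quantity).
DEFAULT_ROUNDING = {"rate_pct": 1, "bias_pp": 1, "est": 1, "variance_across": 4, "range_across": 1, "eta2_percent": 1}


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run.

    ``scenario`` is a YAML path or the name of a bundled scenario
    (``"study_like"``). Seeds are independent for design randomization,
    cohort generation, and the imputation draws.
    """

    scenario: str = "study_like"
    seed_design: int = 20160201
    seed_cohort: int = 20160202
    seed_mi: int = 20160203
    m_imputations: int = 25
    em_tol: float = 1e-6
    em_max_iter: int = 500
    outdir: str = "nrbias_run"
    rounding: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_ROUNDING))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def load_scenario(name_or_path: str | Path) -> dict:
    """Load a scenario mapping from a bundled name or a YAML path."""
    path = Path(name_or_path)
    if path.suffix in (".yaml", ".yml") and path.exists():
        text = path.read_text()
    else:
        ref = resources.files("nrbias") / "scenarios" / f"{name_or_path}.yaml"
        if not ref.is_file():
            raise PipelineError(f"stage 'scenario': unknown scenario {name_or_path!r}")
        text = ref.read_text()
    raw = yaml.safe_load(text)
    for key in ("frame", "outcomes", "response"):
        if key not in raw:
            raise PipelineError(f"stage 'scenario': missing section {key!r}")
    return raw


def scenario_models(raw: dict) -> tuple[FrameSpec, OutcomeModel, ResponseModel]:
    frame_raw = dict(raw["frame"])
    dependence = frame_raw.pop("covariate_dependence", None)
    if dependence is not None:
        dependence = {tuple(k.split("~")): v for k, v in dependence.items()}
    spec = FrameSpec(covariate_dependence=dependence, **frame_raw)
    outcome = OutcomeModel(beta=raw["outcomes"])
    response = ResponseModel(
        alpha=raw["response"]["alpha"], gamma=raw["response"].get("gamma", {})
    )
    return spec, outcome, response


def simulate_cohort(
    config: PipelineConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (frame, assignment, latent, responses) for the scenario."""
    try:
        raw = load_scenario(config.scenario)
        spec, outcome_model, response_model = scenario_models(raw)
        frame = generate_frame(spec, seed=config.seed_cohort)
        assignment = randomize_blocked(frame, seed=config.seed_design)
        latent = simulate_self_reports(frame, outcome_model, seed=config.seed_cohort + 1)
        responses = simulate_response(
            frame, assignment, latent, response_model, seed=config.seed_cohort + 2
        )
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - stage-named contract
        raise PipelineError(f"stage 'simulate' failed: {exc}") from exc
    return frame, assignment, latent, responses


def analyze(
    frame: pd.DataFrame,
    assignment: pd.DataFrame,
    responses: pd.DataFrame,
    config: PipelineConfig,
) -> dict[str, object]:
    """All report tables from (frame, assignment, responses)."""
    out: dict[str, object] = {}
    try:
        out["response_rates"] = response_rate_table(assignment, responses)
        out["response_tests"] = margin_homogeneity_tests(assignment, responses)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"stage 'response_metrics' failed: {exc}") from exc
    try:
        out["characteristics"] = characteristics_table(frame, responses)
        out["bias_by_arm"] = pd.concat(
            [bias_by_arm(frame, assignment, responses, c) for c in CORRELATES],
            ignore_index=True,
        )
        out["eta2"] = eta2_table(frame, assignment, responses)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"stage 'bias_analysis' failed: {exc}") from exc
    try:
        mech_frames = []
        diagnostics: dict[str, dict] = {"caveat": MNAR_CAVEAT, "fits": {}}
        outcome_cols = [c for c in responses.columns if c not in ("subject_id", "returned")]
        for outcome in outcome_cols:
            table, fits = mechanism_table(
                frame,
                assignment,
                responses,
                outcome,
                m=config.m_imputations,
                seed=config.seed_mi,
                em_tol=config.em_tol,
                em_max_iter=config.em_max_iter,
            )
            mech_frames.append(table)
            for key, fit in fits.items():
                diagnostics["fits"][f"{outcome}/{key}"] = {
                    "loglik": fit.loglik,
                    "n_iter": fit.n_iter,
                    "converged": fit.converged,
                    "gamma": fit.gamma,
                }
        out["mechanisms"] = pd.concat(mech_frames, ignore_index=True)
        out["em_diagnostics"] = diagnostics
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"stage 'missingness' failed: {exc}") from exc
    return out


def _rounded(df: pd.DataFrame, rounding: dict[str, int]) -> pd.DataFrame:
    df = df.copy()
    for col in df.columns:
        nd = None
        if col in rounding:
            nd = rounding[col]
        elif col.startswith("est_"):
            nd = rounding.get("est")
        elif col.endswith("_pct"):
            nd = rounding.get("rate_pct")
        if nd is not None and pd.api.types.is_float_dtype(df[col]):
            df[col] = df[col].round(nd)
    return df


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run simulate -> analyze -> report; return the written file map."""
    outdir = Path(config.outdir)
    frame, assignment, latent, responses = simulate_cohort(config)
    results = analyze(frame, assignment, responses, config)
    outdir.mkdir(parents=True, exist_ok=True)

    written: dict[str, Path] = {}
    try:
        written["frame"] = write_table(frame, outdir / "frame.csv")
        written["assignment"] = write_table(assignment, outdir / "assignment.csv")
        written["latent"] = write_table(latent, outdir / "latent_self_reports.csv")
        written["responses"] = write_table(responses, outdir / "responses.csv")
        for name in (
            "response_rates",
            "response_tests",
            "characteristics",
            "bias_by_arm",
            "eta2",
            "mechanisms",
        ):
            written[name] = write_table(
                _rounded(results[name], config.rounding), outdir / f"{name}.csv"
            )
        diag_path = outdir / "em_diagnostics.json"
        diag_path.write_text(json.dumps(results["em_diagnostics"], indent=1))
        written["em_diagnostics"] = diag_path
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"stage 'report' failed: {exc}") from exc

    manifest = {
        "package": "nrbias",
        "version": __version__,
        "config": asdict(config),
        "config_sha256": hashlib.sha256(
            json.dumps(asdict(config), sort_keys=True).encode()
        ).hexdigest(),
        "outputs": {
            name: hashlib.sha256(Path(p).read_bytes()).hexdigest()
            for name, p in written.items()
        },
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    written["manifest"] = manifest_path
    return written


def run_from_manifest(path: str | Path) -> dict[str, Path]:
    """Re-run a pipeline from a manifest's recorded configuration."""
    manifest = json.loads(Path(path).read_text())
    return run_pipeline(PipelineConfig(**manifest["config"]))
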