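"""Staged analysis pipeline: simulate -> GLM -> selection -> meta -> empirical.

Ties the modules into the three-step workflow (reference GLM with feature
ranking, meta-analysis of study-level counts, interaction model on the
selected features), writing machine-readable artifacts and a log so that
every number is reproducible from (config, seed) alone.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import io as lio
from .diagnostics import check_convergence
from .empirical import EmpiricalSpec, fit_empirical, summarize_effects
from .glm import PriorSpec, bayes_r2, build_design, posterior_predictive_check, sample_posterior
from .meta import compute_effects, fit_hierarchical, shrinkage_summaries
from .projection import evaluate_path, forward_search
from .synthetic import default_cohort_template, default_meta_template, generate_meta_studies, generate_patient_table

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "ALL_STAGES"]

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "glm", "select", "meta", "empirical")


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Pipeline settings.  The seed is mandatory: every random quantity in
    the run flows from it, and the full configuration is echoed into the run
    summary."""

    seed: int
    outdir: str
    stages: tuple[str, ...] = ALL_STAGES
    # simulate stage
    n_patients: int = 2000
    # sampler settings
    chains: int = 4
    iterations: int = 2000
    warmup: int = 1000
    # prior
    coef_prior_scale: float = 1.0
    intercept_prior_scale: float = 2.5
    # selection
    folds: int = 5
    max_size: int | None = None
    n_proj_draws: int = 50
    # meta
    study_csv: str | None = None
    tau_max: float = 10.0
    # inputs
    patient_csv: str | None = None

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")

    def to_dict(self) -> dict:
        return {k: (list(v) if isinstance(v, tuple) else v)
                for k, v in self.__dict__.items()}


def _stage_seed(root_seed: int, stage: str) -> int:
    idx = ALL_STAGES.index(stage)
    return int(np.random.SeedSequence([root_seed, idx]).generate_state(1)[0] % (2**31 - 1))


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages in order and return the JSON-serializable
    run summary (also written to ``<outdir>/summary.json``).

    Artifacts per stage: simulated tables + ground truth, posterior draw
    summaries, the selection path CSV, forest-plot CSV and meta summaries,
    and the empirical-model effect CSV.  ``summary['diagnostics_ok']`` is
    False when any convergence threshold failed.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run_log.txt"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root_logger = logging.getLogger("litbayes")
    root_logger.addHandler(handler)
    root_logger.setLevel(logging.INFO)

    prior = PriorSpec(coef_scale=config.coef_prior_scale,
                      intercept_scale=config.intercept_prior_scale)
    summary: dict = {"config": config.to_dict(), "diagnostics_ok": True}
    table = None
    try:
        if "simulate" in config.stages:
            stage = "simulate"
            cohort_cfg = default_cohort_template(
                n_patients=config.n_patients, seed=_stage_seed(config.seed, stage))
            table = generate_patient_table(cohort_cfg)
            lio.write_patient_csv(table, outdir / "patients.csv",
                                  outdir / "patients_truth.json")
            summary[stage] = {"n_patients": table.n,
                              "birth_rate": float(table.outcome.mean())}
        elif config.patient_csv and set(config.stages) & {"glm", "select", "empirical"}:
            specs = default_cohort_template().factors
            table = lio.read_patient_csv(config.patient_csv, list(specs))

        if "glm" in config.stages:
            stage = "glm"
            if table is None:
                raise PipelineError(stage, "no patient table (run simulate or pass patient_csv)")
            design = build_design(table, table.factor_names)
            fit = sample_posterior(design, table.outcome, prior=prior,
                                   chains=config.chains, iterations=config.iterations,
                                   warmup=config.warmup, seed=_stage_seed(config.seed, stage))
            lio.write_summary_json(fit, outdir / "glm_summary.json")
            diag = check_convergence(fit)
            _, r2_median = bayes_r2(fit, design)
            ppc = posterior_predictive_check(fit, design, table.outcome,
                                             seed=_stage_seed(config.seed, stage))
            ok = bool(diag["rhat_ok"].all() and diag["ess_ok"].all())
            summary[stage] = {
                "rhat_max": float(diag["rhat"].max()),
                "ess_min": float(diag["ess"].min()),
                "bayes_r2_median": r2_median,
                "ppc_p_value": ppc.p_value,
                "diagnostics_ok": ok,
            }
            summary["diagnostics_ok"] &= ok
            summary["_glm_fit"] = (fit, design)

        if "select" in config.stages:
            stage = "select"
            if "_glm_fit" not in summary:
                raise PipelineError(stage, "selection requires the glm stage")
            fit, design = summary["_glm_fit"]
            path = forward_search(fit, design, max_size=config.max_size,
                                  n_proj_draws=min(20, config.n_proj_draws))
            path = evaluate_path(path, table, folds=config.folds,
                                 seed=_stage_seed(config.seed, stage), prior=prior,
                                 n_proj_draws=config.n_proj_draws,
                                 chains=max(2, config.chains // 2),
                                 iterations=max(600, config.iterations // 2),
                                 warmup=max(300, config.warmup // 2))
            lio.write_selection_csv(path, outdir / "selection_path.csv")
            summary[stage] = {
                "ranking": list(path.ranked_factors),
                "reference_accuracy": path.reference_accuracy,
                "reference_elpd": path.reference_elpd,
            }

        if "meta" in config.stages:
            stage = "meta"
            seed = _stage_seed(config.seed, stage)
            if config.study_csv:
                studies = lio.read_study_csv(config.study_csv)
            else:
                studies, _ = generate_meta_studies(default_meta_template(seed=seed))
                lio.write_study_csv(studies, outdir / "studies.csv")
            effects = compute_effects(studies)
            post = fit_hierarchical(effects, chains=config.chains,
                                    iterations=config.iterations, warmup=config.warmup,
                                    seed=seed, tau_max=config.tau_max)
            lio.write_meta_json(post, outdir / "meta_summary.json", seed=seed,
                                force=True)
            lio.write_forest_csv(shrinkage_summaries(post, effects, force=True),
                                 outdir / "forest.csv")
            summary[stage] = post.summaries(force=True, seed=seed)
            summary[stage]["diagnostics_ok"] = bool(post.diagnostics_ok)
            summary["diagnostics_ok"] &= bool(post.diagnostics_ok)

        if "empirical" in config.stages:
            stage = "empirical"
            if table is None:
                raise PipelineError(stage, "no patient table (run simulate or pass patient_csv)")
            spec = EmpiricalSpec()
            try:
                draws, design = fit_empirical(
                    table, spec, prior=prior, chains=config.chains,
                    iterations=config.iterations, warmup=config.warmup,
                    seed=_stage_seed(config.seed, stage))
            except (KeyError, ValueError) as exc:
                raise PipelineError(stage, str(exc)) from exc
            eff = summarize_effects(draws, design, spec)
            eff.table.to_csv(outdir / "empirical_effects.csv", index=False)
            diag = check_convergence(draws)
            ok = bool(diag["rhat_ok"].all() and diag["ess_ok"].all())
            summary[stage] = {
                "rhat_max": float(diag["rhat"].max()),
                "ess_min": float(diag["ess"].min()),
                "diagnostics_ok": ok,
            }
            summary["diagnostics_ok"] &= ok
    except PipelineError:
        raise
    except Exception as exc:  # tag unexpected failures with their stage
        raise PipelineError(stage, str(exc)) from exc
    finally:
        root_logger.removeHandler(handler)
        handler.close()

    summary.pop("_glm_fit", None)
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
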