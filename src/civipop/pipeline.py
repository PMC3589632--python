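"""End-to-end orchestration: simulate -> preprocess -> base fit -> covariate
selection -> final fit -> bootstrap -> exposure report.

Every stage writes plain CSV/JSON intermediates into the output directory so
each step can be audited or re-run from its inputs.  One global seed is
split deterministically into independent per-stage seeds.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import covariates as cov
from .bootstrap import run_bootstrap
from .dataset import StudyDataset, flag_outliers_and_assign_groups, load_dataset, write_dataset
from .exposure import exposure_table, renal_effect_summary
from .nlme import ModelSpec, fit_model, gof_table
from .simulate import SyntheticConfig, generate_study

logger = logging.getLogger(__name__)

__all__ = ["AnalysisConfig", "run_full_analysis", "stage_seeds"]

_STAGES = ("simulate", "base_fit", "selection", "final_fit", "bootstrap", "exposure")


def stage_seeds(seed: int) -> dict[str, int]:
    """Deterministic per-stage seeds spawned from one global seed."""
    children = np.random.SeedSequence(seed).spawn(len(_STAGES))
    return {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(_STAGES, children)
    }


@dataclass
class AnalysisConfig:
    """Configuration of a full analysis run."""

    seed: int
    out_dir: str | Path = "civipop_out"
    dataset_path: str | Path | None = None  # if None, simulate
    synthetic: SyntheticConfig | None = None
    init_model: ModelSpec = field(default_factory=ModelSpec)
    alpha_screen: float = 0.1
    alpha_forward: float = 0.05
    alpha_backward: float = 0.01
    continuous_candidates: tuple = cov.DEFAULT_CONTINUOUS
    categorical_candidates: tuple = cov.DEFAULT_CATEGORICAL
    run_selection: bool = True
    bootstrap_n: int = 300
    bootstrap_stratify: bool = True
    renal_grid: tuple = (20.0, 40.0, 60.0, 79.22, 100.0, 120.0)

    def __post_init__(self) -> None:
        for a in (self.alpha_screen, self.alpha_forward, self.alpha_backward):
            if not 0 < a < 1:
                raise ValueError(f"significance level {a} outside (0, 1)")


def run_full_analysis(config: AnalysisConfig) -> dict:
    """Run every stage in order and write the report bundle.

    Returns a dict with the in-memory stage results and output paths.  On a
    stage failure the bundle up to that stage is kept and an ``error.json``
    record is written.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed)
    from . import __version__

    logger.info("civipop %s, global seed %d, stage seeds %s",
                __version__, config.seed, seeds)
    bundle: dict = {"out_dir": out, "seeds": seeds}

    try:
        # --- data -------------------------------------------------------
        if config.dataset_path is not None:
            dataset = load_dataset(config.dataset_path)
        else:
            syn = config.synthetic or SyntheticConfig(seed=seeds["simulate"])
            syn = dataclasses.replace(syn, seed=seeds["simulate"])
            dataset, truth = generate_study(syn)
            bundle["truth"] = truth
            with open(out / "ground_truth.json", "w") as fh:
                json.dump(
                    dict(
                        model=truth.model.to_dict(),
                        etas=truth.etas,
                        individual_cl=truth.individual_cl,
                        contaminated=truth.contaminated,
                        seed=truth.seed,
                    ),
                    fh,
                    indent=2,
                    sort_keys=True,
                )

        # --- preprocess: outlier flags and error groups -------------------
        thresholds, dataset = flag_outliers_and_assign_groups(dataset)
        bundle["dataset"] = dataset
        bundle["thresholds"] = thresholds
        write_dataset(dataset, out / "dataset.csv")
        with open(out / "outlier_thresholds.json", "w") as fh:
            json.dump(
                dict(
                    q1=thresholds.q1,
                    q3=thresholds.q3,
                    iqr=thresholds.iqr,
                    low_limit=thresholds.low_limit,
                    high_limit=thresholds.high_limit,
                ),
                fh,
                indent=2,
                sort_keys=True,
            )

        # --- base fit -----------------------------------------------------
        base_model = dataclasses.replace(config.init_model, covariate_terms=())
        base_fit = fit_model(base_model, dataset, seed=seeds["base_fit"])
        bundle["base_fit"] = base_fit
        base_fit.parameter_table().to_csv(out / "base_parameters.csv", index=False)
        pd.DataFrame(
            [dict(patient_id=e.patient_id, eta_cl=e.eta_cl,
                  individual_cl=e.individual_cl, n_obs=e.n_obs)
             for e in base_fit.etas]
        ).to_csv(out / "base_etas.csv", index=False)

        # --- covariate selection -----------------------------------------
        if config.run_selection:
            candidates = cov.screen_covariates(
                base_fit,
                dataset,
                alpha_screen=config.alpha_screen,
                continuous=config.continuous_candidates,
                categorical=config.categorical_candidates,
            )
            full_model, fwd_trace = cov.forward_addition(
                base_fit.model, candidates, dataset,
                alpha=config.alpha_forward, base_fit=base_fit,
            )
            final_model, bwd_trace = cov.backward_elimination(
                full_model, dataset, alpha=config.alpha_backward
            )
            trace = pd.concat(
                [fwd_trace.to_frame(), bwd_trace.to_frame()], ignore_index=True
            )
            trace.to_csv(out / "selection_trace.csv", index=False)
            bundle["selection_trace"] = trace
        else:
            final_model = config.init_model

        # --- final fit ----------------------------------------------------
        final_fit = fit_model(final_model, dataset, seed=seeds["final_fit"])
        bundle["final_fit"] = final_fit
        final_fit.model.to_json(out / "final_model.json")
        final_fit.parameter_table().to_csv(out / "final_parameters.csv", index=False)
        gof = gof_table(final_fit, dataset)
        gof.to_csv(out / "gof.csv", index=False)
        bundle["gof"] = gof

        # --- bootstrap ----------------------------------------------------
        if config.bootstrap_n > 0:
            boot = run_bootstrap(
                final_fit.model,
                dataset,
                n_replicates=config.bootstrap_n,
                seed=seeds["bootstrap"],
                stratify=config.bootstrap_stratify,
            )
            bundle["bootstrap"] = boot
            boot.estimates.to_csv(out / "bootstrap_estimates.csv", index=False)
            boot.summary(point_fit=final_fit).to_csv(out / "bootstrap_summary.csv")

        # --- exposure -----------------------------------------------------
        exp = exposure_table(dataset, final_fit.etas)
        exp.to_csv(out / "exposure.csv", index=False)
        bundle["exposure"] = exp
        clcr_terms = [
            t for t in final_fit.model.covariate_terms
            if t.covariate == "CLCR" and t.form == "power"
        ]
        if clcr_terms:
            renal = renal_effect_summary(
                clcr_terms[0].coefficient,
                config.renal_grid,
                reference=clcr_terms[0].reference,
            )
            renal.to_csv(out / "renal_effect.csv", index=False)
            bundle["renal_effect"] = renal
    except Exception as exc:  # record the failure, keep partial bundle
        logger.exception("pipeline stage failed")
        with open(out / "error.json", "w") as fh:
            json.dump(dict(error=type(exc).__name__, message=str(exc)), fh, indent=2)
        bundle["error"] = exc
    return bundle


def load_analysis_config(path, seed: int | None = None, out_dir=None) -> AnalysisConfig:
    """Read an :class:`AnalysisConfig` from a YAML or JSON file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if seed is not None:
        raw["seed"] = seed
    if out_dir is not None:
        raw["out_dir"] = out_dir
    if "synthetic" in raw and raw["synthetic"] is not None:
        syn = dict(raw["synthetic"])
        syn.setdefault("seed", raw["seed"])
        if "true_model" in syn:
            syn["true_model"] = ModelSpec.from_dict(syn["true_model"])
        raw["synthetic"] = SyntheticConfig(**syn)
    if "init_model" in raw and raw["init_model"] is not None:
        raw["init_model"] = ModelSpec.from_dict(raw["init_model"])
    for key in ("continuous_candidates", "categorical_candidates", "renal_grid"):
        if key in raw and raw[key] is not None:
            raw[key] = tuple(raw[key])
    return AnalysisConfig(**raw)
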