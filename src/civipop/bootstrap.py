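"""Nonparametric bootstrap validation of a fitted population model.

Whole patients are resampled with replacement (optionally stratified by
study so every cancer-type indicator stays non-degenerate), the model is
refit on each replicate with the point estimates as starting values, and
95% confidence intervals are read off as the 2.5th / 97.5th percentiles of
the converged replicate estimates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import StudyDataset
from .nlme import ModelSpec, _parameter_names_values, fit_model

logger = logging.getLogger(__name__)

__all__ = ["BootstrapResult", "run_bootstrap"]


@dataclass
class BootstrapResult:
    n_requested: int
    n_converged: int
    estimates: pd.DataFrame  # one row per converged replicate
    ci_low: pd.Series
    ci_high: pd.Series
    seed: int

    def summary(self, point: ModelSpec | None = None, point_fit=None) -> pd.DataFrame:
        """Bootstrap mean and percentile CI per parameter.

        With ``point`` (or a ``point_fit`` :class:`~civipop.nlme.FitResult`)
        the original estimates are appended; a fit additionally contributes
        approximate Wald 95% intervals from its CV% standard errors.
        """
        out = pd.DataFrame(
            dict(
                mean=self.estimates.mean(),
                ci_low=self.ci_low,
                ci_high=self.ci_high,
            )
        )
        if point_fit is not None and point is None:
            point = point_fit.model
        if point is not None:
            names, values = _parameter_names_values(point)
            out["original"] = pd.Series(dict(zip(names, values)))
        if point_fit is not None and point_fit.standard_errors:
            half = {
                name: 1.96 * point_fit.standard_errors.get(name, np.nan) / 100.0
                for name in out.index
            }
            out["original_ci_low"] = out["original"] * (1.0 - pd.Series(half))
            out["original_ci_high"] = out["original"] * (1.0 + pd.Series(half))
        out.index.name = "parameter"
        return out


def _resample_ids(dataset: StudyDataset, rng: np.random.Generator, stratify: bool):
    ids = dataset.patient_ids
    if not stratify:
        return list(rng.choice(ids, size=len(ids), replace=True))
    out: list[str] = []
    for study in sorted({p.study for p in dataset.patients}):
        members = [p.patient_id for p in dataset.patients if p.study == study]
        out.extend(rng.choice(members, size=len(members), replace=True))
    return out


def run_bootstrap(
    model: ModelSpec,
    dataset: StudyDataset,
    n_replicates: int,
    seed: int,
    stratify: bool = True,
    maxiter: int = 400,
) -> BootstrapResult:
    """Resample patients, refit, and summarise percentile intervals.

    ``model`` should carry the point estimates from the original fit; they
    are used as starting values for every replicate.  Replicates that fail
    to converge are counted but excluded from the percentiles.  The same
    seed reproduces the replicate index sets and the result exactly.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    names, _ = _parameter_names_values(model)
    rows = []
    n_converged = 0
    n_failed = 0
    for r in range(n_replicates):
        ids = _resample_ids(dataset, rng, stratify)
        replicate = dataset.subset(ids, relabel=True)
        try:
            fit = fit_model(model, replicate, compute_se=False, maxiter=maxiter)
        except Exception as exc:
            logger.warning("replicate %d failed: %s", r, exc)
            n_failed += 1
            continue
        if not fit.converged:
            n_failed += 1
            continue
        n_converged += 1
        _, values = _parameter_names_values(fit.model)
        rows.append(dict(zip(names, values)))
    if n_converged == 0:
        raise RuntimeError(
            f"all {n_replicates} bootstrap replicates failed to converge"
        )
    estimates = pd.DataFrame(rows, columns=names)
    ci_low = estimates.quantile(0.025, interpolation="linear")
    ci_high = estimates.quantile(0.975, interpolation="linear")
    return BootstrapResult(
        n_requested=n_replicates,
        n_converged=n_converged,
        estimates=estimates,
        ci_low=ci_low,
        ci_high=ci_high,
        seed=seed,
    )
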