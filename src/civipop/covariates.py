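"""Covariate model terms and stepwise covariate selection on clearance.

Typical clearance for patient j is a multiplicative model

    CL_j = CL_pop * prod (X_j / X_ref)^theta_power * prod theta_ratio^Z_j

with power terms for continuous covariates (normalised to a reference value
near the population median) and ratio terms for 0/1 indicators.  Selection
follows standard pharmacometric practice: screening of empirical-Bayes eta
estimates against each covariate, forward addition by likelihood-ratio test
at alpha = 0.05, then backward elimination at alpha = 0.01.  Cancer type
(two indicator columns against the reference study) moves as one 2-df block.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import PatientRecord, StudyDataset

logger = logging.getLogger(__name__)

__all__ = [
    "CovariateTerm",
    "SelectionStep",
    "SelectionTrace",
    "evaluate_typical_cl",
    "screen_covariates",
    "forward_addition",
    "backward_elimination",
    "REFERENCE_VALUES",
    "DEFAULT_CONTINUOUS",
    "DEFAULT_CATEGORICAL",
]

# Fixed reference values for covariate normalisation (population medians of
# the original three-study cohort); other continuous covariates fall back to
# the dataset median.
REFERENCE_VALUES = {"CLCR": 79.22, "ALT": 19.0}

DEFAULT_CONTINUOUS = ("CLCR", "ALT", "AGE", "WT", "BSA", "SCR", "ALB", "AAG", "AST")
DEFAULT_CATEGORICAL = ("STUDY", "SEXF", "ECOG")


@dataclass(frozen=True)
class CovariateTerm:
    """One multiplicative covariate factor on typical clearance.

    ``form='power'`` contributes ``(X/reference)^coefficient`` for a
    continuous covariate; ``form='ratio'`` contributes
    ``coefficient^Z`` for a 0/1 indicator.  Terms sharing a ``block`` label
    enter and leave selection together (e.g. the two cancer-type ratios).
    """

    covariate: str
    form: str
    coefficient: float
    reference: float | None = None
    block: str | None = None

    def __post_init__(self) -> None:
        if self.form not in ("power", "ratio"):
            raise ValueError(f"form must be 'power' or 'ratio', got {self.form!r}")
        if self.form == "power" and (self.reference is None or self.reference <= 0):
            raise ValueError(f"power term {self.covariate} needs a positive reference")
        if self.form == "ratio" and self.coefficient <= 0:
            raise ValueError(f"ratio term {self.covariate} needs a positive coefficient")

    @property
    def name(self) -> str:
        return f"{self.covariate}_{self.form}"

    @property
    def block_name(self) -> str:
        return self.block if self.block is not None else self.name

    def null_valued(self) -> "CovariateTerm":
        """The same term at its no-effect value (power 0 / ratio 1)."""
        return replace(self, coefficient=0.0 if self.form == "power" else 1.0)


def evaluate_typical_cl(
    cl_pop: float, terms: Sequence[CovariateTerm], patient: PatientRecord
) -> float:
    """Typical (pre-eta) clearance for one patient, L/h."""
    cl = cl_pop
    for term in terms:
        x = patient.covariate(term.covariate)
        if term.form == "power":
            if x <= 0:
                raise ValueError(
                    f"patient {patient.patient_id}: covariate {term.covariate} "
                    f"must be positive for a power term, got {x}"
                )
            cl *= (x / term.reference) ** term.coefficient
        else:
            cl *= term.coefficient ** x
    return cl


# ---------------------------------------------------------------------------
# candidate construction
# ---------------------------------------------------------------------------


def _continuous_candidate(name: str, dataset: StudyDataset) -> tuple[CovariateTerm, ...]:
    ref = REFERENCE_VALUES.get(name)
    if ref is None:
        values = [p.covariate(name) for p in dataset.patients]
        ref = float(np.median(values))
    return (CovariateTerm(name, "power", 0.0, reference=ref),)


def _categorical_candidate(name: str) -> tuple[CovariateTerm, ...]:
    if name == "STUDY":
        return (
            CovariateTerm("HRPC", "ratio", 1.0, block="STUDY"),
            CovariateTerm("MM", "ratio", 1.0, block="STUDY"),
        )
    if name == "ECOG":
        return (
            CovariateTerm("ECOG1", "ratio", 1.0, block="ECOG"),
            CovariateTerm("ECOG2", "ratio", 1.0, block="ECOG"),
        )
    return (CovariateTerm(name, "ratio", 1.0),)


def _categorical_groups(name: str, dataset: StudyDataset, etas: np.ndarray, ids: list):
    """Eta values grouped by category level for the screening test."""
    lookup = {pid: e for pid, e in zip(ids, etas)}
    groups: dict[object, list[float]] = {}
    for p in dataset.patients:
        if p.patient_id not in lookup:
            continue
        if name == "STUDY":
            key = p.study
        elif name == "ECOG":
            key = p.ecog
        else:
            key = p.covariate(name)
        groups.setdefault(key, []).append(lookup[p.patient_id])
    return [np.asarray(v) for v in groups.values() if len(v) > 0]


# ---------------------------------------------------------------------------
# screening
# ---------------------------------------------------------------------------


def screen_covariates(
    base_fit,
    dataset: StudyDataset,
    alpha_screen: float = 0.1,
    continuous: Sequence[str] = DEFAULT_CONTINUOUS,
    categorical: Sequence[str] = DEFAULT_CATEGORICAL,
) -> list[tuple[CovariateTerm, ...]]:
    """Screen covariates against the base model's empirical-Bayes etas.

    Continuous covariates are tested by simple linear regression of eta_CL
    on the covariate; categorical covariates by a two-sample t-test (one-way
    ANOVA for more than two levels).  Covariates with p < ``alpha_screen``
    pass and are returned as candidate term blocks for forward addition.
    Constant covariates are skipped with a warning.
    """
    etas, ids = [], []
    for e in base_fit.etas:
        if e.n_obs > 0:
            etas.append(e.eta_cl)
            ids.append(e.patient_id)
    etas = np.asarray(etas)

    candidates: list[tuple[CovariateTerm, ...]] = []
    lookup = set(ids)
    for name in continuous:
        try:
            x = np.asarray(
                [p.covariate(name) for p in dataset.patients if p.patient_id in lookup]
            )
        except Exception:
            warnings.warn(f"covariate {name} unavailable; skipped")
            continue
        if np.ptp(x) == 0:
            warnings.warn(f"covariate {name} is constant; skipped")
            continue
        res = stats.linregress(x, etas)
        logger.info("screen %s: slope p=%.4g", name, res.pvalue)
        if res.pvalue < alpha_screen:
            candidates.append(_continuous_candidate(name, dataset))
    for name in categorical:
        groups = _categorical_groups(name, dataset, etas, ids)
        if len(groups) < 2:
            warnings.warn(f"covariate {name} has a single level; skipped")
            continue
        if len(groups) == 2:
            p_value = stats.ttest_ind(groups[0], groups[1]).pvalue
        else:
            p_value = stats.f_oneway(*groups).pvalue
        logger.info("screen %s: group p=%.4g", name, p_value)
        if p_value < alpha_screen:
            candidates.append(_categorical_candidate(name))
    return candidates


# ---------------------------------------------------------------------------
# stepwise selection
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SelectionStep:
    stage: str  # "forward" | "backward"
    candidate: str
    delta_ofv: float
    df: int
    p_value: float
    decision: str  # "added" | "removed" | "kept" | "rejected" | "skipped"


@dataclass
class SelectionTrace:
    steps: list[SelectionStep]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                dict(
                    stage=s.stage,
                    candidate=s.candidate,
                    delta_ofv=s.delta_ofv,
                    df=s.df,
                    p_value=s.p_value,
                    decision=s.decision,
                )
                for s in self.steps
            ]
        )


def _fit(model, dataset, **kw):
    from .nlme import fit_model

    return fit_model(model, dataset, compute_se=False, **kw)


def forward_addition(
    base,
    candidates: Sequence[tuple[CovariateTerm, ...]],
    dataset: StudyDataset,
    alpha: float = 0.05,
    base_fit=None,
):
    """Greedy forward covariate addition by likelihood-ratio test.

    Each round refits the current model with each remaining candidate block
    and adds the block with the largest significant drop in OFV (chi-square
    with df = number of added parameters).  Stops when no candidate reaches
    ``alpha``.  Ties in the OFV drop are broken by candidate list order.
    Returns the selected (fitted) model and the decision trace.
    """
    if base_fit is None:
        base_fit = _fit(base, dataset)
    current_fit = base_fit
    remaining = list(candidates)
    steps: list[SelectionStep] = []
    while remaining:
        trials = []
        for block in remaining:
            trial_model = replace(
                current_fit.model,
                covariate_terms=current_fit.model.covariate_terms + tuple(block),
            )
            try:
                trial_fit = _fit(trial_model, dataset)
            except Exception as exc:  # fit failure: skip this round
                logger.warning("candidate %s failed: %s", block[0].block_name, exc)
                steps.append(
                    SelectionStep("forward", block[0].block_name, np.nan, len(block), np.nan, "skipped")
                )
                trials.append(None)
                continue
            delta = current_fit.ofv - trial_fit.ofv
            df = len(block)
            p = float(stats.chi2.sf(max(delta, 0.0), df))
            trials.append((delta, df, p, block, trial_fit))
        scored = [t for t in trials if t is not None]
        significant = [t for t in scored if t[2] < alpha]
        if not significant:
            for t in scored:
                steps.append(
                    SelectionStep("forward", t[3][0].block_name, t[0], t[1], t[2], "rejected")
                )
            break
        best = max(significant, key=lambda t: t[0])
        for t in scored:
            decision = "added" if t is best else "rejected"
            steps.append(
                SelectionStep("forward", t[3][0].block_name, t[0], t[1], t[2], decision)
            )
        current_fit = best[4]
        remaining = [b for b in remaining if b is not best[3]]
    return current_fit.model, SelectionTrace(steps)


def backward_elimination(
    full,
    dataset: StudyDataset,
    alpha: float = 0.01,
    full_fit=None,
):
    """Backward elimination at the stricter retention level.

    Repeatedly removes the term block whose exclusion raises OFV least,
    whenever that rise is not significant at ``alpha`` (chi-square test);
    stops when every remaining block is significant.
    """
    if full_fit is None:
        full_fit = _fit(full, dataset)
    current_fit = full_fit
    steps: list[SelectionStep] = []
    while current_fit.model.covariate_terms:
        blocks: dict[str, tuple[CovariateTerm, ...]] = {}
        for term in current_fit.model.covariate_terms:
            blocks.setdefault(term.block_name, ())
            blocks[term.block_name] += (term,)
        trials = []
        for name, block in blocks.items():
            reduced = replace(
                current_fit.model,
                covariate_terms=tuple(
                    t for t in current_fit.model.covariate_terms if t not in block
                ),
            )
            try:
                reduced_fit = _fit(reduced, dataset)
            except Exception as exc:
                logger.warning("removal of %s failed: %s", name, exc)
                continue
            rise = reduced_fit.ofv - current_fit.ofv
            df = len(block)
            p = float(stats.chi2.sf(max(rise, 0.0), df))
            trials.append((rise, df, p, name, reduced_fit))
        removable = [t for t in trials if t[2] >= alpha]
        if not removable:
            for t in trials:
                steps.append(SelectionStep("backward", t[3], t[0], t[1], t[2], "kept"))
            break
        worst = min(removable, key=lambda t: t[0])
        for t in trials:
            decision = "removed" if t is worst else "kept"
            steps.append(SelectionStep("backward", t[3], t[0], t[1], t[2], decision))
        current_fit = worst[4]
    return current_fit.model, SelectionTrace(steps)
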