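"""Virtual-study generator for the three-study continuous-infusion design.

The generator emulates a pooled phase-2 population: 96 patients (33 NSCLC,
34 HRPC, 29 MM) receiving 4.8 mg/m2/day as a 168-h constant infusion every
21 days, with about six sparse plasma samples per patient — during the
infusion, immediately before its stop, in two windows (0.5-4 h and 6-24 h)
after the stop in cycle 1, and during the infusion of a later cycle.

Covariates are drawn from truncated marginals matched to the published
screening table (normal for age, weight, height; log-normal for the skewed
laboratory values); BSA follows from weight and height (Mosteller), and
creatinine clearance from Cockcroft-Gault, which induces the realistic
age-weight-renal-function correlation.  True individual clearances follow
the multiplicative covariate model with a log-normal random effect, and
observations get proportional noise.

A configurable fraction of patients is "contaminated": one or two of their
during-infusion samples are multiplied by a large spike factor, and their
noise uses the larger residual variance.  The spike mechanism is a synthetic
fiction — the original fluctuations had no identified cause — but it gives
the outlier-flagging rule a known ground truth to recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .covariates import CovariateTerm
from .dataset import (
    ConcentrationRecord,
    DoseEvent,
    PatientRecord,
    StudyDataset,
    cockcroft_gault_umol,
)
from .nlme import ModelSpec
from .structural import PKParameters, predict_concentrations

__all__ = [
    "CovariateSpec",
    "SyntheticConfig",
    "GroundTruth",
    "reference_final_model",
    "reference_base_model",
    "generate_study",
]


def reference_final_model() -> ModelSpec:
    """The published final covariate model (point estimates)."""
    return ModelSpec(
        cl=42.1,
        v=319.0,
        omega2=0.0385,
        sigma2_normal=0.0934,
        sigma2_outlier=1.0,  # generating value for the outlier group, CV 100%
        covariate_terms=(
            CovariateTerm("CLCR", "power", 0.425, reference=79.22),
            CovariateTerm("ALT", "power", 0.124, reference=19.0),
            CovariateTerm("HRPC", "ratio", 0.955, block="STUDY"),
            CovariateTerm("MM", "ratio", 1.24, block="STUDY"),
        ),
    )


def reference_base_model() -> ModelSpec:
    """The published base (covariate-free) model."""
    return ModelSpec(
        cl=45.6, v=317.0, omega2=0.0838, sigma2_normal=0.0934, sigma2_outlier=1.0
    )


@dataclass(frozen=True)
class CovariateSpec:
    """Truncated marginal for one covariate.

    ``dist='normal'``: mean = ``loc``, sd = ``scale``;
    ``dist='lognormal'``: median = ``loc``, log-scale sd = ``scale``.
    """

    dist: str
    loc: float
    scale: float
    lo: float
    hi: float

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.lo > self.hi:
            raise ValueError(f"infeasible truncation [{self.lo}, {self.hi}]")
        out = np.empty(n)
        filled = 0
        while filled < n:
            m = (n - filled) * 2 + 8
            if self.dist == "normal":
                draw = rng.normal(self.loc, self.scale, size=m)
            elif self.dist == "lognormal":
                draw = self.loc * np.exp(rng.normal(0.0, self.scale, size=m))
            else:
                raise ValueError(f"unknown distribution {self.dist!r}")
            ok = draw[(draw >= self.lo) & (draw <= self.hi)]
            take = min(len(ok), n - filled)
            out[filled : filled + take] = ok[:take]
            filled += take
        return out


# Marginals matched to the screening table of the pooled cohort (median /
# mean / SD / min / max).  Skewed laboratory values are log-normal.
DEFAULT_COVARIATES: dict[str, CovariateSpec] = {
    "age": CovariateSpec("normal", 63.0, 11.7, 29.0, 90.0),
    "weight": CovariateSpec("normal", 82.0, 14.3, 50.0, 114.0),
    "height": CovariateSpec("normal", 1.75, 0.08, 1.53, 1.92),
    "scr": CovariateSpec("lognormal", 88.0, 0.26, 53.0, 180.0),
    "alt": CovariateSpec("lognormal", 20.0, 0.78, 6.0, 185.0),
    "ast": CovariateSpec("lognormal", 25.0, 0.50, 12.0, 92.0),
    "albumin": CovariateSpec("normal", 37.0, 4.8, 22.0, 45.0),
    "a1agp": CovariateSpec("lognormal", 31.0, 0.42, 13.0, 91.0),
}


@dataclass
class SyntheticConfig:
    """Design and generating parameters for one virtual study.

    The defaults reproduce the pooled three-study design; ``true_model``
    defaults to the published final-model estimates.  ``seed`` is mandatory.
    """

    seed: int
    n_per_study: dict = field(
        default_factory=lambda: {"NSCLC": 33, "HRPC": 34, "MM": 29}
    )
    true_model: ModelSpec = field(default_factory=reference_final_model)
    covariates: dict = field(default_factory=lambda: dict(DEFAULT_COVARIATES))
    dose_per_m2_day: float = 4.8  # mg/m2/day
    infusion_duration: float = 168.0  # h
    cycle_length: float = 504.0  # h (21 days)
    n_cycles: int = 2
    # fixed during-infusion sampling times, h after each cycle's start
    cycle1_infusion_times: tuple = (24.0, 96.0, 168.0)
    later_cycle_infusion_times: tuple = (72.0,)
    # cycle-1 post-infusion sampling windows, h after stop (one draw each)
    post_infusion_windows: tuple = ((0.5, 4.0), (6.0, 24.0))
    contaminate: bool = True
    outlier_fraction: float = 11.0 / 96.0
    spike_range: tuple = (5.0, 50.0)
    spikes_per_patient: tuple = (1, 2)
    female_fraction_nonhrpc: float = 17.0 / 62.0  # all HRPC patients are male
    ecog_probs: tuple = (0.396, 0.552, 0.052)
    lloq: float = 0.05


@dataclass
class GroundTruth:
    """Everything the generator knows that an analyst would not."""

    model: ModelSpec
    etas: dict  # patient_id -> true eta_CL
    individual_cl: dict  # patient_id -> true CL (L/h)
    contaminated: dict  # patient_id -> list of spiked observation indices
    seed: int


def generate_study(config: SyntheticConfig) -> tuple[StudyDataset, GroundTruth]:
    """Simulate one virtual study; same seed gives a bit-identical dataset."""
    rng = np.random.default_rng(config.seed)
    model = config.true_model

    patients: list[PatientRecord] = []
    doses: list[DoseEvent] = []
    observations: list[ConcentrationRecord] = []
    etas: dict[str, float] = {}
    cls: dict[str, float] = {}
    contaminated: dict[str, list[int]] = {}

    n_total = sum(config.n_per_study.values())
    draws = {name: spec.draw(rng, n_total) for name, spec in config.covariates.items()}

    i = 0
    for study, n_study in config.n_per_study.items():
        for _ in range(n_study):
            pid = f"{study}-{i + 1:03d}"
            if study == "HRPC":
                sex = "male"
            else:
                sex = "female" if rng.random() < config.female_fraction_nonhrpc else "male"
            ecog_probs = np.asarray(config.ecog_probs)
            if study == "MM":  # melanoma patients were grade 0 or 1 only
                ecog_probs = ecog_probs[:2] / ecog_probs[:2].sum()
            ecog = int(rng.choice(len(ecog_probs), p=ecog_probs))
            weight = draws["weight"][i]
            height = draws["height"][i]
            bsa = float(np.clip(np.sqrt(height * 100.0 * weight / 3600.0), 1.48, 2.40))
            patient = PatientRecord(
                patient_id=pid,
                study=study,
                age=float(draws["age"][i]),
                sex=sex,
                body_weight=float(weight),
                bsa=bsa,
                serum_creatinine=float(draws["scr"][i]),
                alt=float(draws["alt"][i]),
                height=float(height),
                ast=float(draws["ast"][i]),
                albumin=float(draws["albumin"][i]),
                a1agp=float(draws["a1agp"][i]),
                ecog=ecog,
            )
            patients.append(patient)

            eta = float(rng.normal(0.0, np.sqrt(model.omega2)))
            cl_true = model.typical_cl(patient) * np.exp(eta)
            etas[pid] = eta
            cls[pid] = float(cl_true)

            amount = config.dose_per_m2_day * bsa * config.infusion_duration / 24.0
            for c in range(config.n_cycles):
                doses.append(
                    DoseEvent(
                        patient_id=pid,
                        start_time=c * config.cycle_length,
                        duration=config.infusion_duration,
                        amount=amount,
                    )
                )
            i += 1

    # sampling schedule and concentrations
    for patient in patients:
        pid = patient.patient_id
        params = PKParameters(cl=cls[pid], v=model.v)
        pat_doses = [d for d in doses if d.patient_id == pid]
        times: list[tuple[float, int, bool]] = []  # (time, cycle, during)
        for t in config.cycle1_infusion_times:
            times.append((t, 1, True))
        for lo, hi in config.post_infusion_windows:
            t = config.infusion_duration + rng.uniform(lo, hi)
            times.append((t, 1, False))
        for c in range(2, config.n_cycles + 1):
            start = (c - 1) * config.cycle_length
            for t in config.later_cycle_infusion_times:
                times.append((start + t, c, True))
        tvals = [t for t, _, _ in times]
        pred = predict_concentrations(params, pat_doses, tvals)
        group_sigma2 = model.sigma2_normal  # contaminated patients set below
        for (t, cyc, during), f in zip(times, pred):
            eps = rng.normal(0.0, 1.0)
            observations.append(
                ConcentrationRecord(
                    patient_id=pid,
                    time=t,
                    concentration=float(f),  # noise applied after grouping
                    cycle=cyc,
                    during_infusion=during,
                    blq=False,
                )
            )
            observations[-1]._eps = eps  # stash the standard-normal draw

    # contamination assignment, then apply noise with the patient's group sigma
    if config.contaminate and config.outlier_fraction > 0:
        n_contam = int(round(config.outlier_fraction * len(patients)))
        chosen = rng.choice(len(patients), size=n_contam, replace=False)
        contam_ids = {patients[j].patient_id for j in chosen}
    else:
        contam_ids = set()

    for idx, o in enumerate(observations):
        sigma2 = (
            model.sigma2_outlier if o.patient_id in contam_ids else model.sigma2_normal
        )
        eps = o._eps * np.sqrt(sigma2)
        del o._eps
        o.concentration = max(o.concentration * (1.0 + eps), 0.0)

    lo_m, hi_m = config.spike_range
    for pid in sorted(contam_ids):
        idx_during = [
            j
            for j, o in enumerate(observations)
            if o.patient_id == pid and o.during_infusion
        ]
        n_spikes = int(rng.integers(config.spikes_per_patient[0],
                                    config.spikes_per_patient[1] + 1))
        n_spikes = min(n_spikes, len(idx_during))
        picked = sorted(rng.choice(idx_during, size=n_spikes, replace=False).tolist())
        for j in picked:
            observations[j].concentration *= float(rng.uniform(lo_m, hi_m))
        contaminated[pid] = picked

    for o in observations:
        o.blq = o.concentration < config.lloq

    dataset = StudyDataset(patients, doses, observations, lloq=config.lloq)
    truth = GroundTruth(
        model=model,
        etas=etas,
        individual_cl=cls,
        contaminated=contaminated,
        seed=config.seed,
    )
    return dataset, truth
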