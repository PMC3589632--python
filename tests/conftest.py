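import numpy as np
import pytest

from civipop.dataset import (
    ConcentrationRecord,
    DoseEvent,
    PatientRecord,
    StudyDataset,
    flag_outliers_and_assign_groups,
)
from civipop.simulate import SyntheticConfig, generate_study, reference_final_model
from civipop.structural import PKParameters, predict_concentrations


def make_patient(pid="P1", study="NSCLC", **overrides) -> PatientRecord:
    fields = dict(
        patient_id=pid,
        study=study,
        age=64.0,
        sex="male",
        body_weight=81.0,
        bsa=1.97,
        serum_creatinine=88.0,
        alt=20.0,
        height=1.76,
        ecog=0,
    )
    fields.update(overrides)
    return PatientRecord(**fields)


def make_simple_dataset(
    cl=42.1,
    v=319.0,
    n_patients=1,
    obs_times=(24.0, 96.0, 168.0, 170.0, 180.0),
    duration=168.0,
    amount=66.19,
    sigma_cv=0.0,
    omega2=0.0,
    seed=0,
    patient_kwargs=(),
):
    """Small deterministic dataset with concentrations from the closed form."""
    rng = np.random.default_rng(seed)
    patients, doses, observations = [], [], []
    kwargs_list = list(patient_kwargs) + [{}] * (n_patients - len(patient_kwargs))
    for i in range(n_patients):
        pid = f"P{i + 1}"
        patients.append(make_patient(pid, **kwargs_list[i]))
        doses.append(DoseEvent(pid, start_time=0.0, duration=duration, amount=amount))
        eta = rng.normal(0.0, np.sqrt(omega2)) if omega2 > 0 else 0.0
        params = PKParameters(cl=cl * np.exp(eta), v=v)
        conc = predict_concentrations(params, doses[-1:], obs_times)
        for t, f in zip(obs_times, conc):
            y = f * (1.0 + rng.normal(0.0, sigma_cv)) if sigma_cv > 0 else f
            observations.append(
                ConcentrationRecord(
                    patient_id=pid,
                    time=float(t),
                    concentration=float(max(y, 0.0)),
                    during_infusion=bool(t <= duration),
                )
            )
    return StudyDataset(patients, doses, observations)


@pytest.fixture(scope="session")
def final_truth():
    return reference_final_model()


@pytest.fixture(scope="session")
def clean_study():
    """One default 96-patient virtual study without contamination, flagged."""
    dataset, truth = generate_study(SyntheticConfig(seed=1, contaminate=False))
    _, flagged = flag_outliers_and_assign_groups(dataset)
    return flagged, truth


@pytest.fixture(scope="session")
def clean_study_base_fit(clean_study, final_truth):
    from civipop.nlme import fit_model
    from civipop.nlme import ModelSpec

    dataset, _ = clean_study
    return fit_model(ModelSpec(), dataset, compute_se=False)
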