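"""Dataset I/O, Cockcroft-Gault derivation, BLQ handling and the outlier rule."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from civipop.dataset import (
    ConcentrationRecord,
    DatasetError,
    DoseEvent,
    InsufficientDataError,
    OutlierThresholds,
    SchemaError,
    StudyDataset,
    cockcroft_gault,
    cockcroft_gault_umol,
    flag_outliers_and_assign_groups,
    load_dataset,
    write_dataset,
)
from conftest import make_patient, make_simple_dataset


# ---------------------------------------------------------------------------
# Cockcroft-Gault
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "age, wt, scr, sex, expected",
    [
        (40.0, 72.0, 1.0, "male", 100.0),
        (40.0, 72.0, 1.0, "female", 85.0),
        (63.0, 82.0, 1.0, "male", (140 - 63) * 82 / 72.0),
    ],
)
def test_cockcroft_gault_reference_values(age, wt, scr, sex, expected):
    assert cockcroft_gault(age, wt, scr, sex) == pytest.approx(expected)


def test_cockcroft_gault_umol_conversion():
    # 88.4 umol/L is exactly 1.0 mg/dL
    assert cockcroft_gault_umol(63.0, 82.0, 88.4, "male") == pytest.approx(
        cockcroft_gault(63.0, 82.0, 1.0, "male")
    )
    assert cockcroft_gault_umol(63.0, 82.0, 88.4, "male") == pytest.approx(87.69, abs=0.01)


def test_cockcroft_gault_rejects_nonpositive_creatinine():
    with pytest.raises(ValueError):
        cockcroft_gault(40.0, 72.0, 0.0, "male")


@settings(deadline=None, max_examples=50)
@given(
    age=st.floats(20, 90),
    wt=st.floats(40, 120),
    scr=st.floats(0.3, 3.0),
    bump=st.floats(0.5, 10.0),
)
def test_cockcroft_gault_monotonicity(age, wt, scr, bump):
    base = cockcroft_gault(age, wt, scr, "male")
    assert cockcroft_gault(min(age + bump, 139.0), wt, scr, "male") < base
    assert cockcroft_gault(age, wt + bump, scr, "male") > base
    assert cockcroft_gault(age, wt, scr + bump, "male") < base


# ---------------------------------------------------------------------------
# loading / writing
# ---------------------------------------------------------------------------


def _write_csv(path, drop_amt=False):
    rows = []
    for pid in ("A", "B"):
        rows.append(dict(ID=pid, TIME=0.0, EVID=1, AMT=66.0, RATE=66.0 / 168.0,
                         DV=np.nan, MDV=1, CYCLE=1))
        for t, dv in ((24.0, 9.0), (96.0, 10.0), (170.0, 0.04 if pid == "B" else 8.0)):
            rows.append(dict(ID=pid, TIME=t, EVID=0, AMT=np.nan, RATE=np.nan,
                             DV=dv, MDV=0, CYCLE=1))
    frame = pd.DataFrame(rows)
    for cov, value in dict(AGE=60.0, SEX=0, WT=80.0, BSA=1.9, SCR=88.0, ALT=20.0,
                           STUDY="NSCLC").items():
        frame[cov] = value
    if drop_amt:
        frame = frame.drop(columns=["AMT"])
    frame.to_csv(path, index=False)
    return path


def test_load_preserves_counts(tmp_path):
    ds = load_dataset(_write_csv(tmp_path / "d.csv"))
    assert len(ds.patients) == 2
    assert len(ds.doses) == 2
    assert len(ds.observations) == 6


def test_load_marks_blq_and_excludes(tmp_path):
    ds = load_dataset(_write_csv(tmp_path / "d.csv"))
    blq = [o for o in ds.observations if o.blq]
    assert len(blq) == 1
    assert blq[0].patient_id == "B" and blq[0].concentration == pytest.approx(0.04)
    assert len(ds.included_observations()) == 5


def test_load_derives_clcr_and_infusion_windows(tmp_path):
    ds = load_dataset(_write_csv(tmp_path / "d.csv"))
    p = ds.patient("A")
    assert p.clcr == pytest.approx(cockcroft_gault_umol(60.0, 80.0, 88.0, "male"))
    during = {o.time: o.during_infusion for o in ds.observations if o.patient_id == "A"}
    assert during[24.0] and during[96.0] and not during[170.0]


def test_missing_amount_is_schema_error(tmp_path):
    with pytest.raises(SchemaError):
        load_dataset(_write_csv(tmp_path / "d.csv", drop_amt=True))


def test_missing_required_column_is_schema_error(tmp_path):
    path = _write_csv(tmp_path / "d.csv")
    frame = pd.read_csv(path).drop(columns=["SCR"])
    frame.to_csv(path, index=False)
    with pytest.raises(SchemaError):
        load_dataset(path)


def test_negative_time_rejected(tmp_path):
    path = _write_csv(tmp_path / "d.csv")
    frame = pd.read_csv(path)
    frame.loc[1, "TIME"] = -1.0
    frame.to_csv(path, index=False)
    with pytest.raises(DatasetError):
        load_dataset(path)


def test_roundtrip_preserves_analysed_fields(tmp_path):
    ds = make_simple_dataset(n_patients=3, sigma_cv=0.1, seed=4)
    path = tmp_path / "rt.csv"
    write_dataset(ds, path)
    back = load_dataset(path)
    assert sorted(back.patient_ids) == sorted(ds.patient_ids)
    for pid in ds.patient_ids:
        orig = sorted((o.time, o.concentration) for o in ds.observations if o.patient_id == pid)
        re = sorted((o.time, o.concentration) for o in back.observations if o.patient_id == pid)
        assert re == orig  # float round-trip through CSV is exact
        assert back.patient(pid).clcr == pytest.approx(ds.patient(pid).clcr)


# ---------------------------------------------------------------------------
# outlier rule
# ---------------------------------------------------------------------------


def _dataset_with_values(values, pid_of=None):
    patients, doses, observations = [], [], []
    pids = pid_of or [f"P{i + 1}" for i in range(len(values))]
    for pid in dict.fromkeys(pids):
        patients.append(make_patient(pid))
        doses.append(DoseEvent(pid, 0.0, 168.0, 66.0))
    for i, (v, pid) in enumerate(zip(values, pids)):
        observations.append(
            ConcentrationRecord(pid, time=float(24 + i), concentration=float(v))
        )
    return StudyDataset(patients, doses, observations)


def test_quartile_fences_linear_interpolation():
    values = [1, 2, 3, 4, 5, 6, 7, 8, 100]
    thresholds, flagged = flag_outliers_and_assign_groups(_dataset_with_values(values))
    assert thresholds.q1 == pytest.approx(3.0)
    assert thresholds.q3 == pytest.approx(7.0)
    assert thresholds.iqr == pytest.approx(4.0)
    assert thresholds.high_limit == pytest.approx(19.0)
    hits = [o for o in flagged.observations if o.high_outlier]
    assert [o.concentration for o in hits] == [100.0]
    assert flagged.patient(hits[0].patient_id).error_group == "outlier_patient"
    others = [p for p in flagged.patients if p.patient_id != hits[0].patient_id]
    assert all(p.error_group == "normal" for p in others)


def test_degenerate_spread_yields_no_flags():
    thresholds, flagged = flag_outliers_and_assign_groups(
        _dataset_with_values([5.0] * 8)
    )
    assert thresholds.iqr == 0.0
    assert thresholds.low_limit == thresholds.high_limit == 5.0
    assert not any(o.high_outlier or o.low_outlier for o in flagged.observations)


def test_too_few_observations_raises():
    with pytest.raises(InsufficientDataError):
        flag_outliers_and_assign_groups(_dataset_with_values([1.0, 2.0, 3.0]))


def test_flags_invariant_under_reordering():
    values = list(np.random.default_rng(7).lognormal(2.3, 0.4, size=40)) + [500.0]
    ds = _dataset_with_values(values)
    t1, f1 = flag_outliers_and_assign_groups(ds)
    shuffled = StudyDataset(
        list(reversed(ds.patients)),
        list(reversed(ds.doses)),
        list(np.random.default_rng(0).permutation(np.array(ds.observations, dtype=object))),
    )
    t2, f2 = flag_outliers_and_assign_groups(shuffled)
    assert (t1.q1, t1.q3) == (t2.q1, t2.q3)
    flags1 = {(o.patient_id, o.time): o.high_outlier for o in f1.observations}
    flags2 = {(o.patient_id, o.time): o.high_outlier for o in f2.observations}
    assert flags1 == flags2


def test_only_during_infusion_rows_enter_the_fences():
    """Adding post-infusion rows must not move the thresholds or the flags."""
    values = [1, 2, 3, 4, 5, 6, 7, 8, 100]
    ds = _dataset_with_values(values)
    t_ref, f_ref = flag_outliers_and_assign_groups(ds)
    augmented = ds.copy()
    for k in range(5):
        augmented.observations.append(
            ConcentrationRecord("P1", time=200.0 + k, concentration=1000.0,
                                during_infusion=False)
        )
    t_aug, f_aug = flag_outliers_and_assign_groups(augmented)
    assert (t_aug.q1, t_aug.q3) == (t_ref.q1, t_ref.q3)
    during_flags = [o.high_outlier for o in f_aug.observations if o.during_infusion]
    assert during_flags == [o.high_outlier for o in f_ref.observations]
    assert not any(o.high_outlier for o in f_aug.observations if not o.during_infusion)


def test_flagged_observations_are_retained():
    values = [1, 2, 3, 4, 5, 6, 7, 8, 100]
    _, flagged = flag_outliers_and_assign_groups(_dataset_with_values(values))
    assert len(flagged.observations) == len(values)
    assert len(flagged.included_observations()) == len(values)


def test_thresholds_invariants():
    t = OutlierThresholds.from_values([1.0, 2.0, 3.0, 4.0])
    assert t.q1 <= t.q3
    assert t.iqr == pytest.approx(t.q3 - t.q1)
    assert t.low_limit <= t.q1 <= t.q3 <= t.high_limit
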