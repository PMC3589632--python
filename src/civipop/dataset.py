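"""Study data model, NONMEM-dialect CSV I/O, renal-function derivation and
the outlier-driven residual-error-group assignment.

A study is a rectangular table with one row per dose event or plasma
concentration observation, plus screening covariates carried on every row of
a patient.  Concentrations below the lower limit of quantitation (LLOQ,
0.05 ng/mL by default) are flagged ``blq`` and excluded from the analysis
set; they are never imputed.

Unusually high concentrations during the infusion are not removed.  Instead,
observations outside ``[Q1 - 3*IQR, Q3 + 3*IQR]`` of the pooled
during-infusion concentrations are flagged, and every patient owning at
least one flagged observation is moved to a second, larger proportional
residual-error group.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LLOQ_DEFAULT",
    "UMOL_PER_MGDL",
    "STUDIES",
    "DatasetError",
    "SchemaError",
    "InsufficientDataError",
    "PatientRecord",
    "DoseEvent",
    "ConcentrationRecord",
    "StudyDataset",
    "OutlierThresholds",
    "cockcroft_gault",
    "cockcroft_gault_umol",
    "flag_outliers_and_assign_groups",
    "load_dataset",
    "write_dataset",
]

LLOQ_DEFAULT = 0.05
"""Lower limit of quantitation of the plasma assay, ng/mL."""

UMOL_PER_MGDL = 88.4
"""Serum creatinine unit conversion: 1 mg/dL = 88.4 umol/L."""

STUDIES = ("NSCLC", "HRPC", "MM")

NORMAL = "normal"
OUTLIER_PATIENT = "outlier_patient"


class DatasetError(ValueError):
    """Invalid dataset content."""


class SchemaError(DatasetError):
    """A required column could not be resolved."""


class InsufficientDataError(DatasetError):
    """Too few eligible observations for the requested computation."""


# ---------------------------------------------------------------------------
# domain records
# ---------------------------------------------------------------------------


@dataclass
class PatientRecord:
    """Screening covariates for one patient.

    Continuous covariates keep the units of the source table: age in years,
    body weight in kg, BSA in m2, height in m, serum creatinine in umol/L,
    ALT/AST in U/L, albumin in g/L, alpha1-acid glycoprotein in umol/L.
    ``clcr`` (mL/min) is derived at load time via Cockcroft-Gault.
    """

    patient_id: str
    study: str
    age: float
    sex: str  # "male" | "female"
    body_weight: float
    bsa: float
    serum_creatinine: float  # umol/L
    alt: float
    clcr: float = float("nan")
    height: float | None = None
    ast: float | None = None
    albumin: float | None = None
    a1agp: float | None = None
    ecog: int | None = None
    error_group: str = NORMAL

    def __post_init__(self) -> None:
        if self.study not in STUDIES:
            raise DatasetError(
                f"patient {self.patient_id}: study {self.study!r} not one of {STUDIES}"
            )
        if self.sex not in ("male", "female"):
            raise DatasetError(f"patient {self.patient_id}: sex {self.sex!r}")
        for name in ("age", "body_weight", "bsa", "serum_creatinine", "alt"):
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0:
                raise DatasetError(
                    f"patient {self.patient_id}: {name} must be positive, got {value}"
                )
        if np.isnan(self.clcr):
            self.clcr = cockcroft_gault_umol(
                self.age, self.body_weight, self.serum_creatinine, self.sex
            )

    def covariate(self, name: str) -> float:
        """Look up a covariate by its canonical short name (e.g. ``CLCR``)."""
        value = _COVARIATE_GETTERS[name.upper()](self)
        if value is None:
            raise DatasetError(f"patient {self.patient_id}: covariate {name} missing")
        return value


_COVARIATE_GETTERS = {
    "AGE": lambda p: p.age,
    "WT": lambda p: p.body_weight,
    "BSA": lambda p: p.bsa,
    "HT": lambda p: p.height,
    "SCR": lambda p: p.serum_creatinine,
    "ALT": lambda p: p.alt,
    "AST": lambda p: p.ast,
    "ALB": lambda p: p.albumin,
    "AAG": lambda p: p.a1agp,
    "CLCR": lambda p: p.clcr,
    "ECOG": lambda p: float(p.ecog) if p.ecog is not None else None,
    "ECOG1": lambda p: (1.0 if p.ecog == 1 else 0.0) if p.ecog is not None else None,
    "ECOG2": lambda p: (1.0 if p.ecog >= 2 else 0.0) if p.ecog is not None else None,
    "HRPC": lambda p: 1.0 if p.study == "HRPC" else 0.0,
    "MM": lambda p: 1.0 if p.study == "MM" else 0.0,
    "SEXF": lambda p: 1.0 if p.sex == "female" else 0.0,
}


@dataclass(frozen=True)
class DoseEvent:
    """One constant-rate infusion: ``rate = amount / duration``.

    Times are hours since the patient's first infusion start; amounts are mg
    of the cationic moiety.
    """

    patient_id: str
    start_time: float
    duration: float
    amount: float

    def __post_init__(self) -> None:
        if self.amount <= 0:
            raise DatasetError(f"patient {self.patient_id}: dose amount {self.amount}")
        if self.duration <= 0:
            raise DatasetError(f"patient {self.patient_id}: duration {self.duration}")
        if self.start_time < 0:
            raise DatasetError(f"patient {self.patient_id}: start {self.start_time}")

    @property
    def rate(self) -> float:
        """Infusion rate, mg/h."""
        return self.amount / self.duration


@dataclass
class ConcentrationRecord:
    """One plasma concentration (ng/mL) at ``time`` hours post first dose."""

    patient_id: str
    time: float
    concentration: float
    cycle: int = 1
    during_infusion: bool = True
    blq: bool = False
    high_outlier: bool = False
    low_outlier: bool = False

    def __post_init__(self) -> None:
        if not np.isfinite(self.time) or self.time < 0:
            raise DatasetError(f"patient {self.patient_id}: time {self.time}")
        if self.cycle < 1:
            raise DatasetError(f"patient {self.patient_id}: cycle {self.cycle}")


@dataclass
class StudyDataset:
    """Dose events, observations and covariates for one analysis population."""

    patients: list[PatientRecord]
    doses: list[DoseEvent]
    observations: list[ConcentrationRecord]
    lloq: float = LLOQ_DEFAULT

    def __post_init__(self) -> None:
        ids = {p.patient_id for p in self.patients}
        if len(ids) != len(self.patients):
            raise DatasetError("duplicate patient ids")
        for d in self.doses:
            if d.patient_id not in ids:
                raise DatasetError(f"dose references unknown patient {d.patient_id}")
        for o in self.observations:
            if o.patient_id not in ids:
                raise DatasetError(
                    f"observation references unknown patient {o.patient_id}"
                )

    # -- accessors ---------------------------------------------------------

    @property
    def patient_ids(self) -> list[str]:
        return [p.patient_id for p in self.patients]

    def patient(self, patient_id: str) -> PatientRecord:
        for p in self.patients:
            if p.patient_id == patient_id:
                return p
        raise KeyError(patient_id)

    def doses_of(self, patient_id: str) -> list[DoseEvent]:
        return [d for d in self.doses if d.patient_id == patient_id]

    def included_observations(self) -> list[ConcentrationRecord]:
        """The analysis set: observations that are not BLQ."""
        return [o for o in self.observations if not o.blq]

    def copy(self) -> "StudyDataset":
        return StudyDataset(
            patients=[dataclasses.replace(p) for p in self.patients],
            doses=list(self.doses),
            observations=[dataclasses.replace(o) for o in self.observations],
            lloq=self.lloq,
        )

    def subset(self, patient_ids: Sequence[str], relabel: bool = False) -> "StudyDataset":
        """Dataset restricted to ``patient_ids`` (with repetition allowed).

        With ``relabel`` each selected patient gets a fresh unique id, which
        makes repeated selections (bootstrap resamples) valid datasets.
        """
        patients: list[PatientRecord] = []
        doses: list[DoseEvent] = []
        observations: list[ConcentrationRecord] = []
        for k, pid in enumerate(patient_ids):
            src = self.patient(pid)
            new_id = f"{pid}#{k}" if relabel else pid
            patients.append(dataclasses.replace(src, patient_id=new_id))
            doses.extend(
                dataclasses.replace(d, patient_id=new_id) for d in self.doses_of(pid)
            )
            observations.extend(
                dataclasses.replace(o, patient_id=new_id)
                for o in self.observations
                if o.patient_id == pid
            )
        return StudyDataset(patients, doses, observations, lloq=self.lloq)

    # -- tabular form ------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """NONMEM-dialect table: dose rows (EVID=1) then observation rows."""
        rows = []
        covs = {p.patient_id: p for p in self.patients}
        for d in self.doses:
            p = covs[d.patient_id]
            rows.append(
                dict(
                    ID=d.patient_id,
                    TIME=d.start_time,
                    EVID=1,
                    AMT=d.amount,
                    RATE=d.rate,
                    DV=np.nan,
                    MDV=1,
                    CYCLE=np.nan,
                    DUR=d.duration,
                    BLQFLAG=0,
                    OUTLIER=0,
                    **_covariate_columns(p),
                )
            )
        for o in self.observations:
            p = covs[o.patient_id]
            rows.append(
                dict(
                    ID=o.patient_id,
                    TIME=o.time,
                    EVID=0,
                    AMT=np.nan,
                    RATE=np.nan,
                    DV=o.concentration,
                    MDV=1 if o.blq else 0,
                    CYCLE=o.cycle,
                    DUR=np.nan,
                    BLQFLAG=int(o.blq),
                    OUTLIER=int(o.high_outlier) - int(o.low_outlier),
                    **_covariate_columns(p),
                )
            )
        frame = pd.DataFrame(rows)
        return frame.sort_values(["ID", "TIME", "EVID"], kind="stable", ascending=[True, True, False]).reset_index(drop=True)


def _covariate_columns(p: PatientRecord) -> dict:
    return dict(
        STUDY=p.study,
        AGE=p.age,
        SEX=0 if p.sex == "male" else 1,
        WT=p.body_weight,
        HT=np.nan if p.height is None else p.height,
        BSA=p.bsa,
        SCR=p.serum_creatinine,
        ALT=p.alt,
        AST=np.nan if p.ast is None else p.ast,
        ALB=np.nan if p.albumin is None else p.albumin,
        AAG=np.nan if p.a1agp is None else p.a1agp,
        ECOG=np.nan if p.ecog is None else p.ecog,
        CLCR=p.clcr,
        ERRGRP=0 if p.error_group == NORMAL else 1,
    )


# ---------------------------------------------------------------------------
# Cockcroft-Gault
# ---------------------------------------------------------------------------


def cockcroft_gault(
    age: float, body_weight: float, serum_creatinine: float, sex: str
) -> float:
    """Creatinine clearance (mL/min) from the Cockcroft-Gault formula.

    ``serum_creatinine`` is in mg/dL.  The estimate is
    ``(140 - age) * weight / (72 * Scr)``, times 0.85 for females.
    """
    if serum_creatinine <= 0:
        raise ValueError("serum creatinine must be positive")
    if age <= 0 or body_weight <= 0:
        raise ValueError("age and body weight must be positive")
    if sex not in ("male", "female"):
        raise ValueError(f"sex must be 'male' or 'female', got {sex!r}")
    clcr = (140.0 - age) * body_weight / (72.0 * serum_creatinine)
    if sex == "female":
        clcr *= 0.85
    return clcr


def cockcroft_gault_umol(
    age: float, body_weight: float, serum_creatinine_umol: float, sex: str
) -> float:
    """Cockcroft-Gault with serum creatinine in umol/L (divides by 88.4)."""
    return cockcroft_gault(
        age, body_weight, serum_creatinine_umol / UMOL_PER_MGDL, sex
    )


# ---------------------------------------------------------------------------
# outlier rule
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OutlierThresholds:
    """Fence limits derived from pooled during-infusion concentrations."""

    q1: float
    q3: float

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1

    @property
    def low_limit(self) -> float:
        return self.q1 - 3.0 * self.iqr

    @property
    def high_limit(self) -> float:
        return self.q3 + 3.0 * self.iqr

    @classmethod
    def from_values(
        cls, values: Iterable[float], method: str = "linear"
    ) -> "OutlierThresholds":
        arr = np.asarray(list(values), dtype=float)
        if arr.size < 4:
            raise InsufficientDataError(
                f"need >=4 during-infusion observations for quartiles, got {arr.size}"
            )
        q1, q3 = np.quantile(arr, [0.25, 0.75], method=method)
        return cls(q1=float(q1), q3=float(q3))


def flag_outliers_and_assign_groups(
    dataset: StudyDataset,
    quantile_method: str = "linear",
    pooled: bool = True,
    group_level: str = "patient",
) -> tuple[OutlierThresholds, StudyDataset]:
    """Flag extreme during-infusion concentrations and split the error groups.

    Quartiles are computed over all non-BLQ during-infusion concentrations,
    pooled across patients and cycles (``pooled=False`` computes per-patient
    fences instead).  Observations strictly above ``Q3 + 3*IQR`` or strictly
    below ``Q1 - 3*IQR`` are flagged but retained.  With the default
    patient-level grouping, every patient owning a flagged observation is
    assigned to the ``outlier_patient`` residual-error group.

    Returns the pooled thresholds and a flagged copy of the dataset.
    """
    if group_level not in ("patient", "observation"):
        raise ValueError(f"group_level {group_level!r}")
    out = dataset.copy()
    eligible = [o for o in out.observations if o.during_infusion and not o.blq]
    thresholds = OutlierThresholds.from_values(
        [o.concentration for o in eligible], method=quantile_method
    )

    def limits_for(pid: str) -> OutlierThresholds:
        if pooled:
            return thresholds
        return OutlierThresholds.from_values(
            [o.concentration for o in eligible if o.patient_id == pid],
            method=quantile_method,
        )

    flagged_patients: set[str] = set()
    for o in out.observations:
        o.high_outlier = False
        o.low_outlier = False
        if not o.during_infusion or o.blq:
            continue
        lim = limits_for(o.patient_id)
        if o.concentration > lim.high_limit:
            o.high_outlier = True
        elif o.concentration < lim.low_limit:
            o.low_outlier = True
        if o.high_outlier or o.low_outlier:
            flagged_patients.add(o.patient_id)
    if group_level == "patient":
        for p in out.patients:
            p.error_group = OUTLIER_PATIENT if p.patient_id in flagged_patients else NORMAL
    else:
        # observation-level grouping leaves patient records untouched; the
        # estimation layer reads the per-observation flags directly
        for p in out.patients:
            p.error_group = NORMAL
    return thresholds, out


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_REQUIRED_COLUMNS = ("ID", "TIME", "EVID", "AMT", "DV", "AGE", "SEX", "WT", "BSA", "SCR", "ALT", "STUDY")

_SEX_CODES = {0: "male", 1: "female", "0": "male", "1": "female",
              "M": "male", "F": "female", "male": "male", "female": "female"}


def load_dataset(
    path, schema: Mapping[str, str] | None = None, lloq: float = LLOQ_DEFAULT,
    scr_unit: str = "umol/L",
) -> StudyDataset:
    """Read a NONMEM-dialect CSV into a validated :class:`StudyDataset`.

    ``schema`` maps canonical column names (ID, TIME, AMT, RATE, EVID, DV,
    MDV, CYCLE, AGE, SEX, WT, BSA, SCR, ALT, STUDY, ...) to the file's actual
    header names.  Observation rows with a missing DV or DV below ``lloq``
    are kept but marked BLQ, which excludes them from the analysis set.
    Serum creatinine is stored in umol/L; ``scr_unit='mg/dL'`` converts.
    """
    frame = pd.read_csv(path, float_precision="round_trip")
    schema = dict(schema or {})

    def col(name: str, required: bool = False):
        actual = schema.get(name, name)
        if actual in frame.columns:
            return frame[actual]
        if required:
            raise SchemaError(f"required column {name!r} (as {actual!r}) not found")
        return None

    for name in _REQUIRED_COLUMNS:
        col(name, required=True)

    scale = UMOL_PER_MGDL if scr_unit == "mg/dL" else 1.0

    evid = col("EVID").astype(int)
    patients: dict[str, PatientRecord] = {}
    doses: list[DoseEvent] = []
    observations: list[ConcentrationRecord] = []

    opt = {name: col(name) for name in ("RATE", "MDV", "CYCLE", "DUR", "HT", "AST", "ALB", "AAG", "ECOG")}

    for idx, row in frame.iterrows():
        pid = str(row[schema.get("ID", "ID")])
        time = float(row[schema.get("TIME", "TIME")])
        if not np.isfinite(time) or time < 0:
            raise DatasetError(f"row {idx}: invalid TIME {time}")
        if pid not in patients:
            def opt_val(name):
                series = opt[name]
                if series is None:
                    return None
                v = series.loc[idx]
                return None if pd.isna(v) else float(v)

            ecog = opt_val("ECOG")
            patients[pid] = PatientRecord(
                patient_id=pid,
                study=str(row[schema.get("STUDY", "STUDY")]),
                age=float(row[schema.get("AGE", "AGE")]),
                sex=_SEX_CODES[row[schema.get("SEX", "SEX")]],
                body_weight=float(row[schema.get("WT", "WT")]),
                bsa=float(row[schema.get("BSA", "BSA")]),
                serum_creatinine=float(row[schema.get("SCR", "SCR")]) * scale,
                alt=float(row[schema.get("ALT", "ALT")]),
                height=opt_val("HT"),
                ast=opt_val("AST"),
                albumin=opt_val("ALB"),
                a1agp=opt_val("AAG"),
                ecog=None if ecog is None else int(ecog),
            )
        if evid.loc[idx] == 1:
            amt = row[schema.get("AMT", "AMT")]
            if pd.isna(amt):
                raise SchemaError(f"row {idx}: dose row lacks AMT")
            amt = float(amt)
            if amt <= 0:
                raise DatasetError(f"row {idx}: non-positive dose amount {amt}")
            dur = opt["DUR"].loc[idx] if opt["DUR"] is not None else np.nan
            rate = opt["RATE"].loc[idx] if opt["RATE"] is not None else np.nan
            if not pd.isna(dur):
                duration = float(dur)
            elif not pd.isna(rate):
                duration = amt / float(rate)
            else:
                raise SchemaError(f"row {idx}: dose row needs RATE or DUR")
            doses.append(DoseEvent(pid, start_time=time, duration=duration, amount=amt))
        else:
            dv = row[schema.get("DV", "DV")]
            mdv = opt["MDV"].loc[idx] if opt["MDV"] is not None else np.nan
            missing = pd.isna(dv) or (not pd.isna(mdv) and int(mdv) == 1)
            conc = 0.0 if pd.isna(dv) else float(dv)
            cyc = opt["CYCLE"].loc[idx] if opt["CYCLE"] is not None else np.nan
            observations.append(
                ConcentrationRecord(
                    patient_id=pid,
                    time=time,
                    concentration=conc,
                    cycle=int(cyc) if not pd.isna(cyc) else 1,
                    blq=bool(missing or conc < lloq),
                )
            )

    # during-infusion status from the dose windows
    windows: dict[str, list[tuple[float, float]]] = {}
    for d in doses:
        windows.setdefault(d.patient_id, []).append((d.start_time, d.start_time + d.duration))
    for o in observations:
        o.during_infusion = any(
            lo <= o.time <= hi for lo, hi in windows.get(o.patient_id, [])
        )
    return StudyDataset(list(patients.values()), doses, observations, lloq=lloq)


def write_dataset(dataset: StudyDataset, path) -> None:
    """Write the NONMEM-dialect CSV (including derived columns).

    Floats are written with 17 significant digits so numeric fields
    round-trip exactly through :func:`load_dataset`.
    """
    dataset.to_frame().to_csv(path, index=False, float_format="%.17g")
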