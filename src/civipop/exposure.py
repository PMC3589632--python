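"""Steady-state exposure (Css) and covariate-effect summaries.

During a constant-rate infusion the steady-state plasma concentration is
rate / clearance; expressed per dosing cycle,

    Css (ng/mL) = Dose (mg) / [CL (L/h) * infusion duration (h)] * 1000.

Because Css is inversely proportional to CL, a covariate's multiplicative
effect on CL maps to the reciprocal effect on exposure — the basis of the
renal-impairment projection.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .dataset import StudyDataset

__all__ = ["ExposureResult", "compute_css", "renal_effect_summary", "exposure_table"]


@dataclass(frozen=True)
class ExposureResult:
    patient_id: str
    dose: float  # mg per cycle
    cl: float  # L/h, post-hoc individual
    css: float  # ng/mL
    infusion_duration: float  # h


def compute_css(dose: float, cl: float, duration: float) -> float:
    """Steady-state concentration (ng/mL) for one infusion cycle."""
    if dose <= 0 or cl <= 0 or duration <= 0:
        raise ValueError("dose, CL and duration must all be positive")
    return dose / (cl * duration) * 1000.0


def exposure_table(dataset: StudyDataset, etas, ae_grades=None) -> pd.DataFrame:
    """Per-patient Css from the first-cycle dose and the post-hoc CL.

    ``ae_grades`` may map patient ids to adverse-event grades; the grades
    are carried through as a grouping column for external exposure-safety
    tabulation (no statistics are computed here).
    """
    cl_by_id = {e.patient_id: e.individual_cl for e in etas}
    rows = []
    for p in dataset.patients:
        doses = dataset.doses_of(p.patient_id)
        if not doses:
            continue
        first = min(doses, key=lambda d: d.start_time)
        cl = cl_by_id[p.patient_id]
        rows.append(
            dict(
                patient_id=p.patient_id,
                dose=first.amount,
                cl=cl,
                css=compute_css(first.amount, cl, first.duration),
                infusion_duration=first.duration,
            )
        )
    out = pd.DataFrame(rows)
    if ae_grades is not None:
        out["ae_grade"] = out["patient_id"].map(dict(ae_grades))
    return out


def renal_effect_summary(
    power: float,
    clcr_values: Sequence[float],
    reference: float = 79.22,
) -> pd.DataFrame:
    """Percent change in CL and Css across a grid of creatinine clearances.

    With a power covariate model the CL ratio at a given CLCR is
    ``(CLCR/reference)^power`` and the Css ratio is its reciprocal.  Percent
    changes are relative to a patient at the reference CLCR.
    """
    if reference <= 0:
        raise ValueError("reference CLCR must be positive")
    clcr = np.asarray(clcr_values, dtype=float)
    if np.any(clcr <= 0):
        raise ValueError("CLCR values must be positive")
    cl_ratio = (clcr / reference) ** power
    css_ratio = 1.0 / cl_ratio
    return pd.DataFrame(
        dict(
            clcr=clcr,
            cl_ratio=cl_ratio,
            cl_percent_change=100.0 * (cl_ratio - 1.0),
            css_ratio=css_ratio,
            css_percent_change=100.0 * (css_ratio - 1.0),
        )
    )
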