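"""Closed-form one-compartment kinetics under piecewise-constant infusions.

The drug is given as a constant-rate intravenous infusion; with first-order
elimination the plasma concentration has the classic closed form

    C(t) = (R / CL) * (1 - exp(-k (t - t0)))                 during infusion
    C(t) = C(t_stop) * exp(-k (t - t_stop))                  after stop

with ``k = CL / V``.  The model is linear, so concentrations from multiple
infusions superpose additively.  Amounts are mg, volumes L, times h; the
returned concentrations are ng/mL (mg/L x 1000).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .dataset import DoseEvent

__all__ = [
    "PKParameters",
    "predict_concentrations",
    "infusion_concentration",
    "export_profile",
]

MGL_TO_NGML = 1000.0


@dataclass(frozen=True)
class PKParameters:
    """Clearance (L/h) and apparent volume of distribution (L)."""

    cl: float
    v: float

    def __post_init__(self) -> None:
        if not (self.cl > 0 and self.v > 0):
            raise ValueError(f"CL and V must be positive, got CL={self.cl}, V={self.v}")

    @property
    def k(self) -> float:
        """Elimination rate constant, 1/h."""
        return self.cl / self.v


def infusion_concentration(t_rel, duration, rate, cl, k):
    """Concentration (ng/mL) of one infusion, vectorised.

    ``t_rel`` is time since infusion start (h); negative times give 0.
    Query times exactly at the stop use the during-infusion branch, which is
    continuous there anyway.
    """
    t_rel = np.asarray(t_rel, dtype=float)
    during = (rate / cl) * -np.expm1(-k * np.clip(t_rel, 0.0, None))
    c_stop = (rate / cl) * -np.expm1(-k * duration)
    after = c_stop * np.exp(-k * np.clip(t_rel - duration, 0.0, None))
    out = np.where(t_rel <= duration, during, after)
    return np.where(t_rel < 0.0, 0.0, out) * MGL_TO_NGML


def predict_concentrations(
    params: PKParameters, doses: Sequence[DoseEvent], times
) -> np.ndarray:
    """Superposed concentration (ng/mL) at ``times`` for a dose history."""
    times = np.asarray(times, dtype=float)
    out = np.zeros_like(times)
    for dose in doses:
        out += infusion_concentration(
            times - dose.start_time, dose.duration, dose.rate, params.cl, params.k
        )
    return out


def export_profile(params: PKParameters, doses: Sequence[DoseEvent], times, path) -> None:
    """Write a two-column (time, concentration) CSV of the predicted profile."""
    import pandas as pd

    times = np.asarray(times, dtype=float)
    pd.DataFrame(
        dict(time=times, concentration=predict_concentrations(params, doses, times))
    ).to_csv(path, index=False)
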