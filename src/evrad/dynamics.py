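"""ΔEV PD-L1: the paired extracellular-vesicle PD-L1 dynamics statistic.

For each patient, plasma EV PD-L1 band densitometry is normalized to the
tetraspanin loading control CD9 at baseline (T1) and at the 9±1-week
on-treatment draw (T2):

    ΔEV PD-L1 = (PD-L1/CD9 at T2) / (PD-L1/CD9 at T1)

Patients with Δ > 1 are classified as *increase* (the clinically alarming
state, associated with non-durable response and shorter survival) and
Δ < 1 as *decrease*. Δ exactly 1 is never defined clinically; it is
assigned to the non-increase ("decrease") class with a warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .errors import UndefinedRatioError, ValidationError
from .simulate import BlotPanel

logger = logging.getLogger(__name__)

INCREASE = "increase"
DECREASE = "decrease"


@dataclass(frozen=True)
class EVPDL1Dynamics:
    """Per-patient EV PD-L1 dynamics result."""

    patient_id: str
    ratio_t1: float
    ratio_t2: float
    delta: float
    dynamics_class: str


def classify_dynamics(delta: float) -> str:
    """Classify a ΔEV PD-L1 value as ``increase`` (>1) or ``decrease`` (<1).

    Δ = 1 is assigned to ``decrease`` (non-increase) and logged; the
    clinical definition uses strict inequalities only.
    """
    if not delta > 0:
        raise ValidationError(f"delta must be positive, got {delta}")
    if delta == 1.0:
        logger.warning("delta exactly 1.0: classifying as non-increase ('decrease')")
        return DECREASE
    return INCREASE if delta > 1.0 else DECREASE


def compute_delta(panel: BlotPanel) -> EVPDL1Dynamics:
    """Compute ΔEV PD-L1 and its dynamics class from paired blot bands.

    Raises
    ------
    UndefinedRatioError
        If any band is non-positive; such patients are excluded upstream,
        mirroring the exclusion of low-quality plasma samples.
    """
    bands = (panel.pdl1_t1, panel.cd9_t1, panel.pdl1_t2, panel.cd9_t2)
    if any(not (b > 0) for b in bands):
        raise UndefinedRatioError(
            f"patient {panel.patient_id}: all four bands must be strictly "
            f"positive, got {bands}"
        )
    ratio_t1 = panel.pdl1_t1 / panel.cd9_t1
    ratio_t2 = panel.pdl1_t2 / panel.cd9_t2
    delta = ratio_t2 / ratio_t1
    return EVPDL1Dynamics(
        patient_id=panel.patient_id,
        ratio_t1=ratio_t1,
        ratio_t2=ratio_t2,
        delta=delta,
        dynamics_class=classify_dynamics(delta),
    )


def dynamics_table(panels: Iterable[BlotPanel]) -> pd.DataFrame:
    """Tabulate ΔEV PD-L1 for a cohort (one row per evaluable patient)."""
    rows = [compute_delta(p) for p in panels]
    return pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in rows],
            "ratio_t1": [r.ratio_t1 for r in rows],
            "ratio_t2": [r.ratio_t2 for r in rows],
            "delta": [r.delta for r in rows],
            "dynamics_class": [r.dynamics_class for r in rows],
        }
    )
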