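"""Urodynamic indices and patient grouping.

Pressure-flow studies summarise voiding with the detrusor pressure at
maximal flow (PdetQmax, cmH2O), the maximal flow rate (Qmax, ml/s) and the
post-void residual volume (RV, ml).  Two derived indices are standard:

* bladder contractility index  BCI  = PdetQmax + 5 * Qmax
* bladder outlet obstruction index  BOOI = PdetQmax - 2 * Qmax

Patients are split into a high-pressure (HP) group at PdetQmax >= 90 cmH2O
and a medium-pressure (MP) group below, and the BOOI nomogram classifies
obstruction as relieved (< 20), equivocal (20-40) or obstructed (> 40).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

__all__ = [
    "UrodynamicRecord",
    "UrodynamicIndices",
    "compute_bci",
    "compute_booi",
    "classify_pressure_group",
    "classify_obstruction",
    "compute_indices",
]

#: BOOI nomogram bands (lower bound of equivocal, lower bound of obstructed).
BOOI_UNOBSTRUCTED_BELOW = 20.0
BOOI_OBSTRUCTED_ABOVE = 40.0

#: HP/MP split on pre-operative PdetQmax (inclusive on the HP side).
HP_PDETQMAX_THRESHOLD = 90.0


@dataclass(frozen=True)
class UrodynamicRecord:
    """One patient-timepoint pressure-flow measurement."""

    patient_id: str
    timepoint: Literal["before", "after"]
    pdet_qmax: float  # cmH2O
    qmax: float  # ml/s
    rv: float  # ml
    age: float  # years

    def __post_init__(self) -> None:
        for name in ("pdet_qmax", "qmax", "rv"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")
        if self.timepoint not in ("before", "after"):
            raise ValueError(f"timepoint must be 'before' or 'after', got {self.timepoint!r}")


@dataclass(frozen=True)
class UrodynamicIndices:
    patient_id: str
    timepoint: str
    bci: float
    booi: float
    pressure_group: Literal["HP", "MP"]
    obstruction_class: Literal["obstructed", "equivocal", "unobstructed"]


def _check_nonneg(name: str, value: float) -> None:
    if not math.isfinite(value) or value < 0:
        raise ValueError(f"{name} must be finite and non-negative, got {value!r}")


def compute_bci(pdet_qmax: float, qmax: float) -> float:
    """Bladder contractility index, BCI = PdetQmax + 5 * Qmax."""
    _check_nonneg("pdet_qmax", pdet_qmax)
    _check_nonneg("qmax", qmax)
    return pdet_qmax + 5.0 * qmax


def compute_booi(pdet_qmax: float, qmax: float) -> float:
    """Bladder outlet obstruction index, BOOI = PdetQmax - 2 * Qmax (may be negative)."""
    _check_nonneg("pdet_qmax", pdet_qmax)
    _check_nonneg("qmax", qmax)
    return pdet_qmax - 2.0 * qmax


def classify_pressure_group(pdet_qmax: float, threshold: float = HP_PDETQMAX_THRESHOLD) -> str:
    """'HP' iff pdet_qmax >= threshold (default 90 cmH2O, inclusive), else 'MP'."""
    _check_nonneg("pdet_qmax", pdet_qmax)
    return "HP" if pdet_qmax >= threshold else "MP"


def classify_obstruction(
    booi: float,
    unobstructed_below: float = BOOI_UNOBSTRUCTED_BELOW,
    obstructed_above: float = BOOI_OBSTRUCTED_ABOVE,
) -> str:
    """BOOI nomogram class: <20 unobstructed, 20-40 equivocal, >40 obstructed.

    The band boundaries are the conventional nomogram values and are
    configurable.
    """
    if not math.isfinite(booi):
        raise ValueError("booi must be finite")
    if booi < unobstructed_below:
        return "unobstructed"
    if booi > obstructed_above:
        return "obstructed"
    return "equivocal"


def compute_indices(record: UrodynamicRecord) -> UrodynamicIndices:
    """Derive BCI, BOOI, pressure group and obstruction class for one record."""
    bci = compute_bci(record.pdet_qmax, record.qmax)
    booi = compute_booi(record.pdet_qmax, record.qmax)
    return UrodynamicIndices(
        patient_id=record.patient_id,
        timepoint=record.timepoint,
        bci=bci,
        booi=booi,
        pressure_group=classify_pressure_group(record.pdet_qmax),
        obstruction_class=classify_obstruction(booi),
    )
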