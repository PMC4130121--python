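"""Clamp-derived insulin sensitivity (M value) from euglycemic clamp traces.

The euglycemic hyperinsulinemic clamp infuses insulin at a constant rate
(80 mU per m^2 body surface area per minute here) while a variable 20%
glucose infusion holds blood glucose at the 100 mg/dL target.  Once the
plateau is reached, the exogenous glucose infusion rate (GIR) equals
whole-body insulin-mediated glucose uptake.  M is the mean GIR over the
final 20 minutes (80-100 min), corrected for between-subject deviations
of steady-state glucose from the group mean ("glucose space" correction)
and normalised per kg of fat-free mass (adjusted M) or per kg of body
weight (unadjusted M).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

from .exceptions import DomainError, InsufficientDataError
from .indices import SubjectRecord

#: nominal insulin sampling times during the steady-state window (min)
INSULIN_SAMPLE_TIMES = (80.0, 90.0, 100.0)

#: default steady-state analysis window (min), endpoints inclusive
DEFAULT_WINDOW = (80.0, 100.0)

#: protocol insulin infusion rate, mU per m^2 per min
PROTOCOL_INSULIN_RATE = 80.0

#: tolerance when matching nominal sample times to the trace grid (min)
TIME_MATCH_TOL = 0.5

#: a within-window glucose CV at or above this (%) is flagged
CV_WARN_THRESHOLD = 5.0


@dataclass
class ClampTrace:
    """Timed blood glucose / glucose infusion / insulin samples for one clamp.

    ``time`` is in minutes on a 5-min grid covering 0-100+, ``blood_glucose``
    in mg/dL, ``gir`` in mg/min (whole-body exogenous glucose infusion),
    ``insulin_samples`` maps sample time (min) to plasma insulin (uU/mL);
    insulin is drawn fasting and at 80/90/100 min.
    """

    subject_id: str
    time: np.ndarray
    blood_glucose: np.ndarray
    gir: np.ndarray
    insulin_samples: dict = field(default_factory=dict)
    insulin_infusion_rate: float = PROTOCOL_INSULIN_RATE

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.blood_glucose = np.asarray(self.blood_glucose, dtype=float)
        self.gir = np.asarray(self.gir, dtype=float)
        if not (len(self.time) == len(self.blood_glucose) == len(self.gir)):
            raise DomainError("time, blood_glucose and gir must have equal length")
        if np.any(np.diff(self.time) <= 0):
            raise DomainError("time must be strictly increasing")
        if np.any(self.blood_glucose < 0) or np.any(self.gir < 0):
            raise DomainError("blood_glucose and gir must be non-negative")


@dataclass(frozen=True)
class MValueResult:
    """Steady-state summary and M values for one subject."""

    subject_id: str
    mean_gir: float  # mg/min over the window
    ss_glucose: float  # mg/dL, individual steady-state mean
    cv_glucose: float  # % within window
    ss_insulin: Optional[float]  # uU/mL, mean of 80/90/100-min samples
    space_correction: float  # dimensionless
    m_unadjusted: float  # mg/min per kg body weight
    m_adjusted: float  # mg/min per kg fat-free mass
    m_per_insulin: Optional[float] = None  # auxiliary: m_adjusted / ss_insulin
    cv_flagged: bool = False


def steady_state_summary(
    trace: ClampTrace, window: Tuple[float, float] = DEFAULT_WINDOW
) -> Tuple[float, float, float, Optional[float]]:
    """Mean GIR, steady-state glucose, glucose CV (%) and steady-state insulin.

    Means are arithmetic over the samples falling inside ``window``
    (endpoints inclusive).  Steady-state insulin is the mean of whatever
    80/90/100-min samples are present (``None`` if none are).  A glucose
    CV at or above 5% is flagged with a warning but the record is kept.
    """
    lo, hi = window
    if lo < trace.time[0] or hi > trace.time[-1]:
        raise InsufficientDataError(
            f"window [{lo}, {hi}] not covered by trace extent "
            f"[{trace.time[0]}, {trace.time[-1]}]"
        )
    mask = (trace.time >= lo) & (trace.time <= hi)
    if mask.sum() < 3:
        raise InsufficientDataError(
            f"only {int(mask.sum())} glucose samples inside [{lo}, {hi}]; need >= 3"
        )
    glu = trace.blood_glucose[mask]
    mean_gir = float(trace.gir[mask].mean())
    ss_glucose = float(glu.mean())
    cv = float(100.0 * glu.std(ddof=1) / ss_glucose) if ss_glucose > 0 else float("inf")
    if cv >= CV_WARN_THRESHOLD:
        warnings.warn(
            f"subject {trace.subject_id}: within-window glucose CV "
            f"{cv:.1f}% >= {CV_WARN_THRESHOLD:g}%"
        )
    ins_vals = [
        v
        for t_nom in INSULIN_SAMPLE_TIMES
        for t, v in trace.insulin_samples.items()
        if abs(float(t) - t_nom) <= TIME_MATCH_TOL and v is not None
    ]
    ss_insulin = float(np.mean(ins_vals)) if ins_vals else None
    return mean_gir, ss_glucose, cv, ss_insulin


def glucose_space_correction(individual_ss_glucose: float, group_mean_ss_glucose: float) -> float:
    """Group-mean steady-state glucose divided by the individual's steady-state glucose."""
    for name, v in (
        ("individual_ss_glucose", individual_ss_glucose),
        ("group_mean_ss_glucose", group_mean_ss_glucose),
    ):
        if v is None or not math.isfinite(v) or v <= 0:
            raise DomainError(f"{name} must be positive and finite, got {v}")
    return group_mean_ss_glucose / individual_ss_glucose


def m_value(
    trace: ClampTrace,
    subject: SubjectRecord,
    group_mean_ss_glucose: float,
    window: Tuple[float, float] = DEFAULT_WINDOW,
) -> MValueResult:
    """Compute the clamp M value for one subject.

    m_adjusted = mean GIR x space correction / fat-free mass (mg/min/kg FFM);
    m_unadjusted uses total body weight in the denominator.  The group-mean
    steady-state glucose must be computed over the analysis cohort *before*
    calling this per subject.
    """
    if subject.weight is None or subject.weight <= 0:
        raise DomainError(f"subject {subject.subject_id}: weight missing or non-positive")
    if subject.fat_free_mass is None or subject.fat_free_mass <= 0:
        raise DomainError(f"subject {subject.subject_id}: fat_free_mass missing or non-positive")
    mean_gir, ss_glu, cv, ss_ins = steady_state_summary(trace, window)
    corr = glucose_space_correction(ss_glu, group_mean_ss_glucose)
    corrected_gir = mean_gir * corr
    m_adj = corrected_gir / subject.fat_free_mass
    m_unadj = corrected_gir / subject.weight
    return MValueResult(
        subject_id=trace.subject_id,
        mean_gir=mean_gir,
        ss_glucose=ss_glu,
        cv_glucose=cv,
        ss_insulin=ss_ins,
        space_correction=corr,
        m_unadjusted=m_unadj,
        m_adjusted=m_adj,
        m_per_insulin=(m_adj / ss_ins) if ss_ins else None,
        cv_flagged=cv >= CV_WARN_THRESHOLD,
    )


def group_mean_ss_glucose(
    traces: Sequence[ClampTrace], window: Tuple[float, float] = DEFAULT_WINDOW
) -> float:
    """Mean over subjects of the individual steady-state glucose values."""
    if not traces:
        raise InsufficientDataError("no clamp traces supplied")
    return float(np.mean([steady_state_summary(t, window)[1] for t in traces]))
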