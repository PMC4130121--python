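"""Fasting surrogate indices of insulin sensitivity and derived clinical quantities.

Conventions
-----------
HOMA-IR and FIRI take fasting glucose in mmol/L and fasting insulin in
uU/mL (the published formulas: G*I/22.5 and G*I/25).  QUICKI and the
glucose/insulin ratio default to glucose in mg/dL, QUICKI with base-10
logarithms, matching the original publications; both are configurable
because unit usage varies across the clinical literature.

Higher HOMA-IR/FIRI means more insulin *resistant*; higher QUICKI and
G/I ratio mean more insulin *sensitive*.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, fields
from typing import Optional

from .exceptions import DomainError, UnitsError, ValidityError

#: mg/dL of glucose per mmol/L (molar mass of glucose / 10)
MG_DL_PER_MMOL_L = 18.016

_BMI_LEAN_UPPER = 25.0
_BMI_OVERWEIGHT_UPPER = 30.0

#: Friedewald's formula is unreliable above this triglyceride level (mg/dL)
FRIEDEWALD_TG_LIMIT = 400.0


@dataclass
class SubjectRecord:
    """One participant's demographics, anthropometry and fasting labs.

    Units: height/waist/hip in cm, weight and fat-free mass in kg, BMI in
    kg/m^2, percent fat in %, fasting glucose in mmol/L, fasting insulin
    in uU/mL, lipids in mg/dL, blood pressure in mmHg.  Missing values
    are ``None``.
    """

    subject_id: str
    sex: str  # "M" or "F"
    age: Optional[float] = None
    height: Optional[float] = None
    weight: Optional[float] = None
    bmi: Optional[float] = None
    waist: Optional[float] = None
    hip: Optional[float] = None
    whtr: Optional[float] = None
    percent_fat: Optional[float] = None
    fat_free_mass: Optional[float] = None
    fasting_glucose: Optional[float] = None
    fasting_insulin: Optional[float] = None
    total_chol: Optional[float] = None
    hdl: Optional[float] = None
    ldl: Optional[float] = None
    triglycerides: Optional[float] = None
    sbp: Optional[float] = None
    dbp: Optional[float] = None

    def __post_init__(self) -> None:
        if self.sex not in ("M", "F"):
            raise DomainError(f"sex must be 'M' or 'F', got {self.sex!r}")
        for name in ("height", "weight", "waist", "hip", "fat_free_mass"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise DomainError(f"{name} must be strictly positive, got {v}")
        if self.bmi is None and self.height is not None and self.weight is not None:
            self.bmi = self.weight / (self.height / 100.0) ** 2
        if self.whtr is None and self.waist is not None and self.height is not None:
            self.whtr = self.waist / self.height

    def validate_consistency(self) -> None:
        """Check the redundant anthropometry fields against each other."""
        if None not in (self.bmi, self.height, self.weight):
            implied = self.weight / (self.height / 100.0) ** 2
            if abs(implied - self.bmi) > 0.1:
                raise DomainError(
                    f"subject {self.subject_id}: bmi {self.bmi:.2f} inconsistent "
                    f"with weight/height ({implied:.2f})"
                )
        if None not in (self.whtr, self.waist, self.height):
            implied = self.waist / self.height
            if abs(implied - self.whtr) > 0.005:
                raise DomainError(
                    f"subject {self.subject_id}: whtr {self.whtr:.3f} inconsistent "
                    f"with waist/height ({implied:.3f})"
                )
        if self.fasting_glucose is not None and self.fasting_glucose >= 7.0:
            raise DomainError(
                f"subject {self.subject_id}: fasting glucose "
                f"{self.fasting_glucose} mmol/L is in the diabetic range (>= 7.0)"
            )

    @classmethod
    def field_names(cls) -> list[str]:
        return [f.name for f in fields(cls)]


@dataclass(frozen=True)
class FastingIndices:
    """The fasting surrogate indices for one subject."""

    homa_ir: float
    firi: float
    quicki: float
    gi_ratio: float
    fasting_insulin: float


def _require_positive(**values: Optional[float]) -> None:
    for name, v in values.items():
        if v is None:
            raise DomainError(f"{name} is missing")
        if not math.isfinite(v) or v <= 0:
            raise DomainError(f"{name} must be positive and finite, got {v}")


def homa_ir(glucose: float, insulin: float) -> float:
    """Homeostasis-model insulin resistance: glucose (mmol/L) x insulin (uU/mL) / 22.5."""
    _require_positive(glucose=glucose, insulin=insulin)
    return glucose * insulin / 22.5


def firi(glucose: float, insulin: float) -> float:
    """Fasting insulin resistance index: glucose (mmol/L) x insulin (uU/mL) / 25.

    Algebraically exactly 0.9 x HOMA-IR.
    """
    _require_positive(glucose=glucose, insulin=insulin)
    return glucose * insulin / 25.0


def quicki(glucose: float, insulin: float, log_base: float = 10) -> float:
    """Quantitative insulin sensitivity check index: 1/(log I0 + log G0).

    Parameters
    ----------
    glucose : fasting glucose in mg/dL (the published convention).
    insulin : fasting insulin in uU/mL.
    log_base : 10 (default, as published) or ``math.e``.
    """
    _require_positive(glucose=glucose, insulin=insulin)
    if log_base == 10:
        denom = math.log10(insulin) + math.log10(glucose)
    elif log_base == math.e:
        denom = math.log(insulin) + math.log(glucose)
    else:
        raise UnitsError(f"log_base must be 10 or e, got {log_base}")
    if abs(denom) < 1e-12:
        raise DomainError("QUICKI denominator log(I0) + log(G0) is zero")
    return 1.0 / denom


def gi_ratio(glucose: float, insulin: float, glucose_units: str = "mg/dL") -> float:
    """Fasting glucose-to-insulin ratio, in the stated glucose units per uU/mL."""
    _require_positive(glucose=glucose, insulin=insulin)
    if glucose_units not in ("mg/dL", "mmol/L"):
        raise UnitsError(f"unknown glucose unit {glucose_units!r}")
    return glucose / insulin


def friedewald_ldl(total_chol: float, hdl: float, triglycerides: float) -> float:
    """LDL cholesterol by Friedewald's formula: TC - HDL - TG/5 (all mg/dL).

    Valid only for TG <= 400 mg/dL; a negative result is returned with a
    warning (it indicates implausible inputs, not a computational error).
    The formula is linear, so applied to group means it returns the group
    mean of per-subject LDL.
    """
    for name, v in (("total_chol", total_chol), ("hdl", hdl), ("triglycerides", triglycerides)):
        if v is None or not math.isfinite(v) or v < 0:
            raise DomainError(f"{name} must be non-negative and finite, got {v}")
    if triglycerides > FRIEDEWALD_TG_LIMIT:
        raise ValidityError(
            f"Friedewald's formula is invalid for triglycerides > "
            f"{FRIEDEWALD_TG_LIMIT:g} mg/dL (got {triglycerides:g})"
        )
    ldl = total_chol - hdl - triglycerides / 5.0
    if ldl < 0:
        warnings.warn(f"Friedewald LDL is negative ({ldl:.1f} mg/dL); check inputs")
    return ldl


def convert_glucose(value: float, from_units: str, to_units: str) -> float:
    """Convert a glucose concentration between mg/dL and mmol/L (factor 18.016)."""
    known = ("mg/dL", "mmol/L")
    if from_units not in known or to_units not in known:
        raise UnitsError(f"glucose units must be one of {known}")
    if value < 0:
        raise DomainError(f"glucose concentration must be non-negative, got {value}")
    if from_units == to_units:
        return value
    if from_units == "mmol/L":
        return value * MG_DL_PER_MMOL_L
    return value / MG_DL_PER_MMOL_L


def bmi_category(bmi: float) -> str:
    """Classify BMI into 'lean' [0,25), 'overweight' [25,30) or 'obese' [30,inf)."""
    if bmi is None or not math.isfinite(bmi) or bmi <= 0:
        raise DomainError(f"bmi must be positive and finite, got {bmi}")
    if bmi < _BMI_LEAN_UPPER:
        return "lean"
    if bmi < _BMI_OVERWEIGHT_UPPER:
        return "overweight"
    return "obese"


def fasting_indices(
    subject: SubjectRecord,
    quicki_log_base: float = 10,
    gi_glucose_units: str = "mg/dL",
) -> FastingIndices:
    """Compute all fasting surrogate indices for one subject.

    Fasting glucose is stored in mmol/L on the record; QUICKI and the G/I
    ratio convert it to mg/dL by default.
    """
    g_mmol = subject.fasting_glucose
    ins = subject.fasting_insulin
    _require_positive(fasting_glucose=g_mmol, fasting_insulin=ins)
    g_mg = convert_glucose(g_mmol, "mmol/L", "mg/dL")
    g_for_ratio = g_mg if gi_glucose_units == "mg/dL" else g_mmol
    return FastingIndices(
        homa_ir=homa_ir(g_mmol, ins),
        firi=firi(g_mmol, ins),
        quicki=quicki(g_mg, ins, log_base=quicki_log_base),
        gi_ratio=gi_ratio(g_for_ratio, ins, glucose_units=gi_glucose_units),
        fasting_insulin=ins,
    )
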