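"""Seeded synthetic cohorts and clamp traces with a controllable latent structure.

No subject-level data accompany the study this package models, so every
downstream stage is exercised on synthetic cohorts whose marginal
distributions (per sex x BMI-category stratum) and whose correlation
between *true* insulin sensitivity and the fasting/adiposity measures
are configurable.

Construction
------------
Each subject gets a latent trivariate standard normal ``(Z_S, Z_A, Z_H)``:

* ``Z_S`` drives true insulin sensitivity ``S_true`` (log-normal, calibrated
  to the clamp M distribution, mean 10.5, SD 3.2 mg/min/kg FFM);
* ``Z_A`` is a single adiposity factor: it selects the BMI category (via its
  quantile and the stratum proportions) and shifts BMI, waist, hip and
  percent fat within stratum;
* ``Z_H`` drives log HOMA-IR; fasting insulin is then derived as
  ``HOMA x 22.5 / glucose`` with glucose drawn independently per stratum
  (truncated below the diabetic threshold of 7 mmol/L).

Targeting log-HOMA rather than log-insulin makes the end-to-end recovery
experiment well-posed: the population correlation between log HOMA-IR and
log S_true *is* the configured ``r_homa``; the log-insulin correlation is
the same value attenuated slightly (~2%) by independent glucose variation.

Clamp traces impose the steady state rather than simulating
glucose-insulin kinetics: blood glucose ramps onto the 100 mg/dL target
by 40 min and the glucose infusion rate onto ``S_true x fat-free mass``,
with multiplicative noise.  With all noise set to zero the M-value
computation recovers ``S_true`` exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from importlib import resources
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy import stats

from .clamp import ClampTrace, PROTOCOL_INSULIN_RATE
from .exceptions import ConfigurationError
from .indices import SubjectRecord, convert_glucose
from . import clamp as _clamp

_CATEGORIES = ("lean", "overweight", "obese")

#: clamp blood-glucose target, mg/dL
GLUCOSE_TARGET = 100.0

#: effective conversion from insulin infusion rate (mU/m^2/min, at BSA 1.73 m^2)
#: to steady-state plasma insulin increment (uU/mL); an inverse clearance.
INSULIN_RATE_TO_SS = 1.9


def load_default_params() -> dict:
    """Load the bundled per-stratum parameter file."""
    with resources.files("clampval.data").joinpath("cohort_defaults.json").open() as fh:
        return json.load(fh)


@dataclass
class CohortSpec:
    """Configuration of one synthetic study.

    ``latent_structure`` holds the three latent correlations:
    ``r_homa`` between log HOMA-IR and log S_true (the headline
    surrogate-vs-clamp association), ``r_adiposity`` between the adiposity
    factor and log S_true, and ``r_adiposity_homa`` between adiposity and
    log HOMA-IR.  ``glycemic_cv`` is the multiplicative noise CV (%) of the
    clamped blood glucose, ``gir_noise_cv`` the per-sample CV (%) of the
    glucose infusion rate.
    """

    n_subjects: int = 87
    sex_ratio: float = 51.0 / 87.0  # fraction male
    latent_structure: Dict[str, float] = dc_field(
        default_factory=lambda: {
            "r_homa": -0.30,
            "r_adiposity": -0.45,
            "r_adiposity_homa": 0.45,
        }
    )
    glycemic_cv: float = 2.0
    gir_noise_cv: float = 3.0
    insulin_noise_cv: float = 3.0
    seed: int = 0
    group_params: Optional[dict] = None
    #: within-stratum loading of waist/hip/percent-fat on the adiposity factor
    adiposity_loading: float = 0.5

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ConfigurationError("n_subjects must be >= 2")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise ConfigurationError("sex_ratio must lie in [0, 1]")
        for k, v in self.latent_structure.items():
            if not -1.0 < v < 1.0:
                raise ConfigurationError(f"latent correlation {k}={v} outside (-1, 1)")
        for k in ("glycemic_cv", "gir_noise_cv", "insulin_noise_cv"):
            if getattr(self, k) < 0:
                raise ConfigurationError(f"{k} must be >= 0")
        if self.group_params is None:
            self.group_params = load_default_params()
        # fail fast if the implied latent correlation matrix is not PD
        np.linalg.cholesky(self.latent_corr())

    def latent_corr(self) -> np.ndarray:
        ls = self.latent_structure
        r = np.array(
            [
                [1.0, ls["r_adiposity"], ls["r_homa"]],
                [ls["r_adiposity"], 1.0, ls["r_adiposity_homa"]],
                [ls["r_homa"], ls["r_adiposity_homa"], 1.0],
            ]
        )
        try:
            np.linalg.cholesky(r)
        except np.linalg.LinAlgError as exc:
            raise ConfigurationError(
                "latent_structure implies a non-positive-definite correlation matrix"
            ) from exc
        return r


def _lognormal_params(mean: float, sd: float) -> Tuple[float, float]:
    """(mu, sigma) of a log-normal with the given arithmetic mean and SD."""
    sigma2 = np.log1p((sd / mean) ** 2)
    return float(np.log(mean) - sigma2 / 2.0), float(np.sqrt(sigma2))


def _trunc_normal(rng: np.random.Generator, mean, sd, lo, hi, size=None):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _stratum_value(
    rng: np.random.Generator, params, z: float, loading: float, lo: float = -np.inf
) -> float:
    """Draw mean + sd*(loading*z + sqrt(1-loading^2)*e), truncated below at lo."""
    mean, sd = params
    resid = loading * z + np.sqrt(1.0 - loading**2) * rng.standard_normal()
    v = mean + sd * resid
    if v <= lo:
        v = lo + abs(v - lo) * 0.1 + 1e-6  # reflect softly off the bound
    return float(v)


def generate_cohort(spec: CohortSpec) -> Tuple[List[SubjectRecord], np.ndarray]:
    """Generate the cohort; returns (records, hidden S_true per subject).

    Deterministic given ``spec.seed``.  S_true is in mg/min per kg
    fat-free mass.
    """
    rng = np.random.default_rng(spec.seed)
    params = spec.group_params
    iv = params["insulin_sensitivity"]
    mu_s, sig_s = _lognormal_params(iv["mean"], iv["sd"])
    mu_h, sig_h = _lognormal_params(params["homa_ir"]["mean"], params["homa_ir"]["sd"])

    n = spec.n_subjects
    n_male = int(round(spec.sex_ratio * n))
    sexes = np.array(["M"] * n_male + ["F"] * (n - n_male))

    chol = np.linalg.cholesky(spec.latent_corr())
    z = rng.standard_normal((n, 3)) @ chol.T  # columns: Z_S, Z_A, Z_H
    s_true = np.exp(mu_s + sig_s * z[:, 0])

    records: List[SubjectRecord] = []
    for i in range(n):
        sex = str(sexes[i])
        strata = params["strata"][sex]
        props = np.array([strata[c]["n"] for c in _CATEGORIES], dtype=float)
        cum = np.cumsum(props / props.sum())
        p_a = float(stats.norm.cdf(z[i, 1]))
        k = int(np.searchsorted(cum, p_a, side="right"))
        k = min(k, 2)
        cat = _CATEGORIES[k]
        st = strata[cat]
        # position of Z_A inside its category slab, mapped back to a normal score
        c_lo = 0.0 if k == 0 else cum[k - 1]
        u = (p_a - c_lo) / max(cum[k] - c_lo, 1e-12)
        z_within = float(np.clip(stats.norm.ppf(np.clip(u, 1e-6, 1 - 1e-6)), -3, 3))

        height = _trunc_normal(
            rng, params["height"][sex]["mean"], params["height"][sex]["sd"], 140, 200
        )
        bmi = max(st["bmi"][0] + st["bmi"][1] * z_within, 15.0)
        weight = bmi * (height / 100.0) ** 2
        lam = spec.adiposity_loading
        waist = _stratum_value(rng, st["waist"], z_within, lam, lo=50.0)
        hip = _stratum_value(rng, st["hip"], z_within, lam, lo=60.0)
        pfat = float(np.clip(_stratum_value(rng, st["percent_fat"], z_within, lam), 5.0, 60.0))
        ffm = weight * (1.0 - pfat / 100.0)

        glucose = float(_trunc_normal(rng, st["fasting_glucose"][0], st["fasting_glucose"][1], 3.0, 6.99))
        homa = float(np.exp(mu_h + sig_h * z[i, 2]))
        insulin = homa * 22.5 / glucose

        records.append(
            SubjectRecord(
                subject_id=f"S{i + 1:04d}",
                sex=sex,
                age=float(np.clip(_stratum_value(rng, st["age"], 0.0, 0.0), 21, 75)),
                height=float(height),
                weight=float(weight),
                waist=waist,
                hip=hip,
                percent_fat=pfat,
                fat_free_mass=float(ffm),
                fasting_glucose=glucose,
                fasting_insulin=float(insulin),
                total_chol=_stratum_value(rng, st["total_chol"], 0.0, 0.0, lo=60.0),
                hdl=_stratum_value(rng, st["hdl"], 0.0, 0.0, lo=15.0),
                triglycerides=float(
                    np.clip(_stratum_value(rng, st["triglycerides"], 0.0, 0.0, lo=20.0), 20, 395)
                ),
                sbp=_stratum_value(rng, st["sbp"], 0.0, 0.0, lo=80.0),
                dbp=_stratum_value(rng, st["dbp"], 0.0, 0.0, lo=45.0),
            )
        )
        rec = records[-1]
        rec.ldl = rec.total_chol - rec.hdl - rec.triglycerides / 5.0
    return records, s_true


def du_bois_bsa(height_cm: float, weight_kg: float) -> float:
    """Body surface area (m^2) by the Du Bois formula."""
    return 0.007184 * height_cm**0.725 * weight_kg**0.425


def steady_state_insulin(subject: SubjectRecord, rate: float = PROTOCOL_INSULIN_RATE) -> float:
    """Deterministic steady-state plasma insulin (uU/mL) for a given infusion rate."""
    bsa = du_bois_bsa(subject.height, subject.weight)
    basal = subject.fasting_insulin or 0.0
    return basal + INSULIN_RATE_TO_SS * rate * bsa / 1.73


def generate_clamp_trace(
    subject: SubjectRecord,
    s_true: float,
    spec: CohortSpec,
    rng: Optional[np.random.Generator] = None,
) -> ClampTrace:
    """Simulate one clamp trace on the 0-100 min, 5-min grid.

    Blood glucose ramps from the fasting level onto the 100 mg/dL target
    (reached exactly by 40 min), GIR onto ``s_true x fat_free_mass``;
    both carry multiplicative noise at the spec's CVs.  Steady-state
    insulin is deterministic in infusion rate and Du Bois body surface
    area, plus noise.  Noise-free traces make the M computation exact.
    """
    if s_true <= 0:
        raise ConfigurationError(f"s_true must be positive, got {s_true}")
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    t = np.arange(0.0, 101.0, 5.0)
    g0 = convert_glucose(subject.fasting_glucose, "mmol/L", "mg/dL")
    ramp = np.clip(1.0 - t / 40.0, 0.0, None) ** 2
    glucose = GLUCOSE_TARGET + (g0 - GLUCOSE_TARGET) * ramp
    gir_plateau = s_true * subject.fat_free_mass
    gir = gir_plateau * np.clip(t / 40.0, 0.0, 1.0) ** 1.5
    if spec.glycemic_cv > 0:
        glucose = glucose * (1.0 + spec.glycemic_cv / 100.0 * rng.standard_normal(t.size))
    if spec.gir_noise_cv > 0:
        gir = gir * (1.0 + spec.gir_noise_cv / 100.0 * rng.standard_normal(t.size))
    gir = np.clip(gir, 0.0, None)
    glucose = np.clip(glucose, 1.0, None)

    i_ss = steady_state_insulin(subject, PROTOCOL_INSULIN_RATE)
    noise = (
        1.0 + spec.insulin_noise_cv / 100.0 * rng.standard_normal(3)
        if spec.insulin_noise_cv > 0
        else np.ones(3)
    )
    samples = {0.0: subject.fasting_insulin}
    for j, t_nom in enumerate(_clamp.INSULIN_SAMPLE_TIMES):
        samples[t_nom] = float(i_ss * noise[j])
    return ClampTrace(
        subject_id=subject.subject_id,
        time=t,
        blood_glucose=glucose,
        gir=gir,
        insulin_samples=samples,
        insulin_infusion_rate=PROTOCOL_INSULIN_RATE,
    )


def generate_study(spec: CohortSpec) -> Tuple[List[SubjectRecord], np.ndarray, List[ClampTrace]]:
    """Cohort plus one clamp trace per subject, all from one seeded stream."""
    records, s_true = generate_cohort(spec)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    traces = [
        generate_clamp_trace(rec, float(s), spec, rng=rng)
        for rec, s in zip(records, s_true)
    ]
    return records, s_true, traces
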