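"""Reference clinical risk scores and the twin-derived POAF probability.

Implements the published additive CHA2DS2-VASc and HAS-BLED point scores
from the cohort's comorbidity flags, a configurable logistic surrogate
standing in for the proprietary STS risk calculator (labelled a
surrogate in all outputs), and the logistic mapping from the calibrated
twin's vulnerability index (plus clinical covariates) to a POAF
probability — the score evaluated downstream as "the digital twin".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = [
    "cha2ds2_vasc",
    "has_bled",
    "sts_surrogate",
    "twin_risk_probability",
    "score_panel",
    "StsCoefficients",
    "TwinRiskCoefficients",
]


def _col(rec, name):
    if isinstance(rec, pd.DataFrame):
        return rec[name].to_numpy()
    if isinstance(rec, (pd.Series, dict)):
        return np.asarray(rec[name])
    return np.asarray(getattr(rec, name))


def cha2ds2_vasc(record) -> int | np.ndarray:
    """CHA2DS2-VASc: CHF+1, hypertension+1, age>=75 +2, diabetes+1,
    stroke/TIA+2, vascular disease+1, age 65-74 +1, female sex+1 (max 9)."""
    age = _col(record, "age").astype(float)
    score = (
        _col(record, "chf").astype(int)
        + _col(record, "hypertension").astype(int)
        + 2 * (age >= 75).astype(int)
        + _col(record, "diabetes").astype(int)
        + 2 * _col(record, "prior_stroke_tia").astype(int)
        + _col(record, "vascular_disease").astype(int)
        + ((age >= 65) & (age < 75)).astype(int)
        + (_col(record, "sex") == "female").astype(int)
    )
    return int(score) if np.ndim(score) == 0 else score


def has_bled(record) -> int | np.ndarray:
    """HAS-BLED: one point each for hypertension, renal disease, liver
    disease, prior stroke, bleeding history, labile INR, age > 65,
    antiplatelet/NSAID use, alcohol use (max 9)."""
    age = _col(record, "age").astype(float)
    score = (
        _col(record, "hypertension").astype(int)
        + _col(record, "renal_disease").astype(int)
        + _col(record, "liver_disease").astype(int)
        + _col(record, "prior_stroke_tia").astype(int)
        + _col(record, "bleeding_history").astype(int)
        + _col(record, "labile_inr").astype(int)
        + (age > 65).astype(int)
        + _col(record, "antiplatelet_use").astype(int)
        + _col(record, "alcohol_use").astype(int)
    )
    return int(score) if np.ndim(score) == 0 else score


@dataclass(frozen=True)
class StsCoefficients:
    """Logistic surrogate for the STS risk calculator (NOT the official
    proprietary model; coefficients are package defaults, configurable)."""

    intercept: float = -2.1
    age_per_decade: float = 0.35
    renal_disease: float = 0.5
    chf: float = 0.45
    surgery: dict | None = None

    def surgery_weights(self) -> dict:
        return self.surgery or {
            "CABG": 0.0, "valve": 0.25, "combined": 0.6, "aortic": 0.45
        }


def sts_surrogate(record, coefficients: StsCoefficients | None = None):
    """Surrogate STS-style probability: logistic-linear in age, surgery
    type, renal disease and CHF."""
    c = coefficients or StsCoefficients()
    surgery = _col(record, "surgery_type")
    weights = c.surgery_weights()
    unknown = set(np.atleast_1d(surgery)) - set(weights)
    if unknown:
        raise KeyError(f"no surgery coefficient for {sorted(unknown)}")
    w = np.vectorize(weights.__getitem__, otypes=[float])(surgery)
    lin = (
        c.intercept
        + c.age_per_decade * (_col(record, "age").astype(float) - 66.0) / 10.0
        + c.renal_disease * _col(record, "renal_disease").astype(float)
        + c.chf * _col(record, "chf").astype(float)
        + w
    )
    out = expit(lin)
    return float(out) if np.ndim(out) == 0 else out


@dataclass(frozen=True)
class TwinRiskCoefficients:
    intercept: float = -3.2
    vulnerability: float = 3.6
    age_per_decade: float = 0.3
    chf: float = 0.2
    hypertension: float = 0.1


def twin_risk_probability(twin, record,
                          coefficients: TwinRiskCoefficients | None = None):
    """Twin POAF probability: logistic in the vulnerability index plus
    clinical covariates.

    ``twin`` may be a TwinModel, a twin-table DataFrame (from
    ``build_twins``) or an array of vulnerability values aligned with
    ``record``.  Non-converged twins are used as-is (the caller sees the
    convergence flag in the twin table).
    """
    c = coefficients or TwinRiskCoefficients()
    if isinstance(twin, pd.DataFrame):
        vuln = twin["vulnerability"].to_numpy(float)
    elif hasattr(twin, "vulnerability"):
        vuln = np.asarray(twin.vulnerability, dtype=float)
    else:
        vuln = np.asarray(twin, dtype=float)
    lin = (
        c.intercept
        + c.vulnerability * vuln
        + c.age_per_decade * (_col(record, "age").astype(float) - 66.0) / 10.0
        + c.chf * _col(record, "chf").astype(float)
        + c.hypertension * _col(record, "hypertension").astype(float)
    )
    out = expit(lin)
    return float(out) if np.ndim(out) == 0 else out


def score_panel(cohort: pd.DataFrame, twins: pd.DataFrame,
                sts: StsCoefficients | None = None,
                twin_coefs: TwinRiskCoefficients | None = None) -> pd.DataFrame:
    """All four scores per patient, keyed by patient id.

    ``sts_surrogate`` is a package surrogate for the proprietary STS
    calculator, not the official model.
    """
    return pd.DataFrame({
        "patient_id": cohort["id"].to_numpy(),
        "chads_vasc": cha2ds2_vasc(cohort),
        "has_bled": has_bled(cohort),
        "sts_surrogate": sts_surrogate(cohort, sts),
        "twin_prob": twin_risk_probability(twins, cohort, twin_coefs),
    })
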