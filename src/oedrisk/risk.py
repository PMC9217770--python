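"""Organ equivalent dose (OED) and excess absolute risk (EAR).

The carcinogenesis dose-response is linear at low dose; at radiotherapy
doses cell killing suppresses induction.  The risk-equivalent dose (RED)
kernel captures this:

* ``linear``:              RED(D) = D                   (low-dose limit)
* ``linear_exponential``:  RED(D) = D * exp(-alpha * D) (cell killing, default)
* ``plateau``:             RED(D) = (1 - exp(-delta*D)) / delta (optional)

``alpha`` (per Gy) is the organ-specific cell-sterilization parameter.  The
OED of a non-uniform dose distribution is the volume-weighted mean of RED
over the DVH,

    OED = sum_i (v_i / V_T) * RED(D_i),

with D_i the bin-center doses — the uniform dose producing the same
radiation-induced cancer incidence as the actual distribution.  The projected
excess absolute risk is then EAR = mu * OED, with mu the organ-specific risk
coefficient in cases per 10,000 person-years per Gy of OED.  An EAR of 1
means one additional malignancy per 1000 treated patients over 10 years.

Default coefficients shipped here: alpha = 0.129 (lung), 0.033 (thyroid),
0.274 (esophagus), 0.25 (breast); mu = 9.47 (lung), 0.86 (thyroid),
1.9 (esophagus), 2.49 (breast).  The coefficients are fixed: no age-at-
exposure or latency modification is applied, so the EARs are projections,
not absolute predictions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .dvh import DifferentialDVH, PatientRecord, mean_dose

__all__ = [
    "DoseResponseModel",
    "AlphaTable",
    "RiskCoefficientTable",
    "OrganRisk",
    "DEFAULT_ALPHAS",
    "DEFAULT_RISK_COEFFICIENTS",
    "red",
    "oed",
    "ear_from_oed",
    "excess_cases",
    "patient_risk_profile",
]

_FORMS = ("linear", "linear_exponential", "plateau")

#: Organ-at-risk label -> tissue carrying the coefficients.  The three lung
#: structures (combined, ipsilateral, contralateral) share the lung
#: coefficients.
ORGAN_TISSUE = {
    "breast_contralateral": "breast",
    "lungs_both": "lung",
    "lung_ipsilateral": "lung",
    "lung_contralateral": "lung",
    "thyroid": "thyroid",
    "esophagus": "esophagus",
}


@dataclass(frozen=True)
class DoseResponseModel:
    """RED functional form with its tissue parameter."""

    form: str = "linear_exponential"
    alpha: float | None = None  # per Gy, cell sterilization
    delta: float | None = None  # per Gy, plateau rate

    def __post_init__(self) -> None:
        if self.form not in _FORMS:
            raise ValueError(f"unknown dose-response form {self.form!r}; expected {_FORMS}")
        if self.form == "linear_exponential":
            if self.alpha is None or self.alpha < 0:
                raise ValueError("linear_exponential requires alpha >= 0")
        if self.form == "plateau":
            if self.delta is None or self.delta <= 0:
                raise ValueError("plateau requires delta > 0")


class _TissueTable:
    """Tissue -> coefficient mapping resolvable by organ-at-risk label."""

    def __init__(self, values: Mapping[str, float], name: str) -> None:
        for tissue, v in values.items():
            if v <= 0:
                raise ValueError(f"{name} for {tissue!r} must be positive, got {v}")
        self._values = dict(values)
        self._name = name

    def __getitem__(self, tissue: str) -> float:
        return self._values[tissue]

    def items(self):
        return self._values.items()

    def for_organ(self, organ: str) -> float:
        tissue = ORGAN_TISSUE.get(organ, organ)
        if tissue not in self._values:
            raise KeyError(
                f"no {self._name} for organ {organ!r} (tissue {tissue!r}); "
                f"known tissues: {sorted(self._values)}"
            )
        return self._values[tissue]

    def __repr__(self) -> str:  # provenance in run logs
        body = ", ".join(f"{k}={v}" for k, v in sorted(self._values.items()))
        return f"{type(self).__name__}({body})"


class AlphaTable(_TissueTable):
    """Cell-sterilization parameters alpha, per Gy, by tissue."""

    def __init__(self, values: Mapping[str, float]) -> None:
        super().__init__(values, "alpha")

    def model_for_organ(self, organ: str) -> DoseResponseModel:
        return DoseResponseModel("linear_exponential", alpha=self.for_organ(organ))


class RiskCoefficientTable(_TissueTable):
    """Risk coefficients mu, EAR per 10,000 person-years per Gy OED, by tissue."""

    def __init__(self, values: Mapping[str, float]) -> None:
        super().__init__(values, "risk coefficient mu")


DEFAULT_ALPHAS = AlphaTable({"lung": 0.129, "thyroid": 0.033, "esophagus": 0.274, "breast": 0.25})
DEFAULT_RISK_COEFFICIENTS = RiskCoefficientTable(
    {"lung": 9.47, "thyroid": 0.86, "esophagus": 1.9, "breast": 2.49}
)


@dataclass(frozen=True)
class OrganRisk:
    """OED (Gy) and projected EAR (per 10,000 person-years) of one organ."""

    organ: str
    oed: float
    ear: float


def red(dose, model: DoseResponseModel):
    """Risk-equivalent dose of ``dose`` (Gy, scalar or array) under ``model``."""
    d = np.asarray(dose, dtype=float)
    if np.any(d < 0):
        raise ValueError("dose must be non-negative")
    if model.form == "linear":
        out = d
    elif model.form == "linear_exponential":
        out = d * np.exp(-model.alpha * d)
    else:  # plateau
        out = (1.0 - np.exp(-model.delta * d)) / model.delta
    return float(out) if np.isscalar(dose) else out


def oed(d: DifferentialDVH, model: DoseResponseModel) -> float:
    """Organ equivalent dose: volume-weighted mean RED over the DVH bins."""
    return float(np.dot(d.bin_volumes, red(d.bin_centers, model)) / d.total_volume)


def ear_from_oed(
    oed_gy: float, organ: str, coeffs: RiskCoefficientTable = DEFAULT_RISK_COEFFICIENTS
) -> float:
    """Projected EAR = mu(organ) * OED, per 10,000 person-years."""
    if oed_gy < 0:
        raise ValueError("OED must be non-negative")
    return coeffs.for_organ(organ) * oed_gy


def excess_cases(ear: float, persons: float, years: float) -> float:
    """Expected excess malignancies in ``persons`` followed for ``years``."""
    if ear < 0 or persons < 0 or years < 0:
        raise ValueError("ear, persons and years must be non-negative")
    return ear * persons * years / 1e4


def patient_risk_profile(
    patient: PatientRecord,
    alphas: AlphaTable = DEFAULT_ALPHAS,
    coeffs: RiskCoefficientTable = DEFAULT_RISK_COEFFICIENTS,
    organs: tuple[str, ...] | None = None,
) -> dict[str, OrganRisk]:
    """OED and EAR for each requested organ of one patient.

    Raises ``KeyError`` naming the organ and patient when a DVH is missing.
    """
    wanted = tuple(patient.dvhs) if organs is None else tuple(organs)
    profile: dict[str, OrganRisk] = {}
    for organ in wanted:
        if organ not in patient.dvhs:
            raise KeyError(f"patient {patient.patient_id}: no DVH for organ {organ!r}")
        model = alphas.model_for_organ(organ)
        o = oed(patient.dvhs[organ], model)
        profile[organ] = OrganRisk(organ, o, ear_from_oed(o, organ, coeffs))
    return profile
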