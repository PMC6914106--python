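"""Framingham 10-year general-cardiovascular-disease risk.

Sex-specific Cox-model risk functions on log-transformed continuous
covariates (age, total and HDL cholesterol, systolic blood pressure with
separate treated/untreated coefficients) plus smoking and diabetes
indicators.  Risk is ``1 - S0(10)**exp(sum(beta*x) - mean_sum)``.

Coefficients are transcribed from the primary-care general-CVD risk profile
publication (D'Agostino et al., Circulation 2008) and verified against its
worked example (61-year-old woman, TC 180, HDL 47, untreated SBP 125->124,
smoker, non-diabetic: 10-year risk 10.5%).
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

AGE_RANGE = (30.0, 74.0)

_COEFFS = {
    "F": dict(ln_age=2.32888, ln_tc=1.20904, ln_hdl=-0.70833,
              ln_sbp_untreated=2.76157, ln_sbp_treated=2.82263,
              smoker=0.52873, diabetic=0.69154,
              baseline_survival=0.95012, mean_sum=26.1931),
    "M": dict(ln_age=3.06117, ln_tc=1.12370, ln_hdl=-0.93263,
              ln_sbp_untreated=1.93303, ln_sbp_treated=1.99881,
              smoker=0.65451, diabetic=0.57367,
              baseline_survival=0.88936, mean_sum=23.9802),
}


@dataclass(frozen=True)
class FraminghamProfile:
    """Covariates for one representative individual."""

    age: float
    sex: str                     # "F" or "M"
    systolic_bp: float
    bp_treated: bool
    smoker: bool
    diabetic: bool
    total_cholesterol: float
    hdl_cholesterol: float


def framingham_10yr_risk(profile: FraminghamProfile, clamp: bool = True) -> float:
    """10-year general-CVD risk in [0, 1] for ``profile``.

    Ages outside the equation's 30-74 validity range raise a warning and are
    clamped when ``clamp`` is true, else rejected.
    """
    sex = profile.sex.upper()[:1]
    if sex not in _COEFFS:
        raise ValueError(f"sex must be 'F' or 'M', got {profile.sex!r}")
    if profile.systolic_bp <= 0 or profile.total_cholesterol <= 0 or profile.hdl_cholesterol <= 0:
        raise ValueError("pressures and lipids must be positive")
    age = profile.age
    if not (AGE_RANGE[0] <= age <= AGE_RANGE[1]):
        if not clamp:
            raise ValueError(f"age {age} outside Framingham validity range {AGE_RANGE}")
        warnings.warn(f"age {age} outside Framingham validity range {AGE_RANGE}; clamping",
                      stacklevel=2)
        age = min(max(age, AGE_RANGE[0]), AGE_RANGE[1])

    c = _COEFFS[sex]
    s = (c["ln_age"] * math.log(age)
         + c["ln_tc"] * math.log(profile.total_cholesterol)
         + c["ln_hdl"] * math.log(profile.hdl_cholesterol)
         + (c["ln_sbp_treated"] if profile.bp_treated else c["ln_sbp_untreated"])
         * math.log(profile.systolic_bp)
         + c["smoker"] * float(profile.smoker)
         + c["diabetic"] * float(profile.diabetic))
    return 1.0 - c["baseline_survival"] ** math.exp(s - c["mean_sum"])


def annual_to_10yr(p1: float) -> float:
    """Constant-hazard conversion of an annual event probability to 10 years."""
    if p1 < 0:
        raise ValueError("annual probability must be >= 0")
    if p1 >= 1:
        raise ValueError("annual probability must be < 1")
    return 1.0 - (1.0 - p1) ** 10


def tenyr_to_annual(p10: float) -> float:
    """Constant-hazard conversion of a 10-year event probability to 1 year."""
    if p10 < 0:
        raise ValueError("10-year probability must be >= 0")
    if p10 >= 1:
        raise ValueError("10-year probability must be < 1")
    return 1.0 - (1.0 - p10) ** 0.1
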