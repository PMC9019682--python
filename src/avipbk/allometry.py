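"""Allometric scaling of small-intestine length with body weight.

Three single-predictor OLS forms:

- ``linear``: length (cm) vs body weight (g);
- ``log_log``: log10 length vs log10 weight — the allometric power law,
  whose slope is the scaling exponent;
- ``relative_vs_log``: relative length (cm per g body weight × 100) vs
  log10 weight.

Fits are ordinary least squares (statsmodels) on the transformed
variables; adjusted R² uses the single-predictor formula
1 − (1−R²)(n−1)/(n−2) and slope p-values are two-sided.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence, Tuple

import numpy as np
import statsmodels.api as sm
from pydantic import BaseModel, field_validator

__all__ = ["SpeciesPoint", "AllometricFit", "fit_allometry", "correlate_age"]

Form = Literal["linear", "log_log", "relative_vs_log"]


class SpeciesPoint(BaseModel):
    """One species' body weight (g) and small-intestine length (cm)."""

    species: str
    body_weight_g: float
    intestine_length_cm: float

    @field_validator("body_weight_g", "intestine_length_cm")
    @classmethod
    def _positive(cls, v: float) -> float:
        if not math.isfinite(v) or v <= 0:
            raise ValueError("weights and lengths must be finite and > 0")
        return v


@dataclass(frozen=True)
class AllometricFit:
    form: Form
    slope: float
    slope_se: float
    intercept: float
    adj_r2: float
    p_value: float
    n: int


def _transform(points: Sequence[SpeciesPoint], form: Form
               ) -> Tuple[np.ndarray, np.ndarray]:
    w = np.array([p.body_weight_g for p in points], dtype=float)
    l = np.array([p.intestine_length_cm for p in points], dtype=float)
    if form == "linear":
        return w, l
    if form == "log_log":
        return np.log10(w), np.log10(l)
    if form == "relative_vs_log":
        return np.log10(w), 100.0 * l / w
    raise ValueError(f"unknown form {form!r}")


def _ols_fit(x: np.ndarray, y: np.ndarray, form: Form) -> AllometricFit:
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("predictor has no variation (rank-deficient design)")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    slope = float(model.params[1])
    tss = float(((y - y.mean()) ** 2).sum())
    if tss == 0.0:
        # constant response: nothing to explain; slope is exactly 0
        r2, p, se = 0.0, 1.0, 0.0
    else:
        r2 = float(model.rsquared)
        p = float(model.pvalues[1])
        se = float(model.bse[1])
    return AllometricFit(
        form=form,
        slope=slope,
        slope_se=se,
        intercept=float(model.params[0]),
        adj_r2=float(1.0 - (1.0 - r2) * (n - 1) / (n - 2)),
        p_value=p,
        n=n,
    )


def fit_allometry(points: Sequence[SpeciesPoint], form: Form = "log_log"
                  ) -> AllometricFit:
    """Fit one of the three length-vs-weight regression forms."""
    for p in points:
        if form in ("log_log",) and (p.body_weight_g <= 0 or p.intestine_length_cm <= 0):
            raise ValueError(f"non-positive value under log transform: {p.species}")
    x, y = _transform(points, form)
    return _ols_fit(x, y, form)


def correlate_age(pairs: Sequence[Tuple[float, float]]) -> AllometricFit:
    """Linear OLS of intestine length on age (same contract as ``linear``)."""
    x = np.array([a for a, _ in pairs], dtype=float)
    y = np.array([l for _, l in pairs], dtype=float)
    return _ols_fit(x, y, "linear")
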