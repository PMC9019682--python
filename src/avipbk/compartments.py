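"""Body-fluid compartment bookkeeping, blood composition, and
yolk-precursor bio-concentration ratios.

Fluid spaces are carried as percent of body weight and must balance:
total body water = intracellular + extracellular, and extracellular =
plasma + interstitial.  Printed tables round to 0.1 percentage point, so
balance checks default to a 0.2-point tolerance (accepts rounding,
rejects transcription errors).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

from pydantic import BaseModel, field_validator

from . import units

__all__ = [
    "CompartmentProfile", "PrecursorPartition", "BalanceReport",
    "fluid_balance_check", "bioconcentration_ratio",
    "cardiac_output_per_kg", "convert_unit",
]


class CompartmentProfile(BaseModel):
    """Fluid spaces (% of body weight) and cardiovascular summary."""

    total_water_pct: float
    intracellular_pct: float
    extracellular_pct: float
    plasma_pct: float
    interstitial_pct: float
    hematocrit_pct: Optional[float] = None
    hemoglobin_g_dL: Optional[float] = None
    co_mL_min: Optional[float] = None
    co_mL_min_kg: Optional[float] = None
    body_weight_kg: Optional[float] = None

    @field_validator("total_water_pct", "intracellular_pct", "extracellular_pct",
                     "plasma_pct", "interstitial_pct", "hematocrit_pct")
    @classmethod
    def _pct_range(cls, v: Optional[float]) -> Optional[float]:
        if v is not None and not (0.0 <= v <= 100.0):
            raise ValueError(f"percentage {v} outside [0, 100]")
        return v


class PrecursorPartition(BaseModel):
    """Concentrations of one yolk precursor in plasma, yolk, interstitium."""

    analyte: str
    plasma_g_dL: float
    yolk_g_dL: float
    interstitial_g_dL: Optional[float] = None

    @field_validator("plasma_g_dL", "yolk_g_dL", "interstitial_g_dL")
    @classmethod
    def _nonneg(cls, v: Optional[float]) -> Optional[float]:
        if v is not None and v < 0:
            raise ValueError("concentrations must be >= 0")
        return v


@dataclass(frozen=True)
class BalanceReport:
    total_ok: bool
    ecw_ok: bool
    residual_total_pct: float
    residual_ecw_pct: float
    tol_pct: float


def fluid_balance_check(p: CompartmentProfile, tol_pct: float = 0.2) -> BalanceReport:
    """Report-only check of the two water-space balance identities."""
    r_total = abs(p.total_water_pct - (p.intracellular_pct + p.extracellular_pct))
    r_ecw = abs(p.extracellular_pct - (p.plasma_pct + p.interstitial_pct))
    return BalanceReport(
        total_ok=r_total <= tol_pct,
        ecw_ok=r_ecw <= tol_pct,
        residual_total_pct=r_total,
        residual_ecw_pct=r_ecw,
        tol_pct=tol_pct,
    )


def bioconcentration_ratio(p: PrecursorPartition,
                           reference: Literal["plasma", "interstitial"] = "plasma"
                           ) -> float:
    """Yolk concentration over the reference fluid concentration."""
    if reference == "plasma":
        ref = p.plasma_g_dL
    elif reference == "interstitial":
        if p.interstitial_g_dL is None:
            raise ValueError(f"no interstitial concentration for {p.analyte}")
        ref = p.interstitial_g_dL
    else:
        raise ValueError(f"reference must be 'plasma' or 'interstitial', got {reference!r}")
    if ref <= 0:
        raise ValueError(f"reference concentration must be > 0 for {p.analyte}")
    return p.yolk_g_dL / ref


def cardiac_output_per_kg(co_mL_min: float, body_weight_kg: float) -> float:
    """CO normalized by body weight, mL/(min·kg).

    Note: dividing an across-study mean CO by an assumed body weight does
    not in general reproduce a separately aggregated per-kg meta-mean — the
    per-kg studies are aggregated on their own scale.
    """
    if co_mL_min <= 0 or body_weight_kg <= 0:
        raise ValueError("cardiac output and body weight must be > 0")
    return co_mL_min / body_weight_kg


def convert_unit(value: float, from_unit: str, to_unit: str) -> float:
    """Exact linear unit conversion (see :mod:`avipbk.units`)."""
    return units.convert(value, from_unit, to_unit)
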