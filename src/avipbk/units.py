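"""Minimal linear unit registry for physiological quantities.

Covers the units that appear in avian physiology compendia: concentrations
(g/dL, g/L, mg/g), flows (mL/min, L/hr), per-body-weight rates, lengths
(um .. m), areas, small volumes (fL .. L), and mass-fraction percentages.
All conversions are linear scalings; dimensional compatibility is checked
against an explicit base-dimension vector (mass, length, time, volume,
count).  Unit strings are case-normalized through an alias table so that
e.g. ``g/dl`` and ``g/dL`` are the same unit.
"""

from __future__ import annotations

from fractions import Fraction
from typing import Dict, Tuple

__all__ = ["UnitError", "parse_unit", "convert", "is_convertible", "normalize_unit"]


class UnitError(ValueError):
    """Raised for unresolvable unit strings or incompatible dimensions."""


# dimension vector order: (mass, length, time, volume, count)
_DIM_NAMES = ("mass", "length", "time", "volume", "count")
Dim = Tuple[int, int, int, int, int]

_DIMLESS: Dim = (0, 0, 0, 0, 0)

# atomic units: symbol -> (dimension vector, scale to base unit as Fraction)
# base units: g, m, s, L, count
_ATOMIC: Dict[str, Tuple[Dim, Fraction]] = {
    # mass
    "g": ((1, 0, 0, 0, 0), Fraction(1)),
    "kg": ((1, 0, 0, 0, 0), Fraction(1000)),
    "mg": ((1, 0, 0, 0, 0), Fraction(1, 10**3)),
    "ug": ((1, 0, 0, 0, 0), Fraction(1, 10**6)),
    "ng": ((1, 0, 0, 0, 0), Fraction(1, 10**9)),
    "pg": ((1, 0, 0, 0, 0), Fraction(1, 10**12)),
    # length
    "m": ((0, 1, 0, 0, 0), Fraction(1)),
    "cm": ((0, 1, 0, 0, 0), Fraction(1, 100)),
    "mm": ((0, 1, 0, 0, 0), Fraction(1, 1000)),
    "um": ((0, 1, 0, 0, 0), Fraction(1, 10**6)),
    # time
    "s": ((0, 0, 1, 0, 0), Fraction(1)),
    "min": ((0, 0, 1, 0, 0), Fraction(60)),
    "hr": ((0, 0, 1, 0, 0), Fraction(3600)),
    "day": ((0, 0, 1, 0, 0), Fraction(86400)),
    # volume (its own base dimension; all table volumes are litre-family)
    "L": ((0, 0, 0, 1, 0), Fraction(1)),
    "dL": ((0, 0, 0, 1, 0), Fraction(1, 10)),
    "mL": ((0, 0, 0, 1, 0), Fraction(1, 10**3)),
    "uL": ((0, 0, 0, 1, 0), Fraction(1, 10**6)),
    "nL": ((0, 0, 0, 1, 0), Fraction(1, 10**9)),
    "pL": ((0, 0, 0, 1, 0), Fraction(1, 10**12)),
    "fL": ((0, 0, 0, 1, 0), Fraction(1, 10**15)),
    # dimensionless / count
    "1": (_DIMLESS, Fraction(1)),
    "count": ((0, 0, 0, 0, 1), Fraction(1)),
    "%": (_DIMLESS, Fraction(1, 100)),
    "fraction": (_DIMLESS, Fraction(1)),
    "fold": (_DIMLESS, Fraction(1)),
}

# aliases normalized before parsing (lower-cased key)
_ALIASES = {
    "g/dl": "g/dL",
    "g/l": "g/L",
    "mg/dl": "mg/dL",
    "ml/min": "mL/min",
    "ml/min/kg": "mL/min/kg",
    "ml/kg/min": "mL/min/kg",
    "l/hr/kg": "L/hr/kg",
    "l/h/kg": "L/hr/kg",
    "ml/hr/kg": "mL/hr/kg",
    "ml/h/kg": "mL/hr/kg",
    "pl": "pL",
    "fl": "fL",
    "h": "hr",
    "g/100g": "%",
    "g per 100 g": "%",
    "#/um2": "1/um2",
    "per_um2": "1/um2",
    "per_g": "1/g",
    "#/g": "1/g",
    "dimensionless": "1",
    "": "1",
    "pct": "%",
}

_CASE_MAP = {sym.lower(): sym for sym in _ATOMIC}


def _normalize_token(tok: str) -> Tuple[str, int]:
    """Split a token like ``um2`` or ``m^2`` into (symbol, exponent)."""
    tok = tok.strip().replace("^", "")
    if tok == "1":
        return "1", 1
    exp = 1
    if len(tok) > 1 and tok[-1].isdigit():
        exp = int(tok[-1])
        tok = tok[:-1]
    low = tok.lower()
    if tok in _ATOMIC:
        return tok, exp
    if low in _CASE_MAP:
        return _CASE_MAP[low], exp
    raise UnitError(f"unknown unit symbol {tok!r}")


def normalize_unit(unit: str) -> str:
    """Return the canonical spelling of ``unit`` (alias and case folding)."""
    key = unit.strip()
    key = _ALIASES.get(key.lower(), key)
    # re-join with canonical token case
    parts = key.split("/")
    out = []
    for part in parts:
        sym, exp = _normalize_token(part)
        out.append(sym if exp == 1 else f"{sym}{exp}")
    return "/".join(out)


def parse_unit(unit: str) -> Tuple[Dim, Fraction]:
    """Parse a unit string into (dimension vector, scale to base units).

    Supported grammar: ``A``, ``A/B``, ``A/B/C`` (= A per B per C); tokens
    may carry a small integer exponent (``um2``, ``m^2``).
    """
    key = unit.strip()
    key = _ALIASES.get(key.lower(), key)
    parts = key.split("/")
    dim = [0, 0, 0, 0, 0]
    scale = Fraction(1)
    for i, part in enumerate(parts):
        sym, exp = _normalize_token(part)
        d, f = _ATOMIC[sym]
        sign = 1 if i == 0 else -1
        for j in range(5):
            dim[j] += sign * exp * d[j]
        scale *= f**exp if sign == 1 else Fraction(1) / (f**exp)
    return tuple(dim), scale  # type: ignore[return-value]


def is_convertible(from_unit: str, to_unit: str) -> bool:
    try:
        da, _ = parse_unit(from_unit)
        db, _ = parse_unit(to_unit)
    except UnitError:
        return False
    return da == db


def convert(value: float, from_unit: str, to_unit: str) -> float:
    """Convert ``value`` between dimensionally compatible units.

    Scale factors are exact rationals, so round trips are exact up to one
    float rounding each way (<= 1e-12 relative for the factors in use).
    """
    da, fa = parse_unit(from_unit)
    db, fb = parse_unit(to_unit)
    if da != db:
        raise UnitError(
            f"incompatible dimensions: {from_unit!r} "
            f"({_dim_repr(da)}) vs {to_unit!r} ({_dim_repr(db)})"
        )
    return float(value * fa / fb)


def _dim_repr(dim: Dim) -> str:
    parts = [f"{n}^{e}" for n, e in zip(_DIM_NAMES, dim) if e != 0]
    return "·".join(parts) if parts else "dimensionless"
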