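"""Gut morphometric calculators: absorptive area and DNA-based cellularity.

The small-intestine absorptive area is built in three multiplicative
steps: (1) nominal area of a cylinder, A = π·d·L; (2) the villus
amplification factor VAF = 1 + π·L′·(2R′)·D′ from villus height L′,
diameter 2R′ and areal density D′ (all in μm, μm⁻²); (3) the microvillus
amplification factor MAF = 1 + π·L·(2R)·D from the brush-border geometry.
Villi and microvilli are treated as right circular cylinders; no tip-cap
correction is applied.

Tissue cellularity comes from the DNA concentration: cells per gram =
DNA (mg/g) × 10⁹ / diploid genome mass (pg).  Cell mass is the reciprocal
(in ng for ~10⁹ cells/g) and, at a tissue density of 1.0 kg/L, the cell
volume in pl is numerically equal to the mass in ng.

Genome mass is always an explicit argument: 2.19 pg/cell reproduces the
printed mucosal cellularity, while the hepatic calculations used
2.15 pg/cell; both defaults are exported as named constants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Literal, Sequence, Tuple

from pydantic import BaseModel, field_validator

__all__ = [
    "GENOME_MASS_PG_MUCOSA", "GENOME_MASS_PG_LIVER",
    "VillusGeometry", "MicrovillusGeometry", "GutSegmentGeometry",
    "CellularityResult", "villus_amplification_factor",
    "microvillus_amplification_factor", "nominal_cylinder_area",
    "segment_absorptive_area", "total_absorptive_area",
    "cells_per_gram", "cell_mass_volume", "villus_density_from_vaf",
]

GENOME_MASS_PG_MUCOSA = 2.19  # pg DNA per diploid chicken cell (mucosa tables)
GENOME_MASS_PG_LIVER = 2.15   # pg DNA per diploid chicken cell (hepatic tables)


class _PositiveGeometry(BaseModel):
    @field_validator("*")
    @classmethod
    def _positive(cls, v: float) -> float:
        if not math.isfinite(v) or v <= 0:
            raise ValueError("geometry values must be finite and > 0")
        return v


class VillusGeometry(_PositiveGeometry):
    """Villus geometry in μm: height L′, width 2R′, areal density D′ (μm⁻²)."""

    height_um: float
    width_um: float
    density_per_um2: float


class MicrovillusGeometry(_PositiveGeometry):
    """Microvillus geometry in μm: length L, diameter 2R, density D (μm⁻²)."""

    length_um: float
    diameter_um: float
    density_per_um2: float


class GutSegmentGeometry(BaseModel):
    segment: Literal["duodenum", "jejunum", "ileum", "ceca", "colon"]
    length_cm: float
    lumen_diameter_cm: float
    villus: VillusGeometry
    microvillus: MicrovillusGeometry

    @field_validator("length_cm", "lumen_diameter_cm")
    @classmethod
    def _positive(cls, v: float) -> float:
        if not math.isfinite(v) or v <= 0:
            raise ValueError("lengths and diameters must be finite and > 0")
        return v


@dataclass(frozen=True)
class CellularityResult:
    cells_per_g: float
    cell_mass_ng: float
    cell_volume_pl: float
    genome_mass_pg: float


def villus_amplification_factor(v: VillusGeometry) -> float:
    """VAF = 1 + π·L′·(2R′)·D′  (dimensionless, always >= 1)."""
    return 1.0 + math.pi * v.height_um * v.width_um * v.density_per_um2


def microvillus_amplification_factor(m: MicrovillusGeometry) -> float:
    """MAF = 1 + π·L·(2R)·D  (dimensionless, always >= 1)."""
    return 1.0 + math.pi * m.length_um * m.diameter_um * m.density_per_um2


def villus_density_from_vaf(vaf: float, height_um: float, width_um: float) -> float:
    """Invert the VAF formula for the areal density: D′ = (VAF−1)/(π·L′·2R′).

    Used to reconstruct unpublished villus densities from a tabulated VAF.
    """
    if vaf < 1:
        raise ValueError("VAF must be >= 1")
    if height_um <= 0 or width_um <= 0:
        raise ValueError("geometry must be > 0")
    return (vaf - 1.0) / (math.pi * height_um * width_um)


def nominal_cylinder_area(length_cm: float, lumen_diameter_cm: float) -> float:
    """Nominal (smooth-cylinder) mucosal area, cm²: A = π·d·L."""
    if length_cm <= 0 or lumen_diameter_cm <= 0:
        raise ValueError("length and diameter must be > 0")
    return math.pi * lumen_diameter_cm * length_cm


def segment_absorptive_area(g: GutSegmentGeometry) -> float:
    """Absorptive area of one segment, cm²: nominal × VAF × MAF."""
    return (nominal_cylinder_area(g.length_cm, g.lumen_diameter_cm)
            * villus_amplification_factor(g.villus)
            * microvillus_amplification_factor(g.microvillus))


def total_absorptive_area(segments: Sequence[GutSegmentGeometry],
                          body_weight_kg: float) -> Tuple[float, float]:
    """Total absorptive area over segments in m², and per kg body weight."""
    if not segments:
        raise ValueError("need at least one segment")
    if body_weight_kg <= 0:
        raise ValueError("body weight must be > 0")
    total_cm2 = math.fsum(segment_absorptive_area(g) for g in segments)
    total_m2 = total_cm2 / 1e4
    return total_m2, total_m2 / body_weight_kg


def cells_per_gram(dna_mg_per_g: float, genome_mass_pg: float) -> float:
    """Cells per gram of tissue = DNA (mg/g) × 10⁹ / genome mass (pg)."""
    if dna_mg_per_g <= 0 or genome_mass_pg <= 0:
        raise ValueError("DNA concentration and genome mass must be > 0")
    return dna_mg_per_g * 1e9 / genome_mass_pg


def cell_mass_volume(cells_per_g: float,
                     genome_mass_pg: float = float("nan")) -> CellularityResult:
    """Complete the cellularity bookkeeping from a cell count per gram.

    Mass per cell (ng) = 10⁹ / cells-per-gram; at density 1.0 kg/L the
    volume in pl equals the mass in ng numerically.
    """
    if cells_per_g <= 0:
        raise ValueError("cells_per_g must be > 0")
    mass_ng = 1e9 / cells_per_g
    return CellularityResult(cells_per_g=cells_per_g, cell_mass_ng=mass_ng,
                             cell_volume_pl=mass_ng, genome_mass_pg=genome_mass_pg)
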