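"""Controlled vocabulary of physiological parameter keys.

Keys are stable snake_case identifiers; intestinal parameters carry an
explicit segment suffix (``.duodenum`` / ``.jejunum`` / ``.ileum`` /
``.ceca`` / ``.colon``) and per-analyte concentrations carry the analyte
as suffix, so free-text drift cannot occur.  Each key maps to a
:class:`ParameterDefinition` with a canonical unit and optional plausibility
bounds used when validating aggregates.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Tuple

from pydantic import BaseModel, field_validator, model_validator

from . import units


class ParameterDefinition(BaseModel):
    key: str
    canonical_unit: str
    description: str = ""
    bounds: Optional[Tuple[float, float]] = None

    @field_validator("canonical_unit")
    @classmethod
    def _unit_resolvable(cls, v: str) -> str:
        units.parse_unit(v)  # raises UnitError if unresolvable
        return v

    @model_validator(mode="after")
    def _bounds_ordered(self) -> "ParameterDefinition":
        if self.bounds is not None and self.bounds[0] > self.bounds[1]:
            raise ValueError(f"bounds out of order for {self.key}: {self.bounds}")
        return self


SEGMENTS = ("duodenum", "jejunum", "ileum", "ceca", "colon")
SI_SEGMENTS = ("duodenum", "jejunum", "ileum")
ORGANS = (
    "heart", "liver", "kidneys", "spleen", "gizzard", "ovary", "oviduct",
    "small_intestine", "blood", "proventriculus", "duodenum", "jejunum",
    "ileum", "colon", "liver_arterial", "liver_portal", "muscle_pectoralis",
    "lungs", "infundibulum", "magnum", "isthmus", "uterus", "vagina",
    "cerebrum", "cerebellum",
)
ANALYTES = (
    "albumin", "alpha2_glycoprotein", "igy", "vitellogenin",
    "triglyceride", "phospholipids",
)


def _build() -> Dict[str, ParameterDefinition]:
    defs: List[ParameterDefinition] = []

    def add(key: str, unit: str, desc: str, bounds=None) -> None:
        defs.append(ParameterDefinition(key=key, canonical_unit=unit,
                                        description=desc, bounds=bounds))

    # fluid compartments (% of body weight)
    for k, d in [
        ("total_body_water_pct", "total body water"),
        ("intracellular_water_pct", "intracellular water"),
        ("extracellular_water_pct", "extracellular water"),
        ("plasma_pct", "plasma"),
        ("interstitial_fluid_pct", "interstitial fluid"),
    ]:
        add(k, "%", f"{d}, percent of body weight", (0.0, 100.0))

    # cardiovascular
    add("co_mL_min", "mL/min", "cardiac output")
    add("co_mL_min_kg", "mL/min/kg", "cardiac output per kg body weight")
    add("co_L_hr_kg", "L/hr/kg", "cardiac output per kg body weight")
    add("hematocrit_pct", "%", "hematocrit / packed cell volume", (0.0, 100.0))
    add("hemoglobin_g_dL", "g/dL", "blood hemoglobin")
    add("hepatic_portal_flow_mL_min", "mL/min", "hepatic portal blood flow")
    add("hepatic_portal_flow_mL_min_kg", "mL/min/kg",
        "hepatic portal blood flow per kg")

    # blood chemistry (g/dL)
    for k, d in [
        ("plasma_protein_g_dL", "total plasma/serum protein"),
        ("albumin_g_dL", "plasma/serum albumin"),
        ("igy_g_dL", "immunoglobulin Y"),
        ("iga_g_dL", "immunoglobulin A"),
        ("igm_g_dL", "immunoglobulin M"),
        ("vitellogenin_g_dL", "plasma vitellogenin"),
        ("triglyceride_g_dL", "plasma triglyceride"),
        ("cholesterol_g_dL", "plasma cholesterol"),
        ("phospholipids_g_dL", "plasma phospholipids"),
    ]:
        add(k, "g/dL", d)

    # yolk-precursor partitioning (per analyte)
    for a in ANALYTES:
        add(f"plasma_conc_g_dL.{a}", "g/dL", f"{a} in plasma/serum")
        add(f"yolk_conc_g_dL.{a}", "g/dL", f"{a} in egg yolk")
        add(f"interstitial_conc_g_dL.{a}", "g/dL", f"{a} in interstitial fluid")
        add(f"yolk_plasma_ratio.{a}", "1", f"yolk:plasma ratio for {a}")
        add(f"yolk_interstitial_ratio.{a}", "1", f"yolk:interstitial ratio for {a}")

    # organ relative weights and blood flows
    for org in ORGANS:
        add(f"rel_wt_g_100g.{org}", "g/100g",
            f"relative weight of {org}", (0.0, 100.0))
        add(f"blood_flow_mL_min.{org}", "mL/min", f"blood flow to {org}")

    # liver cellularity / composition
    add("liver_cells_per_g", "1/g", "hepatocyte number per gram liver")
    add("liver_cell_volume_fL", "fL", "liver cell volume")
    add("liver_lipid_g_100g", "g/100g", "liver lipid content", (0.0, 100.0))
    add("liver_dna_mg_g", "mg/g", "hepatic DNA concentration")

    # small-intestine morphometry (per segment)
    for seg in SEGMENTS:
        add(f"length_cm.{seg}", "cm", f"{seg} length")
        add(f"length_cm_kg.{seg}", "cm/kg", f"{seg} length per kg body weight")
        add(f"microvillus_length_um.{seg}", "um", f"{seg} microvillus length")
        add(f"microvillus_diameter_um.{seg}", "um", f"{seg} microvillus diameter")
        add(f"microvillus_density_per_um2.{seg}", "1/um2",
            f"{seg} microvillus density")
        add(f"maf.{seg}", "1", f"{seg} microvillus amplification factor",
            (1.0, float("inf")))
    for seg in SI_SEGMENTS:
        add(f"mucosa_thickness_um.{seg}", "um", f"{seg} mucosal thickness")
        add(f"mucosa_dna_mg_g.{seg}", "mg/g", f"{seg} mucosal DNA concentration")
        add(f"mucosa_cells_per_g.{seg}", "1/g", f"{seg} mucosal cellularity")
        add(f"mucosa_cell_mass_ng.{seg}", "ng", f"{seg} mucosal cell mass")
        add(f"villus_height_um.{seg}", "um", f"{seg} villus height")
        add(f"villus_width_um.{seg}", "um", f"{seg} villus width")
        add(f"vaf.{seg}", "1", f"{seg} villus amplification factor",
            (1.0, float("inf")))
    add("small_intestine_length_cm", "cm", "total small intestine length")

    # gastro-intestinal / accessory
    add("bile_production_mL_hr_kg", "mL/hr/kg", "bile production rate")
    add("absorptive_area_m2", "m2", "small-intestine absorptive area")
    add("absorptive_area_m2_kg", "m2/kg", "absorptive area per kg body weight")

    add("body_weight_kg", "kg", "body weight")

    return {d.key: d for d in defs}


VOCABULARY: Dict[str, ParameterDefinition] = _build()


def get_definition(key: str) -> ParameterDefinition:
    try:
        return VOCABULARY[key]
    except KeyError:
        known = ", ".join(sorted(VOCABULARY)[:12])
        raise KeyError(
            f"unknown parameter key {key!r}; known keys include: {known}, ..."
        ) from None
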