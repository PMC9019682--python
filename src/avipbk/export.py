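"""Assembly and serialization of unit-harmonized PBK parameter sets.

A :class:`PBKParameterSet` bundles, for one species and reproductive
state, the quantities a physiologically based kinetic model needs:
body weight, fluid-space fractions, organ weight fractions, flows
(L·hr⁻¹·kg⁻¹ for cardiac output), binding-relevant plasma concentrations
(g/L), gut geometry summaries, and hematology — every value with a unit
and a provenance record.

Missing values are filled along an explicit surrogate ladder and the
level used is always recorded:

1. species + state match (state relaxed within the species if needed,
   noted in provenance);
2. domesticated-duck surrogate, for mallard targets;
3. chicken surrogate.  With ``prefer_immature_surrogate=True`` the
   chicken surrogate prefers sexually immature females over laying hens
   (laying-specific physiology — yolk precursors, oviduct growth — does
   not transfer to a non-laying wild bird).

A parameter with no record at any level is exported as an explicit null
with a reason; there is no silent substitution.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import yaml
from pydantic import BaseModel, model_validator

from . import units
from .store import StudyRecord, query

__all__ = [
    "Provenance", "ParameterEntry", "PBKParameterSet",
    "assemble_parameter_set", "write_parameter_set", "read_parameter_set",
    "SchemaVersionError",
]

SCHEMA_VERSION = 1

BODY_WEIGHT_ASSUMPTIONS_KG = {"chicken": 1.6}  # tabulated per-kg CO assumes 1.6 kg

ORGANS_EXPORTED = ("heart", "liver", "kidneys", "spleen", "gizzard",
                   "ovary", "oviduct", "small_intestine", "blood")

# exported key -> (source parameter key, exported unit)
_EXPORT_MAP: List[Tuple[str, str, str]] = (
    [
        ("hematocrit_fraction", "hematocrit_pct", "fraction"),
        ("hemoglobin_g_L", "hemoglobin_g_dL", "g/L"),
        ("cardiac_output_L_hr_kg", "co_mL_min_kg", "L/hr/kg"),
        ("total_body_water_fraction", "total_body_water_pct", "fraction"),
        ("intracellular_water_fraction", "intracellular_water_pct", "fraction"),
        ("extracellular_water_fraction", "extracellular_water_pct", "fraction"),
        ("plasma_fraction", "plasma_pct", "fraction"),
        ("interstitial_fluid_fraction", "interstitial_fluid_pct", "fraction"),
        ("albumin_g_L", "albumin_g_dL", "g/L"),
        ("total_protein_g_L", "plasma_protein_g_dL", "g/L"),
        ("vitellogenin_g_L", "vitellogenin_g_dL", "g/L"),
        ("triglyceride_g_L", "triglyceride_g_dL", "g/L"),
        ("bile_production_mL_hr_kg", "bile_production_mL_hr_kg", "mL/hr/kg"),
        ("absorptive_area_m2", "absorptive_area_m2", "m2"),
        ("absorptive_area_m2_kg", "absorptive_area_m2_kg", "m2/kg"),
    ]
    + [(f"organ_fraction.{o}", f"rel_wt_g_100g.{o}", "fraction")
       for o in ORGANS_EXPORTED]
    + [(f"intestine_length_cm.{s}", f"length_cm.{s}", "cm")
       for s in ("duodenum", "jejunum", "ileum")]
)


class SchemaVersionError(ValueError):
    """Raised when a serialized parameter set has an unsupported version."""


class Provenance(BaseModel):
    source: str                     # fixture provenance string or derivation note
    surrogate_level: Optional[int] = None   # 1/2/3 when a value is present
    study_id: Optional[str] = None
    reason: Optional[str] = None    # populated when value is null

    @model_validator(mode="after")
    def _level_valid(self) -> "Provenance":
        if self.surrogate_level is not None and self.surrogate_level not in (1, 2, 3):
            raise ValueError("surrogate_level must be in {1, 2, 3}")
        return self


class ParameterEntry(BaseModel):
    value: Optional[float]
    unit: str
    provenance: Provenance

    @model_validator(mode="after")
    def _consistent(self) -> "ParameterEntry":
        units.parse_unit(self.unit)
        if self.value is not None and self.provenance.surrogate_level is None:
            raise ValueError("filled entries must record a surrogate level")
        if self.value is None and not self.provenance.reason:
            raise ValueError("null entries must carry a reason")
        if self.unit == "fraction" and self.value is not None:
            if not (0.0 <= self.value <= 1.0):
                raise ValueError(f"fraction {self.value} outside [0, 1]")
        return self


class PBKParameterSet(BaseModel):
    schema_version: int = SCHEMA_VERSION
    species: str
    repro_state: str
    body_weight_kg: Optional[ParameterEntry] = None
    entries: Dict[str, ParameterEntry] = {}

    def organ_fraction_sum(self) -> float:
        return sum(e.value for k, e in self.entries.items()
                   if k.startswith("organ_fraction.") and e.value is not None)

    def sanity_check(self, tol: float = 0.05) -> bool:
        """Mass bookkeeping: organ fractions and water spaces within 1.0.

        Organ weight fractions summed with the plasma space must not
        exceed unit body weight, nor may total body water; both checks
        carry a small tolerance for rounding of the printed inputs.
        """
        plasma = self.entries.get("plasma_fraction")
        total = self.organ_fraction_sum() + (
            plasma.value if plasma and plasma.value is not None else 0.0)
        blood = self.entries.get("organ_fraction.blood")
        if blood and blood.value is not None and plasma and plasma.value is not None:
            total -= plasma.value  # plasma already inside the blood fraction
        if total > 1.0 + tol:
            return False
        tbw = self.entries.get("total_body_water_fraction")
        if tbw and tbw.value is not None and tbw.value > 1.0 + tol:
            return False
        return True


def _state_preference(repro_state: str, prefer_immature: bool) -> List[str]:
    if prefer_immature:
        order = ["immature", repro_state, "unknown", "adult_nonlaying",
                 "laying", "broiler_juvenile"]
    else:
        order = [repro_state, "unknown", "adult_nonlaying", "laying",
                 "immature", "broiler_juvenile"]
    seen: List[str] = []
    for s in order:
        if s not in seen:
            seen.append(s)
    return seen


def _pick(records: Sequence[StudyRecord], species: str, parameter: str,
          states: Sequence[str]) -> Optional[StudyRecord]:
    candidates = query(records, species=species, parameter=parameter)
    for state in states:
        for rec in candidates:
            if rec.repro_state == state:
                return rec
    return None


def _ladder(records: Sequence[StudyRecord], species: str, repro_state: str,
            parameter: str, prefer_immature: bool
            ) -> Tuple[Optional[StudyRecord], Optional[int], Optional[str]]:
    """Walk the surrogate ladder; return (record, level, state_note)."""
    states = _state_preference(repro_state, prefer_immature=False)
    rec = _pick(records, species, parameter, states)
    if rec is not None:
        note = None if rec.repro_state == repro_state else (
            f"state relaxed to {rec.repro_state}")
        return rec, 1, note
    if species == "mallard":
        rec = _pick(records, "domestic_duck", parameter, states)
        if rec is not None:
            return rec, 2, "domestic duck surrogate"
    if species != "chicken":
        rec = _pick(records, "chicken", parameter,
                    _state_preference(repro_state, prefer_immature))
        if rec is not None:
            return rec, 3, f"chicken surrogate ({rec.repro_state})"
    return None, None, None


def _derive_body_weight(records: Sequence[StudyRecord], species: str
                        ) -> Optional[ParameterEntry]:
    if species in BODY_WEIGHT_ASSUMPTIONS_KG:
        return ParameterEntry(
            value=BODY_WEIGHT_ASSUMPTIONS_KG[species], unit="kg",
            provenance=Provenance(
                source="stated body-weight assumption for laying hens",
                surrogate_level=1))
    co = query(records, species=species, parameter="co_mL_min")
    co_kg = query(records, species=species, parameter="co_mL_min_kg")
    if co and co_kg and co_kg[0].value > 0:
        return ParameterEntry(
            value=co[0].value / co_kg[0].value, unit="kg",
            provenance=Provenance(
                source=f"derived: co_mL_min / co_mL_min_kg "
                       f"({co[0].study_id} / {co_kg[0].study_id})",
                surrogate_level=1))
    return ParameterEntry(
        value=None, unit="kg",
        provenance=Provenance(source="none", reason="no body-weight basis in store"))


def assemble_parameter_set(records: Sequence[StudyRecord], species: str,
                           repro_state: str,
                           prefer_immature_surrogate: bool = False,
                           overrides: Optional[Dict[str, float]] = None
                           ) -> PBKParameterSet:
    """Fill a PBK parameter set from the store along the surrogate ladder."""
    if species not in {"chicken", "mallard", "domestic_duck"}:
        raise ValueError(f"unknown species {species!r}")
    if repro_state not in {"laying", "immature", "adult_nonlaying",
                           "broiler_juvenile", "unknown"}:
        raise ValueError(f"unknown repro_state {repro_state!r}")
    overrides = overrides or {}
    entries: Dict[str, ParameterEntry] = {}
    for out_key, src_key, out_unit in _EXPORT_MAP:
        if out_key in overrides:
            entries[out_key] = ParameterEntry(
                value=overrides[out_key], unit=out_unit,
                provenance=Provenance(source="user override", surrogate_level=1))
            continue
        rec, level, note = _ladder(records, species, repro_state, src_key,
                                   prefer_immature_surrogate)
        if rec is None:
            entries[out_key] = ParameterEntry(
                value=None, unit=out_unit,
                provenance=Provenance(
                    source="none",
                    reason=f"no record for {src_key} at any surrogate level"))
            continue
        value = units.convert(rec.value, rec.unit, out_unit)
        src = rec.provenance or rec.citation or rec.study_id
        if note:
            src = f"{src} [{note}]"
        entries[out_key] = ParameterEntry(
            value=value, unit=out_unit,
            provenance=Provenance(source=src, surrogate_level=level,
                                  study_id=rec.study_id))
    return PBKParameterSet(
        species=species, repro_state=repro_state,
        body_weight_kg=_derive_body_weight(records, species),
        entries=entries,
    )


def write_parameter_set(pset: PBKParameterSet, path) -> None:
    """Serialize to a versioned YAML document plus a flat CSV twin."""
    path = Path(path)
    doc = pset.model_dump(mode="json")
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
    flat = path.with_suffix(".csv")
    with open(flat, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["key", "value", "unit", "surrogate_level", "source"])
        rows = [("body_weight_kg", pset.body_weight_kg)] + sorted(pset.entries.items())
        for key, e in rows:
            if e is None:
                continue
            w.writerow([key, "" if e.value is None else repr(e.value), e.unit,
                        e.provenance.surrogate_level or "", e.provenance.source])


def read_parameter_set(path) -> PBKParameterSet:
    """Read a YAML parameter set back; lossless including provenance.

    Units are normalized through the registry on read (so a hand-edited
    ``g/l`` becomes ``g/L``); a missing provenance block or an unsupported
    schema version is rejected.
    """
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    version = doc.get("schema_version")
    if version != SCHEMA_VERSION:
        raise SchemaVersionError(
            f"unsupported schema_version {version!r}; this build reads "
            f"{SCHEMA_VERSION}")
    for key, entry in (doc.get("entries") or {}).items():
        if "provenance" not in entry or entry["provenance"] is None:
            raise ValueError(f"entry {key!r} is missing its provenance block")
        entry["unit"] = units.normalize_unit(entry["unit"])
    return PBKParameterSet(**doc)
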