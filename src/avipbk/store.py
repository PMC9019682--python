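"""Study-level parameter records: data model, delimited-text I/O, filtering.

A :class:`StudyRecord` is one published study's mean for one parameter in
one species/state.  The packaged fixture files (one per source table)
additionally carry a ``provenance`` field of the form
``table=tab1;row=Hematocrit %;n_studies=10`` — fixture rows are printed
aggregate means (the per-study values behind them are not deposited), so
``n_studies`` rides along in provenance.
"""

from __future__ import annotations

import csv
import logging
import math
import re
import statistics
from importlib import resources
from pathlib import Path
from typing import Dict, Iterable, List, Literal, Optional, Sequence, Tuple

from pydantic import BaseModel, field_validator, model_validator

from . import units
from .vocab import VOCABULARY, ParameterDefinition, get_definition

logger = logging.getLogger(__name__)

__all__ = [
    "StudyRecord", "AggregateResult", "StoreParseError",
    "read_study_records", "write_study_records", "load_fixture_tables",
    "screen_outliers", "query", "FIXTURE_TABLES",
]

COLUMNS = [
    "study_id", "species", "sex", "repro_state", "parameter", "value",
    "unit", "n_birds", "dispersion_type", "dispersion_value", "citation",
]

SPECIES_BASE = {"chicken", "mallard", "domestic_duck"}
SEXES = {"female", "male", "mixed", "unknown"}
REPRO_STATES = {"laying", "immature", "adult_nonlaying", "broiler_juvenile", "unknown"}

FIXTURE_TABLES = ("tab1", "tab2", "tab3", "tab4", "tab5", "tab6", "tab7",
                  "tab8", "results_blood")

_MISSING = {"", "NA", "NR", "nan", "None"}


class StoreParseError(ValueError):
    """Raised when a delimited-text file cannot be parsed into records."""


class Dispersion(BaseModel):
    type: Literal["SD", "SEM"]
    value: float


class StudyRecord(BaseModel):
    study_id: str
    species: str
    sex: Literal["female", "male", "mixed", "unknown"]
    repro_state: Literal["laying", "immature", "adult_nonlaying",
                         "broiler_juvenile", "unknown"]
    parameter: str
    value: float
    unit: str
    n_birds: Optional[int] = None
    dispersion: Optional[Dispersion] = None
    citation: str = ""
    provenance: Optional[str] = None

    @field_validator("species")
    @classmethod
    def _species_valid(cls, v: str) -> str:
        if v in SPECIES_BASE or re.fullmatch(r"mammal:[a-z0-9_]+", v):
            return v
        raise ValueError(
            f"species must be one of {sorted(SPECIES_BASE)} or 'mammal:<name>', got {v!r}"
        )

    @field_validator("value")
    @classmethod
    def _finite(cls, v: float) -> float:
        if not math.isfinite(v):
            raise ValueError("value must be finite")
        return v

    @field_validator("unit")
    @classmethod
    def _unit_ok(cls, v: str) -> str:
        return units.normalize_unit(v)

    @field_validator("n_birds")
    @classmethod
    def _n_birds_pos(cls, v: Optional[int]) -> Optional[int]:
        if v is not None and v < 1:
            raise ValueError("n_birds must be >= 1 when present")
        return v

    @property
    def n_studies(self) -> Optional[int]:
        """Study count parsed from fixture provenance, if any."""
        if self.provenance:
            m = re.search(r"n_studies=(\d+)", self.provenance)
            if m:
                return int(m.group(1))
        return None

    @property
    def group(self) -> Tuple[str, str, str]:
        return (self.species, self.sex, self.repro_state)


class AggregateResult(BaseModel):
    """Mean of study means with across-study SEM ("Mean ± (n = studies) SEM")."""

    parameter: str
    group: Tuple[str, str, str]
    mean: float
    sem: Optional[float] = None
    n_studies: int
    excluded_study_ids: List[str] = []

    @model_validator(mode="after")
    def _consistent(self) -> "AggregateResult":
        if (self.sem is None) != (self.n_studies == 1):
            raise ValueError("sem must be undefined iff n_studies == 1")
        if self.n_studies < 1:
            raise ValueError("n_studies must be >= 1")
        defn = VOCABULARY.get(self.parameter)
        if defn is not None and defn.bounds is not None:
            lo, hi = defn.bounds
            if not (lo <= self.mean <= hi):
                raise ValueError(
                    f"mean {self.mean} outside bounds {defn.bounds} for {self.parameter}"
                )
        return self


def _parse_row(row: Dict[str, str], lineno: int,
               schema: Dict[str, ParameterDefinition]) -> Optional[StudyRecord]:
    key = row["parameter"].strip()
    if key not in schema:
        raise StoreParseError(
            f"row {lineno}: unknown parameter key {key!r} "
            f"(not in the supplied schema)"
        )
    raw = row["value"].strip()
    if raw in _MISSING:
        logger.warning("row %d: missing value (%r) for %s — skipped",
                       lineno, raw, key)
        return None
    try:
        value = float(raw)
    except ValueError:
        raise StoreParseError(
            f"row {lineno}, column 'value': malformed numeric cell {raw!r}"
        ) from None
    try:
        unit = units.normalize_unit(row["unit"].strip())
    except units.UnitError as e:
        raise StoreParseError(f"row {lineno}, column 'unit': {e}") from None

    n_raw = row.get("n_birds", "").strip()
    n_birds = None
    if n_raw not in _MISSING:
        try:
            n_birds = int(n_raw)
        except ValueError:
            raise StoreParseError(
                f"row {lineno}, column 'n_birds': malformed integer {n_raw!r}"
            ) from None

    disp = None
    dt = row.get("dispersion_type", "").strip()
    dv = row.get("dispersion_value", "").strip()
    if dt not in _MISSING and dv not in _MISSING:
        try:
            disp = Dispersion(type=dt, value=float(dv))
        except (ValueError, TypeError):
            raise StoreParseError(
                f"row {lineno}: malformed dispersion {dt!r}/{dv!r}"
            ) from None

    return StudyRecord(
        study_id=row["study_id"].strip(),
        species=row["species"].strip(),
        sex=row["sex"].strip(),
        repro_state=row["repro_state"].strip(),
        parameter=key,
        value=value,
        unit=unit,
        n_birds=n_birds,
        dispersion=disp,
        citation=row.get("citation", "").strip(),
        provenance=row.get("provenance", "").strip() or None,
    )


def read_study_records(path, schema: Optional[Dict[str, ParameterDefinition]] = None
                       ) -> List[StudyRecord]:
    """Read study records from a comma-delimited UTF-8 file with header.

    Rows with a missing-value marker (``NA``/``NR``/empty) are skipped with
    a logged warning; unknown parameter keys and malformed cells raise
    :class:`StoreParseError` naming the row (and column).
    """
    if schema is None:
        schema = VOCABULARY
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: List[StudyRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing_cols = [c for c in COLUMNS if c not in (reader.fieldnames or [])]
        if missing_cols:
            raise StoreParseError(
                f"{path.name}: header missing required columns {missing_cols}; "
                f"expected {COLUMNS}"
            )
        for lineno, row in enumerate(reader, start=2):
            rec = _parse_row(row, lineno, schema)
            if rec is not None:
                records.append(rec)
    return records


def write_study_records(records: Iterable[StudyRecord], path) -> None:
    """Write records in the same delimited layout ``read_study_records`` reads."""
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(COLUMNS + ["provenance"])
        for r in records:
            writer.writerow([
                r.study_id, r.species, r.sex, r.repro_state, r.parameter,
                repr(r.value), r.unit,
                "" if r.n_birds is None else r.n_birds,
                "" if r.dispersion is None else r.dispersion.type,
                "" if r.dispersion is None else repr(r.dispersion.value),
                r.citation, r.provenance or "",
            ])


def load_fixture_tables(tables: Optional[Sequence[str]] = None) -> List[StudyRecord]:
    """Load the packaged fixture tables (printed aggregates with provenance)."""
    tables = tuple(tables) if tables is not None else FIXTURE_TABLES
    records: List[StudyRecord] = []
    for tab in tables:
        if tab not in FIXTURE_TABLES:
            raise KeyError(f"unknown fixture table {tab!r}; known: {FIXTURE_TABLES}")
        ref = resources.files("avipbk.data") / f"{tab}.csv"
        with resources.as_file(ref) as p:
            records.extend(read_study_records(p))
    return records


def screen_outliers(records: Sequence[StudyRecord], k: float = 4.0,
                    two_sided: bool = False
                    ) -> Tuple[List[StudyRecord], List[Dict]]:
    """Leave-one-out k-SD screen for one parameter+group collection.

    A record is excluded when its value exceeds mean(others) + k·SD(others)
    (one-sided by default: values far *above* the rest).  Screening iterates
    to a fixed point so re-screening the kept set excludes nothing.  With
    fewer than 3 records no screening is performed.
    """
    if k <= 0:
        raise ValueError(f"k must be > 0, got {k}")
    kept = list(records)
    excluded: List[Dict] = []
    if len(kept) < 3:
        return kept, excluded
    changed = True
    while changed and len(kept) >= 3:
        changed = False
        for i, rec in enumerate(kept):
            others = [r.value for j, r in enumerate(kept) if j != i]
            mu = statistics.fmean(others)
            sd = statistics.stdev(others)
            hi = mu + k * sd
            lo = mu - k * sd
            out = rec.value > hi or (two_sided and rec.value < lo)
            if out:
                excluded.append({
                    "record": rec,
                    "loo_mean": mu,
                    "loo_sd": sd,
                    "threshold": hi if rec.value > hi else lo,
                })
                kept.pop(i)
                changed = True
                break
    return kept, excluded


def query(records: Sequence[StudyRecord], species: Optional[str] = None,
          sex: Optional[str] = None, repro_state: Optional[str] = None,
          parameter: Optional[str] = None) -> List[StudyRecord]:
    """Order-stable exact-match filter; ``None`` means no constraint.

    ``repro_state="unknown"`` matches only records labeled unknown — there
    are no implicit wildcards.
    """
    if parameter is not None:
        get_definition(parameter)  # raises KeyError listing known keys
    if sex is not None and sex not in SEXES:
        raise ValueError(f"unknown sex {sex!r}; known: {sorted(SEXES)}")
    if repro_state is not None and repro_state not in REPRO_STATES:
        raise ValueError(
            f"unknown repro_state {repro_state!r}; known: {sorted(REPRO_STATES)}")
    out = []
    for r in records:
        if species is not None and r.species != species:
            continue
        if sex is not None and r.sex != sex:
            continue
        if repro_state is not None and r.repro_state != repro_state:
            continue
        if parameter is not None and r.parameter != parameter:
            continue
        out.append(r)
    return out
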