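"""Synthetic inputs with the statistical structure the analyses assume.

The meta-analytic pipeline consumes collections of study means.  The
underlying per-study tables are not deposited with the source compendium,
so these generators emulate them: study means drawn from a normal
between-study law around a true parameter value, species points following
an allometric power law with log-normal residual scatter, and gut
geometries jittered multiplicatively around a species template.

All generators are pure functions of (spec, seed).  A single global seed
namespace is used: each generator derives its own deterministic substream
from the user seed via ``numpy.random.SeedSequence(seed, spawn_key=...)``.
"""

from __future__ import annotations

import warnings
from importlib import resources
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import yaml
from pydantic import BaseModel, field_validator, model_validator

from .allometry import SpeciesPoint
from .gut import (GutSegmentGeometry, MicrovillusGeometry, VillusGeometry,
                  villus_density_from_vaf)
from .store import StudyRecord
from .vocab import get_definition

__all__ = [
    "StudySetSpec", "generate_study_set", "generate_allometry",
    "generate_gut_geometry", "load_gut_template",
]

# substream ids keeping the generators independent under one seed
_STREAM_STUDY = 1
_STREAM_ALLOMETRY = 2
_STREAM_GUT = 3


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream,)))


class StudySetSpec(BaseModel):
    """Specification of a collection of study means for one parameter."""

    true_mean: float
    between_study_sd: float
    n_studies: int
    n_birds_range: Tuple[int, int] = (6, 30)
    seed: int = 0
    lognormal: bool = False

    @field_validator("between_study_sd")
    @classmethod
    def _sd_nonneg(cls, v: float) -> float:
        if v < 0:
            raise ValueError("between_study_sd must be >= 0")
        return v

    @field_validator("n_studies")
    @classmethod
    def _n_pos(cls, v: int) -> int:
        if v < 1:
            raise ValueError("n_studies must be >= 1")
        return v

    @model_validator(mode="after")
    def _range_valid(self) -> "StudySetSpec":
        lo, hi = self.n_birds_range
        if not (1 <= lo <= hi):
            raise ValueError(f"invalid n_birds_range {self.n_birds_range}")
        return self


def generate_study_set(spec: StudySetSpec, parameter: str,
                       group: Tuple[str, str, str] = ("chicken", "female", "laying")
                       ) -> List[StudyRecord]:
    """Draw study means from N(true_mean, between_study_sd²), reproducibly.

    With ``lognormal=True`` the between-study law is log-normal with the
    same mean and SD (for strictly positive parameters).
    """
    defn = get_definition(parameter)
    rng = _rng(spec.seed, _STREAM_STUDY)
    if spec.between_study_sd == 0:
        means = np.full(spec.n_studies, spec.true_mean)
    elif spec.lognormal:
        m, s = spec.true_mean, spec.between_study_sd
        sigma2 = np.log1p((s / m) ** 2)
        mu = np.log(m) - sigma2 / 2
        means = rng.lognormal(mu, np.sqrt(sigma2), spec.n_studies)
    else:
        means = rng.normal(spec.true_mean, spec.between_study_sd, spec.n_studies)
    n_birds = rng.integers(spec.n_birds_range[0], spec.n_birds_range[1] + 1,
                           spec.n_studies)
    species, sex, repro = group
    return [
        StudyRecord(
            study_id=f"sim-{parameter}-{i:03d}",
            species=species, sex=sex, repro_state=repro,
            parameter=parameter, value=float(v), unit=defn.canonical_unit,
            n_birds=int(n), citation="synthetic",
        )
        for i, (v, n) in enumerate(zip(means, n_birds))
    ]


def generate_allometry(n_species: int = 31, intercept: float = 0.9,
                       slope: float = 0.344, residual_sd_log10: float = 0.2,
                       weight_range_g: Tuple[float, float] = (10.0, 12000.0),
                       seed: int = 0) -> List[SpeciesPoint]:
    """Species points following log10 L = intercept + slope·log10 W + noise.

    Defaults emulate a 31-species small-intestine data set: scaling
    exponent 0.344 over body weights from small passerines (~10 g) to
    large waterfowl (~12 kg), with the residual SD (0.2 log10 units)
    chosen so the log-log fit's adjusted R² is about 0.69.
    """
    if n_species < 3:
        raise ValueError("need at least 3 species")
    lo, hi = weight_range_g
    if lo <= 0 or hi <= 0:
        raise ValueError("weights must be > 0")
    if lo == hi:
        warnings.warn("degenerate weight range: all species equal weight; "
                      "regression on these points will be rank-deficient")
    rng = _rng(seed, _STREAM_ALLOMETRY)
    logw = rng.uniform(np.log10(lo), np.log10(hi), n_species)
    logl = intercept + slope * logw + rng.normal(0.0, residual_sd_log10, n_species)
    return [
        SpeciesPoint(species=f"species_{i:02d}", body_weight_g=float(10 ** w),
                     intestine_length_cm=float(10 ** l))
        for i, (w, l) in enumerate(zip(logw, logl))
    ]


def load_gut_template(species: str = "chicken") -> Dict:
    """Load a packaged gut-geometry template (reconstructed fields noted)."""
    ref = resources.files("avipbk.data") / f"gut_geometry_{species}.yaml"
    try:
        text = ref.read_text(encoding="utf-8")
    except FileNotFoundError:
        raise KeyError(f"no gut geometry template for species {species!r}") from None
    return yaml.safe_load(text)


def _segment_from_template(name: str, seg: Dict) -> GutSegmentGeometry:
    vil = seg["villus"]
    density = vil.get("density_per_um2")
    if density is None:
        density = villus_density_from_vaf(vil["vaf_tabulated"],
                                          vil["height_um"], vil["width_um"])
    return GutSegmentGeometry(
        segment=name,
        length_cm=seg["length_cm"],
        lumen_diameter_cm=seg["lumen_diameter_cm"],
        villus=VillusGeometry(height_um=vil["height_um"], width_um=vil["width_um"],
                              density_per_um2=density),
        microvillus=MicrovillusGeometry(**seg["microvillus"]),
    )


def generate_gut_geometry(species_template: str = "chicken",
                          jitter_fraction: float = 0.0, seed: int = 0
                          ) -> List[GutSegmentGeometry]:
    """Gut segment geometries with multiplicative jitter around a template.

    Each positive geometry component is scaled by an independent factor
    drawn uniformly from [1 − j, 1 + j]; with j = 0 the template is
    returned exactly.  Amplification-factor invariants (VAF, MAF >= 1)
    are preserved for any admissible jitter (j < 0.5 keeps all values
    positive).
    """
    if not (0.0 <= jitter_fraction < 0.5):
        raise ValueError("jitter_fraction must be in [0, 0.5)")
    tpl = load_gut_template(species_template)
    rng = _rng(seed, _STREAM_GUT)

    def j(x: float) -> float:
        if jitter_fraction == 0.0:
            return float(x)
        return float(x * rng.uniform(1 - jitter_fraction, 1 + jitter_fraction))

    out = []
    for name, seg in tpl["segments"].items():
        base = _segment_from_template(name, seg)
        out.append(GutSegmentGeometry(
            segment=name,
            length_cm=j(base.length_cm),
            lumen_diameter_cm=j(base.lumen_diameter_cm),
            villus=VillusGeometry(
                height_um=j(base.villus.height_um),
                width_um=j(base.villus.width_um),
                density_per_um2=j(base.villus.density_per_um2),
            ),
            microvillus=MicrovillusGeometry(
                length_um=j(base.microvillus.length_um),
                diameter_um=j(base.microvillus.diameter_um),
                density_per_um2=j(base.microvillus.density_per_um2),
            ),
        ))
    return out
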