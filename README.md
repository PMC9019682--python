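# avipbk

Physiologically based kinetic (PBK) models predict the absorption,
distribution, metabolism and excretion of a chemical from the physiology
of the exposed animal. Building such a model for birds — the laying hen
(*Gallus gallus*) and the mallard (*Anas platyrhynchos*) are the two
species that matter most in avian toxicology and pesticide risk
assessment — requires a species-specific physiological parameter set:
fluid-compartment fractions, hematology, cardiac output, organ weight
fractions, plasma protein and lipid concentrations, gut geometry and
absorptive area, and tissue cellularity.

`avipbk` implements the derivation pipeline that turns study-level
literature values into such a parameter set, for modellers and
risk assessors who need transparent, provenance-tracked numbers:

- **Meta-analytic aggregation** — the unweighted mean of per-study means
  with its across-study standard error, `mean ± SEM, n = studies`;
  comparative statistics (percent differences, fold changes, Student *t*
  tests, one-way ANOVA with Dunnett's many-to-one test via a seeded
  Monte-Carlo reference distribution); and a one-sided leave-one-out
  4-SD outlier screen for anomalous study means.
- **Gut morphometry** — intestinal absorptive area in three
  multiplicative steps, A = π·d·L × VAF × MAF, with the villus
  amplification factor VAF = 1 + π·L′·(2R′)·D′ and the microvillus
  amplification factor MAF = 1 + π·L·(2R)·D; and DNA-based cellularity,
  cells/g = DNA(mg/g)·10⁹ / diploid genome mass (pg), with cell mass its
  reciprocal and cell volume numerically equal at tissue density 1 kg/L.
- **Compartment bookkeeping** — water-space balance checks
  (total = ICW + ECW; ECW = plasma + interstitium), yolk-precursor
  bio-concentration ratios (yolk : plasma), and an exact linear unit
  registry for the physiological units involved.
- **Allometry** — OLS fits of small-intestine length against body weight
  in linear, log₁₀–log₁₀ (power-law) and relative-length forms, with
  adjusted R², slope ± SE and two-sided p.
- **Provenance-tracked export** — PBK-ready parameter bundles per
  species and reproductive state, filled along an explicit surrogate
  ladder (species match → domestic duck → chicken), each value carrying
  its unit, source and surrogate level; serialized as versioned YAML
  plus a flat CSV.
- **Synthetic data** — seeded generators for study-mean collections,
  allometric species tables and jittered gut geometries, so every stage
  is testable without any download.

The per-study values behind the source tables were never deposited, so
the packaged fixtures carry the printed aggregates cell-for-cell with a
provenance column, and the synthetic generators emulate the underlying
study collections.

## Worked example

Per-segment absorptive-area breakdown for the chicken small intestine:

```sh
$ avipbk gut-area --species chicken
```

```
segment    VAF     MAF    area (cm²)
duodenum   11.62   37.6   25959
jejunum    9.04    26.0   31064
ileum      7.93    27.5   20779
total: 7.78 m², 4.86 m²/kg at 1.6 kg body weight
```

Each segment's area is its nominal cylinder area multiplied by the two
amplification factors; summing the three segments and dividing by the
1.6 kg laying-hen body weight gives the specific absorptive area. (The
lumen diameter in the packaged template is a reconstructed input — see
`docs/methods.md`.)

Comparing hematocrit between laying hens and mallards:

```sh
$ avipbk compare --parameter hematocrit_pct \
    --test-species chicken --test-state laying \
    --ref-species mallard --ref-state unknown
```

```json
{
  "parameter": "hematocrit_pct",
  "kind": "percent_lower",
  "test": {"group": "chicken/laying", "mean": 27.1},
  "reference": {"group": "mallard/unknown", "mean": 45.4},
  "statistic": 40.30837004405286
}
```

The laying hen's hematocrit is 40.3% below the mallard's — one of the
largest species differences in the compendium, and one that directly
affects the blood binding capacity a PBK model sees.

Other subcommands: `avipbk reproduce` (recompute every derivable table
value and compare at printed precision, reporting non-derivable cells as
"stored, not asserted"), `avipbk export --species mallard --state laying
--out mallard.yaml` (write a provenance-tracked parameter set),
`avipbk balance`, `avipbk allometry`, `avipbk simulate`.

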