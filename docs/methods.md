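# Methods

This note documents the models, numerical conventions and design
choices behind `avipbk`, in the spirit of a statistical package's
methods documentation. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Meta-analytic aggregation

The across-study summary of a physiological parameter is the
*unweighted* arithmetic mean of per-study means, reported with its
across-study standard error:

    mean = (1/n) Σ xᵢ,   SEM = s / √n,   s² = Σ (xᵢ − mean)² / (n − 1)

where each xᵢ is one study's mean and n is the number of studies. SEM
is undefined (carried as null) when n = 1. Studies are weighted equally
regardless of the number of birds each enrolled — the source compendium
reports means of study means, and per-study bird counts are often
unavailable; an n-weighted option exists behind a flag but is off by
default.

### Outlier screening

Anomalous study means are screened with a leave-one-out k-SD rule
(k = 4 by default): a study is excluded when its value exceeds
mean(others) + k·SD(others), computed over all other candidate studies.
Screening is one-sided (values *above* the rest), matching how the rule
was applied to implausibly high plasma-albumin reports; a flag enables
two-sided screening. The screen iterates to a fixed point, which makes
it idempotent (re-screening the kept set excludes nothing). With fewer
than three studies no screening is performed. Screening is off by
default and enabled per parameter — in the source analysis it was
applied only to albumin.

### Comparative statistics

Percent differences follow the "lower than" convention,
100·(reference − test)/reference, with a separate percent-increase form
100·(test − reference)/reference; fold change is the plain ratio.
Two-sample comparisons use the pooled-variance Student *t* by default
("Student's t test" is the stated method); Welch is available by flag.
Degenerate zero-variance inputs return t = 0, p = 1 for equal means and
an underflow-floored p (10⁻³⁰⁰) for unequal means.

Dunnett's many-to-one test is computed from first principles: the
observed statistics Tⱼ = (x̄ⱼ − x̄₀)/√(s²ₚ(1/nⱼ + 1/n₀)) are referred to
a seeded Monte-Carlo sample (50,000 draws by default) of the null
distribution of maxⱼ|Tⱼ|, simulated exactly (group means as N(0, 1/n),
pooled variance as χ²(df)/df, shared control and variance inducing the
many-to-one correlation). The adjusted p is the add-one Monte-Carlo
exceedance probability, floored at the unadjusted two-sided t p (an
exact lower bound). A Monte-Carlo reference was chosen over tabulated
critical values because it is transparent, works for unbalanced designs,
and is directly testable; `scipy.stats.dunnett` serves as an independent
cross-check in the tests, never as the implementation.

### Printed-precision comparison

When a recomputed quantity is compared with a figure printed in the
source tables, agreement is accepted within **one unit in the last
printed digit**. The printed derived statistics were evidently formed
from unrounded study means and sometimes truncated rather than rounded
(e.g. a hemoglobin difference of 40.26% printed as 40.2), so a half-ulp
rule would reject values that are arithmetically correct from the
printed inputs. One ulp accepts both rounding and truncation while still
rejecting transcription errors. This single rule is used everywhere
(`avipbk.meta.matches_printed`).

## Gut morphometry

The absorptive area of an intestinal segment is built in three
multiplicative steps, treating the segment as a cylinder and villi and
microvilli as right circular cylinders (no tip-cap correction):

    A_nominal = π · d · L                 (cm²)
    VAF = 1 + π · L′ · (2R′) · D′         (villus height, diameter, density)
    MAF = 1 + π · L · (2R) · D            (microvillus geometry)
    A = A_nominal · VAF · MAF

Amplification-factor geometry is carried in μm (densities in μm⁻²),
gross anatomy in cm; both factors are dimensionless and ≥ 1 by
construction, strictly increasing in every geometric component.

Cellularity from tissue DNA content:

    cells/g = DNA (mg/g) · 10⁹ / m_genome (pg)
    cell mass (ng) = 10⁹ / (cells/g)
    cell volume (pl) = cell mass (ng)     (tissue density 1.0 kg/L)

The diploid genome mass is always an explicit argument, never a buried
constant, because the source calculations used two values: 2.19 pg/cell
reproduces the tabulated mucosal cellularity (`GENOME_MASS_PG_MUCOSA`)
while the hepatic calculations cite 2.15 pg/cell
(`GENOME_MASS_PG_LIVER`).

### Reconstructed geometry inputs

Two inputs needed by the area calculation were never published and are
carried as flagged reconstructions in the packaged chicken template:

- **Villus density D′** is inverted from the tabulated villus
  amplification factors, D′ = (VAF − 1)/(π·L′·2R′), at template load
  time (≈ 9.0·10⁻⁶ μm⁻² for the duodenum).
- **Lumen diameter** is set to a uniform 0.7107 cm, the value at which
  the template's total absorptive area *as computed by this package*
  (nominal × VAF × MAF per segment, summed) equals the tabulated
  7.78 m² (4.86 m²/kg at 1.6 kg body weight). Note the tabulated
  jejunal MAF (38.8) is a literature mean from other studies; the MAF
  computed from the tabulated jejunal microvillus geometry is 26.0, and
  the reconstruction uses the computed value for internal consistency.

Because these are reconstructions, neither the tabulated VAFs nor the
absorptive-area totals are asserted by the reproduction checks; they are
reported as "stored, not asserted".

## Compartments and units

Fluid spaces are percentages of body weight and must satisfy two
identities: total body water = intracellular + extracellular, and
extracellular = plasma + interstitial. The balance check is report-only
with a default tolerance of 0.2 percentage points: printed values are
rounded to 0.1 points, so the laying-hen ECW split disagrees by exactly
0.1 (4.6 + 21.7 = 26.3 vs 26.2) — a rounding artifact the tolerance
accepts while still rejecting transcription errors. The mallard plasma
space comes from a different source pair than the other mallard fluid
spaces, so only the mallard total-water identity is asserted.

Bio-concentration ratios are yolk : plasma (or yolk : interstitial)
concentration ratios of yolk precursors, computed from the printed
(rounded) concentrations. Two printed ratios (albumin 0.61, IgY
interstitial 4.54) do not equal the ratio of their printed inputs
(0.635, 4.30) — the authors used unrounded means — and are therefore
stored but not asserted.

Unit conversion uses a small registry of atomic units with explicit
dimension vectors (mass, length, time, volume, count) and exact rational
scale factors, so conversions like 176 mL·min⁻¹·kg⁻¹ → 10.56 L·hr⁻¹·kg⁻¹
are exact to float rounding and round trips are identities to < 10⁻¹².
A registry was written in-package because the units involved are few and
fixed, and exactness on the 60/10/10⁴ factors is the property that
matters.

Dividing the absolute cardiac-output meta-mean (316 mL/min) by the
assumed 1.6 kg body weight gives 197.5 mL·min⁻¹·kg⁻¹, which does *not*
equal the separately aggregated per-kg meta-mean (176): studies
reporting per-kg values were aggregated on their own scale. The package
documents rather than hides this divergence.

## Allometry

Three single-predictor OLS forms relate small-intestine length to body
weight across species: linear (cm vs g), log₁₀–log₁₀ (the allometric
power law; the slope is the scaling exponent), and relative length vs
log₁₀ weight. Relative length is taken as length/weight × 100 (cm per g,
as a percentage) — the normalization is not fully specified in the
source and this is the natural reading. Adjusted R² uses the
single-predictor formula 1 − (1 − R²)(n − 1)/(n − 2); slope p-values are
two-sided. A constant response is reported as slope 0, p 1, with the
adjusted R² computed from R² = 0 (legitimately negative). The published
fits (adj R² 0.805/0.692/0.707; slopes 0.00454/0.344/−36.6 across 31
species) depend on an undeposited species table; they are carried as
reference metadata that the synthetic generator is tuned to mimic, not
as reproduction targets.

## Synthetic data

The generators emulate the statistical structure of the undeposited
study-level material; they are pure functions of (spec, seed), with
per-generator substreams derived from one seed namespace.

- **Study sets**: study means drawn from N(true mean, between-study
  SD²); a log-normal option (moment-matched) exists for strictly
  positive parameters. The hematocrit-like default conditions
  (mean 27.1, SD 2.7, 10 studies) correspond to the tabulated
  across-study SEM of 0.86·√10 ≈ 2.7.
- **Allometric tables**: 31 species with log₁₀ weights uniform between
  10 g and 12 kg (small passerine to large waterfowl), slope 0.344,
  intercept 0.9 (a 1.6 kg bird then has a ~100 cm small intestine), and
  residual SD 0.2 log₁₀ units — the value at which the log-log adjusted
  R² averages ≈ 0.69, matching the published fit quality.
- **Gut geometries**: multiplicative jitter (uniform in [1−j, 1+j],
  j < 0.5) around the species template; positivity, hence the
  VAF/MAF ≥ 1 invariants, is preserved for any admissible jitter.

What the generators do **not** emulate: publication bias, heteroscedastic
study quality, within-study bird-level variance structure, phylogenetic
correlation among species, or covariance between parameters. Passing
tests therefore demonstrate the correctness and calibration of the
pipeline's arithmetic and statistics under the stated noise model, not
the field validity of the literature values themselves.

## Export and the surrogate ladder

Parameter sets are filled in priority order: (1) records for the
requested species (preferring the requested reproductive state, then
unlabeled, then other states — any relaxation is noted in provenance);
(2) domesticated-duck records, for mallard targets; (3) chicken records.
The level used (1/2/3) is recorded on every filled value; a parameter
with no record at any level is exported as an explicit null with a
reason. The optional `prefer_immature_surrogate` policy makes the
chicken rung prefer sexually immature females over laying hens, because
laying-specific physiology (circulating vitellogenin and triglyceride,
oviduct hypertrophy) does not transfer to a non-laying wild bird.

Exports are unit-harmonized (fractions for percentages, g/L for blood
chemistry, L·hr⁻¹·kg⁻¹ for cardiac output) and serialized as a versioned
YAML document plus a flat CSV twin. Reading rejects unknown schema
versions and entries lacking a provenance block, and normalizes unit
spellings. Mallard body weight is not tabulated; it is derived as the
ratio of the absolute and per-kg cardiac-output means (1203/416 ≈
2.89 kg) with the derivation recorded in provenance.

A sanity bound checks that exported organ fractions (each required to be
below 0.25) plus the plasma space do not exceed unit body weight (the
plasma term is dropped when a whole-blood fraction is present, since
plasma is part of blood), and that total body water stays ≤ 1, both with
a 0.05 tolerance for rounded inputs.

## Problem sizes and determinism

Calibration checks use 5,000 simulated null replicates (t-test type-I
error; Dunnett familywise error against the package's own 50,000-draw
Monte-Carlo null), 1,000 seeds for aggregation coverage, and 100–200
seeds for allometric calibration — sizes at which the binomial noise of
the estimated rates is several times smaller than the width of the
acceptance bands. All stochastic components are seeded; repeated runs
are byte-identical.

## Known limitations

- Fixture records are printed aggregates; statistics that would need the
  underlying per-study values (exact reproduction of published p-values
  and regression coefficients) are out of reach by construction.
- The unit registry covers the fixed set of physiological units used
  here; it is not a general quantity calculus.
- Blood-flow entries carry a reliability flag (the two available ovary
  estimates disagree several-fold) and are exported as data, not
  endorsed values.
- The liver cell-volume entries (526/682 fL) are inconsistent with the
  reciprocal-cellularity formula at density 1.0 even under the stated
  90%-cells assumption; they are stored and flagged, never derived.
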