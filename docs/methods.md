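# Methods

## Phenotyping rules

The classifier is a deterministic rule walk over a patient's coded events,
evaluated against an explicit `index_date` (the "query date"); nothing
depends on the wall clock or on event ordering.

**Case criterion (V2).** A qualifying AMD diagnosis is an ICD-9 code from
the exact set {362.50, 362.51, 362.52, 362.16, 362.57} on a `DIAGNOSIS`
event entered by an ophthalmologist (`provider_specialty = OPHTHALMOLOGY`;
the requirement can be disabled). "≥2 visits with AMD codes" is
implemented as ≥2 *distinct calendar dates* bearing qualifying diagnoses:
EMRs routinely duplicate a code within one encounter, so distinct dates
are the robust proxy for distinct visits. Age is completed whole years
(floor) at the first qualifying date, the standard clinical convention;
the boundary (60th birthday itself qualifies) is pinned by tests.

**Wet criterion (V2).** Among established cases only — mirroring the
algorithm's flow, an injection never creates a case — a date must carry
both an anti-VEGF exposure (HCPCS procedure J2778/J9035/J3490/J3590, or a
medication order matching a configurable synonym list:
ranibizumab/Lucentis, bevacizumab/Avastin, aflibercept/Eylea) and a
diagnosis whose code *starts with* 362.5. Prefix matching operates on the
literal decimal string, so codes are stored as strings, never floats:
`362.5` (prefix) covers 362.50–362.57 while `362` (exact) matches only the
bare three-digit code. Cases that never meet the wet criterion are dry.

**Control criterion.** An ophthalmology-attributed event in the half-open
window `(index_date − lookback, index_date]` (lookback 2 years by
default), age ≥60 at that event (V2), and *no* diagnosis ever matching the
control-exclusion set. That set defaults to the AMD codes plus the 362.5x
prefix and is user-extensible with further "AMD-associated" codes; the
non-specific codes `362` and `377.21` are deliberately excluded from it —
we read the source material's ambiguous parenthetical as whitelisting
those codes rather than disqualifying their carriers, and the set is
configurable precisely because the full associated-code list is not
enumerated anywhere.

**Versions.** V1 reproduces the pilot form of the rules: one qualifying
diagnosis date suffices, no age gates anywhere, and any injection makes a
case wet regardless of same-date coding. V2's criteria are strictly
stronger, so V2 cases are a subset of V1 cases (property-tested). Patients
meeting neither case nor control criteria are `UNCLASSIFIED`; every
patient receives exactly one label, and a case (≥2 AMD dx dates) can never
simultaneously satisfy the control criterion (no AMD dx ever).

## Chart-review metrics

All metrics are exact rationals on the 3×3 algorithm-vs-expert table.
For a positive class P: PPV = TP/(TP+FP), NPV = TN/(TN+FN),
FNR = FN/(FN+TP). Subtype rows treat "not called X" (the other subtype
plus controls) as test-negative; this is the only collapse under which the
published subtype NPVs and FNRs are simultaneously reproducible.
`overall_accuracy` is the binary AMD-vs-control agreement; the stricter
3-class trace agreement is reported separately as
`three_class_agreement`. Zero-denominator metrics carry an explicit
undefined marker — silently reporting 0 or 1 would corrupt aggregates.

The 100-chart fixture is a *synthetic reconstruction*: the unique 3×3
assignment consistent with every published figure (dry bin 22/4/4, wet bin
26/3/1, control bin 39 non-AMD + 1 missed wet pathology). The 20-chart
pilot fixture pins only 9 correct / 11 incorrect — the text does not
determine the dry/wet split of the correct charts — so it supports only
the accuracy computation.

## Synthetic EMR generator

Each patient draws from an independent stream seeded by `(seed, patient
index)`, so cohorts are byte-reproducible and enlarging `n_patients`
extends rather than reshuffles. Ages come from a truncated normal
(mean 70, sd 12, range 40–95): the cohort deliberately spans well below
the 60-year gate so age criteria are exercised, matching a biorepository
open to all ages. Default class mix: 5% true dry, 3% true wet, 7%
mimicker, 85% healthy — AMD enriched relative to the general population,
as in an ophthalmology-heavy EMR. Mimicker types and their own ICD-9
codes: diabetic retinopathy (362.01), pattern dystrophy (362.76), central
serous chorioretinopathy (362.41), polypoidal choroidal vasculopathy
(363.8), macular scar (363.32) — none inside the AMD code family, so an
un-miscoded mimicker is a legitimate control.

Noise knobs plant the documented failure modes: `p_miscode_amd` (default
0.10) gives a mimicker AMD codes on two dates — and, for the wet-like
mimickers PCV and macular scar, an injection with a same-date 362.5x code,
the classic wet false positive; `p_missed_second_visit` (0.05) leaves a
true case with a single coded date; `p_injection_coded_same_date` (0.90)
controls whether a wet case's injection carries the same-date diagnosis;
`p_specialty_other` (0.05) attributes a diagnosis to a non-ophthalmologist.
In the noise-free limit the phenotyper achieves PPV 1 and FNR 0 against
planted truth among classified patients, and raising `p_miscode_amd`
strictly lowers PPV (both tested).

What the generator does *not* emulate: longitudinal dry→wet progression,
per-eye laterality, free-text notes, visit-level billing structure, and
correlated comorbidity coding. Passing tests therefore certify the rule
logic and its noise response, not performance on any real EMR.

## Association statistics

`fit_logistic_additive` is a from-scratch IRLS maximum-likelihood fit
(intercept + dosage + covariates): convergence when the maximum absolute
score < 1e-8 or the relative log-likelihood change < 1e-10, at most 50
iterations. Complete separation is *diagnosed* — log-likelihood
approaching 0 or diverging coefficients raise `SeparationError` — rather
than surfacing as silent non-convergence; a constant or collinear
predictor raises `RankDeficiencyError` before iteration. The fit is
cross-checked against `statsmodels.Logit` in the test suite, and the
unadjusted binary-exposure OR against the 2×2 cross-product ratio at
1e-6 relative.

Inference is Wald (matching the convention of the standard GWAS toolchain):
OR = exp(β), CI = exp(β ± z₀.₉₇₅·SE), two-sided normal P. Imputed
dosages enter the regression as continuous expected counts, never rounded;
hard calls are integers. Sex is coded 0/1 (female reference), smoking
ever/never 0/1; samples with missing covariates are dropped per model
(complete case) with counts reported per SNP. The pooled allelic 2×2 path
(`method="allelic_2x2"`) uses the Woolf log-scale interval with a 0.5
continuity correction applied only when a cell is zero and a 1-df χ²
without continuity correction; because the count table requires integers,
expected-dosage sums are rounded to the nearest allele count there (the
regression path is the default output). Imputation quality (info ≥ 0.75)
is accepted as an upstream input flag; the info statistic itself is out of
scope, as is any LD, population-structure or genome-wide machinery.

`pool_and_associate` merges disjoint imputed and directly genotyped sample
sets over shared SNPs (a SNP present in one source only is analyzed on the
available samples with a warning), applies the European-ancestry filter
when the pheno table carries `ancestry_european`, and flags significance
at the Bonferroni threshold α/m across the configured panel size (m = 11
by default, giving 0.05/11 ≈ 4.5×10⁻³).

## Genotype simulator

Population genotypes are Hardy–Weinberg at the specified risk-allele
frequency; disease follows the additive logistic model with the intercept
solved (Brent's method) so the population prevalence hits its target
(default 0.10, a plausible figure for AMD in an over-60 clinic
population). Without covariates, case and control genotype distributions
are sampled from their exact conditional laws — equivalent to
retrospective sampling at any requested size without rejection; with a
covariate model (`name → (mean, sd, beta)`; sd = 0 makes a Bernoulli
covariate), statuses are rejection-sampled from the population and an
unattainable case count raises. Calibration at the study's own sample
size (57 cases / 142 controls, planted OR 2.43 at control RAF 0.363) is
measured over 500 replicates: 95%-CI coverage and type-I error at
α = 0.05 sit within binomial noise of nominal.

## Problem sizes and numerical choices

The shipped tests and the acceptance script use a 5,000-patient synthetic
cohort for rule properties, 1,200–1,500 patients for generative checks,
100 random tables for the OR-equivalence oracle, and 500 replicates for
each calibration estimate — sizes chosen so binomial/3-SE bounds are
meaningful while the whole suite runs in seconds. All randomness flows
from explicit integer seeds through `numpy.random.Generator`
(seed-sequence spawning per patient/replicate); there are no hidden RNG
defaults, and reruns are byte-identical.

## Known limitations

* The published per-SNP ORs and P values are not reproducible from first
  principles — the underlying individual-level EMR and genotype data are
  not public — so the association machinery is certified by planted-
  parameter recovery and calibration instead.
* The phenotyper has no per-eye resolution (ICD-9/CPT codes are not
  eye-linked) and no free-text/NLP signal.
* The control-exclusion code list is a conservative default, not a
  complete nosology of "AMD-associated" diagnoses; extend it via
  configuration for stricter control hygiene.
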