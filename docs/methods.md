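# Methods

## The twin variance-decomposition model

For a trait standardized within the cohort, each twin pair is modelled as
zero-mean bivariate normal with common variance `v = vA + vC + vE` and
cross-twin covariance `vA + vC` for monozygotic (MZ) pairs and
`vA/2 + vC` for dizygotic (DZ) pairs.  The model rests on the equal
environment assumption — MZ and DZ pairs share environment to the same
degree, so excess MZ similarity is attributed to additive genetic variance —
and on the absence of dominance and assortative mating (no ADE or
sex-limitation models; the emulated cohort is all-female).

Fitting is maximum likelihood over the raw variance components with
components constrained nonnegative (L-BFGS-B from three fixed starting
points: shares 1/3:1/3:1/3, 0.6:0.1:0.3 and 0.1:0.6:0.3 of the total sample
variance; the unique-environment variance is bounded strictly above zero so
the pair covariance matrix stays positive definite).  Means are removed and
the scale freed: traits are pre-standardized, the likelihood carries no mean
parameters, and results are reported as shares `a², c², e²` summing to 1.
Because pairs are exchangeable, the likelihood depends on the data only
through per-zygosity sums of `x₁² + x₂²` and `x₁x₂`; every evaluation is
closed-form in these sufficient statistics, which is what makes the power
and coverage simulations cheap.

Covariate adjustment (age, batch) is by pre-residualization rather than
joint estimation: residuals of the trait on age and batch indicators are
rescaled to unit variance before the twin likelihood sees them.  This keeps
the pair likelihood two-dimensional and matches the reported
"adjusted" analysis; only a linear age term is used.

**Model selection.** Starting from ACE, C and A are dropped sequentially and
each drop tested by a likelihood-ratio test at α = 0.05 (χ² reference, df =
parameters removed; E is tested against ACE with df 2).  Drops with p ≥ α
survive; among surviving models the lowest AIC (−2ℓ + 2k) wins, with exact
ties broken toward fewer parameters and AE over CE.  The plain χ² reference
is used although the null value a² = 0 sits on the parameter boundary —
this is the convention of the era the analysis emulates and makes the test
conservative (measured size ≈ 0.02 at α = 0.05 under a pure-noise null); a
`mixture` flag switches the power simulation to the 50:50 χ²₀/χ²₁ mixture
reference for sensitivity analyses.

**Intervals.** Component CIs are profile-likelihood intervals on the
standardized shares: values whose profiled log-likelihood (inner
maximization over the remaining share split, total variance profiled in
closed form) lies within χ²₁(0.95)/2 ≈ 1.921 of the maximum, truncated to
[0, 1].  Coverage measured by simulation at the cohort's size (530 pairs,
a² = 0.6, AE truth) is ≈ 95%.  The intra-class correlation uses the
double-entry Pearson convention with a Fisher-z CI on the number of pairs;
the one-way ANOVA ICC is used only as a test oracle (the two agree within
0.02 at 200 pairs).

**Heritability classes.** A trait is "low heritability" when its selected
model has no additive component or when `a² ≤ 0.35`.  The threshold is
inclusive: published per-trait flags treat a trait sitting exactly at 0.35
as not-high, and the inclusive rule reproduces the 12-trait low class.

**Design power.** Power for the additive component is estimated by
simulation: each replicate draws the full cohort, fits all four submodels,
picks the best A-containing model by the shared-environment drop (LRT at
α), and tests it against its A-free counterpart (AE vs E, or ACE vs CE)
with a 1-df LRT.  At 220 MZ + 310 DZ pairs, a² = 0.4, the measured power is
≈ 89% for c² = 0.1 and ≈ 100% for c² = 0.5 (1000 replicates).  The original
design description quotes 95% across this range from an external power
calculation; our Monte-Carlo value for the low-c² arm is lower under the
plain-χ² sequential procedure (the mixture reference gives ≈ 92%, and a
pure familial AE-vs-E test — which does not separate A from C — reaches
100%).  We report the procedure-faithful number.

## Glycan traits

The 24 UPLC peaks are mapped to structural features (core fucose F,
bisecting GlcNAc B, galactose count G0–G2, sialic acid count S1–S2) by an
editable annotation table.  Only four assignments are fixed by the source
analysis (GP4 = FA2, GP8/GP9 = FA2G1, GP14 = FA2G2, GP21 = A2G2S2); the
remainder is the conventional IgG UPLC assignment and is flagged
`conventional` in the shipped file, so alternative annotations can be
substituted without touching code.

Derived traits are ratios of feature-group sums written in a small grammar
(see the `glycans` module docstring): e.g. `FGS/(FG+FGS)` is the
sialylation rate of fucosylated galactosylated structures, and an `n`
suffix moves a group onto the neutral basis, where each asialylated peak is
renormalized to % of the summed asialylated peaks.  The shipped definition
file reproduces the 76-trait panel of the emulated study (22 directly
measured peaks + 54 derived traits; the source text also mentions 53
derived traits, i.e. 77 in total, but its per-trait table lists 76 rows —
the shipped panel follows the table, and the discrepancy is simply
recorded).  Scales (ratio, percent, permille) follow the published trait
magnitudes.  Division by zero yields missing values, not exceptions, so
cohort stages can drop affected samples.

## EWAS

Probes are column-standardized (mean 0, unit sample variance; constant
probes dropped).  Each (probe, trait) pair is tested with a linear
family-random-intercept model estimated by REML — the statsmodels MixedLM
implementation — with fixed effects for age, BMI and categorical chip /
chip-position / batch indicators; aliased design columns are dropped with a
warning.  Although the emulated analysis describes "random intercept
logistic regression", the outcomes are continuous glycan traits and the
published effect sizes are linear betas with SEs, so the linear model is
the default and a `dichotomize` switch (median split + cluster-robust GEE
logistic) exists for sensitivity only.  Wald p-values use the normal
reference by default (t on residual df by flag).  Standard errors are
model-based GLS errors, `sqrt(diag((X'V̂⁻¹X)⁻¹))` with the block-diagonal
compound-symmetric V̂ — the lme4 convention — which collapses exactly to
OLS when the family-variance estimate hits the zero boundary (the
equivalence is a test oracle).  Zygosity is not a default covariate
(adjusting for it is reported not to change results); a flag adds it.

Array-wide significance is Bonferroni: α / n_probes, e.g.
0.05 / 24,641 ≈ 2.03×10⁻⁶, reported to one significant figure as 2×10⁻⁶.

## Enrichment

Hits are counted by association *row* (probe × trait pair) while
denominators are trait-class sizes — the counting convention of the
emulated report (5/12 vs 4/64).  A trait with several hits can therefore
push its class numerator above the trait count; the complementary cell then
floors at zero (documented quirk).  The primary test is the one-sided
Fisher exact tail computed by log-factorial hypergeometric enumeration
(cross-checked in tests against full enumeration and scipy); a Pearson χ²
and a Haldane-corrected odds ratio accompany it, since the emulated report
states only a p bound without naming its test.  Reported class percentages
are truncated (not rounded) to one decimal, which reproduces the published
41.6% / 6.2% from 5/12 and 4/64.  Group comparisons from printed summary
statistics use the Welch unequal-variance t-test (the published age
comparison reproduces p = 0.14; the published BMI p of 0.60 does not
reproduce from its summaries — Welch gives 0.62 — suggesting a
differently specified test, and is not used as an oracle).

## The synthetic cohort generator

Defaults emulate the study conditions: 220 MZ + 310 DZ all-female pairs;
ages drawn per pair (co-twins identical, both zygosity groups from one law,
mean ≈ 58.4, SD ≈ 9.5); BMI individual (≈ 26.6 ± 4.8); batch assigned at
random, chips in blocks with within-chip position recorded.  Trait cores
follow the ACE algebra exactly — A shared in MZ pairs and split into
shared/segregating halves in DZ pairs — with unit variance before covariate
effects (default age slope 0.01/yr, batch offsets ~N(0, 0.1²)) are added.
Default trait specs span the fitted range of the real panel (a² from 0 to
0.8, shared environment up to ≈ 0.66).

Peak profiles are Dirichlet compositions scaled to 100 with expected values
equal to the configured means (defaults anchored to the published MZ peak
means; the two unreported peaks get small filler means and the vector is
renormalized).  The `dispersion` parameter is the inverse Dirichlet
concentration; the default 1/36 matches the coefficient of variation of the
major peaks.  A single concentration cannot match every peak: minor peaks
come out relatively noisier than real data, so ratio traits with tiny
denominators (e.g. FS1/FS2) are heavier-tailed in synthetic cohorts than in
the published table.  Peak compositions carry no twin structure — they
exercise the trait engine, while the directly simulated trait matrix (with
known a²/c²/e²) exercises the heritability and EWAS stages.

Methylation is simulated directly on the standardized scale (the analysis
standardizes probes, so raw beta-values add nothing testable): each probe
is a family-shared intercept plus individual noise, column-standardized.
The within-family variance share defaults to 0.2 — a free parameter of the
generator, not a published value.  A planted (probe, trait, β) adds
β·probe to the trait's generating equation, so the EWAS stage faces a true
regression coefficient of exactly β.  Probe annotation (chromosome,
position, nearest gene) is synthetic bookkeeping.

Randomness uses one master seed with per-stage substreams derived by
hashing the stage name, so cohorts are bit-for-bit reproducible and stages
are statistically independent.

### What passing tests do and do not show

The generator realizes the model assumptions exactly (bivariate normality,
equal environments, compound-symmetric methylation covariance, linear
covariate effects).  Parameter recovery, CI coverage and planted-effect
retrieval on these cohorts validate the estimators and the pipeline
plumbing; they do not probe violations found in real data — non-normal
trait distributions, batch-by-trait interactions, cell-composition
confounding of methylation, or peak-integration artefacts.

## Problem sizes used in the test suite

Simulation-heavy checks run at sizes chosen to keep the full suite around
five minutes on one core while leaving Monte-Carlo error well inside each
assertion's tolerance: Falconer-limit and covariance checks at 10⁵–2×10⁵
pairs per zygosity; selection-consistency and CI-coverage runs at 100–200
replicates of cohort-sized samples; power at 250–1000 replicates;
mixed-model recovery/calibration at 100–500 replicates of 120–200-sample
cohorts; the planted-truth EWAS at 60 pairs × 40 probes over three seeds.
The acceptance script uses 600 replicates per power arm.

## Known limitations

- The LRT boundary issue makes the default additive test conservative; the
  mixture reference is available but off by default (see above).
- Profile CIs assume a unimodal profile likelihood; at a handful of pairs
  the interval degenerates toward [0, 1] with a logged warning.
- The EWAS loop refits the full mixed model per probe; at array scale
  (~25k probes) this is hours of CPU, acceptable for the emulated subset
  sizes but not optimized for modern 450k/EPIC arrays.
- Structural annotation of peaks beyond the four anchored assignments is a
  documented convention, not measured truth; traits built purely from
  grouped sums are robust to within-group reassignment but cross-group
  corrections require editing the annotation file.
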