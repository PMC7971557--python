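# Methods

This note documents the statistical models, defaults and design choices
behind `purinomics`, and what the synthetic-data generators do and do not
emulate.

## Metabolomics preprocessing

Peak areas (AUC, arbitrary positive units) are log₂-transformed and each
metabolite is standardized against the designated control group:
z_ij = (log₂ x_ij − μ_ctrl,j) / σ_ctrl,j, with μ and σ the control-group
mean and *sample* SD (denominator n−1; at n = 7–8 this is the standard
choice).  Consequences and conventions:

- Control-group z-scores have mean 0 and SD 1 per metabolite exactly;
  effect sizes downstream are in control-SD units.
- z is invariant to any positive rescaling of a metabolite's AUCs.
- Metabolites with zero control SD are excluded with a warning; the
  control arm must have ≥ 3 samples.
- Missing values are a hard error everywhere; there is no imputation path.
- Each comparison is z-scored against its own cohort's control arm (when a
  study has multiple cohorts, standardize within the cohort, not across).
- A generalized log transform glog₂(y) = log₂(y+1) is provided for
  cytokine-like concentrations that can fall in (0, 1) pg/ml.

## Univariate statistics and multiplicity

Two-group comparisons use the Mann-Whitney U test: exact enumeration when
the pooled sample is ≤ 16 and tie-free, otherwise the normal approximation
with midrank tie correction and continuity correction.  The worst-case gap
between exact and approximate two-sided p at 8 + 8 is 0.0109 (at U = 24/40),
which is why tests of their agreement use an 0.011 bound.  Welch's t is
computed alongside; three or more groups use one-way ANOVA with Fisher's
*protected* LSD (pairwise pooled-MSE t tests reported only when the omnibus
p < 0.05).

Multiplicity control: Benjamini-Hochberg step-up adjustment (monotone,
capped at 1) and Storey q-values.  π₀ is estimated by the smoother method —
π₀(λ) = #{p > λ}/(m(1−λ)) over λ ∈ {0.05, …, 0.95}, cubic smoothing spline
evaluated at λ = 0.95, clipped to (0, 1] — falling back to π₀ = 1 with a
warning below m = 20 p-values.  With π₀ = 1 the q-values reduce exactly to
BH-adjusted p-values.

The headline "changed metabolite" filter is the conjunction
FDR < 0.05 ∧ VIP ≥ 0.9 ∧ Welch-t p < 0.05 (all thresholds configurable;
thresholds set exactly to 1 are treated as inclusive so a degenerate
configuration passes everything).  BH FDR (not Storey q) feeds the filter
by default.

## PLSDA and VIP

PLSDA is fit by NIPALS against a centered one-hot group encoding (for two
groups this is ±1 coding).  Predictors are mean-centered but *not*
rescaled — the control-SD z matrix is already on a common scale and the
z-scoring step is the single normalization authority.  Components are
extracted with X-deflation (scores of distinct components are orthogonal);
convergence is a weight-vector change < 1e-10 or 500 iterations.  Default
A = 2 components; VIP uses all fitted components.

Per-component explained response sum of squares is SS_a = (tᵀt)(qᵀq), the
response variation captured by regressing Y on the component's score.  VIP
is VIP_j = √(p · Σ_a SS_a w²_aj / Σ_a SS_a) with unit-norm weight vectors,
which forces the algebraic identity mean(VIP²) = 1 on every fit — the
identity is asserted in the tests and is the calibration that makes
"VIP ≥ 1" a meaningful importance cut.  The implementation is cross-checked
in the tests against an independent PLS implementation (first-component
weights and scores agree to 1e-8 up to sign).

PCA explained-variance fractions come from the covariance spectrum of the
z matrix (full SVD).

## MDA (bagged-tree permutation importance)

Mean decrease in accuracy is computed from scratch: unpruned decision
trees (√p feature subsampling) are grown on bootstrap samples; for each
tree the out-of-bag accuracy is compared with the accuracy after permuting
one variable's out-of-bag values, and MDA_j is the mean drop across trees.
Out-of-bag permutation (not impurity) is used because that is what "mean
decrease in accuracy" denotes.  Fixed seed ⇒ fixed result; default 200
trees.

## Pathway impact and superclusters

Pathway impact is the sum of VIP scores over a pathway's *significant*
members, ranked descending (ties broken by member count, then name); sums
over pathways conserve the total significant VIP.  A pathway is classified
increased/decreased if all significant members' mean treated z share a
sign, otherwise mixed.

"k-NN clustering" of metabolites is implemented as Ward-linkage
agglomerative merging constrained to a symmetric k-nearest-neighbor graph
(Euclidean distance between metabolite z-profiles across samples,
default k = 10), merged until exactly n_clusters (default 10) remain.
This reproduces the intent — clusters of metabolites that behave in
similar ways, free to cross pathway boundaries — while being deterministic;
k, the linkage constraint and the cluster count are all configurable
because no canonical "k-NN clustering" algorithm exists.  Clusters are
ranked by threshold-gated summed VIP (Σ member VIP | VIP ≥ threshold;
1.0 for acute tables, 1.5 recommended for late timepoints), with summed
positive MDA as the secondary key; a cluster's impact fraction is its
gated VIP share of the total, so fractions sum to 1.

## Physiology

- RER = VCO₂/VO₂ per interval; group summaries average per-interval RER
  within animal and then across animals.  The order matters: for the
  study-scale group means (4324/5302 ml/kg/hr) the ratio of means is
  0.816 while interval-level averaging sits near 0.84, and the
  per-interval convention is what a per-animal RER summary reports.
- Radiated heat uses the Lusk caloric equivalent of oxygen,
  CV = 3.815 + 1.232·RER kcal/L O₂, heat = CV · VO₂ · mass (cal/hour),
  with RER clipped to the non-protein band [0.65, 1.05] (warning) and a
  default body mass of 0.025 kg when none is recorded.
- Percent changes are 100·(treated − baseline)/baseline, reported as
  signed integers (half away from zero); RER change is reported as an
  absolute difference because it is already dimensionless.
- The summary window over the calorimetry trace (e.g. minutes 26–52,
  where the response is fully developed) is an explicit parameter.
- Dose-response: OLS per sex; the sex difference is the F test (1, N−4 df)
  on the sex×dose interaction in the pooled model.
- Temperature phase analysis replaces longitudinal mixed models with
  defined phase windows (baseline, spike, dip, rebound): per group and
  window, mean ± SD, delta vs the group's own baseline, and a Welch test
  of window vs baseline observations.
- The mouse→human age conversion is piecewise-linear cumulative
  (12, 6, 3, 3, 3, 3, then 2.5 years per month), continuous and strictly
  increasing; 8 months ⇒ 35 years.
- PBRS: six 0/1/2 items (center avoidance, decreased locomotion,
  imbalance/ataxia, piloerection, rapid shallow breathing, shivering),
  total 0–12, out-of-range items are errors.

## Breathomics

Excess mixing ratios are sample − mean(room-air background), clipped at
zero (physical non-negativity; a signed mode exists).  Each species'
excess is divided by the same canister's excess CO₂ (ppb per ppm),
removing any multiplicative minute-volume confound exactly in the
noiseless case; canisters with zero excess CO₂ are excluded with a
warning.  Per-canister (rather than fitted-rate) normalization is the
default because it makes no assumption about kinetics across the 1/5/10
minute samples.  The three timepoints are pooled per animal before a
Welch t comparison per species with BH correction across species (the
species panel is ~10–100 wide and group sizes are ~3, so a
heavy-tailed-robust location test with FDR control is the pragmatic
choice).

## Synthetic-data generators

The generators define the conditions under which the pipeline is tested.

**Metabolome.**  Lognormal AUC model: log₂ values are normal with
per-metabolite control mean (default range 12–24) and SD (0.35–0.95).
`effect_z` is defined as the displacement in *measured* control-SD units —
the quantity the paper-style z-tables report — so treated values are
shifted by effect_z times the *realized control-sample SD* of the draw.
Shifting by the population SD instead would make the measured z biased
upward by E[σ/s] ≈ 1.126 at n = 8 (7 df), i.e. a planted −5.0 would be
read out as −5.7; under the measured-SD definition the pipeline's
z-statistic is unbiased for effect_z.  Superclusters add a shared
per-treated-sample latent N(0,1) factor scaled by loading × SD
(default loading 0.5, a free choice — within-pathway correlations are not
published — chosen so coordinated change is genuine correlation of
moderate strength).  The study-scale default plants 401 metabolites in 37
pathways, n = 8 + 8: a decreased supercluster of 63 (containing all 19
amino acids at mean −5.0, SD 2.6), an increased supercluster of 71
(containing 11 microbiome metabolites at mean +3.5), 76 moderate
responders (|z| ≈ 1.4–2.2) and null background pathways.  Effect values
use a deterministic spread with exact mean and SD rather than random
draws, so the planted truth is identical across seeds.

**Calorimetry.**  One trace per animal, 13-minute intervals over 3 hours;
treated groups sit at control means before the injection minute and at
their own means after.  Between-animal offsets use the stated group SDs
with a VO₂/VCO₂ correlation of 0.7 — independent offsets would imply a
per-animal RER spread of ~0.16, double the ~0.08 the measured feature
table shows — plus interval-level noise at 5% of the local mean.  With
all SDs zero every interval equals the spec mean exactly.  Defaults:
saline VO₂ 5302 ± 710 and VCO₂ 4324 ± 647 ml/kg/hr vs treated 1382 ± 325
and 1034 ± 226, n = 6 per group.

**Dose-response.**  response = intercept + β·dose + N(0, σ), default
slopes −27.8 (female) / −16.5 (male) °C per μmol/g over doses 0–0.2, with
residual σ of 1.4 / 0.42 °C back-computed from the reported slope
standard errors at the study design.

**Temperature.**  A triphasic template: baseline (day 0), +0.7 °C day-1
spike, −0.8 °C dip on days 2–4, a rebound plateau on days 6–14 (+0.8 °C
for primed animals, 0 for controls; primed baseline 35.8 °C vs control
36.3 °C), then a linear return to baseline by day 28; daily noise SD
0.4 °C.

**Breath.**  Room-air backgrounds plus per-animal excesses; a per-animal
lognormal minute-volume factor scales every species alike (the confound
CO₂ normalization removes) and lognormal measurement noise applies per
value.  Treated effects are multiplicative on the excess.

All generators consume a single explicitly seeded `numpy` Generator; no
global random state; equal seeds give bitwise-identical outputs.

**What the generators do not emulate** — and hence what passing tests do
not establish about real data: chromatographic drift, batch effects and
internal-standard scaling; heteroscedastic or heavy-tailed AUC noise;
missingness (real runs may need imputation upstream; this pipeline
refuses it); pharmacokinetics of the injected nucleotide; circadian
structure in calorimetry and temperature; instrument calibration and
cross-sensitivity in breath measurements.  Tests against these generators
validate the statistical machinery under its own assumptions, not the
assumptions themselves.

## Problem sizes used in the checks

The self-checks run the study-scale metabolome (401 × 16) once per seed
where a single run suffices, and smaller matrices (50–120 metabolites) for
the 100–200-seed Monte-Carlo loops (null FDR control, effect-size
recovery, supercluster impact, slope-CI coverage), sizes at which the
Monte-Carlo standard errors are comfortably below the tolerances being
asserted.

## Known limitations

- Storey's smoother π₀ is unstable for small m; the fallback is π₀ = 1
  (conservative, q = BH).
- Protected LSD controls error only weakly for > 3 groups; with many
  groups prefer the BH-adjusted pairwise output.
- The MDA loop is O(trees × features × OOB predictions) in pure Python
  over scikit-learn trees; at thousands of features prefer fewer trees.
- The k-NN-graph clustering's cluster count is user-set, not selected by
  any criterion; results at other counts can differ qualitatively.
- Percent-change reporting assumes a positive baseline; an all-zero
  control window yields NaN rather than a percent.
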