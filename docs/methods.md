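# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the design decisions taken where the design was genuinely open.
It states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Cohort definition and demographics

Progression groups are defined on the monthly ALSFRS-R decline: fast ≥ 1.0
unit/month (boundary inclusive), slow < 0.5, intermediate otherwise;
intermediates are excluded from every analysis. Group comparisons of
categorical demographics use the two-sided Fisher exact test (total
probability of all tables with the observed margins no more likely than the
observed table). Continuous demographics use an **exact Mann–Whitney test**:
all C(n, n₁) assignments of the pooled values are enumerated with mid-ranks
for ties, and the two-sided p doubles the smaller tail (capped at 1). The
enumeration is implemented in-package because standard exact routines
decline tied data, and the cohort ages contain ties; it is cross-checked in
the tests against an independent brute-force oracle that computes U from
pairwise comparisons. Pooled samples larger than 15 fall back to the
tie-corrected normal approximation.

## Synthetic cohorts

The generator (`synthetic_cohort`) emulates the longitudinal LFQ structure
the analyses assume. For protein p and sample s (patient i, visit v):

y_ps = b_p + d_p·1[i fast] + a_ip + g_{p,batch(s)} + ε_ps

- protein baselines b_p ~ N(20, 2²) on the log2 scale;
- signed group effects d_p of magnitude `group_effect_log2` (default 1.0,
  alternating sign) for the first `n_signal_proteins` proteins (default 59),
  **constant across visits** — the planted markers shift between groups but do
  not drift, matching the finding that the candidate markers remain largely
  unchanged over time;
- patient random effects a_ip ~ N(0, 0.3²) per patient × protein;
- additive batch effects g ~ N(0, 0.3²) per protein × batch, drawn once;
- visit noise ε with group-specific SD — defaults 0.6 (fast) vs 0.2 (slow),
  encoding the higher visit-to-visit proteome variance of fast progressors
  that the state-transition model targets.

Cohort shape defaults mirror the discovery design: 6 fast / 5 slow patients,
3–5 visits at ~6-month spacing (uniform ±50% jitter). ALSFRS-R slopes are
drawn uniformly from [1.0, 2.7] (fast) and [0.0, 0.48] (slow), bracketing the
published per-patient values; group labels downstream are always re-derived
from the slopes, never stored.

Missingness follows a blend of uniform and intensity-dependent dropout:
entry dropout probability (1−w)·r + w·r·g, where g falls linearly from 2
(lowest intensity rank) to 0 (highest), so the expected missing fraction is r
for any MNAR weight w (defaults r = 0.1, w = 0.5). Real LFQ missingness is
left-censored rather than rank-linear; the generator reproduces the
low-abundance bias, not the censoring mechanism.

What the generator does **not** emulate: peptide-level structure, correlated
protein modules, heavy-tailed intensity noise, informative dropout tied to
disease state, or visit-count imbalance between groups. Passing recovery
tests therefore establish that the pipeline recovers the structure it
assumes, not that real cohorts satisfy those assumptions.

## Preprocessing

Normalization is a transparent variance-stabilizing stand-in: log2(x+1) when
the input is raw-scale, then each sample column is shifted so its median
equals the grand median (exact to 1e-9, rank-preserving, idempotent). Batch
adjustment removes per-protein batch means and restores the protein grand
mean; singleton batches are passed through with a warning because their
offset is unidentifiable. Missing values are never imputed for testing —
all rank tests drop them pairwise; only consumers that require a complete
matrix (PCA projection, random forests) use protein-mean imputation, and
flag it. The protein filter drops proteins missing in more than a configured
fraction of samples (default 0.5).

## Differential abundance and the candidate panel

Per protein, log2 fold change is the difference of group means on the log2
scale; significance requires |log₂FC| ≥ log₂ 1.5 **and** BH-adjusted
p ≤ 0.0125. Proteins with fewer than two observations in a group are flagged
untestable and excluded from the BH family. The candidate panel intersects
the significant sets of the four cross sections (fast vs slow at
first/first, last/last, first/last, last/first visits) and additionally
requires a consistent direction of change across all four (a flag disables
this; the coherent up/down blocks in group heatmaps motivate the default).

A granularity consequence worth stating explicitly: with 6 vs 5 patients per
cross section, the exact two-sided Mann–Whitney p cannot go below
2/462 ≈ 0.0043, so BH adjustment over ~1150 proteins can only reach 0.0125
if several hundred proteins move. The planted-signal recovery study
therefore uses 20 patients per group, where the asymptotic test has
essentially unbounded resolution; the study-sized cohort is kept in the
analysis drivers to demonstrate the power limit honestly.

## rdCV random-forest selection

Repeated double cross-validation: per repetition, patients are dealt into
`n_outer_folds` class-balanced folds (all visits of a patient travel
together, so no model predicts a patient it trained on). Within each outer
training set, `n_inner_folds` inner folds evaluate a recursive elimination
loop: fit a random forest, rank variables by importance, drop
`drop_fraction` per step down to 2 variables. The variable count minimizing
mean inner misclassification is refit on the outer training set and applied
to the outer test fold. Defaults: 30 repetitions, 6 outer / 5 inner folds,
drop 0.2, 100 trees.

Model choice: among counts tied at the minimal inner error, **min** takes
the smallest (default — the most parsimonious model), **max** the largest,
**mid** the middle of the tied set. The all-relevant recovery study in the
benchmarks uses the mid model: when two of three redundant strong markers
already achieve zero inner error, the min model correctly returns the
2-variable subset, which is parsimony, not failure. Variable importance is
impurity (Gini) importance by default; permutation importance on the inner
validation fold is available via config at ~10× the cost. Per-sample class
probabilities are averaged over all repetitions in which the sample sat in
an outer test fold; a sample is misclassified when its mean own-class
probability is below 0.5; patient-level calls are visit majorities with
probability-mean tie-breaks.

## Panel evaluation

Logistic panel scores are maximum-likelihood fits of class on the marker
submatrix; under complete separation (detected by divergent coefficients,
|β| > 25) the fit falls back to a ridge-stabilised logistic model and is
flagged. AUC is the normalized Mann–Whitney U with ties counted ½.
Confidence intervals are percentile bootstrap over 1000 stratified resamples
(within-class resampling keeps both classes present by construction). The
operating criterion maximizes Youden's J = sensitivity + specificity − 1,
with "positive" meaning score ≥ criterion and ties broken toward the
higher-specificity cutoff — the selection rule behind criterion tables is
rarely stated; Youden is the conventional default.

## Longitudinal mixed models

Marker trajectories are fit by ML with statsmodels MixedLM:
value ~ group + group:months + centered age + (1 + months | patient).
Group-slope significance uses a likelihood-ratio test against the model with
that slope removed (χ²₁) rather than Satterthwaite degrees of freedom — the
two agree asymptotically, and the LRT composes cleanly with the ML fit. If
the 2×2 random-effects covariance cannot be estimated (non-PSD or
non-convergence), the model refits with a random intercept only and flags
it. A zero-variance response short-circuits to the exact degenerate answer.
At fewer than 3 patients per group the fit warns; simulation checks in the
tests keep the type-I rate near nominal at the sizes used.

## Mutual-information ranking

MI between protein abundance (continuous) and progression class (discrete)
uses the nearest-neighbour continuous–discrete estimator with k = 3
neighbours, in nats. Estimates are clipped into [0, H(label)]: MI cannot
exceed the label entropy (≈ 0.689 nats for a 6/5 split, ln 2 balanced), and
k-NN estimators fluctuate outside the feasible range at small n. Ranking
drops missing values pairwise per protein, requires ≥ 3 observed samples per
class (else the protein scores 0), and breaks ties by protein ID for
determinism.

## Ornstein–Uhlenbeck state-transition model

The scalar proteome state is PC1 of the complete (imputed) protein × sample
matrix, samples as observations and proteins centered, with the sign fixed
so the fast-group mean is ≥ the slow-group mean (the raw orientation of a
principal component is arbitrary). The state follows
dX_t = θ(μ − X_t)dt + √(2β⁻¹)dB_t.

- **Simulation** uses the exact Gaussian transition
  X_{t+Δ} | X_t ~ N(μ + (X_t−μ)e^{−θΔ}, (β⁻¹/θ)(1−e^{−2θΔ})) rather than
  Euler–Maruyama, eliminating step-size bias at any visit spacing; β⁻¹ = 0 is
  allowed and yields the deterministic relaxation.
- **Likelihood** sums the transition log-densities over consecutive visits,
  conditioning on the first observation by default — the first CSF draw is
  not the start of the disease process; an option adds the stationary
  density of the first point instead.
- **Fitting** is joint ML per progression group (shared θ, μ, β⁻¹ across the
  group's patients), Nelder–Mead on (log θ, μ, log β⁻¹) from three θ starts
  (0.02, 0.1, 0.5 /month) to avoid the shallow-likelihood local optima that
  sparse designs produce; positivity is enforced by the log parameterization.
  μ can be held fixed and shared across groups (one "state of ALS"
  threshold); per-group μ is the default as it costs one parameter and the
  acceptance surface is ordering-based. Constant trajectories return β⁻¹ at
  the 0 boundary, flagged unconverged.
- **Backcasting** simulates presymptomatic paths on [−T, 0] from the
  reference state x = 0, conditioned to end at the observed baseline via
  sequential sampling of the exact OU diffusion bridge: at each step the
  Gaussian transition prior is combined with the Gaussian likelihood of the
  endpoint, giving conditional mean
  (m₁u₂ + c(b − μ(1−c))u₁)/(u₂ + c²u₁) and variance β⁻¹u₁u₂/(u₂ + c²u₁)
  with u(Δ) = (1−e^{−2θΔ})/θ and c = e^{−θ·remaining}. Written this way the
  β⁻¹ → 0 limit is exact (deterministic bridge) and the final step lands on
  the endpoint identically. An unconditioned forward mode is available.
- **Variance biomarker**: per patient, the mean squared PC1 increment per
  month (a diffusion-rate estimate robust to the sparse, irregular visit
  grid); per group, the median across patients; reported with the fast/slow
  ratio. Single-visit patients are excluded with a warning.

The ordering-recovery study simulates 10 patients per group × 8 visits at
3-month spacing with θ = 0.08 vs 0.4 /month and β⁻¹ = 0.3 vs 1.5 (slow vs
fast), initial states drawn from the stationary law. The study-sized design
(5–6 patients, 3–5 visits at ~6 months) leaves θ weakly identified — at
θ = 0.4 the 6-month autocorrelation is already 0.09 — so a conventional
recovery-study size is used and reported alongside the rate.

## Problem sizes in the tests and acceptance script

Simulation studies are sized for a single CPU: OU closed-form checks use
2000 paths (3 Monte-Carlo-SE tolerances); ordering recovery 50 replicates;
differential-panel recovery 20 seeded cohorts of 1150 proteins at 20
patients/group; rdCV recovery 8 repetitions over 303 proteins with a scaled
fold plan (5 outer / 4 inner, drop 0.3, 32 trees) plus a 4-repetition
patient-permuted control; MI calibration 200 null simulations at n = 200.
The pipeline defaults (30 repetitions, 100 trees, 1000 bootstrap samples)
are for real use.

## Known limitations

- The normalization is a median-calibration stand-in, not the arcsinh
  variance-stabilizing fit used by vsn-style tools; heteroscedasticity
  across the intensity range is reduced only by the log transform.
- The OU model is one-dimensional; multi-component state dynamics, hazard or
  onset-time modeling are out of scope.
- Patient-level non-independence is handled by fold stratification in rdCV
  and random effects in the mixed models, but the differential cross
  sections treat patients as independent units (one sample per patient per
  cross section, which is exactly what makes them valid).
- Pathway enrichment and protein–protein interaction annotation depend on
  external knowledgebases and are not implemented.
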