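# Methods

This note documents the models implemented in `proteoscreen`, the defaults
and why they were chosen, the numerical conventions, and what the synthetic
data generator does and does not emulate.

## Intensity post-processing

Inputs are feature × sample matrices of linear-scale intensities (iBAQ-like
protein quantities, p-site intensities). Zeros and empty cells in
search-engine output tables denote non-detection and are read as missing,
never as observed zeros — otherwise half-minimum imputation would anchor on
spurious exact zeros.

Processing order: decoy/contaminant removal → log10 transform →
median-centring → imputation. Median-centring shifts each sample
additively on the log10 scale so its median of observed values equals the
grand median of all observed cells (equivalent to multiplicative scaling
of linear intensities; it corrects loading-amount differences). The grand
median is computed over observed cells only. The operation is idempotent
and exactly absorbs per-sample offsets, which the activity-score tests
exploit.

"Half-minimum" imputation is interpreted on the linear scale — halving is
a linear-scale notion for abundance — so a missing cell in a row with
linear minimum *m* becomes log10(*m*/2). Observed cells are bit-identical
before and after; rows without any observation are left missing and
reported.

## Dose–response

Viability is normalised per plate between the negative-control (vehicle)
mean and the positive-control (pan-kill) mean, clipped to [0, 1.2] and
capped at 1 for fitting. Replicates are averaged per dose before fitting.

The symmetric four-parameter log-logistic model uses the natural log
internally (the model is base-agnostic; the slope *b* absorbs the base —
stated so fitted *b* values are comparable). Fit initialisation: *d* =
max(viability), *c* = min(viability), *e* = dose nearest the half-maximal
response, *b* = 1; bounds *c*, *d* ∈ [−0.2, 1.3], *e* ∈
[x_min/100, x_max·100], *b* ∈ (0, 50]. These stabilise the well-known
identifiability problems of flat curves. Non-convergence is reported
honestly (`converged=False`) and callers fall back to the empirical
trapezoid AUC. Flat curves (no dose effect) carry an ED50 of +inf as a
sentinel; their AUC is the constant viability level.

The standardised AUC integrates the fitted curve over the tested dose
range in log space by adaptive quadrature (absolute and relative tolerance
1e-8) and divides by the log range, then clips to [0, 1]; it is invariant
to the dose unit because the range normalisation cancels the scale.

"Relative inhibition effect" (max inhibition) is defined as 1 minus the
minimum of the fitted curve over the tested range, i.e.
1 − min(c, f(x_max)) — a noise-robust fitted-curve quantity rather than a
raw-data minimum. The potency filter counts kinase inhibitors with
EC50 < 0.1 µM, AUC < 0.9 and max inhibition > 0.5 per cell line. Plate QC
uses the standard Z′-factor with sample standard deviations.

## Kinase activity landscape

Four evidence layers, each row-standardised across cell lines (z-scores
with the sample SD, n−1 — the standardisation tool convention is fixed and
documented rather than inherited):

- (a) log10 kinase protein abundance;
- (b) the kinase's own p-site intensities summed on the linear scale, then
  log10, then z-scored;
- (c) as (b) restricted to annotated activation-loop sites;
- (d) as (b) over annotated substrate sites.

Within a sum, a missing site counts as zero as long as at least one site
is observed for that kinase in that line (evidence is additive on the
linear scale); lines with no observed site stay missing. Rows observed in
fewer than two lines are dropped (SD undefined); constant rows get z = 0
rather than missing so layer availability remains meaningful. Sites shared
between kinases (e.g. substrates of two kinases) contribute to both.

Combination: the score is the plain **sum** of available layers — not the
average — so a kinase with more corroborating evidence scores higher;
averaging would change cross-kinase comparability and was rejected.
Protein-level abundance is a hard requirement, and additionally at least
one phospho layer (b, c, d) must be present; kinases with abundance only
are flagged (`abundance_only`) instead of scored, keeping the output
transparent about single-layer cases. Rankings are per cell line,
descending score, ties broken lexicographically; an optional restriction
to druggable kinases uses the annotation set.

## Cell-cycle proportions

Cluster sums of periodic (cell-cycle-oscillating) proteins act as phase
surrogates: per cluster, member intensities are summed per line; each
cluster is min–max rescaled across lines (removing the bias of clusters
with more members); each line's five rescaled values are normalised to sum
to 1. A cluster constant across lines rescales degenerately and is set to
0.5 for all lines — defined and uninformative. Cluster→phase labels
(1: G1, 2: S, 3: G2, 4: early M, 5: M) are annotation metadata, not
computed. Note the documented sensitivity: because rescaling is across
lines, a uniform per-line intensity scaling *does* shift proportions —
which is why loading normalisation precedes this step in the pipeline.

The drug-correlation screen keeps drugs with minimum AUC < 0.8 (drugs with
essentially no effect anywhere would only contribute noise correlations)
and flags Pearson r < −0.5 as phase-linked sensitivity and r > +0.5 as
resistance.

## Sparse multiblock PLS

Each component maximises the summed squared covariance between per-block
latent scores and the response-block score under hard sparsity. The L1
penalty is implemented in its cardinality (top-k hard-threshold +
renormalise) form because the target sparsity is specified as exact counts
(6 drugs, 50 features per component); this reproduces the configured
support sizes deterministically, which a penalty-weight formulation would
not. The 50-feature budget is pooled across the predictor blocks and split
proportionally to each block's gradient mass Σ|X_kᵀ s| (largest-remainder
rounding, capped at block dimensions), i.e. the pooled reading of
"proteins and phosphorylation sites" as one list.

The alternating solver updates u_k ∝ top-k(X_kᵀ s) and
v ∝ top-k(Yᵀ Σ_k t_k), accepting only objective-improving iterates
(monotone ascent; convergence when the relative objective change drops
below `tol`, default 1e-6). Because alternating ascent only finds local
optima, the default is a deterministic multi-start: the leading right
singular vector of Y, every single-drug indicator vector and — on problems
with at most 64 pooled features, where it is affordable — the drug-score
direction induced by every single feature, keeping the best objective.
This makes the solver agree with exhaustive support enumeration on small
instances while remaining fully deterministic (`multi_start=False`
restores the single SVD start). Sign indeterminacy is
resolved by forcing the largest-|loading| drug entry positive; a negative
feature loading against a positive drug loading then reads as higher
abundance ↔ lower AUC (sensitivity).

Deflation is the standard PLS scheme: each block is deflated by its own
score, the response by the summed block score; column centring is
preserved, and deflated blocks are orthogonal to their scores. Covariances
use the n−1 denominator; columns are centred but not scaled. The model
stops early with a warning if the residual response block is numerically
exhausted.

## Elastic net

Objective: (1/2n)‖y − Xβ − β₀‖² + λ(α‖β‖₁ + ½(1−α)‖β‖₂²), solved by
scikit-learn's coordinate descent on internally standardised features
(coefficients returned on the original scale; constant features get 0;
λ = 0 falls back to least squares). Missing abundances are half-minimum
imputed before regression, reusing the preprocessing step.

Tuning is two-stage: λ on a 50-point log path from
λ_max = max|Xᵀy|/(nα) down 3 decades at fixed α = 0.05, then α from
{0.01, 0.05, 0.1} at the chosen λ. Cross-validation is leave-one-out for
panels of ≤ 20 samples (the stable choice at n = 17) and 5-fold otherwise,
with deterministic fold assignment from the seed. Both stages pick the
**sparsest model within one standard error of the CV minimum, computed on
paired fold-error differences**: at n = 17 the absolute spread of LOO fold
errors is so wide that the classical (unpaired) one-SE rule erases even
exact marker signals, while the raw CV minimum chases noise at the dense
end of the path on null responses; pairing the comparisons on the same
folds cancels the shared fold-difficulty variance and threads between the
two failure modes.

With tuned hyperparameters, 100 bootstrap resamples of the sample index
(with replacement, size n) are refitted; resamples with constant response
are redrawn up to 10 times. The report aggregates the mean coefficient
over all models (zeros included, so magnitude is comparable to frequency)
and the selection frequency (fraction of models with a nonzero
coefficient). A known limitation at panel scale: with 17 samples and
hundreds of features, a permuted (null) response still produces chance
correlates with |r| up to ~0.5–0.8 whose cross-validated predictivity is
computed on the same 17 samples, so some null datasets yield a stably
selected feature regardless of the tuning rule; selection frequencies from
small panels should therefore be read as candidate rankings, not error-
controlled discoveries.

The pairwise screen computes Pearson r per (feature, drug) over
pairwise-complete observations of the non-imputed matrix and keeps pairs
with more than eight complete observations ("more than eight" = n ≥ 9;
the boundary n = 8 is excluded). p-values use the t-transform of r and are
reported but not used as a filter.

## Time course

Channels are scaled multiplicatively so all channel medians equal the
grand median. Methionine-oxidation tokens are stripped from modified
sequences (phospho tokens are preserved — they define the analyte) and
rows that become identical are summed channel-wise. Ratios are taken
against the time-zero channel; features with missing or zero t0 are
dropped and reported. The duplicated t0 bridge channel (channel 2 in the
default 11-channel map) is excluded from the time grid after
normalisation; it exists to scale batches against each other.

Interpolation is linear on the minute axis and never extrapolates.
"Absolute maximal response" is measured on the log2-ratio scale so 4-fold
down (0.25) and 4-fold up (4.0) are equally extreme. Regulation calls use
strict inequalities at the fold boundary (ratio < 0.5 or > 2 for the
default two-fold rule); direction is the sign of the log2 ratio at the
maximal-response time point.

## Synthetic data generator

The generator emulates the full data footprint of a panel study at desk
scale: 17 cell lines, 2000 proteins (60 kinases), 4000 p-sites, 30 drugs
(24 kinase inhibitors), a 10-point 1:3 dose ladder of final assay
concentrations topping at 10000/21 ≈ 476 µM (a 10 mM top stock dosed
2.5 µl into 50 µl wells), triplicate wells, and a two-arm
(treated/vehicle) time course on the grid
{0, 5, 10, 15, 30, 90, 180, 360, 720, 1440} min.

Generative model and defaults:

- log10 intensities ~ Normal(per-feature baseline, 0.25) across lines;
  baselines ~ Normal(6.5, 0.8) for proteins, Normal(5.5, 0.8) for p-sites.
  Missingness is uniform at random at rate 0.1.
- Each line carries one planted active kinase; the kinase's protein, own
  p-sites, activation-loop site and substrates are shifted +0.7 log10 in
  that line. Drugs targeting an active kinase have their true ED50 lowered
  100-fold there. A zero activity effect disables the sensitisation too —
  the causal chain is activity → sensitivity, so the zero-effect
  configuration is a clean null panel.
- True curves: b ~ U(0.8, 1.5), c ~ U(0, 0.1), d = 1,
  log10 e ~ U(log10 2, log10 200) µM.
- Screen signals are drawn from the true curve between control levels with
  Gaussian noise of SD 2% of the negative-control mean, mimicking the
  low replicate variability of a well-run ATP-luminescence screen (the
  implied Z′ is ≈ 0.88, inside the range such screens report).
- Periodic proteins (119 by default, five clusters of 24/24/24/24/23) are
  drawn from a narrower baseline band (Normal(6.0, 0.35)): the phase
  signature must be carried by the cluster sum, which a single very
  abundant member would otherwise dominate with its own sampling noise.
  Each line's planted dominant cluster is boosted +0.5 log10. One
  non-inhibitor drug is cycle-coupled: sensitive (ED50 0.3 µM) exactly in
  the S-phase-dominant lines, resistant (200 µM) elsewhere.
- Marker links tie a feature's log10 abundance linearly to a drug's true
  AUC profile (1 log10 unit per AUC SD, noise SD 0.1), with alternating
  signs.
- Time-course: 10% of 1000 features are regulated with plateau
  |log2 fold| ~ U(1.2, 3) and exponential approach (τ ~ U(20, 180) min) in
  the treated arm only; multiplicative log2 noise SD 0.1 everywhere except
  the t0 reference channel.

One global seed fans out to per-table child seeds (numpy `SeedSequence`),
so regenerating one table does not perturb the others, and all outputs are
byte-identical under a fixed seed.

What the generator does **not** emulate — and what passing recovery tests
therefore do not show about real data: peptide-level quantification and
roll-up, TMT reporter interference and isotope impurities, batch effects
and chromatographic drift, missingness that depends on abundance
(left-censoring), correlated co-regulation structure beyond the planted
effects, off-target drug polypharmacology, and biological replicate
variability of cell culture. Recovery rates on this generator are
best-case calibrations of the pipeline's logic, not performance claims for
laboratory data.

## Problem sizes used in the test suite

Module tests run on a scaled-down panel (10 lines, 300 proteins, 600
p-sites, 8 drugs); end-to-end checks use the full default panel and
repeat stochastic analyses over 10–50 fixed seeds (10 panel seeds for
kinase recovery and time-course calling, 50 curve-fit seeds, 20 null-panel
seeds for the distributional null, 120 small instances for the sparse-PLS
oracle sweep). These sizes keep the whole suite in the low minutes on one
CPU while leaving every recovery margin wide.
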