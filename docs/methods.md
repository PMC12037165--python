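# Methods

This note documents the models, estimators, and numerical choices behind
`graspcode`, and what the synthetic-data generator does and does not
emulate.

## Task model and synthetic sessions

A session is a balanced 2 × 2 design: grip ∈ {side, precision} × force ∈
{low, high}, default 30 correct trials per cell. Event times live on a
per-trial clock (ms, switch-on = 0) in the fixed order switch-on → grip
cue (after 800 ms, 300 ms long) → delay (1,000 ms) → go/force cue →
movement onset → object touch → pull onset → release → reward. Reaction
time (go → movement onset) and movement time (movement onset → touch) are
drawn from normal distributions truncated below at 20 ms; only means/SDs
of these distributions are meaningful task parameters, so the truncated
normal is a pragmatic choice, not a behavioral model. The object is held
≥500 ms after pull onset (plus a half-normal extra hold, mean 100 ms) to
mirror the minimum-hold requirement of the task.

**Spiking.** Each unit is an inhomogeneous Poisson process with rate

    r(t) = max(0, baseline · profile(t) · (1 + g·s_g·w_g(t)) · (1 + f·s_f·w_f(t)))

where `s_g, s_f ∈ {−1, +1}` encode the trial's conditions, `w_g`/`w_f` are
indicator windows anchored to task events, and `profile(t)` is an optional
condition-independent gain (default: a perimovement Gaussian bump with
random per-unit latency, amplitude set by `time_amp`). Effects are
multiplicative gains rather than additive rates: rates stay nonnegative
for |gain| ≤ 1 and the induced auROC effect size is independent of the
baseline. A gain of 0.5 yields a 3:1 rate ratio between preferred and
anti-preferred conditions. Spikes are drawn by thinning against the
per-trial rate maximum, which is exact for these piecewise-smooth rates.
The recording window spans 600 ms before switch-on to 2,300 ms after
movement onset, covering every analysis window including the causal-kernel
lookback.

**Coding schemes.** Under `static`, each selective unit carries one long
effect window (grip: from grip cue onward; force: from go onward). Under
`dynamic`, each unit gets a brief (300 ms) window whose onset is drawn
uniformly across the perimovement period, producing a chain of
successively selective units — the two schemes are the generative
counterparts of temporally stable vs transient population codes, and they
are what the static/dynamic separation tests discriminate.

**Force traces.** ~0 before pull onset, linear ramp (150 ms default) to
the condition's level (low 1.0, high 2.0, arbitrary units), hold until
release, ramp down, plus additive Gaussian noise (sd 0.05). Traces are
sampled on the same 20 ms clock as the smoothed rates.

**What the generator does not emulate:** spike-history structure
(refractoriness, bursting), inter-unit correlations beyond shared
condition coding, behavioral errors, electrode/sorting artifacts, and
nonstationarity across a session. Passing tests therefore demonstrate the
*estimators'* calibration and recovery properties under Poisson
variability, not robustness to those real-data features.

**Seeding.** One pipeline seed expands to named per-stage child seeds via
`SeedSequence` (CRC32 of the stage name as entropy), so each stage is
independently reproducible and all child seeds stay below 2³¹.

## Rate estimation

Smoothed rates use a causal exponential kernel, rate(t) = Σ_spikes (1/τ)
exp(−(t − t_spike)/τ) for t ≥ t_spike, τ = 100 ms, evaluated every 20 ms
and aligned to movement onset; the unit-area kernel makes the trace an
instantaneous rate in spikes/s. The kernel is truncated at 5τ (<1% mass
lost). Binned rates are counts in 100 ms windows divided by 0.1 s. The
canonical decoding grid has 51 bins spanning −2,000..+2,000 ms; disjoint
100 ms bins cannot produce 51 bins over 4 s, so window centers step every
80 ms (20 ms overlap between adjacent windows) — the only sliding scheme
consistent with both the window count and the bin width. Windows that
would extend beyond a trial's recorded extent raise an error naming the
trial rather than being silently padded.

## Single-unit selectivity

auROC(t) compares the two levels of one parameter at each bin via the
Mann–Whitney formulation: midranks across trials give
U/(n₁n₂) = P(rate_A > rate_B) + ½P(tie), exactly equal to the exhaustive
pairwise comparison (tested against that oracle). Significance is a label
permutation test, two-sided through |auROC − 0.5| (selectivity direction
is a sign, not evidence), add-one p-values, default 5,000 permutations
(resolving p < 0.001 with margin), and a mask keeping runs of ≥2
consecutive bins with p < α = 0.001. Because ranks are label-free, each
permutation is a subset sum of precomputed midranks — one matrix product
per permutation chunk — which keeps 5,000 permutations on a 100-unit
session to a few seconds. A unit encodes a parameter iff its mask is
nonempty; classes are grip-only / force-only / mixed / none.

**Independence battery.** Per time bin, the marginal-independence χ²
compares the observed 2D histogram of (force, grip) auROC pairs across
units (10 × 10 equal-width bins on [0,1]²; empty-expectation cells
skipped) with the product of its 1D marginals; the null permutes force
values across units. The covariance ellipse of the same scatter reports
the principal-eigenvector angle in [0°, 180°) and 95% axes
(√(χ²₂,0.95 · eigenvalues)); θ near 90° means grip modulation varies with
no covarying force preference. Modulation-*strength* coupling uses Pearson
R between ΔauROC series per bin, with a null that shuffles both Δ matrices
jointly across time and units without replacement (1,000 shuffles), and a
cross-temporal variant correlates grip Δ at each bin with force Δ at lags
−400..+400 ms in 20 ms steps (41 lags), requiring ≥2 consecutive
significant time bins at a lag.

## Demixed PCA

The trial-averaged tensor X (unit × grip × force × time; balanced
equal-weight condition means so unequal counts cannot leak condition
structure) is centered per unit and split into time (condition mean),
grip (grip-conditional mean − time), force (symmetric), and interaction
(remainder). The parts sum to the centered tensor exactly and are mutually
orthogonal. Per marginalization φ, reduced-rank ridge regression minimizes
‖X_φ − D F X‖² + μ‖D F‖²: the ridge projector A = X_φ Xᵀ(X Xᵀ + μI)⁻¹ is
rank-truncated through the SVD of A X, giving orthonormal encoders
D = U_q and decoders F = U_qᵀA. A component's explained variance is the
reduction in reconstruction error of *its own* marginalization,
2⟨e f X, X_φ⟩ − ‖f X‖², as a share of total centered variance; with
orthogonal parts and orthonormal within-marginalization encoders the
retained components can never account for more than 100% in total. With
μ = 0 and data containing a single marginalization, the decomposition
reduces to PCA of that marginalization (verified to <1° principal angles).
Default μ = 10⁻⁶ × total variance — small enough not to bias the
noiseless identities, large enough to stabilize the inverse; the pipeline
exposes it per run.

Single-trial classifiers project trials onto one decoder axis and assign
held-out trials to the nearest training-class mean per bin, using
stratified Monte Carlo leave-group-out CV (one held-out trial per
condition cell, 100 iterations). Chance comes from 100 label shuffles; a
bin is significant when the actual accuracy exceeds *all* shuffles
(the strictest reading of a 100-sample Monte Carlo chance distribution)
for ≥10 consecutive bins. The "first significant" component of a
marginalization is the lowest-variance-rank component with a nonempty
mask; interaction components typically have none on grip/force-separable
data and are then reported as nonsignificant.

## Cross-temporal decoding

Per 100 ms bin, a linear max-margin classifier (standardization fit on
training folds only; C = 1 — the parameter-free field default for a
~100-feature, 50-trial design) is trained on 25 trials per class and
tested on 5, repeated 50 times; the cross-temporal matrix M[i, j] trains
at bin i and tests the held-out trials at bin j, reusing each repetition's
split across train bins so rows are comparable. The shuffled-label null
permutes labels and computes a full matrix from a single split per
iteration (default 1,000 iterations), trading repetition averaging for
null-sample count at fixed cost.

A cell is **static** when (1) it belongs to an 8-connected supra-threshold
cluster (pointwise threshold: per-cell 95th null percentile; cluster mass:
Σ(accuracy − chance)) whose mass exceeds the 99th percentile of null
maximum cluster masses, (2) it exceeds the 99th percentile of its own
cellwise null, and (3) both of its diagonal bins pass a permutation test
Bonferroni-corrected over diagonal bins. For (3) the p-value is the plain
exceedance fraction: with any practical null count an add-one p-value can
never clear 0.01/51, so the criterion operationally means "above every
null sample". Surviving cells are pruned to runs of ≥2 along the test-time
axis (the generalization index is a function of test time). The
generalization index GI_E(t_test) is the fraction of train bins inside
epoch E (preparation: mean grip-cue onset to mean go; execution: mean
movement onset to mean release, in movement-aligned coordinates) that are
static at t_test.

## Behavior and force coupling

RT/MT are summarized per subject; two-subject comparisons use the
Wilcoxon rank-sum normal approximation (z and two-sided p). Trialwise
coupling between the pulling-force trace (normalized to unit peak) and a
component projection is the maximum squared Pearson correlation over lags
±500 ms; its null uses random circular time-shifts of the force trace,
which preserve autocorrelation, with significance at the 99th percentile.
This null is conservative for very low-frequency traces (a circularly
shifted plateau can still correlate at some lag), so the significant
proportion under-rather than over-states coupling. Group structure is a
two-way ANOVA (component family × force level) on the per-trial R²;
factors with a single observed level are dropped from the formula.

## Problem sizes in the shipped tests

The test suite regenerates all data programmatically at the study's scale
where the property demands it (100-unit populations, 30 trials per
condition, 51-bin decoding grids) and at reduced sizes elsewhere;
null-matrix counts in the static/dynamic separation tests use 200
shuffled-label iterations, and auROC calibration tests use 2,000
permutations — both chosen as the smallest counts that resolve the
relevant quantiles with margin.

## Known limitations

- The Poisson generator cannot probe sensitivity to non-Poisson count
  dispersion or correlated noise; calibration results are exact-model
  results.
- The χ² independence test with 10 × 10 bins is underpowered for <50
  units per subpopulation; the bin count is configurable.
- The cluster-based permutation test treats the full matrix as one plane
  (not per train row); both choices are defensible and the plane-wise one
  is implemented.
- dPCA regularization defaults to a fixed small multiple of total
  variance rather than a per-dataset cross-validated grid; for the
  high-SNR trial averages used here the fitted axes are insensitive to μ
  over several orders of magnitude.
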