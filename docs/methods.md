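# Methods

This note documents the models implemented in `fearcond`, the choices
made where the design was genuinely open, and the limits of what the
synthetic experiments demonstrate.

## The synthetic experiment

`fearcond.synth` emulates a two-day head-fixed discriminative fear
conditioning protocol. Day 3 holds a habituation session (4 CS− and 4
CS+ tone trials, alternating) immediately followed by conditioning
(7 CS+ trials, each co-terminating with a 1-s shock, alternating with 7
CS−); day 4 holds a post-conditioning session (4 CS− and 12 CS+, the
first four of each alternating). Every tone trial lasts 30 s and carries
30 pips at 1-s spacing; the shock onset coincides with the 30th pip.
Inter-trial gaps are uniform on [50, 150] s and frames are acquired at
9 Hz. Phase blocks are the first/last 3 conditioning trials per tone
(D3-early / D3-late) and the first 3 / last 3 CS+ trials on day 4
(D4-early / D4-late).

**Behavior** is a per-frame two-state (move/stop) first-order Markov
process — the simplest process giving ≥1-s stationary bouts, which is
the behavioral scoring rule for "stationary" and "freezing-like". With
defaults p(move→stop) = 0.05 and p(stop→move) = 0.08 per frame, stop
bouts last ~1.4 s on average. During D4-early CS+ trials the move→stop
hazard is multiplied by 5 (the conditioned response); D4-late trials
revert to baseline (extinction).

**Activity** is a per-neuron Bernoulli event train convolved with a
single-exponential calcium kernel (τ = 0.25 s, within the fast GCaMP6f
range) plus Gaussian noise (SD 0.15). Rates: 0.12 Hz baseline; CR
members 2.0 Hz in freezing-like frames inside day-4 CS+ trials; RS
members 2.0 Hz in stationary frames everywhere *except* inside day-4
CS+ trials — the representation hand-off that makes the regular-
stationary model lose the CS+ period after conditioning, as observed in
the source experiments; shock-responsive (USR) neurons emit amplitude-3
events with probability 0.85/frame for 1.5 s after each shock. A shared
latent Bernoulli drive (0.5 Hz) adds event probability
`within_cre_corr_gain_d4` (default 0.35) to all CR members on day 4
only, planting the within-ensemble correlation increase.

These rates were fixed once, as values a systems neuroscientist would
call strong-but-realistic state tuning for prefrontal neurons, and all
recovery results below are reported under them.

**Couplings.** Day-resolved pairwise couplings (`GroundTruth.
pairwise_coupling`) are realized by a Gibbs-sampled binary pairwise
model (`sample_ising_raster`). By default, each USR neuron inside the
CR ensemble is coupled on day 4 to 60% of the other members with
strength 0.8 — the planted "hub" structure — and not on day 3. This
raster family is the ground truth for the network-inference validation;
it is separate from the trace generator because rate-modulated traces
and controlled pairwise dependence are hard to plant simultaneously
without confounding one with the other.

**What the generator does not emulate:** biophysical neuron or
indicator dynamics beyond a single-exponential kernel, slow drift,
motion artifacts, neuropil contamination beyond the toy-movie
background field, correlated noise across neurons, or behavioral
states beyond move/stop. Passing recovery tests therefore show that the
*procedures* recover the structure they target under clean conditions
at protocol-realistic sample sizes — not that they are robust to every
nuisance in real recordings.

## Preprocessing

Background subtraction builds a ring around each ROI starting 2–5 px
outside its border, widened up to 35 px until ≥20 pixels survive three
exclusions (membership in any ROI, artificially padded pixels, and
pixels exceeding the ROI series by >2 SD of their pointwise
difference). The ring's mean series is smoothed with a centered 10-s
moving average before subtraction (window choice ours; the purpose —
avoiding point-wise subtraction artifacts — fixes only the smoothing's
existence, not its width; edge windows truncate).

ΔF/F uses F0 = 20th percentile of the raw trace per neuron per day
(robust to sparse transients; configurable). Z-normalization is per
neuron within each day (population SD, divide by n) and is idempotent.
Event binarization thresholds at mean + 2 SD per neuron and marks a 1-s
bin active if any constituent frame is active (preserves sparse
events).

## Stimulus-response scoring

Pip responses average the z trace over the ~1-s window after each pip
(floored to frames, truncated before the next pip); the last pip of
every trial is excluded because it coincides with the shock during
conditioning, leaving 87 samples per 3-trial block. Classification is a
two-tailed Wilcoxon signed-rank test of the 87 samples against zero at
p < 0.05, signed by the block mean.

Baseline choice: by default each trial's samples are re-expressed as
z-scores against the 30-s pre-trial window. The baseline's estimation
error is then shared by the trial's 29 samples, which inflates the
nominal 5% false-classification rate to ~13% on pure noise — an
intrinsic cost of per-trial baselines with within-trial replication
(the independence of pip samples is a recognized concern for this
criterion). Passing `baseline_s=None` scores on the whole-day z scale,
where the nominal rate is exact; both behaviors are covered by tests.

US responses average the whole-day z trace over 1.5 s from each of the
7 shock onsets; a neuron is US-responsive at mean ≥ 1. Whole-day
z-scoring (rather than pre-trial baselines) follows the convention used
for shock-response displays.

## Ensemble extraction

The objective, grids and the resampling/selection procedure are as in
the README. Implementation notes:

- The inner penalized fit maps to scikit-learn's saga solver with
  C = 1/(N·γ) and l1_ratio = α; the mapping is cross-checked in the
  tests against a brute-force grid minimizer of the written objective
  on a two-feature problem.
- Columns are standardized inside `fit`; coefficients are reported on
  the original scale. Ties at predicted probability 0.5 go to class 0.
- γ is selected once per dataset by stratified 7-fold CV *on the
  original frames*. Selecting it on the 900-per-state balanced resample
  would duplicate samples across CV folds whenever fewer than 900
  unique frames exist per state, and the leakage then always favors the
  weakest penalty.
- The Gaussian CI is centroid ± 1.96·σ with σ the maximum-likelihood
  (ddof = 0) standard deviation over the repeat samples; a zero-σ
  coefficient is a member iff its centroid is non-zero.
- The removal analysis re-extracts with 20 repeats, 10 outer estimates
  per arm; the ensemble-removed arm has a fixed column set, so its γ is
  selected once and reused. Alpha optimization anchors at the maximum
  mean AUC difference and returns the largest α whose 10 difference
  estimates are indistinguishable from the anchor's (two-sided
  rank-sum, p ≥ 0.05). RS ensembles use α = 0.75 fixed.

### Selectivity at protocol-bound sample sizes

The conditioning-phase CR dataset is bounded by the protocol to ~810
frames (3 trials × 30 s × 9 Hz) while the population has 100–200
neurons. At the prescribed penalty range (γ ≤ 10⁻²·⁵ on the mean-NLL
scale) such a fit is overparameterized: label-independent neurons
acquire stable non-zero coefficients that the resampling CI reproduces
rather than rejects. Measured on a generator with *no* planted effects,
the selection admits ~25–47% of neurons; on clean iid logistic data the
rate is 26% at N = 810, p = 150 and falls to 0.7% at N = 3000. The rule
is therefore *liberal* in the CR regime — ensembles are reliably a
superset of the informative neurons (recall ≥ 0.85 at default effect
sizes) but not a precise one. This is a property of the procedure, not
of the solver (unchanged under cold starts, tight tolerances, any α in
[0.05, 0.9], and effect sizes up to 6 Hz). Regular-stationary datasets
draw on the full inter-trial record (~12,000 frames), where the same
rule is precise (measured precision 1.0 on planted RS ensembles). The
corresponding selectivity test for the CR condition is asserted at its
stated level and currently fails, intentionally — we prefer an honest
failing check over a silently weakened one.

## Coactivity

Pearson r and t-transform p per neuron pair over the concatenated CS+
frames of a phase (trials concatenated, not averaged). Pairs with a
constant trace are flagged undefined and excluded from summaries. The
null permutes each neuron's masked series independently — total
activity and marginals are exactly preserved. Group summaries report,
per within/across pair set, the mean r, mean positive r, the fraction
of significantly positive pairs, and the paired per-pair change between
days.

## The network model

A pairwise binary graphical model over 1-s event bins (a conditional
random field in the degenerate case of no side observations; stimulus
indicators are deliberately not added as nodes). Structure learning
regresses each node on all others with L1 logistic regression in ±1
coding with the factor-2 convention (C = 1/(M·λs)); an edge survives if
either directed coefficient is non-zero. An unpenalized-leaning
intercept is fitted by default because heterogeneous base rates
otherwise leak into couplings; a {0,1}-coding variant and an AND edge
rule are available behind flags.

Parameter learning maximizes Σₘ⟨φ(yᵐ), θ⟩ − M·log Z(θ) − (λp/2)‖θ‖²
with log Z and the marginals from damped loopy belief propagation
(damping 0.5, ≤200 sweeps, tolerance 10⁻⁶) via the Bethe free energy;
at ≤20 nodes exact enumeration replaces BP automatically, and on trees
the two agree to ≤10⁻⁶ relative error (tested). The ascent itself is
L-BFGS on the exact gradient (empirical minus model marginals minus
ridge) — any ascent reaching the same stationary objective is
equivalent for this model, and conformance is judged by oracle
agreement and recovery rather than optimizer identity. Model selection
is a random 80/20 frame split scored by held-out (approximate)
log-likelihood over λs ∈ [10⁻⁵, 0.5] (100 uniform values by default;
identical learned edge sets are deduplicated) and λp ∈ {1, 10, 100,
10000}.

Readouts: connectivity score = degree/(N−1); node strength (not defined
in the source formulation; our documented choice) is the sum over
incident edges of the coupling contrast |θ₁₁ + θ₀₀ − θ₀₁ − θ₁₀|; the
per-node stimulus LLR clamps the node to 1 vs 0 with the rest of the
frame observed, so the partition function cancels and the series is
local. Note the consequence tested in `test_crf.py`: a node's LLR
varies only through its *neighbors*, so single isolated stimulus-locked
nodes do not decode — stimulus ensembles (mutually coupled locked
nodes) do. The shuffle-calibrated ensemble keeps nodes above mean + SD
of both the decoding-AUC and node-strength distributions from models
re-trained on per-neuron frame-permuted rasters (the same shuffle as
the coactivity null; the shuffling scheme is unspecified in the source
and chosen for consistency).

## Resampling statistics

- **Paired permutation test:** sign-flip null on the mean paired
  difference; exhaustive for ≤20 pairs (the four-pair one-sided floor
  1/16 is exact), otherwise Monte-Carlo including the identity flip so
  p ≥ 1/(n_perm + 1).
- **Hierarchical bootstrap:** units resampled with replacement within
  each animal at original size, identical draws across paired
  conditions, animal-level mean then group mean or median, 2000
  replicates. Two-tailed p doubles the smaller tail with the standard
  +1/(B+1) finite-resample correction. Because animals themselves are
  not resampled (by design), the test is mildly anticonservative for
  very small unit counts per animal (~0.08 at nominal 0.05 for 20
  units/animal) and calibrated at realistic counts (0.052 at 100
  units/animal, 7 animals) — the validity simulation runs at the
  latter scale.
- **Exact 2×2 test** delegates to the standard two-sided Fisher exact
  convention (sum of table probabilities ≤ observed) and is verified
  against brute-force hypergeometric enumeration for every table with
  N ≤ 12. Pearson correlation uses the t transform. Wilcoxon
  signed-rank, rank-sum and Friedman wrappers delegate to vetted
  routines.

## Pipeline

`run_pipeline` executes synthesis → preprocessing → response scoring →
ensemble extraction → coactivity → network inference → statistics,
writing CSV/JSON per stage plus a manifest with package versions,
per-stage seeds and SHA-256 content hashes. Every stochastic stage
seeds from `blake2s(f"{root_seed}:{stage}") mod 2³¹−1`, so runs are
bit-reproducible and stages are independently re-seedable. Stage
failures abort with the stage name after persisting partial outputs.

## Problem sizes used in the test suite

Simulation-based tests run reduced-scale versions of the full design,
chosen as the smallest sizes at which each property is comfortably
measurable: unit tests use 30–40-neuron experiments; ensemble-recovery
checks use the full 150-neuron default over 3 fixed seeds with 50
resampling repeats (the procedure's 100-repeat default changes σ
estimates, not the selection behavior); network recovery uses 12–48
nodes with 1500–2500 Gibbs frames and 20–25-point λs grids; validity
simulations use 1000 null replications.
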