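# Methods

This note documents the models, conventions and numerical choices behind
`statedyn`, and what the synthetic studies do and do not establish.

## State-space model and inference

Each state k of the K-state HMM emits a P-dimensional multivariate normal
N(μ_k, Σ_k) on the standardized, temporally concatenated envelope data of all
subjects; the latent sequence is first-order Markov with row-stochastic
transition matrix A and initial distribution π. Fitting is maximum-likelihood
EM (Baum–Welch):

- **Initialization**: k-means++ clustering of the pooled samples; cluster
  centers seed the means, within-cluster covariances (ridge-floored) seed Σ_k,
  and the smoothed label transition counts seed A.
- **Restarts**: `n_restarts` independent EM runs (default 4 for standalone
  fits, 2 in the pipeline); the run with the best final log-likelihood wins.
  All restart seeds derive deterministically from one root seed.
- **Subject boundaries**: forward–backward and Viterbi restart from π at every
  subject boundary, so no transition is counted across subjects.
- **Numerics**: emission densities are evaluated via Cholesky factors in log
  space; the recursions carry per-sample normalization constants, which is
  stable for concatenated lengths of 10⁵ and beyond. Equal-length subjects are
  processed as one vectorized batch.
- **Regularization**: after every M-step each Σ_k receives a ridge of
  `reg × mean data variance` (default `reg = 1e-6`); a collapse below half
  that floor triggers additional ridge and a log message.
- **Convergence**: relative log-likelihood improvement below `tol`
  (default 1e-6) within `max_iter` (default 100); non-convergence returns the
  model flagged `converged=False` rather than raising.

This is a deliberate substitute for variational Bayesian HMM inference: at
the level the analysis uses the model — point estimates plus hard Viterbi
paths — maximum-likelihood EM is equivalent and fully deterministic given the
seed. Viterbi ties break toward the lower state index.

## Temporal metrics

For each subject and state: FO = samples-in-state / T (unitless), NO = visit
count, MLT = dt · samples-in-state / NO (seconds), MIL = dt · mean
offset-to-onset gap between consecutive visits (seconds). The MIL convention
counts only the NO − 1 gaps strictly between visits; time before the first
and after the last visit is excluded. Since alternatives (including edge
intervals) exist, the convention is recorded in the metrics CSV metadata.

A never-visited state has FO = 0, NO = 0 and missing MLT/MIL; a single-visit
state has missing MIL. These are flags: the matrix assembler drops subjects
with any missing cell by default (logging their IDs) because PLS cannot take
NaNs; `drop_incomplete=False` keeps them.

`TemporalMetrics` carries the integer sample and visit counts alongside the
float ratios. The accounting identities (occupancies sum to one;
FO·T = NO·MLT/dt) are exact in the integer representation; float-level
assertions use 1e-12, since IEEE rounding makes literal float equality
ill-posed.

## PLS and the permutation test

Both blocks are z-scored (n−1 denominator; constant columns raise, naming the
column — ordinal sleep components are z-scored like continuous variables).
The decomposition is the SVD of `C = XᵀY/(n−1)`; component signs are fixed so
the mean behavioral salience is nonnegative. The |0.2| interpretation
threshold is applied to **structure loadings** (variable–score Pearson
correlations), because those are bounded in [−1, 1] and an absolute cut-off
on them is meaningful; raw weights are also reported.

The permutation test shuffles whole subject rows of Y; the k-th observed
singular value is compared with the k-th permuted singular values (no
re-alignment), with `p = (1 + #{s_perm ≥ s_obs}) / (1 + n_perm)` — ties count
against the hypothesis, guaranteeing valid p-values on the grid
{1/(n_perm+1), …, 1}. A conservative familywise alternative
(`statistic="max"`, comparing against the permuted largest singular value) is
available. The observed statistic is computed with the same SVD routine as
the permuted ones so that an identity permutation ties exactly.

## Moderation and profile comparison

The moderation model regresses the z-scored behavioral latent on the z-scored
brain latent, z-scored age, and their interaction, by OLS; reported β are
standardized, with two-sided t tests on n − (k+1) residual df. The
interaction is **z-then-product**: z-score brain and age, multiply, re-z the
product (the raw-product-then-z alternative is a flag). No automatic outlier
removal is performed anywhere.

Profile comparison correlates the brain-side loading vectors of two PLS
analyses (component: first significant by default, explicit indices
supported), overall and within named feature groups, plus the per-subject
brain scores; the second analysis is sign-aligned to the first and the flip
recorded. Per-group correlations do not average to the overall correlation —
the test suite demonstrates this on a constructed counter-example rather than
asserting any such identity.

## Synthetic cohort generator

The generator is the study bed: subjects get Markov state paths (desk scale:
K = 3 states over 5 parcels, sticky transitions with stay probability 0.8,
dt = 0.1 s, i.e. mean dwell 0.5 s; paper scale: K = 8 over 38 parcels),
Gaussian envelope emissions on a positive baseline (amplitude 6 ± ~0.9, so
negative draws are ~7σ events; any that occur are clipped and counted), and
behavior built from the true metrics:

- b = z(w·z(metrics)), the standardized planted brain latent (unit salience
  w follows a "neural shift" pattern: the first half of the states load
  positively on FO/NO and negatively on MIL, the second half oppositely);
- sleep latent s = ρ·b + γ_std·z(age) + δ·z(b·z(age)) + noise, with
  γ_std = γ_per-year · SD(age) and noise completing s to unit population
  variance by default, so ρ (default 0.5), γ (default −0.015/yr ≈ −0.30
  standardized) and δ (default 0) are standardized effect sizes directly
  comparable to the second-level β̂. The interaction uses the same
  z-then-product convention as the moderation model — with age in raw years
  the product would inject a mean-age-scaled main effect (~53·δ) and the
  planted δ would not be recoverable as a standardized coefficient;
- seven sleep components λ_j·s + N(0, 0.6), discretized to {0,1,2,3} by
  within-cohort quartile cutpoints (balanced ordinal categories, which keep
  the planted covariance detectable after coarsening); λ puts the strongest
  loadings on the efficiency/duration/medication analogues and the weakest on
  daytime dysfunction;
- thirteen cognitive scores c_j·(−b) + N(0, 0.6): a higher brain latent
  accompanies worse cognition, with the fluid-intelligence analogue loading
  strongest.

Ages are uniform on [18, 88] years, entered in years and standardized
downstream. All randomness flows from the scenario seed through named
substreams, so identical configs reproduce cohorts bitwise.

One caveat the tests make explicit: the population singular vector of the
metrics↔sleep-latent cross-covariance is R·w (R = metric correlation matrix),
not w itself, because the planted salience acts through correlated features.
Salience-recovery accuracy is therefore validated on a direct rank-1 block
construction (`planted_rank1_blocks`), where the planted pair and the
singular pair coincide.

**What the generator does not emulate**: sensor-space MEG, source leakage,
head motion, non-Gaussian envelope marginals, heavy-tailed or skewed sleep
score distributions, item-level PSQI scoring, missing behavioral data, and
any realistic anatomical structure in the state maps. Passing tests show the
statistical machinery is correct and calibrated under the planted model, not
that real cohort effects of a given size would be detected.

## Problem sizes in the shipped studies

The verification studies run at desk scale by the package's own choice:
Viterbi oracle at K = 3, T = 8 (3⁸ enumerable sequences, 100 instances);
metric identities on 10,000 random paths; HMM recovery on 20 subjects × 1,000
samples (K = 3, P = 5, well-separated means); PLS recovery at n = 500;
permutation calibration over 200 null cohorts × 199 permutations; moderation
calibration over 500 null cohorts and 200 effect cohorts (δ = 0.2, n = 500);
the end-to-end profile comparison over 20 cohorts of 500 subjects × 150
samples. The paper-scale scenario (K = 8, 38 parcels) is exercised
structurally (32-column feature matrix) and available for demo runs.

## Known limitations

- EM finds local optima; restarts mitigate but do not guarantee the global
  maximum (the restart-robustness property is tested at desk scale).
- Hard Viterbi paths discard posterior uncertainty; soft (posterior
  probability) occupancy variants are out of scope.
- The quartile discretization of sleep components is a stand-in, not an
  inference about any real response process; real PSQI components are
  unbalanced and skewed.
- With K approaching the parcel count or short series, never-visited states
  make subject drop-out under `drop_incomplete` non-negligible.
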