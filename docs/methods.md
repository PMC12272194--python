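# Methods

`parcelrsa` implements a representational-similarity analysis (RSA) of
high-dimensional spatiotemporal fMRI response patterns and a synthetic-data
generator that emulates the design and statistical structure of a
familiarization experiment, so that every analysis stage can be exercised and
validated without access to MRI data.

## The experimental design being emulated

Observers view runs of 200 objects: 180 presentations of κ = 15 *recurring*
objects (which become familiar) interleaved with 20 *non-recurring* objects
(each shown exactly once, hence permanently novel). Six runs form a session;
three sessions give 18 runs, 3,240 recurring and 360 novel presentations per
dataset. Recurring objects follow a constrained random walk: no immediate
repetitions (X→X) and, by default, no direct returns (X→Y→X). "Structured"
sequences limit each object to 3 successors; since the original transition
graph is external to this package, a deterministic ring lattice
({i+1, i+2, i+3} mod κ) stands in, and an explicit successor table can be
supplied. "Unstructured" sequences allow all admissible successors.

**Counterbalancing.** Appearance counts of every recurring object are meant
to be balanced within each session. Pure rejection sampling of uniform walks
is infeasible: per-object session counts are 72 ± 4.7 (SD), so the
probability that all 15 objects land within ±2 of the target is of order
10⁻⁶. Instead, successors are sampled with probabilities proportional to each
object's remaining session quota, multiplied by a softened run-level balance
factor; a session is regenerated if any count still deviates by more than the
tolerance (default ±2). The softness constant (5.0) was chosen so the per-run
appearance counts show a dispersion of about 12 ± 1.9, the value reported for
the original design; session-level post-selection then nearly always accepts.

## Synthetic response patterns

A trial's pattern is a point in an N_dim = N_t · N_vox dimensional space
(default 9 time points × 200 voxels). The generator composes:

* **Class structure.** κ centroids drawn isotropically with expected norm
  `class_separation` (in units of the within-class SD, default 1.0 — chosen
  so the cross-validated decoding accuracy of a default dataset falls in the
  middle of the range reported for identity-selective parcels); isotropic
  Gaussian within-class noise with SD `within_sd` (default 1).
* **Learning dynamics**, piecewise-linear in the batch index m = 1..5
  (batches are chronological quintiles of each object's presentations):
  the between-class spread scales by 1 + `identity_ssb_rate`·(m−1)
  (default −0.03, a slight decline); the novel-pattern cloud's center moves
  along a fixed direction at `novelty_offset_rate` (default 0.25 within-SD
  per batch) and the cloud contracts at `novel_contraction_rate` (default
  0.10 per batch), applied both to the spread of per-exemplar means and to
  the novel trials' within-noise. Novel-cloud directions are drawn within
  the span of the recurring centroids: novel objects are represented in the
  same representational space as recurring ones (their pairwise distances are
  initially comparable to those between different recurring objects when
  measured in the discriminative subspace), and a random direction in a
  ~10³-dimensional pattern space would be almost orthogonal to that subspace.
  Contracting the novel trials' within-noise (not only the exemplar-mean
  cloud) is what lets novel–novel distances fall below same-object distances
  with learning, as observed.
* **Temporal correlation.** A within-run latent component with a Toeplitz lag
  covariance solved from the target delay profile (default: distances ~5%
  smaller at lags < 4 trials, ~2% larger at lags 6–15). The kernel's positive
  semidefiniteness is checked at construction; `latent_share` (default 0.3)
  sets the variance fraction carried by the latent. Because class-mean
  separation dilutes the measured modulation, profile-recovery checks are run
  at `class_separation = 0` (the profile is defined for statistically
  identical patterns).
* **Amplitude drift.** A multiplicative factor linear in the trial number,
  centered on 1 (default +2% across a run).

Not emulated: hemodynamic convolution, voxel-level spatial correlation,
physiological noise spectra, or session-level scanner effects. Passing tests
therefore demonstrate the correctness and calibration of the *analysis*, not
the realism of raw BOLD time series.

## Direct linear discriminant analysis

With κ classes, at most κ−1 dimensions carry discriminative signal. Direct
LDA first diagonalizes the between-class scatter (size-weighted by class
counts, 1/N normalization), keeps the eigenvectors with non-negligible
eigenvalues (relative threshold 10⁻¹⁰ of the largest, with an absolute anchor
at 10⁻¹² of the total variance so colliding class means are detected), then
diagonalizes the within-class scatter in that basis and rescales every
dimension to unit within-class variance. Near-zero within-class eigenvalues
are floored at 10⁻⁸ of the mean within eigenvalue before inversion (a
"discard" mode is available); flooring events are recorded in the model
metadata. Euclidean distances in the resulting subspace S realize the
standardized (Mahalanobis) metric, so no second whitening is applied
anywhere downstream.

The projection is purely linear (a zero pattern maps to zero coordinates);
the training grand mean enters only the scatter computations. Each projection
column's sign is fixed (largest-magnitude loading positive) so repeated fits
are bitwise identical. Back-projection uses the right inverse
P (PᵀP)⁻¹, making project∘back-project the identity on S.

## Metrics

* **Confusion / accuracy.** Nearest training-centroid assignment in S, ties
  broken to the lowest class index; α is weighted by the test-set priors.
* **Pairwise discriminability.** δ_ij = |μ_i − μ_j| / √(½(σ_i² + σ_j²)) from
  projections onto the line connecting the two *test-set* centroids
  (training centroids available as an option); δ̄ is the mean over unordered
  pairs. Projection variances use the unbiased (ddof = 1) estimator.
* **Variance decompositions.** All SS terms are normalized by the number of
  exemplars; SST = SSW + SSB holds to 10⁻⁹ relative on any input. The
  identity pseudo-F is SSB(N−κ)/(SSW(κ−1)) (PERMANOVA statistic); the
  novelty pseudo-F is SSB(N+M−2)/SSW with SSB computed two ways
  (size-weighted centroids and NM/(N+M)²‖c_fam−c_nov‖²) and cross-checked
  numerically. Per-dimension dispersions follow σ_W = √(SSW·N/(N−κ)) and
  σ_B = √(SSB·N/(κ−1)); this convention is stated explicitly because the SS
  terms are already N-normalized.
* **Normalized geometry.** a_k = ‖x_k‖/√(κ−1), d_kl = ‖x_k−x_l‖/√(κ−1).
* **Lag correction.** T(Δk) is the mean distance at trial lag Δk pooled
  within runs (and across datasets via pair-count-weighted pooling); the
  corrected distance is d − T(Δk) + ⟨T⟩_Δk. Lags with fewer than two pairs
  are interpolated from neighbors; lags beyond the profile, and cross-run
  pairs, receive no net correction. Variance decompositions use raw
  coordinates (centroid distances cannot be lag-corrected); only pairwise
  distance summaries use corrected distances. Amplitudes are not corrected.
* **Per-run summaries.** A and D averages over the stated trial/pair sets
  with actual pair-count denominators; R_identity = SS_diff(N−κ)/(SS_same(κ−1))
  and R_novelty = SS_novfam(N+M−2)/(SS_nov + SS_fam). The R_novelty
  denominator is taken as the within-class total SS_nov + SS_fam (the
  rendering of this formula is ambiguous in its source; the within-total is
  the only choice consistent with the novelty pseudo-F).

## Inference

Cross-validation uses N_r repeated stratified 90/10 splits; only recurring
trials ever enter training sets. Batch-restricted schemes draw test trials
from one chronological batch — by default half of the batch's trials per
class, matching the reported test-set sizes of ~21 out of a 42-trial batch
(the unrestricted scheme's 10% fraction would give ~4) — with the training
set the complement across all batches.

First-level nulls permute the test-set labels (or the recurring/novel
partition) with the DLDA projections held fixed; the observed statistic is
computed by the identical pipeline. The global null over n datasets uses the
minimum statistic m = min_k α_k (or F_k): each second-level draw samples one
first-level value per dataset (the observed value included in each pool) and
takes the minimum; p-values use the (r+1)/(k+1) inclusion convention.
Multiple comparisons are corrected by Bonferroni (default 758 parcels × 2
conditions). The prevalence bound
P(γ_true < γ₀) ≤ [(1−γ₀)p*^{1/n} + γ₀]^n and the estimate
γ_est = (α^{1/n} − p*^{1/n})/(1 − p*^{1/n}) are closed forms; a parcel is
declared selective when the bound falls below α. Solving the bound equation
for p at n = 16, γ₀ = 0.5, α = 0.05 gives p* ≈ 1.25 × 10⁻³.

Note that with γ₀ = 0.5 the bound cannot fall below (γ₀)^n, so selectivity is
unreachable with fewer than ⌈log α / log γ₀⌉ = 5 datasets; the demo pipeline
therefore uses 8.

## Trends and stability

Linear rates β are estimated by REML mixed models (random intercept and slope
per dataset). When both parcels and datasets group the data, the grouping
factor is their interaction (a pragmatic stand-in for fully crossed random
effects, which the underlying fitter does not support cleanly). Degenerate
fits fall back to a random-intercept-only model and finally to per-group OLS
slopes with a one-sample t-test; every fallback is flagged in the result.

Fixed-subspace analyses fit DLDA once on *all* recurring trials of a dataset
(deliberately non-cross-validated, trading optimism for a stable frame).
Run-level stability compares per-class per-run centroids C_r against their
across-run average C_ave (DC_r = ‖C_r − C_ave‖) and against the previous run
(ΔDC_r = ‖C_r − C_{r−1}‖), with 15 recurring classes plus one pooled novel
class; aggregates are unweighted means over classes. Centroid distances are
not lag-corrected. The pseudo-run baseline permutes trials within each
response class (preserving per-run class composition) and recomputes DC/ΔDC
over N_r replicates (default 1,000).

For i.i.d. isotropic run centroids the expected ratio ΔDC/DC is
√2 · (1 − 1/R)^{-1/2} ≈ 1.456 at R = 18 runs (the finite-sample C_ave shrinks
DC slightly); the large-R limit is √2 ≈ 1.414. The reference mean distance
between two independent points uniform on the unit hypersphere *surface* in
n dimensions is d̄ = 2^{n−1} Γ(n/2)² / (√π Γ(n−½)), ≈ 1.4007 at n = 14
(verified against Monte-Carlo; the ball-interior analogue would be ≈ 1.31 and
is clearly not the intended reference).

## Numerical and scale choices

Tests and the reproduction script run the full pipeline at reduced problem
sizes chosen to keep every check statistically meaningful: parcels of 60–270
dimensions instead of ~1,800, N_r = 2–5 split repeats, 60–300 permutations
per null, 10⁴ second-level draws, and 100–200 replicate simulations for
calibration/recovery properties. Type-I calibration asserts the rejection
rate ≤ α plus two binomial standard errors of the replicate count; sign
recovery pools two datasets per replicate (the analysis it mirrors pools 16).

## Known limitations

* The mixed-model grouping is an interaction, not truly crossed.
* The generator's learning dynamics are piecewise-linear in batch index; the
  real time courses are nonlinear (rapid early change).
* The lag-profile latent induces the target modulation exactly only for
  statistically identical patterns; class separation dilutes it by a few
  percent at default settings.
* MDS uses SMACOF (metric stress) with random restarts; stress values are
  reported raw and are not comparable across matrix sizes.
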