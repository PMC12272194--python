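# parcelrsa

Representational similarity analysis (RSA) of learning-dependent object
representations in parcel-level fMRI patterns: multi-class discriminant
subspaces, permutation/prevalence inference, and representational-geometry
drift tracking — together with a synthetic-data generator that emulates the
underlying familiarization experiment, so the whole pipeline is testable
without any imaging data.

## The problem

In a multi-session familiarization experiment, observers view runs of 200
rotating 3-D objects — 180 presentations of κ = 15 *recurring* objects that
gradually become familiar, interleaved with 20 *non-recurring* objects that
each appear exactly once and remain novel. Each trial evokes a spatiotemporal
activity pattern **x**ₖ ∈ ℝ^{N_t·N_vox} in every cortical parcel (typically
9 time points × ~200 voxels ≈ O(10³) dimensions). Two questions drive the
analysis: which parcels carry information about object *identity* (the 15
recurring classes) and object *novelty* (recurring vs non-recurring), and how
the geometry of these representations changes as familiarity grows.

## The method

* **Direct LDA (DLDA).** For each parcel, the (κ−1)-dimensional subspace S
  that optimally discriminates the κ classes is found by diagonalizing the
  between-class scatter first and the within-class scatter second, avoiding
  the singular inversion of classical LDA in the n ≪ d regime. Dimensions of
  S are rescaled to unit within-class variance, so Euclidean distance in S is
  the standardized (Mahalanobis) metric.
* **Metrics in S.** Nearest-centroid confusion matrix and accuracy α;
  pairwise discriminability δᵢⱼ = |μᵢ−μⱼ|/√(½(σᵢ²+σⱼ²)) from projections
  onto centroid lines; PERMANOVA-style variance decomposition SST = SSW + SSB
  with pseudo-F = [SSB/(κ−1)]/[SSW/(N−κ)]; normalized amplitudes
  aₖ = ‖xₖ‖/√(κ−1) and distances d_kl = ‖xₖ−x_l‖/√(κ−1), with a trial-lag
  (temporal autocorrelation) correction d − T(Δk) + ⟨T⟩.
* **Inference.** Cross-validation with repeated stratified 90/10 splits;
  first-level label permutations; the *minimum statistic* m = min_k α_k over
  n datasets to test the global null; Bonferroni correction; and a
  closed-form *prevalence* bound P(γ_true < γ₀) ≤ [(1−γ₀)p*^{1/n} + γ₀]^n
  deciding which parcels are identity-selective in the majority of datasets.
* **Learning trends and stability.** Per-batch cross-validated pseudo-F
  z-scored against shuffle nulls, linear rates β from REML mixed models,
  fixed-subspace run-level geometry (amplitudes, category distances, variance
  fractions), per-run class centroids with DC/ΔDC displacement statistics
  against a pseudo-run permutation baseline, and the hypersphere reference
  d̄(n) = 2^{n−1}Γ(n/2)²/(√π Γ(n−½)) for fully random displacements.

See `docs/methods.md` for the full model description, conventions, and
numerical choices.

## Worked example

```python
import parcelrsa as pr

design = pr.DesignSpec(structure="unstructured")
sequences = pr.generate_experiment(design, rng_seed=0)
parcel = pr.ParcelSpec(n_voxels=50, n_timepoints=9)
dataset, truth = pr.simulate_parcel_responses(sequences, parcel,
                                              pr.GeneratorParams(), rng_seed=0)
print(f"dataset: {dataset.n_trials} trials x {dataset.n_dim} dimensions")

metrics = pr.crossval_metrics(dataset, pr.CVScheme(n_repeats=20), rng_seed=0)
print(f"accuracy alpha = {metrics.accuracy:.3f}  (chance 1/15 = {1/15:.3f})")
print(f"mean pairwise discriminability delta = {metrics.delta_mean:.2f}")
print(f"pseudo-F identity = {metrics.f_ratio:.2f}")

null = pr.permutation_null(dataset, pr.CVScheme(n_repeats=5), n_perm=500,
                           rng_seed=1)
print(f"permutation p = {null.pvalue:.4g}  (observed {null.observed:.3f}, "
      f"null mean {null.samples.mean():.3f})")

res = pr.prevalence(p_corrected=0.0012, n=16)
print(f"prevalence bound = {res.bound:.3f}, gamma_est = {res.gamma_est:.2f}, "
      f"selective = {res.selective}")
```

Output:

```
dataset: 3600 trials x 450 dimensions
accuracy alpha = 0.138  (chance 1/15 = 0.067)
mean pairwise discriminability delta = 1.32
pseudo-F identity = 1.37
permutation p = 0.001996  (observed 0.116, null mean 0.066)
prevalence bound = 0.049, gamma_est = 0.50, selective = True
```

The synthetic parcel carries a genuine identity code: cross-validated
decoding of 15 classes reaches 13.8% against the 6.7% chance level, the
label-permutation null confirms it (p ≈ 0.002 at 500 permutations), and a
corrected minimum-statistic probability of 0.0012 over 16 datasets sits
exactly at the γ₀ = 0.5 prevalence threshold — the parcel would be declared
identity-selective in the majority of datasets.

A command-line interface mirrors the library:

```bash
parcelrsa simulate-design --structure unstructured --seed 0 --out design.tsv
parcelrsa simulate-bold --design design.tsv --parcel-voxels 50 --seed 0 --out ds.h5
parcelrsa crossval --data ds.h5 --seed 0
parcelrsa run --seed 1 --out report/      # end-to-end synthetic pipeline
```

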