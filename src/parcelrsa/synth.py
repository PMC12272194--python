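"""Synthetic parcel-level spatiotemporal response patterns.

Emulates the statistical structure the analysis assumes, so every downstream
stage can be exercised with known ground truth:

* kappa recurring classes with Gaussian class-structured means and isotropic
  within-class noise of unit SD,
* batchwise decline of the recurring between-class spread (learning makes
  identity geometry contract slightly),
* a novel-pattern cloud that drifts away from the recurring centroids while
  its dispersion contracts,
* a delay-dependent distance modulation (weak temporal correlation between
  nearby trials, induced by a within-run latent component with a lag
  covariance solved from the target profile),
* a slight multiplicative amplitude drift over the course of each run.

Not modelled: hemodynamic convolution, voxel spatial correlation maps, or
physiological noise spectra — the generator produces the *pattern-space*
statistics the method consumes, not raw BOLD time series.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.linalg import toeplitz

from .design import NOVEL, TrialSequence


class DimensionalityError(ValueError):
    """Pattern dimensionality too small for the requested class count."""


class ProfileError(ValueError):
    """Delay profile invalid (non-positive or not realizable)."""


@dataclass(frozen=True)
class ParcelSpec:
    """Dimensions of one parcel's spatiotemporal patterns: n_dim = N_t * N_vox."""

    n_voxels: int = 200
    n_timepoints: int = 9

    def __post_init__(self):
        if self.n_voxels <= 0 or self.n_timepoints <= 0:
            raise ValueError("counts must be positive")

    @property
    def n_dim(self) -> int:
        return self.n_timepoints * self.n_voxels


def default_autocorr_profile() -> dict[int, float]:
    """Observed modulation: ~5% smaller distances below lag 4, ~2% larger at
    lags 6-15, none elsewhere."""
    prof = {k: 0.95 for k in (1, 2, 3)}
    prof.update({k: 1.02 for k in range(6, 16)})
    return prof


@dataclass
class GeneratorParams:
    """Tunable statistical structure of the synthetic data.

    class_separation is the expected distance of a recurring class centroid
    from the grand centroid, in units of the within-class SD.  The batchwise
    rates are piecewise-linear in the batch index m = 1..5: between-class
    spread scales as 1 + identity_ssb_rate (m-1); the novel-cloud center is
    offset by novelty_offset_rate (m-1) (within-SD units) along a fixed
    direction; the novel-cloud dispersion is novel_dispersion0
    (1 - novel_contraction_rate (m-1)), floored at 0.
    """

    class_separation: float = 1.0
    within_sd: float = 1.0
    identity_ssb_rate: float = -0.03
    novelty_offset_rate: float = 0.25
    novel_contraction_rate: float = 0.10
    novel_dispersion0: float | None = None   # defaults to class_separation
    autocorr_profile: Mapping[int, float] = field(default_factory=default_autocorr_profile)
    latent_share: float = 0.3                # variance fraction carried by the lag latent
    amplitude_drift_per_run: float = 0.02
    same_object_distance_boost: float = 0.0  # optional, default off
    n_batches: int = 5
    rng_seed: int = 0

    def __post_init__(self):
        if self.within_sd <= 0:
            raise ValueError("within_sd must be positive")
        if any(v <= 0 for v in self.autocorr_profile.values()):
            raise ProfileError("autocorr_profile values must be positive")
        if not 0 <= self.latent_share < 1:
            raise ValueError("latent_share must be in [0, 1)")
        if self.novel_dispersion0 is None:
            self.novel_dispersion0 = self.class_separation


@dataclass
class ResponseDataset:
    """Trials x n_dim pattern matrix with labels and design indices."""

    patterns: np.ndarray            # (n_trials, n_dim) float32
    labels: np.ndarray              # object id 1..kappa, NOVEL (0) for novel
    novel_exemplar_id: np.ndarray
    run: np.ndarray
    session: np.ndarray
    batch: np.ndarray
    trial: np.ndarray               # 1-based index within run
    observer_id: str = "obs1"
    condition: str = "cond1"
    parcel_id: str = "parcel1"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        n = len(self.labels)
        for name in ("novel_exemplar_id", "run", "session", "batch", "trial"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length mismatch")
        if self.patterns.shape[0] != n:
            raise ValueError("patterns row count mismatch")

    @property
    def n_trials(self) -> int:
        return len(self.labels)

    @property
    def n_dim(self) -> int:
        return self.patterns.shape[1]

    @property
    def is_novel(self) -> np.ndarray:
        return self.labels == NOVEL

    @property
    def kappa(self) -> int:
        return int(len(np.unique(self.labels[~self.is_novel])))


@dataclass
class GroundTruth:
    """Injected quantities, recomputable deterministically from the seed."""

    class_centroids: np.ndarray        # (n_batches, kappa, n_dim) noiseless means
    novel_center: np.ndarray           # (n_batches, n_dim)
    novel_dispersion: np.ndarray       # (n_batches,) exemplar-cloud spread
    novel_exemplar_means: np.ndarray   # (n_novel, n_dim)
    autocorr_profile: dict
    amplitude_drift_per_run: float
    within_sd: float
    latent_share: float
    batch: np.ndarray                  # per-trial batch index
    novel_noise_scale: np.ndarray = None   # (n_batches,) trial-noise factor


def chronological_batches(labels: np.ndarray, n_batches: int = 5) -> np.ndarray:
    """Assign each trial a batch 1..n_batches: successive chronological
    quantiles of each recurring object's presentations (novel trials are
    pooled as one class); earlier batches receive the extra trials."""
    y = np.asarray(labels)
    batch = np.zeros(len(y), dtype=np.int64)
    for obj in np.unique(y):
        pos = np.flatnonzero(y == obj)
        for m, chunk in enumerate(np.array_split(pos, n_batches), start=1):
            batch[chunk] = m
    return batch


def _lag_latent_covariance(profile: Mapping[int, float], latent_share: float,
                           run_len: int) -> np.ndarray | None:
    """Per-dimension lag covariance of the within-run latent component.

    Solving E d^2(dk) proportional to p(dk)^2 for the latent autocorrelation
    gives rho(dk) = (1 - p(dk)^2) / latent_share at profiled lags and 0
    elsewhere.  The resulting Toeplitz kernel must be positive semidefinite.
    """
    if not profile or all(v == 1.0 for v in profile.values()):
        return None
    if latent_share == 0:
        raise ProfileError("non-flat autocorr_profile requires latent_share > 0")
    rho = np.zeros(run_len)
    rho[0] = 1.0
    for lag, p in profile.items():
        if not 1 <= int(lag):
            raise ProfileError(f"invalid profile lag {lag}")
        if lag < run_len:
            rho[int(lag)] = (1.0 - p ** 2) / latent_share
    if np.any(np.abs(rho[1:]) > 1):
        raise ProfileError("profile too strong for the configured latent_share")
    cov = toeplitz(rho)
    evals = np.linalg.eigvalsh(cov)
    if evals.min() < -1e-8:
        raise ProfileError(
            f"profile not realizable: lag covariance has eigenvalue {evals.min():.3g}")
    return cov


def _latent_factor(cov: np.ndarray) -> np.ndarray:
    evals, vecs = np.linalg.eigh(cov)
    return vecs * np.sqrt(np.clip(evals, 0.0, None))


def simulate_parcel_responses(sequences: Sequence[TrialSequence],
                              parcel: ParcelSpec, params: GeneratorParams,
                              rng_seed=None) -> tuple[ResponseDataset, GroundTruth]:
    """Generate one dataset of spatiotemporal patterns for the given design.

    Each trial's pattern is its (batch-dependent) noiseless class mean plus
    isotropic Gaussian noise, plus a within-run latent component inducing the
    delay-dependent distance profile, scaled by the within-run amplitude
    drift.  Returns the dataset and the injected ground truth.
    """
    rng = np.random.default_rng(params.rng_seed if rng_seed is None else rng_seed)
    d = parcel.n_dim
    labels = np.concatenate([s.object_id for s in sequences])
    novel_id = np.concatenate([s.novel_exemplar_id for s in sequences])
    run = np.concatenate([np.full(len(s), s.run) for s in sequences])
    session = np.concatenate([np.full(len(s), s.session) for s in sequences])
    trial = np.concatenate([s.trial for s in sequences])
    n = len(labels)
    rec_classes = np.unique(labels[labels != NOVEL])
    kappa = len(rec_classes)
    if d < kappa:
        raise DimensionalityError(f"n_dim={d} < kappa={kappa}: DLDA infeasible")
    batch = chronological_batches(labels, params.n_batches)

    sd = params.within_sd
    # recurring class centroids: expected norm = class_separation * within_sd
    base_centroids = (params.class_separation * sd / np.sqrt(d)
                      * rng.standard_normal((kappa, d)))
    scale_m = 1.0 + params.identity_ssb_rate * (np.arange(params.n_batches))
    centroids_per_batch = scale_m[:, None, None] * base_centroids[None, :, :]

    # Novel objects are represented in the same representational space as
    # recurring ones (their between-exemplar distances are initially
    # comparable to those between recurring objects, measured in the
    # discriminative subspace), and the novel cloud drifts to the margins of
    # that space with learning.  Both the cloud offset and the per-exemplar
    # spread therefore live in the span of the recurring centroids; random
    # pattern-space directions would be almost orthogonal to the
    # discriminative subspace at realistic dimensionality.
    centered = base_centroids - base_centroids.mean(axis=0)
    if np.linalg.norm(centered) > 1e-12:
        span, _ = np.linalg.qr(centered.T)          # d x kappa basis
        span = span[:, :max(kappa - 1, 1)]
    else:                                           # no class structure
        span, _ = np.linalg.qr(rng.standard_normal((d, max(kappa - 1, 1))))
    k_span = span.shape[1]
    offset_dir = span @ rng.standard_normal(k_span)
    offset_dir /= np.linalg.norm(offset_dir)
    offsets = (params.novelty_offset_rate * sd
               * np.arange(params.n_batches))[:, None] * offset_dir[None, :]
    disp_m = params.novel_dispersion0 * sd * np.clip(
        1.0 - params.novel_contraction_rate * np.arange(params.n_batches), 0.0, None)

    # per-exemplar novel means, drawn in exemplar order
    nov_rows = np.flatnonzero(labels == NOVEL)
    n_nov = len(nov_rows)
    nov_dirs = (rng.standard_normal((n_nov, k_span)) @ span.T) / np.sqrt(k_span)
    nov_means = np.empty((n_nov, d))
    for j, row in enumerate(nov_rows):
        m = batch[row] - 1
        nov_means[j] = offsets[m] + disp_m[m] * nov_dirs[j]

    means = np.empty((n, d))
    lut = {c: i for i, c in enumerate(rec_classes)}
    rec_rows = np.flatnonzero(labels != NOVEL)
    means[rec_rows] = centroids_per_batch[batch[rec_rows] - 1,
                                          [lut[c] for c in labels[rec_rows]]]
    means[nov_rows] = nov_means

    # contraction of the novel-pattern cloud: novel trials' within-noise and
    # exemplar spread shrink together (the observed novel-novel distances
    # fall below the same-object distances with learning, which pattern-mean
    # contraction alone cannot produce)
    contraction = np.clip(1.0 - params.novel_contraction_rate
                          * np.arange(params.n_batches), 0.0, None)
    noise_sd = sd * np.sqrt(1.0 - params.latent_share)
    noise = noise_sd * rng.standard_normal((n, d))
    noise[nov_rows] *= contraction[batch[nov_rows] - 1][:, None]
    X = means + noise
    if params.same_object_distance_boost > 0:
        # extra isotropic jitter on recurring trials: inflates same-object
        # distances by ~boost (different-object distances inflate slightly too)
        extra = sd * np.sqrt(max((1 + params.same_object_distance_boost) ** 2 - 1, 0))
        X[rec_rows] += extra * rng.standard_normal((len(rec_rows), d))

    # within-run latent component with the target lag covariance
    run_len = max(len(s) for s in sequences)
    cov = _lag_latent_covariance(params.autocorr_profile, params.latent_share, run_len)
    latent_sd = sd * np.sqrt(params.latent_share)
    if cov is not None:
        F = _latent_factor(cov)
        for s in sequences:
            rows = np.flatnonzero(run == s.run)
            g = F[:len(rows), :] @ rng.standard_normal((cov.shape[0], d))
            X[rows] += latent_sd * g
    elif params.latent_share > 0:
        X += latent_sd * rng.standard_normal((n, d))

    # multiplicative amplitude drift, linear within run, centered on 1
    if params.amplitude_drift_per_run != 0:
        for s in sequences:
            rows = np.flatnonzero(run == s.run)
            tt = (trial[rows] - 1) / max(len(rows) - 1, 1)
            X[rows] *= (1.0 + params.amplitude_drift_per_run * (tt - 0.5))[:, None]

    ds = ResponseDataset(patterns=X.astype(np.float32), labels=labels,
                         novel_exemplar_id=novel_id, run=run, session=session,
                         batch=batch, trial=trial,
                         meta={"seed": rng_seed if rng_seed is not None else params.rng_seed,
                               "n_voxels": parcel.n_voxels,
                               "n_timepoints": parcel.n_timepoints})
    gt = GroundTruth(class_centroids=centroids_per_batch, novel_center=offsets,
                     novel_dispersion=disp_m, novel_noise_scale=contraction, novel_exemplar_means=nov_means,
                     autocorr_profile=dict(params.autocorr_profile),
                     amplitude_drift_per_run=params.amplitude_drift_per_run,
                     within_sd=sd, latent_share=params.latent_share, batch=batch)
    return ds, gt


def make_multi_dataset(sequences_per_dataset, parcel: ParcelSpec,
                       shared_params: GeneratorParams, n_observers: int = 8,
                       n_conditions: int = 2, effect_present: bool = True,
                       rng_seed=0) -> list[ResponseDataset]:
    """Generate n_observers x n_conditions datasets for one parcel.

    ``sequences_per_dataset`` is either one list of TrialSequence shared by
    all datasets or a callable (observer, condition, seed) -> sequences.
    With ``effect_present=False`` the datasets carry no class structure
    (class_separation 0 and all novelty/learning rates 0): pure noise labels.
    """
    if n_observers <= 0 or n_conditions <= 0:
        raise ValueError("counts must be positive")
    params = shared_params
    if not effect_present:
        params = GeneratorParams(
            class_separation=0.0, within_sd=shared_params.within_sd,
            identity_ssb_rate=0.0, novelty_offset_rate=0.0,
            novel_contraction_rate=0.0, novel_dispersion0=0.0,
            autocorr_profile=dict(shared_params.autocorr_profile),
            latent_share=shared_params.latent_share,
            amplitude_drift_per_run=shared_params.amplitude_drift_per_run,
            n_batches=shared_params.n_batches)
    ss = (rng_seed if isinstance(rng_seed, np.random.SeedSequence)
          else np.random.SeedSequence(rng_seed))
    seeds = ss.spawn(n_observers * n_conditions)
    out = []
    k = 0
    for o in range(1, n_observers + 1):
        for c in range(1, n_conditions + 1):
            child = np.random.default_rng(seeds[k])
            seqs = (sequences_per_dataset(o, c, seeds[k])
                    if callable(sequences_per_dataset) else sequences_per_dataset)
            ds, _ = simulate_parcel_responses(seqs, parcel, params, rng_seed=child)
            ds.observer_id = f"obs{o}"
            ds.condition = f"cond{c}"
            out.append(ds)
            k += 1
    return out
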