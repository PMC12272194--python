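"""Cross-validation, permutation nulls, and prevalence inference.

The decoding statistics (classification accuracy alpha and pseudo-F) are
cross-validated with repeated stratified 90/10 splits (optionally restricted
so that test trials come from one chronological batch).  Significance is
assessed without parametric assumptions:

1. *first level*: object identities of the test trials are permuted and the
   full metric pipeline is re-run, yielding a per-dataset null distribution;
2. *second level*: the global null over n datasets is tested with the
   minimum statistic m = min_k alpha_k (or min_k F_k), whose null is built by
   drawing one first-level value per dataset and taking the minimum;
3. the resulting p-value is Bonferroni-corrected and fed into a closed-form
   *prevalence* bound: an upper bound on P(gamma_true < gamma0), where
   gamma_true is the fraction of datasets in which the effect is truly
   present.  Parcels are called selective when the bound falls below alpha.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .dlda import fit_dlda, project
from .metrics import (NoveltyMetrics, RSAMetrics, confusion_and_accuracy,
                      identity_decomposition, novelty_decomposition,
                      pairwise_discriminability)
from .synth import ResponseDataset


@dataclass(frozen=True)
class CVScheme:
    """Repeated stratified train/test splitting.

    ``test_fraction`` applies per class for unrestricted splits; with
    ``batch_restriction`` set, test trials are drawn only from that batch and
    comprise ``batch_test_fraction`` of the class's batch trials (the
    training set is the complement across all batches).
    """

    test_fraction: float = 0.10
    n_repeats: int = 20
    batch_restriction: int | None = None
    batch_test_fraction: float = 0.5
    stratified: bool = True
    n_batches: int = 5

    def __post_init__(self):
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must be in (0, 1)")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        if self.batch_restriction is not None and not (
                1 <= self.batch_restriction <= self.n_batches):
            raise ValueError("batch_restriction out of range")


class StratificationError(ValueError):
    """A class is too small for the requested stratified split."""


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def make_splits(dataset: ResponseDataset, scheme: CVScheme, rng_seed=0,
                include_novel_in_test: bool = False
                ) -> list[tuple[np.ndarray, np.ndarray]]:
    """N_r (train, test) index pairs into the dataset's trials.

    Training sets contain only recurring-object trials.  Test sets are
    stratified per recurring class (plus, optionally, a sample of novel
    trials for novelty metrics, drawn with the same fraction).
    """
    rng = _as_rng(rng_seed)
    rec = np.flatnonzero(~dataset.is_novel)
    nov = np.flatnonzero(dataset.is_novel)
    if len(rec) == 0:
        raise ValueError("dataset has no recurring trials")
    batch = dataset.batch
    labels = dataset.labels

    def class_pools():
        pools = []
        groups = [(c, rec[labels[rec] == c]) for c in np.unique(labels[rec])]
        if include_novel_in_test and len(nov):
            groups.append((None, nov))
        for c, idx in groups:
            if scheme.batch_restriction is not None:
                pool = idx[batch[idx] == scheme.batch_restriction]
                n_test = int(round(scheme.batch_test_fraction * len(pool)))
            else:
                pool = idx
                n_test = int(round(scheme.test_fraction * len(pool)))
            n_test = max(n_test, 1)
            if len(pool) < n_test or (c is not None and len(idx) - n_test < 2):
                raise StratificationError(
                    f"class {c!r}: pool of {len(pool)} cannot supply {n_test} "
                    "test trials while keeping >=2 training trials")
            pools.append((c, idx, pool, n_test))
        return pools

    if scheme.stratified:
        pools = class_pools()
        splits = []
        for _ in range(scheme.n_repeats):
            test_parts = [rng.choice(pool, size=n_test, replace=False)
                          for _, _, pool, n_test in pools]
            test = np.sort(np.concatenate(test_parts))
            train = np.setdiff1d(rec, test)
            splits.append((train, test))
        return splits
    # unstratified: plain random test subset of the recurring pool
    pool = rec if scheme.batch_restriction is None else rec[
        batch[rec] == scheme.batch_restriction]
    frac = (scheme.test_fraction if scheme.batch_restriction is None
            else scheme.batch_test_fraction)
    n_test = max(int(round(frac * len(pool))), 1)
    splits = []
    for _ in range(scheme.n_repeats):
        test = np.sort(rng.choice(pool, size=n_test, replace=False))
        if include_novel_in_test and len(nov):
            n_nov = max(int(round(frac * len(nov))), 1)
            test = np.sort(np.concatenate(
                [test, rng.choice(nov, size=n_nov, replace=False)]))
        train = np.setdiff1d(rec, test)
        splits.append((train, test))
    return splits


@dataclass
class _Repeat:
    """Cached per-repeat projections (avoids refitting under permutation)."""

    classes: np.ndarray
    train_centroids: np.ndarray
    test_coords: np.ndarray        # recurring test trials
    test_labels: np.ndarray
    novel_coords: np.ndarray | None = None


def _project_splits(dataset: ResponseDataset, scheme: CVScheme, rng,
                    include_novel: bool) -> list[_Repeat]:
    splits = make_splits(dataset, scheme, rng, include_novel_in_test=include_novel)
    X = dataset.patterns
    y = dataset.labels
    novel = dataset.is_novel
    reps = []
    for train, test in splits:
        model = fit_dlda(X[train], y[train])
        test_rec = test[~novel[test]]
        rep = _Repeat(classes=model.classes,
                      train_centroids=model.class_centroids,
                      test_coords=project(model, X[test_rec]),
                      test_labels=y[test_rec])
        if include_novel:
            test_nov = test[novel[test]]
            rep.novel_coords = (project(model, X[test_nov])
                                if len(test_nov) else np.empty((0, model.n_components)))
        reps.append(rep)
    return reps


def _identity_metrics(rep: _Repeat, labels=None) -> RSAMetrics:
    y = rep.test_labels if labels is None else labels
    conf, acc = confusion_and_accuracy(rep.test_coords, y, rep.train_centroids,
                                       rep.classes)
    delta, dmean = pairwise_discriminability(rep.test_coords, y)
    dec = identity_decomposition(rep.test_coords, y)
    dec.confusion, dec.accuracy = conf, acc
    dec.delta_matrix, dec.delta_mean = delta, dmean
    return dec


def _average_identity(metrics: list[RSAMetrics]) -> RSAMetrics:
    return RSAMetrics(
        confusion=np.mean([m.confusion for m in metrics], axis=0),
        accuracy=float(np.mean([m.accuracy for m in metrics])),
        delta_matrix=np.mean([m.delta_matrix for m in metrics], axis=0),
        delta_mean=float(np.mean([m.delta_mean for m in metrics])),
        ss_within=float(np.mean([m.ss_within for m in metrics])),
        ss_between=float(np.mean([m.ss_between for m in metrics])),
        ss_total=float(np.mean([m.ss_total for m in metrics])),
        f_ratio=float(np.mean([m.f_ratio for m in metrics])),
        sigma_w=float(np.mean([m.sigma_w for m in metrics])),
        sigma_b=float(np.mean([m.sigma_b for m in metrics])),
        n_per_class=metrics[0].n_per_class, classes=metrics[0].classes)


def _average_novelty(metrics: list[NoveltyMetrics]) -> NoveltyMetrics:
    return NoveltyMetrics(
        ss_fam=float(np.mean([m.ss_fam for m in metrics])),
        ss_nov=float(np.mean([m.ss_nov for m in metrics])),
        ss_novfam=float(np.mean([m.ss_novfam for m in metrics])),
        ss_total=float(np.mean([m.ss_total for m in metrics])),
        f_novelty=float(np.mean([m.f_novelty for m in metrics])),
        n_familiar=metrics[0].n_familiar, n_novel=metrics[0].n_novel)


def crossval_metrics(dataset: ResponseDataset, scheme: CVScheme,
                     include_novel: bool = False, rng_seed=0):
    """Cross-validated identity metrics, averaged over the N_r repeats.

    Per repeat: fit DLDA on the training set, project the test set through
    the model, compute all identity metrics (novelty metrics too when
    ``include_novel``: novel test trials are projected through the same
    model).  Returns RSAMetrics, or (RSAMetrics, NoveltyMetrics).
    """
    rng = _as_rng(rng_seed)
    reps = _project_splits(dataset, scheme, rng, include_novel)
    ident = _average_identity([_identity_metrics(r) for r in reps])
    if not include_novel:
        return ident
    novs = []
    for r in reps:
        if r.novel_coords is None or len(r.novel_coords) == 0:
            continue
        coords = np.vstack([r.test_coords, r.novel_coords])
        flags = np.concatenate([np.zeros(len(r.test_coords), bool),
                                np.ones(len(r.novel_coords), bool)])
        novs.append(novelty_decomposition(coords, flags))
    if not novs:
        raise ValueError("no novel trials available in any test set")
    return ident, _average_novelty(novs)


@dataclass
class FirstLevelNull:
    """Per-dataset first-level permutation distribution."""

    statistic: str                 # "accuracy" | "f_identity" | "f_novelty"
    samples: np.ndarray            # (n_perm,) permutation values
    observed: float
    n_perm: int
    extra: dict = field(default_factory=dict)

    @property
    def pvalue(self) -> float:
        """One-sided permutation p with the (r+1)/(k+1) inclusion convention."""
        return (1 + int(np.sum(self.samples >= self.observed))) / (self.n_perm + 1)


def permutation_null(dataset: ResponseDataset, scheme: CVScheme,
                     n_perm: int = 1000, rng_seed=0,
                     statistic: str = "accuracy") -> FirstLevelNull:
    """First-level permutation null of the cross-validated statistic.

    Identity statistics permute the object identities of the recurring test
    trials (within each of the N_r test sets); the novelty statistic permutes
    the recurring/novel partition of the test trials.  The DLDA projections
    are fixed across permutations — only the labels entering the metric are
    shuffled — matching a test-set label permutation scheme.
    """
    import warnings
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} gives coarse p-value resolution",
                      stacklevel=2)
    rng = _as_rng(rng_seed)
    include_novel = statistic == "f_novelty"
    reps = _project_splits(dataset, scheme, rng, include_novel)

    def observed_value() -> float:
        if statistic == "accuracy":
            return float(np.mean([_identity_metrics(r).accuracy for r in reps]))
        if statistic == "f_identity":
            return float(np.mean([
                identity_decomposition(r.test_coords, r.test_labels).f_ratio
                for r in reps]))
        vals = []
        for r in reps:
            coords = np.vstack([r.test_coords, r.novel_coords])
            flags = np.concatenate([np.zeros(len(r.test_coords), bool),
                                    np.ones(len(r.novel_coords), bool)])
            vals.append(novelty_decomposition(coords, flags).f_novelty)
        return float(np.mean(vals))

    obs = observed_value()
    samples = np.empty(n_perm)
    for p in range(n_perm):
        vals = []
        for r in reps:
            if statistic == "f_novelty":
                coords = np.vstack([r.test_coords, r.novel_coords])
                flags = np.concatenate([np.zeros(len(r.test_coords), bool),
                                        np.ones(len(r.novel_coords), bool)])
                vals.append(novelty_decomposition(
                    coords, rng.permutation(flags)).f_novelty)
            else:
                perm = rng.permutation(r.test_labels)
                if statistic == "accuracy":
                    _, acc = confusion_and_accuracy(
                        r.test_coords, perm, r.train_centroids, r.classes)
                    vals.append(acc)
                else:
                    vals.append(identity_decomposition(r.test_coords, perm).f_ratio)
        samples[p] = np.mean(vals)
    return FirstLevelNull(statistic=statistic, samples=samples, observed=obs,
                          n_perm=n_perm)


def min_statistic_pvalue(observed: np.ndarray, nulls: list[np.ndarray],
                         n_second: int = 100_000, rng_seed=0
                         ) -> tuple[float, float]:
    """Global-null test of the minimum statistic over n datasets.

    m_obs = min_k observed_k.  Each second-level draw takes one first-level
    value per dataset — sampled with replacement from that dataset's
    permutation pool, which includes the observed value per the permutation
    convention — and records the minimum.  Returns (m_obs, p_global), with
    p_global = P(min >= m_obs) under the +1 inclusion convention.
    """
    observed = np.asarray(observed, dtype=float)
    n = len(observed)
    if n == 0:
        raise ValueError("need at least one dataset")
    if len(nulls) != n:
        raise ValueError(f"{n} observed values but {len(nulls)} null distributions")
    rng = _as_rng(rng_seed)
    m_obs = float(np.min(observed))
    pools = [np.append(np.asarray(nl, dtype=float), observed[k])
             for k, nl in enumerate(nulls)]
    minima = np.full(n_second, np.inf)
    for pool in pools:
        draws = pool[rng.integers(len(pool), size=n_second)]
        np.minimum(minima, draws, out=minima)
    p_global = (1 + int(np.sum(minima >= m_obs))) / (n_second + 1)
    return m_obs, float(p_global)


def correct_multiple(p_global: float, n_comparisons: int = 758 * 2) -> float:
    """Bonferroni correction."""
    if not 0 <= p_global <= 1:
        raise ValueError("p must be in [0, 1]")
    return min(1.0, p_global * n_comparisons)


@dataclass
class PrevalenceResult:
    """Minimum-statistic prevalence inference for one parcel."""

    m_obs: float | None
    p_global: float | None
    p_corrected: float
    n_datasets: int
    gamma0: float
    alpha: float
    bound: float                # upper bound on P(gamma_true < gamma0)
    gamma_est: float            # NaN when undefined
    selective: bool


def prevalence_bound(p_corrected: float, n: int, gamma0: float = 0.5) -> float:
    """Closed-form upper bound on P(gamma_true < gamma0):

        [(1 - gamma0) p*^(1/n) + gamma0]^n
    """
    return float(((1 - gamma0) * p_corrected ** (1 / n) + gamma0) ** n)


def prevalence(p_corrected: float, n: int, gamma0: float = 0.5,
               alpha: float = 0.05, m_obs: float | None = None,
               p_global: float | None = None) -> PrevalenceResult:
    """Prevalence inference from the corrected minimum-statistic probability.

    gamma_est = (alpha^(1/n) - p*^(1/n)) / (1 - p*^(1/n)), the largest
    prevalence threshold for which the prevalence null can still be rejected;
    clamped to [0, 1] and undefined (NaN) when p_corrected > alpha or = 1.
    """
    if not 0 <= p_corrected <= 1:
        raise ValueError("p_corrected must be in [0, 1]")
    if n < 1:
        raise ValueError("n must be >= 1")
    bound = prevalence_bound(p_corrected, n, gamma0)
    root = p_corrected ** (1 / n)
    if p_corrected >= 1 or p_corrected > alpha:
        g = np.nan
    else:
        g = float(np.clip((alpha ** (1 / n) - root) / (1 - root), 0.0, 1.0))
    return PrevalenceResult(m_obs=m_obs, p_global=p_global,
                            p_corrected=p_corrected, n_datasets=n,
                            gamma0=gamma0, alpha=alpha, bound=bound,
                            gamma_est=g, selective=bool(bound <= alpha))


def prevalence_threshold(n: int = 16, gamma0: float = 0.5,
                         alpha: float = 0.05) -> float:
    """Corrected p at which the prevalence bound sits exactly at alpha
    (numerical root of bound(p) = alpha; bound is increasing in p)."""
    lo, hi = 1e-300, 1.0
    if prevalence_bound(lo, n, gamma0) > alpha:
        raise ValueError("bound exceeds alpha even at p -> 0")
    return float(brentq(lambda p: prevalence_bound(p, n, gamma0) - alpha,
                        lo, hi, xtol=1e-18, rtol=8.9e-16))


def zscore_against_null(statistic: float, null_samples: np.ndarray) -> float:
    """Z = (F - mu) / sigma against the permutation null."""
    s = np.asarray(null_samples, dtype=float)
    if len(s) < 2:
        raise ValueError("need >= 2 null samples")
    sd = float(np.std(s))
    if sd == 0:
        raise ValueError("degenerate null: zero standard deviation")
    return float((statistic - float(np.mean(s))) / sd)


def analyze_parcel(datasets: list[ResponseDataset], scheme: CVScheme,
                   n_perm: int = 1000, n_second: int = 100_000,
                   n_comparisons: int = 758 * 2, gamma0: float = 0.5,
                   alpha: float = 0.05, statistic: str = "accuracy",
                   rng_seed=0) -> dict:
    """Full per-parcel inference chain across datasets.

    Runs the cross-validated statistic and its first-level null per dataset,
    the second-level minimum-statistic test, multiple-comparison correction,
    and the prevalence bound.  Returns a JSON-ready summary dict.
    """
    rng = _as_rng(rng_seed)
    nulls = []
    for ds in datasets:
        nulls.append(permutation_null(ds, scheme, n_perm=n_perm, rng_seed=rng,
                                      statistic=statistic))
    observed = np.array([nl.observed for nl in nulls])
    m_obs, p_global = min_statistic_pvalue(
        observed, [nl.samples for nl in nulls], n_second=n_second, rng_seed=rng)
    p_corr = correct_multiple(p_global, n_comparisons)
    prev = prevalence(p_corr, n=len(datasets), gamma0=gamma0, alpha=alpha,
                      m_obs=m_obs, p_global=p_global)
    return {"parcel_id": datasets[0].parcel_id, "statistic": statistic,
            "observed_per_dataset": observed.tolist(),
            "alpha_mean": float(np.mean(observed)), "m_obs": m_obs,
            "p_global": p_global, "p_corrected": p_corr,
            "bound": prev.bound, "gamma_est": prev.gamma_est,
            "selective": prev.selective}
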