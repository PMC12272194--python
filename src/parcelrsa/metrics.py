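"""Representational-similarity measurements in the discriminative subspace.

All quantities operate on coordinates in the scaled DLDA subspace, where
within-class variance is unit per dimension, so Euclidean distances realize
the standardized (Mahalanobis) metric.  The module provides

* nearest-centroid confusion matrix and classification accuracy,
* pairwise discriminability delta_ij from projections onto centroid lines,
* PERMANOVA-style variance decompositions (identity: kappa classes;
  novelty: familiar vs novel) with their pseudo-F ratios,
* normalized amplitudes/distances and the trial-lag (temporal
  autocorrelation) correction of pairwise distances,
* per-run summaries of amplitudes, distances and variance fractions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform


# ---------------------------------------------------------------------------
# confusion / accuracy

def confusion_and_accuracy(test_coords: np.ndarray, test_labels: np.ndarray,
                           train_centroids: np.ndarray,
                           classes: np.ndarray) -> tuple[np.ndarray, float]:
    """Nearest-centroid assignment of test exemplars.

    Returns the row-normalized confusion matrix P(reported j | true i) and
    the prior-weighted accuracy alpha = sum_i P(i|i) P(i), with P(i) the
    test-set class frequencies.  Ties are broken to the lowest class index.
    """
    X = np.asarray(test_coords, dtype=np.float64)
    y = np.asarray(test_labels)
    classes = np.asarray(classes)
    kappa = len(classes)
    d2 = ((X[:, None, :] - train_centroids[None, :, :]) ** 2).sum(axis=2)
    assigned = np.argmin(d2, axis=1)          # argmin takes the first (lowest) index
    lut = {c: i for i, c in enumerate(classes)}
    true_idx = np.array([lut[v] for v in y])
    conf = np.zeros((kappa, kappa))
    np.add.at(conf, (true_idx, assigned), 1.0)
    n_i = conf.sum(axis=1)
    if np.any(n_i == 0):
        missing = classes[n_i == 0]
        raise ValueError(f"empty test class(es): {missing.tolist()}")
    conf /= n_i[:, None]
    prior = n_i / n_i.sum()
    accuracy = float(np.sum(np.diag(conf) * prior))
    return conf, accuracy


# ---------------------------------------------------------------------------
# pairwise discriminability

def pairwise_discriminability(test_coords: np.ndarray, test_labels: np.ndarray,
                              *, centroids: np.ndarray | None = None,
                              ddof: int = 1) -> tuple[np.ndarray, float]:
    """Pairwise discriminability delta_ij between object classes.

    Exemplars of classes i and j are projected onto the line connecting the
    two class centroids (test-set centroids unless explicit ``centroids`` are
    supplied, e.g. training centroids for sensitivity checks), and

        delta_ij = |mu_i - mu_j| / sqrt((sigma_i^2 + sigma_j^2) / 2)

    is evaluated from the projection means and variances.  ``delta_mean`` is
    the mean over unordered class pairs.  Pairs with zero pooled variance are
    flagged infinite and excluded from the mean.
    """
    X = np.asarray(test_coords, dtype=np.float64)
    y = np.asarray(test_labels)
    classes = np.unique(y)
    kappa = len(classes)
    groups = [X[y == c] for c in classes]
    for c, g in zip(classes, groups):
        if len(g) < 2:
            raise ValueError(f"class {c} has <2 exemplars; variance undefined")
    if centroids is None:
        centroids = np.stack([g.mean(axis=0) for g in groups])
    delta = np.zeros((kappa, kappa))
    vals = []
    for i in range(kappa):
        for j in range(i + 1, kappa):
            u = centroids[j] - centroids[i]
            norm = np.linalg.norm(u)
            if norm == 0:
                delta[i, j] = delta[j, i] = 0.0
                vals.append(0.0)
                continue
            u = u / norm
            pi = groups[i] @ u
            pj = groups[j] @ u
            pooled = 0.5 * (pi.var(ddof=ddof) + pj.var(ddof=ddof))
            if pooled == 0:
                delta[i, j] = delta[j, i] = np.inf
                continue
            d = abs(pi.mean() - pj.mean()) / np.sqrt(pooled)
            delta[i, j] = delta[j, i] = d
            vals.append(d)
    delta_mean = float(np.mean(vals)) if vals else 0.0
    return delta, delta_mean


# ---------------------------------------------------------------------------
# variance decompositions

@dataclass
class RSAMetrics:
    """Identity metrics for kappa recurring classes."""

    confusion: np.ndarray | None
    accuracy: float | None
    delta_matrix: np.ndarray | None
    delta_mean: float | None
    ss_within: float
    ss_between: float
    ss_total: float
    f_ratio: float
    sigma_w: float
    sigma_b: float
    n_per_class: np.ndarray | None = None
    classes: np.ndarray | None = None


def identity_decomposition(coords: np.ndarray, labels: np.ndarray) -> RSAMetrics:
    """Huygens decomposition SST = SSW + SSB over kappa classes.

    SSW = (1/N) sum_i sum_k ||x_k^i - c_i||^2, SSB = (1/N) sum_i n_i
    ||c_i - c||^2, and the PERMANOVA pseudo-F

        F_identity = [SSB / (kappa-1)] / [SSW / (N-kappa)].

    Per-dimension dispersions follow sigma_W = sqrt(SSW N / (N-kappa)) and
    sigma_B = sqrt(SSB N / (kappa-1)) (the SS terms are N-normalized).
    """
    X = np.asarray(coords, dtype=np.float64)
    y = np.asarray(labels)
    classes, inv, counts = np.unique(y, return_inverse=True, return_counts=True)
    kappa = len(classes)
    if kappa < 2:
        raise ValueError("F undefined for a single class")
    N = len(y)
    if N <= kappa:
        raise ValueError("need N > kappa")
    C = np.zeros((kappa, X.shape[1]))
    np.add.at(C, inv, X)
    C /= counts[:, None]
    c = X.mean(axis=0)
    ssw = float(np.sum((X - C[inv]) ** 2)) / N
    ssb = float(counts @ np.sum((C - c) ** 2, axis=1)) / N
    sst = float(np.sum((X - c) ** 2)) / N
    f = np.inf if ssw == 0 else (ssb / (kappa - 1)) / (ssw / (N - kappa))
    return RSAMetrics(confusion=None, accuracy=None, delta_matrix=None,
                      delta_mean=None, ss_within=ssw, ss_between=ssb,
                      ss_total=sst, f_ratio=float(f),
                      sigma_w=float(np.sqrt(ssw * N / (N - kappa))),
                      sigma_b=float(np.sqrt(ssb * N / (kappa - 1))),
                      n_per_class=counts, classes=classes)


@dataclass
class NoveltyMetrics:
    """Two-class (familiar vs novel) decomposition."""

    ss_fam: float
    ss_nov: float
    ss_novfam: float
    ss_total: float
    f_novelty: float
    n_familiar: int
    n_novel: int
    c_fam: np.ndarray = None
    c_nov: np.ndarray = None
    c_tot: np.ndarray = None

    @property
    def ss_within(self) -> float:
        return self.ss_fam + self.ss_nov


def novelty_decomposition(coords: np.ndarray, is_novel: np.ndarray) -> NoveltyMetrics:
    """Familiar-vs-novel variance decomposition.

    With N familiar and M novel exemplars (all terms normalized by N + M):
    SSW = SS_fam + SS_nov; SSB = SS_novfam is computed both from
    size-weighted centroid-to-grand-centroid distances and from the identity
    NM/(N+M)^2 ||c_fam - c_nov||^2 (the two agree analytically);
    F_novelty = SSB (N+M-2) / SSW.
    """
    X = np.asarray(coords, dtype=np.float64)
    novel = np.asarray(is_novel, dtype=bool)
    N = int(np.sum(~novel))
    M = int(np.sum(novel))
    if N == 0 or M == 0:
        raise ValueError("both familiar and novel classes must be non-empty")
    tot = N + M
    c_fam = X[~novel].mean(axis=0)
    c_nov = X[novel].mean(axis=0)
    c_tot = (N * c_fam + M * c_nov) / tot
    ss_fam = float(np.sum((X[~novel] - c_fam) ** 2)) / tot
    ss_nov = float(np.sum((X[novel] - c_nov) ** 2)) / tot
    ssb = (N * float(np.sum((c_fam - c_tot) ** 2))
           + M * float(np.sum((c_nov - c_tot) ** 2))) / tot
    ssb_direct = N * M / tot ** 2 * float(np.sum((c_fam - c_nov) ** 2))
    if not np.isclose(ssb, ssb_direct, rtol=1e-9, atol=1e-12):
        raise AssertionError("between-class SS identities disagree")
    ssw = ss_fam + ss_nov
    sst = float(np.sum((X - c_tot) ** 2)) / tot
    f = np.inf if ssw == 0 else ssb * (tot - 2) / ssw
    return NoveltyMetrics(ss_fam=ss_fam, ss_nov=ss_nov, ss_novfam=ssb,
                          ss_total=sst, f_novelty=float(f), n_familiar=N,
                          n_novel=M, c_fam=c_fam, c_nov=c_nov, c_tot=c_tot)


# ---------------------------------------------------------------------------
# normalized geometry and the trial-lag correction

def normalized_geometry(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Normalized amplitudes a_k = ||x_k|| / sqrt(kappa-1) and pairwise
    distances d_kl = ||x_k - x_l|| / sqrt(kappa-1) (square symmetric matrix,
    zero diagonal)."""
    X = np.atleast_2d(np.asarray(coords, dtype=np.float64))
    root = np.sqrt(X.shape[1])
    a = np.linalg.norm(X, axis=1) / root
    d = squareform(pdist(X)) / root
    return a, d


@dataclass
class DelayProfile:
    """Mean pairwise distance T(dk) vs trial lag dk within runs."""

    lags: np.ndarray           # 1..max_lag
    values: np.ndarray         # T(dk), gaps interpolated
    counts: np.ndarray         # pair counts per lag
    interpolated: np.ndarray = field(default=None)  # lags that were gaps

    @property
    def mean(self) -> float:
        """Unweighted mean of T over lags."""
        return float(np.mean(self.values))

    def lookup(self, lag: np.ndarray) -> np.ndarray:
        """T at the requested lags; lags beyond the profile get the profile
        mean (i.e. no net correction)."""
        lag = np.asarray(lag)
        out = np.full(lag.shape, self.mean, dtype=float)
        inside = (lag >= self.lags[0]) & (lag <= self.lags[-1])
        out[inside] = self.values[np.searchsorted(self.lags, lag[inside])]
        return out


def estimate_delay_profile(distances: np.ndarray, trial_index: np.ndarray,
                           run: np.ndarray, max_lag: int | None = None) -> DelayProfile:
    """Estimate T(dk): mean pairwise distance at trial lag dk, pooling pairs
    within runs.  Lags with fewer than 2 pairs are interpolated from
    neighboring lags."""
    D = np.asarray(distances, dtype=np.float64)
    t = np.asarray(trial_index)
    r = np.asarray(run)
    n = len(t)
    ii, jj = np.triu_indices(n, k=1)
    same = r[ii] == r[jj]
    ii, jj = ii[same], jj[same]
    lag = np.abs(t[ii] - t[jj])
    d = D[ii, jj]
    top = int(lag.max()) if max_lag is None else int(max_lag)
    keep = lag <= top
    lag, d = lag[keep], d[keep]
    sums = np.bincount(lag, weights=d, minlength=top + 1)[1:]
    cnts = np.bincount(lag, minlength=top + 1)[1:]
    lags = np.arange(1, top + 1)
    vals = np.divide(sums, cnts, out=np.full(top, np.nan), where=cnts > 0)
    sparse = cnts < 2
    good = ~sparse & ~np.isnan(vals)
    if not np.any(good):
        raise ValueError("no lag has >=2 pairs; profile unidentifiable")
    interp_mask = ~good
    if np.any(interp_mask):
        vals[interp_mask] = np.interp(lags[interp_mask], lags[good], vals[good])
    return DelayProfile(lags=lags, values=vals, counts=cnts,
                        interpolated=lags[interp_mask])


def pool_delay_profiles(profiles: list[DelayProfile]) -> DelayProfile:
    """Pair-count-weighted pooling of per-dataset profiles (average over
    subjects and runs)."""
    top = max(int(p.lags[-1]) for p in profiles)
    sums = np.zeros(top)
    cnts = np.zeros(top)
    for p in profiles:
        k = len(p.lags)
        sums[:k] += p.values * p.counts
        cnts[:k] += p.counts
    lags = np.arange(1, top + 1)
    good = cnts > 0
    vals = np.divide(sums, cnts, out=np.full(top, np.nan), where=good)
    if np.any(~good):
        vals[~good] = np.interp(lags[~good], lags[good], vals[good])
    return DelayProfile(lags=lags, values=vals, counts=cnts,
                        interpolated=lags[~good])


def correct_distances(distances: np.ndarray, trial_index: np.ndarray,
                      run: np.ndarray, profile: DelayProfile) -> np.ndarray:
    """Subtract the lag profile and restore the grand mean over lags:

        d_corrected(dk) = d(dk) - T(dk) + <T(dk)>_dk

    Cross-run pairs (no defined lag) are left uncorrected."""
    D = np.array(distances, dtype=np.float64, copy=True)
    t = np.asarray(trial_index)
    r = np.asarray(run)
    lag = np.abs(t[:, None] - t[None, :])
    same = r[:, None] == r[None, :]
    corr = np.where(same, profile.lookup(lag) - profile.mean, 0.0)
    np.fill_diagonal(corr, 0.0)
    return D - corr


def delay_profile_and_correct(distances: np.ndarray, trial_index: np.ndarray,
                              run: np.ndarray,
                              profile: DelayProfile | None = None,
                              max_lag: int | None = None
                              ) -> tuple[DelayProfile, np.ndarray]:
    """Convenience wrapper: estimate (or reuse) the lag profile and return it
    with the corrected distance matrix."""
    if profile is None:
        profile = estimate_delay_profile(distances, trial_index, run, max_lag)
    return profile, correct_distances(distances, trial_index, run, profile)


# ---------------------------------------------------------------------------
# per-run category summaries

def _pair_mean(D: np.ndarray, rows: np.ndarray, cols: np.ndarray | None = None) -> float:
    """Mean of D over unordered pairs within ``rows`` (or across two disjoint
    index sets)."""
    if cols is None:
        if len(rows) < 2:
            return np.nan
        sub = D[np.ix_(rows, rows)]
        iu = np.triu_indices(len(rows), k=1)
        return float(sub[iu].mean())
    if len(rows) == 0 or len(cols) == 0:
        return np.nan
    return float(D[np.ix_(rows, cols)].mean())


def category_summaries(coords: np.ndarray, corrected_distances: np.ndarray,
                       amplitudes: np.ndarray, labels: np.ndarray,
                       is_novel: np.ndarray, run: np.ndarray) -> pd.DataFrame:
    """Per-run amplitude/distance/variance summaries in a fixed subspace.

    For every run: average amplitudes A_tot/A_fam/A_nov; average corrected
    distances D_tot/D_fam/D_nov/D_novfam and, for recurring trials,
    D_same/D_diff over same- and different-class pairs; variance fractions
    SS_fam/SS_tot etc.; and the ratios

        R_identity = SS_diff (N - kappa) / (SS_same (kappa - 1))
        R_novelty  = SS_novfam (N + M - 2) / (SS_nov + SS_fam).

    Runs without novel trials get NaN in the novelty columns.
    """
    y = np.asarray(labels)
    novel = np.asarray(is_novel, dtype=bool)
    r = np.asarray(run)
    a = np.asarray(amplitudes, dtype=np.float64)
    D = np.asarray(corrected_distances, dtype=np.float64)
    rows = []
    for rr in np.unique(r):
        m = r == rr
        idx = np.flatnonzero(m)
        fam = idx[~novel[idx]]
        nov = idx[novel[idx]]
        rec_labels = y[fam]
        row = {"run": int(rr),
               "A_tot": float(a[idx].mean()),
               "A_fam": float(a[fam].mean()) if len(fam) else np.nan,
               "A_nov": float(a[nov].mean()) if len(nov) else np.nan,
               "D_tot": _pair_mean(D, idx),
               "D_fam": _pair_mean(D, fam),
               "D_nov": _pair_mean(D, nov) if len(nov) >= 2 else np.nan,
               "D_novfam": _pair_mean(D, nov, fam) if len(nov) else np.nan}
        # same/diff recurring pairs
        sub = D[np.ix_(fam, fam)]
        same_mask = rec_labels[:, None] == rec_labels[None, :]
        iu = np.triu_indices(len(fam), k=1)
        same_pairs = sub[iu][same_mask[iu]]
        diff_pairs = sub[iu][~same_mask[iu]]
        row["D_same"] = float(same_pairs.mean()) if len(same_pairs) else np.nan
        row["D_diff"] = float(diff_pairs.mean()) if len(diff_pairs) else np.nan
        # variance decompositions (uncorrected coordinates)
        classes, counts = np.unique(rec_labels, return_counts=True)
        if len(classes) >= 2 and np.all(counts >= 1) and len(fam) > len(classes):
            ident = identity_decomposition(coords[fam], rec_labels)
            row.update(SS_same=ident.ss_within, SS_diff=ident.ss_between,
                       SS_fam=ident.ss_total,
                       F_same=ident.ss_within / ident.ss_total if ident.ss_total else np.nan,
                       F_diff=ident.ss_between / ident.ss_total if ident.ss_total else np.nan,
                       R_identity=ident.f_ratio)
        else:
            row.update(SS_same=np.nan, SS_diff=np.nan, SS_fam=np.nan,
                       F_same=np.nan, F_diff=np.nan, R_identity=np.nan)
        if len(nov) and len(fam):
            novm = novelty_decomposition(coords[idx], novel[idx])
            row.update(SS_nov=novm.ss_nov, SS_novfam=novm.ss_novfam,
                       SS_tot=novm.ss_total,
                       F_fam=novm.ss_fam / novm.ss_total if novm.ss_total else np.nan,
                       F_nov=novm.ss_nov / novm.ss_total if novm.ss_total else np.nan,
                       F_novfam=novm.ss_novfam / novm.ss_total if novm.ss_total else np.nan,
                       R_novelty=novm.f_novelty)
        else:
            row.update(SS_nov=np.nan, SS_novfam=np.nan, SS_tot=np.nan,
                       F_fam=np.nan, F_nov=np.nan, F_novfam=np.nan,
                       R_novelty=np.nan)
        rows.append(row)
    return pd.DataFrame(rows)
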