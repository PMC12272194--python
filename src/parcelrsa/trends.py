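"""Learning-trend estimation and centroid-stability analysis.

Learning is tracked two ways: coarsely, over five chronological *batches* of
presentations using cross-validated variance ratios z-scored against their
shuffle nulls; and finely, over the 18 runs in a *fixed* discriminative
subspace fitted once on all recurring trials.  Linear rates are estimated
with mixed models (random intercept and slope per dataset, REML), with a
documented fallback chain when the fit degenerates.  Run-level centroid
stability is compared against a pseudo-run permutation baseline, and the
analytical mean chord length of a hypersphere provides the fully-random
reference for centroid displacements.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .design import NOVEL
from .dlda import fit_dlda, project
from .inference import CVScheme, permutation_null, zscore_against_null
from .synth import ResponseDataset


# ---------------------------------------------------------------------------
# linear mixed-model rates

@dataclass
class TrendResult:
    """Fixed-effect slope of a quantity over time (batch or run index)."""

    beta: float
    intercept: float
    pvalue: float
    se: float
    random_intercept_var: float
    random_slope_var: float
    residual_var: float
    scope: str = "batch"
    fallback: bool = False
    method: str = "mixedlm"


def fit_rate(values: np.ndarray, time: np.ndarray, group: np.ndarray,
             group2: np.ndarray | None = None, scope: str = "batch") -> TrendResult:
    """Fit Y = beta0 + beta * time + xi0_g + xi1_g * time + eps by REML.

    ``group`` identifies the grouping factor (datasets); when ``group2``
    (parcels) is given, the grouping factor is the dataset x parcel
    interaction.  Degenerate fits fall back to a random-intercept-only model
    and finally to per-group OLS slopes with a one-sample t-test; fallbacks
    are flagged in the result.
    """
    import statsmodels.formula.api as smf

    y = np.asarray(values, dtype=float)
    t = np.asarray(time, dtype=float)
    g = np.asarray(group)
    if group2 is not None:
        g = np.array([f"{a}|{b}" for a, b in zip(g, np.asarray(group2))])
    if len(np.unique(t)) < 3:
        raise ValueError("need >= 3 time points")
    df = pd.DataFrame({"y": y, "t": t, "g": g})
    n_groups = df["g"].nunique()

    if n_groups >= 2:
        for re_formula in ("~t", "~1"):
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    model = smf.mixedlm("y ~ t", df, groups=df["g"],
                                        re_formula=re_formula)
                    fit = model.fit(reml=True)
                if not np.isfinite(fit.bse["t"]) or fit.bse["t"] == 0:
                    continue
                cov_re = np.asarray(fit.cov_re)
                ri_var = float(cov_re[0, 0])
                rs_var = float(cov_re[1, 1]) if cov_re.shape[0] > 1 else 0.0
                return TrendResult(
                    beta=float(fit.params["t"]),
                    intercept=float(fit.params["Intercept"]),
                    pvalue=float(fit.pvalues["t"]), se=float(fit.bse["t"]),
                    random_intercept_var=ri_var, random_slope_var=rs_var,
                    residual_var=float(fit.scale), scope=scope,
                    fallback=re_formula == "~1", method="mixedlm")
            except Exception:
                continue
    # final fallback: per-group OLS slopes + one-sample t-test
    slopes, intercepts = [], []
    for _, sub in df.groupby("g"):
        if sub["t"].nunique() < 2:
            continue
        b, a = np.polyfit(sub["t"], sub["y"], 1)
        slopes.append(b)
        intercepts.append(a)
    slopes = np.asarray(slopes)
    if len(slopes) == 0:
        raise ValueError("no group with >= 2 time points")
    if len(slopes) == 1:
        # single group: OLS slope with its regression p-value
        res = stats.linregress(df["t"], df["y"])
        return TrendResult(beta=float(res.slope), intercept=float(res.intercept),
                           pvalue=float(res.pvalue), se=float(res.stderr),
                           random_intercept_var=0.0, random_slope_var=0.0,
                           residual_var=float(np.var(df["y"])), scope=scope,
                           fallback=True, method="ols")
    tt = stats.ttest_1samp(slopes, 0.0)
    return TrendResult(beta=float(np.mean(slopes)),
                       intercept=float(np.mean(intercepts)),
                       pvalue=float(tt.pvalue),
                       se=float(stats.sem(slopes)),
                       random_intercept_var=float(np.var(intercepts)),
                       random_slope_var=float(np.var(slopes)),
                       residual_var=np.nan, scope=scope, fallback=True,
                       method="ols_slopes_ttest")


# ---------------------------------------------------------------------------
# batch series

def batch_series(dataset: ResponseDataset, scheme: CVScheme | None = None,
                 n_perm: int = 200, rng_seed=0,
                 include_novelty: bool = True) -> pd.DataFrame:
    """Per-batch cross-validated variance ratios, z-scored against the
    batch-matched shuffle null.

    Returns one row per batch with raw and z-scored F_identity (and
    F_novelty when requested).
    """
    rng = np.random.default_rng(rng_seed) if not isinstance(
        rng_seed, np.random.Generator) else rng_seed
    base = scheme or CVScheme()
    rows = []
    for m in range(1, base.n_batches + 1):
        sch = CVScheme(test_fraction=base.test_fraction,
                       n_repeats=base.n_repeats, batch_restriction=m,
                       batch_test_fraction=base.batch_test_fraction,
                       stratified=base.stratified, n_batches=base.n_batches)
        null_i = permutation_null(dataset, sch, n_perm=n_perm, rng_seed=rng,
                                  statistic="f_identity")
        row = {"batch": m, "f_identity": null_i.observed,
               "z_identity": zscore_against_null(null_i.observed, null_i.samples)}
        if include_novelty:
            null_n = permutation_null(dataset, sch, n_perm=n_perm, rng_seed=rng,
                                      statistic="f_novelty")
            row["f_novelty"] = null_n.observed
            row["z_novelty"] = zscore_against_null(null_n.observed, null_n.samples)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# run-level centroid stability

NOVEL_CLASS = NOVEL  # pooled non-recurring trials form one response class


@dataclass
class StabilityResult:
    """Per-class per-run centroid displacements.

    DC[i, r] = ||C_{i,r} - C_{i,ave}||, dDC[i, r] = ||C_{i,r} - C_{i,r-1}||
    (NaN for the first run and for missing (class, run) cells).  Aggregates
    average over recurring classes (``D_same``/``dD_same``) and report the
    pooled novel class separately (``D_nov``/``dD_nov``).
    """

    classes: np.ndarray
    runs: np.ndarray
    DC: np.ndarray                 # (n_classes, n_runs)
    dDC: np.ndarray
    centroids: np.ndarray          # (n_classes, n_runs, dim)
    baseline_DC: np.ndarray | None = None
    baseline_dDC: np.ndarray | None = None
    baseline_spread_DC: np.ndarray | None = None
    baseline_spread_dDC: np.ndarray | None = None
    n_baseline_reps: int = 0
    missing: list = field(default_factory=list)

    def aggregate(self) -> pd.DataFrame:
        rec = self.classes != NOVEL_CLASS
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN first-run dDC
            df = pd.DataFrame({
                "run": self.runs,
                "D_same": np.nanmean(self.DC[rec], axis=0),
                "dD_same": np.nanmean(self.dDC[rec], axis=0)})
            if np.any(~rec):
                df["D_nov"] = np.nanmean(self.DC[~rec], axis=0)
                df["dD_nov"] = np.nanmean(self.dDC[~rec], axis=0)
            if self.baseline_DC is not None:
                df["D_same_baseline"] = np.nanmean(self.baseline_DC[rec], axis=0)
                df["dD_same_baseline"] = np.nanmean(self.baseline_dDC[rec], axis=0)
                if np.any(~rec):
                    df["D_nov_baseline"] = np.nanmean(self.baseline_DC[~rec], axis=0)
                    df["dD_nov_baseline"] = np.nanmean(self.baseline_dDC[~rec], axis=0)
        return df


def _centroid_table(coords: np.ndarray, cls: np.ndarray, runs: np.ndarray,
                    classes: np.ndarray, run_vals: np.ndarray) -> np.ndarray:
    dim = coords.shape[1]
    table = np.full((len(classes), len(run_vals), dim), np.nan)
    for i, c in enumerate(classes):
        for j, r in enumerate(run_vals):
            m = (cls == c) & (runs == r)
            if np.any(m):
                table[i, j] = coords[m].mean(axis=0)
    return table


def _stability_from_table(table: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        c_ave = np.nanmean(table, axis=1)           # mean of run centroids
    DC = np.linalg.norm(table - c_ave[:, None, :], axis=2)
    dDC = np.full(DC.shape, np.nan)
    dDC[:, 1:] = np.linalg.norm(np.diff(table, axis=1), axis=2)
    return DC, dDC


def run_centroids(coords: np.ndarray, labels: np.ndarray, is_novel: np.ndarray,
                  run: np.ndarray) -> StabilityResult:
    """Per-run class centroids and their displacements in a fixed subspace.

    Response classes are the recurring objects plus one pooled novel class.
    The per-class average centroid C_ave is the unweighted mean of that
    class's run centroids; missing (class, run) cells are flagged.
    """
    y = np.asarray(labels).copy()
    novel = np.asarray(is_novel, dtype=bool)
    y[novel] = NOVEL_CLASS
    r = np.asarray(run)
    classes = np.unique(y)
    run_vals = np.unique(r)
    table = _centroid_table(np.asarray(coords, float), y, r, classes, run_vals)
    missing = [(classes[i], run_vals[j])
               for i, j in zip(*np.where(np.isnan(table[:, :, 0])))]
    DC, dDC = _stability_from_table(table)
    return StabilityResult(classes=classes, runs=run_vals, DC=DC, dDC=dDC,
                           centroids=table, missing=missing)


def fixed_subspace_coords(dataset: ResponseDataset) -> np.ndarray:
    """Project all trials through a DLDA subspace fitted once on *all*
    recurring trials (the non-cross-validated, fixed-frame analysis)."""
    rec = ~dataset.is_novel
    model = fit_dlda(dataset.patterns[rec], dataset.labels[rec])
    return project(model, dataset.patterns)


def pseudo_run_baseline(coords: np.ndarray, labels: np.ndarray,
                        is_novel: np.ndarray, run: np.ndarray,
                        n_rep: int = 1000, rng_seed=0,
                        observed: StabilityResult | None = None) -> StabilityResult:
    """Sampling-noise baseline for centroid stability.

    Trial coordinates are permuted within each response class (preserving the
    per-run class composition), regrouping the trials into pseudo-runs; DC
    and dDC are recomputed per replicate and averaged.  Returns the observed
    result with baseline mean and spread attached.
    """
    rng = np.random.default_rng(rng_seed) if not isinstance(
        rng_seed, np.random.Generator) else rng_seed
    if observed is None:
        observed = run_centroids(coords, labels, is_novel, run)
    y = np.asarray(labels).copy()
    y[np.asarray(is_novel, dtype=bool)] = NOVEL_CLASS
    r = np.asarray(run)
    X = np.asarray(coords, float)
    classes, run_vals = observed.classes, observed.runs
    acc_DC = np.zeros_like(observed.DC)
    acc_dDC = np.zeros_like(observed.dDC)
    acc_DC2 = np.zeros_like(observed.DC)
    acc_dDC2 = np.zeros_like(observed.dDC)
    class_rows = [np.flatnonzero(y == c) for c in classes]
    Xp = X.copy()
    for _ in range(n_rep):
        for rows in class_rows:
            Xp[rows] = X[rows[rng.permutation(len(rows))]]
        table = _centroid_table(Xp, y, r, classes, run_vals)
        DC, dDC = _stability_from_table(table)
        acc_DC += DC
        acc_dDC = acc_dDC + np.nan_to_num(dDC)
        acc_DC2 += DC ** 2
        acc_dDC2 = acc_dDC2 + np.nan_to_num(dDC) ** 2
    mean_DC = acc_DC / n_rep
    mean_dDC = acc_dDC / n_rep
    mean_dDC[:, 0] = np.nan
    sd_DC = np.sqrt(np.maximum(acc_DC2 / n_rep - mean_DC ** 2, 0))
    sd_dDC = np.sqrt(np.maximum(acc_dDC2 / n_rep - mean_dDC ** 2, 0))
    observed.baseline_DC = mean_DC
    observed.baseline_dDC = mean_dDC
    observed.baseline_spread_DC = sd_DC
    observed.baseline_spread_dDC = sd_dDC
    observed.n_baseline_reps = n_rep
    return observed


def run_rates(summary: pd.DataFrame, quantity: str, session_of_run,
              group: np.ndarray | None = None) -> pd.DataFrame:
    """Session-wise linear rates beta_s of a per-run quantity.

    ``summary`` has one row per (run, [group]) with a column ``quantity``;
    ``session_of_run`` maps run -> session.  Within each session the rate is
    fitted over its runs (mixed model when groups are present)."""
    df = summary.copy()
    df["session"] = df["run"].map(session_of_run)
    rows = []
    for s, sub in df.groupby("session"):
        g = (np.asarray(sub[group]) if isinstance(group, str)
             else (group if group is not None else np.zeros(len(sub))))
        res = fit_rate(sub[quantity].to_numpy(), sub["run"].to_numpy(),
                       g, scope=f"run-within-session {s}")
        rows.append({"session": s, "quantity": quantity, "beta": res.beta,
                     "se": res.se, "p": res.pvalue, "fallback": res.fallback,
                     "method": res.method})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# hypersphere reference

def hypersphere_mean_distance(n: int) -> float:
    """Mean Euclidean distance between two independent points uniform on the
    surface of the unit hypersphere in n-dimensional space:

        d_ave = 2^(n-1) Gamma(n/2)^2 / (sqrt(pi) Gamma(n - 1/2))

    Increasing in n, -> sqrt(2) as n -> infinity; d_ave(14) ~ 1.4007.
    """
    if not isinstance(n, (int, np.integer)) or n < 1:
        raise ValueError("n must be an integer >= 1")
    return float(np.exp((n - 1) * np.log(2.0) + 2 * gammaln(n / 2)
                        - 0.5 * np.log(np.pi) - gammaln(n - 0.5)))
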