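"""Cross-validation splits, permutation nulls, minimum-statistic global-null
testing, multiple-comparison correction, and the prevalence bound."""

import numpy as np
import pytest

from parcelrsa import (CVScheme, GeneratorParams, ParcelSpec, correct_multiple,
                       crossval_metrics, fit_dlda, identity_decomposition,
                       make_splits, min_statistic_pvalue,
                       pairwise_discriminability, permutation_null, prevalence,
                       prevalence_bound, prevalence_threshold, project,
                       simulate_parcel_responses, zscore_against_null,
                       confusion_and_accuracy)
from parcelrsa.inference import StratificationError
from parcelrsa.synth import ResponseDataset


def _dataset_from_labels(labels, runs=None, patterns=None, batch=None):
    n = len(labels)
    labels = np.asarray(labels)
    return ResponseDataset(
        patterns=(patterns if patterns is not None
                  else np.zeros((n, 16), np.float32)),
        labels=labels, novel_exemplar_id=(labels == 0).astype(np.int64),
        run=runs if runs is not None else np.ones(n, np.int64),
        session=np.ones(n, np.int64),
        batch=batch if batch is not None else np.ones(n, np.int64),
        trial=np.arange(1, n + 1))


class TestSplits:
    def test_ninety_ten_split_sizes(self):
        labels = np.repeat(np.arange(1, 4), 200)
        ds = _dataset_from_labels(labels)
        splits = make_splits(ds, CVScheme(test_fraction=0.10, n_repeats=3),
                             rng_seed=0)
        for train, test in splits:
            assert len(test) == 60 and len(train) == 540
            for c in range(1, 4):
                assert np.sum(ds.labels[test] == c) == 20
            assert len(np.intersect1d(train, test)) == 0

    def test_batch_quintile_sizes_for_210_presentations(self):
        from parcelrsa import chronological_batches
        labels = np.ones(210, np.int64)
        batch = chronological_batches(labels, 5)
        _, counts = np.unique(batch, return_counts=True)
        assert np.array_equal(counts, [42, 42, 42, 42, 42])

    def test_batch_restricted_test_sets(self):
        from parcelrsa import chronological_batches
        labels = np.repeat(np.arange(1, 4), 100)
        batch = chronological_batches(labels, 5)
        ds = _dataset_from_labels(labels, batch=batch)
        scheme = CVScheme(n_repeats=2, batch_restriction=2,
                          batch_test_fraction=0.5)
        for train, test in make_splits(ds, scheme, rng_seed=1):
            assert np.all(ds.batch[test] == 2)
            # half of each class's 20 batch-2 trials
            for c in range(1, 4):
                assert np.sum(ds.labels[test] == c) == 10
            assert len(np.intersect1d(train, test)) == 0

    def test_full_batch_tests_cover_each_trial_once(self):
        from parcelrsa import chronological_batches
        labels = np.repeat(np.arange(1, 4), 100)
        batch = chronological_batches(labels, 5)
        ds = _dataset_from_labels(labels, batch=batch)
        seen = []
        for m in range(1, 6):
            scheme = CVScheme(n_repeats=1, batch_restriction=m,
                              batch_test_fraction=1.0)
            _, test = make_splits(ds, scheme, rng_seed=0)[0]
            seen.append(test)
        union = np.concatenate(seen)
        assert np.array_equal(np.sort(union), np.arange(300))

    def test_train_sets_exclude_novel_trials(self):
        labels = np.concatenate([np.repeat([1, 2], 50), np.zeros(10, np.int64)])
        ds = _dataset_from_labels(labels)
        for train, test in make_splits(ds, CVScheme(n_repeats=2), rng_seed=0,
                                       include_novel_in_test=True):
            assert np.all(ds.labels[train] != 0)
            assert np.any(ds.labels[test] == 0)

    def test_stratification_error_for_tiny_class(self):
        labels = np.concatenate([np.repeat(1, 100), [2, 2]])
        ds = _dataset_from_labels(labels)
        with pytest.raises(StratificationError):
            make_splits(ds, CVScheme(test_fraction=0.5, n_repeats=1), rng_seed=0)


class TestCrossval:
    def test_well_separated_classes(self, small_sequences):
        params = GeneratorParams(class_separation=8.0, autocorr_profile={},
                                 amplitude_drift_per_run=0.0)
        ds, _ = simulate_parcel_responses(small_sequences, ParcelSpec(20, 3),
                                          params, rng_seed=0)
        m = crossval_metrics(ds, CVScheme(n_repeats=3), rng_seed=0)
        assert m.accuracy >= 0.99

    def test_chance_level_without_class_structure(self, small_sequences):
        params = GeneratorParams(class_separation=0.0, identity_ssb_rate=0.0,
                                 novelty_offset_rate=0.0,
                                 novel_contraction_rate=0.0,
                                 novel_dispersion0=0.0, autocorr_profile={},
                                 amplitude_drift_per_run=0.0)
        ds, _ = simulate_parcel_responses(small_sequences, ParcelSpec(20, 3),
                                          params, rng_seed=1)
        m = crossval_metrics(ds, CVScheme(n_repeats=10), rng_seed=0)
        n_test = 10 * 15 * 7   # repeats x classes x per-class test trials
        se = np.sqrt((1 / 15) * (14 / 15) / n_test)
        assert abs(m.accuracy - 1 / 15) < 5 * se

    def test_matches_hand_chained_pipeline_on_fixed_split(self, small_dataset):
        ds, _ = small_dataset
        scheme = CVScheme(n_repeats=1)
        m = crossval_metrics(ds, scheme, rng_seed=42)
        # oracle: same split, fit -> project -> metrics chained by hand
        train, test = make_splits(ds, scheme, np.random.default_rng(42))[0]
        model = fit_dlda(ds.patterns[train], ds.labels[train])
        coords = project(model, ds.patterns[test])
        y = ds.labels[test]
        _, acc = confusion_and_accuracy(coords, y, model.class_centroids,
                                        model.classes)
        _, dmean = pairwise_discriminability(coords, y)
        dec = identity_decomposition(coords, y)
        assert m.accuracy == pytest.approx(acc, abs=0)
        assert m.delta_mean == pytest.approx(dmean, abs=0)
        assert m.f_ratio == pytest.approx(dec.f_ratio, abs=0)

    def test_novelty_metrics_produced(self, small_dataset):
        ds, _ = small_dataset
        ident, nov = crossval_metrics(ds, CVScheme(n_repeats=2),
                                      include_novel=True, rng_seed=0)
        assert nov.f_novelty > 0 and nov.n_novel > 0


class TestPermutationNull:
    def test_null_mean_at_chance_and_observed_consistency(self, small_dataset):
        ds, _ = small_dataset
        scheme = CVScheme(n_repeats=2)
        null = permutation_null(ds, scheme, n_perm=300, rng_seed=5)
        assert null.samples.mean() == pytest.approx(1 / 15, abs=0.01)
        m = crossval_metrics(ds, scheme, rng_seed=5)
        assert null.observed == pytest.approx(m.accuracy, abs=0)

    def test_planted_effect_hits_p_floor(self, small_dataset):
        ds, _ = small_dataset
        null = permutation_null(ds, CVScheme(n_repeats=2), n_perm=200,
                                rng_seed=0)
        assert null.pvalue == pytest.approx(1 / 201)

    def test_low_n_perm_warns(self, small_dataset):
        ds, _ = small_dataset
        with pytest.warns(UserWarning, match="n_perm"):
            permutation_null(ds, CVScheme(n_repeats=1), n_perm=50, rng_seed=0)


class TestMinStatistic:
    def test_single_dataset_reduces_to_permutation_p(self, rng):
        null = rng.uniform(size=999)
        obs = np.quantile(null, 0.95)
        m, p = min_statistic_pvalue([obs], [null], n_second=200_000, rng_seed=0)
        direct = (1 + np.sum(np.append(null, obs) >= obs)) / 1001
        assert m == obs
        assert p == pytest.approx(direct, abs=0.002)

    def test_observed_at_null_median_order_statistic(self, rng):
        # analytic oracle: with independent U(0,1) nulls and every observed
        # value at the null median, P(min of n draws >= median) = 2^-n
        n = 6
        nulls = [rng.uniform(size=2000) for _ in range(n)]
        obs = np.full(n, 0.5)
        _, p = min_statistic_pvalue(obs, nulls, n_second=100_000, rng_seed=1)
        assert p == pytest.approx(2.0 ** -n, rel=0.15)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="null"):
            min_statistic_pvalue([0.5, 0.6], [np.zeros(10)])


class TestCorrections:
    @pytest.mark.parametrize("p,n,expected", [(0.0001, 1516, 0.1516),
                                              (0.0, 10, 0.0),
                                              (0.01, 10, 0.1),
                                              (0.5, 1516, 1.0)])
    def test_bonferroni(self, p, n, expected):
        assert correct_multiple(p, n) == pytest.approx(expected)


class TestPrevalence:
    def test_threshold_case_bound_near_alpha(self):
        res = prevalence(0.0012, n=16, gamma0=0.5)
        assert res.bound == pytest.approx(0.05, abs=0.002)

    def test_gamma_est_zero_at_alpha(self):
        res = prevalence(0.05, n=16, gamma0=0.5, alpha=0.05)
        assert res.gamma_est == pytest.approx(0.0, abs=1e-12)

    def test_gamma_est_undefined_beyond_alpha(self):
        res = prevalence(0.2, n=16)
        assert np.isnan(res.gamma_est)
        res1 = prevalence(1.0, n=16)
        assert np.isnan(res1.gamma_est)

    def test_monotonicity_in_p(self):
        ps = np.linspace(1e-6, 1.0, 50)
        bounds = [prevalence_bound(p, 16, 0.5) for p in ps]
        assert np.all(np.diff(bounds) >= 0)
        gs = [prevalence(p, 16).gamma_est for p in ps if p <= 0.05]
        assert np.all(np.diff(gs) <= 1e-12)
        assert all(prevalence_bound(p, 16, 0.5) >= p for p in ps)

    def test_threshold_root(self):
        root = prevalence_threshold(n=16, gamma0=0.5, alpha=0.05)
        assert prevalence_bound(root, 16, 0.5) == pytest.approx(0.05, abs=1e-12)

    def test_coverage_when_true_prevalence_below_threshold(self, rng):
        # gamma_true = 0.3125 (5 of 16): the prevalence-null rejection rate
        # must stay at or below alpha
        n, n_rep = 16, 300
        rejections = 0
        for _ in range(n_rep):
            effect = np.zeros(n, bool)
            effect[:5] = True
            obs = np.where(effect, 1.0, rng.uniform(size=n))
            nulls = [rng.uniform(size=200) for _ in range(n)]
            _, p = min_statistic_pvalue(obs, nulls, n_second=2000, rng_seed=rng)
            res = prevalence(min(1.0, p), n=n)     # no multiple-comparison here
            rejections += res.selective
        assert rejections / n_rep <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / n_rep)


class TestZscore:
    def test_trivial_values(self, rng):
        null = rng.normal(10, 2, 5000)
        mu, sd = null.mean(), null.std()
        assert zscore_against_null(mu, null) == pytest.approx(0.0, abs=1e-12)
        assert zscore_against_null(mu + 2 * sd, null) == pytest.approx(2.0)

    def test_degenerate_null(self):
        with pytest.raises(ValueError, match="degenerate"):
            zscore_against_null(1.0, np.ones(10))

    def test_monotone_in_effect_size(self, small_sequences):
        zs = []
        for sep in (0.0, 1.0, 3.0):
            params = GeneratorParams(class_separation=sep, autocorr_profile={},
                                     amplitude_drift_per_run=0.0,
                                     identity_ssb_rate=0.0,
                                     novelty_offset_rate=0.0,
                                     novel_contraction_rate=0.0)
            ds, _ = simulate_parcel_responses(small_sequences, ParcelSpec(15, 3),
                                              params, rng_seed=6)
            null = permutation_null(ds, CVScheme(n_repeats=2), n_perm=150,
                                    rng_seed=0, statistic="f_identity")
            zs.append(zscore_against_null(null.observed, null.samples))
        assert zs[0] < zs[1] < zs[2]
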