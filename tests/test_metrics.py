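"""RSA metrics: confusion/accuracy, pairwise discriminability, variance
decompositions (with a distance-based PERMANOVA oracle), normalized geometry,
the trial-lag correction, and per-run category summaries."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import pdist

from parcelrsa import (category_summaries, confusion_and_accuracy,
                       correct_distances, delay_profile_and_correct,
                       estimate_delay_profile, identity_decomposition,
                       normalized_geometry, novelty_decomposition,
                       pairwise_discriminability)
from parcelrsa.metrics import DelayProfile


class TestConfusion:
    def test_points_at_centroids(self):
        centroids = np.array([[0.0, 0.0], [3.0, 0.0], [0.0, 3.0]])
        conf, acc = confusion_and_accuracy(centroids, np.array([0, 1, 2]),
                                           centroids, np.array([0, 1, 2]))
        assert np.array_equal(conf, np.eye(3))
        assert acc == 1.0

    def test_handcrafted_two_class_enumeration(self):
        # centroids at 0 and 1 on a line; four test points assigned by hand
        centroids = np.array([[0.0], [1.0]])
        coords = np.array([[0.1], [0.9], [0.4], [1.4]])
        labels = np.array([0, 0, 1, 1])
        conf, acc = confusion_and_accuracy(coords, labels, centroids,
                                           np.array([0, 1]))
        # class 0: 0.1 -> 0, 0.9 -> 1;  class 1: 0.4 -> 0, 1.4 -> 1
        assert np.allclose(conf, [[0.5, 0.5], [0.5, 0.5]])
        assert acc == pytest.approx(0.5)

    def test_shuffled_labels_near_chance_for_15_classes(self, rng):
        kappa, n = 15, 6000
        centroids = rng.standard_normal((kappa, 14))
        coords = rng.standard_normal((n, 14))
        labels = rng.integers(0, kappa, n)
        _, acc = confusion_and_accuracy(coords, labels, centroids,
                                        np.arange(kappa))
        assert abs(acc - 1 / 15) < 4 * np.sqrt((1 / 15) * (14 / 15) / n)

    def test_empty_test_class_error(self):
        with pytest.raises(ValueError, match="empty"):
            confusion_and_accuracy(np.zeros((2, 2)), np.array([0, 0]),
                                   np.zeros((2, 2)), np.array([0, 1]))

    def test_tie_broken_to_lowest_class_index(self):
        centroids = np.array([[0.0], [2.0]])
        conf, _ = confusion_and_accuracy(np.array([[1.0], [1.0]]),
                                         np.array([0, 1]), centroids,
                                         np.array([0, 1]))
        assert conf[0, 0] == 1.0 and conf[1, 0] == 1.0


class TestDelta:
    def test_identical_distributions_give_zero_mean_separation(self, rng):
        g = rng.standard_normal((200, 3))
        coords = np.vstack([g, g])
        labels = np.repeat([0, 1], 200)
        _, dmean = pairwise_discriminability(coords, labels)
        assert dmean == pytest.approx(0.0, abs=1e-12)

    def test_formula_evaluation_in_one_dimension(self):
        a = np.array([[-1.0], [1.0], [0.0]]) + 0
        coords = np.vstack([a, a + 2.0])
        labels = np.repeat([0, 1], 3)
        delta, dmean = pairwise_discriminability(coords, labels, ddof=0)
        sigma2 = np.var([-1, 1, 0])
        assert delta[0, 1] == pytest.approx(2 / np.sqrt(sigma2))

    def test_matches_direct_formula_oracle(self, rng):
        coords = rng.standard_normal((90, 4)) + np.repeat(
            rng.normal(0, 2, (3, 4)), 30, axis=0)
        labels = np.repeat([0, 1, 2], 30)
        delta, dmean = pairwise_discriminability(coords, labels)
        # oracle: raw recomputation for one pair
        for i, j in [(0, 1), (0, 2), (1, 2)]:
            gi, gj = coords[labels == i], coords[labels == j]
            u = gj.mean(0) - gi.mean(0)
            u /= np.linalg.norm(u)
            pi, pj = gi @ u, gj @ u
            d = abs(pi.mean() - pj.mean()) / np.sqrt(
                0.5 * (pi.var(ddof=1) + pj.var(ddof=1)))
            assert delta[i, j] == pytest.approx(d, rel=1e-12)
        pairs = [delta[i, j] for i in range(3) for j in range(i + 1, 3)]
        assert dmean == pytest.approx(np.mean(pairs), rel=1e-12)

    def test_zero_pooled_variance_flagged_infinite(self):
        coords = np.array([[0.0], [0.0], [1.0], [1.0], [2.0], [3.0]])
        labels = np.array([0, 0, 1, 1, 2, 2])
        delta, dmean = pairwise_discriminability(coords, labels)
        assert np.isinf(delta[0, 1])
        assert np.isfinite(dmean)


class TestIdentityDecomposition:
    def test_huygens_decomposition_random_inputs(self, rng):
        for _ in range(10):
            coords = rng.standard_normal((60, 5))
            labels = rng.integers(0, 4, 60)
            m = identity_decomposition(coords, labels)
            assert m.ss_total == pytest.approx(m.ss_within + m.ss_between,
                                               rel=1e-9)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_huygens_decomposition_property(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(8, 40))
        coords = rng.normal(0, rng.uniform(0.1, 10), (n, int(rng.integers(1, 6))))
        labels = rng.integers(0, 3, n)
        if len(np.unique(labels)) < 2 or n <= len(np.unique(labels)):
            return
        m = identity_decomposition(coords, labels)
        assert m.ss_total == pytest.approx(m.ss_within + m.ss_between,
                                           rel=1e-9, abs=1e-12)

    def test_points_at_centroids_give_infinite_f(self):
        coords = np.repeat(np.array([[0.0, 0.0], [1.0, 1.0]]), 3, axis=0)
        m = identity_decomposition(coords, np.repeat([0, 1], 3))
        assert m.ss_within == 0 and np.isinf(m.f_ratio)

    def test_matches_distance_based_permanova_oracle(self, rng):
        # pseudo-F recomputed from the pairwise-distance formulation
        coords = rng.standard_normal((40, 6))
        labels = rng.integers(0, 3, 40)
        m = identity_decomposition(coords, labels)
        N = 40
        kappa = 3
        d2 = pdist(coords) ** 2
        sst = d2.sum() / N
        ssw = 0.0
        ii, jj = np.triu_indices(N, k=1)
        for c in range(kappa):
            sel = (labels[ii] == c) & (labels[jj] == c)
            ssw += d2[sel].sum() / np.sum(labels == c)
        f_oracle = ((sst - ssw) / (kappa - 1)) / (ssw / (N - kappa))
        assert m.f_ratio == pytest.approx(f_oracle, rel=1e-9)

    def test_matches_scikit_bio_permanova_statistic(self, rng):
        from skbio.stats.distance import DistanceMatrix, permanova
        from scipy.spatial.distance import squareform
        coords = rng.standard_normal((30, 4)) + np.repeat(
            rng.normal(0, 1, (3, 4)), 10, axis=0)
        labels = np.repeat([0, 1, 2], 10)
        m = identity_decomposition(coords, labels)
        dm = DistanceMatrix(squareform(pdist(coords)))
        res = permanova(dm, grouping=[str(c) for c in labels], permutations=0)
        assert m.f_ratio == pytest.approx(res["test statistic"], rel=1e-9)

    def test_single_class_error(self):
        with pytest.raises(ValueError):
            identity_decomposition(np.zeros((5, 2)), np.zeros(5))


class TestNoveltyDecomposition:
    def test_equal_centroids_give_zero_between(self, rng):
        g = rng.standard_normal((50, 3))
        m = novelty_decomposition(np.vstack([g, g]),
                                  np.repeat([False, True], 50))
        assert m.ss_novfam == pytest.approx(0.0, abs=1e-12)
        assert m.f_novelty == pytest.approx(0.0, abs=1e-10)

    def test_formula_evaluation_equal_sizes(self):
        fam = np.array([[0.0], [0.0]])
        nov = np.array([[2.0], [2.0]])
        m = novelty_decomposition(np.vstack([fam, nov]),
                                  np.array([False, False, True, True]))
        assert m.ss_novfam == pytest.approx(1.0)     # NM/(N+M)^2 * 4 = 1/4 * 4

    def test_ssb_identities_agree_on_random_instances(self, rng):
        for _ in range(10):
            n, m_ = rng.integers(5, 30, 2)
            coords = rng.standard_normal((n + m_, 4))
            flags = np.concatenate([np.zeros(n, bool), np.ones(m_, bool)])
            met = novelty_decomposition(coords, flags)   # internal cross-check
            assert met.ss_total == pytest.approx(met.ss_within + met.ss_novfam,
                                                 rel=1e-9)

    def test_empty_class_error(self):
        with pytest.raises(ValueError, match="non-empty"):
            novelty_decomposition(np.zeros((3, 2)), np.zeros(3, bool))


class TestNormalizedGeometry:
    def test_unit_vector_amplitude(self):
        x = np.zeros((1, 14))
        x[0, 0] = 1.0
        a, _ = normalized_geometry(x)
        assert a[0] == pytest.approx(1 / np.sqrt(14))

    def test_identical_points_zero_distance(self, rng):
        x = rng.standard_normal(5)
        a, d = normalized_geometry(np.vstack([x, x]))
        assert d[0, 1] == 0.0

    def test_rms_distance_between_random_amplitude_099_patterns(self, rng):
        # independent isotropic patterns of fixed normalized amplitude 0.99:
        # RMS normalized pairwise distance = sqrt(2) * 0.99 ~ 1.400
        n, dim = 2000, 14
        x = rng.standard_normal((n, dim))
        x *= 0.99 * np.sqrt(dim) / np.linalg.norm(x, axis=1, keepdims=True)
        a, d = normalized_geometry(x)
        assert np.allclose(a, 0.99)
        rms = np.sqrt(np.mean(d[np.triu_indices(n, 1)] ** 2))
        assert rms == pytest.approx(np.sqrt(2) * 0.99, rel=0.01)


class TestDelayCorrection:
    def _coords(self, rng, n_runs=4, run_len=60, dim=6):
        run = np.repeat(np.arange(1, n_runs + 1), run_len)
        trial = np.tile(np.arange(1, run_len + 1), n_runs)
        coords = rng.standard_normal((n_runs * run_len, dim))
        return coords, trial, run

    def test_flat_profile_correction_is_identity(self, rng):
        coords, trial, run = self._coords(rng)
        _, D = normalized_geometry(coords)
        flat = DelayProfile(lags=np.arange(1, 60), values=np.full(59, 1.3),
                            counts=np.full(59, 10))
        corrected = correct_distances(D, trial, run, flat)
        assert np.allclose(corrected, D)

    def test_per_lag_mean_of_corrected_equals_profile_mean(self, rng):
        coords, trial, run = self._coords(rng)
        _, D = normalized_geometry(coords)
        prof, corrected = delay_profile_and_correct(D, trial, run)
        prof_c = estimate_delay_profile(corrected, trial, run)
        assert np.allclose(prof_c.values, prof.mean, atol=1e-9)

    def test_cross_run_pairs_untouched(self, rng):
        coords, trial, run = self._coords(rng, n_runs=2)
        _, D = normalized_geometry(coords)
        prof, corrected = delay_profile_and_correct(D, trial, run)
        cross = run[:, None] != run[None, :]
        assert np.array_equal(corrected[cross], D[cross])

    def test_gap_interpolation(self, rng):
        # only lags 1 and 3 observable -> lag 2 interpolated
        run = np.array([1, 1, 2, 2, 3, 3, 1, 2, 3])
        trial = np.array([1, 2, 1, 2, 1, 2, 5, 5, 5])
        coords = rng.standard_normal((9, 3))
        _, D = normalized_geometry(coords)
        prof = estimate_delay_profile(D, trial, run)
        assert 2 in prof.interpolated


class TestCategorySummaries:
    def test_hand_computed_two_class_geometry(self):
        # two classes of two identical points each, centroids 1 apart
        coords = np.array([[0.0, 0], [0, 0], [1, 0], [1, 0]])
        labels = np.array([1, 1, 2, 2])
        novel = np.zeros(4, bool)
        run = np.ones(4, int)
        a, D = normalized_geometry(coords)
        D_raw = D * np.sqrt(2)            # undo the 1/sqrt(kappa-1) for clarity
        out = category_summaries(coords, D_raw, a, labels, novel, run)
        assert out.loc[0, "D_same"] == pytest.approx(0.0)
        assert out.loc[0, "D_diff"] == pytest.approx(1.0)

    def test_pair_counts_by_combinatorics(self, rng):
        labels = np.concatenate([np.full(n, i) for i, n in enumerate([4, 6, 5])])
        n_same = sum(n * (n - 1) // 2 for n in [4, 6, 5])
        coords = rng.standard_normal((15, 3))
        novel = np.zeros(15, bool)
        run = np.ones(15, int)
        a, D = normalized_geometry(coords)
        out = category_summaries(coords, D, a, labels, novel, run)
        ii, jj = np.triu_indices(15, 1)
        same_pairs = np.sum(labels[ii] == labels[jj])
        assert same_pairs == n_same
        same_vals = D[ii, jj][labels[ii] == labels[jj]]
        assert out.loc[0, "D_same"] == pytest.approx(same_vals.mean())

    def test_run_without_novel_trials_flagged_missing(self, rng):
        coords = rng.standard_normal((20, 3))
        labels = np.tile([1, 2], 10)
        novel = np.zeros(20, bool)
        novel[0] = True
        labels[0] = 0
        run = np.repeat([1, 2], 10)
        a, D = normalized_geometry(coords)
        out = category_summaries(coords, D, a, labels, novel, run).set_index("run")
        assert np.isnan(out.loc[2, "D_nov"])
        assert np.isfinite(out.loc[2, "D_same"])
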