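"""Deep clustering and validity metrics against brute-force oracles."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score, silhouette_score

from peanutstore import clustering as cl
from peanutstore.synthetic import make_blob_fixture


# ---------------------------------------------------------------------------
# brute-force oracles: literal double loops over the definitions
# ---------------------------------------------------------------------------

def brute_silhouette(X, labels):
    n = len(X)
    dist = lambda i, j: np.sqrt(((X[i] - X[j]) ** 2).sum())
    scores = []
    for i in range(n):
        own = [j for j in range(n) if labels[j] == labels[i] and j != i]
        a = sum(dist(i, j) for j in own) / len(own) if own else 0.0
        b = min(
            np.mean([dist(i, j) for j in range(n) if labels[j] == c])
            for c in set(labels) if c != labels[i])
        scores.append(0.0 if max(a, b) == 0 else (b - a) / max(a, b))
    return float(np.mean(scores))


def brute_davies_bouldin(X, labels):
    clusters = sorted(set(labels))
    cents = {c: X[labels == c].mean(axis=0) for c in clusters}
    scatter = {c: np.mean(np.linalg.norm(X[labels == c] - cents[c], axis=1))
               for c in clusters}
    total = 0.0
    for ci in clusters:
        worst = max(
            (scatter[ci] + scatter[cj]) / np.linalg.norm(cents[ci] - cents[cj])
            for cj in clusters if cj != ci)
        total += worst
    return total / len(clusters)


def brute_calinski_harabasz(X, labels):
    clusters = sorted(set(labels))
    n, k = len(X), len(clusters)
    mean = X.mean(axis=0)
    between = sum(len(X[labels == c])
                  * ((X[labels == c].mean(axis=0) - mean) ** 2).sum()
                  for c in clusters)
    within = sum(((X[labels == c] - X[labels == c].mean(axis=0)) ** 2).sum()
                 for c in clusters)
    return (between / (k - 1)) / (within / (n - k))


# ---------------------------------------------------------------------------
# autoencoder
# ---------------------------------------------------------------------------

class TestAutoencoder:
    def test_recovers_planar_subspace(self, rng):
        basis = rng.normal(size=(2, 6))
        Z = rng.normal(size=(200, 2))
        X = Z @ basis  # exact 2-D plane in 6-D
        model = cl.train_autoencoder(X, latent_dim=2, epochs=400, seed=0)
        mse = float(((model.reconstruct(X) - X) ** 2).mean())
        assert mse < 1e-3

    def test_deterministic_given_seed(self, rng):
        X = rng.normal(size=(50, 6))
        m1 = cl.train_autoencoder(X, 2, epochs=20, seed=3)
        m2 = cl.train_autoencoder(X, 2, epochs=20, seed=3)
        for a, b in zip(m1.state_dict(), m2.state_dict()):
            assert np.array_equal(a, b)

    def test_latent_dim_must_compress(self):
        with pytest.raises(ValueError, match="latent_dim"):
            cl.Autoencoder(6, 6)


# ---------------------------------------------------------------------------
# clustering methods
# ---------------------------------------------------------------------------

class TestMethods:
    @pytest.mark.parametrize("k,fixture", [(2, None), (3, "blob_3"),
                                           (5, "blob_5")])
    def test_kmeanspp_perfect_on_blobs(self, k, fixture, request):
        if fixture is None:
            X, y = make_blob_fixture(k=2, n_per_cluster=40, separation=10.0,
                                     seed=2)
        else:
            X, y = request.getfixturevalue(fixture)
        cm = cl.kmeanspp_cluster(X, k=k, seed=0)
        assert adjusted_rand_score(y, cm.labels) == 1.0

    def test_kmeanspp_k_equals_n(self):
        X = np.arange(8.0).reshape(4, 2)
        cm = cl.kmeanspp_cluster(X, k=4, seed=0)
        assert cm.inertia == pytest.approx(0.0)
        assert len(set(cm.labels)) == 4

    def test_kmeanspp_duplicates_collapse(self):
        X = np.vstack([np.zeros((5, 2)), np.ones((5, 2))])
        cm = cl.kmeanspp_cluster(X, k=2, seed=0)
        assert adjusted_rand_score([0] * 5 + [1] * 5, cm.labels) == 1.0

    def test_dcn_perfect_on_blobs(self, blob_3):
        X, y = blob_3
        cm = cl.dcn_cluster(X, k=3, seed=0)
        assert adjusted_rand_score(y, cm.labels) == 1.0

    def test_dcn_code_centroid_distance_shrinks(self, blob_3):
        X, _ = blob_3
        cm = cl.dcn_cluster(X, k=3, lambda_cluster=4.0, seed=0)
        d = cm.history["mean_code_centroid_dist"]
        assert d[-1] < d[0]

    def test_dcn_lambda_zero_is_posthoc_kmeans(self, blob_3):
        """Without the cluster loss, DCN is AE pretraining + k-means."""
        X, _ = blob_3
        cm = cl.dcn_cluster(X, k=3, lambda_cluster=0.0, seed=0,
                            outer_iters=1)
        ae = cl.train_autoencoder(X, 2, epochs=200, seed=0, lr=1e-2)
        from sklearn.cluster import KMeans
        km = KMeans(n_clusters=3, init="k-means++", n_init=10,
                    random_state=0).fit(ae.encode(X))
        assert adjusted_rand_score(km.labels_, cm.labels) == 1.0

    def test_k_one_rejected(self, blob_3):
        X, _ = blob_3
        with pytest.raises(ValueError):
            cl.dcn_cluster(X, k=1, seed=0)
        with pytest.raises(ValueError):
            cl.dec_cluster(X, k=1, seed=0)

    def test_dec_soft_assignments_normalised(self, blob_3):
        X, _ = blob_3
        cm = cl.dec_cluster(X, k=3, seed=0, finetune_epochs=10)
        assert np.allclose(cm.soft_assignments.sum(axis=1), 1.0, atol=1e-8)

    def test_dec_perfect_on_blobs(self):
        X, y = make_blob_fixture(k=2, n_per_cluster=40, separation=10.0,
                                 seed=5)
        cm = cl.dec_cluster(X, k=2, seed=0)
        assert adjusted_rand_score(y, cm.labels) == 1.0

    def test_dec_zero_finetuning_equals_kmeans_on_codes(self, blob_3):
        X, _ = blob_3
        cm = cl.dec_cluster(X, k=3, seed=0, finetune_epochs=0)
        ae = cl.train_autoencoder(X, 2, epochs=200, seed=0, lr=1e-2)
        from sklearn.cluster import KMeans
        km = KMeans(n_clusters=3, init="k-means++", n_init=10,
                    random_state=0).fit(ae.encode(X))
        assert adjusted_rand_score(km.labels_, cm.labels) == 1.0


# ---------------------------------------------------------------------------
# validity metrics
# ---------------------------------------------------------------------------

class TestValidity:
    def test_two_singletons_score_one(self):
        X = np.array([[0.0, 0.0], [3.0, 0.0]])
        assert cl.silhouette(X, np.array([0, 1])) == 1.0

    def test_matches_sklearn_on_regular_clusters(self, blob_3):
        X, y = blob_3
        assert cl.silhouette(X, y) == pytest.approx(
            silhouette_score(X, y), abs=1e-10)

    def test_agrees_with_brute_force(self, rng):
        X = rng.normal(size=(60, 4))
        labels = rng.integers(0, 3, 60)
        rep = cl.validity_metrics(X, labels)
        assert rep.sc == pytest.approx(brute_silhouette(X, labels), abs=1e-8)
        assert rep.db == pytest.approx(brute_davies_bouldin(X, labels),
                                       abs=1e-8)
        assert rep.ch == pytest.approx(brute_calinski_harabasz(X, labels),
                                       abs=1e-8)

    def test_random_labels_near_zero_silhouette(self):
        gen = np.random.default_rng(17)
        X = gen.normal(size=(500, 3))
        labels = gen.integers(0, 2, 500)
        assert abs(cl.silhouette(X, labels)) < 0.1

    def test_label_permutation_invariance(self, blob_3):
        X, y = blob_3
        rep1 = cl.validity_metrics(X, y)
        rep2 = cl.validity_metrics(X, (y + 1) % 3)
        # identical up to floating-point summation order
        assert rep1.sc == pytest.approx(rep2.sc, rel=1e-12)
        assert rep1.db == pytest.approx(rep2.db, rel=1e-12)
        assert rep1.ch == pytest.approx(rep2.ch, rel=1e-12)

    def test_metric_ranges_on_fuzzed_inputs(self):
        gen = np.random.default_rng(5)
        for _ in range(20):
            n = int(gen.integers(10, 40))
            k = int(gen.integers(2, 5))
            X = gen.normal(size=(n, 3))
            labels = np.r_[np.arange(k), gen.integers(0, k, n - k)]
            rep = cl.validity_metrics(X, labels)
            assert -1.0 <= rep.sc <= 1.0
            assert rep.db >= 0.0
            assert rep.ch > 0.0

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError, match="SC, DB, CH"):
            cl.validity_metrics(np.zeros((5, 2)), np.zeros(5))


# ---------------------------------------------------------------------------
# K selection
# ---------------------------------------------------------------------------

class TestSelectK:
    def test_five_profile_fixture_selects_five(self, blob_5):
        X, _ = blob_5
        best_k, table = cl.select_k(X, method="kmeans++",
                                    k_range=range(2, 9), seeds=(0, 1, 2))
        assert best_k == 5
        assert len(table) == 7

    def test_identical_seeds_give_zero_std(self, blob_3):
        X, _ = blob_3
        _, table = cl.select_k(X, k_range=range(2, 4), seeds=(0, 0, 0))
        assert np.allclose(table[["sc_std", "db_std", "ch_std"]], 0.0)
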