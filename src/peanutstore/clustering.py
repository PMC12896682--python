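"""Quality-grade discovery by deep clustering.

Three methods are compared on the same representation problem:

* **K-Means++** (scikit-learn): D^2 seeding plus Lloyd iterations, best of
  ``n_init`` starts by inertia.
* **DCN**: an autoencoder trained jointly with a k-means objective on its
  latent codes, ``L = sum ||x - g(f(x))||^2 + (lambda/2) sum ||f(x) - M s||^2``,
  optimised by alternating network updates, hard reassignment, and centroid
  means.
* **DEC**: after autoencoder pretraining, soft Student-t assignments to
  latent centroids are sharpened toward a target distribution under a KL
  objective that tunes encoder and centroids together.

Internal validity is scored by silhouette (SC), Davies-Bouldin (DB) and
Calinski-Harabasz (CH); :func:`select_k` sweeps K over randomized restarts
and picks the K with the best mean silhouette.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans
from sklearn.metrics import calinski_harabasz_score, davies_bouldin_score

from . import nn
from .nn import Tensor


# ---------------------------------------------------------------------------
# autoencoder
# ---------------------------------------------------------------------------

class Autoencoder(nn.Module):
    """Fully connected encoder/decoder: D -> 32 -> 16 -> latent and back."""

    def __init__(self, d_in: int, latent_dim: int, seed: int = 0,
                 hidden: tuple[int, int] = (32, 16)):
        if latent_dim >= d_in:
            raise ValueError("latent_dim must be smaller than the input "
                             "dimension")
        rng = np.random.default_rng(seed)
        dims = [d_in, *hidden, latent_dim]
        self.encoder = nn.MLP(dims, rng)
        self.decoder = nn.MLP(list(reversed(dims)), rng)

    def encode(self, X: np.ndarray) -> np.ndarray:
        return self.encoder(Tensor(np.asarray(X, dtype=float))).numpy()

    def reconstruct(self, X: np.ndarray) -> np.ndarray:
        z = self.encoder(Tensor(np.asarray(X, dtype=float)))
        return self.decoder(z).numpy()


def train_autoencoder(X: np.ndarray, latent_dim: int = 2, epochs: int = 300,
                      seed: int = 0, lr: float = 1e-2,
                      batch_size: int = 64) -> Autoencoder:
    """Train a reconstruction autoencoder; deterministic given ``seed``."""
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    model = Autoencoder(X.shape[1], latent_dim, seed=seed)
    rng = np.random.default_rng(seed)
    opt = nn.Adam(model.parameters(), lr=lr)
    for _ in range(epochs):
        order = rng.permutation(len(X))
        for i in range(0, len(order), batch_size):
            idx = order[i:i + batch_size]
            xb = Tensor(X[idx])
            loss = nn.mse_loss(model.decoder(model.encoder(xb)), X[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
    return model


# ---------------------------------------------------------------------------
# cluster model container
# ---------------------------------------------------------------------------

@dataclass
class ClusterModel:
    """Fitted clustering: hard assignments plus (latent) centroids."""

    method: str
    labels: np.ndarray
    centroids: np.ndarray
    seed: int
    autoencoder: Autoencoder | None = None
    inertia: float | None = None
    soft_assignments: np.ndarray | None = None
    history: dict | None = None

    def __post_init__(self):
        if not np.all(np.isfinite(self.centroids)):
            raise ValueError("centroids must be finite")


def _check_k(k: int, n: int, allow_equal: bool = False) -> None:
    upper = n if allow_equal else n - 1
    if not 2 <= k <= upper:
        raise ValueError(f"k must satisfy 2 <= k <= {upper}, got {k}")


# ---------------------------------------------------------------------------
# K-Means++
# ---------------------------------------------------------------------------

def kmeanspp_cluster(X: np.ndarray, k: int, n_init: int = 10,
                     seed: int = 0) -> ClusterModel:
    """K-Means with D^2 seeding, best of ``n_init`` runs by inertia."""
    X = np.asarray(X, dtype=float)
    _check_k(k, len(X), allow_equal=True)
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_init,
                random_state=seed).fit(X)
    return ClusterModel(method="KMeans++", labels=km.labels_.copy(),
                        centroids=km.cluster_centers_.copy(), seed=seed,
                        inertia=float(km.inertia_))


# ---------------------------------------------------------------------------
# DCN
# ---------------------------------------------------------------------------

def _reseed_empty(centroids: np.ndarray, codes: np.ndarray,
                  labels: np.ndarray) -> None:
    """Re-seed empty-cluster centroids from the farthest assigned point."""
    for j in range(len(centroids)):
        if not np.any(labels == j):
            far = np.argmax(np.linalg.norm(codes - centroids[labels], axis=1))
            centroids[j] = codes[far]
            labels[far] = j


def dcn_cluster(X: np.ndarray, k: int, lambda_cluster: float = 1.0,
                seed: int = 0, latent_dim: int = 2,
                pretrain_epochs: int = 200, outer_iters: int = 10,
                inner_epochs: int = 20, lr: float = 1e-2,
                batch_size: int = 64) -> ClusterModel:
    """Joint reconstruction + latent k-means clustering.

    Alternates (i) gradient updates of the autoencoder on
    ``recon + (lambda/2)*||f(x) - m_s||^2`` with assignments fixed,
    (ii) hard reassignment of codes to centroids, (iii) centroid means.
    Empty clusters are re-seeded from the farthest point.
    """
    X = np.asarray(X, dtype=float)
    _check_k(k, len(X))
    model = train_autoencoder(X, latent_dim, epochs=pretrain_epochs,
                              seed=seed, lr=lr, batch_size=batch_size)
    codes = model.encode(X)
    km = KMeans(n_clusters=k, init="k-means++", n_init=10,
                random_state=seed).fit(codes)
    centroids, labels = km.cluster_centers_.copy(), km.labels_.copy()

    rng = np.random.default_rng(seed + 1)
    opt = nn.Adam(model.parameters(), lr=lr)
    mean_dist = []
    for _ in range(outer_iters):
        if lambda_cluster > 0:
            for _ in range(inner_epochs):
                order = rng.permutation(len(X))
                for i in range(0, len(order), batch_size):
                    idx = order[i:i + batch_size]
                    xb = Tensor(X[idx])
                    z = model.encoder(xb)
                    recon = nn.mse_loss(model.decoder(z), X[idx])
                    diff = z - Tensor(centroids[labels[idx]])
                    cl = (diff * diff).mean()
                    loss = recon + cl * (lambda_cluster / 2.0)
                    opt.zero_grad()
                    loss.backward()
                    opt.step()
        codes = model.encode(X)
        labels = np.argmin(cdist(codes, centroids), axis=1)
        for j in range(k):
            mask = labels == j
            if mask.any():
                centroids[j] = codes[mask].mean(axis=0)
        _reseed_empty(centroids, codes, labels)
        mean_dist.append(float(np.linalg.norm(
            codes - centroids[labels], axis=1).mean()))
    return ClusterModel(method="DCN", labels=labels, centroids=centroids,
                        seed=seed, autoencoder=model,
                        history={"mean_code_centroid_dist": mean_dist})


# ---------------------------------------------------------------------------
# DEC
# ---------------------------------------------------------------------------

def _student_t(codes: np.ndarray, centroids: np.ndarray,
               alpha: float = 1.0) -> np.ndarray:
    d2 = cdist(codes, centroids, metric="sqeuclidean")
    q = (1.0 + d2 / alpha) ** (-(alpha + 1.0) / 2.0)
    return q / q.sum(axis=1, keepdims=True)


def dec_cluster(X: np.ndarray, k: int, seed: int = 0, latent_dim: int = 2,
                pretrain_epochs: int = 200, finetune_epochs: int = 50,
                lr: float = 1e-3, alpha: float = 1.0,
                update_interval: int = 5) -> ClusterModel:
    """Deep embedded clustering with Student-t soft assignments.

    The target distribution sharpens ``q`` (squared, frequency-normalised)
    and is refreshed every ``update_interval`` epochs; KL(p||q) is minimised
    over encoder weights and centroids jointly.  With
    ``finetune_epochs=0`` the hard labels equal plain k-means on the
    pretrained codes.
    """
    X = np.asarray(X, dtype=float)
    _check_k(k, len(X))
    model = train_autoencoder(X, latent_dim, epochs=pretrain_epochs,
                              seed=seed, lr=1e-2)
    codes = model.encode(X)
    km = KMeans(n_clusters=k, init="k-means++", n_init=10,
                random_state=seed).fit(codes)
    centroids = Tensor(km.cluster_centers_.copy(), requires_grad=True)

    q = _student_t(codes, centroids.numpy(), alpha)
    if finetune_epochs > 0:
        params = model.encoder.parameters() + [centroids]
        opt = nn.Adam(params, lr=lr)
        p = None
        for epoch in range(finetune_epochs):
            if epoch % update_interval == 0:
                codes = model.encode(X)
                q = _student_t(codes, centroids.numpy(), alpha)
                f = q.sum(axis=0)
                p = (q**2 / f) / (q**2 / f).sum(axis=1, keepdims=True)
            z = model.encoder(Tensor(X))
            diff = z.reshape(len(X), 1, -1) - centroids.reshape(1, k, -1)
            d2 = (diff * diff).sum(axis=-1)
            logits = ((d2 / alpha) + 1.0).log() * (-(alpha + 1.0) / 2.0)
            qt = nn.softmax(logits, axis=1)
            kl = (Tensor(p) * (Tensor(p + 1e-12).log() - (qt + 1e-12).log())).sum() * (1.0 / len(X))
            opt.zero_grad()
            kl.backward()
            opt.step()
        codes = model.encode(X)
        q = _student_t(codes, centroids.numpy(), alpha)
    labels = np.argmax(q, axis=1)
    return ClusterModel(method="DEC", labels=labels,
                        centroids=centroids.numpy().copy(), seed=seed,
                        autoencoder=model, soft_assignments=q)


# ---------------------------------------------------------------------------
# validity metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ValidityReport:
    """Internal clustering validity scores for one labelling."""

    sc: float   # silhouette, in [-1, 1]; higher better
    db: float   # Davies-Bouldin, >= 0; lower better
    ch: float   # Calinski-Harabasz, > 0; higher better
    k: int
    n: int


def silhouette(X: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette with the a=0 convention for singleton clusters.

    For a point alone in its cluster the intra-cluster distance ``a`` is
    taken as 0, so an isolated well-separated point scores 1 (scikit-learn
    instead scores it 0; the difference only arises for singleton clusters).
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("silhouette is undefined for a single cluster")
    D = cdist(X, X)
    s = np.zeros(len(X))
    masks = {c: labels == c for c in uniq}
    for i in range(len(X)):
        own = masks[labels[i]]
        n_own = own.sum()
        a = D[i, own].sum() / (n_own - 1) if n_own > 1 else 0.0
        b = min(D[i, masks[c]].mean() for c in uniq if c != labels[i])
        denom = max(a, b)
        s[i] = 0.0 if denom == 0 else (b - a) / denom
    return float(s.mean())


def validity_metrics(X: np.ndarray, labels: np.ndarray) -> ValidityReport:
    """SC/DB/CH for one clustering; every cluster must be non-empty."""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("validity metrics (SC, DB, CH) are undefined for "
                         "fewer than 2 clusters")
    return ValidityReport(
        sc=silhouette(X, labels),
        db=float(davies_bouldin_score(X, labels)),
        ch=float(calinski_harabasz_score(X, labels)),
        k=len(uniq), n=len(X))


_METHODS = {
    "kmeans++": lambda X, k, seed, n_init: kmeanspp_cluster(X, k, n_init, seed),
    "dcn": lambda X, k, seed, n_init: dcn_cluster(X, k, seed=seed),
    "dec": lambda X, k, seed, n_init: dec_cluster(X, k, seed=seed),
}


def select_k(X: np.ndarray, method: str = "kmeans++",
             k_range: range = range(2, 9), n_init: int = 10,
             seeds: tuple[int, ...] = (0, 1, 2)) -> tuple[int, pd.DataFrame]:
    """Sweep K over randomized restarts; pick best mean silhouette.

    Ties break toward lower mean DB, then higher mean CH.  Returns the
    chosen K and a table of mean +/- std per metric per K.
    """
    method_key = method.lower()
    if method_key not in _METHODS:
        raise ValueError(f"unknown method {method!r}")
    fit = _METHODS[method_key]
    rows = []
    for k in k_range:
        scs, dbs, chs = [], [], []
        for seed in seeds:
            cm = fit(np.asarray(X, dtype=float), k, seed, n_init)
            rep = validity_metrics(X, cm.labels)
            scs.append(rep.sc)
            dbs.append(rep.db)
            chs.append(rep.ch)
        rows.append({
            "k": k,
            "sc_mean": np.mean(scs), "sc_std": np.std(scs),
            "db_mean": np.mean(dbs), "db_std": np.std(dbs),
            "ch_mean": np.mean(chs), "ch_std": np.std(chs),
        })
    table = pd.DataFrame(rows).set_index("k")
    order = table.sort_values(["sc_mean", "db_mean", "ch_mean"],
                              ascending=[False, True, False])
    return int(order.index[0]), table
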