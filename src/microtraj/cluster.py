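"""Sample clustering on the selected-feature space.

k-means with gap-statistic model selection, stabilised by resampling-based
consensus: the clustering is repeated on random 80% subsamples, co-clustering
frequencies are aggregated into a consensus matrix, and the final partition is
an average-linkage cut of 1 - consensus. Silhouette widths validate the
result.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_samples
from sklearn.utils.validation import validate_data

logger = logging.getLogger(__name__)

DEFAULT_RUNS = 1000
DEFAULT_FRAC = 0.8
DEFAULT_RESTARTS = 50
DEFAULT_B = 50


@dataclass
class ClusteringResult:
    labels: np.ndarray  # 1..k
    k: int
    consensus: np.ndarray
    silhouette: np.ndarray
    gap_curve: pd.DataFrame | None = None


def kmeans_fit(X: np.ndarray, k: int, restarts: int = DEFAULT_RESTARTS, seed: int = 0) -> np.ndarray:
    """Best-of-restarts Lloyd k-means; labels returned in 1..k."""
    X = np.asarray(X, dtype=float)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > X.shape[0]:
        raise ValueError("k cannot exceed the number of samples")
    km = KMeans(n_clusters=k, n_init=restarts, tol=1e-6, random_state=seed)
    return km.fit_predict(X) + 1


def _within_dispersion(X: np.ndarray, labels: np.ndarray) -> float:
    w = 0.0
    for lab in np.unique(labels):
        block = X[labels == lab]
        w += float(((block - block.mean(axis=0)) ** 2).sum())
    return w


def estimate_k_gap(
    X: np.ndarray,
    k_max: int = 10,
    B: int = DEFAULT_B,
    seed: int = 0,
    restarts: int = 10,
    return_curve: bool = False,
):
    """Gap-statistic choice of the number of clusters.

    Reference datasets are drawn uniformly over the PCA-aligned bounding box
    of the data; the estimate is the smallest k with
    gap(k) >= gap(k+1) - se(k+1).
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if k_max < 1 or B < 1:
        raise ValueError("k_max and B must be >= 1")
    if n < 2 or np.allclose(X, X[0]):
        return (1, None) if return_curve else 1
    k_max = min(k_max, n)
    rng = np.random.default_rng(seed)
    centered = X - X.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    proj = centered @ vt.T
    lo, hi = proj.min(axis=0), proj.max(axis=0)

    log_w = np.empty(k_max)
    log_w_ref = np.empty((B, k_max))
    for k in range(1, k_max + 1):
        labels = kmeans_fit(X, k, restarts=restarts, seed=seed)
        log_w[k - 1] = np.log(max(_within_dispersion(X, labels), 1e-300))
    for b in range(B):
        ref = rng.uniform(lo, hi, size=proj.shape) @ vt + X.mean(axis=0)
        for k in range(1, k_max + 1):
            labels = kmeans_fit(ref, k, restarts=restarts, seed=seed)
            log_w_ref[b, k - 1] = np.log(max(_within_dispersion(ref, labels), 1e-300))

    gap = log_w_ref.mean(axis=0) - log_w
    se = log_w_ref.std(axis=0, ddof=0) * np.sqrt(1.0 + 1.0 / B)
    k_hat = k_max
    for k in range(1, k_max):
        if gap[k - 1] >= gap[k] - se[k]:
            k_hat = k
            break
    curve = pd.DataFrame({"k": np.arange(1, k_max + 1), "gap": gap, "se": se})
    return (k_hat, curve) if return_curve else k_hat


def consensus_cluster(
    X: np.ndarray,
    k: int,
    runs: int = DEFAULT_RUNS,
    frac: float = DEFAULT_FRAC,
    seed: int = 0,
    subsample_restarts: int = 3,
) -> ClusteringResult:
    """Resampling consensus: k-means on random subsamples, aggregated co-clustering.

    consensus_ij = (# times i,j co-clustered) / (# times i,j co-sampled);
    final labels cut an average-linkage dendrogram of 1 - consensus at k.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if not 0 < frac <= 1:
        raise ValueError("frac must be in (0, 1]")
    rng = np.random.default_rng(seed)
    m = max(int(round(frac * n)), k)
    together = np.zeros((n, n))
    co_sampled = np.zeros((n, n))
    for r in range(runs):
        idx = rng.choice(n, size=m, replace=False) if m < n else np.arange(n)
        labels = kmeans_fit(X[idx], k, restarts=subsample_restarts,
                            seed=int(rng.integers(0, 2**31 - 1)))
        co_sampled[np.ix_(idx, idx)] += 1
        for lab in range(1, k + 1):
            members = idx[labels == lab]
            together[np.ix_(members, members)] += 1
    never = co_sampled == 0
    n_never = int(never.sum() - np.diag(never).sum()) // 2
    if n_never:
        logger.warning("%d sample pairs never co-sampled; consensus imputed 0", n_never)
    with np.errstate(invalid="ignore", divide="ignore"):
        consensus = np.where(never, 0.0, together / np.maximum(co_sampled, 1))
    np.fill_diagonal(consensus, 1.0)
    consensus = (consensus + consensus.T) / 2.0

    if k == 1:
        final = np.ones(n, dtype=int)
    else:
        dist = 1.0 - consensus
        np.fill_diagonal(dist, 0.0)
        final = fcluster(linkage(squareform(dist, checks=False), method="average"),
                         k, criterion="maxclust")
        final = _absorb_micro_clusters(X, final)
    k_eff = int(np.unique(final).size)
    sil = silhouette_widths(X, final) if k_eff > 1 else np.zeros(n)
    return ClusteringResult(labels=final, k=k_eff, consensus=consensus, silhouette=sil)


def _absorb_micro_clusters(X: np.ndarray, labels: np.ndarray,
                           min_frac: float = 0.02) -> np.ndarray:
    """Reassign members of near-empty clusters to the nearest real centroid.

    The maxclust cut of a consensus dendrogram can split off singleton or
    two-sample clusters; these are artifacts of the cut, not community
    states, and would surface downstream as spurious graph leaves."""
    labels = labels.copy()
    n = labels.size
    min_size = max(2, int(round(min_frac * n)))
    sizes = {lab: int((labels == lab).sum()) for lab in np.unique(labels)}
    keep = [lab for lab, sz in sizes.items() if sz >= min_size]
    if not keep or len(keep) == len(sizes):
        return _relabel(labels)
    centroids = {lab: X[labels == lab].mean(axis=0) for lab in keep}
    for lab, sz in sizes.items():
        if lab in keep:
            continue
        logger.info("absorbing micro-cluster of %d samples", sz)
        for i in np.flatnonzero(labels == lab):
            labels[i] = min(centroids, key=lambda c: float(((X[i] - centroids[c]) ** 2).sum()))
    return _relabel(labels)


def _relabel(labels: np.ndarray) -> np.ndarray:
    mapping = {lab: i + 1 for i, lab in enumerate(np.unique(labels))}
    return np.array([mapping[lab] for lab in labels], dtype=int)


def silhouette_widths(X: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Standard silhouette s(i) = (b_i - a_i)/max(a_i, b_i) on Euclidean distances."""
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("silhouette needs at least 2 clusters")
    return silhouette_samples(np.asarray(X, dtype=float), labels)


class ConsensusKMeans(ClusterMixin, BaseEstimator):
    """Consensus k-means with optional gap-statistic choice of k.

    Fitted attributes: ``labels_`` (1..k), ``k_``, ``consensus_``,
    ``silhouette_``, ``gap_curve_`` (None unless k was estimated).
    """

    def __init__(
        self,
        n_clusters="gap",
        k_max: int = 10,
        gap_B: int = DEFAULT_B,
        runs: int = DEFAULT_RUNS,
        frac: float = DEFAULT_FRAC,
        random_state: int = 0,
    ):
        self.n_clusters = n_clusters
        self.k_max = k_max
        self.gap_B = gap_B
        self.runs = runs
        self.frac = frac
        self.random_state = random_state

    def fit(self, X, y=None):
        X = validate_data(self, X, dtype=float)
        if self.n_clusters == "gap":
            k, curve = estimate_k_gap(
                X, k_max=self.k_max, B=self.gap_B, seed=self.random_state, return_curve=True
            )
        else:
            k, curve = int(self.n_clusters), None
        res = consensus_cluster(X, k, runs=self.runs, frac=self.frac, seed=self.random_state)
        self.k_ = k
        self.labels_ = res.labels
        self.consensus_ = res.consensus
        self.silhouette_ = res.silhouette
        self.gap_curve_ = curve
        self.result_ = res
        return self
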