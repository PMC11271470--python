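"""Enterotype discovery: JSD distances, PAM clustering, CH-index model selection.

Samples are clustered on genus-level compositions with the square root of
the Jensen-Shannon divergence (a metric) and partitioning around medoids
(PAM, k-medoids).  The number of community states is chosen by maximising
the distance-based Calinski-Harabasz (CH) index over a range of k.
Driver taxa (the dominant genus of each cluster) and signature taxa (an
effect-size screen honouring the LDA > 2, p < 0.05 convention) summarise
what distinguishes the states.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from skbio import DistanceMatrix

from enterodyn.diversity import _as_square

#: Maximum of sqrt(JSD) with natural logarithms (disjoint supports).
MAX_JSD_DISTANCE = float(np.sqrt(np.log(2.0)))


@dataclass
class ClusteringResult:
    """A PAM partition: k, medoid samples, per-sample labels, total cost.

    ``labels`` maps each sample to a cluster in 1..k; clusters are
    numbered by ascending medoid index so the labelling is deterministic.
    ``total_cost`` is the sum over samples of the distance to the assigned
    medoid.
    """

    k: int
    medoid_indices: tuple
    medoids: tuple
    labels: np.ndarray
    total_cost: float


@dataclass
class OptimalK:
    """CH scores over a scanned k range and the argmax."""

    k_range: tuple
    ch_scores: tuple
    best_k: int
    results: dict  # k -> ClusteringResult


def jsd_distance(tbl: pd.DataFrame, pseudocount: float = 1e-6,
                 chunk: int = 128) -> DistanceMatrix:
    """Pairwise sqrt-Jensen-Shannon-divergence distances between samples.

    Zeros are replaced by ``pseudocount`` and columns re-closed before the
    divergence is computed with natural logarithms:
    d(a, b) = sqrt(H(m) - (H(a) + H(b)) / 2) with m = (a + b) / 2.
    The square root makes the divergence a metric, bounded by
    sqrt(ln 2) ~= 0.8326.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    X = tbl.to_numpy(dtype=float).T  # samples x taxa
    if X.size == 0:
        raise ValueError("empty abundance table")
    if (X < 0).any():
        raise ValueError("relative abundances must be non-negative")
    X = np.where(X == 0.0, pseudocount, X)
    X /= X.sum(axis=1, keepdims=True)
    n = X.shape[0]
    h = -np.sum(X * np.log(X), axis=1)  # per-sample Shannon entropy (nats)
    d = np.zeros((n, n))
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        m = 0.5 * (X[start:stop, None, :] + X[None, :, :])
        hm = -np.sum(m * np.log(m), axis=2)
        jsd = hm - 0.5 * (h[start:stop, None] + h[None, :])
        d[start:stop] = np.sqrt(np.clip(jsd, 0.0, None))
    d = 0.5 * (d + d.T)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d, ids=list(tbl.columns))


def _pam_build(d: np.ndarray, k: int) -> list[int]:
    """Greedy BUILD phase: add the medoid giving the largest cost drop."""
    n = d.shape[0]
    medoids = [int(np.argmin(d.sum(axis=0)))]
    d_nearest = d[:, medoids[0]].copy()
    while len(medoids) < k:
        # gain of candidate h = sum_j max(d_nearest_j - d_jh, 0)
        gains = np.maximum(d_nearest[:, None] - d, 0.0).sum(axis=0)
        gains[medoids] = -np.inf
        best = int(np.argmax(gains))  # first occurrence = lowest index on ties
        medoids.append(best)
        d_nearest = np.minimum(d_nearest, d[:, best])
    return medoids


def _pam_swap(d: np.ndarray, medoids: list[int]) -> list[int]:
    """SWAP phase: exchange (medoid, non-medoid) pairs while cost drops."""
    n = d.shape[0]
    medoids = sorted(medoids)
    while True:
        sub = d[:, medoids]  # n x k distances to current medoids
        order = np.argsort(sub, axis=1, kind="stable")
        n1 = order[:, 0]  # index into medoids of the nearest medoid
        d1 = sub[np.arange(n), n1]
        d2 = sub[np.arange(n), order[:, 1]]
        # swap cost deltas, vectorised over the added candidate h:
        # A_jh = contribution of j when its nearest medoid survives
        # C_jh = extra contribution when j's nearest medoid is removed
        A = np.minimum(d, d1[:, None]) - d1[:, None]
        C = np.minimum(d, d2[:, None]) - d1[:, None] - A
        delta = A.sum(axis=0)[None, :] + np.vstack(
            [C[n1 == i].sum(axis=0) for i in range(len(medoids))]
        )
        delta[:, medoids] = np.inf
        i_pos, h = np.unravel_index(np.argmin(delta), delta.shape)
        if delta[i_pos, h] >= -1e-12:
            return medoids
        medoids[int(i_pos)] = int(h)
        medoids = sorted(medoids)


def pam(d, k: int) -> ClusteringResult:
    """Partitioning around medoids on a precomputed distance matrix.

    Deterministic BUILD + SWAP k-medoids: BUILD greedily seeds the k
    medoids, SWAP exchanges (medoid, non-medoid) pairs while any exchange
    strictly lowers the total within-cluster distance to medoids; all ties
    break towards the lowest index.  Samples are assigned to their nearest
    medoid.
    """
    arr, ids = _as_square(d)
    n = arr.shape[0]
    if not 2 <= k < n:
        raise ValueError(f"need 2 <= k < n samples (k={k}, n={n})")
    medoids = _pam_swap(arr, _pam_build(arr, k))
    sub = arr[:, medoids]
    assign = np.argmin(sub, axis=1)  # first occurrence = lowest medoid index
    labels = assign + 1
    total_cost = float(sub[np.arange(n), assign].sum())
    if ids is None:
        ids = list(range(n))
    return ClusteringResult(
        k=k,
        medoid_indices=tuple(medoids),
        medoids=tuple(ids[m] for m in medoids),
        labels=labels,
        total_cost=total_cost,
    )


def ch_index(d, labels) -> float:
    """Distance-based Calinski-Harabasz index of a partition.

    Uses the sum-of-squares decomposition expressed through pairwise
    distances: W = sum_c (1/n_c) sum_{i<j in c} d_ij^2,
    T = (1/n) sum_{i<j} d_ij^2, B = T - W and
    CH = (B / (k - 1)) / (W / (n - k)).  For Euclidean distances this
    equals the classical centroid-based CH index.
    """
    arr, _ = _as_square(d)
    labels = np.asarray(labels)
    n = arr.shape[0]
    if len(labels) != n:
        raise ValueError("one label per sample required")
    clusters = np.unique(labels)
    k = len(clusters)
    if not 2 <= k <= n - 1:
        raise ValueError(f"CH index needs 2 <= k <= n-1 clusters (k={k}, n={n})")
    d2 = arr**2
    t_total = d2[np.triu_indices(n, k=1)].sum() / n
    w_total = 0.0
    for c in clusters:
        idx = np.nonzero(labels == c)[0]
        sub = d2[np.ix_(idx, idx)]
        w_total += sub[np.triu_indices(len(idx), k=1)].sum() / len(idx)
    b_total = t_total - w_total
    if w_total == 0.0:
        return float("inf")
    return float((b_total / (k - 1)) / (w_total / (n - k)))


def select_k(d, k_min: int = 2, k_max: int = 10) -> OptimalK:
    """Scan k, cluster with PAM, and pick the k maximising the CH index.

    ``k_max`` is clamped to n - 1.  Ties break towards the smallest k.
    """
    arr, _ = _as_square(d)
    n = arr.shape[0]
    k_max = min(k_max, n - 1)
    if k_min < 2 or k_min > k_max:
        raise ValueError(f"empty or invalid k range [{k_min}, {k_max}] for n={n}")
    ks, scores, results = [], [], {}
    for k in range(k_min, k_max + 1):
        res = pam(d, k)
        ks.append(k)
        scores.append(ch_index(d, res.labels))
        results[k] = res
    best_k = ks[int(np.argmax(scores))]  # first occurrence = smallest k on ties
    return OptimalK(k_range=tuple(ks), ch_scores=tuple(scores),
                    best_k=best_k, results=results)


def driver_taxa(tbl: pd.DataFrame, labels, top_n: int = 5) -> dict:
    """Per-cluster taxa ranked by mean relative abundance.

    Returns ``{cluster: DataFrame(taxon, mean_abundance)}`` with the
    ``top_n`` taxa of each cluster; ties break by taxon ID order.
    """
    labels = np.asarray(labels)
    if len(labels) != tbl.shape[1]:
        raise ValueError("one label per sample column required")
    out = {}
    for c in np.unique(labels):
        means = tbl.loc[:, labels == c].mean(axis=1)
        ranked = means.to_frame("mean_abundance")
        ranked["taxon"] = ranked.index
        ranked = ranked.sort_values(
            ["mean_abundance", "taxon"], ascending=[False, True]
        ).head(top_n)
        out[int(c) if np.issubdtype(type(c), np.integer) else c] = (
            ranked[["taxon", "mean_abundance"]].reset_index(drop=True)
        )
    return out


def signature_taxa(
    tbl: pd.DataFrame,
    labels,
    p_cut: float = 0.05,
    score_cut: float = 2.0,
) -> pd.DataFrame:
    """Effect-size screen for cluster-discriminating taxa.

    A taxon is a signature of the cluster where its mean relative
    abundance is maximal if (a) a Kruskal-Wallis test of its abundance
    across clusters gives p < ``p_cut`` and (b) its effect-size score
    exceeds ``score_cut`` (strictly), with
    score = log10(max over cluster pairs |mean difference| x 10^6) --
    a mean-difference analogue of the conventional LDA-score scale on
    which 2 corresponds to a 10^-4 abundance difference.

    Returns a frame (taxon, cluster, p_value, score) sorted by descending
    score; taxa identical across clusters are excluded.
    """
    labels = np.asarray(labels)
    clusters = np.unique(labels)
    if len(clusters) < 2:
        raise ValueError("need at least two clusters")
    rows = []
    X = tbl.to_numpy(dtype=float)
    for i, taxon in enumerate(tbl.index):
        values = X[i]
        groups = [values[labels == c] for c in clusters]
        means = np.array([g.mean() for g in groups])
        max_diff = float(means.max() - means.min())
        if max_diff <= 0:
            continue  # identical across clusters: no signature
        score = float(np.log10(max_diff * 1e6))
        if np.ptp(values) == 0:
            continue
        _, p = stats.kruskal(*groups)
        if p < p_cut and score > score_cut:
            best = clusters[int(np.argmax(means))]
            rows.append((taxon, best, float(p), score))
    frame = pd.DataFrame(rows, columns=["taxon", "cluster", "p_value", "score"])
    return frame.sort_values(["score", "taxon"],
                             ascending=[False, True]).reset_index(drop=True)
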