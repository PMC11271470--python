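"""Co-occurrence networks and their robustness.

Per-enterotype networks connect taxa whose Spearman rank correlation
across samples is both strong (|r| > 0.5) and significant (p < 0.05,
both strict).  Network robustness is measured by natural connectivity --
the log-average of e^lambda over adjacency eigenvalues, which strictly
increases with edge addition -- and by "anti-interference" curves that
track natural connectivity while nodes are removed at random or in
descending-degree order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp
from statsmodels.stats.multitest import multipletests


@dataclass
class CooccurrenceNetwork:
    """An undirected taxon co-occurrence graph with its edge statistics.

    ``edges`` holds one row per retained edge (source, target, r, p, sign)
    with source < target; ``excluded`` lists taxa dropped because their
    abundance was constant (rank correlation undefined).
    """

    graph: nx.Graph
    edges: pd.DataFrame
    excluded: tuple = ()
    params: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


@dataclass
class RobustnessCurve:
    """Mean natural connectivity against the fraction of removed nodes."""

    fractions: np.ndarray
    mean_nc: np.ndarray
    sd_nc: np.ndarray
    strategy: str
    n_reps: int

    @property
    def auc(self) -> float:
        """Area under the curve (trapezoid): the scalar stability score."""
        return float(np.trapezoid(self.mean_nc, self.fractions))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"fraction_removed": self.fractions, "mean_nat_conn": self.mean_nc,
             "sd_nat_conn": self.sd_nc}
        )


def spearman_edges(
    tbl: pd.DataFrame,
    r_thresh: float = 0.5,
    p_thresh: float = 0.05,
    min_prevalence: float = 0.0,
    bh_correct: bool = False,
) -> CooccurrenceNetwork:
    """All-pairs Spearman screen returning the thresholded network.

    Every taxon pair is tested with average-rank Spearman correlation and
    the two-sided t-approximation p-value; an edge is kept only when
    |r| > ``r_thresh`` AND p < ``p_thresh`` (both strict).  Constant taxa
    are excluded and reported.  ``min_prevalence`` optionally drops taxa
    present in too few samples before testing (rank-degenerate vectors);
    ``bh_correct`` applies Benjamini-Hochberg to the edge p-values before
    thresholding (off by default: the convention is raw p < 0.05).
    """
    n_samples = tbl.shape[1]
    if n_samples < 5:
        raise ValueError(f"need >= 5 samples for rank correlation, got {n_samples}")
    work = tbl
    if min_prevalence > 0:
        prevalence = (work > 0).mean(axis=1)
        work = work.loc[prevalence > min_prevalence]
    X = work.to_numpy(dtype=float)
    constant = np.ptp(X, axis=1) == 0
    excluded = tuple(work.index[constant])
    work = work.loc[~constant]
    X = work.to_numpy(dtype=float)
    taxa = list(work.index)
    g = nx.Graph()
    g.add_nodes_from(taxa)
    if len(taxa) >= 2:
        rho, pval = stats.spearmanr(X.T)
        if len(taxa) == 2:  # scipy returns scalars for a single pair
            rho = np.array([[1.0, rho], [rho, 1.0]])
            pval = np.array([[0.0, pval], [pval, 0.0]])
        iu = np.triu_indices(len(taxa), k=1)
        r_flat, p_flat = rho[iu], pval[iu]
        if bh_correct and len(p_flat):
            p_flat = multipletests(p_flat, method="fdr_bh")[1]
        keep = (np.abs(r_flat) > r_thresh) & (p_flat < p_thresh)
        rows = []
        for idx in np.nonzero(keep)[0]:
            i, j = iu[0][idx], iu[1][idx]
            a, b = sorted((taxa[i], taxa[j]))
            r = float(r_flat[idx])
            rows.append((a, b, r, float(p_flat[idx]), 1 if r > 0 else -1))
            g.add_edge(a, b, r=r, p=float(p_flat[idx]), sign=1 if r > 0 else -1)
        edges = pd.DataFrame(rows, columns=["source", "target", "r", "p", "sign"])
    else:
        edges = pd.DataFrame(columns=["source", "target", "r", "p", "sign"])
    return CooccurrenceNetwork(
        graph=g,
        edges=edges.sort_values(["source", "target"]).reset_index(drop=True),
        excluded=excluded,
        params={"r_thresh": r_thresh, "p_thresh": p_thresh,
                "min_prevalence": min_prevalence, "bh_correct": bh_correct},
    )


def degree_stats(net: CooccurrenceNetwork) -> tuple[pd.Series, dict]:
    """Per-node degree and a summary (node/edge counts, positive-edge fraction)."""
    degrees = pd.Series(dict(net.graph.degree()), dtype=int).sort_index()
    n_edges = net.n_edges
    pos_frac = float((net.edges["sign"] > 0).mean()) if n_edges else float("nan")
    summary = {
        "n_nodes": net.n_nodes,
        "n_edges": n_edges,
        "positive_edge_fraction": pos_frac,
        "mean_degree": float(degrees.mean()) if len(degrees) else 0.0,
    }
    return degrees, summary


def natural_connectivity(graph) -> float:
    """Natural connectivity ln((1/N) sum_i e^{lambda_i}) of a simple graph.

    ``lambda_i`` are the eigenvalues of the unweighted symmetric adjacency
    matrix.  Zero for an edgeless graph of any size; strictly increases
    when an edge is added.
    """
    if isinstance(graph, CooccurrenceNetwork):
        graph = graph.graph
    n = graph.number_of_nodes()
    if n < 1:
        raise ValueError("natural connectivity needs at least one node")
    if graph.number_of_edges() == 0:
        return 0.0
    adj = nx.to_numpy_array(graph, weight=None)
    eig = np.linalg.eigvalsh(adj)
    return float(logsumexp(eig) - np.log(n))


def robustness_curve(
    net: CooccurrenceNetwork,
    strategy: str = "random",
    n_reps: int = 100,
    seed: int = 0,
    grid=None,
) -> RobustnessCurve:
    """Anti-interference test: natural connectivity under node removal.

    For each removal fraction f of the grid, round(f*N) nodes are deleted
    -- uniformly at random per replicate, or deterministically in
    descending-degree order (ties by node ID) -- and natural connectivity
    of the remaining graph is recomputed and averaged over replicates.
    The trapezoid area under the mean curve is the stability score.
    """
    if grid is None:
        grid = np.arange(0.0, 0.501, 0.05)
    grid = np.asarray(grid, dtype=float)
    if (grid >= 1.0).any() or (grid < 0).any():
        raise ValueError("removal fractions must lie in [0, 1)")
    if n_reps < 1:
        raise ValueError("need n_reps >= 1")
    if strategy not in ("random", "degree"):
        raise ValueError(f"unknown strategy {strategy!r}")
    g = net.graph
    nodes = sorted(g.nodes())
    n = len(nodes)
    if n == 0:
        raise ValueError("empty network")
    rng = np.random.default_rng(seed)
    reps = n_reps if strategy == "random" else 1
    values = np.empty((reps, len(grid)))
    if strategy == "degree":
        order = sorted(nodes, key=lambda v: (-g.degree(v), v))
    for rep in range(reps):
        if strategy == "random":
            order = [nodes[i] for i in rng.permutation(n)]
        for gi, f in enumerate(grid):
            n_remove = int(round(f * n))
            remaining = g.copy()
            remaining.remove_nodes_from(order[:n_remove])
            if remaining.number_of_nodes() == 0:
                values[rep, gi] = 0.0
            else:
                values[rep, gi] = natural_connectivity(remaining)
    return RobustnessCurve(
        fractions=grid,
        mean_nc=values.mean(axis=0),
        sd_nc=values.std(axis=0, ddof=0),
        strategy=strategy,
        n_reps=reps,
    )


def cluster_networks(
    tbl: pd.DataFrame,
    labels,
    min_prevalence: float = 0.2,
    r_thresh: float = 0.5,
    p_thresh: float = 0.05,
) -> dict:
    """Build one co-occurrence network per cluster of samples.

    Taxa are restricted to those present in more than ``min_prevalence``
    of the cluster's samples to avoid rank-degenerate vectors.  Clusters
    with fewer than 5 samples are skipped.
    """
    labels = np.asarray(labels)
    out = {}
    for c in np.unique(labels):
        sub = tbl.loc[:, labels == c]
        if sub.shape[1] < 5:
            continue
        out[int(c) if np.issubdtype(type(c), np.integer) else c] = spearman_edges(
            sub, r_thresh=r_thresh, p_thresh=p_thresh, min_prevalence=min_prevalence
        )
    return out
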