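"""Enterotype temporal dynamics: transition counting and Markov-chain estimation.

Adjacent observed time points of each subject's enterotype sequence are
pooled (regardless of the calendar gap between sampling ages, i.e.
subject-independent transition probabilities) into a K x K count matrix;
row-normalising the counts gives the maximum-likelihood transition matrix
of a first-order Markov chain.  The stationary distribution, bootstrap
confidence intervals over subjects and window-persistence summaries
describe the long-run and short-run behaviour of the chain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from enterodyn.synth import MISSING, TrajectorySet


@dataclass
class TransitionCounts:
    """K x K matrix of observed adjacent-time state moves, pooled over subjects."""

    K: int
    N: np.ndarray

    def __post_init__(self):
        self.N = np.asarray(self.N)
        if self.N.shape != (self.K, self.K) or (self.N < 0).any():
            raise ValueError("N must be a K x K non-negative matrix")

    @property
    def total(self) -> int:
        return int(self.N.sum())


@dataclass
class TransitionModel:
    """MLE transition matrix with optional stationary vector and CIs.

    Rows of ``P`` with no observed transitions are NaN (undefined), and
    ``defined_rows`` marks the estimable ones.  ``stationary`` is the
    probability vector pi with pi P = pi when the chain restricted to
    visited states is irreducible and aperiodic, else ``None``.
    """

    P: np.ndarray
    counts: TransitionCounts
    defined_rows: np.ndarray
    stationary: np.ndarray | None = None
    ci: np.ndarray | None = None  # (K, K, 2) percentile bounds

    def to_edge_frame(self) -> pd.DataFrame:
        """Long-format edge list (from, to, count, probability[, ci]) for Sankey plots."""
        rows = []
        K = self.counts.K
        for i in range(K):
            for j in range(K):
                row = {
                    "from": i + 1,
                    "to": j + 1,
                    "count": int(self.counts.N[i, j]),
                    "probability": self.P[i, j],
                }
                if self.ci is not None:
                    row["ci_low"] = self.ci[i, j, 0]
                    row["ci_high"] = self.ci[i, j, 1]
                rows.append(row)
        return pd.DataFrame(rows)


def count_transitions(traj: TrajectorySet, K: int | None = None) -> TransitionCounts:
    """Pool all adjacent observed state pairs into a K x K count matrix.

    Missing time points are skipped: only consecutively *observed* pairs
    count, and a subject observed once contributes nothing.  All intervals
    of the schedule are pooled.
    """
    states = np.asarray(traj.states)
    observed = states[states != MISSING]
    if observed.size == 0:
        raise ValueError("no observed states")
    k_seen = int(observed.max())
    if K is None:
        K = k_seen
    elif k_seen > K:
        raise ValueError(f"state label {k_seen} exceeds K={K}")
    N = np.zeros((K, K), dtype=np.int64)
    for row in states:
        seq = row[row != MISSING]
        for a, b in zip(seq[:-1], seq[1:]):
            N[a - 1, b - 1] += 1
    return TransitionCounts(K=K, N=N)


def count_transitions_by_interval(traj: TrajectorySet, K: int | None = None) -> dict:
    """Per-interval transition counts, keyed by (age_from, age_to).

    Stratified alternative to the pooled default: only pairs observed at
    consecutive *schedule* positions contribute, split by interval.
    """
    states = np.asarray(traj.states)
    observed = states[states != MISSING]
    if observed.size == 0:
        raise ValueError("no observed states")
    if K is None:
        K = int(observed.max())
    out = {}
    for t in range(len(traj.schedule) - 1):
        N = np.zeros((K, K), dtype=np.int64)
        a, b = states[:, t], states[:, t + 1]
        ok = (a != MISSING) & (b != MISSING)
        for i, j in zip(a[ok], b[ok]):
            N[i - 1, j - 1] += 1
        out[(traj.schedule[t], traj.schedule[t + 1])] = TransitionCounts(K=K, N=N)
    return out


def _stationary_from_P(P: np.ndarray, tol: float = 1e-10) -> np.ndarray | None:
    """Stationary vector of the chain restricted to visited states.

    Returns None unless that restricted chain is irreducible and
    aperiodic.  Uses the leading left eigenvector, with power iteration as
    a fallback when the eigen solution is numerically unusable.
    """
    import networkx as nx

    K = P.shape[0]
    defined = ~np.isnan(P).any(axis=1)
    visited = np.nonzero(defined)[0]
    if len(visited) == 0:
        return None
    sub = P[np.ix_(visited, visited)]
    # rows must keep full mass inside the visited set, else mass escapes
    if not np.allclose(sub.sum(axis=1), 1.0, atol=1e-9):
        return None
    G = nx.DiGraph()
    G.add_nodes_from(range(len(visited)))
    for i in range(len(visited)):
        for j in range(len(visited)):
            if sub[i, j] > 0:
                G.add_edge(i, j)
    if not nx.is_strongly_connected(G) or not nx.is_aperiodic(G):
        return None
    w, v = np.linalg.eig(sub.T)
    lead = int(np.argmin(np.abs(w - 1.0)))
    pi = np.real(v[:, lead])
    pi = pi / pi.sum()
    if (pi < -1e-8).any() or np.abs(pi @ sub - pi).max() > 1e-8:
        pi = np.full(len(visited), 1.0 / len(visited))  # power-iteration fallback
        for _ in range(100000):
            nxt = pi @ sub
            if np.abs(nxt - pi).max() < tol:
                pi = nxt
                break
            pi = nxt
        pi = pi / pi.sum()
        if np.abs(pi @ sub - pi).max() > 1e-8:
            return None
    full = np.zeros(K)
    full[visited] = np.clip(pi, 0.0, None)
    full /= full.sum()
    return full


def estimate_markov(counts: TransitionCounts, smoothing: float = 0.0) -> TransitionModel:
    """Maximum-likelihood (optionally additively smoothed) transition matrix.

    P_ij = (N_ij + smoothing) / (sum_j N_ij + K * smoothing).  With
    ``smoothing = 0`` rows without observations are undefined (NaN) rather
    than uniform.  The stationary distribution is reported only when the
    chain on visited states is irreducible and aperiodic.
    """
    N = counts.N.astype(float)
    if N.sum() == 0 and smoothing == 0:
        raise ValueError("no transitions observed and no smoothing requested")
    K = counts.K
    row_tot = N.sum(axis=1) + K * smoothing
    P = np.full((K, K), np.nan)
    defined = row_tot > 0
    P[defined] = (N[defined] + smoothing) / row_tot[defined, None]
    return TransitionModel(
        P=P,
        counts=counts,
        defined_rows=defined,
        stationary=_stationary_from_P(P),
    )


def bootstrap_ci(
    traj: TrajectorySet,
    n_boot: int = 1000,
    seed: int = 0,
    level: float = 0.95,
    smoothing: float = 0.0,
) -> np.ndarray:
    """Subject-resampling percentile intervals for each transition probability.

    Subjects are resampled with replacement ``n_boot`` times; each
    replicate re-counts transitions and re-estimates P.  Returns a
    (K, K, 2) array of (lower, upper) bounds; entries never estimable in a
    replicate are ignored (NaN-aware percentiles).
    """
    if n_boot < 100:
        raise ValueError("use at least 100 bootstrap replicates")
    rng = np.random.default_rng(seed)
    states = np.asarray(traj.states)
    counts = count_transitions(traj)
    K = counts.K
    n = states.shape[0]
    reps = np.full((n_boot, K, K), np.nan)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        N = np.zeros((K, K), dtype=np.int64)
        for row in states[idx]:
            seq = row[row != MISSING]
            for a, c in zip(seq[:-1], seq[1:]):
                N[a - 1, c - 1] += 1
        row_tot = N.sum(axis=1) + K * smoothing
        ok = row_tot > 0
        reps[b, ok] = (N[ok] + smoothing) / row_tot[ok, None]
    alpha = (1.0 - level) / 2.0
    with np.errstate(all="ignore"):
        lo = np.nanpercentile(reps, 100 * alpha, axis=0)
        hi = np.nanpercentile(reps, 100 * (1 - alpha), axis=0)
    return np.stack([lo, hi], axis=-1)


def persistence_summary(traj: TrajectorySet, from_state: int, window: tuple) -> dict:
    """Where subjects in ``from_state`` at age t_a end up at age t_b.

    Returns ``{destination state: fraction}`` over the subjects observed
    in ``from_state`` at ``window[0]`` and observed (in any state) at
    ``window[1]``; fractions sum to 1.
    """
    t_a, t_b = window
    schedule = list(traj.schedule)
    for t in (t_a, t_b):
        if t not in schedule:
            raise ValueError(f"age {t} not in schedule {schedule}")
    ia, ib = schedule.index(t_a), schedule.index(t_b)
    states = np.asarray(traj.states)
    sel = (states[:, ia] == from_state) & (states[:, ib] != MISSING)
    if not sel.any():
        raise ValueError(f"no subject observed in state {from_state} at age {t_a}")
    dest = states[sel, ib]
    values, freq = np.unique(dest, return_counts=True)
    return {int(v): float(c) / int(sel.sum()) for v, c in zip(values, freq)}
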