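"""Alpha/beta diversity and the group-comparison statistics of the workflow.

Alpha diversity uses the bias-corrected Chao1 richness estimator and the
Shannon index; beta diversity uses Bray-Curtis dissimilarity.  Group
structure in distance space is tested with rank-based ANOSIM and
distance-based PERMANOVA (both permutation tests); univariate group
comparisons use Kruskal-Wallis with Dunn's Bonferroni-adjusted post-hoc
and classical one-way ANOVA.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix


@dataclass
class TestResult:
    """Outcome of a statistical test.

    ``pairwise`` maps a (group_a, group_b) tuple to
    ``(statistic, adjusted_p)`` for post-hoc comparisons; ``extra`` holds
    test-specific quantities (e.g. ``r_squared`` for PERMANOVA).
    """

    statistic: float
    p_value: float
    n_permutations: int | None = None
    pairwise: dict | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def _as_square(d) -> tuple[np.ndarray, list | None]:
    """Coerce a distance input to (square ndarray, labels-or-None)."""
    if isinstance(d, DistanceMatrix):
        return d.data.astype(float, copy=False), list(d.ids)
    if isinstance(d, pd.DataFrame):
        return d.to_numpy(dtype=float), list(d.index)
    arr = np.asarray(d, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValueError("distance matrix must be square")
    return arr, None


def chao1(counts) -> float:
    """Bias-corrected Chao1 richness: S_obs + F1(F1-1) / (2(F2+1)).

    F1 and F2 are the numbers of taxa observed exactly once and twice.
    Defined (and equal to S_obs) when there are no singletons; always
    >= S_obs.
    """
    c = np.asarray(counts)
    if (c < 0).any():
        raise ValueError("counts must be non-negative")
    if not (c > 0).any():
        raise ValueError("Chao1 undefined for an all-zero sample")
    s_obs = int((c > 0).sum())
    f1 = int((c == 1).sum())
    f2 = int((c == 2).sum())
    return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))


def shannon(p, base: float | None = None) -> float:
    """Shannon entropy H = -sum p_i log p_i of a composition.

    Natural log by default; pass ``base`` (e.g. 2) to change units.
    Zero entries contribute nothing.
    """
    v = np.asarray(p, dtype=float)
    if (v < 0).any():
        raise ValueError("composition entries must be non-negative")
    total = v.sum()
    if total <= 0:
        raise ValueError("composition sums to zero")
    if not np.isclose(total, 1.0, atol=1e-6):
        raise ValueError(f"composition sums to {total}, expected 1")
    nz = v[v > 0]
    h = float(-(nz * np.log(nz)).sum())
    if base is not None:
        h /= np.log(base)
    return h


def bray_curtis(tbl: pd.DataFrame) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity between sample columns.

    For compositions (columns summing to 1) this equals
    1 - sum_i min(a_i, b_i).
    """
    X = tbl.to_numpy(dtype=float).T  # samples x taxa
    condensed = pdist(X, metric="braycurtis")
    return DistanceMatrix(squareform(condensed), ids=list(tbl.columns))


def one_way_anova(values, groups) -> TestResult:
    """Classical one-way ANOVA F test across >= 2 groups of >= 2 values."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = pd.unique(groups)
    if len(levels) < 2:
        raise ValueError("need at least two groups")
    arrays = [values[groups == g] for g in levels]
    if any(len(a) < 2 for a in arrays):
        small = [str(g) for g, a in zip(levels, arrays) if len(a) < 2]
        raise ValueError(f"groups with fewer than 2 observations: {small}")
    f_stat, p = stats.f_oneway(*arrays)
    return TestResult(statistic=float(f_stat), p_value=float(p))


def kruskal_dunn(values, groups, alpha: float = 0.05) -> TestResult:
    """Kruskal-Wallis H test with Dunn's Bonferroni-adjusted post-hoc.

    The omnibus H statistic (tie-corrected) comes from the rank-sum
    formula; the pairwise Dunn z statistics compare mean ranks with the
    tie-corrected pooled variance, and two-sided normal p-values are
    Bonferroni-multiplied by the number of pairs (capped at 1).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = list(pd.unique(groups))
    if len(levels) < 2:
        raise ValueError("need at least two groups")
    sizes = {g: int((groups == g).sum()) for g in levels}
    empty = [str(g) for g, n in sizes.items() if n < 1]
    if empty:
        raise ValueError(f"empty groups: {empty}")

    if np.ptp(values) == 0:  # all observations identical: no evidence
        h_stat, p_omnibus = 0.0, 1.0
    else:
        h_stat, p_omnibus = stats.kruskal(*[values[groups == g] for g in levels])

    # Dunn post-hoc on pooled average ranks
    n_total = len(values)
    ranks = stats.rankdata(values)
    mean_rank = {g: float(ranks[groups == g].mean()) for g in levels}
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (12.0 * (n_total - 1)))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term

    pairs = [(a, b) for i, a in enumerate(levels) for b in levels[i + 1:]]
    pairwise = {}
    for a, b in pairs:
        se = np.sqrt(base_var * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_rank[a] - mean_rank[b]) / se if se > 0 else 0.0
        p_raw = 2.0 * stats.norm.sf(abs(z))
        pairwise[(a, b)] = (float(z), float(min(1.0, p_raw * len(pairs))))
    return TestResult(
        statistic=float(h_stat),
        p_value=float(p_omnibus),
        pairwise=pairwise,
        extra={"alpha": alpha},
    )


def _condensed_pairs(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Row/column index arrays of the condensed upper-triangle ordering."""
    iu = np.triu_indices(n, k=1)
    return iu[0], iu[1]


def _validate_grouping(labels: np.ndarray, min_size: int = 2) -> None:
    levels, counts = np.unique(labels, return_counts=True)
    if len(levels) < 2:
        raise ValueError("grouping factor must have at least two levels")
    if (counts < min_size).any():
        bad = [str(g) for g, c in zip(levels, counts) if c < min_size]
        raise ValueError(f"groups with fewer than {min_size} samples: {bad}")


def anosim_r(d, groups) -> float:
    """The ANOSIM R statistic for a fixed labelling (no permutation test).

    R = (mean rank of between-group distances - mean rank of within-group
    distances) / (M/2) with M = n(n-1)/2; bounded in [-1, 1].
    """
    arr, _ = _as_square(d)
    labels = np.asarray(groups)
    n = arr.shape[0]
    if len(labels) != n:
        raise ValueError("one group label per sample required")
    ranks = stats.rankdata(squareform(arr, checks=False))
    ii, jj = _condensed_pairs(n)
    within = labels[ii] == labels[jj]
    m = n * (n - 1) / 2.0
    return float((ranks[~within].mean() - ranks[within].mean()) / (m / 2.0))


def anosim(d, groups, n_perm: int = 999, seed: int | None = 0) -> TestResult:
    """ANOSIM permutation test of group separation in distance space.

    The p-value uses the add-one convention
    p = (1 + #{R_perm >= R_obs}) / (1 + n_perm), so p >= 1/(1 + n_perm).
    """
    if n_perm < 99:
        raise ValueError("use at least 99 permutations")
    arr, _ = _as_square(d)
    labels = np.asarray(groups)
    _validate_grouping(labels)
    n = arr.shape[0]
    ranks = stats.rankdata(squareform(arr, checks=False))
    ii, jj = _condensed_pairs(n)
    m = n * (n - 1) / 2.0

    def r_of(lab):
        within = lab[ii] == lab[jj]
        return (ranks[~within].mean() - ranks[within].mean()) / (m / 2.0)

    r_obs = r_of(labels)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        exceed += r_of(rng.permutation(labels)) >= r_obs
    p = (1.0 + exceed) / (1.0 + n_perm)
    return TestResult(statistic=float(r_obs), p_value=float(p), n_permutations=n_perm)


def _permanova_stats(d2_sq: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """(pseudo-F, R^2) from a squared-distance matrix and labels."""
    n = d2_sq.shape[0]
    ss_t = d2_sq[np.triu_indices(n, k=1)].sum() / n
    ss_w = 0.0
    for g in np.unique(labels):
        idx = np.nonzero(labels == g)[0]
        sub = d2_sq[np.ix_(idx, idx)]
        ss_w += sub[np.triu_indices(len(idx), k=1)].sum() / len(idx)
    n_groups = len(np.unique(labels))
    ss_b = ss_t - ss_w
    f = (ss_b / (n_groups - 1)) / (ss_w / (n - n_groups))
    r2 = 1.0 - ss_w / ss_t
    return float(f), float(r2)


def permanova(d, factor, n_perm: int = 999, seed: int | None = 0) -> TestResult:
    """Single-factor PERMANOVA with permutation p and R^2.

    Tests one factor at a time (marginal): the distance-based
    sum-of-squares decomposition gives pseudo-F and the fraction of
    distance variance explained, R^2 = 1 - SS_W / SS_T.
    """
    if n_perm < 99:
        raise ValueError("use at least 99 permutations")
    arr, _ = _as_square(d)
    labels = np.asarray(factor)
    if len(np.unique(labels)) < 2:
        raise ValueError("factor must have at least two levels")
    _validate_grouping(labels, min_size=1)
    d2 = arr**2
    f_obs, r2 = _permanova_stats(d2, labels)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        f_perm, _ = _permanova_stats(d2, rng.permutation(labels))
        exceed += f_perm >= f_obs
    p = (1.0 + exceed) / (1.0 + n_perm)
    return TestResult(
        statistic=f_obs, p_value=float(p), n_permutations=n_perm,
        extra={"r_squared": r2},
    )


def alpha_diversity_table(counts: pd.DataFrame) -> pd.DataFrame:
    """Chao1 and Shannon per sample column of a count table."""
    rel = counts.to_numpy(dtype=float)
    rel = rel / rel.sum(axis=0)
    rows = []
    for j, sample in enumerate(counts.columns):
        rows.append(
            (sample, chao1(counts.iloc[:, j].to_numpy()), shannon(rel[:, j]))
        )
    return pd.DataFrame(rows, columns=["sample", "chao1", "shannon"]).set_index("sample")


def results_to_frame(results: dict) -> pd.DataFrame:
    """Tidy TSV-ready frame (one row per test or post-hoc pair)."""
    rows = []
    for name, res in results.items():
        rows.append(
            {
                "test": name, "comparison": "omnibus",
                "statistic": res.statistic, "p_value": res.p_value,
                **{k: v for k, v in res.extra.items() if np.isscalar(v)},
            }
        )
        if res.pairwise:
            for (a, b), (stat, p_adj) in res.pairwise.items():
                rows.append(
                    {"test": name, "comparison": f"{a} vs {b}",
                     "statistic": stat, "p_value": p_adj}
                )
    return pd.DataFrame(rows)
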