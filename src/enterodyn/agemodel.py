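"""Microbiota-based age regression with out-of-bag evaluation.

Chronological age (days) is regressed on genus relative abundances with a
bagged ensemble of regression trees.  The bagging loop, out-of-bag (OOB)
bookkeeping and the permutation importance (%IncMSE: percent increase in
OOB mean squared error when one taxon's values are permuted) are
implemented here; the individual trees are scikit-learn regression trees.
OOB prediction for a sample averages the trees whose bootstrap did not
contain it, giving an unbiased error estimate without a held-out set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeRegressor


@dataclass
class AgeModel:
    """A fitted bagged-tree age regressor with its OOB state.

    ``oob_predictions`` holds, for every sample that was out-of-bag for at
    least one tree, the average prediction of those trees (NaN otherwise).
    """

    trees: list
    bootstrap_indices: list
    feature_names: tuple
    sample_ids: tuple
    X: np.ndarray
    y: np.ndarray
    oob_predictions: np.ndarray
    params: dict = field(default_factory=dict)

    @property
    def ntree(self) -> int:
        return len(self.trees)


def fit_age_model(
    tbl: pd.DataFrame,
    ages,
    ntree: int = 1000,
    mtry: int | None = None,
    seed: int = 0,
) -> AgeModel:
    """Fit the bagged regression-tree age model.

    Parameters
    ----------
    tbl : DataFrame (taxa x samples)
        Relative abundances.
    ages : sequence of float
        Chronological age (days) per sample column.
    ntree : int
        Number of bootstrap trees (1,000 by default; raise to 10,000 for
        maximum stability at proportional cost).
    mtry : int, optional
        Features tried per split; defaults to floor(G / 3), the standard
        regression-forest choice.
    seed : int
        Seeds the bootstraps and the trees; identical seeds give
        identical models and OOB predictions.
    """
    X = tbl.to_numpy(dtype=float).T  # samples x taxa
    y = np.asarray(ages, dtype=float)
    n, G = X.shape
    if n < 20:
        raise ValueError(f"need >= 20 samples for stable OOB estimates, got {n}")
    if len(y) != n:
        raise ValueError("one age per sample column required")
    if (y < 0).any():
        raise ValueError("ages must be non-negative")
    if ntree < 1:
        raise ValueError("ntree must be >= 1")
    if mtry is None:
        mtry = max(1, G // 3)
    rng = np.random.default_rng(seed)
    trees, boots = [], []
    oob_sum = np.zeros(n)
    oob_count = np.zeros(n, dtype=int)
    for t in range(ntree):
        idx = rng.integers(0, n, size=n)
        tree = DecisionTreeRegressor(
            max_features=mtry, random_state=int(rng.integers(0, 2**31 - 1))
        )
        tree.fit(X[idx], y[idx])
        oob_mask = np.ones(n, dtype=bool)
        oob_mask[idx] = False
        if oob_mask.any():
            oob_sum[oob_mask] += tree.predict(X[oob_mask])
            oob_count[oob_mask] += 1
        trees.append(tree)
        boots.append(idx)
    oob_pred = np.full(n, np.nan)
    seen = oob_count > 0
    oob_pred[seen] = oob_sum[seen] / oob_count[seen]
    return AgeModel(
        trees=trees,
        bootstrap_indices=boots,
        feature_names=tuple(tbl.index),
        sample_ids=tuple(tbl.columns),
        X=X,
        y=y,
        oob_predictions=oob_pred,
        params={"ntree": ntree, "mtry": mtry, "seed": seed},
    )


def evaluate(model: AgeModel, ages=None) -> tuple[float, float]:
    """Out-of-bag (MAE, R^2) of the fitted model.

    MAE = mean |prediction - age| in days; R^2 = 1 - SSE / SST, both over
    the samples with at least one OOB prediction.
    """
    y = model.y if ages is None else np.asarray(ages, dtype=float)
    pred = model.oob_predictions
    ok = ~np.isnan(pred)
    if not ok.any():
        raise ValueError("no OOB predictions available")
    resid = pred[ok] - y[ok]
    mae = float(np.abs(resid).mean())
    sst = float(((y[ok] - y[ok].mean()) ** 2).sum())
    r2 = float(1.0 - (resid**2).sum() / sst) if sst > 0 else float("nan")
    return mae, r2


def importance(
    model: AgeModel,
    n_perm_reps: int = 5,
    seed: int = 0,
    top_n: int | None = None,
) -> pd.DataFrame:
    """Permutation importance (%IncMSE) per taxon.

    For each taxon g and each repetition, g's values are permuted within
    every tree's out-of-bag samples, OOB predictions are re-aggregated and
    %IncMSE_g = 100 * (MSE_OOB(permuted g) - MSE_OOB) / MSE_OOB
    is averaged over repetitions.  Uninformative taxa score near 0;
    negative values are noise.  Ranking ties break by taxon ID.

    Returns a frame (taxon, inc_mse_pct, rank) sorted by rank; ``top_n``
    truncates it.
    """
    n, G = model.X.shape
    ok = ~np.isnan(model.oob_predictions)
    base_mse = float(((model.oob_predictions[ok] - model.y[ok]) ** 2).mean())
    if base_mse == 0:
        raise ValueError("baseline OOB MSE is zero; %IncMSE undefined")
    rng = np.random.default_rng(seed)
    oob_masks = []
    for idx in model.bootstrap_indices:
        m = np.ones(n, dtype=bool)
        m[idx] = False
        oob_masks.append(np.nonzero(m)[0])
    scores = np.zeros(G)
    for g in range(G):
        deltas = []
        for _ in range(n_perm_reps):
            psum = np.zeros(n)
            pcount = np.zeros(n, dtype=int)
            for tree, oob in zip(model.trees, oob_masks):
                if oob.size == 0:
                    continue
                Xp = model.X[oob].copy()
                Xp[:, g] = Xp[rng.permutation(oob.size), g]
                psum[oob] += tree.predict(Xp)
                pcount[oob] += 1
            seen = pcount > 0
            pred = psum[seen] / pcount[seen]
            mse = float(((pred - model.y[seen]) ** 2).mean())
            deltas.append(100.0 * (mse - base_mse) / base_mse)
        scores[g] = float(np.mean(deltas))
    frame = pd.DataFrame(
        {"taxon": list(model.feature_names), "inc_mse_pct": scores}
    ).sort_values(["inc_mse_pct", "taxon"], ascending=[False, True])
    frame["rank"] = np.arange(1, G + 1)
    frame = frame.reset_index(drop=True)
    if top_n is not None:
        frame = frame.head(top_n)
    return frame


def predictions_frame(model: AgeModel) -> pd.DataFrame:
    """Tidy (sample, age, oob_prediction) frame for serialisation."""
    return pd.DataFrame(
        {
            "sample": list(model.sample_ids),
            "age": model.y,
            "oob_prediction": model.oob_predictions,
        }
    )
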