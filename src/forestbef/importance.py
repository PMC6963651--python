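"""Permutation importance (%IncMSE) from a bagged regression-tree ensemble.

A regression forest is grown as a bagging loop over CART trees
(``sklearn.tree.DecisionTreeRegressor`` with variance-reduction splits,
``mtry`` predictors considered per split, unpruned beyond a minimum leaf
size). The bootstrap bookkeeping is done here so each tree's out-of-bag
(OOB) rows are known exactly — that is what the importance measure needs:

* **%IncMSE** — for predictor j, permute column j within each tree's OOB
  rows, take the increase in that tree's OOB MSE, average the increase
  over trees, and express it as a percentage of the forest-level OOB MSE.
* **permutation significance** — the null distribution of each predictor's
  importance comes from re-growing the forest on permuted responses;
  p = (1 + #{null >= observed}) / (n_perm + 1), which can never be zero.
* **variance explained** — the OOB pseudo-R^2, 1 - OOB MSE / var(y).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeRegressor

from .errors import DegenerateDataError


@dataclass
class ForestSettings:
    """Regression-forest settings; defaults follow common practice for
    regression forests (mtry = ceil(p/3), leaves of 5)."""

    n_trees: int = 5000
    mtry: int | None = None  # None -> ceil(p / 3)
    min_leaf: int = 5
    n_perm: int = 500

    def resolved_mtry(self, p: int) -> int:
        m = self.mtry if self.mtry is not None else math.ceil(p / 3)
        if not 1 <= m <= p:
            raise ValueError(f"mtry must be in [1, {p}], got {m}")
        return m


@dataclass
class RegressionForest:
    trees: list[DecisionTreeRegressor]
    bootstrap_idx: list[np.ndarray]
    oob_idx: list[np.ndarray]
    oob_pred: np.ndarray        # OOB-aggregated prediction per row (NaN if never OOB)
    oob_mse: float
    pseudo_r2: float
    feature_names: list[str]


@dataclass
class ImportanceResult:
    """Per-predictor %IncMSE with optional permutation p-values."""

    pct_inc_mse: pd.Series
    p_values: pd.Series | None = None
    variance_explained: float = np.nan

    def table(self, alpha: float = 0.05) -> pd.DataFrame:
        df = pd.DataFrame({"pct_inc_mse": self.pct_inc_mse})
        if self.p_values is not None:
            df["p_value"] = self.p_values
            df["significant"] = self.p_values < alpha
        return df.sort_values("pct_inc_mse", ascending=False)


def _as_matrix(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    X = np.asarray(X, dtype=float)
    return X, [f"x{j + 1}" for j in range(X.shape[1])]


def grow_forest(
    X, y, settings: ForestSettings, rng: np.random.Generator
) -> RegressionForest:
    """Grow a bagged CART regression forest with OOB records.

    Each tree sees a bootstrap sample of the rows and considers a random
    ``mtry``-subset of predictors at every split. Trees are grown
    row-order-independently: the bootstrap draw and tree seeds consume
    the generator stream in a fixed order, so identical seeds give
    bit-identical forests.
    """
    Xm, names = _as_matrix(X)
    y = np.asarray(y, dtype=float)
    n, p = Xm.shape
    if n < 10:
        raise DegenerateDataError("forest needs at least 10 rows")
    if np.isnan(Xm).any() or np.isnan(y).any():
        raise DegenerateDataError("missing values in forest inputs")
    if np.var(y) == 0:
        raise DegenerateDataError("constant response")
    mtry = settings.resolved_mtry(p)

    trees, boots, oobs = [], [], []
    oob_sum = np.zeros(n)
    oob_count = np.zeros(n, dtype=int)
    for _ in range(settings.n_trees):
        boot = rng.integers(0, n, size=n)
        oob = np.setdiff1d(np.arange(n), boot)
        tree = DecisionTreeRegressor(
            max_features=mtry,
            min_samples_leaf=settings.min_leaf,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        tree.fit(Xm[boot], y[boot])
        if len(oob):
            pred = tree.predict(Xm[oob])
            oob_sum[oob] += pred
            oob_count[oob] += 1
        trees.append(tree)
        boots.append(boot)
        oobs.append(oob)

    covered = oob_count > 0
    oob_pred = np.full(n, np.nan)
    oob_pred[covered] = oob_sum[covered] / oob_count[covered]
    oob_mse = float(np.mean((y[covered] - oob_pred[covered]) ** 2))
    pseudo_r2 = 1.0 - oob_mse / float(np.var(y[covered]))
    return RegressionForest(
        trees=trees,
        bootstrap_idx=boots,
        oob_idx=oobs,
        oob_pred=oob_pred,
        oob_mse=oob_mse,
        pseudo_r2=pseudo_r2,
        feature_names=names,
    )


def importance(
    forest: RegressionForest, X, y, rng: np.random.Generator
) -> ImportanceResult:
    """%IncMSE per predictor from per-tree OOB permutation."""
    Xm, _ = _as_matrix(X)
    y = np.asarray(y, dtype=float)
    n, p = Xm.shape
    increases = np.zeros(p)
    used = 0
    for tree, oob in zip(forest.trees, forest.oob_idx):
        if len(oob) < 2:
            continue
        used += 1
        base_mse = float(np.mean((y[oob] - tree.predict(Xm[oob])) ** 2))
        for j in range(p):
            Xperm = Xm[oob].copy()
            Xperm[:, j] = Xperm[rng.permutation(len(oob)), j]
            perm_mse = float(np.mean((y[oob] - tree.predict(Xperm)) ** 2))
            increases[j] += perm_mse - base_mse
    if used == 0:
        raise DegenerateDataError("no tree has a usable OOB set")
    increases /= used
    pct = 100.0 * increases / forest.oob_mse
    return ImportanceResult(
        pct_inc_mse=pd.Series(pct, index=forest.feature_names),
        variance_explained=forest.pseudo_r2,
    )


def permutation_significance(
    X,
    y,
    settings: ForestSettings,
    rng: np.random.Generator,
) -> ImportanceResult:
    """Observed %IncMSE plus permutation p-values against a no-signal null.

    The null permutes the response and re-grows the whole forest; each
    predictor's p-value is the add-one tail probability of its observed
    importance under that null.
    """
    if settings.n_perm < 99:
        raise ValueError("permutation significance needs n_perm >= 99")
    y = np.asarray(y, dtype=float)
    forest = grow_forest(X, y, settings, rng)
    observed = importance(forest, X, y, rng)
    p = len(observed.pct_inc_mse)
    exceed = np.zeros(p, dtype=int)
    for _ in range(settings.n_perm):
        y_null = y[rng.permutation(len(y))]
        null_forest = grow_forest(X, y_null, settings, rng)
        null_imp = importance(null_forest, X, y_null, rng)
        exceed += (
            null_imp.pct_inc_mse.to_numpy() >= observed.pct_inc_mse.to_numpy()
        ).astype(int)
    p_values = (1 + exceed) / (settings.n_perm + 1)
    return ImportanceResult(
        pct_inc_mse=observed.pct_inc_mse,
        p_values=pd.Series(p_values, index=observed.pct_inc_mse.index),
        variance_explained=observed.variance_explained,
    )
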