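"""Predicting circadian stimulus (CS) from wearable-sensor features.

CS cannot be measured by the wearable directly — it requires a full
spectral power distribution.  This module builds a training table
pairing sensor outputs (four channel irradiances, raw illuminance, raw
CCT) with ground-truth CS computed from the scene spectrum, then fits
and evaluates two regressors:

* ordinary linear regression, and
* a random forest (500 trees, min leaf 2, bootstrap), whose per-tree
  mean is the prediction.

Both are evaluated on a 70/30 split and by seeded k-fold
cross-validation (default k=5), with the cross-validated metric taken
as the arithmetic mean over folds.  For the forest, feature importance
is reported two ways: %IncMSE (percent increase in held-out MSE when a
feature is permuted, averaged over seeded repeats) and IncNodePurity
(total variance-impurity decrease attributed to the feature across all
trees, the quantity R's randomForest prints).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import LinearRegression
from sklearn.model_selection import KFold, train_test_split

from .calibration import MetricSet, compute_metrics, screen_data
from .observers import ObserverTables, load_observer_tables
from .spectral import CircadianParams, spd_to_metrics

__all__ = [
    "PREDICTOR_FEATURES",
    "ForestParams",
    "PredictionModel",
    "build_training_table",
    "fit_cs_model",
    "cross_validate",
    "feature_importance",
]

PREDICTOR_FEATURES = ("r", "g", "b", "ir", "lux_raw", "cct_raw")


@dataclass(frozen=True)
class ForestParams:
    """Random-forest hyperparameters (defaults follow the common
    randomForest-style configuration: many trees, shallow leaves)."""

    n_trees: int = 500
    max_depth: int | None = None
    min_leaf: int = 2


@dataclass(frozen=True)
class PredictionModel:
    method: str                    # "linear" | "random_forest"
    features: tuple
    estimator: object = field(compare=False)
    fit_metrics: MetricSet | None = None        # on the held-out test split
    train_metrics: MetricSet | None = None
    overall_metrics: MetricSet | None = None    # fit evaluated on all rows
    cv_metrics: dict | None = None              # {"folds": [...], "mean": MetricSet}
    importance: pd.DataFrame | None = field(default=None, compare=False)
    forest_params: ForestParams | None = None
    seed: int = 0

    def predict(self, table) -> np.ndarray:
        X = (
            table[list(self.features)].to_numpy(dtype=float)
            if isinstance(table, pd.DataFrame)
            else np.asarray(table, dtype=float)
        )
        return self.estimator.predict(X)


def build_training_table(
    scene_pairs,
    tables: ObserverTables | None = None,
    params: CircadianParams = CircadianParams(),
) -> pd.DataFrame:
    """Feature/target table from (SPD, SensorReading) pairs.

    Features are the sensor outputs; the target ``cs`` is recomputed
    from each scene spectrum via the spectral pipeline.  Rows are
    screened for negative light values.
    """
    rows = []
    tables = tables or load_observer_tables()
    for spd, reading in scene_pairs:
        m = spd_to_metrics(spd, tables, params)
        rows.append(
            {
                "r": reading.r,
                "g": reading.g,
                "b": reading.b,
                "ir": reading.ir,
                "lux_raw": reading.lux_raw,
                "cct_raw": reading.cct_raw,
                "cs": m.cs,
            }
        )
    table = pd.DataFrame(rows)
    cleaned, _ = screen_data(table)
    return cleaned


def _make_estimator(method: str, seed: int, forest: ForestParams):
    if method == "linear":
        return LinearRegression()
    if method == "random_forest":
        return RandomForestRegressor(
            n_estimators=forest.n_trees,
            max_depth=forest.max_depth,
            min_samples_leaf=forest.min_leaf,
            bootstrap=True,
            random_state=seed,
            n_jobs=1,
        )
    raise ValueError(f"unknown method {method!r}")


def fit_cs_model(
    table: pd.DataFrame,
    method: str = "random_forest",
    seed: int = 0,
    train_frac: float = 0.7,
    forest: ForestParams = ForestParams(),
    target: str = "cs",
    features=PREDICTOR_FEATURES,
) -> PredictionModel:
    """Seeded 70/30 split, fit, and test metrics for one method."""
    if len(table) < 20:
        raise ValueError(f"need >= 20 rows to fit, got {len(table)}")
    y = table[target].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("degenerate target: cs is constant")
    features = tuple(f for f in features if f in table.columns)
    train, test = train_test_split(
        table, train_size=train_frac, random_state=seed, shuffle=True
    )
    est = _make_estimator(method, seed, forest)
    est.fit(train[list(features)].to_numpy(float), train[target].to_numpy(float))
    p = len(features)
    test_pred = est.predict(test[list(features)].to_numpy(float))
    train_pred = est.predict(train[list(features)].to_numpy(float))
    all_pred = est.predict(table[list(features)].to_numpy(float))
    return PredictionModel(
        method=method,
        features=features,
        estimator=est,
        fit_metrics=compute_metrics(test[target], test_pred, p),
        train_metrics=compute_metrics(train[target], train_pred, p),
        overall_metrics=compute_metrics(table[target], all_pred, p),
        forest_params=forest if method == "random_forest" else None,
        seed=seed,
    )


def cross_validate(
    table: pd.DataFrame,
    method: str = "random_forest",
    k: int = 5,
    seed: int = 0,
    forest: ForestParams = ForestParams(),
    target: str = "cs",
    features=PREDICTOR_FEATURES,
) -> dict:
    """Seeded k-fold cross-validation.

    Each row appears in exactly one validation fold; the summary metric
    is the arithmetic mean of the per-fold metrics.  Returns
    ``{"folds": [MetricSet, ...], "mean": MetricSet-like dict}``.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(table):
        raise ValueError(f"k={k} exceeds {len(table)} rows")
    features = tuple(f for f in features if f in table.columns)
    X = table[list(features)].to_numpy(dtype=float)
    y = table[target].to_numpy(dtype=float)
    folds = []
    assignments = np.full(len(table), -1)
    for fold_i, (tr, va) in enumerate(
        KFold(n_splits=k, shuffle=True, random_state=seed).split(X)
    ):
        assignments[va] = fold_i
        est = _make_estimator(method, seed, forest)
        est.fit(X[tr], y[tr])
        folds.append(compute_metrics(y[va], est.predict(X[va]), len(features)))
    assert np.all(assignments >= 0)
    mean = {
        name: float(np.mean([getattr(f, name) for f in folds]))
        for name in ("mae", "mse", "rmse", "r2", "adjusted_r2")
    }
    return {"folds": folds, "mean": mean, "assignments": assignments}


def feature_importance(
    model: PredictionModel,
    table: pd.DataFrame,
    n_repeats: int = 10,
    seed: int = 0,
    target: str = "cs",
    holdout: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Dual importance for a fitted forest.

    %IncMSE permutes one feature at a time in the held-out table
    (default: the full table) and reports the mean percent increase in
    MSE over ``n_repeats`` seeded permutations.  IncNodePurity sums the
    sample-weighted variance decrease of every split on the feature
    across all trees.  Rows are sorted by %IncMSE with per-metric ranks.
    """
    if model.method != "random_forest":
        raise ValueError("feature importance requires a random forest model")
    df = table if holdout is None else holdout
    X = df[list(model.features)].to_numpy(dtype=float)
    y = df[target].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    base_mse = float(np.mean((y - model.estimator.predict(X)) ** 2))
    pct_inc = []
    for j in range(X.shape[1]):
        incs = []
        for _ in range(n_repeats):
            Xp = X.copy()
            Xp[:, j] = rng.permutation(Xp[:, j])
            mse = float(np.mean((y - model.estimator.predict(Xp)) ** 2))
            incs.append(100.0 * (mse - base_mse) / base_mse)
        pct_inc.append(float(np.mean(incs)))

    purity = np.zeros(X.shape[1])
    for est in model.estimator.estimators_:
        tree = est.tree_
        for node in range(tree.node_count):
            left, right = tree.children_left[node], tree.children_right[node]
            if left == -1:  # leaf
                continue
            w = tree.weighted_n_node_samples
            decrease = (
                w[node] * tree.impurity[node]
                - w[left] * tree.impurity[left]
                - w[right] * tree.impurity[right]
            )
            purity[tree.feature[node]] += decrease

    out = pd.DataFrame(
        {
            "feature": list(model.features),
            "pct_inc_mse": pct_inc,
            "inc_node_purity": purity,
        }
    )
    out["rank_pct_inc_mse"] = out["pct_inc_mse"].rank(ascending=False).astype(int)
    out["rank_inc_node_purity"] = (
        out["inc_node_purity"].rank(ascending=False).astype(int)
    )
    return out.sort_values("pct_inc_mse", ascending=False).reset_index(drop=True)
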