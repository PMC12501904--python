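"""Linear calibration of wearable-sensor lux and CCT against ground truth.

The sensor's raw illuminance and color temperature are corrected with
no-intercept multiple linear regressions on candidate features
(CCT', IR, lux', and the visible channels), mirroring the reference
calibration functions

    lux = 0.0596·CCT' + 1.6064·IR + 0.8432·lux'
    CCT = 1.048·CCT' − 0.5427·IR + 0.1761·lux'

Workflow: screen invalid rows (negative light quantities), split
70/30 train/test (seeded), select features by coefficient significance
in the full no-intercept model, fit by least squares through the
origin, and report MAE / MSE / RMSE / R² / adjusted R² on both splits.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.model_selection import train_test_split

__all__ = [
    "CANDIDATE_FEATURES",
    "MetricSet",
    "CalibrationModel",
    "screen_data",
    "select_features",
    "fit_calibration",
    "apply_calibration",
    "compute_metrics",
]

#: candidate features in tie-break priority order
CANDIDATE_FEATURES = ("cct_raw", "ir", "lux_raw", "r", "g", "b")

#: columns that must be nonnegative to be physically valid
LIGHT_COLUMNS = (
    "lux_ref", "cct_ref", "lux_raw", "cct_raw", "r", "g", "b", "ir",
)


class EmptyDataError(ValueError):
    pass


class CollinearityError(ValueError):
    pass


@dataclass(frozen=True)
class MetricSet:
    """Regression goodness-of-fit metrics.

    MAE = (1/N)·Σ|y−ŷ|, MSE = (1/N)·Σ(y−ŷ)², R² = 1 − SS_res/SS_tot,
    adjusted R² = 1 − (1−R²)(N−1)/(N−p−1) (Wherry), RMSE = √MSE.
    """

    mae: float
    mse: float
    rmse: float
    r2: float
    adjusted_r2: float
    n: int

    def as_dict(self) -> dict:
        return asdict(self)


def compute_metrics(y_true, y_pred, n_features: int) -> MetricSet:
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.size == 0 or y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must be nonempty and equal length")
    resid = y_true - y_pred
    mae = float(np.mean(np.abs(resid)))
    mse = float(np.mean(resid**2))
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("R² undefined: y_true has zero variance")
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
    n = y_true.size
    denom = n - n_features - 1
    adj = 1.0 - (1.0 - r2) * (n - 1) / denom if denom > 0 else float("nan")
    return MetricSet(mae=mae, mse=mse, rmse=float(np.sqrt(mse)), r2=r2,
                     adjusted_r2=adj, n=n)


def screen_data(
    table: pd.DataFrame, drop_clamped: bool = False
) -> tuple[pd.DataFrame, dict]:
    """Remove physically invalid rows.

    Rows with a negative value in any light column present are dropped;
    optionally rows flagged ``clamped`` (instrument-range saturation)
    are dropped too.  Returns the cleaned table and a per-column
    removal report.
    """
    report = {}
    keep = pd.Series(True, index=table.index)
    for col in LIGHT_COLUMNS:
        if col in table.columns:
            bad = table[col] < 0
            report[col] = int(bad.sum())
            keep &= ~bad
    if drop_clamped and "clamped" in table.columns:
        bad = table["clamped"].astype(bool)
        report["clamped"] = int((bad & keep).sum())
        keep &= ~bad
    cleaned = table.loc[keep].reset_index(drop=True)
    if cleaned.empty:
        raise EmptyDataError("no rows survive data screening")
    return cleaned, report


def _drop_collinear(X: pd.DataFrame) -> list:
    """Greedy rank filter: keep features in candidate order, dropping
    any column linearly dependent on those already kept."""
    kept = []
    for col in X.columns:
        trial = kept + [col]
        if np.linalg.matrix_rank(X[trial].to_numpy()) == len(trial):
            kept.append(col)
    return kept


def select_features(
    table: pd.DataFrame,
    target: str,
    alpha: float = 0.05,
    candidates=CANDIDATE_FEATURES,
) -> list:
    """Significance-based feature selection for the no-intercept model.

    Fits the full no-intercept least-squares model on all (non-
    collinear) candidates and keeps features whose coefficient p-value
    is below ``alpha``.  If none is significant, all candidates are
    retained with a warning.  Perfectly collinear features are resolved
    by keeping the earliest in candidate order.
    """
    present = [c for c in candidates if c in table.columns]
    if not present:
        raise ValueError("no candidate features present in table")
    usable = _drop_collinear(table[present])
    fit = sm.OLS(table[target].to_numpy(), table[usable].to_numpy()).fit()
    selected = [c for c, p in zip(usable, fit.pvalues) if p < alpha]
    if not selected:
        warnings.warn(
            "no feature reached significance; retaining all candidates",
            stacklevel=2,
        )
        return usable
    return selected


@dataclass(frozen=True)
class CalibrationModel:
    """A fitted no-intercept linear calibration."""

    target: str                 # "photopic_lux" | "cct"
    features: tuple
    coefficients: tuple
    train_metrics: MetricSet
    test_metrics: MetricSet | None
    overall_metrics: MetricSet | None = None  # refit-on-all-data variant
    intercept: float = 0.0
    n_train: int = 0
    n_test: int = 0
    seed: int = 0
    screening_report: dict = field(default_factory=dict, compare=False)

    def predict(self, table) -> np.ndarray:
        return apply_calibration(self, table)

    def to_json(self) -> str:
        d = {
            "target": self.target,
            "features": list(self.features),
            "coefficients": list(self.coefficients),
            "intercept": self.intercept,
            "n_train": self.n_train,
            "n_test": self.n_test,
            "seed": self.seed,
            "train_metrics": self.train_metrics.as_dict(),
            "test_metrics": self.test_metrics.as_dict() if self.test_metrics else None,
            "overall_metrics": (
                self.overall_metrics.as_dict() if self.overall_metrics else None
            ),
        }
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "CalibrationModel":
        d = json.loads(text)
        ms = {
            k: MetricSet(**d[k]) if d.get(k) else None
            for k in ("train_metrics", "test_metrics", "overall_metrics")
        }
        return cls(
            target=d["target"],
            features=tuple(d["features"]),
            coefficients=tuple(d["coefficients"]),
            intercept=d.get("intercept", 0.0),
            n_train=d["n_train"],
            n_test=d["n_test"],
            seed=d["seed"],
            **ms,
        )


def _lstsq(X: np.ndarray, y: np.ndarray, features) -> np.ndarray:
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise CollinearityError(
            f"rank-deficient design over features {list(features)}"
        )
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return coef


def fit_calibration(
    table: pd.DataFrame,
    target: str,
    train_frac: float = 0.7,
    seed: int = 0,
    alpha: float = 0.05,
    drop_clamped: bool = True,
    fit_intercept: bool = False,
    refit_all: bool = True,
) -> CalibrationModel:
    """Screen, split, select and fit a calibration for one target.

    ``target`` is a column of ``table`` (``lux_ref`` or ``cct_ref``).
    With ``train_frac == 1.0`` no test split is made and the train
    metrics are the overall metrics.  ``refit_all`` additionally refits
    the selected features on all screened rows, reproducing the
    "overall" metric convention.  An intercept can be added behind
    ``fit_intercept`` but the reference calibrations pass through the
    origin.
    """
    cleaned, report = screen_data(table, drop_clamped=drop_clamped)
    if len(cleaned) < 10:
        raise EmptyDataError(f"only {len(cleaned)} rows post-screening; need >= 10")
    if not 0.0 < train_frac <= 1.0:
        raise ValueError("train_frac must be in (0, 1]")
    if train_frac < 1.0:
        train, test = train_test_split(
            cleaned, train_size=train_frac, random_state=seed, shuffle=True
        )
    else:
        train, test = cleaned, None

    features = select_features(train, target, alpha=alpha)

    def design(df):
        X = df[features].to_numpy(dtype=float)
        if fit_intercept:
            X = np.column_stack([X, np.ones(len(df))])
        return X

    y_train = train[target].to_numpy(dtype=float)
    coef = _lstsq(design(train), y_train, features)
    intercept = float(coef[-1]) if fit_intercept else 0.0
    weights = coef[:-1] if fit_intercept else coef

    def metrics(df):
        y = df[target].to_numpy(dtype=float)
        pred = df[features].to_numpy(dtype=float) @ weights + intercept
        return compute_metrics(y, pred, n_features=len(features))

    train_metrics = metrics(train)
    test_metrics = metrics(test) if test is not None else None
    overall = None
    if refit_all:
        coef_all = _lstsq(design(cleaned), cleaned[target].to_numpy(float), features)
        w_all = coef_all[:-1] if fit_intercept else coef_all
        b_all = float(coef_all[-1]) if fit_intercept else 0.0
        pred = cleaned[features].to_numpy(float) @ w_all + b_all
        overall = compute_metrics(
            cleaned[target].to_numpy(float), pred, n_features=len(features)
        )
    return CalibrationModel(
        target=target,
        features=tuple(features),
        coefficients=tuple(float(w) for w in weights),
        intercept=intercept,
        train_metrics=train_metrics,
        test_metrics=test_metrics,
        overall_metrics=overall,
        n_train=len(train),
        n_test=0 if test is None else len(test),
        seed=seed,
        screening_report=report,
    )


def apply_calibration(model: CalibrationModel, table) -> np.ndarray:
    """Apply a fitted calibration: dot product of coefficients with the
    model's features (vectorized over a DataFrame, dict, or mapping of
    arrays)."""
    if isinstance(table, pd.DataFrame):
        missing = [f for f in model.features if f not in table.columns]
        if missing:
            raise KeyError(f"reading lacks calibration features {missing}")
        X = table[list(model.features)].to_numpy(dtype=float)
    else:
        try:
            cols = [np.atleast_1d(np.asarray(table[f], dtype=float))
                    for f in model.features]
        except (KeyError, TypeError) as exc:
            raise KeyError(f"reading lacks calibration feature: {exc}") from exc
        X = np.column_stack(cols)
    out = X @ np.asarray(model.coefficients) + model.intercept
    return out if out.size > 1 else float(out[0])
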