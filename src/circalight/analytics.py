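"""Deployment analytics for calibrated, CS-annotated exposure logs.

Turns a raw wearable log into the quantities a lighting-health study
reports: calibrated lux and CCT, predicted CS, day/night segmentation,
nonwear/malfunction flags, weekly day/night exposure summaries,
between-person paired t-tests on weekly means, and post hoc power for
a paired/one-sample design.

Conventions (each configurable):

* "daytime" is a fixed local clock window, 06:00-18:00 by default —
  the only reproducible choice absent per-site sunrise data;
* nonwear: an interval is flagged when the illuminance rolling range
  stays below 1 lux *and* no motion is registered for longer than 2 h
  in the daytime or 4 h at night;
* CCT is unreliable in dim light, so it is masked at night and wherever
  calibrated lux falls below a 10 lux floor before any CCT statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import time

import numpy as np
import pandas as pd
from scipy import stats

from .calibration import CalibrationModel, apply_calibration

__all__ = [
    "DayWindow",
    "ExposureSeries",
    "annotate",
    "detect_nonwear",
    "mask_dim_cct",
    "weekly_summary",
    "paired_t",
    "post_hoc_power",
]


@dataclass(frozen=True)
class DayWindow:
    """Local clock interval defining 'daytime' (default 06:00-18:00)."""

    start_hour: int = 6
    end_hour: int = 18

    def contains(self, timestamps: pd.Series) -> pd.Series:
        hours = timestamps.dt.hour + timestamps.dt.minute / 60.0
        return (hours >= self.start_hour) & (hours < self.end_hour)


@dataclass
class ExposureSeries:
    """Calibrated, CS-annotated time series for one person.

    ``data`` columns: timestamp, lux, cct, cs, motion, wear_flag,
    day_flag (wear_flag True means the device was worn).
    """

    person_id: str
    data: pd.DataFrame
    day_window: DayWindow = field(default_factory=DayWindow)

    def __post_init__(self):
        ts = self.data["timestamp"]
        if len(ts) > 1 and not ts.is_monotonic_increasing:
            raise ValueError("timestamps must be increasing")
        if ts.duplicated().any():
            raise ValueError("timestamps must be strictly increasing (duplicates)")


def _log_frame(log) -> pd.DataFrame:
    if isinstance(log, pd.DataFrame):
        return log.copy()
    return pd.DataFrame(
        {
            "timestamp": [r.timestamp for r in log],
            "lux_raw": [r.lux_raw for r in log],
            "cct_raw": [r.cct_raw for r in log],
            "r": [r.r for r in log],
            "g": [r.g for r in log],
            "b": [r.b for r in log],
            "ir": [r.ir for r in log],
            "motion": [r.motion for r in log],
        }
    )


def annotate(
    log,
    lux_model: CalibrationModel,
    cct_model: CalibrationModel,
    cs_model,
    person_id: str = "anonymous",
    day_window: DayWindow = DayWindow(),
    day_threshold_h: float = 2.0,
    night_threshold_h: float = 4.0,
) -> ExposureSeries:
    """Calibrate and annotate a raw sensor log record-by-record."""
    df = _log_frame(log)
    required = {"timestamp", "lux_raw", "cct_raw", "r", "g", "b", "ir", "motion"}
    missing = required - set(df.columns)
    if missing:
        raise KeyError(f"log lacks columns {sorted(missing)}")
    out = pd.DataFrame({"timestamp": pd.to_datetime(df["timestamp"])})
    if len(df):
        out["lux"] = np.atleast_1d(apply_calibration(lux_model, df))
        out["cct"] = np.atleast_1d(apply_calibration(cct_model, df))
        out["cs"] = np.clip(cs_model.predict(df), 0.0, None)
        out["motion"] = df["motion"].astype(bool).to_numpy()
        out["day_flag"] = day_window.contains(out["timestamp"]).to_numpy()
    else:
        for col in ("lux", "cct", "cs"):
            out[col] = pd.Series(dtype=float)
        out["motion"] = pd.Series(dtype=bool)
        out["day_flag"] = pd.Series(dtype=bool)
    series = ExposureSeries(person_id=person_id, data=out, day_window=day_window)
    intervals = detect_nonwear(
        series, day_threshold_h=day_threshold_h, night_threshold_h=night_threshold_h
    )
    wear = np.ones(len(out), dtype=bool)
    for i0, i1 in intervals:
        wear[i0 : i1 + 1] = False
    out["wear_flag"] = wear
    return series


def _flat_runs(lux: np.ndarray, motion: np.ndarray, tol: float):
    """Maximal index runs [i, j] with lux range < tol and no motion."""
    n = len(lux)
    runs = []
    i = 0
    while i < n:
        if motion[i]:
            i += 1
            continue
        j = i
        lo = hi = lux[i]
        while j + 1 < n and not motion[j + 1]:
            nlo, nhi = min(lo, lux[j + 1]), max(hi, lux[j + 1])
            if nhi - nlo >= tol:
                break
            lo, hi = nlo, nhi
            j += 1
        runs.append((i, j))
        i = j + 1
    return runs


def detect_nonwear(
    series: ExposureSeries,
    day_threshold_h: float = 2.0,
    night_threshold_h: float = 4.0,
    lux_tolerance: float = 1.0,
) -> list:
    """Flag nonwear/malfunction intervals.

    A maximal run of readings with illuminance rolling range below
    ``lux_tolerance`` and no motion events is flagged when its duration
    exceeds 2 h if any part falls in the day window, else 4 h.  Returns
    a list of (start_index, end_index) pairs, maximal and
    non-overlapping.
    """
    df = series.data
    if len(df) < 2:
        return []
    ts = pd.to_datetime(df["timestamp"])
    cadence_min = (ts.iloc[1] - ts.iloc[0]).total_seconds() / 60.0
    if cadence_min > 30.0:
        raise ValueError(f"cadence {cadence_min:.0f} min too coarse (need <= 30)")
    lux = df["lux"].to_numpy(dtype=float) if "lux" in df else df["lux_raw"].to_numpy(
        dtype=float
    )
    motion = df["motion"].to_numpy(dtype=bool)
    day = series.day_window.contains(ts).to_numpy()
    flagged = []
    for i, j in _flat_runs(lux, motion, lux_tolerance):
        duration_h = (j - i + 1) * cadence_min / 60.0
        threshold = day_threshold_h if day[i : j + 1].any() else night_threshold_h
        if duration_h > threshold:
            flagged.append((i, j))
    return flagged


def mask_dim_cct(series: ExposureSeries, lux_floor: float = 10.0) -> ExposureSeries:
    """Suppress CCT where it is unreliable: every nighttime record,
    plus any record with calibrated lux below ``lux_floor``.  Lux and
    CS are untouched."""
    df = series.data.copy()
    unreliable = (~df["day_flag"]) | (df["lux"] < lux_floor)
    df.loc[unreliable, "cct"] = np.nan
    return ExposureSeries(series.person_id, df, series.day_window)


def weekly_summary(series: ExposureSeries, metrics=("lux", "cct", "cs")) -> pd.DataFrame:
    """Per-week day/night means and variances, nonwear excluded.

    Weeks are 7-day blocks aligned to the series start.  Returns tidy
    rows (week, period, metric, mean, variance, n); a week x period
    cell with no worn records is reported with n=0 and missing stats.
    """
    df = series.data
    if len(df) == 0:
        raise ValueError("empty series")
    ts = pd.to_datetime(df["timestamp"])
    cadence_s = (
        (ts.iloc[1] - ts.iloc[0]).total_seconds() if len(ts) > 1 else 0.0
    )
    span_days = ((ts.iloc[-1] - ts.iloc[0]).total_seconds() + cadence_s) / 86400.0
    if span_days < 7.0 - 1e-9:
        raise ValueError("need at least one complete week of records")
    week = ((ts - ts.iloc[0]).dt.total_seconds() // (7 * 86400)).astype(int)
    worn = df["wear_flag"].astype(bool) if "wear_flag" in df else pd.Series(
        True, index=df.index
    )
    rows = []
    for w in range(int(week.max()) + 1):
        for period, dayflag in (("day", True), ("night", False)):
            cell = df[(week == w) & (df["day_flag"] == dayflag) & worn]
            for metric in metrics:
                vals = cell[metric].dropna()
                rows.append(
                    {
                        "week": w,
                        "period": period,
                        "metric": metric,
                        "mean": float(vals.mean()) if len(vals) else np.nan,
                        "variance": float(vals.var(ddof=1)) if len(vals) > 1 else (
                            0.0 if len(vals) == 1 else np.nan
                        ),
                        "n": int(len(vals)),
                    }
                )
    return pd.DataFrame(rows)


def paired_t(values_a, values_b) -> dict:
    """Two-tailed paired t test on per-week values.

    t = mean(d) / (sd(d)/sqrt(n)) with d = a − b, df = n − 1.  Raises
    on zero-variance differences (t undefined).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need equal-length paired vectors with n >= 2")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0:
        if np.all(d == 0):
            return {"t": 0.0, "df": a.size - 1, "p_two_tailed": 1.0}
        raise ValueError("degenerate paired differences: zero variance")
    n = a.size
    t = float(d.mean() / (sd / np.sqrt(n)))
    p = float(2.0 * stats.t.sf(abs(t), df=n - 1))
    return {"t": t, "df": n - 1, "p_two_tailed": p}


def post_hoc_power(
    n: int, d: float, alpha: float = 0.05, tails: int = 1
) -> float:
    """Post hoc power of a one-sample/paired t test.

    Uses the noncentral t distribution with noncentrality d·√n and
    df = n − 1 (the G*Power convention for this design).
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if n < 2:
        raise ValueError("need n >= 2")
    if d <= 0:
        raise ValueError("effect size d must be positive")
    if tails not in (1, 2):
        raise ValueError("tails must be 1 or 2")
    df = n - 1
    ncp = d * np.sqrt(n)
    if tails == 1:
        crit = stats.t.ppf(1.0 - alpha, df)
        return float(stats.nct.sf(crit, df, ncp))
    crit = stats.t.ppf(1.0 - alpha / 2.0, df)
    return float(stats.nct.sf(crit, df, ncp) + stats.nct.cdf(-crit, df, ncp))
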