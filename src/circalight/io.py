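"""File formats and run configuration.

* SPD CSV: header ``wavelength_nm,irradiance_w_m2_nm``; 1 or 5 nm
  uniform grids; writer emits shortest round-trip float representations so
  round-trips are lossless.
* Sensor log CSV: ``timestamp,lux_raw,cct_raw,r_wm2,g_wm2,b_wm2,
  ir_wm2,motion`` with ISO-8601 timestamps; rows must be
  time-ordered.
* RunConfig: one YAML document collecting every tunable default of the
  pipeline; round-trips losslessly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from datetime import datetime
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .sensor import SensorReading
from .spectral import SPD

__all__ = [
    "SPD_HEADER",
    "LOG_COLUMNS",
    "RunConfig",
    "read_spd",
    "write_spd",
    "read_sensor_log",
    "write_sensor_log",
]

SPD_HEADER = "wavelength_nm,irradiance_w_m2_nm"
LOG_COLUMNS = [
    "timestamp", "lux_raw", "cct_raw", "r_wm2", "g_wm2", "b_wm2", "ir_wm2", "motion",
]


class ParseError(ValueError):
    pass


def read_spd(path) -> SPD:
    """Read an SPD CSV, validating header and grid monotonicity with
    line numbers in error messages."""
    lines = Path(path).read_text().strip().splitlines()
    if not lines or lines[0].strip() != SPD_HEADER:
        raise ParseError(
            f"{path}:1: expected header {SPD_HEADER!r}, "
            f"got {lines[0].strip() if lines else '<empty>'!r}"
        )
    lam, val = [], []
    for lineno, line in enumerate(lines[1:], start=2):
        parts = line.split(",")
        if len(parts) != 2:
            raise ParseError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
        try:
            w, v = float(parts[0]), float(parts[1])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
        if lam and w <= lam[-1]:
            raise ParseError(
                f"{path}:{lineno}: wavelengths not strictly increasing "
                f"({w} after {lam[-1]})"
            )
        lam.append(w)
        val.append(v)
    return SPD(np.array(lam), np.array(val))


def write_spd(spd: SPD, path) -> None:
    with open(path, "w") as fh:
        fh.write(SPD_HEADER + "\n")
        for w, v in zip(spd.wavelengths, spd.values):
            fh.write(f"{float(w)!r},{float(v)!r}\n")


def write_sensor_log(readings, path) -> None:
    """Write a sensor log CSV (datasheet channel labels, see sensor
    module for the R/B wavelength inversion)."""
    with open(path, "w") as fh:
        fh.write(",".join(LOG_COLUMNS) + "\n")
        for r in readings:
            fh.write(
                f"{r.timestamp.isoformat()},{float(r.lux_raw)!r},{float(r.cct_raw)!r},"
                f"{float(r.r)!r},{float(r.g)!r},{float(r.b)!r},{float(r.ir)!r},"
                f"{int(r.motion)}\n"
            )


def read_sensor_log(path) -> list:
    """Read a sensor log CSV into SensorReading records; out-of-order
    timestamps are an error listing the offending rows."""
    df = pd.read_csv(path)
    missing = [c for c in LOG_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    ts = pd.to_datetime(df["timestamp"])
    bad = ts[ts.diff().dt.total_seconds() <= 0]
    if len(bad):
        raise ParseError(
            f"{path}: rows out of time order at "
            + ", ".join(str(t) for t in bad.head(5))
        )
    return [
        SensorReading(
            timestamp=ts.iloc[i].to_pydatetime(),
            lux_raw=float(df["lux_raw"].iloc[i]),
            cct_raw=float(df["cct_raw"].iloc[i]),
            r=float(df["r_wm2"].iloc[i]),
            g=float(df["g_wm2"].iloc[i]),
            b=float(df["b_wm2"].iloc[i]),
            ir=float(df["ir_wm2"].iloc[i]),
            motion=bool(df["motion"].iloc[i]),
        )
        for i in range(len(df))
    ]


@dataclass
class RunConfig:
    """Every tunable of the end-to-end pipeline, with its default."""

    out_dir: str = "run_output"
    seed: int = 0
    protocol: str = "lab"          # lab | field
    n_scenarios: int = 100
    reps: int = 5
    train_frac: float = 0.7
    alpha: float = 0.05
    cv_folds: int = 5
    forest_trees: int = 500
    forest_min_leaf: int = 2
    cs_method: str = "random_forest"
    lux_noise_cv: float = 0.05
    cct_noise_cv: float = 0.02
    channel_noise_cv: float = 0.05
    day_window: str = "06:00-18:00"
    nonwear_day_h: float = 2.0
    nonwear_night_h: float = 4.0
    dim_cct_lux_floor: float = 10.0
    log_days: int = 35             # five project weeks
    log_cadence_min: int = 15
    residents: tuple = ("resident_1", "resident_2")

    def day_hours(self) -> tuple:
        start, end = self.day_window.split("-")
        return int(start.split(":")[0]), int(end.split(":")[0])

    def to_yaml(self) -> str:
        d = asdict(self)
        d["residents"] = list(self.residents)
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        d = yaml.safe_load(text)
        if "residents" in d:
            d["residents"] = tuple(d["residents"])
        return cls(**d)
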