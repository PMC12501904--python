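"""End-to-end pipeline: simulate -> calibrate -> train -> analyze.

All randomness flows from ``config.seed``: each stage derives its own
seed as ``sha256(stage_name)[:4] XOR seed  (mod 2**31)``, so any stage
can be re-run independently and reproducibly.  The run directory
contains scene files, the paired calibration table, fitted model JSONs,
annotated logs, weekly summaries, and a manifest of seeds and output
checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
from datetime import datetime, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .analytics import DayWindow, annotate, mask_dim_cct, paired_t, weekly_summary
from .calibration import fit_calibration
from .cs_prediction import (
    ForestParams,
    build_training_table,
    cross_validate,
    feature_importance,
    fit_cs_model,
)
from .io import RunConfig, write_sensor_log, write_spd
from .observers import load_observer_tables, table_checksums
from .scenes import field_protocol, lab_protocol
from .sensor import DistortionSpec, WearSchedule, channel_response, distort, generate_log
from .spectral import cct_of_spd, photopic_illuminance

log = logging.getLogger("circalight")

__all__ = ["stage_seed", "make_paired_table", "run_pipeline"]


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    h = int.from_bytes(hashlib.sha256(stage.encode()).digest()[:4], "big")
    return (seed ^ h) % (2**31)


def make_paired_table(scene_pairs, spec: DistortionSpec, tables, seed: int):
    """Ground-truth/sensor paired table from (Scenario, SPD) pairs.

    Each pair becomes one row: reference lux and CCT from the spectrum,
    sensor channels and distorted raw outputs from the sensor model.
    Returns (DataFrame, readings list).
    """
    rng = np.random.default_rng(seed)
    rows, readings = [], []
    t0 = datetime(2024, 1, 1, 12, 0)
    for i, (_, spd) in enumerate(scene_pairs):
        visible = spd.restrict()
        lux = photopic_illuminance(visible, tables)
        cct = cct_of_spd(visible, tables).cct
        ch = channel_response(spd)
        reading = distort(
            lux, cct, ch, spec, timestamp=t0 + timedelta(minutes=i), rng=rng
        )
        readings.append(reading)
        rows.append(
            {
                "lux_ref": lux,
                "cct_ref": cct,
                "lux_raw": reading.lux_raw,
                "cct_raw": reading.cct_raw,
                "r": reading.r,
                "g": reading.g,
                "b": reading.b,
                "ir": reading.ir,
                "clamped": reading.clamped,
            }
        )
    return pd.DataFrame(rows), readings


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Run every stage and write a deterministic artifact directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables = load_observer_tables()
    stage = "init"
    try:
        # --- stage 1: scenes -------------------------------------------------
        stage = "simulate-scenes"
        protocol = lab_protocol if config.protocol == "lab" else field_protocol
        pairs = protocol(
            config.n_scenarios, config.reps, seed=stage_seed(config.seed, stage),
            tables=tables,
        )
        scenes_dir = out / "scenes"
        scenes_dir.mkdir(exist_ok=True)
        scenario_records = []
        for i in range(0, len(pairs), config.reps):
            sc, spd = pairs[i]
            write_spd(spd, scenes_dir / f"scene_{i // config.reps:04d}.csv")
            scenario_records.append(sc.to_dict())
        (out / "scenarios.json").write_text(
            json.dumps(scenario_records, indent=2) + "\n"
        )
        log.info("%s: %d scenarios x %d reps", stage, config.n_scenarios, config.reps)

        # --- stage 2: sensor + paired table ---------------------------------
        stage = "sensor-readings"
        spec = DistortionSpec(
            lux_cv=config.lux_noise_cv, cct_cv=config.cct_noise_cv,
            channel_cv=config.channel_noise_cv,
            seed=stage_seed(config.seed, stage),
        )
        paired, readings = make_paired_table(
            pairs, spec, tables, seed=stage_seed(config.seed, stage)
        )
        paired.to_csv(out / "paired_table.csv", index=False)
        write_sensor_log(readings, out / "lab_sensor_log.csv")

        # --- stage 3: calibrations -------------------------------------------
        stage = "calibrate"
        cal_seed = stage_seed(config.seed, stage)
        lux_model = fit_calibration(
            paired, "lux_ref", train_frac=config.train_frac, seed=cal_seed,
            alpha=config.alpha,
        )
        cct_model = fit_calibration(
            paired, "cct_ref", train_frac=config.train_frac, seed=cal_seed,
            alpha=config.alpha,
        )
        (out / "lux_calibration.json").write_text(lux_model.to_json() + "\n")
        (out / "cct_calibration.json").write_text(cct_model.to_json() + "\n")
        log.info(
            "%s: lux test R2=%.3f, cct test R2=%.3f (screened %s)",
            stage, lux_model.test_metrics.r2, cct_model.test_metrics.r2,
            lux_model.screening_report,
        )

        # --- stage 4: CS prediction ------------------------------------------
        stage = "train-cs"
        cs_seed = stage_seed(config.seed, stage)
        spd_by_reading = list(zip((p[1] for p in pairs), readings))
        cs_table = build_training_table(spd_by_reading, tables)
        cs_table.to_csv(out / "cs_training_table.csv", index=False)
        forest = ForestParams(
            n_trees=config.forest_trees, min_leaf=config.forest_min_leaf
        )
        cs_model = fit_cs_model(
            cs_table, method=config.cs_method, seed=cs_seed,
            train_frac=config.train_frac, forest=forest,
        )
        result = {
            "method": cs_model.method,
            "test_metrics": cs_model.fit_metrics.as_dict(),
            "overall_metrics": cs_model.overall_metrics.as_dict(),
        }
        if config.cs_method == "random_forest":
            cv = cross_validate(
                cs_table, "random_forest", k=config.cv_folds, seed=cs_seed,
                forest=forest,
            )
            result["cv_mean"] = cv["mean"]
            imp = feature_importance(cs_model, cs_table, seed=cs_seed)
            imp.to_csv(out / "cs_feature_importance.csv", index=False)
        (out / "cs_model.json").write_text(json.dumps(result, indent=2) + "\n")

        # --- stage 5: resident logs + analytics -------------------------------
        stage = "analyze-exposure"
        an_seed = stage_seed(config.seed, stage)
        day_start, day_end = config.day_hours()
        window = DayWindow(day_start, day_end)
        bright = [spd for (sc, spd), _ in zip(pairs[:: config.reps], range(200))
                  if sc.daylight_fraction > 0.3][:20]
        dim = [spd.scaled(0.02) for sc, spd in pairs[:: config.reps]
               if sc.daylight_fraction <= 0.3][:20]
        if not bright or not dim:
            bright = bright or [pairs[0][1]]
            dim = dim or [pairs[0][1].scaled(0.02)]
        summaries = {}
        for i, person in enumerate(config.residents):
            schedule = WearSchedule(
                start=datetime(2024, 3, 4, 0, 0),
                days=config.log_days,
                cadence_min=config.log_cadence_min,
                day_start_hour=day_start,
                day_end_hour=day_end,
            )
            readings_p = generate_log(
                schedule, bright, dim, spec=spec, tables=tables,
                seed=an_seed + i,
            )
            write_sensor_log(readings_p, out / f"{person}_log.csv")
            series = annotate(
                readings_p, lux_model, cct_model, cs_model,
                person_id=person, day_window=window,
                day_threshold_h=config.nonwear_day_h,
                night_threshold_h=config.nonwear_night_h,
            )
            series = mask_dim_cct(series, lux_floor=config.dim_cct_lux_floor)
            summary = weekly_summary(series)
            summary.to_csv(out / f"{person}_weekly_summary.csv", index=False)
            summaries[person] = summary

        tests = {}
        if len(config.residents) >= 2:
            a, b = (summaries[p] for p in config.residents[:2])
            for metric in ("lux", "cs"):
                for period in ("day", "night"):
                    sel = lambda s: s[
                        (s["metric"] == metric) & (s["period"] == period)
                    ].sort_values("week")["mean"].to_numpy()
                    va, vb = sel(a), sel(b)
                    ok = ~(np.isnan(va) | np.isnan(vb))
                    if ok.sum() >= 2:
                        tests[f"{metric}_{period}"] = paired_t(va[ok], vb[ok])
        (out / "paired_tests.json").write_text(json.dumps(tests, indent=2) + "\n")

        # --- manifest ---------------------------------------------------------
        stage = "manifest"
        artifacts = sorted(
            p for p in out.rglob("*") if p.is_file() and p.name != "manifest.json"
        )
        manifest = {
            "version": __version__,
            "seed": config.seed,
            "stage_seeds": {
                s: stage_seed(config.seed, s)
                for s in (
                    "simulate-scenes", "sensor-readings", "calibrate",
                    "train-cs", "analyze-exposure",
                )
            },
            "observer_tables": table_checksums(),
            "config": config.to_yaml(),
            "files": {str(p.relative_to(out)): _sha256(p) for p in artifacts},
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    except Exception as exc:
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc
    return out
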