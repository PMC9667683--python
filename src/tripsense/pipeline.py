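"""End-to-end orchestration: simulate -> features -> models -> report.

``full_run`` executes the whole analysis on a synthetic cohort:

1. generate the cohort and write its CSV files;
2. build the labelled minute-level predictor table;
3. leave-one-participant-out cross-validation with per-iteration naive
   OOB rates, for each configured feature set, with and without the
   prevalence cut-off correction;
4. moving-majority homogenization of the held-out predictions over the
   configured bandwidths;
5. the three report tables (split comparison, HR contribution,
   bandwidth sweep) in machine- and human-readable form, plus a JSON
   run manifest with config, seeds, versions, output hashes and
   timings.

Identical configuration and seed reproduce every output byte for byte
(timings in the manifest aside).
"""

from __future__ import annotations

import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as tio
from .config import MODES, RunConfig, config_to_dict
from .evaluate import build_report_tables
from .features import build_minute_dataset, default_catalogue
from .forest import LoocvResult, loocv_run
from .simulate import generate_cohort
from .smoothing import PredictionSeries, bandwidth_sweep, mode_filter

logger = logging.getLogger(__name__)


def _prediction_frame(result: LoocvResult, feature_set: str,
                      bandwidths) -> pd.DataFrame:
    """Combined per-minute test predictions for one feature set,
    including vote shares per class and smoothed weighted predictions
    per bandwidth."""
    rows = []
    for fit in result.fits(feature_set):
        df = pd.DataFrame({
            "participant_id": fit.participant_id,
            "minute": fit.test_minutes,
            "truth": fit.test_truth,
            "pred_unweighted": fit.test_pred_unweighted,
            "pred_weighted": fit.test_pred_weighted,
        })
        shares = pd.DataFrame(np.nan, index=df.index,
                              columns=[f"share_{m}" for m in MODES])
        for j, cls in enumerate(fit.model_classes):
            shares[f"share_{cls}"] = fit.test_shares[:, j]
        df = pd.concat([df, shares], axis=1)
        series = PredictionSeries(fit.participant_id, fit.test_minutes,
                                  fit.test_pred_weighted)
        for b in bandwidths:
            if b == 0:
                continue
            df[f"pred_weighted_b{b}"] = mode_filter(series, int(b))
        rows.append(df)
    return pd.concat(rows, ignore_index=True)


def full_run(config: RunConfig, outdir) -> dict:
    """Run the full pipeline into ``outdir``; returns the in-memory
    results (minute table, LOOCV result, report tables)."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    outputs: dict[str, str] = {}

    t0 = time.perf_counter()
    logger.info("simulating cohort: %d participants x %d days (seed %d)",
                config.sim.n_participants, config.sim.n_days,
                config.sim.seed)
    cohort = generate_cohort(config.sim)
    cohort_paths = tio.write_cohort(cohort, outdir / "cohort")
    timings["simulate"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    catalogue = default_catalogue()
    minutes, accounting = build_minute_dataset(
        cohort.gps, cohort.accel, cohort.rr, cohort.timetable,
        cohort.participants, catalogue)
    logger.info("minute dataset: %s", accounting)
    tio.write_minutes(minutes, outdir / "minutes.csv")
    timings["build_features"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    result = loocv_run(minutes, feature_sets=config.feature_sets,
                       n_trees=config.n_trees, seed=config.sim.seed,
                       compute_oob=config.compute_oob, catalogue=catalogue)
    timings["train_evaluate"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    preds_dir = outdir / "predictions"
    preds_dir.mkdir(exist_ok=True)
    for fset in config.feature_sets:
        frame = _prediction_frame(result, fset, config.bandwidths)
        frame.to_csv(preds_dir / f"{fset}_predictions.csv", index=False)

    # Homogenization sweep on the held-out weighted predictions of the
    # richest feature set (with HR when configured).
    sweep_fset = ("with_hr" if "with_hr" in config.feature_sets
                  else config.feature_sets[0])
    series = [PredictionSeries(f.participant_id, f.test_minutes,
                               f.test_pred_weighted, f.test_truth)
              for f in result.fits(sweep_fset)]
    sweep_weighted = bandwidth_sweep(series, config.bandwidths)
    timings["homogenize"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    split_fset = ("without_hr" if "without_hr" in config.feature_sets
                  else config.feature_sets[0])
    split_fits = result.fits(split_fset)
    split_reports = {
        "test_unweighted": [f.test_rates_unweighted for f in split_fits],
        "test_weighted": [f.test_rates_weighted for f in split_fits],
    }
    if config.compute_oob:
        split_reports = {
            "oob_unweighted": [f.oob_rates_unweighted for f in split_fits],
            "oob_weighted": [f.oob_rates_weighted for f in split_fits],
            **split_reports,
        }
    hr_reports = {}
    for fset in config.feature_sets:
        fits = result.fits(fset)
        hr_reports[f"{fset}_unweighted"] = [f.test_rates_unweighted
                                            for f in fits]
        hr_reports[f"{fset}_weighted"] = [f.test_rates_weighted
                                          for f in fits]
    tables = build_report_tables(split_reports, hr_reports, sweep_weighted)

    report_dir = outdir / "report"
    report_dir.mkdir(exist_ok=True)
    for key, fname in (("split_comparison", "table_split_comparison"),
                       ("hr_contribution", "table_hr_contribution"),
                       ("bandwidth_sweep", "table_bandwidth_sweep")):
        num = tables[key]["numeric"].copy()
        num.columns = [f"{c}_{s}" for c, s in num.columns]
        num.to_csv(report_dir / f"{fname}.csv")
        tables[key]["human"].to_csv(report_dir / f"{fname}_human.csv")
    timings["report"] = time.perf_counter() - t0

    for path in sorted(outdir.rglob("*.csv")):
        outputs[str(path.relative_to(outdir))] = tio.file_sha256(path)
    tio.write_manifest(outdir / "manifest.json", config_to_dict(config),
                       config.sim.seed,
                       {"loocv_master": config.sim.seed}, outputs, timings)
    logger.info("run complete: %s", outdir)
    return {"cohort_paths": cohort_paths, "minutes": minutes,
            "accounting": accounting, "loocv": result, "tables": tables,
            "sweep": sweep_weighted}
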