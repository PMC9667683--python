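"""Minute-level feature engineering for the three sensor streams.

Each minute of follow-up with all three sensors present becomes one row
of a labelled predictor table:

* 51 GPS variables — seven summary statistics (mean, median, SD, min,
  max, 10th and 90th percentiles) of speed, elevation, HDOP, VDOP, PDOP
  and the numbers of satellites in view and used, computed over the
  quality-filtered fixes of the minute, plus the count of valid fixes
  and the fraction of raw fixes passing the quality filter;
* 55 accelerometer variables — per filter variant (standard and
  low-frequency extension): the seven statistics of vector-magnitude
  counts and of METs, plus step sum and MVPA / sedentary epoch counts;
  and, for the standard variant only, the seven statistics of each axis;
* 12 heart-rate-variability variables from the RR intervals of the
  minute (time-domain only: one-minute windows are too short for
  frequency-domain HRV);
* 2 time variables — minutes since midnight and a weekend flag.

GPS fixes are kept only when HDOP < 6, VDOP < 7 and PDOP < 8 (strict
inequalities). A minute missing any sensor entirely is dropped from the
merged table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import MODES

STATS = ("mean", "median", "sd", "min", "max", "p10", "p90")

GPS_SIGNALS = ("speed", "elevation", "hdop", "vdop", "pdop",
               "sat_in_view", "sat_used")

HR_FEATURES = ("mean_rr", "median_rr", "sdnn", "rmssd", "sdsd", "pnn50",
               "cv_rr", "mean_hr", "sd_hr", "min_hr", "max_hr", "n_beats")

#: METs = slope * (vector-magnitude counts per minute) + intercept.
#: Coefficients follow the hip-worn tri-axial calibration equation in
#: common use; configurable because calibration studies differ.
SASAKI_SLOPE = 0.000863
SASAKI_INTERCEPT = 0.668876

MVPA_METS_THRESHOLD = 3.0          # moderate-intensity cut-point
SEDENTARY_CPM_THRESHOLD = 100.0    # axis-1 counts/min-equivalent


class InputError(ValueError):
    """Raised for invalid feature-engineering inputs."""


class TimetableError(ValueError):
    """Raised when a timetable does not tile the minutes it must label."""


@dataclass(frozen=True)
class CatalogueEntry:
    name: str
    source: str           # gps | accel | hr | time
    description: str


@dataclass(frozen=True)
class FeatureCatalogue:
    """Ordered, versioned list of predictor definitions."""

    entries: tuple[CatalogueEntry, ...]
    version: str = "tripsense-catalogue-1"

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    def names_by_source(self, source: str) -> list[str]:
        return [e.name for e in self.entries if e.source == source]

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for e in self.entries:
            out[e.source] = out.get(e.source, 0) + 1
        return out

    def feature_set(self, name: str) -> list[str]:
        """Predictor names for a model feature set (with/without HR)."""
        if name == "with_hr":
            return self.names
        if name == "without_hr":
            return [e.name for e in self.entries if e.source != "hr"]
        raise InputError(f"unknown feature set {name!r}")


def default_catalogue() -> FeatureCatalogue:
    entries: list[CatalogueEntry] = []
    for sig in GPS_SIGNALS:
        for st in STATS:
            entries.append(CatalogueEntry(
                f"gps_{sig}_{st}", "gps", f"{st} of {sig} over valid fixes"))
    entries.append(CatalogueEntry(
        "gps_n_valid_fixes", "gps", "fixes passing the DOP quality filter"))
    entries.append(CatalogueEntry(
        "gps_frac_valid", "gps", "fraction of raw fixes passing the filter"))
    for variant in ("std", "lfe"):
        for sig in ("vm", "mets"):
            for st in STATS:
                entries.append(CatalogueEntry(
                    f"acc_{variant}_{sig}_{st}", "accel",
                    f"{st} of epoch {sig} ({variant} filter)"))
        entries.append(CatalogueEntry(
            f"acc_{variant}_steps_sum", "accel",
            f"steps in the minute ({variant} filter)"))
        entries.append(CatalogueEntry(
            f"acc_{variant}_mvpa_epochs", "accel",
            f"epochs at >= {MVPA_METS_THRESHOLD} METs ({variant})"))
        entries.append(CatalogueEntry(
            f"acc_{variant}_sedentary_epochs", "accel",
            f"epochs below {SEDENTARY_CPM_THRESHOLD:.0f} axis-1 cpm ({variant})"))
    for axis in (1, 2, 3):
        for st in STATS:
            entries.append(CatalogueEntry(
                f"acc_std_axis{axis}_{st}", "accel",
                f"{st} of axis-{axis} counts (standard filter)"))
    for name in HR_FEATURES:
        entries.append(CatalogueEntry(
            f"hr_{name}", "hr", f"minute-level HRV statistic {name}"))
    entries.append(CatalogueEntry(
        "time_of_day", "time", "minutes since midnight (0-1439)"))
    entries.append(CatalogueEntry(
        "weekend", "time", "1 on Saturday/Sunday, else 0"))
    return FeatureCatalogue(entries=tuple(entries))


def summarize7(values) -> dict[str, float]:
    """Seven summary statistics of a 1-D sample.

    SD is the sample standard deviation (n - 1 denominator; undefined
    for a single value); percentiles use linear interpolation between
    order statistics. An empty input yields all-missing output.
    """
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if x.size == 0:
        return {st: np.nan for st in STATS}
    return {
        "mean": float(np.mean(x)),
        "median": float(np.median(x)),
        "sd": float(np.std(x, ddof=1)) if x.size > 1 else np.nan,
        "min": float(np.min(x)),
        "max": float(np.max(x)),
        "p10": float(np.percentile(x, 10)),
        "p90": float(np.percentile(x, 90)),
    }


def filter_gps_quality(fixes: pd.DataFrame) -> pd.DataFrame:
    """Keep fixes with HDOP < 6, VDOP < 7 and PDOP < 8 (all strict)."""
    if fixes.empty:
        return fixes
    mask = (fixes["hdop"] < 6) & (fixes["vdop"] < 7) & (fixes["pdop"] < 8)
    return fixes[mask]


def _grouped_summarize7(df: pd.DataFrame, value_cols: list[str],
                        prefix: str) -> pd.DataFrame:
    """Wide per-(participant, minute) frame of the seven statistics."""
    gb = df.groupby(["participant_id", "minute"], sort=True, observed=True)
    agg = gb[value_cols].agg(["mean", "median", "std", "min", "max"])
    q = gb[value_cols].quantile([0.10, 0.90]).unstack(level=-1)
    out = {}
    for col in value_cols:
        out[f"{prefix}{col}_mean"] = agg[(col, "mean")]
        out[f"{prefix}{col}_median"] = agg[(col, "median")]
        out[f"{prefix}{col}_sd"] = agg[(col, "std")]
        out[f"{prefix}{col}_min"] = agg[(col, "min")]
        out[f"{prefix}{col}_max"] = agg[(col, "max")]
        out[f"{prefix}{col}_p10"] = q[(col, 0.10)]
        out[f"{prefix}{col}_p90"] = q[(col, 0.90)]
    return pd.DataFrame(out)


def _with_minute(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    df["minute"] = (df["t_s"] // 60).astype(np.int64)
    return df


def gps_minute_features(fixes: pd.DataFrame) -> pd.DataFrame:
    """Per-minute GPS feature table (51 columns).

    Input: raw fixes with participant_id, t_s and the GPS signals. The
    DOP quality filter is applied here; minutes whose fixes all fail the
    filter produce no row (the GPS sensor is treated as absent).
    """
    if fixes.empty:
        return pd.DataFrame()
    raw = _with_minute(fixes)
    n_raw = raw.groupby(["participant_id", "minute"], observed=True
                        ).size().rename("n_raw")
    valid = filter_gps_quality(raw)
    if valid.empty:
        return pd.DataFrame()
    out = _grouped_summarize7(valid, list(GPS_SIGNALS), "gps_")
    n_valid = valid.groupby(["participant_id", "minute"], observed=True
                            ).size().rename("gps_n_valid_fixes")
    out["gps_n_valid_fixes"] = n_valid
    out["gps_frac_valid"] = n_valid / n_raw.reindex(n_valid.index)
    return out


def accel_epoch_derivations(epochs: pd.DataFrame,
                            body_weight_kg: float | np.ndarray,
                            ) -> pd.DataFrame:
    """Per-epoch derived accelerometer quantities.

    vector-magnitude counts, METs (affine in counts/min; 5-s epoch
    counts are scaled by 12 before applying the equation), kcal/min
    (METs x 3.5 x weight / 200), and MVPA / sedentary flags.
    """
    w = np.asarray(body_weight_kg, dtype=float)
    if np.any(w <= 0):
        raise InputError("body weight must be positive")
    out = epochs.copy()
    vm = np.sqrt(out["counts_axis1"].astype(float) ** 2
                 + out["counts_axis2"].astype(float) ** 2
                 + out["counts_axis3"].astype(float) ** 2)
    epochs_per_min = 60 / 5
    vm_cpm = vm * epochs_per_min
    mets = SASAKI_SLOPE * vm_cpm + SASAKI_INTERCEPT
    out["vm_counts"] = vm
    out["mets"] = mets
    out["kcal_min"] = mets * 3.5 * w / 200.0
    out["mvpa_flag"] = mets >= MVPA_METS_THRESHOLD
    out["sedentary_flag"] = (
        out["counts_axis1"].astype(float) * epochs_per_min
        < SEDENTARY_CPM_THRESHOLD)
    return out


def accel_minute_features(epochs: pd.DataFrame,
                          body_weights: pd.Series | float,
                          ) -> pd.DataFrame:
    """Per-minute accelerometer feature table (55 columns).

    ``body_weights`` maps participant_id to weight in kg (or one scalar
    for all). A minute needs epochs under both filter variants to count
    as accelerometer-present.
    """
    if epochs.empty:
        return pd.DataFrame()
    df = _with_minute(epochs)
    if isinstance(body_weights, pd.Series):
        w = df["participant_id"].map(body_weights).to_numpy()
        if np.isnan(w.astype(float)).any():
            raise InputError("missing body weight for some participants")
    else:
        w = float(body_weights)
    df = accel_epoch_derivations(df, w)

    parts = []
    for variant, tag in (("standard", "std"), ("lfe", "lfe")):
        sub = df[df["filter_variant"] == variant]
        if sub.empty:
            continue
        block = _grouped_summarize7(sub, ["vm_counts", "mets"], f"acc_{tag}_")
        block.columns = [c.replace("vm_counts", "vm") for c in block.columns]
        gb = sub.groupby(["participant_id", "minute"], observed=True)
        block[f"acc_{tag}_steps_sum"] = gb["steps"].sum()
        block[f"acc_{tag}_mvpa_epochs"] = gb["mvpa_flag"].sum()
        block[f"acc_{tag}_sedentary_epochs"] = gb["sedentary_flag"].sum()
        if variant == "standard":
            ax = _grouped_summarize7(
                sub, ["counts_axis1", "counts_axis2", "counts_axis3"],
                "acc_std_")
            ax.columns = [c.replace("counts_axis", "axis") for c in ax.columns]
            block = block.join(ax)
        parts.append(block)
    if len(parts) < 2:
        return pd.DataFrame()            # both variants required
    return parts[0].join(parts[1], how="inner")


def hrv_minute_features(rr: pd.DataFrame) -> pd.DataFrame:
    """Per-minute time-domain HRV feature table (12 columns).

    Within each minute: mean/median RR, SDNN (sample SD of intervals),
    RMSSD (root mean square of successive differences), SDSD (SD of
    successive differences), pNN50 (fraction of successive differences
    exceeding 50 ms in absolute value), the coefficient of variation of
    RR, per-beat heart-rate statistics (60000 / RR), and the beat count.
    Minutes with fewer than 3 intervals get missing variability measures.
    """
    if rr.empty:
        return pd.DataFrame()
    if (rr["rr_ms"] <= 0).any():
        raise InputError("RR intervals must be positive")
    df = _with_minute(rr).sort_values(["participant_id", "t_s"], kind="stable")
    df["hr"] = 60_000.0 / df["rr_ms"]
    d = df["rr_ms"].diff()
    same = (df["participant_id"] == df["participant_id"].shift()) \
        & (df["minute"] == df["minute"].shift())
    df["succ_diff"] = d.where(same)

    gb = df.groupby(["participant_id", "minute"], observed=True)
    out = pd.DataFrame({
        "hr_mean_rr": gb["rr_ms"].mean(),
        "hr_median_rr": gb["rr_ms"].median(),
        "hr_sdnn": gb["rr_ms"].std(),
        "hr_mean_hr": gb["hr"].mean(),
        "hr_sd_hr": gb["hr"].std(),
        "hr_min_hr": gb["hr"].min(),
        "hr_max_hr": gb["hr"].max(),
        "hr_n_beats": gb["rr_ms"].size(),
    })
    sd = gb["succ_diff"]
    out["hr_rmssd"] = sd.apply(lambda s: float(np.sqrt(np.nanmean(s ** 2)))
                               if s.notna().any() else np.nan)
    out["hr_sdsd"] = sd.std()
    out["hr_pnn50"] = sd.apply(
        lambda s: float((s.dropna().abs() > 50).mean())
        if s.notna().any() else np.nan)
    out["hr_cv_rr"] = out["hr_sdnn"] / out["hr_mean_rr"]

    few = out["hr_n_beats"] < 3
    out.loc[few, ["hr_sdnn", "hr_rmssd", "hr_sdsd", "hr_pnn50",
                  "hr_cv_rr", "hr_sd_hr"]] = np.nan
    return out[[f"hr_{n}" for n in HR_FEATURES]]


def time_features(timestamps: pd.Series) -> pd.DataFrame:
    """Minutes since midnight (0-1439) and a weekend flag."""
    ts = pd.to_datetime(timestamps)
    return pd.DataFrame({
        "time_of_day": ts.dt.hour * 60 + ts.dt.minute,
        "weekend": (ts.dt.dayofweek >= 5).astype(int),
    })


def assign_minute_labels(timetable: pd.DataFrame, participant_id: str,
                         minutes: np.ndarray) -> np.ndarray:
    """True mode per minute by the majority-overlap rule.

    Episode boundaries may fall inside a minute (start/end in fractional
    minutes); the minute takes the mode of the episode with the largest
    overlap, ties going to the earlier episode. Raises if some queried
    minute is not covered at all.
    """
    tt = timetable[timetable["participant_id"] == participant_id]
    tt = tt.sort_values("start_minute", kind="stable")
    minutes = np.asarray(minutes, dtype=np.int64)
    if minutes.size == 0:
        return np.empty(0, dtype=object)
    lo, hi = minutes.min(), minutes.max() + 1
    best = np.zeros(hi - lo)
    label = np.full(hi - lo, -1, dtype=np.int64)
    mode_code = {m: i for i, m in enumerate(MODES)}
    for start, end, mode in zip(tt["start_minute"], tt["end_minute"],
                                tt["mode"]):
        m0 = max(int(np.floor(start)), lo)
        m1 = min(int(np.ceil(end)), hi)
        if m1 <= m0:
            continue
        idx = np.arange(m0, m1)
        overlap = np.minimum(end, idx + 1) - np.maximum(start, idx)
        sel = overlap > best[idx - lo]     # strict: ties keep earlier episode
        label[idx[sel] - lo] = mode_code[mode]
        best[idx[sel] - lo] = overlap[sel]
    codes = label[minutes - lo]
    if (codes < 0).any():
        missing = minutes[codes < 0][:5]
        raise TimetableError(
            f"{participant_id}: minutes not covered by any episode "
            f"(e.g. {missing.tolist()}); the timetable must tile follow-up")
    return np.asarray(MODES, dtype=object)[codes]


def build_minute_dataset(gps: pd.DataFrame, accel: pd.DataFrame,
                         rr: pd.DataFrame, timetable: pd.DataFrame,
                         participants: pd.DataFrame,
                         catalogue: FeatureCatalogue | None = None,
                         ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Merge the three per-minute feature tables into the labelled
    minute-level dataset.

    Only minutes with all three sensors present are retained (an inner
    merge); the returned accounting dict reports per-sensor minute
    counts and how many observations the merge removed.

    Returns a frame with participant_id, minute, timestamp, label and
    the feature columns in catalogue order.
    """
    catalogue = catalogue or default_catalogue()
    gf = gps_minute_features(gps)
    af = accel_minute_features(
        accel, participants.set_index("participant_id")["weight_kg"])
    hf = hrv_minute_features(rr)

    accounting = {
        "gps_minutes": len(gf), "accel_minutes": len(af),
        "hr_minutes": len(hf),
    }
    if len(gf) == 0 or len(af) == 0 or len(hf) == 0:
        accounting["merged_minutes"] = 0
        accounting["removed_minutes"] = (len(gf) + len(af) + len(hf))
        return pd.DataFrame(), accounting

    merged = gf.join(af, how="inner").join(hf, how="inner")
    accounting["merged_minutes"] = len(merged)
    accounting["removed_minutes"] = (
        len(gf) + len(af) + len(hf) - 3 * len(merged))

    merged = merged.reset_index()
    start_dates = participants.set_index("participant_id")["start_date"]
    ts = (pd.to_datetime(merged["participant_id"].map(start_dates))
          + pd.to_timedelta(merged["minute"], unit="min"))
    tf = time_features(ts)
    merged["timestamp"] = ts
    merged["time_of_day"] = tf["time_of_day"].to_numpy()
    merged["weekend"] = tf["weekend"].to_numpy()

    labels = np.empty(len(merged), dtype=object)
    for pid, grp in merged.groupby("participant_id", sort=False):
        labels[grp.index.to_numpy()] = assign_minute_labels(
            timetable, pid, grp["minute"].to_numpy())
    merged["label"] = labels

    cols = ["participant_id", "minute", "timestamp", "label"] + catalogue.names
    missing_cols = [c for c in cols if c not in merged.columns]
    if missing_cols:
        raise InputError(f"feature columns missing from build: {missing_cols}")
    return merged[cols], accounting
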