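"""Feature engineering: quality filter, summary statistics, per-sensor
minute features, labelling and the merged dataset."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tripsense.features import (
    SASAKI_INTERCEPT,
    SASAKI_SLOPE,
    STATS,
    InputError,
    TimetableError,
    accel_epoch_derivations,
    accel_minute_features,
    assign_minute_labels,
    build_minute_dataset,
    default_catalogue,
    filter_gps_quality,
    gps_minute_features,
    hrv_minute_features,
    summarize7,
    time_features,
)


def brute_force_summary7(values):
    """Independent re-derivation: sort-based percentile with linear
    interpolation between order statistics, explicit sample SD."""
    x = sorted(values)
    n = len(x)

    def pct(q):
        h = (n - 1) * q
        lo = int(np.floor(h))
        hi = min(lo + 1, n - 1)
        return x[lo] + (h - lo) * (x[hi] - x[lo])

    mean = sum(x) / n
    sd = (sum((v - mean) ** 2 for v in x) / (n - 1)) ** 0.5 \
        if n > 1 else float("nan")
    return {"mean": mean, "median": pct(0.5), "sd": sd, "min": x[0],
            "max": x[-1], "p10": pct(0.10), "p90": pct(0.90)}


class TestGpsQualityFilter:
    @pytest.mark.parametrize("hdop,vdop,pdop,kept", [
        (5.9, 6.9, 7.9, True),    # just inside every threshold
        (6.0, 1.0, 1.0, False),   # HDOP at the threshold is excluded
        (1.0, 7.0, 1.0, False),
        (1.0, 1.0, 8.0, False),
        (1.0, 1.0, 1.0, True),
    ])
    def test_strict_threshold_rule(self, hdop, vdop, pdop, kept):
        fixes = pd.DataFrame({"hdop": [hdop], "vdop": [vdop],
                              "pdop": [pdop]})
        assert (len(filter_gps_quality(fixes)) == 1) is kept

    def test_empty_stream_passes_through(self):
        empty = pd.DataFrame(columns=["hdop", "vdop", "pdop"])
        assert filter_gps_quality(empty).empty

    def test_order_preserved(self):
        fixes = pd.DataFrame({"hdop": [1, 9, 2], "vdop": [1, 1, 1],
                              "pdop": [1, 1, 1], "tag": ["a", "b", "c"]})
        assert filter_gps_quality(fixes)["tag"].tolist() == ["a", "c"]


class TestSummarize7:
    def test_constant_input(self):
        s = summarize7([5, 5, 5])
        for stat in ("mean", "median", "min", "max", "p10", "p90"):
            assert s[stat] == 5
        assert s["sd"] == 0

    def test_two_point_sample_sd(self):
        s = summarize7([0, 10])
        assert s["mean"] == 5
        assert s["sd"] == pytest.approx(7.0711, abs=1e-4)

    def test_percentiles_match_interpolation_oracle(self):
        s = summarize7(list(range(1, 11)))
        oracle = brute_force_summary7(list(range(1, 11)))
        assert s["p10"] == pytest.approx(oracle["p10"])
        assert s["p90"] == pytest.approx(oracle["p90"])

    def test_empty_input_all_missing(self):
        assert all(np.isnan(v) for v in summarize7([]).values())

    @settings(max_examples=60, deadline=None)
    @given(st.lists(st.floats(-1e6, 1e6, allow_nan=False), min_size=2,
                    max_size=40))
    def test_matches_brute_force_oracle(self, values):
        s = summarize7(values)
        oracle = brute_force_summary7(values)
        for stat in STATS:
            assert s[stat] == pytest.approx(oracle[stat], rel=1e-9,
                                            abs=1e-6)


class TestCatalogue:
    def test_group_sizes_match_design(self, catalogue):
        assert catalogue.counts() == {"gps": 51, "accel": 55, "hr": 12,
                                      "time": 2}

    def test_names_unique_and_ordered_deterministically(self, catalogue):
        names = catalogue.names
        assert len(names) == len(set(names)) == 120
        assert names == default_catalogue().names

    def test_feature_sets(self, catalogue):
        assert len(catalogue.feature_set("with_hr")) == 120
        without = catalogue.feature_set("without_hr")
        assert len(without) == 108
        assert not any(n.startswith("hr_") for n in without)
        with pytest.raises(InputError):
            catalogue.feature_set("bogus")


def _fix_frame(n, minute=0, **overrides):
    base = {"participant_id": "p0",
            "t_s": minute * 60.0 + 5.0 * np.arange(n),
            "lat": 48.85, "lon": 2.35, "elevation": 50.0, "speed": 5.0,
            "hdop": 1.0, "vdop": 1.5, "pdop": 1.8,
            "sat_in_view": 10, "sat_used": 8}
    base.update(overrides)
    return pd.DataFrame(base)


class TestGpsMinuteFeatures:
    def test_identical_fixes(self):
        out = gps_minute_features(_fix_frame(12))
        row = out.loc[("p0", 0)]
        for stat in ("mean", "median", "min", "max", "p10", "p90"):
            assert row[f"gps_speed_{stat}"] == 5.0
        assert row["gps_speed_sd"] == 0.0
        assert row["gps_n_valid_fixes"] == 12
        assert row["gps_frac_valid"] == 1.0

    def test_fraction_passing_filter(self):
        fixes = _fix_frame(10)
        fixes.loc[fixes.index[:2], "hdop"] = 9.0   # 2 of 10 fail
        row = gps_minute_features(fixes).loc[("p0", 0)]
        assert row["gps_n_valid_fixes"] == 8
        assert row["gps_frac_valid"] == pytest.approx(0.8)

    def test_minute_with_no_valid_fix_absent(self):
        fixes = _fix_frame(10, hdop=9.0)
        assert gps_minute_features(fixes).empty


class TestAccelDerivations:
    def test_zero_counts_gives_equation_intercept(self):
        epochs = pd.DataFrame({"counts_axis1": [0], "counts_axis2": [0],
                               "counts_axis3": [0], "steps": [0]})
        out = accel_epoch_derivations(epochs, 75.0)
        assert out["mets"].iloc[0] == pytest.approx(0.668876)
        assert bool(out["sedentary_flag"].iloc[0])
        assert not bool(out["mvpa_flag"].iloc[0])

    def test_mvpa_boundary_is_inclusive(self):
        # counts/min solving METs = 3 exactly -> per-epoch vm counts
        vm_cpm = (3.0 - SASAKI_INTERCEPT) / SASAKI_SLOPE
        per_epoch = vm_cpm / 12.0
        epochs = pd.DataFrame({"counts_axis1": [per_epoch],
                               "counts_axis2": [0.0],
                               "counts_axis3": [0.0], "steps": [0]})
        out = accel_epoch_derivations(epochs, 75.0)
        assert out["mets"].iloc[0] == pytest.approx(3.0)
        assert bool(out["mvpa_flag"].iloc[0])

    def test_kcal_identity(self):
        # METs = 1 at weight 200/3.5 kg burns exactly 1 kcal/min
        epochs = pd.DataFrame({"counts_axis1": [0], "counts_axis2": [0],
                               "counts_axis3": [0], "steps": [0]})
        out = accel_epoch_derivations(epochs, 200.0 / 3.5)
        expected = out["mets"].iloc[0]   # kcal/min == mets at this weight
        assert out["kcal_min"].iloc[0] == pytest.approx(expected)

    def test_nonpositive_weight_rejected(self):
        epochs = pd.DataFrame({"counts_axis1": [0], "counts_axis2": [0],
                               "counts_axis3": [0], "steps": [0]})
        with pytest.raises(InputError):
            accel_epoch_derivations(epochs, 0.0)

    def test_mets_monotone_in_vm_counts(self, rng):
        counts = np.sort(rng.integers(0, 3000, 50))
        epochs = pd.DataFrame({"counts_axis1": counts,
                               "counts_axis2": 0, "counts_axis3": 0,
                               "steps": 0})
        mets = accel_epoch_derivations(epochs, 75.0)["mets"]
        assert (np.diff(mets) >= 0).all()


def _epoch_frame(n=12, minute=0, variant="standard", a1=100, steps=2):
    return pd.DataFrame({
        "participant_id": "p0",
        "t_s": minute * 60.0 + 5.0 * np.arange(n),
        "filter_variant": variant,
        "counts_axis1": a1, "counts_axis2": 50, "counts_axis3": 30,
        "steps": steps,
    })


class TestAccelMinuteFeatures:
    def test_steps_sum_and_flag_counts(self):
        both = pd.concat([_epoch_frame(variant="standard"),
                          _epoch_frame(variant="lfe")], ignore_index=True)
        out = accel_minute_features(both, 75.0)
        row = out.loc[("p0", 0)]
        assert row["acc_std_steps_sum"] == 24
        assert row["acc_lfe_steps_sum"] == 24
        # axis1 = 100/epoch -> 1200 cpm: not sedentary, and
        # vm ~ 115.8 -> 1390 cpm -> 1.87 METs: no MVPA either
        assert row["acc_std_sedentary_epochs"] == 0
        assert row["acc_std_mvpa_epochs"] == 0

    def test_all_sedentary_minute(self):
        both = pd.concat([_epoch_frame(a1=0, steps=0),
                          _epoch_frame(a1=0, steps=0, variant="lfe")],
                         ignore_index=True)
        row = accel_minute_features(both, 75.0).loc[("p0", 0)]
        assert row["acc_std_sedentary_epochs"] == 12
        assert row["acc_std_mvpa_epochs"] == 0

    def test_minute_needs_both_variants(self):
        only_std = _epoch_frame(variant="standard")
        assert accel_minute_features(only_std, 75.0).empty

    def test_column_count_is_55(self, tiny_cohort):
        out = accel_minute_features(
            tiny_cohort.accel.head(5000),
            tiny_cohort.participants.set_index("participant_id")
            ["weight_kg"])
        assert out.shape[1] == 55


class TestHrvMinuteFeatures:
    def test_constant_rr(self):
        rr = pd.DataFrame({"participant_id": "p0",
                           "t_s": 1.0 + np.arange(10),
                           "rr_ms": 1000.0})
        row = hrv_minute_features(rr).loc[("p0", 0)]
        assert row["hr_mean_hr"] == pytest.approx(60.0)
        assert row["hr_sdnn"] == 0.0
        assert row["hr_rmssd"] == 0.0
        assert row["hr_pnn50"] == 0.0
        assert row["hr_n_beats"] == 10

    def test_rmssd_and_pnn50_hand_example(self):
        rr = pd.DataFrame({"participant_id": "p0", "t_s": [1.0, 2.0, 3.0],
                           "rr_ms": [1000.0, 900.0, 1000.0]})
        row = hrv_minute_features(rr).loc[("p0", 0)]
        # successive diffs -100, +100 -> RMSSD 100, both > 50 ms
        assert row["hr_rmssd"] == pytest.approx(100.0)
        assert row["hr_pnn50"] == pytest.approx(1.0)

    def test_few_beats_missing_variability(self):
        rr = pd.DataFrame({"participant_id": "p0", "t_s": [1.0, 2.0],
                           "rr_ms": [800.0, 820.0]})
        row = hrv_minute_features(rr).loc[("p0", 0)]
        assert np.isnan(row["hr_sdnn"])
        assert np.isnan(row["hr_rmssd"])
        assert row["hr_n_beats"] == 2
        assert row["hr_mean_rr"] == pytest.approx(810.0)

    def test_nonpositive_rr_rejected(self):
        rr = pd.DataFrame({"participant_id": "p0", "t_s": [1.0],
                           "rr_ms": [0.0]})
        with pytest.raises(InputError):
            hrv_minute_features(rr)

    def test_successive_diffs_do_not_cross_minutes(self):
        # one beat at the end of minute 0, rest in minute 1: the jump
        # between minutes must not enter minute 1's variability
        rr = pd.DataFrame({"participant_id": "p0",
                           "t_s": [59.0, 61.0, 62.0, 63.0, 64.0],
                           "rr_ms": [500.0, 1000.0, 1000.0, 1000.0,
                                     1000.0]})
        out = hrv_minute_features(rr)
        assert out.loc[("p0", 1), "hr_rmssd"] == pytest.approx(0.0)


class TestTimeFeatures:
    @pytest.mark.parametrize("ts,tod,weekend", [
        ("2015-03-07 00:00", 0, 1),       # Saturday midnight
        ("2015-03-04 12:30", 750, 0),     # Wednesday
        ("2015-03-04 23:59", 1439, 0),    # last minute of the day
        ("2015-03-08 10:00", 600, 1),     # Sunday
    ])
    def test_examples(self, ts, tod, weekend):
        out = time_features(pd.Series([pd.Timestamp(ts)]))
        assert out["time_of_day"].iloc[0] == tod
        assert out["weekend"].iloc[0] == weekend


class TestLabelAssignment:
    def test_majority_overlap_at_fractional_boundary(self):
        # walk until second 40 of minute 2, then activity place:
        # 40 s overlap beats 20 s
        tt = pd.DataFrame({
            "participant_id": ["p0", "p0"],
            "start_minute": [0.0, 2 + 40 / 60],
            "end_minute": [2 + 40 / 60, 10.0],
            "mode": ["walk", "activity_place"],
        })
        labels = assign_minute_labels(tt, "p0", np.array([0, 1, 2, 3]))
        assert labels.tolist() == ["walk", "walk", "walk",
                                   "activity_place"]

    def test_exact_half_overlap_keeps_earlier_episode(self):
        tt = pd.DataFrame({
            "participant_id": ["p0", "p0"],
            "start_minute": [0.0, 1.5],
            "end_minute": [1.5, 3.0],
            "mode": ["walk", "bike"],
        })
        labels = assign_minute_labels(tt, "p0", np.array([1]))
        assert labels.tolist() == ["walk"]

    def test_uncovered_minute_raises(self):
        tt = pd.DataFrame({"participant_id": ["p0"], "start_minute": [0],
                           "end_minute": [10], "mode": ["walk"]})
        with pytest.raises(TimetableError):
            assign_minute_labels(tt, "p0", np.array([5, 20]))


class TestBuildMinuteDataset:
    def test_merged_rows_have_all_sensors_and_labels(self, tiny_cohort,
                                                     tiny_minutes,
                                                     catalogue):
        assert set(tiny_minutes.columns) == set(
            ["participant_id", "minute", "timestamp", "label"]
            + catalogue.names)
        assert tiny_minutes["label"].notna().all()
        # every merged minute must exist in all three sensor streams
        gps_minutes = set(map(tuple, pd.DataFrame({
            "p": tiny_cohort.gps["participant_id"],
            "m": (tiny_cohort.gps["t_s"] // 60).astype(int)})
            .drop_duplicates().to_numpy()))
        got = set(map(tuple,
                      tiny_minutes[["participant_id", "minute"]]
                      .to_numpy()))
        assert got <= gps_minutes

    def test_minute_missing_one_sensor_is_dropped(self, tiny_cohort):
        rr = tiny_cohort.rr
        key = rr.iloc[0]["participant_id"], int(rr.iloc[0]["t_s"] // 60)
        trimmed = rr[~((rr["participant_id"] == key[0])
                       & ((rr["t_s"] // 60).astype(int) == key[1]))]
        minutes, _ = build_minute_dataset(
            tiny_cohort.gps, tiny_cohort.accel, trimmed,
            tiny_cohort.timetable, tiny_cohort.participants)
        assert not ((minutes["participant_id"] == key[0])
                    & (minutes["minute"] == key[1])).any()

    def test_accounting_consistency(self, tiny_cohort):
        _, acc = build_minute_dataset(
            tiny_cohort.gps, tiny_cohort.accel, tiny_cohort.rr,
            tiny_cohort.timetable, tiny_cohort.participants)
        assert acc["merged_minutes"] <= min(
            acc["gps_minutes"], acc["accel_minutes"], acc["hr_minutes"])
        assert acc["removed_minutes"] == (
            acc["gps_minutes"] + acc["accel_minutes"] + acc["hr_minutes"]
            - 3 * acc["merged_minutes"])
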