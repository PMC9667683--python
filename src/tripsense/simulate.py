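"""Synthetic multi-sensor cohort generator.

Produces, for each participant, a ground-truth timetable of labelled
episodes (activity places alternating with trips made of one or more
single-mode stages) plus three raw sensor streams covering the worn
minutes: GPS fixes every few seconds, tri-axial accelerometer counts in
5-second epochs under two filter variants, and beat-to-beat RR intervals.

The generator reproduces the statistical structure the downstream
analysis assumes rather than street-level realism: mode-specific speed,
count, step and heart-rate signatures; degraded dilution-of-precision
(DOP) values and satellite counts during underground public transport;
Gaussian participant-level random effects (resting heart rate, walking
speed, count intensity) that make minutes from the same participant more
alike than minutes from different participants; and wear gaps from a
nightly removal window plus per-sensor random dropout.

Everything is driven by one master seed through `numpy.random.SeedSequence`
spawning, so identical configurations yield byte-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import (
    MINUTES_PER_DAY,
    MODES,
    TRANSPORT_MODES,
    ConfigurationError,
    ModeSignature,
    SimConfig,
)

#: Follow-up start for participant 0; a Monday, so staggered starts cover
#: every weekday and weekend day across a cohort.
BASE_START_DATE = pd.Timestamp("2015-03-02 00:00:00")

_EARTH_M_PER_DEG = 111_320.0


@dataclass
class ParticipantEffects:
    """Participant-level random effects drawn once per participant."""

    resting_hr: float        # bpm
    walk_speed_shift: float  # km/h, added to the walking speed signature
    count_mult: float        # multiplicative effect on accelerometer counts
    weight_kg: float


@dataclass
class Episode:
    """Half-open labelled time span [start_minute, end_minute)."""

    participant_id: str
    start_minute: int
    end_minute: int
    mode: str
    underground: bool = False

    @property
    def duration(self) -> int:
        return self.end_minute - self.start_minute


@dataclass
class Cohort:
    """In-memory synthetic cohort: one row per record, long format.

    Streams carry ``t_s`` (seconds since the participant's follow-up
    start); calendar timestamps are recovered through ``participants``
    (``start_date`` column) when writing CSV files.
    """

    participants: pd.DataFrame
    timetable: pd.DataFrame
    gps: pd.DataFrame
    accel: pd.DataFrame
    rr: pd.DataFrame
    config: SimConfig


def draw_participant_effects(config: SimConfig, rng: np.random.Generator
                             ) -> ParticipantEffects:
    het = config.participant_heterogeneity
    rest_hr = 60_000.0 / config.rr_rest_ms + het.sd_resting_hr * rng.standard_normal()
    return ParticipantEffects(
        resting_hr=float(np.clip(rest_hr, 40.0, 110.0)),
        walk_speed_shift=float(het.sd_walk_speed * rng.standard_normal()),
        count_mult=float(np.exp(het.sd_log_counts * rng.standard_normal())),
        weight_kg=float(np.clip(
            rng.normal(config.body_weight_mean_kg, config.body_weight_sd_kg),
            45.0, 130.0)),
    )


def _sample_stage_modes(n_stages: int, config: SimConfig,
                        rng: np.random.Generator) -> list[str]:
    """Modes for consecutive stages of one trip; adjacent stages differ
    (a stage is a maximal single-mode segment)."""
    modes_order = list(TRANSPORT_MODES)
    probs = np.array([config.mode_mix[m] for m in modes_order])
    out: list[str] = []
    for _ in range(n_stages):
        mode = modes_order[rng.choice(len(modes_order), p=probs)]
        while out and mode == out[-1]:
            mode = modes_order[rng.choice(len(modes_order), p=probs)]
        out.append(mode)
    return out


def generate_schedule(config: SimConfig, rng: np.random.Generator,
                      participant_id: str = "p0", day_index: int = 0
                      ) -> list[Episode]:
    """One day's episodes: trips separated by activity-place episodes.

    The daily trip count is Poisson(``trips_per_day``); each trip has
    1 + Poisson(``stages_per_trip`` - 1) stages; stage durations are
    Gamma-distributed with mean chosen so the expected daily transport
    time matches ``time_on_trips_frac``. Episodes tile the whole day;
    every trip is flanked by at least one minute at an activity place.
    """
    day0 = day_index * MINUTES_PER_DAY
    n_trips = int(rng.poisson(config.trips_per_day))

    mean_stage = (config.time_on_trips_frac * MINUTES_PER_DAY
                  / max(config.trips_per_day * config.stages_per_trip, 1e-9))
    mean_stage = max(mean_stage, float(config.min_stage_minutes))

    trips: list[list[tuple[str, int]]] = []
    for _ in range(n_trips):
        n_stages = 1 + int(rng.poisson(max(config.stages_per_trip - 1.0, 0.0)))
        stage_modes = _sample_stage_modes(n_stages, config, rng)
        durs = np.clip(np.round(rng.gamma(2.0, mean_stage / 2.0, n_stages)),
                       config.min_stage_minutes, config.max_stage_minutes
                       ).astype(int)
        trips.append(list(zip(stage_modes, durs.tolist())))

    # Drop trips (rare) until the day can hold them plus >=1-minute gaps.
    def total(tr):
        return sum(d for t in tr for _, d in t)

    while trips and total(trips) > MINUTES_PER_DAY - (len(trips) + 1):
        trips.pop()

    if not trips:
        return [Episode(participant_id, day0, day0 + MINUTES_PER_DAY,
                        "activity_place")]

    # Allocate the remaining minutes to the n_trips + 1 activity-place
    # gaps: Dirichlet weights, each gap at least one minute, integerized
    # so the day is tiled exactly.
    n_gaps = len(trips) + 1
    free = MINUTES_PER_DAY - total(trips)
    w = rng.dirichlet(np.ones(n_gaps))
    raw = 1.0 + w * (free - n_gaps)
    gaps = np.floor(raw).astype(int)
    rem = free - int(gaps.sum())
    order = np.argsort(raw - np.floor(raw))[::-1]
    gaps[order[:rem]] += 1

    episodes: list[Episode] = []
    cursor = day0
    for i, trip in enumerate(trips):
        g = int(gaps[i])
        episodes.append(Episode(participant_id, cursor, cursor + g,
                                "activity_place"))
        cursor += g
        for mode, dur in trip:
            underground = (
                mode == "public_transport"
                and rng.random() < config.metro_gps_degradation.underground_prob)
            episodes.append(Episode(participant_id, cursor, cursor + dur,
                                    mode, underground))
            cursor += dur
    episodes.append(Episode(participant_id, cursor, day0 + MINUTES_PER_DAY,
                            "activity_place"))
    assert cursor < day0 + MINUTES_PER_DAY
    return episodes


def _wear_masks(config: SimConfig, n_minutes: int,
                rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Per-sensor boolean wear mask over follow-up minutes.

    All devices come off during the nightly sleep window; during wake,
    each sensor independently drops whole minutes at its configured rate.
    """
    hour = (np.arange(n_minutes) % MINUTES_PER_DAY) // 60
    lo, hi = config.sleep_end_hour, config.sleep_start_hour
    if lo < hi:
        awake = (hour >= lo) & (hour < hi)
    else:  # sleep window does not span midnight
        awake = (hour >= lo) | (hour < hi)
    return {
        sensor: awake & (rng.random(n_minutes) >= rate)
        for sensor, rate in config.wear_gap_rate.items()
    }


def simulate_gps(episode: Episode, signature: ModeSignature,
                 effects: ParticipantEffects, rng: np.random.Generator,
                 config: SimConfig, minutes: np.ndarray | None = None,
                 origin: tuple[float, float] = (48.85, 2.35),
                 ) -> dict[str, np.ndarray]:
    """GPS fixes for one episode (restricted to ``minutes`` if given).

    Speeds follow the mode signature with a between-minute level (stops,
    traffic) plus per-fix jitter. Underground public transport inflates
    horizontal/vertical DOP by the configured factor and collapses
    satellite counts; PDOP is derived as sqrt(HDOP^2 + VDOP^2).
    """
    if minutes is None:
        minutes = np.arange(episode.start_minute, episode.end_minute)
    minutes = np.asarray(minutes, dtype=np.int64)
    n_min = minutes.size
    fpm = 60 // config.gps_interval_s
    n = n_min * fpm
    if n == 0:
        return {k: np.empty(0) for k in
                ("t_s", "lat", "lon", "elevation", "speed",
                 "hdop", "vdop", "pdop", "sat_in_view", "sat_used")}

    mu = signature.speed_kmh
    if episode.mode == "walk":
        mu = max(mu + effects.walk_speed_shift, 0.5)
    level = np.maximum(mu + signature.speed_minute_sd * rng.standard_normal(n_min), 0.0)
    speed = np.maximum(np.repeat(level, fpm)
                       + signature.speed_fix_sd * rng.standard_normal(n), 0.0)
    if signature.speed_cap_kmh is not None:
        speed = np.minimum(speed, signature.speed_cap_kmh)

    deg = config.metro_gps_degradation
    hdop_min = np.exp(rng.normal(0.18, 0.30, n_min))
    vdop_min = hdop_min * np.exp(rng.normal(0.35, 0.20, n_min))
    if episode.underground:
        hdop_min *= deg.dop_factor
        vdop_min *= deg.dop_factor
    jit = np.exp(rng.normal(0.0, 0.08, n))
    hdop = np.repeat(hdop_min, fpm) * jit
    vdop = np.repeat(vdop_min, fpm) * jit
    pdop = np.hypot(hdop, vdop)

    if episode.underground:
        sat_in_view = 1 + rng.poisson(deg.sat_in_view_mean_degraded, n)
        used_frac = deg.sat_used_frac_degraded
    else:
        sat_in_view = 1 + rng.poisson(10.0, n)
        used_frac = 0.85
    sat_used = rng.binomial(sat_in_view, used_frac)

    elevation = (50.0 + 10.0 * rng.standard_normal(n_min)).repeat(fpm) \
        + rng.normal(0.0, 2.0, n)

    # Random-walk coordinates consistent with speed (carried through the
    # pipeline but not summarized as predictors).
    heading = np.cumsum(rng.normal(0.0, 0.4, n))
    step_m = speed / 3.6 * config.gps_interval_s
    lat0 = origin[0] + rng.normal(0.0, 0.05)
    lon0 = origin[1] + rng.normal(0.0, 0.07)
    lat = lat0 + np.cumsum(step_m * np.cos(heading)) / _EARTH_M_PER_DEG
    lon = lon0 + np.cumsum(step_m * np.sin(heading)) / (
        _EARTH_M_PER_DEG * np.cos(np.deg2rad(lat0)))

    t_s = (np.repeat(minutes * 60, fpm)
           + np.tile(np.arange(fpm) * config.gps_interval_s, n_min)).astype(float)
    return {"t_s": t_s, "lat": lat, "lon": lon, "elevation": elevation,
            "speed": speed, "hdop": hdop, "vdop": vdop, "pdop": pdop,
            "sat_in_view": sat_in_view.astype(np.int64),
            "sat_used": sat_used.astype(np.int64)}


def simulate_accel(episode: Episode, signature: ModeSignature,
                   effects: ParticipantEffects, rng: np.random.Generator,
                   config: SimConfig, minutes: np.ndarray | None = None,
                   ) -> dict[str, np.ndarray]:
    """5-s accelerometer epochs for one episode, both filter variants.

    A minute-level intensity (log-normal around the mode's counts-per-
    minute signature, scaled by the participant's multiplier) drives
    Poisson per-epoch axis counts. Steps only occur in epochs with
    non-sedentary axis-1 counts. The low-frequency-extension (LFE)
    variant adds non-negative low-intensity counts — largest for
    near-sedentary epochs — so LFE counts dominate standard counts
    epoch-wise by construction.
    """
    if minutes is None:
        minutes = np.arange(episode.start_minute, episode.end_minute)
    minutes = np.asarray(minutes, dtype=np.int64)
    n_min = minutes.size
    epm = 60 // config.epoch_s
    n = n_min * epm
    cols = ("t_s", "filter_variant", "counts_axis1", "counts_axis2",
            "counts_axis3", "steps")
    if n == 0:
        return {k: np.empty(0, dtype=object if k == "filter_variant" else None)
                for k in cols}

    level_cpm = (signature.counts_cpm * effects.count_mult
                 * np.exp(signature.counts_log_sd * rng.standard_normal(n_min)))
    lam1 = np.repeat(level_cpm / epm, epm)
    a1 = rng.poisson(lam1)
    a2 = rng.poisson(0.7 * lam1)
    a3 = rng.poisson(0.5 * lam1)

    steps = rng.poisson(signature.steps_per_min / epm, n)
    # No steps in sedentary epochs (< 100 counts/min-equivalent on axis 1).
    steps[a1 * epm < 100] = 0

    vm = np.sqrt(a1.astype(float) ** 2 + a2 ** 2 + a3 ** 2)
    extra_lam = 25.0 * np.exp(-vm / 150.0) + 1.0
    l1 = a1 + rng.poisson(extra_lam)
    l2 = a2 + rng.poisson(0.5 * extra_lam)
    l3 = a3 + rng.poisson(0.3 * extra_lam)

    t_s = (np.repeat(minutes * 60, epm)
           + np.tile(np.arange(epm) * config.epoch_s, n_min)).astype(float)
    return {
        "t_s": np.concatenate([t_s, t_s]),
        "filter_variant": np.concatenate(
            [np.repeat("standard", n), np.repeat("lfe", n)]),
        "counts_axis1": np.concatenate([a1, l1]).astype(np.int64),
        "counts_axis2": np.concatenate([a2, l2]).astype(np.int64),
        "counts_axis3": np.concatenate([a3, l3]).astype(np.int64),
        "steps": np.concatenate([steps, steps]).astype(np.int64),
    }


def simulate_rr(episode: Episode, signature: ModeSignature,
                effects: ParticipantEffects, rng: np.random.Generator,
                config: SimConfig, minutes: np.ndarray | None = None,
                ) -> dict[str, np.ndarray]:
    """Beat-to-beat RR intervals for one episode.

    Minute-level heart rate = participant resting rate + mode elevation
    + noise; beats within the minute get the matching mean RR interval
    plus beat-to-beat jitter, and timestamps are cumulative so the beats
    approximately conserve the minute's duration.
    """
    if minutes is None:
        minutes = np.arange(episode.start_minute, episode.end_minute)
    minutes = np.asarray(minutes, dtype=np.int64)
    if minutes.size == 0:
        return {"t_s": np.empty(0), "rr_ms": np.empty(0)}

    t_all: list[np.ndarray] = []
    rr_all: list[np.ndarray] = []
    hr_min = (effects.resting_hr + signature.hr_elev_bpm
              + config.hr_minute_sd * rng.standard_normal(minutes.size))
    hr_min = np.clip(hr_min, 35.0, 200.0)
    for m, hr in zip(minutes, hr_min):
        n_beats = max(int(round(hr)), 1)
        mean_rr = 60_000.0 / hr
        rr = mean_rr + config.rr_jitter_ms * rng.standard_normal(n_beats)
        rr = np.maximum(rr, 250.0)
        t = m * 60.0 + np.cumsum(rr) / 1000.0
        keep = t < (m + 1) * 60.0   # beats recorded within the minute window
        t_all.append(t[keep])
        rr_all.append(rr[keep])
    return {"t_s": np.concatenate(t_all), "rr_ms": np.concatenate(rr_all)}


def generate_timetable(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Participants table and ground-truth timetable only (no streams).

    A cheap path for calibration checks on schedule statistics.
    """
    config.validate()
    participants, timetables, _ = _participants_and_schedules(config)
    return participants, timetables


def _participants_and_schedules(config: SimConfig):
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_participants)
    rows = []
    all_eps: list[Episode] = []
    rngs = []
    effects_list = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        pid = f"p{i:03d}"
        eff = draw_participant_effects(config, rng)
        start_date = BASE_START_DATE + pd.Timedelta(days=i % 7)
        rows.append({
            "participant_id": pid, "start_date": start_date,
            "weight_kg": eff.weight_kg, "resting_hr": eff.resting_hr,
            "walk_speed_shift": eff.walk_speed_shift,
            "count_mult": eff.count_mult,
        })
        for day in range(config.n_days):
            all_eps.extend(generate_schedule(config, rng, pid, day))
        rngs.append(rng)
        effects_list.append(eff)
    participants = pd.DataFrame(rows)
    timetable = pd.DataFrame({
        "participant_id": [e.participant_id for e in all_eps],
        "start_minute": [e.start_minute for e in all_eps],
        "end_minute": [e.end_minute for e in all_eps],
        "mode": [e.mode for e in all_eps],
        "underground": [e.underground for e in all_eps],
    })
    return participants, timetable, (rngs, effects_list, all_eps)


def generate_cohort(config: SimConfig) -> Cohort:
    """Full synthetic cohort: timetable plus the three sensor streams.

    Streams cover exactly the episode-tiled minutes minus wear gaps.
    Deterministic: the same config and seed give identical output.
    """
    config.validate()
    participants, timetable, (rngs, effects_list, all_eps) = \
        _participants_and_schedules(config)
    n_minutes = config.n_days * MINUTES_PER_DAY

    by_pid: dict[str, list[Episode]] = {}
    for ep in all_eps:
        by_pid.setdefault(ep.participant_id, []).append(ep)

    gps_parts, acc_parts, rr_parts = [], [], []
    for i, pid in enumerate(participants["participant_id"]):
        rng = rngs[i]
        eff = effects_list[i]
        masks = _wear_masks(config, n_minutes, rng)
        for ep in by_pid[pid]:
            sig = config.mode_signatures[ep.mode]
            span = np.arange(ep.start_minute, ep.end_minute)
            m_gps = span[masks["gps"][span]]
            m_acc = span[masks["accel"][span]]
            m_hr = span[masks["hr"][span]]
            if m_gps.size:
                d = simulate_gps(ep, sig, eff, rng, config, minutes=m_gps)
                d["participant_id"] = np.repeat(pid, d["t_s"].size)
                gps_parts.append(d)
            if m_acc.size:
                d = simulate_accel(ep, sig, eff, rng, config, minutes=m_acc)
                d["participant_id"] = np.repeat(pid, d["t_s"].size)
                acc_parts.append(d)
            if m_hr.size:
                d = simulate_rr(ep, sig, eff, rng, config, minutes=m_hr)
                d["participant_id"] = np.repeat(pid, d["t_s"].size)
                rr_parts.append(d)

    def _concat(parts, columns):
        if not parts:
            return pd.DataFrame({c: [] for c in columns})
        return pd.DataFrame({
            c: np.concatenate([p[c] for p in parts]) for c in columns})

    gps = _concat(gps_parts, ["participant_id", "t_s", "lat", "lon",
                              "elevation", "speed", "hdop", "vdop", "pdop",
                              "sat_in_view", "sat_used"])
    accel = _concat(acc_parts, ["participant_id", "t_s", "filter_variant",
                                "counts_axis1", "counts_axis2",
                                "counts_axis3", "steps"])
    rr = _concat(rr_parts, ["participant_id", "t_s", "rr_ms"])
    return Cohort(participants=participants, timetable=timetable,
                  gps=gps, accel=accel, rr=rr, config=config)


def check_timetable_tiling(timetable: pd.DataFrame, n_minutes: int) -> None:
    """Raise if any participant's episodes fail to tile [0, n_minutes)."""
    for pid, grp in timetable.groupby("participant_id", sort=False):
        g = grp.sort_values("start_minute")
        starts = g["start_minute"].to_numpy()
        ends = g["end_minute"].to_numpy()
        if (starts >= ends).any():
            raise ConfigurationError(f"{pid}: empty or inverted episode")
        if starts[0] != 0 or ends[-1] != n_minutes or \
                (starts[1:] != ends[:-1]).any():
            raise ConfigurationError(
                f"{pid}: episodes do not tile the follow-up")
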