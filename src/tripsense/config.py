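"""Configuration objects for cohort simulation and pipeline runs.

The simulator emulates a free-living urban cohort wearing three devices:
a hip GPS receiver, a hip tri-axial accelerometer aggregated into 5-second
epochs, and a chest ECG patch recording beat-to-beat (RR) intervals.
Minute-level ground truth distinguishes five classes: being at an activity
place (a fixed visited location) and four transport modes (walk, bike,
public transport, private motorized vehicle).

Defaults are calibrated to descriptive statistics typical of a dense
European metropolitan cohort: a median of about 5.1 trips per day split
into roughly 1.7 stages each, about 6.9 % of follow-up time spent on
trips, and degraded GPS reception during (often underground) public
transport.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

#: Fixed class order used everywhere (alphabetical; ties in argmax-style
#: decisions are broken toward the earlier class in this tuple).
MODES: tuple[str, ...] = (
    "activity_place",
    "bike",
    "private_motorized",
    "public_transport",
    "walk",
)

#: The four transport modes (everything except being at an activity place).
TRANSPORT_MODES: tuple[str, ...] = (
    "bike",
    "private_motorized",
    "public_transport",
    "walk",
)

MINUTES_PER_DAY = 1440


class ConfigurationError(ValueError):
    """Raised when a simulation or run configuration is invalid."""


@dataclass
class ModeSignature:
    """Per-mode sensor signature.

    speed_kmh / speed_minute_sd / speed_fix_sd
        Mean cruising speed, between-minute variation (stops, traffic
        lights, stations) and within-minute per-fix jitter, all in km/h.
    speed_cap_kmh
        Optional hard cap; activity places stay below walking pace.
    counts_cpm / counts_log_sd
        Geometric-mean axis-1 accelerometer counts per minute and the
        log-normal spread of minute-level intensity. Hip-worn devices
        see high counts for walking but little for biking or riding.
    steps_per_min
        Step-detection rate while in this mode.
    hr_elev_bpm
        Mean heart-rate elevation above the participant's resting rate.
    """

    speed_kmh: float
    speed_minute_sd: float
    speed_fix_sd: float
    counts_cpm: float
    counts_log_sd: float
    steps_per_min: float
    hr_elev_bpm: float
    speed_cap_kmh: float | None = None


def default_mode_signatures() -> dict[str, ModeSignature]:
    return {
        "activity_place": ModeSignature(
            speed_kmh=0.25, speed_minute_sd=0.15, speed_fix_sd=0.15,
            counts_cpm=120.0, counts_log_sd=1.2, steps_per_min=2.0,
            hr_elev_bpm=0.0, speed_cap_kmh=0.95,
        ),
        "walk": ModeSignature(
            speed_kmh=4.8, speed_minute_sd=1.1, speed_fix_sd=0.9,
            counts_cpm=2500.0, counts_log_sd=0.4, steps_per_min=105.0,
            hr_elev_bpm=24.0,
        ),
        "bike": ModeSignature(
            speed_kmh=13.0, speed_minute_sd=5.5, speed_fix_sd=2.5,
            counts_cpm=240.0, counts_log_sd=0.7, steps_per_min=0.0,
            hr_elev_bpm=32.0,
        ),
        "public_transport": ModeSignature(
            speed_kmh=24.0, speed_minute_sd=14.0, speed_fix_sd=4.5,
            counts_cpm=200.0, counts_log_sd=0.8, steps_per_min=0.5,
            hr_elev_bpm=8.0,
        ),
        "private_motorized": ModeSignature(
            speed_kmh=30.0, speed_minute_sd=16.0, speed_fix_sd=5.0,
            counts_cpm=150.0, counts_log_sd=0.8, steps_per_min=0.3,
            hr_elev_bpm=4.0,
        ),
    }


@dataclass
class MetroGpsDegradation:
    """GPS degradation during public transport (often underground).

    A public-transport stage is flagged "underground" with probability
    ``underground_prob``; its DOP values are inflated by ``dop_factor``
    and satellite counts collapse, so most fixes fail the quality filter.
    """

    dop_factor: float = 4.0
    sat_in_view_mean_degraded: float = 3.0
    sat_used_frac_degraded: float = 0.5
    underground_prob: float = 0.55


@dataclass
class ParticipantHeterogeneity:
    """SDs of Gaussian participant-level random effects.

    These between-participant differences (fitness, gait, device wear
    position) are what make minute-level train/test splits optimistic
    compared with participant-level splits: a forest that has seen
    minutes from a participant partially memorizes that participant's
    sensor idiosyncrasies.
    """

    sd_resting_hr: float = 8.0     # bpm
    sd_walk_speed: float = 1.0     # km/h
    sd_log_counts: float = 0.35    # log-scale multiplier on counts


@dataclass
class SimConfig:
    """Synthetic-cohort generator configuration.

    ``trips_per_day`` is the Poisson mean of daily trips (default 5.1,
    giving a median of 5), ``stages_per_trip`` the mean number of
    single-mode stages per trip, and ``time_on_trips_frac`` the target
    fraction of follow-up time spent travelling. Wear gaps combine a
    nightly removal window (devices are taken off for sleep) with
    per-sensor per-minute Bernoulli dropout; the chest HR patch has the
    worst compliance, so merged three-sensor coverage ends up near a
    quarter of total follow-up.
    """

    n_participants: int = 126
    n_days: int = 7
    seed: int = 0
    trips_per_day: float = 5.1
    stages_per_trip: float = 1.7
    time_on_trips_frac: float = 0.069
    mode_mix: dict[str, float] = field(default_factory=lambda: {
        "walk": 0.45, "bike": 0.08,
        "public_transport": 0.25, "private_motorized": 0.22,
    })
    mode_signatures: dict[str, ModeSignature] = field(
        default_factory=default_mode_signatures)
    metro_gps_degradation: MetroGpsDegradation = field(
        default_factory=MetroGpsDegradation)
    participant_heterogeneity: ParticipantHeterogeneity = field(
        default_factory=ParticipantHeterogeneity)
    wear_gap_rate: dict[str, float] = field(default_factory=lambda: {
        "gps": 0.20, "accel": 0.10, "hr": 0.45,
    })
    sleep_start_hour: int = 23
    sleep_end_hour: int = 7
    gps_interval_s: int = 5
    epoch_s: int = 5                  # fixed 5-s accelerometer epochs
    rr_rest_ms: float = 850.0         # resting RR interval (~70.6 bpm)
    rr_jitter_ms: float = 40.0        # beat-to-beat variability SD
    hr_minute_sd: float = 4.0         # minute-level HR noise, bpm
    body_weight_mean_kg: float = 75.0
    body_weight_sd_kg: float = 12.0
    max_stage_minutes: int = 45
    min_stage_minutes: int = 2

    def validate(self) -> None:
        if self.n_participants < 2:
            raise ConfigurationError(
                "n_participants must be >= 2 (leave-one-participant-out "
                "validation needs at least two participants)")
        if self.n_days < 1:
            raise ConfigurationError("n_days must be >= 1")
        if self.trips_per_day < 0:
            raise ConfigurationError("trips_per_day must be >= 0")
        if self.stages_per_trip < 1:
            raise ConfigurationError("stages_per_trip must be >= 1")
        if not 0 <= self.time_on_trips_frac < 1:
            raise ConfigurationError("time_on_trips_frac must be in [0, 1)")
        if set(self.mode_mix) != set(TRANSPORT_MODES):
            raise ConfigurationError(
                f"mode_mix must have exactly the keys {TRANSPORT_MODES}")
        if any(p < 0 or p > 1 for p in self.mode_mix.values()):
            raise ConfigurationError("mode_mix probabilities must be in [0, 1]")
        if abs(sum(self.mode_mix.values()) - 1.0) > 1e-9:
            raise ConfigurationError("mode_mix must sum to 1")
        if set(self.mode_signatures) != set(MODES):
            raise ConfigurationError(
                f"mode_signatures must have exactly the keys {MODES}")
        het = self.participant_heterogeneity
        if min(het.sd_resting_hr, het.sd_walk_speed, het.sd_log_counts) < 0:
            raise ConfigurationError("heterogeneity SDs must be >= 0")
        if set(self.wear_gap_rate) != {"gps", "accel", "hr"}:
            raise ConfigurationError(
                "wear_gap_rate must have exactly the keys gps/accel/hr")
        if any(not 0 <= r < 1 for r in self.wear_gap_rate.values()):
            raise ConfigurationError("wear gap rates must be in [0, 1)")
        if self.epoch_s != 5:
            raise ConfigurationError("epoch_s is fixed at 5 seconds")
        if self.gps_interval_s < 1 or 60 % self.gps_interval_s != 0:
            raise ConfigurationError("gps_interval_s must divide 60")
        if self.rr_rest_ms <= 0:
            raise ConfigurationError("rr_rest_ms must be > 0")


@dataclass
class RunConfig:
    """End-to-end pipeline configuration (simulation + modelling)."""

    sim: SimConfig = field(default_factory=SimConfig)
    n_trees: int = 100
    feature_sets: tuple[str, ...] = ("without_hr", "with_hr")
    bandwidths: tuple[int, ...] = (0, 1, 2, 3, 4, 5)
    compute_oob: bool = True

    def validate(self) -> None:
        self.sim.validate()
        if self.n_trees < 1:
            raise ConfigurationError("n_trees must be >= 1")
        bad = set(self.feature_sets) - {"with_hr", "without_hr"}
        if bad:
            raise ConfigurationError(f"unknown feature sets: {sorted(bad)}")
        if any(b < 0 for b in self.bandwidths):
            raise ConfigurationError("bandwidths must be >= 0")


def _to_dict(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_dict(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _to_dict(v) for k, v in obj.items()}
    if isinstance(obj, tuple):
        return list(obj)
    return obj


def config_to_dict(config: SimConfig | RunConfig) -> dict:
    return _to_dict(config)


def sim_config_from_dict(data: dict) -> SimConfig:
    data = dict(data)
    if "mode_signatures" in data:
        data["mode_signatures"] = {
            mode: ModeSignature(**sig) if isinstance(sig, dict) else sig
            for mode, sig in data["mode_signatures"].items()
        }
    if isinstance(data.get("metro_gps_degradation"), dict):
        data["metro_gps_degradation"] = MetroGpsDegradation(
            **data["metro_gps_degradation"])
    if isinstance(data.get("participant_heterogeneity"), dict):
        data["participant_heterogeneity"] = ParticipantHeterogeneity(
            **data["participant_heterogeneity"])
    known = {f.name for f in dataclasses.fields(SimConfig)}
    unknown = set(data) - known
    if unknown:
        raise ConfigurationError(f"unknown SimConfig keys: {sorted(unknown)}")
    cfg = SimConfig(**data)
    cfg.validate()
    return cfg


def run_config_from_dict(data: dict) -> RunConfig:
    data = dict(data)
    sim = data.pop("sim", {})
    known = {f.name for f in dataclasses.fields(RunConfig)} - {"sim"}
    unknown = set(data) - known
    if unknown:
        raise ConfigurationError(f"unknown RunConfig keys: {sorted(unknown)}")
    if "feature_sets" in data:
        data["feature_sets"] = tuple(data["feature_sets"])
    if "bandwidths" in data:
        data["bandwidths"] = tuple(data["bandwidths"])
    cfg = RunConfig(sim=sim_config_from_dict(sim), **data)
    cfg.validate()
    return cfg


def load_run_config(path) -> RunConfig:
    """Load a pipeline configuration from a YAML file."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    return run_config_from_dict(data)


def save_run_config(config: RunConfig, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)
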