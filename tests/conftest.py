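"""Shared fixtures: one small synthetic cohort reused across modules."""

import numpy as np
import pandas as pd
import pytest

from tripsense.config import SimConfig
from tripsense.features import build_minute_dataset, default_catalogue
from tripsense.simulate import generate_cohort


@pytest.fixture(scope="session")
def tiny_config() -> SimConfig:
    return SimConfig(n_participants=4, n_days=1, seed=11)


@pytest.fixture(scope="session")
def tiny_cohort(tiny_config):
    return generate_cohort(tiny_config)


@pytest.fixture(scope="session")
def tiny_minutes(tiny_cohort):
    minutes, _ = build_minute_dataset(
        tiny_cohort.gps, tiny_cohort.accel, tiny_cohort.rr,
        tiny_cohort.timetable, tiny_cohort.participants)
    return minutes


@pytest.fixture(scope="session")
def catalogue():
    return default_catalogue()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_separable_records(n_per_class=120, classes=("activity_place",
                                                     "walk"),
                           n_features=6, seed=0, participant_ids=("pA",),
                           label_shift=8.0) -> pd.DataFrame:
    """Small perfectly separable labelled table with catalogue-free
    feature columns f0..f{n-1} (for direct forest-level tests)."""
    rng = np.random.default_rng(seed)
    frames = []
    for ci, cls in enumerate(classes):
        X = rng.normal(size=(n_per_class, n_features))
        X[:, 0] += ci * label_shift
        df = pd.DataFrame(X, columns=[f"f{j}" for j in range(n_features)])
        df["label"] = cls
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    out["participant_id"] = np.resize(np.asarray(participant_ids), len(out))
    out["minute"] = np.arange(len(out))
    return out
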