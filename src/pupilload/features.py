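"""The eight per-level features and the labelled dataset they form.

Four gamer-behaviour features come from the session log:

* ``TE`` — total errors: events performed in the wrong way.
* ``TC`` — time to complete the level, in ms.
* ``CP`` — changes of position: moves of an element already placed in play.
* ``A``  — attempts used to complete the level.

Four pupillary features compare the measurement interval (the whole level)
against an individual baseline estimated immediately before play:

* ``MPDC`` — mean diameter over the interval minus the baseline mean (px).
* ``PD``   — maximum diameter over the interval minus the baseline mean (px).
* ``LP``   — latency from interval start to the (first) peak, in seconds.
* ``APCPS``— mean of the per-sample relative change ``(d - b) / b``.

MPDC, PD and LP are subtractive (they remove individual baseline size);
APCPS is divisive.  One record per (participant, level) with the level's
difficulty world as label forms the dataset used for feature selection and
classification.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Iterable

import numpy as np
import pandas as pd

from .io import SessionLog, world_of_level
from .preprocess import BaselineEstimate, CleanTrace

__all__ = [
    "GAME_FEATURES",
    "PUPIL_FEATURES",
    "ALL_FEATURES",
    "FeatureVector",
    "Trial",
    "mpdc",
    "peak_dilation",
    "latency_to_peak",
    "apcps",
    "gamer_features",
    "compute_features",
    "build_dataset",
    "dataset_to_csv",
    "dataset_from_csv",
]

GAME_FEATURES = ("TE", "TC", "CP", "A")
PUPIL_FEATURES = ("MPDC", "PD", "LP", "APCPS")
ALL_FEATURES = GAME_FEATURES + PUPIL_FEATURES

_DATASET_COLUMNS = ("participant_id", "level_id", "world") + ALL_FEATURES


def _valid_measurement(measurement: CleanTrace) -> np.ndarray:
    d = measurement.d
    if not np.isfinite(d).any():
        raise ValueError("no valid samples in measurement interval")
    return d


def mpdc(measurement: CleanTrace, baseline: BaselineEstimate) -> float:
    """Mean pupil diameter change: interval mean minus baseline mean (px).

    Negative values are meaningful — they indicate net constriction relative
    to the baseline, e.g. after a dark baseline slide.
    """
    d = _valid_measurement(measurement)
    return float(np.nanmean(d) - baseline.mean_d)


def peak_dilation(measurement: CleanTrace, baseline: BaselineEstimate) -> float:
    """Peak dilation: interval maximum minus baseline mean (px)."""
    d = _valid_measurement(measurement)
    return float(np.nanmax(d) - baseline.mean_d)


def latency_to_peak(measurement: CleanTrace) -> float:
    """Seconds from interval start to the first sample attaining the maximum."""
    d = _valid_measurement(measurement)
    peak_idx = int(np.nanargmax(d))  # first maximum wins ties
    return float(measurement.t[peak_idx] - measurement.t[0]) / 1000.0


def apcps(measurement: CleanTrace, baseline: BaselineEstimate) -> float:
    """Average percentage change in pupil size, as a dimensionless ratio.

    Equals ``MPDC / baseline`` exactly whenever no samples are missing.
    """
    if baseline.mean_d <= 0:
        raise ValueError("baseline mean must be positive")
    d = _valid_measurement(measurement)
    return float(np.nanmean((d - baseline.mean_d) / baseline.mean_d))


def gamer_features(log: SessionLog) -> tuple[int, float, int, int]:
    """(TE, TC, CP, A) from a session log; TC requires a completed level."""
    if not log.events:
        raise ValueError("empty event list")
    if not log.complete:
        raise ValueError(
            f"{log.participant_id}/{log.level_id}: level incomplete, TC undefined"
        )
    starts = [t for t, k in log.events if k == "attempt_start"]
    if not starts:
        raise ValueError("no attempt_start event")
    t_complete = next(t for t, k in log.events if k == "level_complete")
    te = log.count("error")
    tc = float(t_complete - starts[0])
    cp = log.count("move")
    a = len(starts)
    if tc <= 0:
        raise ValueError("level_complete precedes first attempt_start")
    return te, tc, cp, a


@dataclass(frozen=True)
class FeatureVector:
    """One labelled register: eight features for one participant and level."""

    participant_id: str
    level_id: str
    world: str
    TE: int
    TC: float
    CP: int
    A: int
    MPDC: float
    PD: float
    LP: float
    APCPS: float

    def __post_init__(self) -> None:
        if min(self.TE, self.CP, self.A) < 0:
            raise ValueError("event counts must be non-negative")
        if self.TC <= 0:
            raise ValueError("TC must be positive")
        if self.LP < 0:
            raise ValueError("LP must be non-negative")


@dataclass
class Trial:
    """One participant x level observation awaiting feature extraction."""

    participant_id: str
    level_id: str
    measurement: CleanTrace
    baseline: BaselineEstimate
    log: SessionLog


def compute_features(trial: Trial) -> FeatureVector:
    if trial.log.participant_id != trial.participant_id or \
            trial.log.level_id != trial.level_id:
        raise ValueError(
            f"session log ids {trial.log.participant_id}/{trial.log.level_id} "
            f"do not match trial ids {trial.participant_id}/{trial.level_id}"
        )
    te, tc, cp, a = gamer_features(trial.log)
    return FeatureVector(
        participant_id=trial.participant_id,
        level_id=trial.level_id,
        world=world_of_level(trial.level_id),
        TE=te,
        TC=tc,
        CP=cp,
        A=a,
        MPDC=mpdc(trial.measurement, trial.baseline),
        PD=peak_dilation(trial.measurement, trial.baseline),
        LP=latency_to_peak(trial.measurement),
        APCPS=apcps(trial.measurement, trial.baseline),
    )


def build_dataset(trials: Iterable[Trial]) -> pd.DataFrame:
    """Assemble one labelled record per (participant, level).

    The label of a record is the difficulty world of its level.  Duplicate
    (participant, level) pairs are a data-integrity failure and raise.
    """
    records = [asdict(compute_features(tr)) for tr in trials]
    if not records:
        raise ValueError("no trials")
    df = pd.DataFrame.from_records(records, columns=_DATASET_COLUMNS)
    dup = df.duplicated(subset=["participant_id", "level_id"])
    if dup.any():
        pairs = df.loc[dup, ["participant_id", "level_id"]].to_records(index=False)
        raise ValueError(f"duplicate (participant, level) records: {list(pairs)}")
    return df


def dataset_to_csv(dataset: pd.DataFrame, path) -> None:
    dataset.to_csv(path, index=False, columns=list(_DATASET_COLUMNS))


def dataset_from_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(_DATASET_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    df["participant_id"] = df["participant_id"].astype(str)
    return df[list(_DATASET_COLUMNS)]
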