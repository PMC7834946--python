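"""Domain containers and file I/O for pupil traces, session logs, and level specs.

Time is expressed in milliseconds since the start of the recording throughout
the package.  Pupil diameters are in pixels, as reported by screen-based eye
trackers before any millimetre calibration.  Missing diameters (blinks, track
loss) are represented as NaN in memory and never as zero or a negative value;
zeros and negatives are common tracker sentinels and are converted on ingestion.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "PupilTrace",
    "SessionLog",
    "LevelSpec",
    "RunConfig",
    "EVENT_KINDS",
    "read_pupil_csv",
    "write_pupil_csv",
    "read_session_log",
    "write_session_log",
    "load_level_specs",
    "world_of_level",
]

EVENT_KINDS = ("error", "place", "move", "attempt_start", "level_complete")

#: duration of a trace may deviate from (n-1)/rate by at most this fraction
_DURATION_TOL = 0.10


def _as_float_array(x: Iterable[float]) -> np.ndarray:
    return np.asarray(x, dtype=float)


@dataclass
class PupilTrace:
    """A binocular pupil-diameter time series for one participant and interval.

    Parameters
    ----------
    t
        Sample timestamps in ms, non-negative and strictly increasing.
    d_left, d_right
        Pupil diameters in pixels; NaN marks a missing sample.
    rate_hz
        Nominal sampling rate of the tracker (60 Hz for the consumer-grade
        screen trackers this package targets).
    participant_id
        Opaque participant identifier.
    interval_tag
        Either ``"baseline"`` or ``"measurement"``.
    """

    t: np.ndarray
    d_left: np.ndarray
    d_right: np.ndarray
    rate_hz: float
    participant_id: str = ""
    interval_tag: str = "measurement"

    def __post_init__(self) -> None:
        self.t = _as_float_array(self.t)
        self.d_left = _as_float_array(self.d_left)
        self.d_right = _as_float_array(self.d_right)
        if self.t.size == 0:
            raise ValueError("no samples")
        if not (len(self.t) == len(self.d_left) == len(self.d_right)):
            raise ValueError("t, d_left, d_right must have equal length")
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")
        if self.t[0] < 0:
            raise ValueError("timestamps must be non-negative")
        if self.t.size > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError("timestamps must be strictly increasing")
        if self.interval_tag not in ("baseline", "measurement"):
            raise ValueError(f"unknown interval_tag {self.interval_tag!r}")
        for d in (self.d_left, self.d_right):
            if np.any(d[np.isfinite(d)] <= 0):
                raise ValueError(
                    "non-missing diameters must be positive; convert tracker "
                    "sentinels to NaN before constructing a PupilTrace"
                )
        if self.t.size > 1:
            duration = float(self.t[-1] - self.t[0])
            expected = (self.t.size - 1) / self.rate_hz * 1000.0
            if abs(duration - expected) > _DURATION_TOL * expected:
                raise ValueError(
                    f"trace duration {duration:.1f} ms inconsistent with "
                    f"{self.t.size} samples at {self.rate_hz} Hz "
                    f"(expected {expected:.1f} ms +/- 10%)"
                )

    def __len__(self) -> int:
        return int(self.t.size)

    @property
    def duration_ms(self) -> float:
        return float(self.t[-1] - self.t[0])


@dataclass
class SessionLog:
    """Telemetry for one participant playing one level.

    ``events`` is a time-ordered sequence of ``(t_ms, kind)`` with kinds in
    :data:`EVENT_KINDS`.  A completed level carries exactly one
    ``level_complete`` event.
    """

    participant_id: str
    level_id: str
    events: list[tuple[float, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.events = [(float(t), str(k)) for t, k in self.events]
        for t, k in self.events:
            if k not in EVENT_KINDS:
                raise ValueError(f"unknown event kind {k!r}")
        ts = [t for t, _ in self.events]
        if ts != sorted(ts):
            raise ValueError("events must be time-ordered")
        n_complete = sum(1 for _, k in self.events if k == "level_complete")
        if n_complete > 1:
            raise ValueError("more than one level_complete event")
        if n_complete == 0:
            warnings.warn(
                f"session log {self.participant_id}/{self.level_id} has no "
                "level_complete event; level flagged incomplete",
                stacklevel=2,
            )
        self.world = world_of_level(self.level_id)

    @property
    def complete(self) -> bool:
        return any(k == "level_complete" for _, k in self.events)

    def count(self, kind: str) -> int:
        return sum(1 for _, k in self.events if k == kind)


@dataclass(frozen=True)
class LevelSpec:
    """Game-element counts for one level of the fraction-splitting game."""

    level_id: str
    world: str
    origins: int
    targets: int
    two_way_splitters: int
    three_way_splitters: int
    pipe_bends: int
    obstacles: int

    def __post_init__(self) -> None:
        for name in (
            "origins",
            "targets",
            "two_way_splitters",
            "three_way_splitters",
            "pipe_bends",
            "obstacles",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def total_elements(self) -> int:
        return (
            self.origins
            + self.targets
            + self.two_way_splitters
            + self.three_way_splitters
            + self.pipe_bends
            + self.obstacles
        )


@dataclass
class RunConfig:
    """Analysis-stage settings shared by the CLI subcommands."""

    baseline_window_s: float = 2.0
    observation_s: float = 8.0
    hampel_half_window: int = 5
    hampel_n_mads: float = 3.0
    max_blink_gap_ms: float = 500.0
    grid_cols: int = 8
    grid_rows: int = 6
    seed: int = 0
    alpha: float = 0.05
    n_train_participants: int = 3
    n_split_seeds: int = 50
    rf_n_trees: int = 100

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.baseline_window_s > self.observation_s:
            raise ValueError("baseline window cannot exceed observation length")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**json.load(fh))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2)


def world_of_level(level_id: str) -> str:
    """Map a level id to its difficulty world: trailing 'a' -> A, 'b' -> B."""
    suffix = level_id.strip().lower()[-1:]
    if suffix == "a":
        return "A"
    if suffix == "b":
        return "B"
    raise ValueError(f"unknown level_id {level_id!r}: cannot infer world")


# ---------------------------------------------------------------------------
# Pupil CSV
# ---------------------------------------------------------------------------

def read_pupil_csv(path, rate_hz: float, participant_id: str = "",
                   interval_tag: str = "measurement") -> PupilTrace:
    """Read a pupil-diameter CSV with columns ``t``, ``d_left``, ``d_right``.

    An optional boolean/int ``valid`` column marks tracked samples.  Any
    diameter that is NaN, <= 0, or flagged invalid becomes missing (NaN):
    trackers emit zeros during blinks, and those zeros must never enter
    downstream means.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: no samples") from None
    if df.empty:
        raise ValueError(f"{path}: no samples")
    for col in ("t", "d_left", "d_right"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    for col in ("t", "d_left", "d_right"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna() & (df[col].astype(str).str.strip() != "")
        if bad.any():
            line = int(bad.idxmax()) + 2  # header occupies line 1
            raise ValueError(f"{path}: malformed value in column {col!r} at line {line}")
        df[col] = coerced
    t = df["t"].to_numpy(dtype=float)
    if t.size > 1 and not np.all(np.diff(t) > 0):
        raise ValueError(f"{path}: timestamps are not strictly increasing")
    d_left = df["d_left"].to_numpy(dtype=float)
    d_right = df["d_right"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        d_left = np.where(d_left <= 0, np.nan, d_left)
        d_right = np.where(d_right <= 0, np.nan, d_right)
    if "valid" in df.columns:
        invalid = ~df["valid"].astype(bool).to_numpy()
        d_left[invalid] = np.nan
        d_right[invalid] = np.nan
    return PupilTrace(t, d_left, d_right, rate_hz, participant_id, interval_tag)


def write_pupil_csv(trace: PupilTrace, path) -> None:
    pd.DataFrame(
        {"t": trace.t, "d_left": trace.d_left, "d_right": trace.d_right}
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Session-log CSV
# ---------------------------------------------------------------------------

def read_session_log(path) -> SessionLog:
    """Read a session log CSV with columns participant_id, level_id, t, event."""
    df = pd.read_csv(path)
    for col in ("participant_id", "level_id", "t", "event"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    if df.empty:
        raise ValueError(f"{path}: empty session log")
    pids = df["participant_id"].astype(str).unique()
    lids = df["level_id"].astype(str).unique()
    if len(pids) != 1 or len(lids) != 1:
        raise ValueError(f"{path}: expected a single participant/level per log file")
    df = df.sort_values("t", kind="stable")
    events = list(zip(df["t"].astype(float), df["event"].astype(str)))
    return SessionLog(participant_id=pids[0], level_id=lids[0], events=events)


def write_session_log(log: SessionLog, path) -> None:
    pd.DataFrame(
        {
            "participant_id": log.participant_id,
            "level_id": log.level_id,
            "t": [t for t, _ in log.events],
            "event": [k for _, k in log.events],
        }
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Level specs
# ---------------------------------------------------------------------------

def load_level_specs(path=None) -> dict[str, LevelSpec]:
    """Load level element counts; defaults to the packaged four-level table.

    The stored ``total_elements`` of every record is validated against the sum
    of the six element counts.
    """
    if path is None:
        src = resources.files("pupilload.data").joinpath("level_specs.json")
        raw = json.loads(src.read_text())
    else:
        with open(path) as fh:
            raw = json.load(fh)
    specs: dict[str, LevelSpec] = {}
    for rec in raw["levels"]:
        rec = dict(rec)
        stored_total = rec.pop("total_elements", None)
        spec = LevelSpec(**rec)
        if stored_total is not None and stored_total != spec.total_elements:
            raise ValueError(
                f"{spec.level_id}: stored total {stored_total} != "
                f"sum of element counts {spec.total_elements}"
            )
        if spec.world != world_of_level(spec.level_id):
            raise ValueError(f"{spec.level_id}: world tag inconsistent with id")
        specs[spec.level_id] = spec
    return specs
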