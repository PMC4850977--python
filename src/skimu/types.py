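"""Core in-memory containers shared across the pipeline.

A skiing session is a sequence of trial recordings.  Each recording holds one
roll-angle trace per instrumented body location (sampled at 100 Hz by default)
and a pair of 13-cell insole pressure streams (50 Hz).  Turn segmentation and
all downstream statistics operate on these containers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

#: The 16 candidate IMU body locations of a full-body configuration.
BODY_LOCATIONS: tuple[str, ...] = (
    "head",
    "upper_spine",
    "lower_spine",
    "pelvis",
    "upper_arm_l",
    "upper_arm_r",
    "forearm_l",
    "forearm_r",
    "hand_l",
    "hand_r",
    "thigh_l",
    "thigh_r",
    "shank_l",
    "shank_r",
    "foot_l",
    "foot_r",
)

#: Midline locations need a single sensor; everything else comes in L/R pairs.
MIDLINE_LOCATIONS: frozenset[str] = frozenset(
    {"head", "upper_spine", "lower_spine", "pelvis"}
)

#: Number of pressure cells per insole.
N_INSOLE_CELLS = 13


@dataclass(frozen=True)
class TimeSeries:
    """A uniformly sampled scalar signal.

    Parameters
    ----------
    values : ndarray
        Sample values; must be non-empty and free of infinities.  NaN is
        permitted and marks samples flagged invalid (e.g., airborne phases
        in a pressure ratio).
    rate_hz : float
        Sampling rate in samples per second, > 0.
    t0 : float
        Timestamp of the first sample, seconds.
    label : str
        Free-text identifier used in error messages and reports.
    """

    values: np.ndarray
    rate_hz: float
    t0: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size < 1:
            raise ValueError(f"TimeSeries {self.label!r}: values must be a non-empty 1-D array")
        if np.isinf(values).any():
            raise ValueError(f"TimeSeries {self.label!r}: values must not be infinite")
        if not self.rate_hz > 0:
            raise ValueError(f"TimeSeries {self.label!r}: rate_hz must be > 0")
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return self.values.size

    @property
    def times(self) -> np.ndarray:
        """Sample timestamps in seconds."""
        return self.t0 + np.arange(self.values.size) / self.rate_hz

    @property
    def duration_s(self) -> float:
        """Span from first to last sample, seconds."""
        return (self.values.size - 1) / self.rate_hz

    def with_values(self, values: np.ndarray, label: Optional[str] = None) -> "TimeSeries":
        return replace(self, values=values, label=self.label if label is None else label)


@dataclass(frozen=True)
class TurnSegment:
    """One detected turn: a maximal run of constant roll sign.

    ``side`` is ``"R"`` for positive roll (skier leaning right) and ``"L"``
    for negative roll.  ``start``/``end`` are sample indices, end exclusive.
    """

    side: str
    start: int
    end: int
    rate_hz: float

    def __post_init__(self) -> None:
        if self.side not in ("L", "R"):
            raise ValueError(f"side must be 'L' or 'R', got {self.side!r}")
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid segment bounds [{self.start}, {self.end})")

    @property
    def n_samples(self) -> int:
        return self.end - self.start

    @property
    def duration_s(self) -> float:
        return (self.end - self.start) / self.rate_hz


@dataclass
class InsoleStream:
    """Pressure stream for one foot: ``pressures`` is (n_samples, 13) N/cm^2."""

    foot: str
    pressures: np.ndarray
    rate_hz: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        p = np.asarray(self.pressures, dtype=float)
        if p.ndim != 2 or p.shape[1] != N_INSOLE_CELLS:
            raise ValueError(f"insole stream must have {N_INSOLE_CELLS} cells, got shape {p.shape}")
        if np.any(p < 0):
            raise ValueError("cell pressures must be >= 0")
        if self.foot not in ("L", "R"):
            raise ValueError(f"foot must be 'L' or 'R', got {self.foot!r}")
        self.pressures = p

    @property
    def total_force(self) -> np.ndarray:
        """Per-sample sum over the 13 cells."""
        return self.pressures.sum(axis=1)


@dataclass
class TrialRecording:
    """All sensor traces plus metadata for one run of alternating turns."""

    attempt: int
    roll: dict[str, TimeSeries]
    insole_left: InsoleStream
    insole_right: InsoleStream
    actual_turn_count: int

    def __post_init__(self) -> None:
        if self.attempt < 1:
            raise ValueError("attempt index must be >= 1")
        if self.actual_turn_count < 1:
            raise ValueError("actual turn count must be >= 1")


@dataclass
class GroundTruth:
    """Generating values for one synthetic trial (oracle for recovery tests)."""

    boundaries: np.ndarray  # turn start sample indices plus final end, len = n_turns + 1
    sides: list[str]
    durations_s: np.ndarray
    peak_fractions: np.ndarray

    def __post_init__(self) -> None:
        b = np.asarray(self.boundaries)
        if np.any(np.diff(b) <= 0):
            raise ValueError("boundaries must be strictly increasing")
        if any(a == b_ for a, b_ in zip(self.sides, self.sides[1:])):
            raise ValueError("turn sides must alternate")


@dataclass
class AttemptRecord:
    """One row of a session manifest."""

    attempt: int
    status: str  # "valid" | "excluded"
    actual_turn_count: int = 0
    trace_files: dict[str, str] = field(default_factory=dict)
    insole_files: dict[str, str] = field(default_factory=dict)


@dataclass
class SessionManifest:
    """Attempt roster and sensor metadata for a session."""

    attempts: list[AttemptRecord]
    imu_rate_hz: float = 100.0
    pressure_rate_hz: float = 50.0
    locations: tuple[str, ...] = BODY_LOCATIONS

    def __post_init__(self) -> None:
        idx = [a.attempt for a in self.attempts]
        if len(set(idx)) != len(idx) or idx != sorted(idx):
            raise ValueError("attempt indices must be unique and ordered")

    @property
    def valid_attempts(self) -> list[AttemptRecord]:
        return [a for a in self.attempts if a.status == "valid"]


@dataclass
class SessionDataset:
    """Ordered valid trial recordings plus the full attempt manifest."""

    manifest: SessionManifest
    trials: list[TrialRecording]
    ground_truth: Optional[list[GroundTruth]] = None

    def __post_init__(self) -> None:
        valid = [a.attempt for a in self.manifest.valid_attempts]
        got = [t.attempt for t in self.trials]
        if valid != got:
            raise ValueError(f"trial attempts {got} do not match manifest valid attempts {valid}")
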