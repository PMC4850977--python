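"""Synthetic skiing sessions with known ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes: a latent roll-angle oscillation of alternating half-sine turns
(positive = leaning right, i.e. a right turn), per-location traces that scale
and corrupt that latent signal according to a fidelity profile, 13-cell
insole streams whose outer-foot loading rises smoothly to a configured peak
fraction within each turn, a left/right asymmetry in turn duration and peak
loading, and a linear adaptation trend (turns speeding up across attempts).

Defaults reproduce the study conditions of a giant-slalom training session:
six alternating turns per trial starting with a right turn, 100 Hz roll
sampling, 50 Hz insole sampling, side-mean durations 2.08 s (right) and
1.68 s (left).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .types import (
    BODY_LOCATIONS,
    GroundTruth,
    InsoleStream,
    AttemptRecord,
    SessionDataset,
    SessionManifest,
    TimeSeries,
    TrialRecording,
)

#: Shortest physically plausible turn; draws below this are clipped.
MIN_TURN_DURATION_S = 0.2

# Fixed (arbitrary but deterministic) relative sensitivity of the 13 insole
# cells; heel and forefoot cells carry more load than the arch.
_CELL_WEIGHTS = np.array(
    [1.4, 1.3, 1.2, 1.0, 0.8, 0.6, 0.5, 0.6, 0.8, 1.0, 1.2, 1.3, 1.4]
)
_CELL_WEIGHTS = _CELL_WEIGHTS / _CELL_WEIGHTS.sum()

#: Two-foot total force, N/cm^2 summed over cells (constant while on snow).
_TOTAL_FORCE = 40.0


@dataclass(frozen=True)
class LocationProfile:
    """Signal fidelity of one body location.

    The location's roll trace is ``gain x latent + noise``, optionally plus
    a periodic artifact (arm swing / pole plant) that is uncorrelated with
    the turn cycle.
    """

    location: str
    gain: float = 1.0
    artifact_noise_sd: float = 0.0
    artifact_oscillation: Optional[tuple[float, float]] = None  # (amplitude_deg, freq_hz)

    def __post_init__(self) -> None:
        if self.gain < 0:
            raise ValueError(f"{self.location}: gain must be >= 0")
        if self.artifact_noise_sd < 0:
            raise ValueError(f"{self.location}: artifact_noise_sd must be >= 0")


def default_location_profiles() -> dict[str, LocationProfile]:
    """Fidelity profiles that make the placement ranking nontrivial.

    Trunk and leg locations track the latent roll closely (gain 1, small
    noise, pelvis cleanest); head is attenuated and noisier; arms and hands
    are attenuated with heavy noise plus a 2 Hz swing artifact.
    """
    profiles = {
        "head": LocationProfile("head", gain=0.8, artifact_noise_sd=8.0),
        "upper_spine": LocationProfile("upper_spine", gain=1.0, artifact_noise_sd=4.0),
        "lower_spine": LocationProfile("lower_spine", gain=1.0, artifact_noise_sd=6.0),
        "pelvis": LocationProfile("pelvis", gain=1.0, artifact_noise_sd=0.5),
        "thigh_l": LocationProfile("thigh_l", gain=1.0, artifact_noise_sd=5.0),
        "thigh_r": LocationProfile("thigh_r", gain=1.0, artifact_noise_sd=7.0),
        "shank_l": LocationProfile("shank_l", gain=1.0, artifact_noise_sd=5.5),
        "shank_r": LocationProfile("shank_r", gain=1.0, artifact_noise_sd=4.5),
        "foot_l": LocationProfile("foot_l", gain=1.0, artifact_noise_sd=6.0),
        "foot_r": LocationProfile("foot_r", gain=1.0, artifact_noise_sd=5.0),
    }
    for side in ("l", "r"):
        profiles[f"upper_arm_{side}"] = LocationProfile(
            f"upper_arm_{side}", gain=0.6, artifact_noise_sd=6.0, artifact_oscillation=(10.0, 2.0)
        )
        profiles[f"forearm_{side}"] = LocationProfile(
            f"forearm_{side}", gain=0.6, artifact_noise_sd=7.0, artifact_oscillation=(10.0, 2.0)
        )
        profiles[f"hand_{side}"] = LocationProfile(
            f"hand_{side}", gain=0.6, artifact_noise_sd=9.0, artifact_oscillation=(12.0, 2.0)
        )
    return {loc: profiles[loc] for loc in BODY_LOCATIONS}


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for a synthetic session.

    Side-mean durations and outer-foot peak fractions default to the sample
    statistics of a real giant-slalom training session (right turns slower
    and less cleanly loaded than left turns); the adaptation slope is the
    per-turn change per attempt (negative = speeding up).
    """

    n_trials: int = 8
    turns_per_trial: int = 6
    start_side: str = "R"
    mean_duration_right_s: float = 2.08
    mean_duration_left_s: float = 1.68
    duration_sd_s: float = 0.32
    adaptation_slope_s_per_trial: float = -0.05
    roll_amplitude_deg: float = 30.0
    outer_foot_peak_fraction_left_turns: float = 0.86
    outer_foot_peak_fraction_right_turns: float = 0.81
    peak_fraction_sd_left_turns: float = 0.047
    peak_fraction_sd_right_turns: float = 0.086
    location_profiles: dict[str, LocationProfile] = field(default_factory=default_location_profiles)
    imu_rate_hz: float = 100.0
    pressure_rate_hz: float = 50.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.turns_per_trial < 1:
            raise ValueError("turns_per_trial must be >= 1")
        if self.start_side not in ("L", "R"):
            raise ValueError("start_side must be 'L' or 'R'")
        if self.imu_rate_hz <= 0 or self.pressure_rate_hz <= 0:
            raise ValueError("sampling rates must be positive")
        if min(self.mean_duration_left_s, self.mean_duration_right_s) <= 0:
            raise ValueError("mean durations must be positive")
        for frac in (
            self.outer_foot_peak_fraction_left_turns,
            self.outer_foot_peak_fraction_right_turns,
        ):
            if not 0.5 < frac <= 1.0:
                raise ValueError(f"outer-foot peak fraction must be in (0.5, 1], got {frac}")
        if self.duration_sd_s < 0 or self.noise_sd < 0:
            raise ValueError("spread parameters must be >= 0")
        if self.roll_amplitude_deg <= 0:
            raise ValueError("roll_amplitude_deg must be positive")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def attempt_rng(self, attempt: int) -> np.random.Generator:
        """Per-attempt generator, derived from the seed and attempt index so
        table-level and full-signal paths draw identical turn parameters."""
        return np.random.default_rng([self.seed, attempt])


def _check_drift(config: SimulationConfig, max_attempt: int) -> None:
    drift = config.adaptation_slope_s_per_trial * (max_attempt - 1)
    floor = min(config.mean_duration_left_s, config.mean_duration_right_s) + drift
    if floor <= MIN_TURN_DURATION_S:
        raise ValueError(
            "adaptation drift drives mean turn duration to "
            f"{floor:.3f} s by attempt {max_attempt}; config rejected"
        )


def draw_turn_parameters(
    config: SimulationConfig, trial_index: int, rng: np.random.Generator
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Draw sides, true durations and outer-foot peak fractions for one trial.

    The same draws drive both full signal synthesis and table-level
    Monte-Carlo runs, so either path samples identical study conditions.
    """
    if trial_index < 1:
        raise ValueError("trial_index must be >= 1")
    _check_drift(config, trial_index)
    drift = config.adaptation_slope_s_per_trial * (trial_index - 1)
    sides = []
    side = config.start_side
    for _ in range(config.turns_per_trial):
        sides.append(side)
        side = "L" if side == "R" else "R"
    mean = {
        "R": config.mean_duration_right_s + drift,
        "L": config.mean_duration_left_s + drift,
    }
    peak_mean = {
        "R": config.outer_foot_peak_fraction_right_turns,
        "L": config.outer_foot_peak_fraction_left_turns,
    }
    peak_sd = {
        "R": config.peak_fraction_sd_right_turns,
        "L": config.peak_fraction_sd_left_turns,
    }
    durations = np.array(
        [max(rng.normal(mean[s], config.duration_sd_s), MIN_TURN_DURATION_S) for s in sides]
    )
    peaks = np.array(
        [np.clip(rng.normal(peak_mean[s], peak_sd[s]), 0.501, 1.0) for s in sides]
    )
    return sides, durations, peaks


def _latent_roll(
    sides: Sequence[str], n_samples: np.ndarray, amplitude: float
) -> np.ndarray:
    """Concatenated half-sine turns, one per side, signed + for right turns.

    Samples are placed at half-integer phase so the waveform never hits an
    exact zero: sign runs then correspond one-to-one to turns.
    """
    parts = []
    for side, n in zip(sides, n_samples):
        i = np.arange(n)
        wave = amplitude * np.sin(np.pi * (i + 0.5) / n)
        parts.append(wave if side == "R" else -wave)
    return np.concatenate(parts)


def _insole_streams(
    sides: Sequence[str],
    peaks: np.ndarray,
    n_samples_50: np.ndarray,
    rate_hz: float,
    noise_sd: float,
    rng: np.random.Generator,
) -> tuple[InsoleStream, InsoleStream]:
    """Outer-foot loading rising on a raised cosine from 0.5 to the peak
    fraction and back within each turn; outer = left foot in a right turn."""
    left_frac_parts = []
    for side, peak, n in zip(sides, peaks, n_samples_50):
        i = np.arange(n)
        curve = 0.5 + (peak - 0.5) * np.sin(np.pi * (i + 0.5) / n) ** 2
        left_frac_parts.append(curve if side == "R" else 1.0 - curve)
    left_frac = np.concatenate(left_frac_parts)
    left_force = _TOTAL_FORCE * left_frac
    right_force = _TOTAL_FORCE * (1.0 - left_frac)
    cell_noise = noise_sd * 0.1
    left_cells = left_force[:, None] * _CELL_WEIGHTS[None, :]
    right_cells = right_force[:, None] * _CELL_WEIGHTS[None, :]
    if cell_noise > 0:
        left_cells = left_cells + rng.normal(0.0, cell_noise, left_cells.shape)
        right_cells = right_cells + rng.normal(0.0, cell_noise, right_cells.shape)
    left_cells = np.clip(left_cells, 0.0, None)
    right_cells = np.clip(right_cells, 0.0, None)
    return (
        InsoleStream("L", left_cells, rate_hz),
        InsoleStream("R", right_cells, rate_hz),
    )


def simulate_trial(
    config: SimulationConfig,
    trial_index: int,
    rng: Optional[np.random.Generator] = None,
) -> tuple[TrialRecording, GroundTruth]:
    """Generate one trial of alternating turns with its ground truth.

    ``trial_index`` is the attempt number (1-based); the adaptation drift
    scales with it.  Per-location roll traces are gain x latent plus
    session-level noise, location noise, and any artifact oscillation with a
    random phase.
    """
    if rng is None:
        rng = config.attempt_rng(trial_index)
    sides, durations, peaks = draw_turn_parameters(config, trial_index, rng)
    n100 = np.maximum(np.rint(durations * config.imu_rate_hz).astype(int), 2)
    n50 = np.maximum(np.rint(durations * config.pressure_rate_hz).astype(int), 1)
    latent = _latent_roll(sides, n100, config.roll_amplitude_deg)
    n_total = latent.size
    t = np.arange(n_total) / config.imu_rate_hz

    roll: dict[str, TimeSeries] = {}
    for loc in sorted(config.location_profiles):
        prof = config.location_profiles[loc]
        trace = prof.gain * latent
        if config.noise_sd > 0:
            trace = trace + rng.normal(0.0, config.noise_sd, n_total)
        if prof.artifact_noise_sd > 0:
            trace = trace + rng.normal(0.0, prof.artifact_noise_sd, n_total)
        if prof.artifact_oscillation is not None:
            amp, freq = prof.artifact_oscillation
            phase = rng.uniform(0, 2 * np.pi)
            trace = trace + amp * np.sin(2 * np.pi * freq * t + phase)
        roll[loc] = TimeSeries(trace, config.imu_rate_hz, label=loc)

    insole_left, insole_right = _insole_streams(
        sides, peaks, n50, config.pressure_rate_hz, config.noise_sd, rng
    )
    recording = TrialRecording(
        attempt=trial_index,
        roll=roll,
        insole_left=insole_left,
        insole_right=insole_right,
        actual_turn_count=config.turns_per_trial,
    )
    truth = GroundTruth(
        boundaries=np.concatenate([[0], np.cumsum(n100)]),
        sides=list(sides),
        durations_s=n100 / config.imu_rate_hz,
        peak_fractions=peaks,
    )
    return recording, truth


def simulate_session(
    config: SimulationConfig,
    missing_attempts: Sequence[int] = (),
) -> SessionDataset:
    """Generate a full session: ``n_trials`` recordings plus the manifest.

    ``missing_attempts`` marks attempt slots that were made but whose data
    are excluded (e.g., a corrupted recording): they appear in the manifest
    with status "excluded" and produce no recording, so the attempt axis
    keeps its gaps.  Total attempts = n_trials + len(missing_attempts).
    """
    missing = sorted(set(int(m) for m in missing_attempts))
    n_attempts = config.n_trials + len(missing)
    if any(m < 1 or m > n_attempts for m in missing):
        raise ValueError(f"missing attempt indices must be in 1..{n_attempts}")
    _check_drift(config, n_attempts)
    attempts: list[AttemptRecord] = []
    trials: list[TrialRecording] = []
    truths: list[GroundTruth] = []
    for attempt in range(1, n_attempts + 1):
        if attempt in missing:
            attempts.append(AttemptRecord(attempt=attempt, status="excluded"))
            continue
        recording, truth = simulate_trial(config, attempt, config.attempt_rng(attempt))
        attempts.append(
            AttemptRecord(
                attempt=attempt, status="valid", actual_turn_count=config.turns_per_trial
            )
        )
        trials.append(recording)
        truths.append(truth)
    manifest = SessionManifest(
        attempts=attempts,
        imu_rate_hz=config.imu_rate_hz,
        pressure_rate_hz=config.pressure_rate_hz,
        locations=tuple(sorted(config.location_profiles)),
    )
    return SessionDataset(manifest=manifest, trials=trials, ground_truth=truths)


def simulate_turn_table(
    config: SimulationConfig,
    missing_attempts: Sequence[int] = (),
    rng: Optional[np.random.Generator] = None,
):
    """Table-level shortcut: draw per-turn sides/durations/peaks for every
    attempt without synthesizing signals.

    Useful for Monte-Carlo studies of the downstream statistics; the draws
    are the same family the full signal path uses.
    """
    import pandas as pd

    missing = sorted(set(int(m) for m in missing_attempts))
    n_attempts = config.n_trials + len(missing)
    rows = []
    for attempt in range(1, n_attempts + 1):
        if attempt in missing:
            continue
        attempt_rng = config.attempt_rng(attempt) if rng is None else rng
        sides, durations, peaks = draw_turn_parameters(config, attempt, attempt_rng)
        for turn_no, (s, d, p) in enumerate(zip(sides, durations, peaks), start=1):
            rows.append(
                {
                    "trial": attempt,
                    "turn": turn_no,
                    "side": s,
                    "duration_s": float(d),
                    "max_pressure_ratio": float(p),
                }
            )
    return pd.DataFrame(rows)


def pelvis_only_config(**overrides) -> SimulationConfig:
    """Convenience config with a single clean pelvis profile (fast paths)."""
    profiles = {"pelvis": LocationProfile("pelvis", gain=1.0, artifact_noise_sd=0.0)}
    base = SimulationConfig(location_profiles=profiles)
    return replace(base, **overrides) if overrides else base
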