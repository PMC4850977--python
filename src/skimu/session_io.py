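"""Session persistence: trace CSVs, the session manifest, and packaged
reference fixtures.

Layout on disk (one directory per session): ``manifest.json`` plus one tidy
trace CSV per location per trial and one insole CSV per foot per trial.
Synthetic sessions additionally write a ``ground_truth.json`` sidecar.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
from importlib import resources
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .types import (
    N_INSOLE_CELLS,
    AttemptRecord,
    GroundTruth,
    InsoleStream,
    SessionDataset,
    SessionManifest,
    TimeSeries,
    TrialRecording,
)

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

#: Relative timing jitter tolerated silently; larger jitter is regularized
#: onto the nominal grid with a logged warning.
JITTER_TOLERANCE = 0.01

#: SHA-256 checksums of the packaged reference tables.
FIXTURE_CHECKSUMS = {
    "reference_turns": "62bb15b457fe8a72ebf06971752c2ab3774dad36b5d9918b8d19bc004ca63d33",
    "reference_attempts": "5feef5f2e002958dd5eb011bd78eea04494a24a13b4973d6d8ccee9618598e20",
}


def write_trace_csv(series: TimeSeries, path: PathLike) -> None:
    """Write a series as a two-column CSV (``time_s``, ``value``)."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["time_s", "value"])
        for t, v in zip(series.times, series.values):
            writer.writerow([f"{t:.9g}", f"{v:.12g}"])


def read_trace_csv(path: PathLike, label: str = "") -> TimeSeries:
    """Read a trace CSV back into a :class:`TimeSeries`.

    Time must be strictly increasing; the sampling rate is inferred from the
    median step.  Jitter beyond 1% of the step is tolerated but regularized
    onto the nominal grid with a logged warning.  Structural problems raise
    a ``ValueError`` naming the path and line.
    """
    path = Path(path)
    times, values = [], []
    with path.open() as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: file is empty") from None
        header = [h.strip() for h in header]
        if header[:2] != ["time_s", "value"]:
            raise ValueError(f"{path}:1: expected columns time_s,value, got {header}")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            try:
                t, v = float(row[0]), float(row[1])
            except (ValueError, IndexError):
                raise ValueError(f"{path}:{lineno}: malformed row {row!r}") from None
            if times and t <= times[-1]:
                raise ValueError(f"{path}:{lineno}: time not strictly increasing")
            times.append(t)
            values.append(v)
    if not values:
        raise ValueError(f"{path}: no data rows")
    if len(values) == 1:
        return TimeSeries(np.array(values), rate_hz=1.0, t0=times[0], label=label or path.stem)
    dt = np.diff(times)
    step = float(np.median(dt))
    if step <= 0:
        raise ValueError(f"{path}: cannot infer sampling rate")
    jitter = float(np.max(np.abs(dt - step)) / step)
    if jitter > JITTER_TOLERANCE:
        logger.warning(
            "%s: timing jitter %.1f%% exceeds %.0f%%; regularizing onto nominal %.6g s grid",
            path, 100 * jitter, 100 * JITTER_TOLERANCE, step,
        )
    return TimeSeries(np.array(values), rate_hz=1.0 / step, t0=times[0], label=label or path.stem)


def _insole_path(directory: Path, attempt: int, foot: str) -> Path:
    return directory / f"trial{attempt:02d}_insole_{foot}.csv"


def _trace_path(directory: Path, attempt: int, location: str) -> Path:
    return directory / f"trial{attempt:02d}_{location}.csv"


def write_session(dataset: SessionDataset, directory: PathLike) -> Path:
    """Write a session directory: manifest, trace CSVs, insole CSVs, and a
    ground-truth sidecar when present.  Returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    trials = {t.attempt: t for t in dataset.trials}
    manifest_records = []
    for attempt in dataset.manifest.attempts:
        rec = {
            "attempt": attempt.attempt,
            "status": attempt.status,
            "actual_turn_count": attempt.actual_turn_count,
            "trace_files": {},
            "insole_files": {},
        }
        if attempt.status == "valid":
            trial = trials[attempt.attempt]
            for loc, series in trial.roll.items():
                p = _trace_path(directory, attempt.attempt, loc)
                write_trace_csv(series, p)
                rec["trace_files"][loc] = p.name
            for foot, stream in (("L", trial.insole_left), ("R", trial.insole_right)):
                p = _insole_path(directory, attempt.attempt, foot)
                _write_insole_csv(stream, p)
                rec["insole_files"][foot] = p.name
        manifest_records.append(rec)
    manifest = {
        "imu_rate_hz": dataset.manifest.imu_rate_hz,
        "pressure_rate_hz": dataset.manifest.pressure_rate_hz,
        "locations": list(dataset.manifest.locations),
        "attempts": manifest_records,
    }
    _validate_manifest_schema(manifest)
    manifest_path = directory / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    if dataset.ground_truth is not None:
        truth = [
            {
                "attempt": trial.attempt,
                "boundaries": gt.boundaries.tolist(),
                "sides": gt.sides,
                "durations_s": gt.durations_s.tolist(),
                "peak_fractions": gt.peak_fractions.tolist(),
            }
            for trial, gt in zip(dataset.trials, dataset.ground_truth)
        ]
        (directory / "ground_truth.json").write_text(json.dumps(truth, indent=1))
    return manifest_path


def _write_insole_csv(stream: InsoleStream, path: Path) -> None:
    cols = ["time_s"] + [f"cell_{i+1:02d}" for i in range(N_INSOLE_CELLS)]
    n = stream.pressures.shape[0]
    times = stream.t0 + np.arange(n) / stream.rate_hz
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(cols)
        for t, row in zip(times, stream.pressures):
            writer.writerow([f"{t:.9g}"] + [f"{v:.9g}" for v in row])


def _read_insole_csv(path: Path, foot: str) -> InsoleStream:
    df = pd.read_csv(path)
    expected = ["time_s"] + [f"cell_{i+1:02d}" for i in range(N_INSOLE_CELLS)]
    if list(df.columns) != expected:
        raise ValueError(f"{path}: unexpected insole columns {list(df.columns)}")
    t = df["time_s"].to_numpy()
    if np.any(np.diff(t) <= 0):
        raise ValueError(f"{path}: time not strictly increasing")
    rate = 1.0 / float(np.median(np.diff(t))) if len(t) > 1 else 1.0
    return InsoleStream(foot, df[expected[1:]].to_numpy(), rate_hz=rate, t0=float(t[0]))


def _validate_manifest_schema(manifest: dict) -> None:
    for key in ("imu_rate_hz", "pressure_rate_hz", "locations", "attempts"):
        if key not in manifest:
            raise ValueError(f"manifest missing key {key!r}")
    seen = set()
    for rec in manifest["attempts"]:
        for key in ("attempt", "status"):
            if key not in rec:
                raise ValueError(f"manifest attempt record missing {key!r}")
        if rec["status"] not in ("valid", "excluded"):
            raise ValueError(f"attempt {rec['attempt']}: unknown status {rec['status']!r}")
        if rec["attempt"] in seen:
            raise ValueError(f"duplicate attempt index {rec['attempt']}")
        seen.add(rec["attempt"])
        if rec["status"] == "valid" and rec.get("actual_turn_count", 0) < 1:
            raise ValueError(f"attempt {rec['attempt']}: actual turn count must be >= 1")


def read_session(directory: PathLike) -> SessionDataset:
    """Load a session directory written by :func:`write_session`."""
    directory = Path(directory)
    manifest_path = directory / "manifest.json"
    if not manifest_path.exists():
        raise ValueError(f"{manifest_path}: manifest not found")
    manifest = json.loads(manifest_path.read_text())
    _validate_manifest_schema(manifest)
    attempts = []
    trials = []
    for rec in manifest["attempts"]:
        record = AttemptRecord(
            attempt=rec["attempt"],
            status=rec["status"],
            actual_turn_count=rec.get("actual_turn_count", 0),
            trace_files=rec.get("trace_files", {}),
            insole_files=rec.get("insole_files", {}),
        )
        attempts.append(record)
        if record.status != "valid":
            continue
        roll = {
            loc: read_trace_csv(directory / fname, label=loc)
            for loc, fname in record.trace_files.items()
        }
        insoles = {
            foot: _read_insole_csv(directory / fname, foot)
            for foot, fname in record.insole_files.items()
        }
        trials.append(
            TrialRecording(
                attempt=record.attempt,
                roll=roll,
                insole_left=insoles["L"],
                insole_right=insoles["R"],
                actual_turn_count=record.actual_turn_count,
            )
        )
    session_manifest = SessionManifest(
        attempts=attempts,
        imu_rate_hz=manifest["imu_rate_hz"],
        pressure_rate_hz=manifest["pressure_rate_hz"],
        locations=tuple(manifest["locations"]),
    )
    truth = None
    truth_path = directory / "ground_truth.json"
    if truth_path.exists():
        truth = [
            GroundTruth(
                boundaries=np.asarray(rec["boundaries"]),
                sides=rec["sides"],
                durations_s=np.asarray(rec["durations_s"]),
                peak_fractions=np.asarray(rec["peak_fractions"]),
            )
            for rec in json.loads(truth_path.read_text())
        ]
    return SessionDataset(manifest=session_manifest, trials=trials, ground_truth=truth)


def load_fixture(name: str) -> pd.DataFrame:
    """Load a packaged reference table (``"reference_turns"`` or ``"reference_attempts"``).

    ``reference_turns``: 48 per-turn records (trial, turn, side, duration_s,
    max_pressure_ratio) from an eight-trial session of six turns each.
    ``reference_attempts``: the nine-slot attempt axis with per-trial total durations
    (one attempt excluded, kept as a gap) and self-assessment scores.

    File integrity is verified against a SHA-256 checksum.
    """
    if name not in FIXTURE_CHECKSUMS:
        raise ValueError(f"unknown fixture {name!r}; available: {sorted(FIXTURE_CHECKSUMS)}")
    ref = resources.files("skimu") / "fixtures" / f"{name}.csv"
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != FIXTURE_CHECKSUMS[name]:
        raise ValueError(f"fixture {name!r} checksum mismatch: {digest}")
    from io import BytesIO

    return pd.read_csv(BytesIO(raw))
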