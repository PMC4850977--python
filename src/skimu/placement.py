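"""Candidate IMU placement ranking.

Three complementary analyses identify where on the body a single IMU best
captures ski-turn roll motion:

1. *Pattern correlation* — Pearson correlation between each location's
   normalized roll trace and the normalized foot-pressure ratio, per trial;
   locations are summarized by their median across trials.
2. *Hierarchical clustering* — centroid-linkage agglomeration on correlation
   distance (1 - median correlation), showing which locations move with the
   foot-pressure reference.
3. *Turn detection* — the percentage of actual turns recovered by
   zero-crossing segmentation of the (smoothed) roll trace.

A location is a strong candidate when its median correlation clears a
threshold (0.80 by convention) and it detects every turn in every trial;
ties prefer single midline placements over L/R sensor pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .preprocessing import foot_pressure_ratio, moving_average, resample_to, zscore
from .types import MIDLINE_LOCATIONS, SessionDataset, TimeSeries, TurnSegment

logger = logging.getLogger(__name__)

REFERENCE_LABEL = "foot_pressure"

#: Conventional threshold for judging a strong correlation.
DEFAULT_CORRELATION_THRESHOLD = 0.80

#: Default suppression window for jitter crossings.  Zero reproduces raw
#: zero-crossing counting, where spurious crossings show up as >100%
#: detection.
DEFAULT_MIN_TURN_DURATION_S = 0.5


def pattern_correlation(f: TimeSeries, m: TimeSeries) -> float:
    """Pearson correlation between two equal-length series.

    Computed as the normalized cross-product sum with the n-1 denominator,
    sum((f - mean_f)/sd_f * (m - mean_m)/sd_m) / (N - 1),
    which is the product-moment correlation.  Constant inputs are rejected
    (the correlation is undefined).
    """
    if len(f) != len(m):
        raise ValueError(f"series lengths differ: {len(f)} vs {len(m)}")
    if len(f) < 3:
        raise ValueError("pattern correlation needs length >= 3")
    x = f.values
    y = m.values
    sx = float(np.std(x, ddof=1))
    sy = float(np.std(y, ddof=1))
    if sx == 0.0 or sy == 0.0:
        which = f.label if sx == 0.0 else m.label
        raise ValueError(f"correlation undefined for constant trace {which!r}")
    r = float(np.sum((x - x.mean()) / sx * (y - y.mean()) / sy) / (len(x) - 1))
    return float(np.clip(r, -1.0, 1.0))


def _trial_normalized_signals(
    trial, imu_rate_hz: float, window: int
) -> tuple[TimeSeries, dict[str, TimeSeries]]:
    """Pressure-ratio reference and roll traces on one grid, smoothed and
    standard-scored, with invalid (NaN) ratio samples dropped from both."""
    ratio = foot_pressure_ratio(trial.insole_left, trial.insole_right)
    valid = np.isfinite(ratio.values)
    if valid.sum() < max(window, 3):
        raise ValueError(f"attempt {trial.attempt}: too few valid pressure samples")
    if not valid.all():
        # interpolate over flagged samples before resampling
        idx = np.arange(len(ratio))
        filled = np.interp(idx, idx[valid], ratio.values[valid])
        ratio = ratio.with_values(filled)
    ratio = resample_to(ratio, imu_rate_hz)

    n = min(len(ratio), *(len(ts) for ts in trial.roll.values()))
    ref = zscore(moving_average(TimeSeries(ratio.values[:n], imu_rate_hz, label="foot_pressure"), window))
    traces = {}
    for loc, ts in trial.roll.items():
        traces[loc] = zscore(
            moving_average(TimeSeries(ts.values[:n], imu_rate_hz, label=loc), window)
        )
    return ref, traces


def correlation_table(
    session: SessionDataset,
    window: int = 5,
    locations: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Per-location x per-trial pattern correlations with the foot-pressure
    reference, plus per-location mean and median columns.

    Missing traces yield NaN cells and are excluded from the summaries.
    """
    locations = list(locations) if locations is not None else list(session.manifest.locations)
    attempts = [t.attempt for t in session.trials]
    table = pd.DataFrame(np.nan, index=locations, columns=attempts, dtype=float)
    for trial in session.trials:
        ref, traces = _trial_normalized_signals(trial, session.manifest.imu_rate_hz, window)
        for loc in locations:
            if loc not in traces:
                logger.warning("attempt %d: trace for %s missing; cell left blank", trial.attempt, loc)
                continue
            table.loc[loc, trial.attempt] = pattern_correlation(ref, traces[loc])
    table["mean"] = table[attempts].mean(axis=1)
    table["median"] = table[attempts].median(axis=1)
    return table


@dataclass
class ClusterNode:
    """Node of the placement dendrogram.

    Leaves carry one location; internal nodes carry a merge height in
    correlation-distance units and the centroid of their members'
    coordinates (scalar, reference mode only).
    """

    members: tuple[str, ...]
    height: float = 0.0
    centroid: Optional[float] = None
    children: tuple["ClusterNode", ...] = ()

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def to_newick(self) -> str:
        """Nested-parenthesis text export for inspection."""

        def fmt(node: ClusterNode) -> str:
            if node.is_leaf:
                return node.members[0]
            inner = ",".join(fmt(c) for c in node.children)
            return f"({inner}):{node.height:.4f}"

        return fmt(self) + ";"


def _tree_from_linkage(z: np.ndarray, labels: list[str], coords: Optional[np.ndarray]) -> ClusterNode:
    nodes: dict[int, ClusterNode] = {
        i: ClusterNode(
            members=(lab,),
            centroid=None if coords is None else float(coords[i]),
        )
        for i, lab in enumerate(labels)
    }
    n = len(labels)
    for k, (a, b, height, _) in enumerate(z):
        left, right = nodes.pop(int(a)), nodes.pop(int(b))
        members = left.members + right.members
        centroid = None
        if coords is not None:
            centroid = float(np.mean([coords[labels.index(m)] for m in members]))
        nodes[n + k] = ClusterNode(
            members=members, height=float(height), centroid=centroid, children=(left, right)
        )
    (root,) = nodes.values()
    return root


def cluster_locations(
    table: pd.DataFrame,
    mode: str = "reference",
    session: Optional[SessionDataset] = None,
    window: int = 5,
) -> ClusterNode:
    """Agglomerative clustering of locations on correlation distance with
    centroid linkage, d(r, s) = |x̄_r - x̄_s|.

    ``mode="reference"`` (default): each location sits at the scalar
    coordinate 1 - R_l (its correlation distance to the foot-pressure
    reference, which is included as a leaf at coordinate 0).

    ``mode="pairwise"``: full pairwise correlation-distance matrix among the
    IMU signals plus the pressure-ratio reference (requires ``session``);
    pairwise correlations are computed per trial and summarized by their
    median across trials.
    """
    if mode == "reference":
        medians = table["median"].dropna()
        if len(medians) < 1:
            raise ValueError("need at least one location with a valid median")
        labels = [REFERENCE_LABEL] + list(medians.index)
        coords = np.concatenate([[0.0], 1.0 - medians.to_numpy()])
        if len(labels) < 2:
            raise ValueError("clustering needs at least 2 leaves")
        z = linkage(coords[:, None], method="centroid")
        return _tree_from_linkage(z, labels, coords)
    if mode == "pairwise":
        if session is None:
            raise ValueError("pairwise mode requires the session signals")
        labels, dist = _pairwise_median_distance(session, window)
        if len(labels) < 2:
            raise ValueError("clustering needs at least 2 leaves")
        z = linkage(squareform(dist, checks=False), method="centroid")
        return _tree_from_linkage(z, labels, None)
    raise ValueError(f"unknown clustering mode {mode!r}")


def _pairwise_median_distance(session: SessionDataset, window: int) -> tuple[list[str], np.ndarray]:
    labels = [REFERENCE_LABEL] + list(session.manifest.locations)
    per_trial = []
    for trial in session.trials:
        ref, traces = _trial_normalized_signals(trial, session.manifest.imu_rate_hz, window)
        signals = np.column_stack([ref.values] + [traces[loc].values for loc in session.manifest.locations])
        per_trial.append(np.corrcoef(signals, rowvar=False))
    med = np.median(np.stack(per_trial), axis=0)
    dist = 1.0 - med
    np.fill_diagonal(dist, 0.0)
    return labels, dist


def zero_crossing_segments(
    trace: TimeSeries,
    min_duration_s: float = DEFAULT_MIN_TURN_DURATION_S,
) -> list[TurnSegment]:
    """Segment a (smoothed) roll trace into turns at its zero-crossings.

    A turn is a maximal run of constant roll sign: positive roll (leaning
    right) is a right turn, negative a left turn.  Zero samples close the
    preceding run; leading zeros attach to the first signed run.  Runs
    shorter than ``min_duration_s`` are merged into the following run
    (the last run merges backwards), and adjacent same-side runs are then
    coalesced.  ``min_duration_s=0`` reproduces raw zero-crossing counting.
    """
    if min_duration_s < 0:
        raise ValueError("min_duration_s must be >= 0")
    signs = np.sign(trace.values)
    runs: list[list] = []  # [start, end, side]
    current_side = 0.0
    for i, s in enumerate(signs):
        if s == 0:
            continue  # zero sample stays with the run in progress
        if current_side == 0.0:
            runs.append([0, i + 1, s])  # leading zeros attach here
        elif s != current_side:
            runs[-1][1] = i
            runs.append([i, i + 1, s])
        current_side = s
    if not runs:
        return []
    runs[-1][1] = len(signs)  # trailing zeros attach to the last run

    min_samples = min_duration_s * trace.rate_hz
    while len(runs) > 1:
        short = next((k for k, r in enumerate(runs) if r[1] - r[0] < min_samples), None)
        if short is None:
            break
        if short + 1 < len(runs):
            runs[short + 1][0] = runs[short][0]
        else:
            runs[short - 1][1] = runs[short][1]
        del runs[short]
        # coalesce same-side neighbours produced by the merge
        k = 1
        while k < len(runs):
            if runs[k][2] == runs[k - 1][2]:
                runs[k - 1][1] = runs[k][1]
                del runs[k]
            else:
                k += 1

    return [
        TurnSegment(side="R" if side > 0 else "L", start=int(a), end=int(b), rate_hz=trace.rate_hz)
        for a, b, side in runs
    ]


def turn_detection_measure(detected: int, actual: int) -> int:
    """Turn-detection percentage: detected / actual x 100, rounded to the
    nearest integer percent (half away from zero).  100 iff all and only the
    actual turns were found."""
    if actual < 1:
        raise ValueError("actual turn count must be >= 1")
    if detected < 0:
        raise ValueError("detected turn count must be >= 0")
    return int(np.floor(detected / actual * 100.0 + 0.5))


def detection_table(
    session: SessionDataset,
    window: int = 5,
    min_duration_s: float = 0.0,
    locations: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Turn-detection percentages per location x trial, plus a row average.

    Raw zero-crossing counting (``min_duration_s=0``) is the default here so
    spurious crossings surface as >100% cells.
    """
    locations = list(locations) if locations is not None else list(session.manifest.locations)
    attempts = [t.attempt for t in session.trials]
    table = pd.DataFrame(np.nan, index=locations, columns=attempts, dtype=float)
    for trial in session.trials:
        for loc in locations:
            if loc not in trial.roll:
                continue
            smoothed = moving_average(trial.roll[loc], window)
            segs = zero_crossing_segments(smoothed, min_duration_s)
            table.loc[loc, trial.attempt] = turn_detection_measure(
                len(segs), trial.actual_turn_count
            )
    table["average"] = table[attempts].mean(axis=1)
    return table


@dataclass
class PlacementReport:
    """Ranked candidate locations with pass/fail flags and the selection."""

    correlation: pd.DataFrame
    detection: pd.DataFrame
    dendrogram: ClusterNode
    flags: pd.DataFrame  # columns: median, strong_correlation, perfect_detection, paired
    ranking: list[str]
    candidates: list[str] = field(default_factory=list)
    selected: Optional[str] = None

    def to_dict(self) -> dict:
        return {
            "selected": self.selected,
            "candidates": self.candidates,
            "ranking": self.ranking,
            "flags": self.flags.reset_index().rename(columns={"index": "location"}).to_dict("records"),
            "correlation_medians": self.correlation["median"].round(4).to_dict(),
            "detection_averages": self.detection["average"].round(1).to_dict(),
            "dendrogram": self.dendrogram.to_newick(),
        }

    def to_markdown(self) -> str:
        lines = ["# Sensor placement report", ""]
        lines.append(f"Selected location: **{self.selected or 'none'}**")
        lines.append("")
        lines.append("## Candidate flags")
        lines.append(self.flags.to_markdown())
        lines.append("")
        lines.append("## Correlation table")
        lines.append(self.correlation.round(2).to_markdown())
        lines.append("")
        lines.append("## Detection table")
        lines.append(self.detection.round(0).to_markdown())
        lines.append("")
        lines.append("## Dendrogram (nested text)")
        lines.append("```\n" + self.dendrogram.to_newick() + "\n```")
        return "\n".join(lines)


def rank_locations(
    correlation: pd.DataFrame,
    detection: pd.DataFrame,
    dendrogram: ClusterNode,
    correlation_threshold: float = DEFAULT_CORRELATION_THRESHOLD,
) -> PlacementReport:
    """Flag and rank locations; select the best candidate.

    A location passes the strong-correlation flag when its median pattern
    correlation is at least ``correlation_threshold``, and the
    perfect-detection flag when every trial and the average detect exactly
    100%.  Ranking: both flags first, then higher median correlation, then
    single midline placements ahead of L/R pairs, ties alphabetical.
    """
    locations = list(correlation.index)
    attempts = [c for c in detection.columns if c != "average"]
    rows = []
    for loc in locations:
        median = correlation.loc[loc, "median"]
        strong = bool(median >= correlation_threshold) if np.isfinite(median) else False
        if loc in detection.index:
            cells = detection.loc[loc, attempts].dropna()
            perfect = bool(len(cells) > 0 and (cells == 100).all())
        else:
            perfect = False
        rows.append(
            {
                "location": loc,
                "median": median,
                "strong_correlation": strong,
                "perfect_detection": perfect,
                "paired": loc not in MIDLINE_LOCATIONS,
            }
        )
    flags = pd.DataFrame(rows).set_index("location")
    both = flags["strong_correlation"] & flags["perfect_detection"]
    order = sorted(
        locations,
        key=lambda l: (
            not both[l],
            -(flags.loc[l, "median"] if np.isfinite(flags.loc[l, "median"]) else -np.inf),
            flags.loc[l, "paired"],
            l,
        ),
    )
    candidates = [l for l in order if both[l]]
    return PlacementReport(
        correlation=correlation,
        detection=detection,
        dendrogram=dendrogram,
        flags=flags,
        ranking=order,
        candidates=candidates,
        selected=candidates[0] if candidates else None,
    )


class PlacementSelector(BaseEstimator):
    """Estimator that ranks IMU body locations from a recorded session.

    Parameters
    ----------
    window : int
        Moving-average smoothing window (odd), default 5.
    correlation_threshold : float
        Median-correlation level for the strong-correlation flag.
    detection_min_duration_s : float
        Jitter-suppression window used when counting turns for the
        detection table; the default matches the segmenter's 0.5 s.  Set 0
        for raw zero-crossing counting (spurious crossings then surface as
        >100% cells, at the cost of a fragile perfect-detection flag).
    cluster_mode : str
        "reference" (scalar 1 - R_l coordinates) or "pairwise".

    Attributes
    ----------
    correlation_table_ : DataFrame
    detection_table_ : DataFrame
    dendrogram_ : ClusterNode
    report_ : PlacementReport
    ranking_ : list of str
    selected_location_ : str or None
    """

    def __init__(
        self,
        window: int = 5,
        correlation_threshold: float = DEFAULT_CORRELATION_THRESHOLD,
        detection_min_duration_s: float = DEFAULT_MIN_TURN_DURATION_S,
        cluster_mode: str = "reference",
    ):
        self.window = window
        self.correlation_threshold = correlation_threshold
        self.detection_min_duration_s = detection_min_duration_s
        self.cluster_mode = cluster_mode

    def fit(self, X: SessionDataset, y=None):
        if not isinstance(X, SessionDataset):
            raise TypeError("PlacementSelector.fit expects a SessionDataset")
        if not X.trials:
            raise ValueError("session has no valid trials")
        self.correlation_table_ = correlation_table(X, window=self.window)
        self.detection_table_ = detection_table(
            X, window=self.window, min_duration_s=self.detection_min_duration_s
        )
        self.dendrogram_ = cluster_locations(
            self.correlation_table_, mode=self.cluster_mode, session=X, window=self.window
        )
        self.report_ = rank_locations(
            self.correlation_table_,
            self.detection_table_,
            self.dendrogram_,
            self.correlation_threshold,
        )
        self.ranking_ = self.report_.ranking
        self.selected_location_ = self.report_.selected
        return self

    def predict(self, X=None) -> Optional[str]:
        """Return the selected location (fit result; X is ignored)."""
        check_is_fitted(self, "report_")
        return self.selected_location_
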