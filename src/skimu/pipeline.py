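"""End-to-end orchestration: placement ranking, then performance statistics
from the selected location."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .performance import (
    AdaptationResult,
    MeasureAsymmetry,
    adaptation_analysis,
    asymmetry_analysis,
    asymmetry_summary,
    session_totals,
    session_turn_table,
)
from .placement import PlacementReport, PlacementSelector
from .types import SessionDataset

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    """Everything one run produces: the placement report, the per-turn
    performance table, the asymmetry tests, and the adaptation trend."""

    placement: PlacementReport
    analysis_location: str
    turn_table: pd.DataFrame
    excluded_attempts: list[int]
    asymmetry: dict[str, MeasureAsymmetry]
    adaptation: AdaptationResult

    def to_dict(self) -> dict:
        return {
            "placement": self.placement.to_dict(),
            "analysis_location": self.analysis_location,
            "turn_table": self.turn_table.round(6).to_dict("records"),
            "excluded_attempts": self.excluded_attempts,
            "asymmetry": {
                m: {
                    "normality": [vars(n) for n in res.normality],
                    "variance": vars(res.variance),
                    "ttest": res.ttest.to_dict(),
                }
                for m, res in self.asymmetry.items()
            },
            "adaptation": self.adaptation.to_dict(),
        }

    def to_markdown(self) -> str:
        lines = [self.placement.to_markdown(), ""]
        lines.append("# Performance analysis")
        lines.append(f"Analysis location: **{self.analysis_location}**")
        if self.excluded_attempts:
            lines.append(f"Excluded attempts (segment-count mismatch): {self.excluded_attempts}")
        lines.append("")
        lines.append("## Lateral asymmetry")
        lines.append(asymmetry_summary(self.asymmetry).to_markdown())
        lines.append("")
        lines.append("## Adaptation effect")
        a = self.adaptation
        lines.append(
            f"r = {a.r:.3f}, slope = {a.slope:.3f} s/attempt, "
            f"t = {a.statistic:.2f}, p = {a.p_value:.4f} over n = {a.n} attempts"
        )
        return "\n".join(lines)

    def write(self, directory) -> None:
        """Emit report.json and report.md (schema-validated JSON)."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        payload = self.to_dict()
        for key in ("placement", "analysis_location", "turn_table", "asymmetry", "adaptation"):
            if key not in payload:
                raise ValueError(f"report payload missing {key!r}")
        (directory / "report.json").write_text(json.dumps(payload, indent=1, sort_keys=True))
        (directory / "report.md").write_text(self.to_markdown())


def run_pipeline(
    session: SessionDataset,
    window: int = 5,
    correlation_threshold: float = 0.80,
    alpha: float = 0.05,
    min_turn_duration_s: float = 0.5,
    location: Optional[str] = None,
) -> PipelineResult:
    """Run placement selection, then asymmetry and adaptation analyses on
    the selected (or explicitly given) location.

    Deterministic for a given session.  Every exclusion and branching
    decision is logged by the underlying analyses.
    """
    if not session.trials:
        raise ValueError("session has no valid trials")
    selector = PlacementSelector(
        window=window, correlation_threshold=correlation_threshold
    ).fit(session)
    report = selector.report_
    chosen = location or selector.selected_location_ or report.ranking[0]
    logger.info("analysis location: %s (selected=%s)", chosen, selector.selected_location_)

    table, excluded = session_turn_table(
        session, chosen, window=window, min_duration_s=min_turn_duration_s
    )
    if table.empty:
        raise ValueError("no trials survived segmentation; nothing to analyze")
    asym = asymmetry_analysis(table, alpha=alpha)

    all_attempts: Sequence[int] = [a.attempt for a in session.manifest.attempts]
    attempts, totals = session_totals(table, all_attempts)
    # trials excluded here (wrong segment count) also become axis gaps
    for att in excluded:
        totals[np.asarray(all_attempts) == att] = np.nan
    adaptation = adaptation_analysis(attempts, totals)
    return PipelineResult(
        placement=report,
        analysis_location=chosen,
        turn_table=table,
        excluded_attempts=excluded,
        asymmetry=asym,
        adaptation=adaptation,
    )
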