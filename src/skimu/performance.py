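"""Turn-performance statistics: lateral asymmetry and the adaptation effect.

Lateral asymmetry is tested per measure (turn duration from the IMU; max
outer-foot pressure ratio from the insoles) with a two-sample t-test on left
vs. right turns.  Normality is screened with a Kolmogorov-Smirnov test per
group, and an F ratio of sample variances selects the pooled-variance or
Welch branch.  The adaptation effect is the Pearson correlation (with an OLS
line) between attempt index and per-trial total duration; attempts lost to
data errors stay on the attempt axis as gaps, so the trend is measured
against the true practice count.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .preprocessing import foot_pressure_ratio, resample_to
from .types import SessionDataset, TurnSegment

logger = logging.getLogger(__name__)

MEASURES = ("duration_s", "max_pressure_ratio")


def t_critical(alpha: float, df: float) -> float:
    """Two-sided critical point of Student's t: the upper alpha/2 quantile."""
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if df < 1:
        raise ValueError(f"df must be >= 1, got {df}")
    return float(stats.t.ppf(1 - alpha / 2, df))


@dataclass
class TTestResult:
    """Full record of one two-sample mean test.

    ``df`` is the reported (integer) degrees of freedom — n_a + n_b - 2 for
    the pooled variant, the truncated Welch-Satterthwaite value for Welch.
    ``df_exact`` keeps the unrounded Welch df; p-values use it.
    """

    variant: str  # "pooled" | "welch"
    mean_a: float
    mean_b: float
    var_a: float
    var_b: float
    n_a: int
    n_b: int
    statistic: float
    df: int
    df_exact: float
    critical: float
    alpha: float
    p_value: float
    reject: bool
    pooled_sd: Optional[float] = None

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "variant", "mean_a", "mean_b", "var_a", "var_b", "n_a", "n_b",
            "statistic", "df", "df_exact", "critical", "alpha", "p_value", "reject",
        )}
        d["pooled_sd"] = self.pooled_sd
        return d


def _groups(a: Sequence[float], b: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 samples")
    return a, b


def pooled_t(a: Sequence[float], b: Sequence[float], alpha: float = 0.05) -> TTestResult:
    """Equal-variance two-sample t-test.

    T = (mean_a - mean_b) / (S_p sqrt(1/n_a + 1/n_b)) with the pooled sd
    S_p = sqrt(((n_a-1) s_a^2 + (n_b-1) s_b^2) / (n_a + n_b - 2)).
    The decision compares |T| with the two-sided critical point.
    """
    a, b = _groups(a, b)
    n_a, n_b = a.size, b.size
    va, vb = a.var(ddof=1), b.var(ddof=1)
    df = n_a + n_b - 2
    sp = math.sqrt(((n_a - 1) * va + (n_b - 1) * vb) / df)
    diff = a.mean() - b.mean()
    if sp == 0.0:
        if diff != 0.0:
            raise ValueError("zero pooled variance with unequal means")
        t = 0.0
    else:
        t = diff / (sp * math.sqrt(1 / n_a + 1 / n_b))
    crit = t_critical(alpha, df)
    p = 2 * stats.t.sf(abs(t), df)
    return TTestResult(
        variant="pooled", mean_a=float(a.mean()), mean_b=float(b.mean()),
        var_a=float(va), var_b=float(vb), n_a=n_a, n_b=n_b,
        statistic=float(t), df=df, df_exact=float(df), critical=crit,
        alpha=alpha, p_value=float(p), reject=bool(abs(t) > crit),
        pooled_sd=float(sp),
    )


def welch_t(a: Sequence[float], b: Sequence[float], alpha: float = 0.05) -> TTestResult:
    """Unequal-variance (Welch) two-sample t-test.

    T = (mean_a - mean_b) / sqrt(s_a^2/n_a + s_b^2/n_b) with the
    Welch-Satterthwaite degrees of freedom.  The reported df is the integer
    part of the real-valued df (matching conventional table lookups) and
    sets the critical point; the p-value uses the exact df.
    """
    a, b = _groups(a, b)
    n_a, n_b = a.size, b.size
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / n_a + vb / n_b
    diff = a.mean() - b.mean()
    if se2 == 0.0:
        if diff != 0.0:
            raise ValueError("zero variance in both groups with unequal means")
        t, v = 0.0, float(n_a + n_b - 2)
    else:
        t = diff / math.sqrt(se2)
        v = se2**2 / ((va / n_a) ** 2 / (n_a - 1) + (vb / n_b) ** 2 / (n_b - 1))
    df_report = int(v)
    crit = t_critical(alpha, df_report)
    p = 2 * stats.t.sf(abs(t), v)
    return TTestResult(
        variant="welch", mean_a=float(a.mean()), mean_b=float(b.mean()),
        var_a=float(va), var_b=float(vb), n_a=n_a, n_b=n_b,
        statistic=float(t), df=df_report, df_exact=float(v), critical=crit,
        alpha=alpha, p_value=float(p), reject=bool(abs(t) > crit),
    )


@dataclass
class NormalityResult:
    group: str
    statistic: float
    p_value: float
    alpha: float
    normal: bool


@dataclass
class VarianceTestResult:
    statistic: float
    p_value: float
    alpha: float
    equal: bool
    method: str = "f"


def ks_normality(x: Sequence[float], alpha: float = 0.05, group: str = "") -> NormalityResult:
    """One-sample Kolmogorov-Smirnov test against a normal with the group's
    own sample mean and sd.  Estimating the parameters from the same data
    makes the test conservative (the Lilliefors caveat)."""
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError("normality check needs at least 3 samples")
    res = stats.kstest(x, "norm", args=(x.mean(), x.std(ddof=1)))
    if res.pvalue <= alpha:
        logger.warning("K-S normality rejected for group %s (p=%.4f)", group, res.pvalue)
    return NormalityResult(group, float(res.statistic), float(res.pvalue), alpha, bool(res.pvalue > alpha))


def variance_f_test(a: Sequence[float], b: Sequence[float], alpha: float = 0.05) -> VarianceTestResult:
    """Two-sided F ratio test of variance equality, F = s_a^2 / s_b^2."""
    a, b = _groups(a, b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if vb == 0.0 and va == 0.0:
        return VarianceTestResult(1.0, 1.0, alpha, True)
    if vb == 0.0 or va == 0.0:
        return VarianceTestResult(float("inf"), 0.0, alpha, False)
    f = va / vb
    cdf = stats.f.cdf(f, a.size - 1, b.size - 1)
    p = 2 * min(cdf, 1 - cdf)
    return VarianceTestResult(float(f), float(p), alpha, bool(p > alpha))


def build_turn_table(
    segments_by_attempt: dict[int, list[TurnSegment]],
    ratio_by_attempt: dict[int, "np.ndarray | None"],
    expected_turns: dict[int, int],
) -> tuple[pd.DataFrame, list[int]]:
    """Assemble the per-turn performance table.

    Per segment: duration in seconds and the maximum outer-foot pressure
    fraction over the segment, where the outer foot is the right foot in a
    left turn and the left foot in a right turn.  With the signed ratio
    r = (F_L - F_R)/(F_L + F_R), the outer-foot fraction is (1 + r)/2 in a
    right turn and (1 - r)/2 in a left turn.  ``ratio_by_attempt`` must be
    sample-aligned with the segments' index space.

    Trials whose detected segment count differs from the expected turn count
    are excluded (logged), mirroring how corrupted attempts are dropped.
    Returns the table and the excluded attempt indices.
    """
    rows = []
    excluded: list[int] = []
    for attempt in sorted(segments_by_attempt):
        segs = segments_by_attempt[attempt]
        expected = expected_turns[attempt]
        if len(segs) != expected:
            logger.warning(
                "attempt %d excluded: detected %d turns, expected %d",
                attempt, len(segs), expected,
            )
            excluded.append(attempt)
            continue
        ratio = ratio_by_attempt.get(attempt)
        for turn_no, seg in enumerate(segs, start=1):
            if ratio is None:
                max_ratio = np.nan
            else:
                r = np.asarray(ratio)[seg.start : seg.end]
                r = r[np.isfinite(r)]
                if r.size == 0:
                    max_ratio = np.nan
                else:
                    outer = (1 + r) / 2 if seg.side == "R" else (1 - r) / 2
                    max_ratio = float(outer.max())
            rows.append(
                {
                    "trial": attempt,
                    "turn": turn_no,
                    "side": seg.side,
                    "duration_s": seg.duration_s,
                    "max_pressure_ratio": max_ratio,
                }
            )
    return pd.DataFrame(rows, columns=["trial", "turn", "side", "duration_s", "max_pressure_ratio"]), excluded


def session_turn_table(
    session: SessionDataset,
    location: str,
    window: int = 5,
    min_duration_s: float = 0.5,
) -> tuple[pd.DataFrame, list[int]]:
    """Segment every trial at ``location`` and build the turn table."""
    from .preprocessing import moving_average
    from .placement import zero_crossing_segments

    segments, ratios, expected = {}, {}, {}
    for trial in session.trials:
        smoothed = moving_average(trial.roll[location], window)
        segments[trial.attempt] = zero_crossing_segments(smoothed, min_duration_s)
        ratio = foot_pressure_ratio(trial.insole_left, trial.insole_right)
        valid = np.isfinite(ratio.values)
        if not valid.all():
            idx = np.arange(len(ratio))
            ratio = ratio.with_values(np.interp(idx, idx[valid], ratio.values[valid]))
        ratios[trial.attempt] = resample_to(ratio, session.manifest.imu_rate_hz).values
        expected[trial.attempt] = trial.actual_turn_count
    return build_turn_table(segments, ratios, expected)


@dataclass
class MeasureAsymmetry:
    measure: str
    normality: list[NormalityResult]
    variance: VarianceTestResult
    ttest: TTestResult


def asymmetry_analysis(
    table: pd.DataFrame, alpha: float = 0.05
) -> dict[str, MeasureAsymmetry]:
    """Branched left/right asymmetry test for each performance measure.

    Groups are the left-turn and right-turn values of the measure.  Per
    measure: K-S normality per group, an F test of variance equality, then
    the pooled t-test if variances are judged equal and the Welch test
    otherwise.  Group "a" is left, "b" is right, so a negative duration
    statistic means left turns are faster.
    """
    out = {}
    for measure in MEASURES:
        sub = table.dropna(subset=[measure])
        left = sub.loc[sub["side"] == "L", measure].to_numpy()
        right = sub.loc[sub["side"] == "R", measure].to_numpy()
        if left.size < 2 or right.size < 2:
            raise ValueError(f"measure {measure!r}: need >= 2 turns per side")
        normality = [
            ks_normality(left, alpha, group=f"L/{measure}"),
            ks_normality(right, alpha, group=f"R/{measure}"),
        ]
        var_res = variance_f_test(left, right, alpha)
        test = pooled_t(left, right, alpha) if var_res.equal else welch_t(left, right, alpha)
        logger.info(
            "%s: variance %s (p=%.4f) -> %s branch; |t|=%.3f vs %.3f -> %s",
            measure, "equal" if var_res.equal else "unequal", var_res.p_value,
            test.variant, abs(test.statistic), test.critical,
            "reject" if test.reject else "retain",
        )
        out[measure] = MeasureAsymmetry(measure, normality, var_res, test)
    return out


def asymmetry_summary(results: dict[str, MeasureAsymmetry]) -> pd.DataFrame:
    """Hypothesis-test summary table, one column per measure."""
    cols = {}
    for measure, res in results.items():
        t = res.ttest
        cols[measure] = {
            "variant": t.variant,
            "|t|": round(abs(t.statistic), 2),
            "df": t.df,
            "critical (two-sided)": round(t.critical, 2),
            "alpha": t.alpha,
            "result": "H0 rejected" if t.reject else "H0 retained",
        }
    return pd.DataFrame(cols)


@dataclass
class AdaptationResult:
    """Trend of per-trial total duration across attempts."""

    attempts: np.ndarray  # all attempt indices, missing kept as axis gaps
    totals: np.ndarray  # NaN at missing attempts
    r: float
    slope: float
    intercept: float
    statistic: float
    p_value: float
    n: int

    def to_dict(self) -> dict:
        return {
            "attempts": self.attempts.tolist(),
            "totals": [None if not np.isfinite(v) else float(v) for v in self.totals],
            "r": self.r, "slope": self.slope, "intercept": self.intercept,
            "statistic": self.statistic, "p_value": self.p_value, "n": self.n,
        }


def adaptation_analysis(
    attempt_indices: Sequence[float], total_durations: Sequence[float]
) -> AdaptationResult:
    """Pearson correlation and OLS line between attempt index and per-trial
    total duration.

    Missing attempts are passed as NaN totals: they keep their place on the
    attempt axis (the practice count includes them) but contribute no point.
    Significance uses t = r sqrt(n-2) / sqrt(1 - r^2) on n non-missing
    attempts.
    """
    attempts = np.asarray(attempt_indices, dtype=float)
    totals = np.asarray(total_durations, dtype=float)
    if attempts.shape != totals.shape:
        raise ValueError("attempt indices and totals must have equal length")
    mask = np.isfinite(totals)
    x, y = attempts[mask], totals[mask]
    n = int(x.size)
    if n < 3:
        raise ValueError("adaptation analysis needs >= 3 non-missing attempts")
    if np.std(y) == 0.0:
        raise ValueError("total durations are constant; correlation undefined")
    fit = stats.linregress(x, y)
    r = float(fit.rvalue)
    if abs(r) < 1.0:
        t = r * math.sqrt(n - 2) / math.sqrt(1 - r * r)
        p = 2 * stats.t.sf(abs(t), n - 2)
    else:
        t, p = math.copysign(float("inf"), r), 0.0
    return AdaptationResult(
        attempts=attempts, totals=totals, r=r,
        slope=float(fit.slope), intercept=float(fit.intercept),
        statistic=float(t), p_value=float(p), n=n,
    )


def session_totals(table: pd.DataFrame, all_attempts: Sequence[int]) -> tuple[np.ndarray, np.ndarray]:
    """Per-trial total durations aligned on the full attempt axis (NaN gaps)."""
    sums = table.groupby("trial")["duration_s"].sum()
    attempts = np.asarray(list(all_attempts), dtype=float)
    totals = np.array([sums.get(int(a), np.nan) for a in attempts])
    return attempts, totals


class AsymmetryTester(BaseEstimator):
    """Estimator wrapper around the branched lateral-asymmetry analysis.

    ``fit`` takes a turn table (DataFrame with columns ``side``,
    ``duration_s``, ``max_pressure_ratio``) and exposes ``results_`` (per
    measure) and a Table-style ``summary_``.
    """

    def __init__(self, alpha: float = 0.05):
        self.alpha = alpha

    def fit(self, X: pd.DataFrame, y=None):
        self.results_ = asymmetry_analysis(X, alpha=self.alpha)
        self.summary_ = asymmetry_summary(self.results_)
        return self

    def predict(self, X=None) -> dict[str, bool]:
        """Rejection decision per measure."""
        check_is_fitted(self, "results_")
        return {m: r.ttest.reject for m, r in self.results_.items()}


class AdaptationRegression(RegressorMixin, BaseEstimator):
    """OLS + correlation significance of total duration against attempt index.

    sklearn-style: ``fit(X, y)`` with X of shape (n, 1) (attempt indices;
    NaN y entries are axis gaps), ``predict`` evaluates the fitted line.
    """

    def fit(self, X, y):
        X = np.asarray(X, dtype=float).reshape(-1)
        res = adaptation_analysis(X, y)
        self.result_ = res
        self.r_ = res.r
        self.coef_ = np.array([res.slope])
        self.intercept_ = res.intercept
        self.statistic_ = res.statistic
        self.p_value_ = res.p_value
        self.n_ = res.n
        return self

    def predict(self, X):
        check_is_fitted(self, "result_")
        X = np.asarray(X, dtype=float).reshape(-1)
        return self.intercept_ + self.coef_[0] * X
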