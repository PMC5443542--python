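"""Goal-scoring engine.

Each goal is assessed on four dimensions — current status, recent trend,
pressures and resilience — projected to a likely future status, scored as the
mean of status and future, and aggregated across goals under an arbitrary
nonnegative weight vector.

Conventions
-----------
Status, pressure and resilience live on a 0-100 scale; trend is a total
proportional change over the trend window, in [-1, 1].  The future-status
projection rescales (r - p) to the 0-1 scale internally.  Weight vectors are
used as given: the index is invariant under rescaling all weights by a
positive constant, so "sum to 1" and "sum to 10" conventions coexist.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "GoalParameters",
    "ResilienceComponents",
    "PressureComponents",
    "GoalAssessment",
    "AnnualSeries",
    "combine_resilience",
    "combine_pressure",
    "likely_future_status",
    "goal_score",
    "aggregate_subgoals",
    "aggregate_index",
    "recent_trend",
    "ciw_gdp_index",
    "assess_goal",
    "round_half_away",
    "clamp",
]


def clamp(x: float, lo: float, hi: float) -> float:
    """Clamp ``x`` to the closed interval [lo, hi]."""
    return min(max(x, lo), hi)


def round_half_away(x: float, decimals: int = 2) -> float:
    """Round with ties going away from zero (reporting convention).

    Computation elsewhere is full precision; this is applied only when
    rendering results (64.546 -> 64.55).
    """
    factor = 10.0**decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def _check_score(name: str, value: float) -> None:
    if not (0.0 <= value <= 100.0):
        raise ValueError(f"{name} must be in [0, 100], got {value!r}")


@dataclass(frozen=True)
class GoalParameters:
    """Engine constants.

    beta weights trend against (resilience - pressure) in the future-status
    projection; gamma blends ecological vs social components of pressure and
    resilience; delta is a discount rate on the projection; x_max is the
    maximum attainable status used in the index denominator.
    """

    beta: float = 0.67
    gamma: float = 0.5
    delta: float = 0.0
    x_max: float = 100.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.beta <= 1.0):
            raise ValueError(f"beta must be in [0, 1], got {self.beta!r}")
        if not (0.0 <= self.gamma <= 1.0):
            raise ValueError(f"gamma must be in [0, 1], got {self.gamma!r}")
        if self.delta < 0:
            raise ValueError(f"delta must be >= 0, got {self.delta!r}")
        if self.x_max <= 0:
            raise ValueError(f"x_max must be > 0, got {self.x_max!r}")


@dataclass(frozen=True)
class ResilienceComponents:
    """Ecological integrity, regulations and social integrity, each 0-100."""

    ecological_integrity: float
    regulations: float
    social_integrity: float

    def __post_init__(self) -> None:
        _check_score("ecological_integrity", self.ecological_integrity)
        _check_score("regulations", self.regulations)
        _check_score("social_integrity", self.social_integrity)


@dataclass(frozen=True)
class PressureComponents:
    """Ecological and social pressure, each 0-100."""

    ecological: float
    social: float

    def __post_init__(self) -> None:
        _check_score("ecological", self.ecological)
        _check_score("social", self.social)


@dataclass(frozen=True)
class GoalAssessment:
    """One goal's (or subgoal's) full assessment."""

    goal_id: str
    status: float
    trend: float
    pressure: float
    resilience: float
    future: float
    score: float

    def __post_init__(self) -> None:
        _check_score("status", self.status)
        _check_score("pressure", self.pressure)
        _check_score("resilience", self.resilience)
        _check_score("future", self.future)
        _check_score("score", self.score)
        if not (-1.0 <= self.trend <= 1.0):
            raise ValueError(f"trend must be in [-1, 1], got {self.trend!r}")


@dataclass(frozen=True)
class AnnualSeries:
    """An annual time series with strictly increasing integer years."""

    years: tuple[int, ...]
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.years) != len(self.values):
            raise ValueError("years and values must have equal length")
        if len(self.years) == 0:
            raise ValueError("series must be non-empty")
        if any(b <= a for a, b in zip(self.years, self.years[1:])):
            raise ValueError("years must be strictly increasing")

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[int, float]]) -> "AnnualSeries":
        pairs = sorted(pairs)
        return cls(tuple(int(y) for y, _ in pairs), tuple(float(v) for _, v in pairs))

    def value(self, year: int) -> float:
        try:
            return self.values[self.years.index(year)]
        except ValueError:
            raise KeyError(f"year {year} not in series") from None

    def tail(self, window: int) -> "AnnualSeries":
        """Most recent ``window`` consecutive years; errors on gaps or short series."""
        if len(self.years) < window:
            raise ValueError(
                f"need at least {window} points, series has {len(self.years)}"
            )
        ys, vs = self.years[-window:], self.values[-window:]
        if ys[-1] - ys[0] != window - 1:
            raise ValueError(f"years {ys[0]}..{ys[-1]} contain gaps")
        return AnnualSeries(ys, vs)


def combine_resilience(components: ResilienceComponents, gamma: float = 0.5) -> float:
    """r = gamma * (Y_E + G)/2 + (1 - gamma) * Y_S."""
    if not (0.0 <= gamma <= 1.0):
        raise ValueError(f"gamma must be in [0, 1], got {gamma!r}")
    c = components
    return gamma * (c.ecological_integrity + c.regulations) / 2.0 + (
        1.0 - gamma
    ) * c.social_integrity


def combine_pressure(components: PressureComponents, gamma: float = 0.5) -> float:
    """p = gamma * p_E + (1 - gamma) * p_S."""
    if not (0.0 <= gamma <= 1.0):
        raise ValueError(f"gamma must be in [0, 1], got {gamma!r}")
    return gamma * components.ecological + (1.0 - gamma) * components.social


def likely_future_status(
    status: float,
    trend: float,
    pressure: float,
    resilience: float,
    params: GoalParameters = GoalParameters(),
) -> float:
    """Project status five years out from trend, pressure and resilience.

    future = (1 + delta)^-1 * [1 + beta*T + (1-beta) * (r - p)/100] * x,
    clamped to [0, 100].  Pressure and resilience enter on the 0-100 scale
    and are rescaled to 0-1 inside the bracket.
    """
    _check_score("status", status)
    _check_score("pressure", pressure)
    _check_score("resilience", resilience)
    if not (-1.0 <= trend <= 1.0):
        raise ValueError(f"trend must be in [-1, 1], got {trend!r}")
    raw = (
        (1.0 + params.delta) ** -1
        * (
            1.0
            + params.beta * trend
            + (1.0 - params.beta) * (resilience - pressure) / 100.0
        )
        * status
    )
    return clamp(raw, 0.0, 100.0)


def goal_score(status: float, future: float) -> float:
    """Score = mean of current status and likely future status."""
    _check_score("status", status)
    _check_score("future", future)
    return (status + future) / 2.0


def aggregate_subgoals(values_weights: Sequence[tuple[float, float]]) -> float:
    """Weighted mean of subgoal values (applied dimension-wise by callers)."""
    if len(values_weights) == 0:
        raise ValueError("need at least one subgoal")
    values = np.asarray([v for v, _ in values_weights], dtype=float)
    weights = np.asarray([w for _, w in values_weights], dtype=float)
    if (weights < 0).any():
        raise ValueError("subgoal weights must be nonnegative")
    total = weights.sum()
    if total == 0:
        raise ValueError("subgoal weights must not all be zero")
    return float((values * weights).sum() / total)


def aggregate_index(
    scores: Mapping[str, float],
    weights: Mapping[str, float],
    params: GoalParameters = GoalParameters(),
) -> float:
    """Overall index: sum(alpha_i * I_i) / sum(alpha_i * x_max) * 100.

    Invariant under rescaling all weights by a positive constant.  Every goal
    carrying positive weight must have a score.
    """
    if not weights:
        raise ValueError("weight vector is empty")
    w = np.asarray(list(weights.values()), dtype=float)
    if (w < 0).any():
        raise ValueError("weights must be nonnegative")
    if w.sum() == 0:
        raise ValueError("at least one weight must be positive")
    num = 0.0
    den = 0.0
    for goal, alpha in weights.items():
        if alpha == 0:
            continue
        if goal not in scores:
            raise KeyError(f"goal {goal!r} has weight {alpha} but is missing a score")
        _check_score(f"score[{goal}]", scores[goal])
        num += alpha * scores[goal]
        den += alpha * params.x_max
    return num / den * 100.0


def recent_trend(
    series: AnnualSeries, window: int = 5, mode: str = "absolute"
) -> float:
    """Trend over the most recent ``window`` years, clamped to [-1, 1].

    mode="absolute" (default): OLS slope of status/100 vs year, times the
    window length — the total proportional change of a full-scale goal.
    mode="relative": the slope divided by the fitted value at the start of
    the window, i.e. change relative to the recent status level.
    """
    if mode not in ("absolute", "relative"):
        raise ValueError(f"unknown trend mode {mode!r}")
    recent = series.tail(window)
    years = np.asarray(recent.years, dtype=float)
    values = np.asarray(recent.values, dtype=float)
    if np.ptp(values) == 0.0:  # constant series: avoid float noise in polyfit
        return 0.0
    slope, intercept = np.polyfit(years, values, 1)
    if mode == "absolute":
        total = slope / 100.0 * window
    elif mode == "relative":
        start = intercept + slope * years[0]
        if start == 0:
            raise ValueError("relative trend undefined: fitted start value is 0")
        total = slope / start * window
    return clamp(float(total), -1.0, 1.0)


def ciw_gdp_index(
    ciw: AnnualSeries,
    gdp: AnnualSeries,
    base_year: int = 1994,
    eval_year: int | None = None,
) -> float:
    """Wellbeing:GDP ratio scaled to the base year, 0-100.

    100 * (CIW_t / GDP_t) / (CIW_base / GDP_base), clamped to [0, 100].
    100 means the ratio is at its base-year level; below 100 means GDP grew
    without a matching wellbeing gain.
    """
    if eval_year is None:
        eval_year = ciw.years[-1]
    vals = {}
    for name, series, year in (
        ("CIW", ciw, eval_year),
        ("GDP", gdp, eval_year),
        ("CIW", ciw, base_year),
        ("GDP", gdp, base_year),
    ):
        v = series.value(year)
        if v <= 0:
            raise ValueError(f"{name} value for {year} must be > 0, got {v!r}")
        vals[(name, year)] = v
    ratio_now = vals[("CIW", eval_year)] / vals[("GDP", eval_year)]
    ratio_base = vals[("CIW", base_year)] / vals[("GDP", base_year)]
    return clamp(100.0 * ratio_now / ratio_base, 0.0, 100.0)


def assess_goal(
    goal_id: str,
    status: float,
    trend: float,
    pressure: float,
    resilience: float,
    params: GoalParameters = GoalParameters(),
) -> GoalAssessment:
    """Convenience: project the future and score one goal in one step."""
    future = likely_future_status(status, trend, pressure, resilience, params)
    return GoalAssessment(
        goal_id=goal_id,
        status=status,
        trend=trend,
        pressure=pressure,
        resilience=resilience,
        future=future,
        score=goal_score(status, future),
    )
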