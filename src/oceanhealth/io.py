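"""File formats, validation and pipeline composition.

All formats are plain CSV.  Layer files are tidy (goal_id, subgoal_id,
dimension, year, value) and validated with line-numbered errors; pressure
and resilience may be supplied either combined or as components (which the
engine blends with gamma), but not both for the same (goal, subgoal, year).
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import fixtures
from .carbon import GridField
from .core import (
    GoalParameters,
    PressureComponents,
    ResilienceComponents,
    aggregate_index,
    aggregate_subgoals,
    assess_goal,
    combine_pressure,
    combine_resilience,
    round_half_away,
)
from .needs import CommunityPanel, CommunityRecord
from .weighting import ChoiceTask, SurveyResponse

COMPONENT_DIMENSIONS = {
    "pressure_ecological",
    "pressure_social",
    "resilience_ecological",
    "resilience_regulation",
    "resilience_social",
}
DIMENSIONS = {"status", "trend", "pressure", "resilience"} | COMPONENT_DIMENSIONS

__all__ = [
    "ValidationError",
    "ScoreResult",
    "read_layers",
    "resolve_layers",
    "score_assessment",
    "results_table",
    "flower_report",
    "read_survey",
    "write_survey",
    "read_communities",
    "write_communities",
    "read_grid",
    "write_grid",
]


class ValidationError(ValueError):
    """Input validation failure; ``problems`` lists line-numbered messages."""

    def __init__(self, problems: Sequence[str]):
        self.problems = list(problems)
        super().__init__("\n".join(self.problems))


def _range_for(dimension: str) -> tuple[float, float]:
    return (-1.0, 1.0) if dimension == "trend" else (0.0, 100.0)


def read_layers(path: str | os.PathLike) -> pd.DataFrame:
    """Read and validate a tidy layer CSV.

    Returns columns goal_id, subgoal_id (empty string when absent),
    dimension, year, value.  Raises :class:`ValidationError` listing every
    problem with its 1-based file line number.
    """
    problems: list[str] = []
    try:
        df = pd.read_csv(path, dtype=str)
    except Exception as exc:  # noqa: BLE001 - surfaced as validation failure
        raise ValidationError([f"{path}: cannot parse CSV: {exc}"]) from exc
    required = {"goal_id", "dimension", "year", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(
            [f"{path}: line 1: missing required columns {sorted(missing)}"]
        )
    if "subgoal_id" not in df.columns:
        df["subgoal_id"] = ""
    df["subgoal_id"] = df["subgoal_id"].fillna("")

    rows = []
    seen: dict[tuple, int] = {}
    for pos, row in enumerate(df.itertuples(index=False)):
        line = pos + 2  # header is line 1
        dim = row.dimension
        if dim not in DIMENSIONS:
            problems.append(
                f"line {line}: unknown dimension {dim!r} "
                f"(expected one of {sorted(DIMENSIONS)})"
            )
            continue
        try:
            year = int(row.year)
        except (TypeError, ValueError):
            problems.append(f"line {line}: year {row.year!r} is not an integer")
            continue
        try:
            value = float(row.value)
        except (TypeError, ValueError):
            problems.append(f"line {line}: value {row.value!r} is not numeric")
            continue
        lo, hi = _range_for(dim)
        if not (lo <= value <= hi):
            problems.append(
                f"line {line}: {dim} value {value} outside [{lo}, {hi}]"
            )
            continue
        key = (row.goal_id, row.subgoal_id, dim, year)
        if key in seen:
            problems.append(
                f"line {line}: duplicate of line {seen[key]} "
                f"(goal {row.goal_id!r}, subgoal {row.subgoal_id!r}, "
                f"{dim}, {year})"
            )
            continue
        seen[key] = line
        rows.append(
            {
                "goal_id": row.goal_id,
                "subgoal_id": row.subgoal_id,
                "dimension": dim,
                "year": year,
                "value": value,
            }
        )
    if problems:
        raise ValidationError(problems)
    return pd.DataFrame(rows)


def resolve_layers(
    layers: pd.DataFrame,
    year: int | None = None,
    params: GoalParameters = GoalParameters(),
) -> pd.DataFrame:
    """Collapse tidy layers into per-(goal, subgoal) assessment inputs.

    Combined pressure/resilience values are used as given; component values
    are blended with gamma.  Supplying both for the same unit is an error.
    """
    if year is None:
        year = int(layers["year"].max())
    sub = layers[layers["year"] == year]
    rows = []
    for (goal, subgoal), grp in sub.groupby(["goal_id", "subgoal_id"], sort=True):
        dims = dict(zip(grp["dimension"], grp["value"]))
        for name in ("status", "trend"):
            if name not in dims:
                raise ValidationError(
                    [f"goal {goal!r}/{subgoal!r}: missing {name} for year {year}"]
                )
        if "pressure" in dims and (
            "pressure_ecological" in dims or "pressure_social" in dims
        ):
            raise ValidationError(
                [f"goal {goal!r}/{subgoal!r}: both combined and component pressure"]
            )
        if "pressure" in dims:
            pressure = dims["pressure"]
        elif "pressure_ecological" in dims and "pressure_social" in dims:
            pressure = combine_pressure(
                PressureComponents(
                    dims["pressure_ecological"], dims["pressure_social"]
                ),
                params.gamma,
            )
        else:
            raise ValidationError(
                [f"goal {goal!r}/{subgoal!r}: missing pressure for year {year}"]
            )
        res_components = {
            "resilience_ecological",
            "resilience_regulation",
            "resilience_social",
        }
        if "resilience" in dims and res_components & set(dims):
            raise ValidationError(
                [f"goal {goal!r}/{subgoal!r}: both combined and component resilience"]
            )
        if "resilience" in dims:
            resilience = dims["resilience"]
        elif res_components <= set(dims):
            resilience = combine_resilience(
                ResilienceComponents(
                    dims["resilience_ecological"],
                    dims["resilience_regulation"],
                    dims["resilience_social"],
                ),
                params.gamma,
            )
        else:
            raise ValidationError(
                [f"goal {goal!r}/{subgoal!r}: missing resilience for year {year}"]
            )
        rows.append(
            {
                "goal": goal,
                "subgoal": subgoal,
                "status": dims["status"],
                "trend": dims["trend"],
                "pressure": pressure,
                "resilience": resilience,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ScoreResult:
    """Scored subgoal and goal tables plus the overall index and future."""

    subgoal_table: pd.DataFrame
    goal_table: pd.DataFrame
    index: float
    future: float


def score_assessment(
    inputs: pd.DataFrame,
    goal_weights: Mapping[str, float],
    subgoal_weights: Mapping[str, Mapping[str, float]] | None = None,
    params: GoalParameters = GoalParameters(),
) -> ScoreResult:
    """Run the engine over per-(goal, subgoal) assessment inputs.

    ``inputs`` columns: goal, subgoal (empty for single-unit goals), status,
    trend, pressure, resilience.  Subgoal aggregation is weighted per
    ``subgoal_weights`` (default: equal shares) and applied dimension-wise.
    """
    if subgoal_weights is None:
        subgoal_weights = {}
    sub_rows = []
    for row in inputs.itertuples(index=False):
        a = assess_goal(
            goal_id=f"{row.goal}:{row.subgoal}" if row.subgoal else row.goal,
            status=float(row.status),
            trend=float(row.trend),
            pressure=float(row.pressure),
            resilience=float(row.resilience),
            params=params,
        )
        sub_rows.append(
            {
                "goal": row.goal,
                "subgoal": row.subgoal,
                "status": a.status,
                "trend": a.trend,
                "pressure": a.pressure,
                "resilience": a.resilience,
                "future": a.future,
                "score": a.score,
            }
        )
    sub_table = pd.DataFrame(sub_rows)
    goal_rows = []
    for goal, grp in sub_table.groupby("goal", sort=True):
        if len(grp) == 1 and grp.iloc[0]["subgoal"] == "":
            rec = grp.iloc[0].to_dict()
            rec.pop("subgoal")
            goal_rows.append(rec)
            continue
        weights_for = subgoal_weights.get(goal, {})
        w = [
            weights_for.get(s, 1.0 / len(grp)) for s in grp["subgoal"]
        ]
        rec = {"goal": goal}
        for dim in ("status", "trend", "future", "score"):
            rec[dim] = aggregate_subgoals(list(zip(grp[dim], w)))
        rec["pressure"] = np.nan
        rec["resilience"] = np.nan
        goal_rows.append(rec)
    goal_table = pd.DataFrame(goal_rows)
    scores = dict(zip(goal_table["goal"], goal_table["score"]))
    futures = dict(zip(goal_table["goal"], goal_table["future"]))
    index = aggregate_index(scores, goal_weights, params)
    future = aggregate_index(futures, goal_weights, params)
    return ScoreResult(
        subgoal_table=sub_table, goal_table=goal_table, index=index, future=future
    )


def results_table(result: ScoreResult, decimals: int = 2) -> pd.DataFrame:
    """Render a result as one table mirroring the reporting layout."""
    rows = []
    goal_by_id = result.goal_table.set_index("goal")
    for goal in goal_by_id.index:
        g = goal_by_id.loc[goal]
        rows.append(
            {
                "goal": goal,
                "subgoal": "",
                "score": g["score"],
                "status": g["status"],
                "future": g["future"],
                "trend": g["trend"],
                "pressure": g.get("pressure", np.nan),
                "resilience": g.get("resilience", np.nan),
            }
        )
        subs = result.subgoal_table
        for row in subs[(subs["goal"] == goal) & (subs["subgoal"] != "")].itertuples():
            rows.append(
                {
                    "goal": goal,
                    "subgoal": row.subgoal,
                    "score": row.score,
                    "status": row.status,
                    "future": row.future,
                    "trend": row.trend,
                    "pressure": row.pressure,
                    "resilience": row.resilience,
                }
            )
    rows.append(
        {
            "goal": "OVERALL",
            "subgoal": "",
            "score": result.index,
            "status": np.nan,
            "future": result.future,
            "trend": np.nan,
            "pressure": np.nan,
            "resilience": np.nan,
        }
    )
    df = pd.DataFrame(rows)
    numeric = ["score", "status", "future", "trend", "pressure", "resilience"]
    df[numeric] = df[numeric].map(
        lambda v: round_half_away(v, decimals) if pd.notna(v) else v
    )
    return df


def flower_report(
    result: ScoreResult,
    goal_weights: Mapping[str, float],
    width: int = 40,
) -> str:
    """Plain-text flower: one bar per goal, bar length ~ score, tagged with weight."""
    lines = ["goal  weight  score   " + "-" * width]
    goal_by_id = result.goal_table.set_index("goal")
    for goal in goal_by_id.index:
        score = float(goal_by_id.loc[goal, "score"])
        w = goal_weights.get(goal, 0.0)
        bar = "#" * int(round(score / 100.0 * width))
        lines.append(f"{goal:<5} {w:6.2f} {score:6.2f}  |{bar}")
    lines.append(f"OVERALL index {round_half_away(result.index):.2f} "
                 f"(future {round_half_away(result.future):.2f})")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# survey tables

def write_survey(responses: Sequence[SurveyResponse], out_dir: str | os.PathLike) -> None:
    os.makedirs(out_dir, exist_ok=True)
    likert_rows, task_rows, demo_rows = [], [], []
    for resp in responses:
        for goal, rating in sorted(resp.likert.items()):
            likert_rows.append((resp.respondent_id, goal, rating))
        for t, task in enumerate(resp.tasks):
            task_rows.append(
                (resp.respondent_id, t, "|".join(task.shown), task.best, task.worst)
            )
        demo_rows.append({"respondent_id": resp.respondent_id, **resp.demographics})
    pd.DataFrame(likert_rows, columns=["respondent_id", "goal", "rating"]).to_csv(
        os.path.join(out_dir, "likert.csv"), index=False
    )
    pd.DataFrame(
        task_rows, columns=["respondent_id", "task_id", "shown", "best", "worst"]
    ).to_csv(os.path.join(out_dir, "tasks.csv"), index=False)
    pd.DataFrame(demo_rows).to_csv(
        os.path.join(out_dir, "demographics.csv"), index=False
    )


def read_survey(
    likert_path: str | os.PathLike | None = None,
    tasks_path: str | os.PathLike | None = None,
    demographics_path: str | os.PathLike | None = None,
) -> list[SurveyResponse]:
    """Assemble responses from any subset of the three survey tables."""
    likert: dict[str, dict[str, int]] = {}
    tasks: dict[str, list[ChoiceTask]] = {}
    demo: dict[str, dict[str, str]] = {}
    ids: list[str] = []

    def note(rid: str) -> None:
        if rid not in likert and rid not in tasks and rid not in demo:
            ids.append(rid)

    if likert_path is not None:
        for row in pd.read_csv(likert_path, dtype=str).itertuples():
            note(row.respondent_id)
            likert.setdefault(row.respondent_id, {})[row.goal] = int(row.rating)
    if tasks_path is not None:
        df = pd.read_csv(tasks_path, dtype=str)
        for row in df.itertuples():
            note(row.respondent_id)
            tasks.setdefault(row.respondent_id, []).append(
                ChoiceTask(
                    shown=tuple(row.shown.split("|")), best=row.best, worst=row.worst
                )
            )
    if demographics_path is not None:
        df = pd.read_csv(demographics_path, dtype=str)
        for row in df.itertuples(index=False):
            d = row._asdict()
            rid = d.pop("respondent_id")
            note(rid)
            demo[rid] = {k: v for k, v in d.items() if pd.notna(v)}
    all_ids = sorted(set(likert) | set(tasks) | set(demo))
    return [
        SurveyResponse(
            respondent_id=rid,
            demographics=demo.get(rid, {}),
            likert=likert.get(rid, {}),
            tasks=tuple(tasks.get(rid, ())),
        )
        for rid in all_ids
    ]


# ---------------------------------------------------------------------------
# community tables

def write_communities(panel: CommunityPanel, out_dir: str | os.PathLike) -> None:
    os.makedirs(out_dir, exist_ok=True)
    recs = pd.DataFrame(
        [
            {
                "community_id": r.community_id,
                "group": r.group,
                "population": r.population,
                "lat": r.lat,
                "lon": r.lon,
                "rnfb": r.rnfb,
                "rnfb_dist": r.rnfb_dist,
                "iccpi": r.iccpi,
                "iccpi_dist": r.iccpi_dist,
            }
            for r in panel.records.values()
        ]
    )
    recs.to_csv(os.path.join(out_dir, "communities.csv"), index=False)
    panel.data.to_csv(os.path.join(out_dir, "panel.csv"), index=False)


def read_communities(
    communities_path: str | os.PathLike,
    panel_path: str | os.PathLike,
    base_year: int = 1979,
) -> CommunityPanel:
    recs = {}
    for row in pd.read_csv(communities_path).itertuples():
        recs[str(row.community_id)] = CommunityRecord(
            community_id=str(row.community_id),
            group=row.group,
            population=float(row.population),
            lat=float(row.lat),
            lon=float(row.lon),
            rnfb=float(getattr(row, "rnfb", 0.0)),
            rnfb_dist=float(getattr(row, "rnfb_dist", 0.0)),
            iccpi=float(getattr(row, "iccpi", 0.0)),
            iccpi_dist=float(getattr(row, "iccpi_dist", 0.0)),
        )
    data = pd.read_csv(panel_path)
    data["community_id"] = data["community_id"].astype(str)
    return CommunityPanel(records=recs, data=data, base_year=base_year)


# ---------------------------------------------------------------------------
# grids

def write_grid(grid: GridField, path: str | os.PathLike) -> None:
    """Long-format raster CSV: lat, lon, value."""
    lat = np.repeat(grid.latitudes, grid.longitudes.size)
    lon = np.tile(grid.longitudes, grid.latitudes.size)
    pd.DataFrame(
        {"lat": lat, "lon": lon, "value": grid.values.ravel()}
    ).to_csv(path, index=False)


def read_grid(path: str | os.PathLike) -> GridField:
    df = pd.read_csv(path)
    lat = np.unique(df["lat"].to_numpy())
    lon = np.unique(df["lon"].to_numpy())
    values = (
        df.pivot_table(index="lat", columns="lon", values="value")
        .reindex(index=lat, columns=lon)
        .to_numpy()
    )
    if np.isnan(values).any():
        raise ValidationError([f"{path}: grid is not a complete lat/lon rectangle"])
    return GridField(latitudes=lat, longitudes=lon, values=values)


def fixture_assessment_inputs() -> pd.DataFrame:
    """Engine inputs from the packaged 2013 assessment fixture."""
    return fixtures.assessment_layers()
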