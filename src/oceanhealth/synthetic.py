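"""Synthetic inputs with known ground truth for every pipeline stage.

All generators are pure functions of their configuration (seed included):
the same config yields bitwise-identical output.  Defaults are sized so the
whole test suite runs in minutes on one CPU.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .carbon import GridField
from .needs import FIRST_NATIONS, INUIT, CommunityPanel, CommunityRecord
from .weighting import ChoiceTask, SurveyResponse

__all__ = ["GeneratorConfig", "gen_survey", "gen_communities", "gen_grids"]

_DEFAULT_UTILITIES = {
    "FP": 0.5,
    "AN": -0.3,
    "NP": -0.8,
    "CS": 0.2,
    "CP": 0.1,
    "CL": 0.4,
    "TR": -0.6,
    "SOP": -0.1,
    "CW": 0.9,
    "BD": -0.3,
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs for all generators; only the relevant block matters per call."""

    seed: int = 0
    # survey
    n_respondents: int = 200
    tasks_per_respondent: int = 6
    set_size: int = 5
    true_utilities: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_UTILITIES)
    )
    utility_scale: float = 1.0
    likert_slope: float = 1.5
    likert_noise: float = 0.7
    demographics_choices: Mapping[str, tuple[str, ...]] = field(
        default_factory=lambda: {
            "region": ("BC", "Prairies", "ON", "QC", "Atlantic"),
            "age_group": ("20-24", "25-34", "35-44", "45-54", "55-64", "65+"),
            "party": ("NDP/Green", "LPC", "CPC", "Other"),
            "ngo_member": ("yes", "no"),
        }
    )
    # communities
    n_communities: int = 8
    start_year: int = 1979
    end_year: int = 2013
    gas_growth: float = 5.5  # total factor over the horizon
    food_growth: float = 3.0
    price_noise: float = 0.0
    ice_decline_start: int = 1999
    ice_decline_total: float = 0.2  # absolute drop in ice fraction by end year
    # grids
    grid_nlat: int = 40
    grid_nlon: int = 60
    lat_range: tuple[float, float] = (40.0, 85.0)
    lon_range: tuple[float, float] = (-140.0, -50.0)
    bathy_pattern: str = "step"  # "constant" or "step"
    constant_depth: float = 500.0
    step_lat: float = 60.0
    shallow_depth: float = 60.0
    deep_depth: float = 500.0
    ice_pattern: str = "uniform"  # "uniform" or "north_cap"
    ice_level: float = 0.8
    ice_cap_lat: float = 60.0

    def __post_init__(self) -> None:
        if self.set_size < 3:
            raise ValueError("set_size must be >= 3")
        for name in ("n_respondents", "tasks_per_respondent", "n_communities",
                     "grid_nlat", "grid_nlon"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.set_size > len(self.true_utilities):
            raise ValueError("set_size exceeds the number of goals")


def gen_survey(
    config: GeneratorConfig,
    demographics: Mapping[str, str] | None = None,
) -> list[SurveyResponse]:
    """Respondents with Likert ratings and sequential-maxdiff choice tasks.

    Best picks follow softmax(scale*u) over the shown set; worst picks follow
    softmax(-scale*u) over the remainder.  Likert ratings are a clipped,
    rounded linear map of utility plus Gaussian noise.  If ``demographics``
    is given it is applied to every respondent; otherwise demographics are
    sampled uniformly from ``config.demographics_choices``.
    """
    rng = np.random.default_rng(config.seed)
    goals = sorted(config.true_utilities)
    u = np.asarray([config.true_utilities[g] for g in goals]) * config.utility_scale
    responses = []
    for r in range(config.n_respondents):
        noise = rng.normal(0.0, config.likert_noise, len(goals))
        raw = 3.0 + config.likert_slope * u + noise
        likert = {
            g: int(np.clip(np.rint(v), 1, 5)) for g, v in zip(goals, raw)
        }
        tasks = []
        for _ in range(config.tasks_per_respondent):
            shown_idx = rng.choice(len(goals), size=config.set_size, replace=False)
            us = u[shown_idx]
            p_best = np.exp(us - us.max())
            p_best /= p_best.sum()
            b = rng.choice(config.set_size, p=p_best)
            rest = np.delete(np.arange(config.set_size), b)
            uw = -us[rest]
            p_worst = np.exp(uw - uw.max())
            p_worst /= p_worst.sum()
            w = rest[rng.choice(rest.size, p=p_worst)]
            tasks.append(
                ChoiceTask(
                    shown=tuple(goals[i] for i in shown_idx),
                    best=goals[shown_idx[b]],
                    worst=goals[shown_idx[w]],
                )
            )
        if demographics is None:
            demo = {
                key: choices[rng.integers(len(choices))]
                for key, choices in config.demographics_choices.items()
            }
        else:
            demo = dict(demographics)
        responses.append(
            SurveyResponse(
                respondent_id=f"r{r:05d}",
                demographics=demo,
                likert=likert,
                tasks=tuple(tasks),
            )
        )
    return responses


def gen_communities(config: GeneratorConfig) -> CommunityPanel:
    """Community records plus annual food/gas/ice panel.

    Prices grow geometrically to ``food_growth``x / ``gas_growth``x over the
    horizon (optionally jittered by lognormal noise); ice is flat at the
    community's base level until ``ice_decline_start`` then declines linearly
    by ``ice_decline_total``.  Southern communities (lat < 55) carry an
    all-zero ice series, exercising the ice-ratio exception.
    """
    rng = np.random.default_rng(config.seed + 1)
    years = list(range(config.start_year, config.end_year + 1))
    horizon = max(len(years) - 1, 1)
    records: dict[str, CommunityRecord] = {}
    rows = []
    for i in range(config.n_communities):
        cid = f"c{i:03d}"
        lat = float(rng.uniform(48.0, 75.0))
        group = INUIT if lat >= 60.0 else FIRST_NATIONS
        records[cid] = CommunityRecord(
            community_id=cid,
            group=group,
            population=float(rng.integers(100, 3000)),
            lat=lat,
            lon=float(rng.uniform(-140.0, -55.0)),
            rnfb=float(rng.uniform(300.0, 500.0)),
            rnfb_dist=float(rng.uniform(0.0, 500.0)),
            iccpi=float(rng.uniform(95.0, 140.0)),
            iccpi_dist=float(rng.uniform(0.0, 1500.0)),
        )
        food0 = float(rng.uniform(200.0, 400.0))
        gas0 = float(rng.uniform(20.0, 40.0))
        ice0 = 0.0 if lat < 55.0 else float(rng.uniform(0.5, 0.95))
        for t, year in enumerate(years):
            frac = t / horizon
            food = food0 * config.food_growth**frac
            gas = gas0 * config.gas_growth**frac
            if config.price_noise > 0:
                food *= float(np.exp(rng.normal(0.0, config.price_noise)))
                gas *= float(np.exp(rng.normal(0.0, config.price_noise)))
            if ice0 == 0.0 or year <= config.ice_decline_start:
                ice = ice0
            else:
                span = max(config.end_year - config.ice_decline_start, 1)
                drop = config.ice_decline_total * (year - config.ice_decline_start) / span
                ice = max(ice0 - drop, 0.0)
            rows.append((cid, year, food, gas, ice))
    data = pd.DataFrame(
        rows, columns=["community_id", "year", "food_price", "gas_price", "ice_fraction"]
    )
    return CommunityPanel(records=records, data=data, base_year=config.start_year)


def gen_grids(config: GeneratorConfig) -> tuple[GridField, dict[int, GridField]]:
    """Bathymetry grid plus annual ice-concentration grids.

    Bathymetry patterns: "constant" (every cell at ``constant_depth``) or
    "step" (``shallow_depth`` north of ``step_lat``, ``deep_depth`` south of
    it) — both with closed-form habitat areas.  Ice patterns: "uniform"
    (every cell at the year's level) or "north_cap" (the year's level north
    of ``ice_cap_lat``, zero south).  The per-year level is flat at
    ``ice_level`` until ``ice_decline_start`` then declines linearly by
    ``ice_decline_total``.
    """
    lat = np.linspace(*config.lat_range, config.grid_nlat)
    lon = np.linspace(*config.lon_range, config.grid_nlon)
    if config.bathy_pattern == "constant":
        depth = np.full((lat.size, lon.size), config.constant_depth)
    elif config.bathy_pattern == "step":
        depth = np.where(
            lat[:, None] >= config.step_lat, config.shallow_depth, config.deep_depth
        ) * np.ones((1, lon.size))
    else:
        raise ValueError(f"unknown bathy_pattern {config.bathy_pattern!r}")
    bathy = GridField(latitudes=lat, longitudes=lon, values=depth)

    ice_grids: dict[int, GridField] = {}
    years = range(config.start_year, config.end_year + 1)
    span = max(config.end_year - config.ice_decline_start, 1)
    for year in years:
        if year <= config.ice_decline_start:
            level = config.ice_level
        else:
            level = max(
                config.ice_level
                - config.ice_decline_total * (year - config.ice_decline_start) / span,
                0.0,
            )
        if config.ice_pattern == "uniform":
            vals = np.full((lat.size, lon.size), level)
        elif config.ice_pattern == "north_cap":
            vals = np.where(lat[:, None] >= config.ice_cap_lat, level, 0.0) * np.ones(
                (1, lon.size)
            )
        else:
            raise ValueError(f"unknown ice_pattern {config.ice_pattern!r}")
        ice_grids[year] = GridField(latitudes=lat, longitudes=lon, values=vals)
    return bathy, ice_grids
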