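"""Resource-access goal for northern communities.

Food-basket prices are imputed by group-specific linear regression where not
observed; each community contributes a factor

    (F/G) / (Fb/Gb) * (I/Ib)

comparing its current food:fuel price ratio and ice cover to the base-year
(default 1979) levels, and the goal score is the population-weighted mean of
these factors times 100.  Communities whose ice series is identically zero
(or whose baseline ice is zero) contribute an ice ratio of exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .carbon import EARTH_RADIUS_KM, GridField, cell_areas
from .core import AnnualSeries, recent_trend

INUIT = "inuit"
FIRST_NATIONS = "first_nations"

__all__ = [
    "CommunityRecord",
    "RegressionCoefficients",
    "CommunityPanel",
    "ANResult",
    "impute_rnfb",
    "fit_rnfb_model",
    "haversine_km",
    "ice_cover_fraction",
    "community_an_factor",
    "an_index",
    "an_series",
    "an_trend",
]


@dataclass(frozen=True)
class CommunityRecord:
    """A community's population, location and price-model covariates.

    rnfb: basket price observed at the nearest community with data (dollars);
    rnfb_dist: distance to that community (km); iccpi: food price index of the
    nearest major city; iccpi_dist: distance to that city (km).
    """

    community_id: str
    group: str
    population: float
    lat: float
    lon: float
    rnfb: float = 0.0
    rnfb_dist: float = 0.0
    iccpi: float = 0.0
    iccpi_dist: float = 0.0

    def __post_init__(self) -> None:
        if self.group not in (INUIT, FIRST_NATIONS):
            raise ValueError(
                f"group must be {INUIT!r} or {FIRST_NATIONS!r}, got {self.group!r}"
            )
        if self.population < 0:
            raise ValueError("population must be >= 0")
        if self.rnfb_dist < 0 or self.iccpi_dist < 0:
            raise ValueError("distances must be >= 0")


@dataclass(frozen=True)
class RegressionCoefficients:
    """Group-specific linear predictor of the food-basket price.

    The first-nations variant carries no basket-price terms (b_rnfb and
    b_rnfb_dist are None).
    """

    group: str
    intercept: float
    b_rnfb: float | None
    b_rnfb_dist: float | None
    b_iccpi: float
    b_iccpi_dist: float
    b_pop: float
    std_errors: Mapping[str, float] = field(default_factory=dict)
    adj_r2: float | None = None
    f_stat: float | None = None

    def __post_init__(self) -> None:
        if self.group == FIRST_NATIONS and not (
            self.b_rnfb is None and self.b_rnfb_dist is None
        ):
            raise ValueError("first-nations model must not carry RNFB terms")
        if self.group == INUIT and (self.b_rnfb is None or self.b_rnfb_dist is None):
            raise ValueError("inuit model requires RNFB terms")


def impute_rnfb(
    community: CommunityRecord, coefficients: RegressionCoefficients
) -> float:
    """Predicted food-basket price (dollars) for one community."""
    if community.group != coefficients.group:
        raise ValueError(
            f"community group {community.group!r} does not match "
            f"coefficient group {coefficients.group!r}"
        )
    c = coefficients
    pred = (
        c.intercept
        + c.b_iccpi * community.iccpi
        + c.b_iccpi_dist * community.iccpi_dist
        + c.b_pop * community.population
    )
    if c.group == INUIT:
        pred += c.b_rnfb * community.rnfb + c.b_rnfb_dist * community.rnfb_dist
    return pred


def _design_columns(group: str) -> list[str]:
    if group == INUIT:
        return ["rnfb", "rnfb_dist", "iccpi", "iccpi_dist", "population"]
    return ["iccpi", "iccpi_dist", "population"]


def fit_rnfb_model(
    observed: Sequence[tuple[CommunityRecord, float]], group: str
) -> RegressionCoefficients:
    """Fit the group's price model by ordinary least squares."""
    rows = [(c, p) for c, p in observed if c.group == group]
    if not rows:
        raise ValueError(f"no observations for group {group!r}")
    cols = _design_columns(group)
    if len(rows) <= len(cols) + 1:
        raise ValueError(
            f"need more than {len(cols) + 1} observations, got {len(rows)}"
        )
    X = pd.DataFrame(
        [[getattr(c, col) for col in cols] for c, _ in rows], columns=cols
    )
    y = np.asarray([p for _, p in rows], dtype=float)
    X = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    fit = sm.OLS(y, X).fit()
    params = fit.params
    se = dict(fit.bse)
    se["intercept"] = se.pop("const")
    return RegressionCoefficients(
        group=group,
        intercept=float(params["const"]),
        b_rnfb=float(params["rnfb"]) if group == INUIT else None,
        b_rnfb_dist=float(params["rnfb_dist"]) if group == INUIT else None,
        b_iccpi=float(params["iccpi"]),
        b_iccpi_dist=float(params["iccpi_dist"]),
        b_pop=float(params["population"]),
        std_errors=se,
        adj_r2=float(fit.rsquared_adj),
        f_stat=float(fit.fvalue),
    )


def haversine_km(
    lat1: float, lon1: float, lat2: np.ndarray, lon2: np.ndarray
) -> np.ndarray:
    """Great-circle distance in km from one point to arrays of points."""
    p1, p2 = np.deg2rad(lat1), np.deg2rad(lat2)
    dphi = p2 - p1
    dlam = np.deg2rad(lon2) - np.deg2rad(lon1)
    a = np.sin(dphi / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlam / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))


def ice_cover_fraction(
    ice_grids: Mapping[int, GridField],
    community: CommunityRecord,
    radius_km: float = 300.0,
) -> AnnualSeries:
    """Area-weighted mean ice concentration within ``radius_km`` per year.

    Cell membership is by cell-center great-circle distance.
    """
    pairs = []
    for year in sorted(ice_grids):
        grid = ice_grids[year]
        lat2 = np.repeat(grid.latitudes[:, None], grid.longitudes.size, axis=1)
        lon2 = np.repeat(grid.longitudes[None, :], grid.latitudes.size, axis=0)
        dist = haversine_km(community.lat, community.lon, lat2, lon2)
        mask = dist <= radius_km
        if not mask.any():
            raise ValueError(
                f"no grid cells within {radius_km} km of {community.community_id!r}"
                f" in year {year}"
            )
        areas = cell_areas(grid)
        frac = float((grid.values * areas)[mask].sum() / areas[mask].sum())
        pairs.append((year, frac))
    return AnnualSeries.from_pairs(pairs)


def community_an_factor(
    food: float,
    gas: float,
    ice: float,
    food_base: float,
    gas_base: float,
    ice_base: float,
    ice_all_zero: bool = False,
) -> float:
    """(F/G)/(Fb/Gb) * (I/Ib); the ice ratio is 1 when the series has no ice.

    The factor falls when gasoline rises relative to food, or ice cover
    shrinks, compared with the base year.
    """
    for name, v in (
        ("food", food),
        ("gas", gas),
        ("food_base", food_base),
        ("gas_base", gas_base),
    ):
        if v <= 0:
            raise ValueError(f"{name} price must be > 0, got {v!r}")
    if ice_base < 0:
        raise ValueError("ice_base must be >= 0")
    if ice_all_zero or ice_base == 0:
        ice_ratio = 1.0
    else:
        ice_ratio = ice / ice_base
    return (food / gas) / (food_base / gas_base) * ice_ratio


@dataclass(frozen=True)
class CommunityPanel:
    """Per-community annual food price, gasoline price and ice fraction.

    ``data`` columns: community_id, year, food_price, gas_price, ice_fraction.
    Baselines are the base-year rows.
    """

    records: Mapping[str, CommunityRecord]
    data: pd.DataFrame
    base_year: int = 1979

    def __post_init__(self) -> None:
        required = {"community_id", "year", "food_price", "gas_price", "ice_fraction"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"panel is missing columns: {sorted(missing)}")
        if (self.data["food_price"] <= 0).any() or (self.data["gas_price"] <= 0).any():
            raise ValueError("panel prices must be > 0")
        ice = self.data["ice_fraction"]
        if ((ice < 0) | (ice > 1)).any():
            raise ValueError("ice_fraction must be in [0, 1]")
        for cid in self.data["community_id"].unique():
            if cid not in self.records:
                raise ValueError(f"panel community {cid!r} has no CommunityRecord")

    def years(self) -> list[int]:
        return sorted(self.data["year"].unique())

    def _rows(self, cid: str) -> pd.DataFrame:
        return self.data[self.data["community_id"] == cid].set_index("year")

    def community_factor(self, cid: str, year: int) -> float:
        rows = self._rows(cid)
        if self.base_year not in rows.index:
            raise ValueError(f"{cid!r} has no base-year ({self.base_year}) row")
        if year not in rows.index:
            raise ValueError(f"{cid!r} has no row for year {year}")
        base, cur = rows.loc[self.base_year], rows.loc[year]
        ice_all_zero = bool((rows["ice_fraction"] == 0).all())
        return community_an_factor(
            food=float(cur["food_price"]),
            gas=float(cur["gas_price"]),
            ice=float(cur["ice_fraction"]),
            food_base=float(base["food_price"]),
            gas_base=float(base["gas_price"]),
            ice_base=float(base["ice_fraction"]),
            ice_all_zero=ice_all_zero,
        )


@dataclass(frozen=True)
class ANResult:
    """AN score trajectory plus the per-community factors behind it."""

    scores: AnnualSeries
    factors: pd.DataFrame  # columns community_id, year, factor


def an_index(panel: CommunityPanel, year: int) -> float:
    """Population-weighted mean community factor, scaled to 0-100."""
    cids = [c for c in panel.records if (panel.data["community_id"] == c).any()]
    pops = np.asarray([panel.records[c].population for c in cids], dtype=float)
    if pops.sum() == 0:
        raise ValueError("total population must be > 0")
    factors = np.asarray([panel.community_factor(c, year) for c in cids])
    return float(100.0 * (pops * factors).sum() / pops.sum())


def an_series(panel: CommunityPanel) -> ANResult:
    """AN score for every panel year."""
    rows = []
    scores = []
    for year in panel.years():
        for cid in panel.records:
            if ((panel.data["community_id"] == cid) & (panel.data["year"] == year)).any():
                rows.append((cid, year, panel.community_factor(cid, year)))
        scores.append((year, an_index(panel, year)))
    return ANResult(
        scores=AnnualSeries.from_pairs(scores),
        factors=pd.DataFrame(rows, columns=["community_id", "year", "factor"]),
    )


def an_trend(scores: AnnualSeries, window: int = 5, mode: str = "absolute") -> float:
    """Engine trend convention applied to the AN score series."""
    return recent_trend(scores, window=window, mode=mode)
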