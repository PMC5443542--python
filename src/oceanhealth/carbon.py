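"""Carbon-storage goal: seafloor carbon 'habitats' delimited by depth/latitude.

Habitat extents (subsea permafrost: 0-120 m north of 60N; methane clathrates:
below 300 m) are measured on a regular lat/lon bathymetry grid; habitat health
is a linear function of sea-surface-temperature anomaly anchored at two
printed points; trend comes from the recent slope of a CO2 series; and the
habitat records (including classical coastal habitats supplied as inputs) are
combined area-weighted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .core import AnnualSeries, clamp

EARTH_RADIUS_KM = 6371.0

PERMAFROST_DEPTH_RANGE = (0.0, 120.0)
PERMAFROST_LAT_MIN = 60.0
CLATHRATE_DEPTH_MIN = 300.0

__all__ = [
    "GridField",
    "HabitatRecord",
    "AnomalyAnchors",
    "habitat_mask",
    "cell_areas",
    "masked_area",
    "habitat_health_from_anomaly",
    "carbon_trend_from_co2",
    "combine_habitats",
]


@dataclass(frozen=True)
class GridField:
    """Regular lat/lon raster (depth in m positive down, or ice fraction)."""

    latitudes: np.ndarray  # shape (nlat,)
    longitudes: np.ndarray  # shape (nlon,)
    values: np.ndarray  # shape (nlat, nlon)

    def __post_init__(self) -> None:
        lat = np.asarray(self.latitudes, dtype=float)
        lon = np.asarray(self.longitudes, dtype=float)
        val = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "latitudes", lat)
        object.__setattr__(self, "longitudes", lon)
        object.__setattr__(self, "values", val)
        if val.shape != (lat.size, lon.size):
            raise ValueError(
                f"values shape {val.shape} does not match grid "
                f"({lat.size} lats, {lon.size} lons)"
            )
        if lat.size and (lat.min() < -90 or lat.max() > 90):
            raise ValueError("latitudes must be in [-90, 90]")
        if lon.size and (lon.min() < -180 or lon.max() > 180):
            raise ValueError("longitudes must be in [-180, 180]")

    def spacing(self) -> tuple[float, float]:
        """(dlat, dlon) in degrees; requires regular spacing on both axes."""
        out = []
        for axis, name in ((self.latitudes, "latitude"), (self.longitudes, "longitude")):
            if axis.size < 2:
                raise ValueError(f"need >= 2 {name}s to infer spacing")
            d = np.diff(axis)
            if not np.allclose(d, d[0], rtol=1e-6, atol=1e-9):
                raise ValueError(f"{name} spacing is not regular")
            out.append(abs(float(d[0])))
        return out[0], out[1]


@dataclass(frozen=True)
class HabitatRecord:
    """One habitat's area (km^2), health (0-1) and trend ([-1, 1])."""

    habitat_id: str
    area: float
    health: float
    trend: float

    def __post_init__(self) -> None:
        if self.area < 0:
            raise ValueError(f"area must be >= 0, got {self.area!r}")
        if not (0.0 <= self.health <= 1.0):
            raise ValueError(f"health must be in [0, 1], got {self.health!r}")
        if not (-1.0 <= self.trend <= 1.0):
            raise ValueError(f"trend must be in [-1, 1], got {self.trend!r}")


@dataclass(frozen=True)
class AnomalyAnchors:
    """SST-anomaly anchors of the linear health function.

    Health is 0 at ``zero_health_anomaly`` (3.65 C, a 3 C rise over the
    reference level) and 1 at ``reference_anomaly`` (0.65 C).
    """

    zero_health_anomaly: float = 3.65
    reference_anomaly: float = 0.65

    def __post_init__(self) -> None:
        if self.zero_health_anomaly <= self.reference_anomaly:
            raise ValueError("zero_health_anomaly must exceed reference_anomaly")


def habitat_mask(
    grid: GridField,
    depth_min: float,
    depth_max: float,
    lat_min: float | None = None,
) -> np.ndarray:
    """Boolean mask of cells whose depth lies in [depth_min, depth_max].

    Depth is positive down; cells with depth <= 0 (land/ice surface) are never
    included.  If ``lat_min`` is given, only cells whose center latitude is
    >= lat_min qualify.  Membership is by cell center.
    """
    if depth_min >= depth_max:
        raise ValueError("depth_min must be < depth_max")
    depth = grid.values
    mask = (depth > 0) & (depth >= depth_min) & (depth <= depth_max)
    if lat_min is not None:
        mask &= grid.latitudes[:, None] >= lat_min
    return mask


def cell_areas(grid: GridField) -> np.ndarray:
    """Per-cell area in km^2: R^2 * dlat * dlon * cos(latitude)."""
    dlat, dlon = grid.spacing()
    coslat = np.cos(np.deg2rad(grid.latitudes))
    area_row = EARTH_RADIUS_KM**2 * np.deg2rad(dlat) * np.deg2rad(dlon) * coslat
    return np.repeat(area_row[:, None], grid.longitudes.size, axis=1)


def masked_area(grid: GridField, mask: np.ndarray) -> float:
    """Total area (km^2) of the cells selected by ``mask``."""
    return float((cell_areas(grid) * mask).sum())


def habitat_health_from_anomaly(
    anomaly: float, anchors: AnomalyAnchors = AnomalyAnchors()
) -> float:
    """Linear health through the two anchors, clamped to [0, 1]."""
    span = anchors.zero_health_anomaly - anchors.reference_anomaly
    return clamp((anchors.zero_health_anomaly - anomaly) / span, 0.0, 1.0)


def carbon_trend_from_co2(
    co2: AnnualSeries,
    window: int = 5,
    transform: Callable[[float], float] | None = None,
) -> float:
    """Trend from the recent slope of a CO2 series, clamped to [-1, 1].

    Default transform: the negative of the relative OLS slope times the
    window length (rising CO2 -> declining habitat condition).  The relative
    slope is the fitted slope divided by the fitted value at the start of the
    window, so a series rising by 0.5 %/yr gives -0.025 over 5 years.
    """
    recent = co2.tail(window)
    years = np.asarray(recent.years, dtype=float)
    values = np.asarray(recent.values, dtype=float)
    if np.ptp(values) == 0.0:  # constant series: avoid float noise in polyfit
        return 0.0
    slope, intercept = np.polyfit(years, values, 1)
    start = intercept + slope * years[0]
    if start == 0:
        raise ValueError("relative slope undefined: fitted start value is 0")
    rel = float(slope / start * window)
    raw = transform(rel) if transform is not None else -rel
    return clamp(raw, -1.0, 1.0)


def combine_habitats(records: Sequence[HabitatRecord]) -> tuple[float, float]:
    """Area-weighted (status 0-100, trend) over habitat records."""
    if len(records) == 0:
        raise ValueError("need at least one habitat record")
    areas = np.asarray([r.area for r in records], dtype=float)
    total = areas.sum()
    if total == 0:
        raise ValueError("total habitat area must be > 0")
    health = np.asarray([r.health for r in records], dtype=float)
    trend = np.asarray([r.trend for r in records], dtype=float)
    status = float((areas * health).sum() / total * 100.0)
    return status, float((areas * trend).sum() / total)
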