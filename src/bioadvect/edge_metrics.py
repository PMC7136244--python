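"""Leading-edge statistics, bloom matchup and driver attribution.

The leading edge of the range is the 95th percentile of the longitude
and latitude positions of particles (or bloom pixels) inside the eastern
analysis region, reported also as the great-circle distance from a fixed
reference anchor.  Expansion over a period is the OLS trend of that
distance times the period length; the currents and temperature shares
are the EXP2 and EXP3 expansions as percentages of EXP1's.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .eof_analysis import TrendResult, linear_trend
from .geofields import FieldSeries, degree_arc_km, haversine_km
from .lagrangian import BEACHED, ParticleEnsemble, TrajectorySet


@dataclass
class EdgePosition:
    lon: float
    lat: float
    distance_km: float

    @property
    def missing(self) -> bool:
        return not np.isfinite(self.lon)


MISSING_EDGE = EdgePosition(np.nan, np.nan, np.nan)


@dataclass
class LeadingEdgeSeries:
    """Per-year leading-edge positions for one source (EXP1/2/3 or PIC)."""

    source: str
    years: np.ndarray
    edge_lon: np.ndarray
    edge_lat: np.ndarray
    edge_distance_km: np.ndarray
    reference_point: tuple[float, float] = (np.nan, np.nan)  # (lon, lat)

    def __post_init__(self):
        self.years = np.asarray(self.years, dtype=int)
        if np.any(np.diff(self.years) <= 0):
            raise ValueError("years must be strictly increasing")
        for a in ("edge_lon", "edge_lat", "edge_distance_km"):
            setattr(self, a, np.asarray(getattr(self, a), dtype=float))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"year": self.years, "source": self.source,
                             "edge_lon": self.edge_lon, "edge_lat": self.edge_lat,
                             "edge_distance_km": self.edge_distance_km})


@dataclass
class AttributionResult:
    """Decadal decomposition of edge expansion into drivers."""

    expansion_km: dict  # source -> km over the period
    pct_currents: float  # EXP2 / EXP1 x 100
    pct_temperature: float  # EXP3 / EXP1 x 100
    period: tuple[int, int]
    trends: dict = field(default_factory=dict)  # source -> TrendResult


def percentile_linear(values: np.ndarray, pct: float) -> float:
    """Sorted linear-interpolation percentile (numpy's 'linear' rule)."""
    return float(np.percentile(np.asarray(values, dtype=float), pct, method="linear"))


def leading_edge(
    final_positions: ParticleEnsemble,
    reference_point: tuple[float, float],
    region_lon_min: float = 40.0,
    pct: float = 95.0,
) -> EdgePosition:
    """95th-percentile edge of the particles inside the eastern region.

    Returns a missing marker (never raises) when no particle has entered
    the region.
    """
    sel = final_positions.lon > region_lon_min
    if not np.any(sel):
        return MISSING_EDGE
    lon = percentile_linear(final_positions.lon[sel], pct)
    lat = percentile_linear(final_positions.lat[sel], pct)
    d = haversine_km(reference_point[0], reference_point[1], lon, lat)
    return EdgePosition(lon, lat, d)


def bloom_pixels(pic_summer: FieldSeries, bloom_thresh: float,
                 region_lon_min: float | None = None) -> tuple[np.ndarray, np.ndarray]:
    """(lon, lat) centers of pixels with PIC >= threshold, optionally
    restricted to the eastern region.  Uses the last composite map if the
    series has several."""
    pic = pic_summer.values[-1]
    lat2d, lon2d = pic_summer.grid.mesh()
    sel = np.isfinite(pic) & (pic >= bloom_thresh)
    if region_lon_min is not None:
        sel &= lon2d > region_lon_min
    return lon2d[sel], lat2d[sel]


def pic_leading_edge(
    pic_summer: FieldSeries,
    bloom_thresh: float,
    reference_point: tuple[float, float],
    region_lon_min: float = 40.0,
    pct: float = 95.0,
) -> EdgePosition:
    """Leading edge of the observed bloom: percentile of bloom-pixel
    positions in the eastern region."""
    blon, blat = bloom_pixels(pic_summer, bloom_thresh, region_lon_min)
    if blon.size == 0:
        return MISSING_EDGE
    lon = percentile_linear(blon, pct)
    lat = percentile_linear(blat, pct)
    d = haversine_km(reference_point[0], reference_point[1], lon, lat)
    return EdgePosition(lon, lat, d)


def edge_expansion(series: LeadingEdgeSeries) -> tuple[float, TrendResult]:
    """Expansion (km) over the series period: trend slope x span."""
    ok = np.isfinite(series.edge_distance_km)
    if ok.sum() < 3:
        raise ValueError("edge_expansion needs >= 3 valid years")
    tr = linear_trend(series.edge_distance_km[ok], series.years[ok].astype(float))
    span = float(series.years[ok][-1] - series.years[ok][0])
    return tr.slope * span, tr


class UndefinedAttributionError(ZeroDivisionError):
    """EXP1 shows no expansion, so driver shares are undefined."""


def attribute_drivers(exp1: LeadingEdgeSeries, exp2: LeadingEdgeSeries,
                      exp3: LeadingEdgeSeries) -> AttributionResult:
    """Currents-vs-temperature decomposition of the edge expansion."""
    y0 = max(s.years.min() for s in (exp1, exp2, exp3))
    y1 = min(s.years.max() for s in (exp1, exp2, exp3))
    if y1 <= y0:
        raise ValueError("experiments have no overlapping year range")

    def clip(s: LeadingEdgeSeries) -> LeadingEdgeSeries:
        sel = (s.years >= y0) & (s.years <= y1)
        return LeadingEdgeSeries(s.source, s.years[sel], s.edge_lon[sel],
                                 s.edge_lat[sel], s.edge_distance_km[sel],
                                 s.reference_point)

    expansions, trends = {}, {}
    for s in map(clip, (exp1, exp2, exp3)):
        expansions[s.source], trends[s.source] = edge_expansion(s)
    e1 = expansions[exp1.source]
    if e1 == 0:
        raise UndefinedAttributionError("EXP1 expansion is zero")
    return AttributionResult(
        expansion_km=expansions,
        pct_currents=100.0 * expansions[exp2.source] / e1,
        pct_temperature=100.0 * expansions[exp3.source] / e1,
        period=(y0, y1),
        trends=trends,
    )


def bloom_matchup_fraction(final_positions: ParticleEnsemble, pic_summer: FieldSeries,
                           bloom_thresh: float, radius_km: float = 50.0) -> float:
    """Fraction of non-beached particles within ``radius_km`` of the
    nearest bloom pixel center."""
    blon, blat = bloom_pixels(pic_summer, bloom_thresh)
    keep = final_positions.status != BEACHED
    plon = final_positions.lon[keep]
    plat = final_positions.lat[keep]
    if plon.size == 0:
        return np.nan
    if blon.size == 0:
        import warnings

        warnings.warn("no bloom pixels above threshold; matchup fraction is 0", stacklevel=2)
        return 0.0
    d = haversine_km(plon[:, None], plat[:, None], blon[None, :], blat[None, :])
    return float(np.mean(d.min(axis=1) <= radius_km))


def trajectory_distance_km(traj: TrajectorySet, region_lon_min: float = 40.0) -> float:
    """Mean along-track path length (km) of particles whose final
    position lies east of ``region_lon_min``.  Missing when none do."""
    lon, lat = traj.positions_array()  # (nt, np)
    sel = traj.final.lon > region_lon_min
    if not np.any(sel):
        return np.nan
    seg = haversine_km(lon[:-1, sel], lat[:-1, sel], lon[1:, sel], lat[1:, sel])
    return float(seg.sum(axis=0).mean())


def bloom_area_km2(pic_summer: FieldSeries, bloom_thresh: float,
                   region_lon_min: float | None = None) -> float:
    """Total area of bloom pixels: cell area = meridional arc x zonal arc
    at the cell latitude."""
    pic = pic_summer.values[-1]
    grid = pic_summer.grid
    lat2d, lon2d = grid.mesh()
    sel = np.isfinite(pic) & (pic >= bloom_thresh)
    if region_lon_min is not None:
        sel &= lon2d > region_lon_min
    if not sel.any():
        return 0.0
    return float(grid.cell_area_km2()[sel].sum())


def edge_series_from_runs(trajectories: dict[int, TrajectorySet], source: str,
                          reference_point: tuple[float, float],
                          region_lon_min: float = 40.0, pct: float = 95.0) -> LeadingEdgeSeries:
    """Collect final-snapshot leading edges over a year-keyed run map."""
    years = sorted(trajectories)
    edges = [leading_edge(trajectories[y].final, reference_point, region_lon_min, pct)
             for y in years]
    return LeadingEdgeSeries(
        source=source, years=np.array(years),
        edge_lon=np.array([e.lon for e in edges]),
        edge_lat=np.array([e.lat for e in edges]),
        edge_distance_km=np.array([e.distance_km for e in edges]),
        reference_point=reference_point,
    )
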