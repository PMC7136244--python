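"""Grid geometry, spherical geodesy, masking, compositing and geostrophy.

All geometry is geodesic on a sphere of radius 6371 km.  Gridded series
live on a regular latitude-longitude grid (:class:`GeoGrid`); missing
values are NaN throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

EARTH_RADIUS_KM = 6371.0


def nanmean_quiet(a: np.ndarray, axis=None) -> np.ndarray:
    """nanmean that returns NaN silently for all-NaN slices."""
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        return np.nanmean(a, axis=axis)

KM_PER_DEG = EARTH_RADIUS_KM * np.pi / 180.0  # 111.1949... km per great-circle degree
GRAVITY = 9.81  # m s^-2
OMEGA = 7.2921e-5  # Earth's angular velocity, s^-1


class DegenerateLatitudeError(ValueError):
    """Zonal arc length requested at a pole."""


class GridConfigurationError(ValueError):
    """A grid/mask configuration that makes the operation meaningless."""


class EquatorSingularityError(ValueError):
    """Geostrophic balance is singular where the Coriolis parameter vanishes."""


def degree_arc_km(arc_deg: float, lat: float, axis: Literal["meridional", "zonal"]) -> float:
    """Great-circle length (km) of an arc of ``arc_deg`` degrees.

    Meridional arcs have constant length; zonal arcs shrink with the
    cosine of latitude.  On a 1/4 degree grid this gives 27.8 km of
    latitude by 9.5 km of longitude at 70N.
    """
    if axis not in ("meridional", "zonal"):
        raise ValueError(f"axis must be 'meridional' or 'zonal', got {axis!r}")
    if axis == "zonal":
        if abs(lat) >= 90.0:
            raise DegenerateLatitudeError("zonal arc length is degenerate at the poles")
        return float(arc_deg) * KM_PER_DEG * float(np.cos(np.deg2rad(lat)))
    return float(arc_deg) * KM_PER_DEG


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance in km between points given in degrees.

    Accepts scalars or broadcastable arrays.
    """
    lon1, lat1, lon2, lat2 = (np.deg2rad(np.asarray(x, dtype=float)) for x in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    return float(d) if d.ndim == 0 else d


@dataclass(frozen=True)
class GeoGrid:
    """Regular lat-lon grid: cell-center coordinates plus a land mask."""

    lat_centers: np.ndarray
    lon_centers: np.ndarray
    spacing_deg: float
    land_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        lat = np.asarray(self.lat_centers, dtype=float)
        lon = np.asarray(self.lon_centers, dtype=float)
        object.__setattr__(self, "lat_centers", lat)
        object.__setattr__(self, "lon_centers", lon)
        for name, c in (("lat", lat), ("lon", lon)):
            if c.ndim != 1 or c.size < 2:
                raise GridConfigurationError(f"{name}_centers must be 1-D with >= 2 points")
            if np.any(np.diff(c) <= 0):
                raise GridConfigurationError(f"{name}_centers must be strictly increasing")
            if np.max(np.abs(np.diff(c) - self.spacing_deg)) >= 1e-9:
                raise GridConfigurationError(f"{name} spacing is not uniformly {self.spacing_deg} deg")
        if self.land_mask is None:
            object.__setattr__(self, "land_mask", np.zeros(self.shape, dtype=bool))
        else:
            lm = np.asarray(self.land_mask, dtype=bool)
            if lm.shape != self.shape:
                raise GridConfigurationError(f"land_mask shape {lm.shape} != grid shape {self.shape}")
            object.__setattr__(self, "land_mask", lm)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.lat_centers.size, self.lon_centers.size)

    @property
    def ocean_mask(self) -> np.ndarray:
        return ~self.land_mask

    def mesh(self) -> tuple[np.ndarray, np.ndarray]:
        """(lat2d, lon2d) cell-center meshes with shape (n_lat, n_lon)."""
        return np.meshgrid(self.lat_centers, self.lon_centers, indexing="ij")

    def cell_area_km2(self) -> np.ndarray:
        """Cell areas as meridional arc x zonal arc at the cell latitude."""
        dlat_km = degree_arc_km(self.spacing_deg, 0.0, "meridional")
        dlon_km = self.spacing_deg * KM_PER_DEG * np.cos(np.deg2rad(self.lat_centers))
        return np.broadcast_to((dlat_km * dlon_km)[:, None], self.shape).copy()


@dataclass
class FieldSeries:
    """Time-stamped gridded scalar or vector series.

    ``values`` has shape (n_time, n_lat, n_lon) for scalars; vector series
    carry eastward/northward components in ``values`` / ``values_v``.
    Optional per-pixel companions: ``error_pct`` and ``ice_pct``.
    """

    grid: GeoGrid
    times: np.ndarray  # datetime64[ns], strictly increasing
    values: np.ndarray
    units: str = ""
    name: str = "field"
    values_v: np.ndarray | None = None
    error_pct: np.ndarray | None = None
    ice_pct: np.ndarray | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype="datetime64[ns]")
        if self.times.ndim != 1 or self.times.size == 0:
            raise ValueError("times must be a non-empty 1-D array")
        if np.any(np.diff(self.times).astype("int64") <= 0):
            raise ValueError("times must be strictly increasing")
        expected = (self.times.size,) + self.grid.shape
        for attr in ("values", "values_v", "error_pct", "ice_pct"):
            arr = getattr(self, attr)
            if arr is None:
                continue
            arr = np.asarray(arr, dtype=float)
            if arr.shape != expected:
                raise ValueError(f"{attr} shape {arr.shape} != {expected}")
            setattr(self, attr, arr)
        # land is always missing
        self.values[:, self.grid.land_mask] = np.nan
        if self.values_v is not None:
            self.values_v[:, self.grid.land_mask] = np.nan

    @property
    def is_vector(self) -> bool:
        return self.values_v is not None

    @property
    def n_times(self) -> int:
        return int(self.times.size)

    def copy(self) -> "FieldSeries":
        return FieldSeries(
            grid=self.grid,
            times=self.times.copy(),
            values=self.values.copy(),
            units=self.units,
            name=self.name,
            values_v=None if self.values_v is None else self.values_v.copy(),
            error_pct=None if self.error_pct is None else self.error_pct.copy(),
            ice_pct=None if self.ice_pct is None else self.ice_pct.copy(),
        )

    def speed(self) -> "FieldSeries":
        """Scalar speed sqrt(u^2+v^2) of a vector series."""
        if not self.is_vector:
            raise ValueError("speed() requires a vector series")
        return FieldSeries(
            grid=self.grid,
            times=self.times.copy(),
            values=np.hypot(self.values, self.values_v),
            units=self.units,
            name=f"{self.name}_speed",
        )


def distance_to_coast(grid: GeoGrid) -> np.ndarray:
    """Minimum great-circle distance (km) from each ocean cell center to
    any land cell center.  Land cells are NaN.
    """
    land = grid.land_mask
    if not land.any() or land.all():
        raise GridConfigurationError("distance_to_coast needs both land and ocean cells")
    lat2d, lon2d = grid.mesh()
    land_lat = lat2d[land]
    land_lon = lon2d[land]
    ocean = grid.ocean_mask
    oc_lat = lat2d[ocean]
    oc_lon = lon2d[ocean]
    # chunk over ocean cells to bound the (n_ocean x n_land) matrix
    out = np.full(grid.shape, np.nan)
    dists = np.empty(oc_lat.size)
    step = max(1, int(2e6 // max(1, land_lat.size)))
    for i in range(0, oc_lat.size, step):
        sl = slice(i, i + step)
        d = haversine_km(oc_lon[sl, None], oc_lat[sl, None], land_lon[None, :], land_lat[None, :])
        dists[sl] = d.min(axis=1)
    out[ocean] = dists
    return out


def geostrophic_from_adt(adt: FieldSeries) -> FieldSeries:
    """Surface geostrophic velocity from absolute dynamic topography.

    u = -(g/f) dEta/dy, v = (g/f) dEta/dx with f = 2*Omega*sin(lat).
    Centered differences in the interior, one-sided at the edges; a
    gradient that touches a missing cell is missing.
    """
    grid = adt.grid
    if np.any(np.abs(grid.lat_centers) < 5.0):
        raise EquatorSingularityError("geostrophic balance undefined within 5 deg of the equator")
    lat = grid.lat_centers
    f = 2.0 * OMEGA * np.sin(np.deg2rad(lat))  # s^-1, per latitude row
    dy_m = degree_arc_km(grid.spacing_deg, 0.0, "meridional") * 1000.0
    dx_m = np.array([degree_arc_km(grid.spacing_deg, la, "zonal") for la in lat]) * 1000.0

    eta = adt.values  # (nt, nlat, nlon); NaNs propagate through np.gradient-style stencils
    deta_dy = _grad_axis(eta, axis=1) / dy_m
    deta_dx = _grad_axis(eta, axis=2) / dx_m[None, :, None]
    gf = GRAVITY / f[None, :, None]
    u = -gf * deta_dy
    v = gf * deta_dx
    return FieldSeries(grid=grid, times=adt.times.copy(), values=u, values_v=v,
                       units="m s-1", name="geostrophic")


def _grad_axis(a: np.ndarray, axis: int) -> np.ndarray:
    """Centered first difference (per index step), one-sided at the ends.

    NaNs propagate: any stencil touching a missing cell yields NaN.
    """
    out = np.empty_like(a)
    sl = [slice(None)] * a.ndim

    def take(idx):
        s = list(sl)
        s[axis] = idx
        return tuple(s)

    out[take(slice(1, -1))] = (a[take(slice(2, None))] - a[take(slice(None, -2))]) / 2.0
    out[take(0)] = a[take(1)] - a[take(0)]
    out[take(-1)] = a[take(-1)] - a[take(-2)]
    return out


def quality_mask(fs: FieldSeries, error_thresh_pct: float = 50.0, ice_thresh_pct: float = 15.0) -> FieldSeries:
    """Drop pixels with error estimate or ice concentration above threshold.

    Thresholds are strict ("higher than"): equality retains the pixel.
    Companions that are absent simply contribute no masking.
    """
    for t in (error_thresh_pct, ice_thresh_pct):
        if not 0.0 <= t <= 100.0:
            raise ValueError("thresholds must lie in [0, 100]")
    out = fs.copy()
    bad = np.zeros(out.values.shape, dtype=bool)
    if out.error_pct is not None:
        bad |= out.error_pct > error_thresh_pct
    if out.ice_pct is not None:
        bad |= out.ice_pct > ice_thresh_pct
    out.values[bad] = np.nan
    if out.values_v is not None:
        out.values_v[bad] = np.nan
    return out


def monthly_composite(daily: FieldSeries) -> FieldSeries:
    """Calendar-month means of a daily series; a cell with no valid day
    in a month is missing in that month's composite."""
    if daily.n_times == 0:
        raise ValueError("empty series")
    idx = pd.DatetimeIndex(daily.times)
    periods = idx.to_period("M")
    uniq = periods.unique()
    nt = len(uniq)
    out = np.full((nt,) + daily.grid.shape, np.nan)
    out_v = np.full_like(out, np.nan) if daily.is_vector else None
    times = np.array([p.to_timestamp() for p in uniq], dtype="datetime64[ns]")
    for k, p in enumerate(uniq):
        sel = periods == p
        out[k] = nanmean_quiet(daily.values[sel], axis=0)
        if out_v is not None:
            out_v[k] = nanmean_quiet(daily.values_v[sel], axis=0)
    return FieldSeries(grid=daily.grid, times=times, values=out, values_v=out_v,
                       units=daily.units, name=daily.name)


def deseasonalize(monthly: FieldSeries, clim_period: tuple[int, int]) -> FieldSeries:
    """Remove the mean seasonal cycle: subtract from each month's map the
    multi-year mean map of that calendar month over ``clim_period``
    (inclusive year range)."""
    y0, y1 = clim_period
    if y1 - y0 + 1 < 2:
        raise ValueError("climatology period must span at least 2 years")
    idx = pd.DatetimeIndex(monthly.times)
    in_period = (idx.year >= y0) & (idx.year <= y1)
    clim = {}
    for m in range(1, 13):
        sel = in_period & (idx.month == m)
        if not sel.any():
            raise ValueError(f"calendar month {m} absent from climatology period {clim_period}")
        clim[m] = nanmean_quiet(monthly.values[np.asarray(sel)], axis=0)
    out = monthly.copy()
    for k, m in enumerate(idx.month):
        out.values[k] = monthly.values[k] - clim[m]
    out.name = f"{monthly.name}_anom"
    return out
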