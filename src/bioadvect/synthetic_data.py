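"""Synthetic satellite-product generator.

Emulates the gridded inputs of the bio-advection analysis on a
desk-scale domain: a diagonal "Norwegian/Barents" coastline, a poleward
along-coast jet with a Gaussian cross-section, an optional multi-year
core-speed trend and winter-peaked seasonal cycle, an SST field whose
March 4 degC isotherm migrates poleward at a prescribed rate, summer PIC
blooms placed downstream of the jet (or around supplied particle
positions), and monthly sea-level anomalies built from two prescribed
spatial patterns with an imposed principal-component trend plus ice and
error companion masks.

Everything is deterministic under a fixed seed.  The generator targets
testability of the pipeline, not dynamical realism: the jet is a
kinematic construction, not a balanced geostrophic flow.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .geofields import KM_PER_DEG, FieldSeries, GeoGrid

DAYS_PER_YEAR = 365.25

_CUM_DAYS = np.concatenate([[0], np.cumsum([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])])


def _calendar_doy(times) -> np.ndarray:
    """Day-of-year on a fixed 365-day calendar (Feb 29 folded onto Feb 28),
    so a given month-day has the same phase in every year."""
    idx = pd.DatetimeIndex(times)
    day = np.minimum(idx.day.values, np.where(idx.month.values == 2, 28, 31))
    return _CUM_DAYS[idx.month.values - 1] + day.astype(float)


@dataclass(frozen=True)
class ScenarioSpec:
    """Parameters of one synthetic world.

    Distances in km, speeds in m/s, temperatures in degC, rates per
    calendar year.  The defaults are the desk-scale reference scenario:
    a 0.5 degree grid over 20 (lat) x 30 (lon) degrees and 10 years.
    """

    # grid
    lat_min: float = 58.0
    lat_max: float = 78.0
    lon_min: float = 30.0
    lon_max: float = 60.0
    spacing_deg: float = 0.5
    # years (inclusive)
    year_start: int = 1998
    year_end: int = 2007
    # coastline: land lies south of the line joining these two lat values
    # at the west and east domain edges
    coast_lat_west: float = 60.0
    coast_lat_east: float = 69.0
    # jet: along-coast Gaussian-profile current, offset north of the coast
    jet_offset_deg: float = 1.0
    jet_core_speed: float = 0.055  # m/s at the core
    jet_width_km: float = 120.0  # Gaussian sigma across the jet
    jet_speed_trend_per_year: float = 0.0  # fractional core-speed change per year
    jet_seasonal_amp: float = 0.2  # fractional, peak in mid-January
    # SST: meridional gradient; March 4 degC isotherm at isotherm_lat0 in
    # year_start, migrating poleward
    isotherm_lat0: float = 62.0
    isotherm_migration_km_per_year: float = 0.0
    sst_grad_per_deg: float = 0.5  # degC per degree latitude
    sst_seasonal_amp: float = 2.0  # degC
    # PIC blooms
    pic_magnitude: float = 0.002  # mol/m3 inside bloom pixels
    bloom_along_km: float = 900.0  # blooms start this far along the jet
    # noise
    velocity_noise_sigma: float = 0.05  # m/s, inside the 7-15 cm/s product RMS
    sst_noise_sigma: float = 0.1  # degC
    # SLA construction
    sla_pattern_amp: float = 0.05  # m
    sla_pc_trend_per_year: float = 0.3  # normalized units / yr, carried by PC1
    sla_noise_sigma: float = 0.005  # m
    # masks
    ice_edge_lat_mean: float = 74.0
    ice_edge_lat_seasonal: float = 2.0  # southernmost in March
    seed: int = 0

    def __post_init__(self):
        if self.year_end - self.year_start + 1 < 2:
            raise ValueError("scenario needs at least 2 years")

    @property
    def years(self) -> range:
        return range(self.year_start, self.year_end + 1)

    # -- factorial worlds -------------------------------------------------
    def currents_only(self, trend: float = 0.02) -> "ScenarioSpec":
        """World where only the jet accelerates (stationary SST)."""
        return replace(self, jet_speed_trend_per_year=trend,
                       isotherm_migration_km_per_year=0.0)

    def temperature_only(self, migration_km_per_year: float = 15.0) -> "ScenarioSpec":
        """World where only the winter isotherm migrates (stationary jet)."""
        return replace(self, jet_speed_trend_per_year=0.0,
                       isotherm_migration_km_per_year=migration_km_per_year)

    def combined(self, trend: float = 0.02, migration_km_per_year: float = 15.0) -> "ScenarioSpec":
        """World with both drivers active."""
        return replace(self, jet_speed_trend_per_year=trend,
                       isotherm_migration_km_per_year=migration_km_per_year)

    def stationary(self) -> "ScenarioSpec":
        return replace(self, jet_speed_trend_per_year=0.0,
                       isotherm_migration_km_per_year=0.0,
                       velocity_noise_sigma=0.0, sst_noise_sigma=0.0)

    # -- geometry ----------------------------------------------------------
    def build_grid(self) -> GeoGrid:
        d = self.spacing_deg
        lats = np.arange(self.lat_min + d / 2, self.lat_max, d)
        lons = np.arange(self.lon_min + d / 2, self.lon_max, d)
        land = np.zeros((lats.size, lons.size), dtype=bool)
        coast = self.coast_lat(lons)
        land[:] = lats[:, None] < coast[None, :]
        return GeoGrid(lat_centers=lats, lon_centers=lons, spacing_deg=d, land_mask=land)

    def coast_lat(self, lon) -> np.ndarray:
        """Latitude of the coastline at given longitude(s)."""
        f = (np.asarray(lon, dtype=float) - self.lon_min) / (self.lon_max - self.lon_min)
        return self.coast_lat_west + f * (self.coast_lat_east - self.coast_lat_west)

    @property
    def _lat_ref(self) -> float:
        return 0.5 * (self.coast_lat_west + self.coast_lat_east) + self.jet_offset_deg

    def _project_km(self, lon, lat) -> tuple[np.ndarray, np.ndarray]:
        """Equirectangular projection (km) used for the jet geometry."""
        kx = KM_PER_DEG * np.cos(np.deg2rad(self._lat_ref))
        return np.asarray(lon, float) * kx, np.asarray(lat, float) * KM_PER_DEG

    def jet_axis_km(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """((x0,y0), (x1,y1), tangent unit vector) of the jet axis in km."""
        la0 = self.coast_lat_west + self.jet_offset_deg
        la1 = self.coast_lat_east + self.jet_offset_deg
        x0, y0 = self._project_km(self.lon_min, la0)
        x1, y1 = self._project_km(self.lon_max, la1)
        t = np.array([x1 - x0, y1 - y0])
        t = t / np.hypot(*t)
        return np.array([x0, y0]), np.array([x1, y1]), t

    def jet_coords_km(self, lon, lat) -> tuple[np.ndarray, np.ndarray]:
        """(along, cross) km coordinates of points relative to the jet axis.

        ``along`` is measured from the western end of the axis; ``cross``
        is positive on the poleward side.
        """
        p0, _, t = self.jet_axis_km()
        x, y = self._project_km(lon, lat)
        dx, dy = x - p0[0], y - p0[1]
        along = dx * t[0] + dy * t[1]
        cross = -dx * t[1] + dy * t[0]
        return along, cross

    def along_km_of_lon(self, lon: float) -> float:
        """Along-jet coordinate of the point of the axis at given longitude."""
        a, _ = self.jet_coords_km(lon, self.coast_lat(lon) + self.jet_offset_deg)
        return float(a)

    # -- field generators --------------------------------------------------
    def jet_speed_factor(self, year: int, doy: np.ndarray | float):
        """Multiplicative (trend x season) factor on the core speed."""
        yr = 1.0 + self.jet_speed_trend_per_year * (year - self.year_start)
        season = 1.0 + self.jet_seasonal_amp * np.cos(2 * np.pi * (np.asarray(doy, float) - 15.0) / DAYS_PER_YEAR)
        return yr * season

    def march_isotherm_lat(self, year: int) -> float:
        """Latitude of the March 4 degC isotherm in ``year``."""
        return self.isotherm_lat0 + (self.isotherm_migration_km_per_year / KM_PER_DEG) * (year - self.year_start)

    def gen_velocity_series(self, year: int, t0: str = "03-01", t1: str = "09-01") -> FieldSeries:
        """Daily surface velocity for one year's advection window."""
        grid = self.build_grid()
        times = pd.date_range(f"{year}-{t0}", f"{year}-{t1}", freq="D").values
        doy = _calendar_doy(times)
        lat2d, lon2d = grid.mesh()
        _, cross = self.jet_coords_km(lon2d, lat2d)
        _, _, t = self.jet_axis_km()
        profile = np.exp(-(cross**2) / (2.0 * self.jet_width_km**2))
        fac = self.jet_speed_factor(year, doy)  # (nt,)
        speed = self.jet_core_speed * fac[:, None, None] * profile[None, :, :]
        u = speed * t[0]
        v = speed * t[1]
        if self.velocity_noise_sigma > 0:
            rng = np.random.default_rng((self.seed, year, 1))
            u = u + rng.normal(0, self.velocity_noise_sigma, u.shape)
            v = v + rng.normal(0, self.velocity_noise_sigma, v.shape)
        return FieldSeries(grid=grid, times=times, values=u, values_v=v,
                           units="m s-1", name="geostrophic")

    def gen_sst_series(self, year: int, t0: str = "03-01", t1: str = "09-01") -> FieldSeries:
        """Daily SST with a meridional gradient, a seasonal cycle that
        vanishes in mid-March, and the migrating March isotherm."""
        grid = self.build_grid()
        times = pd.date_range(f"{year}-{t0}", f"{year}-{t1}", freq="D").values
        doy = _calendar_doy(times)
        lat2d, _ = grid.mesh()
        iso = self.march_isotherm_lat(year)
        base = 4.0 + self.sst_grad_per_deg * (iso - lat2d)  # (nlat, nlon)
        season = self.sst_seasonal_amp * np.sin(2 * np.pi * (doy - 74.0) / DAYS_PER_YEAR)
        sst = base[None, :, :] + season[:, None, None]
        if self.sst_noise_sigma > 0:
            rng = np.random.default_rng((self.seed, year, 2))
            sst = sst + rng.normal(0, self.sst_noise_sigma, sst.shape)
        return FieldSeries(grid=grid, times=times, values=sst, units="degC", name="analysed_sst")

    def gen_pic_series(self, year: int, traj_hint=None, bloom_extent_km: float = 600.0) -> FieldSeries:
        """Summer (Jul-Sep) PIC composite.

        With ``traj_hint`` (a TrajectorySet) blooms are placed on the
        cells holding final non-beached particle positions; otherwise a
        band along the jet from ``bloom_along_km`` onward.
        """
        grid = self.build_grid()
        times = np.array([np.datetime64(f"{year}-08-15")], dtype="datetime64[ns]")
        pic = np.zeros((1,) + grid.shape)
        lat2d, lon2d = grid.mesh()
        if traj_hint is not None:
            from .lagrangian import BEACHED

            fin = traj_hint.final
            keep = fin.status != BEACHED
            ii = np.clip(np.round((fin.lat[keep] - grid.lat_centers[0]) / grid.spacing_deg).astype(int), 0, grid.shape[0] - 1)
            jj = np.clip(np.round((fin.lon[keep] - grid.lon_centers[0]) / grid.spacing_deg).astype(int), 0, grid.shape[1] - 1)
            pic[0, ii, jj] = self.pic_magnitude
        else:
            along, cross = self.jet_coords_km(lon2d, lat2d)
            band = (np.abs(cross) < 2 * self.jet_width_km) & (along >= self.bloom_along_km) \
                & (along <= self.bloom_along_km + bloom_extent_km)
            pic[0, band] = self.pic_magnitude
        return FieldSeries(grid=grid, times=times, values=pic, units="mol m-3", name="pic")

    # -- sea level ---------------------------------------------------------
    def sla_patterns(self) -> tuple[np.ndarray, np.ndarray]:
        """Two orthonormal spatial patterns over ocean cells (NaN on land):
        a cross-jet dipole and a broad along-domain gradient mode."""
        grid = self.build_grid()
        lat2d, lon2d = grid.mesh()
        _, cross = self.jet_coords_km(lon2d, lat2d)
        s = self.jet_width_km * 2
        p1 = (cross / s) * np.exp(-(cross**2) / (2 * s**2))
        p2 = (lon2d - lon2d.mean()) / (self.lon_max - self.lon_min)
        ocean = grid.ocean_mask
        v1 = p1[ocean]
        v1 = v1 / np.linalg.norm(v1)
        v2 = p2[ocean]
        v2 = v2 - (v2 @ v1) * v1
        v2 = v2 / np.linalg.norm(v2)
        out1 = np.full(grid.shape, np.nan)
        out2 = np.full(grid.shape, np.nan)
        out1[ocean], out2[ocean] = v1, v2
        return out1, out2

    def sla_pcs(self, n_months: int) -> tuple[np.ndarray, np.ndarray]:
        """Deterministic PC time series (normalized-unit scale); PC1
        carries the imposed linear trend."""
        t_yr = np.arange(n_months) / 12.0
        pc1 = self.sla_pc_trend_per_year * (t_yr - t_yr.mean()) + 1.0 * np.sin(2 * np.pi * t_yr / 3.7)
        pc2 = 0.6 * np.cos(2 * np.pi * t_yr / 2.3)
        return pc1, pc2

    def gen_sla_series(self) -> FieldSeries:
        """Monthly non-seasonal SLA with error and ice companions.

        Built as pattern1*PC1 + pattern2*PC2 + noise; the ice companion
        closes the seasonal northern band, the error companion grows
        toward the ice edge.
        """
        grid = self.build_grid()
        months = pd.date_range(f"{self.year_start}-01-01",
                               f"{self.year_end}-12-01", freq="MS")
        nt = len(months)
        p1, p2 = self.sla_patterns()
        pc1, pc2 = self.sla_pcs(nt)
        amp = self.sla_pattern_amp * np.sqrt(grid.ocean_mask.sum())  # per-cell ~ pattern_amp
        vals = amp * (pc1[:, None, None] * np.nan_to_num(p1)[None] + pc2[:, None, None] * np.nan_to_num(p2)[None])
        if self.sla_noise_sigma > 0:
            rng = np.random.default_rng((self.seed, 3))
            vals = vals + rng.normal(0, self.sla_noise_sigma, vals.shape)
        lat2d, _ = grid.mesh()
        ice = np.zeros((nt,) + grid.shape)
        err = np.zeros((nt,) + grid.shape)
        for k, ts in enumerate(months):
            edge = self.ice_edge_lat(ts.month)
            ice[k] = np.where(lat2d >= edge, 100.0, 0.0)
            err[k] = 10.0 + 80.0 * np.clip((lat2d - (edge - 2.0)) / 4.0, 0.0, 1.0)
        return FieldSeries(grid=grid, times=months.values, values=vals,
                           units="m", name="sla", error_pct=err, ice_pct=ice)

    def ice_edge_lat(self, month: int) -> float:
        """Southernmost in March, northernmost in September."""
        return self.ice_edge_lat_mean - self.ice_edge_lat_seasonal * np.cos(2 * np.pi * (month - 3) / 12.0)
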