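"""Readers/writers and run configuration.

Gridded series are exchanged as CF-style NetCDF (dimensions time,
latitude, longitude; longitudes in [-180, 180)).  Files are written
through xarray's scipy backend (NETCDF3 classic), which round-trips
every layout this package produces.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from .eof_analysis import EOFResult
from .geofields import FieldSeries, GeoGrid
from .lagrangian import STATUS_NAMES, TrajectorySet

_EXPECTED_UNITS = {
    "sla": "m", "adt": "m", "ugos": "m s-1", "vgos": "m s-1",
    "analysed_sst": "degC", "pic": "mol m-3",
}


class FieldLoadError(ValueError):
    """A gridded file violates the expected layout."""


def _grid_from_coords(lat: np.ndarray, lon: np.ndarray, land_mask: np.ndarray | None) -> GeoGrid:
    spacing = float(np.round(np.median(np.diff(lat)), 12))
    return GeoGrid(lat_centers=lat, lon_centers=lon, spacing_deg=spacing, land_mask=land_mask)


def save_field_series(fs: FieldSeries, path: str | Path) -> None:
    """Write a FieldSeries as CF-style NetCDF."""
    coords = {"time": fs.times, "latitude": fs.grid.lat_centers, "longitude": fs.grid.lon_centers}
    dims = ("time", "latitude", "longitude")
    data = {}
    if fs.is_vector:
        data["ugos"] = (dims, fs.values, {"units": fs.units})
        data["vgos"] = (dims, fs.values_v, {"units": fs.units})
    else:
        data[fs.name] = (dims, fs.values, {"units": fs.units})
    if fs.error_pct is not None:
        data["err"] = (dims, fs.error_pct, {"units": "%"})
    if fs.ice_pct is not None:
        data["ice_conc"] = (dims, fs.ice_pct, {"units": "%"})
    data["land_mask"] = (("latitude", "longitude"), fs.grid.land_mask.astype("i1"), {})
    ds = xr.Dataset(data, coords=coords)
    ds.to_netcdf(Path(path), engine="scipy")


def load_field_series(path: str | Path, variable: str) -> FieldSeries:
    """Read one variable (plus companions) from a CF-style NetCDF file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with xr.open_dataset(path, engine="scipy") as ds:
        ds = ds.load()
    names = set(ds.data_vars)
    vector = variable in ("ugos", "vgos", "velocity", "geostrophic")
    need = {"ugos", "vgos"} if vector else {variable}
    if not need <= names:
        raise FieldLoadError(f"variable(s) {sorted(need - names)} absent from {path.name}; present: {sorted(names)}")
    lat = ds["latitude"].values.astype(float)
    lon = ds["longitude"].values.astype(float)
    flipped = False
    if lat.size > 1 and lat[0] > lat[-1]:
        ds = ds.isel(latitude=slice(None, None, -1))
        lat = lat[::-1]
        flipped = True
    lon = (lon + 180.0) % 360.0 - 180.0
    times = ds["time"].values
    if np.any(np.diff(times).astype("int64") <= 0):
        raise FieldLoadError(f"non-monotone time axis in {path.name}")
    land = ds["land_mask"].values.astype(bool) if "land_mask" in names else None
    grid = _grid_from_coords(lat, lon, land)
    main = "ugos" if vector else variable
    units = str(ds[main].attrs.get("units", ""))
    expected = _EXPECTED_UNITS.get(main)
    if expected and units and units != expected:
        raise FieldLoadError(f"unit mismatch for {main}: expected {expected!r}, found {units!r}")
    fs = FieldSeries(
        grid=grid, times=times, values=ds[main].values.astype(float),
        values_v=ds["vgos"].values.astype(float) if vector else None,
        units=units, name=main,
        error_pct=ds["err"].values.astype(float) if "err" in names else None,
        ice_pct=ds["ice_conc"].values.astype(float) if "ice_conc" in names else None,
    )
    if flipped:
        import logging

        logging.getLogger(__name__).info("flipped %s to ascending latitude", path.name)
    return fs


def save_trajectories_csv(traj: TrajectorySet, path: str | Path) -> None:
    rows = []
    for snap in traj.snapshots:
        for i in range(snap.n):
            rows.append((int(snap.ids[i]), pd.Timestamp(snap.time).isoformat(),
                         snap.lon[i], snap.lat[i], STATUS_NAMES[int(snap.status[i])]))
    df = pd.DataFrame(rows, columns=["id", "time", "lon", "lat", "status"])
    df.to_csv(path, index=False, float_format="%.6f")


def save_eof_netcdf(eof: EOFResult, path: str | Path) -> None:
    ds = xr.Dataset(
        {
            "modes": (("mode", "latitude", "longitude"), eof.modes),
            "pcs": (("mode", "time"), eof.pcs),
            "explained_frac": (("mode",), eof.explained_frac),
            "retained": (("latitude", "longitude"), eof.retained_cells.astype("i1")),
        },
        coords={"mode": np.arange(1, eof.n_modes + 1), "time": eof.times,
                "latitude": eof.grid.lat_centers, "longitude": eof.grid.lon_centers},
    )
    ds.to_netcdf(Path(path), engine="scipy")


@dataclass
class RunConfig:
    """All pipeline parameters, with the study's defaults."""

    output_dir: str = "bioadvect_out"
    seed: int = 0
    years: tuple[int, int] = (1998, 2007)
    window: tuple[str, str] = ("03-01", "09-01")
    clim_period: tuple[int, int] | None = None
    sst_min: float = 4.0
    dist_max_km: float = 180.0
    dist_inclusive: bool = False
    error_thresh_pct: float = 50.0
    ice_thresh_pct: float = 15.0
    coverage_thresh: float = 0.5
    edge_pct: float = 95.0
    region_lon_min: float = 40.0
    bloom_thresh: float = 0.001
    matchup_radius_km: float = 50.0
    dt_seconds: float = 10800.0
    seeds_per_cell: int = 2
    noise_sigma: float = 0.0
    scenario: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        d = json.loads(Path(path).read_text())
        for k in ("years", "window", "clim_period"):
            if d.get(k) is not None:
                d[k] = tuple(d[k])
        return cls(**d)
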