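"""Factorial Lagrangian experiments.

Three simulations separate the drivers of the poleward range expansion:

* EXP1 — yearly March SST inoculum, yearly currents (full variability);
* EXP2 — climatological-SST inoculum (identical patch every year),
  yearly currents (isolates the current signal);
* EXP3 — yearly inoculum, climatological currents (isolates the winter
  temperature signal).

Particles are seeded on the 1st of March at every ocean cell center
where March SST >= 4 degC and the distance to the coast is under 180 km,
then advected to the 1st of September.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .geofields import FieldSeries, GeoGrid, distance_to_coast, nanmean_quiet
from .lagrangian import ACTIVE, ParticleEnsemble, TrajectorySet, advect_ensemble


class EmptyInoculumError(ValueError):
    """No grid cell satisfies the inoculum criteria."""


@dataclass
class InoculumPatch:
    year: int
    seed_positions: np.ndarray  # (n, 2) [lon, lat] in row-major cell order
    criteria: dict
    sst_source: str  # "yearly" | "climatology"

    @property
    def n(self) -> int:
        return int(self.seed_positions.shape[0])

    def to_ensemble(self, time: np.datetime64) -> ParticleEnsemble:
        n = self.n
        return ParticleEnsemble(
            ids=np.arange(n), lon=self.seed_positions[:, 0],
            lat=self.seed_positions[:, 1], time=np.datetime64(time, "ns"),
            status=np.full(n, ACTIVE),
        )


@dataclass
class ExperimentSpec:
    name: str  # EXP1 | EXP2 | EXP3
    sst_mode: str  # yearly | climatological
    current_mode: str  # yearly | climatological
    years: tuple[int, int]
    window: tuple[str, str] = ("03-01", "09-01")  # month-day start/end
    clim_period: tuple[int, int] | None = None

    _MODES = {
        "EXP1": ("yearly", "yearly"),
        "EXP2": ("climatological", "yearly"),
        "EXP3": ("yearly", "climatological"),
    }

    def __post_init__(self):
        if self.name in self._MODES and (self.sst_mode, self.current_mode) != self._MODES[self.name]:
            raise ValueError(
                f"{self.name} requires (sst, current) modes {self._MODES[self.name]}, "
                f"got ({self.sst_mode}, {self.current_mode})")
        if self.clim_period is None:
            self.clim_period = self.years

    @classmethod
    def standard(cls, name: str, years: tuple[int, int], clim_period: tuple[int, int] | None = None) -> "ExperimentSpec":
        sst_mode, current_mode = cls._MODES[name]
        return cls(name=name, sst_mode=sst_mode, current_mode=current_mode,
                   years=years, clim_period=clim_period)


def select_inoculum(
    sst_march: np.ndarray,
    coast_dist: np.ndarray,
    grid: GeoGrid,
    sst_min: float = 4.0,
    dist_max: float = 180.0,
    year: int = 0,
    sst_source: str = "yearly",
    dist_inclusive: bool = False,
    seeds_per_cell: int = 1,
) -> InoculumPatch:
    """Seed particles in every ocean cell with SST >= ``sst_min``
    (inclusive) and coast distance < ``dist_max`` (strict by default).

    ``seeds_per_cell`` k places a regular k x k sub-grid inside each
    qualifying cell (k=1: the cell center).  Ordering is deterministic
    (row-major over the grid, then over the sub-grid).
    """
    if sst_march.shape != grid.shape or coast_dist.shape != grid.shape:
        raise ValueError("fields must share the grid shape")
    if seeds_per_cell < 1:
        raise ValueError("seeds_per_cell must be >= 1")
    near = coast_dist <= dist_max if dist_inclusive else coast_dist < dist_max
    sel = grid.ocean_mask & np.isfinite(sst_march) & (sst_march >= sst_min) & np.isfinite(coast_dist) & near
    if not sel.any():
        raise EmptyInoculumError(
            f"no cell satisfies SST >= {sst_min} degC and coast distance < {dist_max} km")
    lat2d, lon2d = grid.mesh()
    k = seeds_per_cell
    n = int(sel.sum())
    offs = ((np.arange(k) + 0.5) / k - 0.5) * grid.spacing_deg
    lon_s = np.broadcast_to(lon2d[sel][:, None, None] + offs[None, None, :], (n, k, k)).ravel()
    lat_s = np.broadcast_to(lat2d[sel][:, None, None] + offs[None, :, None], (n, k, k)).ravel()
    pos = np.column_stack([lon_s, lat_s])
    return InoculumPatch(year=year, seed_positions=pos,
                         criteria={"sst_min_degC": sst_min, "dist_max_km": dist_max,
                                   "dist_inclusive": dist_inclusive, "month": 3},
                         sst_source=sst_source)


def climatological_field(series: FieldSeries, month: int, period: tuple[int, int]) -> np.ndarray:
    """Per-cell multi-year mean of one calendar month (missing-aware)."""
    y0, y1 = period
    idx = pd.DatetimeIndex(series.times)
    sel = np.asarray((idx.month == month) & (idx.year >= y0) & (idx.year <= y1))
    if sel.sum() < 2:
        raise ValueError(f"need >= 2 instances of month {month} in {period}")
    return nanmean_quiet(series.values[sel], axis=0)


def climatological_velocity(vel: FieldSeries, period: tuple[int, int],
                            out_year: int | None = None) -> FieldSeries:
    """Day-of-year mean velocity across years (Feb 29 merged into Feb 28),
    returned as one synthetic daily year labelled ``out_year``."""
    y0, y1 = period
    if y1 - y0 + 1 < 2:
        raise ValueError("climatology period must cover >= 2 years")
    idx = pd.DatetimeIndex(vel.times)
    in_p = np.asarray((idx.year >= y0) & (idx.year <= y1))
    # month-day key; Feb 29 folded onto Feb 28
    keys = np.array([f"{m:02d}-{28 if (m == 2 and d == 29) else d:02d}"
                     for m, d in zip(idx.month, idx.day)])
    uniq = sorted(set(keys[in_p]))
    out_year = y0 if out_year is None else out_year
    times, U, V = [], [], []
    for key in uniq:
        sel = in_p & (keys == key)
        U.append(nanmean_quiet(vel.values[sel], axis=0))
        V.append(nanmean_quiet(vel.values_v[sel], axis=0))
        times.append(np.datetime64(f"{out_year}-{key}"))
    return FieldSeries(grid=vel.grid, times=np.array(times, dtype="datetime64[ns]"),
                       values=np.stack(U), values_v=np.stack(V),
                       units=vel.units, name=f"{vel.name}_clim")


@dataclass
class DataBundle:
    """Inputs for one experiment suite.

    ``sst_daily`` and ``velocity_for_year`` are callables keyed by year so
    big daily stacks can be produced lazily; ``sst_march(year)`` returns
    the March composite map for that year.
    """

    grid: GeoGrid
    sst_march: Callable[[int], np.ndarray]
    velocity_for_year: Callable[[int], FieldSeries]
    coast_dist: np.ndarray | None = None

    def __post_init__(self):
        if self.coast_dist is None:
            self.coast_dist = distance_to_coast(self.grid)


@dataclass
class ExperimentRun:
    spec: ExperimentSpec
    trajectories: dict[int, TrajectorySet] = field(default_factory=dict)
    inocula: dict[int, InoculumPatch] = field(default_factory=dict)
    failures: dict[int, str] = field(default_factory=dict)


def run_experiment(
    spec: ExperimentSpec,
    bundle: DataBundle,
    dt: float = 10800.0,
    sst_min: float = 4.0,
    dist_max: float = 180.0,
    dist_inclusive: bool = False,
    seeds_per_cell: int = 1,
) -> ExperimentRun:
    """Run one factorial experiment over its year range.

    A failed year is recorded in ``failures`` and skipped, never silent.
    """
    y0, y1 = spec.years
    run = ExperimentRun(spec=spec)

    clim_sst = None
    if spec.sst_mode == "climatological":
        maps = [bundle.sst_march(y) for y in range(spec.clim_period[0], spec.clim_period[1] + 1)]
        clim_sst = nanmean_quiet(np.stack(maps), axis=0)
    clim_vel = None
    if spec.current_mode == "climatological":
        years_v = range(spec.clim_period[0], spec.clim_period[1] + 1)
        stacked = _stack_velocity_years(bundle, years_v)
        clim_vel = climatological_velocity(stacked, spec.clim_period)

    for year in range(y0, y1 + 1):
        try:
            sst_map = clim_sst if clim_sst is not None else bundle.sst_march(year)
            patch = select_inoculum(sst_map, bundle.coast_dist, bundle.grid,
                                    sst_min=sst_min, dist_max=dist_max, year=year,
                                    sst_source=spec.sst_mode, dist_inclusive=dist_inclusive,
                                    seeds_per_cell=seeds_per_cell)
            t0 = np.datetime64(f"{year}-{spec.window[0]}")
            t1 = np.datetime64(f"{year}-{spec.window[1]}")
            if clim_vel is not None:
                vel = _relabel_year(clim_vel, year)
            else:
                vel = bundle.velocity_for_year(year)
            traj = advect_ensemble(patch.to_ensemble(t0), vel, t0, t1, dt=dt)
            traj.provenance.update({"experiment": spec.name, "year": year,
                                    "velocity_source": spec.current_mode,
                                    "sst_source": spec.sst_mode})
            run.inocula[year] = patch
            run.trajectories[year] = traj
        except Exception as exc:  # noqa: BLE001 - per-year fault isolation
            run.failures[year] = f"{type(exc).__name__}: {exc}"
    return run


def _stack_velocity_years(bundle: DataBundle, years) -> FieldSeries:
    parts = [bundle.velocity_for_year(y) for y in years]
    times = np.concatenate([p.times for p in parts])
    return FieldSeries(grid=bundle.grid, times=times,
                       values=np.concatenate([p.values for p in parts]),
                       values_v=np.concatenate([p.values_v for p in parts]),
                       units=parts[0].units, name=parts[0].name)


def _relabel_year(clim_vel: FieldSeries, year: int) -> FieldSeries:
    """Shift a climatological daily series onto calendar ``year``."""
    idx = pd.DatetimeIndex(clim_vel.times)
    times = np.array([np.datetime64(f"{year}-{m:02d}-{d:02d}")
                      for m, d in zip(idx.month, idx.day)], dtype="datetime64[ns]")
    return FieldSeries(grid=clim_vel.grid, times=times, values=clim_vel.values.copy(),
                       values_v=clim_vel.values_v.copy(), units=clim_vel.units,
                       name=clim_vel.name)
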