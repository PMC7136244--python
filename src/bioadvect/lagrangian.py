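"""RK4 advection of particle ensembles through time-varying gridded
velocity fields.

Positions are stored in degrees; the kinematics are integrated on the
sphere, d(lambda)/dt = u / (R cos(phi)), d(phi)/dt = v / R, so zonal
displacement respects the metric convergence toward the poles.
Interpolation is bilinear in space with land/missing neighbours given
zero weight (weights renormalized) and linear in time between the two
bracketing daily fields.  A particle whose interpolated velocity becomes
unavailable is flagged beached and stays frozen; a particle leaving the
grid bounds is flagged out-of-domain and frozen.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geofields import EARTH_RADIUS_KM, FieldSeries

EARTH_RADIUS_M = EARTH_RADIUS_KM * 1000.0

ACTIVE = 0
BEACHED = 1
OUT_OF_DOMAIN = 2
STATUS_NAMES = {ACTIVE: "active", BEACHED: "beached", OUT_OF_DOMAIN: "out_of_domain"}


@dataclass
class ParticleEnsemble:
    """Positions and status of virtual inoculum particles at one time."""

    ids: np.ndarray
    lon: np.ndarray
    lat: np.ndarray
    time: np.datetime64
    status: np.ndarray  # int codes per STATUS_NAMES

    def __post_init__(self):
        self.ids = np.asarray(self.ids, dtype=int)
        self.lon = np.asarray(self.lon, dtype=float)
        self.lat = np.asarray(self.lat, dtype=float)
        self.status = np.asarray(self.status, dtype=int)
        if len({self.ids.size, self.lon.size, self.lat.size, self.status.size}) != 1:
            raise ValueError("ids, lon, lat, status must have equal length")
        if np.unique(self.ids).size != self.ids.size:
            raise ValueError("particle ids must be unique")

    @property
    def n(self) -> int:
        return int(self.ids.size)

    def copy(self) -> "ParticleEnsemble":
        return ParticleEnsemble(self.ids.copy(), self.lon.copy(), self.lat.copy(),
                                self.time, self.status.copy())


@dataclass
class TrajectorySet:
    """Ensemble snapshots at fixed output cadence over an advection window."""

    snapshots: list[ParticleEnsemble]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        times = self.times
        if len(self.snapshots) >= 2 and np.any(np.diff(times).astype("int64") <= 0):
            raise ValueError("snapshot times must be strictly increasing")
        ns = {s.n for s in self.snapshots}
        if len(ns) > 1:
            raise ValueError("particle count must be constant across snapshots")

    @property
    def times(self) -> np.ndarray:
        return np.array([s.time for s in self.snapshots], dtype="datetime64[ns]")

    @property
    def final(self) -> ParticleEnsemble:
        return self.snapshots[-1]

    def positions_array(self) -> tuple[np.ndarray, np.ndarray]:
        """(lon, lat) arrays of shape (n_snapshots, n_particles)."""
        return (np.stack([s.lon for s in self.snapshots]),
                np.stack([s.lat for s in self.snapshots]))


class VelocitySampler:
    """Space-time interpolator over a daily vector field series."""

    def __init__(self, vel: FieldSeries):
        if not vel.is_vector:
            raise ValueError("velocity sampler needs a vector series")
        self.vel = vel
        self.grid = vel.grid
        self._t0 = vel.times[0].astype("datetime64[ns]").astype("int64")
        self._t_sec = (vel.times.astype("int64") - self._t0) / 1e9
        self._lat0 = vel.grid.lat_centers[0]
        self._lon0 = vel.grid.lon_centers[0]
        self._dd = vel.grid.spacing_deg

    @property
    def t_span_sec(self) -> tuple[float, float]:
        return float(self._t_sec[0]), float(self._t_sec[-1])

    def seconds_since_start(self, t: np.datetime64) -> float:
        return float((np.datetime64(t, "ns").astype("int64") - self._t0) / 1e9)

    def sample_sec(self, lon: np.ndarray, lat: np.ndarray, t_sec: float) -> tuple[np.ndarray, np.ndarray]:
        """Interpolated (u, v) at positions (deg) and time (s since series
        start).  NaN components mark unavailable velocity."""
        if t_sec < self._t_sec[0] - 1e-6 or t_sec > self._t_sec[-1] + 1e-6:
            raise ValueError(f"time {t_sec} s outside velocity series span")
        t_sec = min(max(t_sec, self._t_sec[0]), self._t_sec[-1])
        k = int(np.searchsorted(self._t_sec, t_sec, side="right") - 1)
        k = min(k, self._t_sec.size - 2) if self._t_sec.size > 1 else 0
        if self._t_sec.size == 1:
            w_t = 0.0
        else:
            w_t = (t_sec - self._t_sec[k]) / (self._t_sec[k + 1] - self._t_sec[k])
        u0, v0 = self._bilinear(self.vel.values[k], self.vel.values_v[k], lon, lat)
        if w_t == 0.0:
            return u0, v0
        u1, v1 = self._bilinear(self.vel.values[k + 1], self.vel.values_v[k + 1], lon, lat)
        return (1 - w_t) * u0 + w_t * u1, (1 - w_t) * v0 + w_t * v1

    def _bilinear(self, U: np.ndarray, V: np.ndarray, lon, lat):
        lon = np.atleast_1d(np.asarray(lon, dtype=float))
        lat = np.atleast_1d(np.asarray(lat, dtype=float))
        nlat, nlon = self.grid.shape
        fi = (lat - self._lat0) / self._dd
        fj = (lon - self._lon0) / self._dd
        finite = np.isfinite(fi) & np.isfinite(fj)
        fi = np.where(finite, fi, 0.0)
        fj = np.where(finite, fj, 0.0)
        inb = finite & (fi >= 0) & (fi <= nlat - 1) & (fj >= 0) & (fj <= nlon - 1)
        i0 = np.clip(np.floor(fi).astype(int), 0, nlat - 2)
        j0 = np.clip(np.floor(fj).astype(int), 0, nlon - 2)
        di = np.clip(fi - i0, 0.0, 1.0)
        dj = np.clip(fj - j0, 0.0, 1.0)
        u_out = np.full(lon.shape, np.nan)
        v_out = np.full(lon.shape, np.nan)
        wsum = np.zeros(lon.shape)
        usum = np.zeros(lon.shape)
        vsum = np.zeros(lon.shape)
        for oi, oj, w in (
            (0, 0, (1 - di) * (1 - dj)),
            (0, 1, (1 - di) * dj),
            (1, 0, di * (1 - dj)),
            (1, 1, di * dj),
        ):
            uu = U[i0 + oi, j0 + oj]
            vv = V[i0 + oi, j0 + oj]
            ok = np.isfinite(uu) & np.isfinite(vv)
            w_ok = np.where(ok, w, 0.0)
            wsum += w_ok
            usum += np.where(ok, uu, 0.0) * w_ok
            vsum += np.where(ok, vv, 0.0) * w_ok
        good = inb & (wsum > 1e-12)
        u_out[good] = usum[good] / wsum[good]
        v_out[good] = vsum[good] / wsum[good]
        return u_out, v_out


def sample_velocity(vel: FieldSeries, lon, lat, t: np.datetime64) -> tuple[np.ndarray, np.ndarray]:
    """One-shot masked bilinear/time-linear velocity sample (m/s)."""
    s = VelocitySampler(vel)
    u, v = s.sample_sec(np.atleast_1d(lon), np.atleast_1d(lat), s.seconds_since_start(t))
    if np.isscalar(lon) or np.ndim(lon) == 0:
        return float(u[0]), float(v[0])
    return u, v


def _wrap_lon(lon: np.ndarray) -> np.ndarray:
    return (lon + 180.0) % 360.0 - 180.0


def rk4_step(lon, lat, sampler: VelocitySampler, t_sec: float, dt: float = 10800.0):
    """One classical RK4 step on the sphere.

    Returns (lon, lat, ok) where ok=False marks particles for which any
    stage velocity was unavailable (their position is returned frozen).
    """
    lon = np.atleast_1d(np.asarray(lon, dtype=float))
    lat = np.atleast_1d(np.asarray(lat, dtype=float))

    def deriv(lo, la, ts):
        u, v = sampler.sample_sec(lo, la, ts)
        cosphi = np.cos(np.deg2rad(la))
        dlon = np.rad2deg(u / (EARTH_RADIUS_M * cosphi))
        dlat = np.rad2deg(v / EARTH_RADIUS_M)
        return dlon, dlat  # deg per second

    k1x, k1y = deriv(lon, lat, t_sec)
    k2x, k2y = deriv(lon + 0.5 * dt * k1x, lat + 0.5 * dt * k1y, t_sec + 0.5 * dt)
    k3x, k3y = deriv(lon + 0.5 * dt * k2x, lat + 0.5 * dt * k2y, t_sec + 0.5 * dt)
    k4x, k4y = deriv(lon + dt * k3x, lat + dt * k3y, t_sec + dt)
    new_lon = lon + dt / 6.0 * (k1x + 2 * k2x + 2 * k3x + k4x)
    new_lat = lat + dt / 6.0 * (k1y + 2 * k2y + 2 * k3y + k4y)
    ok = np.isfinite(new_lon) & np.isfinite(new_lat)
    new_lon = np.where(ok, _wrap_lon(new_lon), lon)
    new_lat = np.where(ok, new_lat, lat)
    return new_lon, new_lat, ok


def advect_ensemble(
    seeds: ParticleEnsemble,
    vel: FieldSeries,
    t0: np.datetime64,
    t1: np.datetime64,
    dt: float = 10800.0,
    output_cadence_days: int = 1,
) -> TrajectorySet:
    """Advect an ensemble from t0 to t1 with RK4 at step ``dt`` seconds.

    Snapshots are recorded every ``output_cadence_days`` days including
    both endpoints.  Beached and out-of-domain particles stay frozen;
    particles are never dropped.
    """
    t0 = np.datetime64(t0, "ns")
    t1 = np.datetime64(t1, "ns")
    if t0 >= t1:
        raise ValueError("t0 must precede t1")
    sampler = VelocitySampler(vel)
    s0 = sampler.seconds_since_start(t0)
    s1 = sampler.seconds_since_start(t1)
    lo_sp, hi_sp = sampler.t_span_sec
    if s0 < lo_sp - 1e-6 or s1 > hi_sp + 1e-6:
        raise ValueError("velocity series does not span the advection window")

    lon = seeds.lon.copy()
    lat = seeds.lat.copy()
    status = seeds.status.copy()
    glon = vel.grid.lon_centers
    glat = vel.grid.lat_centers

    # seeds starting where velocity is unavailable beach immediately
    u, v = sampler.sample_sec(lon, lat, s0)
    start_bad = ~(np.isfinite(u) & np.isfinite(v)) & (status == ACTIVE)
    status[start_bad] = BEACHED

    snapshots = [ParticleEnsemble(seeds.ids.copy(), lon.copy(), lat.copy(), t0, status.copy())]
    cadence_sec = output_cadence_days * 86400.0
    next_out = s0 + cadence_sec

    t_sec = s0
    while t_sec < s1 - 1e-6:
        step = min(dt, s1 - t_sec)
        act = status == ACTIVE
        if act.any():
            nl, nb, ok = rk4_step(lon[act], lat[act], sampler, t_sec, step)
            lon[act], lat[act] = nl, nb
            idx = np.nonzero(act)[0]
            # an unavailable stage velocity near the grid rim means the
            # particle left the domain; elsewhere it ran aground
            half = vel.grid.spacing_deg
            near_rim = ((lon[act] < glon[0] + half) | (lon[act] > glon[-1] - half)
                        | (lat[act] < glat[0] + half) | (lat[act] > glat[-1] - half))
            status[idx[~ok & near_rim]] = OUT_OF_DOMAIN
            status[idx[~ok & ~near_rim]] = BEACHED
            oob = (lon[act] < glon[0]) | (lon[act] > glon[-1]) | (lat[act] < glat[0]) | (lat[act] > glat[-1])
            status[idx[oob]] = OUT_OF_DOMAIN
        t_sec += step
        if t_sec >= next_out - 1e-6 or t_sec >= s1 - 1e-6:
            snap_t = t0 + np.timedelta64(int(round((t_sec - s0) * 1e9)), "ns")
            snapshots.append(ParticleEnsemble(seeds.ids.copy(), lon.copy(), lat.copy(), snap_t, status.copy()))
            next_out += cadence_sec

    return TrajectorySet(snapshots=snapshots, provenance={"t0": str(t0), "t1": str(t1), "dt_sec": dt})


def perturb_velocity(vel: FieldSeries, sigma: float, seed: int) -> FieldSeries:
    """Add zero-mean Gaussian noise (std ``sigma`` m/s) independently per
    component, cell and time step.  Deterministic under a fixed seed."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    out = vel.copy()
    if sigma == 0:
        return out
    rng = np.random.default_rng(seed)
    out.values = out.values + rng.normal(0.0, sigma, out.values.shape)
    out.values_v = out.values_v + rng.normal(0.0, sigma, out.values_v.shape)
    # keep land/missing cells missing
    out.values[~np.isfinite(vel.values)] = np.nan
    out.values_v[~np.isfinite(vel.values_v)] = np.nan
    return out
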