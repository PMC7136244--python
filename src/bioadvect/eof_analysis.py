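"""EOF decomposition of deseasonalized anomaly stacks, linear trends,
trend maps with a coverage threshold, and Pearson correlation tests.

The decomposition is the standard SVD of the (time x cell) anomaly
matrix over complete-case cells, with optional sqrt(cos(lat)) area
weighting.  Principal-component signs are fixed so that each PC has a
non-negative covariance with a linear time ramp, which makes the modes
reproducible run to run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .geofields import FieldSeries, GeoGrid


class UndefinedCorrelationError(ValueError):
    """Pearson correlation requested on a zero-variance series."""


@dataclass
class EOFResult:
    grid: GeoGrid
    times: np.ndarray
    modes: np.ndarray  # (n_modes, n_lat, n_lon); NaN outside retained cells
    pcs: np.ndarray  # (n_modes, n_times)
    explained_frac: np.ndarray  # (n_modes,), fractions of total variance
    retained_cells: np.ndarray  # bool (n_lat, n_lon)
    singular_values: np.ndarray
    area_weighted: bool

    @property
    def n_modes(self) -> int:
        return int(self.pcs.shape[0])

    def mode_vectors(self) -> np.ndarray:
        """Modes flattened to (n_modes, n_retained) over retained cells."""
        return self.modes[:, self.retained_cells]

    def reconstruct(self, n_modes: int | None = None) -> np.ndarray:
        """Anomaly matrix (n_times, n_retained) rebuilt from leading modes."""
        k = self.n_modes if n_modes is None else n_modes
        return self.pcs[:k].T @ self.mode_vectors()[:k]


@dataclass
class TrendResult:
    """OLS trend: slope per year, with a two-sided t-test on N-2 df."""

    slope: float
    intercept: float
    r: float
    p: float
    n: int
    stderr: float


def eof_decompose(anoms: FieldSeries, n_modes: int | None = None, area_weight: bool = True) -> EOFResult:
    """EOF analysis of an anomaly series.

    Cells must be valid at every time step to be retained (complete-case);
    area weighting multiplies each cell column by sqrt(cos(lat)) before
    the SVD and divides the stored spatial modes by the same factor so
    the reconstruction is in physical units.
    """
    vals = anoms.values
    nt = vals.shape[0]
    retained = np.isfinite(vals).all(axis=0) & anoms.grid.ocean_mask
    ncell = int(retained.sum())
    if nt < 3 or ncell < 3:
        raise ValueError(f"EOF needs >= 3 time steps and >= 3 retained cells, got {nt} x {ncell}")
    X = vals[:, retained]  # (nt, ncell)
    X = X - X.mean(axis=0, keepdims=True)
    lat2d = np.broadcast_to(anoms.grid.lat_centers[:, None], anoms.grid.shape)
    w = np.sqrt(np.cos(np.deg2rad(lat2d[retained]))) if area_weight else np.ones(ncell)
    U, s, Vt = np.linalg.svd(X * w, full_matrices=False)
    k_full = s.size
    k = k_full if n_modes is None else min(n_modes, k_full)

    total_var = float(np.sum(s**2))
    explained = s[:k] ** 2 / total_var if total_var > 0 else np.zeros(k)

    pcs = (U[:, :k] * s[:k]).T  # (k, nt)
    spatial = Vt[:k] / w  # unit-norm in weighted space; physical units after /w

    # deterministic sign: PC covaries non-negatively with time
    ramp = np.arange(nt) - (nt - 1) / 2.0
    for i in range(k):
        c = float(pcs[i] @ ramp)
        if c < 0 or (c == 0 and pcs[i][np.argmax(np.abs(pcs[i]))] < 0):
            pcs[i] *= -1.0
            spatial[i] *= -1.0

    modes = np.full((k,) + anoms.grid.shape, np.nan)
    modes[:, retained] = spatial
    return EOFResult(
        grid=anoms.grid,
        times=anoms.times.copy(),
        modes=modes,
        pcs=pcs,
        explained_frac=explained,
        retained_cells=retained,
        singular_values=s[:k],
        area_weighted=area_weight,
    )


def mode_sum_series(eof: EOFResult, mode_ids: list[int], normalize: bool = False) -> np.ndarray:
    """Sum of the selected PCs (1-based mode indices).

    With ``normalize`` each PC is divided by its standard deviation
    before summing ("normalized units").
    """
    for m in mode_ids:
        if not 1 <= m <= eof.n_modes:
            raise IndexError(f"mode id {m} outside 1..{eof.n_modes}")
    out = np.zeros(eof.pcs.shape[1])
    for m in mode_ids:
        pc = eof.pcs[m - 1]
        out = out + (pc / pc.std(ddof=0) if normalize else pc)
    return out


def mode_sum_pattern(eof: EOFResult, mode_ids: list[int]) -> np.ndarray:
    """Spatial pattern paired with :func:`mode_sum_series`."""
    for m in mode_ids:
        if not 1 <= m <= eof.n_modes:
            raise IndexError(f"mode id {m} outside 1..{eof.n_modes}")
    out = np.zeros(eof.grid.shape)
    out[~eof.retained_cells] = np.nan
    for m in mode_ids:
        out[eof.retained_cells] += eof.modes[m - 1][eof.retained_cells]
    return out


def linear_trend(y: np.ndarray, t_years: np.ndarray) -> TrendResult:
    """OLS linear trend of y against time in (fractional) years.

    Missing pairs are dropped; the p-value is a two-sided t-test with
    N-2 degrees of freedom.
    """
    y = np.asarray(y, dtype=float)
    t = np.asarray(t_years, dtype=float)
    ok = np.isfinite(y) & np.isfinite(t)
    y, t = y[ok], t[ok]
    n = y.size
    if n < 3:
        raise ValueError("linear_trend needs >= 3 valid points")
    if np.ptp(t) == 0:
        raise ValueError("zero time variance")
    res = stats.linregress(t, y)
    return TrendResult(slope=float(res.slope), intercept=float(res.intercept),
                       r=float(res.rvalue), p=float(res.pvalue), n=n,
                       stderr=float(res.stderr))


def pearson_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r with a two-sided t-test on N-2 df.

    Pairs with a missing member are deleted first.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("pearson_test needs >= 3 valid pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("zero variance in x or y")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def times_to_years(times: np.ndarray) -> np.ndarray:
    """Decimal years (365.25-day year) for a datetime64 axis."""
    t = np.asarray(times, dtype="datetime64[ns]").astype("int64")
    days = (t - t[0]) / 86400e9
    year0 = pd.Timestamp(times[0]).year + (pd.Timestamp(times[0]).dayofyear - 1) / 365.25
    return year0 + days / 365.25


def velocity_trend_map(speed: FieldSeries, coverage_thresh: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell linear trend of a (monthly) speed series.

    Returns (slopes in units/yr, validity mask).  Cells whose valid
    fraction of time steps is not strictly above ``coverage_thresh``
    are flagged invalid (missing slope).
    """
    t_years = times_to_years(speed.times)
    nt = speed.n_times
    slopes = np.full(speed.grid.shape, np.nan)
    valid = np.zeros(speed.grid.shape, dtype=bool)
    frac = np.isfinite(speed.values).sum(axis=0) / nt
    for i, j in zip(*np.nonzero(frac > coverage_thresh)):
        y = speed.values[:, i, j]
        ok = np.isfinite(y)
        if ok.sum() < 3 or np.ptp(t_years[ok]) == 0:
            continue
        slopes[i, j] = linear_trend(y, t_years).slope
        valid[i, j] = True
    return slopes, valid
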