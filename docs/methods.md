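# Methods

## The question and the design

A planktonic population can shift poleward for two distinct reasons: the
currents that advect its cells can strengthen, or the thermal limit that
bounds its overwintering (inoculum) region can retreat poleward, letting
the seed population start closer to the pole. The package separates the
two with a factorial Lagrangian design. Virtual particles stand in for
the inoculum; they carry no biology (no growth, mortality or behaviour)
— the experiment is purely kinematic, which is exactly what makes the
attribution clean.

Three simulations are run per year over a fixed growing-season window
(March 1 → September 1):

| experiment | inoculum (March SST field) | currents |
|---|---|---|
| EXP1 | that year's | that year's |
| EXP2 | climatology (same patch every year) | that year's |
| EXP3 | that year's | day-of-year climatology |

The inoculum is every ocean cell with March SST ≥ 4 °C (inclusive) lying
strictly within 180 km of the coast. 4 °C is the lower limit for
sustained *E. huxleyi* growth; the coastal cut keeps the patch in the
near-shore current system. The per-year leading edge is the 95th
percentile (sorted linear-interpolation convention) of particle
longitudes and latitudes east of 40 °E, converted to a great-circle
distance from a fixed anchor. Expansion over a period is the OLS slope
of that distance against year times the period span; the driver shares
are EXP2's and EXP3's expansions as percentages of EXP1's.

## Geodesy and fields

All geometry is spherical with R = 6371 km; a 0.25° cell at 70 °N then
spans 27.8 km of latitude by 9.5 km of longitude, matching the
resolution of the altimetry product the pipeline emulates. Distance to
coast is measured cell-center to cell-center of the rasterized land
mask — adequate for a 180-km threshold, and the only coastline the
gridded products define. Geostrophic velocities derive from absolute
dynamic topography with centered differences (one-sided at edges); a
stencil touching a missing cell yields a missing gradient. The
quality-control rule drops pixels whose error estimate exceeds 50 % of
the signal variance or whose sea-ice concentration exceeds 15 %; both
comparisons are strict, so a pixel exactly at a threshold is retained.
Monthly composites are plain calendar-month means of valid days;
deseasonalization subtracts each calendar month's multi-year mean map,
so the per-cell, per-month mean of the output over the climatology
period is zero to rounding.

## EOF conventions

The decomposition is the SVD of the (time × cell) anomaly matrix over
complete-case cells — a cell must be valid at every time step, which
keeps the algebra exact at the cost of discarding gappy cells (the
ice-masked northern band, in practice). √cos(φ) column weighting is on
by default (standard for lat-lon grids) and exposed as a flag; stored
spatial modes are de-weighted back to physical units, so orthogonality
holds in the weighted inner product (exactly, in the plain inner
product, when weighting is off). PC signs are fixed by requiring
non-negative covariance with a linear time ramp — an arbitrary but
deterministic convention without which mode signs depend on LAPACK
internals. Trends are ordinary least squares with two-sided t-tests on
N−2 degrees of freedom, the same test used for Pearson correlations; no
multiple-testing correction is applied. Velocity trend maps only keep
cells with strictly more than 50 % valid time steps.

## Integration

Particles integrate dλ/dt = u/(R cos φ), dφ/dt = v/R with classical RK4
at a 3-h step (configurable). Velocities are sampled bilinearly from
the four surrounding cells with land/missing neighbours given zero
weight and the remaining weights renormalized, and linearly in time
between the two bracketing daily fields — the linear-in-time choice
keeps the field smooth enough for the integrator to exhibit its nominal
order (observed ≈ 3.9 on a rigid-rotation orbit with an exact analytic
solution). A particle whose interpolated velocity becomes unavailable
at any RK4 stage is frozen for the rest of the run: "beached" if it
happens in the interior, "out of domain" near the grid rim. No
re-floating, no diffusion term, no windage. Freezing rather than
deleting keeps the particle count constant, which the trajectory
container enforces.

## The synthetic world

The generator emulates the *structure* of the satellite inputs, not
Barents Sea statistics. Its reference configuration, used by the test
suite and the acceptance study, is desk-scale: a 0.5° grid over
58–78 °N × 30–60 °E, 10 years (1998–2007), with

- a straight diagonal coastline rising from 60 °N (west) to 69 °N
  (east), land to the south — a caricature of the Norwegian/Barents
  coast;
- an along-coast jet offset 1° poleward of the coast, Gaussian
  cross-section (σ = 120 km), core speed 0.055 m/s, a winter-peaked
  seasonal cycle (±20 %, maximum in mid-January), and an optional core
  speed trend (+2 %/yr in "currents" worlds);
- SST with a 0.5 °C/°lat meridional gradient whose March 4 °C isotherm
  sits at 62 °N initially and migrates poleward at a prescribed rate
  (15 km/yr in "temperature" worlds), plus a seasonal cycle phased to
  vanish in mid-March so the March composite recovers the isotherm
  exactly;
- summer PIC blooms placed either downstream of the jet or on supplied
  final particle positions;
- monthly SLA built from two orthonormalized spatial patterns (a
  cross-jet dipole and a broad zonal mode) times prescribed principal
  components, PC1 carrying a linear trend, with seasonal ice and
  error-percentage companions masking the northern band;
- independent Gaussian velocity noise of 0.05 m/s per component, cell
  and day — inside the 7–15 cm/s RMS uncertainty documented for the
  altimetry-derived currents — and 0.1 °C SST noise.

All seasonal phases use a fixed 365-day calendar (Feb 29 folded onto
Feb 28) so that a given month-day has the same phase every year; this
makes "stationary" worlds exactly stationary, which several invariant
tests rely on. Everything is deterministic under the scenario seed.

The jet is a kinematic construction, not a balanced flow: the SLA
patterns and the velocity field are linked only qualitatively (the
dipole straddles the jet), and no test requires dynamical consistency
between them. What passing the recovery tests shows is that the
*pipeline* attributes correctly when the truth is known and additive; it
does not certify the satellite-era attribution itself, which depends on
the real 1993–2016 archives and is out of reach at desk scale.

Speeds and rates were chosen once so that (i) essentially all particles
enter the eastern analysis region (lon > 40 °E) every year — otherwise
the percentile is taken over a subset whose composition drifts with the
drivers and the attribution is contaminated — and (ii) the fastest
particles stay inside the domain in the strongest year, avoiding
saturation at the boundary.

## Numerical and design choices

- **Percentile convention**: sorted linear interpolation, fixed and
  tested, because at n ≲ 100 particles different conventions move the
  edge by visible amounts.
- **Edge-distance anchor**: the centroid of the climatological inoculum
  patch, so distance grows along the advection path; any fixed point
  works, and the attribution is scale-free in the anchor choice.
- **Seeding density**: 2×2 particles per qualifying cell in the
  pipeline default (`RunConfig.seeds_per_cell = 2`; the primitive
  `select_inoculum` defaults to cell centers). At 0.5° the inoculum
  holds only a few dozen cells, and a 95th percentile over ~40 particles
  under 0.05 m/s velocity noise is a noisy estimator of the edge; 4×
  particles halves that estimator noise without changing what is
  measured.
- **Coast cut**: the strict form (< 180 km) is implemented, with the
  comparison operator configurable.
- **Climatological currents (EXP3)**: per-component, per-cell,
  per-day-of-year mean over the climatology period, which under a linear
  interannual trend equals the mid-period field — hence EXP3's edge
  trend vanishes in a currents-only world.
- **Constructed shares**: the combined world's expected attribution is
  computed from noise-free single-driver runs of EXP1 (the deterministic
  construction), against which the noisy combined-world recovery is
  compared.
- **Degenerate inputs**: zonal arcs at the poles, equator-crossing
  geostrophy, empty inocula, zero-variance correlations and
  zero-expansion attributions all raise typed errors; an empty edge
  subset yields a missing-year marker instead, since a bloom-free year
  is data, not a bug.

## Problem sizes

The test suite runs the factorial study at the reference scale (three
noisy worlds, 10 years × 3 experiments each, ~150–250 particles, 3-h
steps) plus two noise-free single-driver runs; the acceptance script
repeats the same study. Unit tests use 3–5-year worlds and a 6-h step
where only structural behaviour is asserted.

## Known limitations

- Particles are passive: no growth, mortality, grazing or vertical
  behaviour, so "inoculum" is purely positional.
- No diffusion/sub-grid dispersion beyond the explicit noise runs.
- The land mask is rasterized; distance-to-coast inherits cell
  granularity (~28 km meridionally at 0.5°).
- Complete-case EOF discards cells that are ever masked; a gappier
  real-data mask would shrink the retained domain quickly.
- The NetCDF layer targets the classic (NETCDF3) format; files from
  providers using NETCDF4-only features would need conversion first.
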