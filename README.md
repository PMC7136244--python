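# bioadvect

Bio-advection analysis of poleward species range expansion: who moves the
leading edge of a bloom-forming phytoplankton into the Arctic — the ocean
currents that carry the cells, or the warming winter water that lets the
seed population start further north?

`bioadvect` implements the full analysis chain used to answer that
question for the coccolithophore *Emiliania huxleyi* in the European
Arctic Corridor:

- **Geophysical fields** — regular lat-lon grids with land/ice/error
  masks, spherical geodesy (R = 6371 km), geostrophic velocities from
  absolute dynamic topography (u = −(g/f) ∂η/∂y, v = (g/f) ∂η/∂x),
  monthly compositing and deseasonalization.
- **EOF analysis** — SVD of the deseasonalized sea-level-anomaly stack
  over complete-case cells with optional √cos(φ) area weighting;
  mode-sum time series; OLS trends and Pearson correlations with
  two-sided t-tests on N−2 degrees of freedom; velocity trend maps with
  a >50% coverage rule.
- **Lagrangian advection** — classical 4th-order Runge–Kutta on the
  sphere (dλ/dt = u/(R cos φ), dφ/dt = v/R) with a 3-h step, masked
  bilinear interpolation in space and linear interpolation in time
  between daily velocity fields, beaching/domain-exit bookkeeping, and
  Gaussian velocity-noise perturbation runs.
- **Factorial experiments** — virtual inoculum particles seeded on
  March 1 wherever March SST ≥ 4 °C within 180 km of the coast, advected
  to September 1. EXP1 varies both temperature and currents, EXP2 fixes
  the inoculum to its climatology (currents signal only), EXP3 advects on
  climatological currents (temperature signal only).
- **Leading-edge metrics** — the range edge as the 95th percentile of
  particle (or bloom-pixel) longitudes and latitudes east of 40 °E,
  edge-distance trends, expansion over a period (slope × span), particle
  vs bloom matchup fractions within 50 km, and the attribution
  percentages `EXP2/EXP1 × 100` (currents) and `EXP3/EXP1 × 100`
  (temperature).
- **Synthetic data** — a deterministic, seeded generator for all the
  gridded inputs (daily jet velocities with an imposed multi-year speed
  trend, SST with a migrating March 4 °C isotherm, summer PIC blooms,
  monthly SLA with imposed principal components and ice/error masks), so
  the entire pipeline runs and is testable without any satellite
  download.

The top-level interface follows the Model/Results convention:
`AttributionModel` is built from per-experiment leading-edge series (or
straight from a synthetic world via `from_scenario`), and `fit()`
returns an `AttributionResults` with the trend diagnostics, the driver
shares and a `summary()` table.

## Worked example

Run the three factorial experiments on the reference synthetic world in
which both drivers are active (+2 %/yr jet acceleration and 15 km/yr
poleward isotherm migration over 10 years):

```python
from bioadvect import ScenarioSpec, AttributionModel

spec = ScenarioSpec(seed=1).combined()
res = AttributionModel.from_scenario(spec).fit()
print(res.summary())
```

```
Leading-edge driver attribution
================================================================
period: 1998-2007   edge percentile: 95

experiment  slope_km_per_yr  stderr_km_per_yr          r          p  n_years  expansion_km
      EXP1            36.16             3.191     0.9702  3.316e-06       10         325.4
      EXP2            13.15             3.389      0.808   0.004678       10         118.3
      EXP3            23.56             2.343     0.9627  8.123e-06       10         212.1

currents share    (EXP2/EXP1):   36.4 %
temperature share (EXP3/EXP1):   65.2 %
```

Reading: the full-variability experiment (EXP1) shows the leading edge
advancing 36 km/yr, i.e. 325 km over the decade. Holding the inoculum
fixed (EXP2) isolates the current contribution (118 km, 36 %); holding
the currents at climatology (EXP3) isolates the winter-temperature
contribution (212 km, 65 %). The shares add to ~100 %, as expected when
the two drivers act additively. Run on worlds built with
`.currents_only()` or `.temperature_only()`, the matching experiment
recovers ~100 % and the other ~0 %.

The same pipeline is scriptable from the shell:

```bash
bioadvect generate --seed 1 --world combined --out run/
bioadvect experiments --seed 1 --world combined --out run/
bioadvect eof --sla run/sla_monthly.nc --out run/
```

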