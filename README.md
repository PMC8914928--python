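# spatialaq

Spatial analysis of outdoor-sensor networks: pick the aggregation scale
that best expresses the spatial structure of the data, then interpolate
and map the field with kriging, on the Air Quality Index (AQI) scale.

Point sensors (air-quality monitors being the motivating case) are sparse
and unevenly placed, so any areal summary depends on the size of the areal
units — the modifiable areal unit problem (MAUP). `spatialaq` treats scale
selection as a two-objective optimization. For each candidate hexagon side
length *s* it aggregates the sensors into a regular hexagonal tessellation
and computes:

* **GM** — global Moran's *I* of the cell values (to maximize),

  *I* = *n*/Σᵢⱼ*wᵢⱼ* · Σᵢⱼ *wᵢⱼ*(yᵢ−ȳ)(yⱼ−ȳ) / Σᵢ(yᵢ−ȳ)²,

  with first-order contiguity weights *wᵢⱼ* (row-standardized by default);
* **LMCV** — the coefficient of variation sd/|mean| of the local Moran
  values *Iᵢ* = (yᵢ−ȳ)·Σⱼ*wᵢⱼ*(yⱼ−ȳ)/(Σ(y−ȳ)²/n) (to minimize),
  a measure of structural instability across the map.

The candidate scales are ranked by iterative non-dominated (Pareto)
sorting on (GM, LMCV); the rank-1 set is the recommended granularity.
Significance for both indices comes from conditional permutation
(pseudo-significance) tests.

For visualization and prediction the package implements the geostatistical
workflow: normalize the values (best-of-family invertible transform),
estimate the empirical (Matheron) variogram, fit an exponential/spherical/
Gaussian model γ(h) = c₀ + c·(1 − e^(−h/a)), and solve the ordinary-kriging
system Ẑ(s₀) = Σᵢ λᵢZ(sᵢ) with Σλᵢ = 1 on a prediction grid. Indicator
kriging of 1{z > t} yields exceedance-probability maps (e.g. P[AQI > 50],
the Good/Moderate boundary). A seeded Gaussian-random-field generator
supplies study data with known range/sill/nugget so the whole pipeline is
testable offline.

## Worked example

```sh
spatialaq simulate --n-points 300 --range 200 --sill 100 --nugget 2 \
    --mean 55 --seed 1 --out sensors.csv
spatialaq granularity --points sensors.csv --scales 100,200,300,400,500 --outdir .
```

```
Pareto-optimal scale(s) [km]: 100.0
```

`granularity_candidates.csv`:

```
scale,GM,LMCV,n_cells,frontier_rank
100.0,0.5738465384641926,1.3747262812093854,46,1
200.0,0.24364676351623898,2.9545557636520665,14,2
300.0,0.2277461542949716,2.043049580113607,8,2
400.0,0.004962838644749059,39.87742093056095,6,3
500.0,-0.21938037529171275,1.8397193728978531,4,2
```

The 100 km units show the strongest global autocorrelation (GM 0.57) *and*
the most stable local structure (LMCV 1.37), so they dominate every other
scale and sit alone on the first frontier; 400 km is essentially
uncorrelated noise (GM ≈ 0) with wildly unstable local values.

Interpolation and exceedance mapping on the same data:

```sh
spatialaq krige --points sensors.csv --resolution 100 --threshold 50 --outdir .
```

writes `kriging.csv` (x, y, estimate, variance), `exceedance.csv`
(P[value > 50] per grid node, all within [0, 1]) and `variogram.json`:

```json
{"model": "exponential", "nugget": 0.048, "partial_sill": 1.355,
 "range": 324.7, "normalize_transform": "ordered-quantile"}
```

(the variogram is fitted on the normalized scale, hence the unit sill).
AQI spot checks:

```sh
$ spatialaq aqi --pollutant O3 --concentration 0.072
O3 0.072 ppm -> AQI 105 (Unhealthy for Sensitive Groups, Orange)
```

The same functionality is available as a library — `simulate_field`,
`evaluate_scales`, `krige_field`, `indicator_kriging`, `compute_aqi` and
friends under `import spatialaq`. Real monitor data in the standard
28-field daily CSV layout is read with `spatialaq.read_epa_daily`, which
joins a site-coordinates sidecar table and reports exact row accounting.

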