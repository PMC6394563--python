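# pcamars

Spatial interpolation of urban NO₂ for exposure assessment, when the
monitoring network is far too sparse for distance-based methods alone.
`pcamars` fuses the station measurements with fourteen GIS-engineered
covariate rasters — IDW-interpolated meteorology, kernel-density surfaces
of roads, population and points of interest with Moran's-I-selected search
radii, elevation and focal-mean elevation, and the grid coordinates —
reduces them to three principal components, and fits a multivariate
adaptive regression splines (MARS) model

    f̂(x) = c₀ + Σᵢ cᵢ Bᵢ(x),   Bᵢ(x) = Π max(0, ±(x_v − t)),

by greedy forward knot search (minimizing SSE) and backward pruning to the
lowest generalized cross-validation score

    GCV = (SSE/n) / (1 − (m + d(m−1)/2)/n)².

Evaluating f̂ at every pixel's component scores yields a full-resolution
concentration map. The package also implements the reference interpolators
the approach is judged against — IDW with LOOCV-selected power, ordinary
kriging with a fitted spherical semivariogram, and MARS3 (MARS on
longitude, latitude and elevation only) — plus a leave-one-out
cross-validation harness scored by RMSE = [n⁻¹ Σ (yᵢ − ŷᵢ)²]^½, and a
synthetic-city generator so every stage is testable without external data.
It is aimed at exposure-mapping and land-use-regression practitioners in
air-pollution epidemiology.

## Worked example

```python
import pcamars as pm

scene = pm.generate_scene(pm.SceneConfig(seed=0))   # synthetic city, 21 stations
result = pm.run_pcamars(scene.inputs)
print(result.provenance["radii"])
print(result.provenance["pca_explained_ratio"])

table, _ = pm.run_crossval(scene.inputs)            # LOOCV comparison
print(table.to_string(index=False))
```

prints (numbers from this exact seed):

```
{'gas': 7500.0, 'petrol': 1000.0, 'green': 7000.0, 'sport': 7500.0,
 'population': 1500.0, 'roads': 500.0, 'avg_elevation': 7500.0}
[0.446, 0.228, 0.115]
 method      rmse
     ok 13.364907
pcamars 14.352894
    idw 14.751590
  mars3 25.074977
```

The first dict is the kernel-density / focal search radius (metres) chosen
for each covariate by maximizing |bivariate Moran's I| against the station
NO₂ values; the list is the fraction of covariate variance carried by the
three retained principal components (~79 %); the table is the leave-one-out
RMSE (µg/m³) of each interpolator on this scene — lower is better, and each
LOOCV fold refits the full pipeline (radius selection included) on the
remaining 20 stations. Across 20 scene seeds the median ordering puts
PCAMARS ahead of both IDW and MARS3 (see `tests/test_acceptance.py`).

The same pipeline is scriptable from the shell:

```
pcamars simulate --seed 0 --out scene/
pcamars fit scene/ --out fit/          # writes no2_map.asc, mars_model.json, pca.json
pcamars crossval scene/ --out cv.csv
```

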