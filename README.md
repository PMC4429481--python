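# rangeselect

Which home-range estimator should you trust for *your* telemetry dataset?

Modern GPS collars produce thousands of autocorrelated relocations per
animal, while legacy VHF tracking yields ~100 sparse, noisier fixes per
year — and the classical home-range estimators were built for the latter.
`rangeselect` implements eight estimators of the utilization distribution
(UD) spanning three methodological generations, and an area-under-the-curve
(AUC) goodness-of-fit framework for choosing among them on a per-dataset
basis, for movement ecologists comparing estimators across animals and
tracking technologies.

**Estimators** (all rasterized to one shared reference grid per animal,
default 100 × 100 m):

| tag | estimator | family |
|-----|-----------|--------|
| `locoh` | k-nearest-neighbour local convex hull | hull |
| `slca` | single-linkage cluster analysis | hull |
| `char` | characteristic hull (Delaunay) | hull |
| `lkde` | fixed KDE, reference bandwidth h_ref | kernel |
| `pkde` | fixed KDE, bivariate plug-in bandwidth matrix | kernel |
| `mkde` | movement-based KDE (biased random bridges) | bridge |
| `bbmm` | Brownian bridge movement model | bridge |
| `dbbmm` | dynamic BBMM (windowed motion variance) | bridge |

plus MCP (`mcp`, the common limit of the hull family) and least-squares
cross-validation (`lscv`, which *declares failure* on duplicate-heavy GPS
data instead of returning a degenerate bandwidth).

**The selection statistic.**  On the shared grid, each cell is scored by
the estimator and marked present/absent by whether it contains a
relocation.  The fit of the estimator's isopleths to the relocations is the
tie-corrected rank-sum AUC

    AUC = (#{presence cell outranks absence cell} + ½·ties) / (n₁·n₀),

which equals the trapezoidal ROC area: 0.5 means no discrimination, 1.0
means every occupied cell outranks every empty one.  Estimators are then
compared across animals with Kruskal–Wallis and Bonferroni pairwise Welch
tests, and with linear mixed models on logit(AUC) — animal as a random
intercept — ranked by AICc over an a priori 12-model covariate set
(estimator type, fix success, GPS schedule, number-of-locations class,
study area).

**Synthetic telemetry.**  Because suitable relocation data are rarely
shareable, the package ships a seedable generator: Ornstein–Uhlenbeck
home-ranging movement (exact transitions), GPS duty cycles with 74% fix
success and 34 m error, and Monday/Wednesday/Friday aerial VHF with 124 m
error — so the full pipeline runs end-to-end with no external data.

## Worked example

Simulate three animals tracked for 120 days on a 7-hour GPS schedule with
concurrent VHF overflights, then score three estimators:

```python
import rangeselect as rs

cfg = rs.CohortConfig(days=120.0, schedule="seven")
trajs, truth = rs.make_benchmark_cohort(3, cfg, seed=7)
config = rs.EstimatorConfig(default_err_sd=34.0)
records = rs.auc_table(trajs, ("locoh", "lkde", "bbmm"), config)
df = rs.records_to_dataframe(records)
print(df.groupby(["technology", "estimator"])["auc"].mean().round(3))
```

```
technology  estimator
GPS         bbmm         0.844
            lkde         0.825
            locoh        0.832
VHF         bbmm         0.792
            lkde         0.793
            locoh        0.756
```

Two patterns the framework exists to expose are already visible: every
estimator fits the GPS data better than the sparse, noisier VHF data
(~300 vs ~35 fixes per animal here), and the Brownian bridge — which uses
the fix timestamps and location errors — leads the GPS column.  Running
`rs.run_comparison(records)` on a full eight-estimator table fits the
12-model AICc set and the group tests; `rs.extract_isopleths` turns any UD
into nested volume contours (e.g. the 50/95/100% home-range polygons).

The same pipeline is available from the shell:

```sh
rangeselect simulate --animals 10 --days 365 --schedule hourly --seed 42 --out sim/
rangeselect estimate --estimator bbmm --err-sd 34 --in sim/locations_gps.csv --out-dir ud/
rangeselect auc --locs sim/locations_gps.csv --err-sd 34 --out auc.csv
rangeselect compare --auc auc.csv --out report/
```

Rasters are written as ESRI ASCII grids, isopleths as GeoJSON, tables as
CSV.  Input coordinates must be projected planar meters; data that look
geographic are refused with guidance.

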