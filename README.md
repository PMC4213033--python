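# invasionfit

Tools for characterizing the local population dynamics of a range-expanding
(invasive) species from long-running survey count data, and for explaining
the resulting demographic parameters with environmental predictors.

The intended user is an ecologist with per-site abundance time series —
e.g. Breeding Bird Survey routes (summed stop counts) or Christmas Bird
Count circles (counts per party-hour of effort) — plus a per-site table of
land-cover, climate, and historical/geographical covariates.

## What it computes

**Per-site growth models.** For every site with at least 8 years of data,
three trajectory families are fitted to abundance N(t) (t = years since
first local observation) by Gaussian least squares on the count scale:

- exponential: N(t) = N₀ e^(rt)
- quadratic: N(t) = at² + bt + c (hump-shaped when a < 0)
- logistic: N(t) = K / (1 + e^(−r(t − t_mid)))

Families are compared with the small-sample Akaike criterion,
AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1), and the lowest-AICc family labels the
trajectory. Sites whose best fit is monotone non-increasing over the
observed window are discarded as having missed the colonization dynamics.
Carrying capacity **K** is the quadratic vertex maximum (c − b²/4a) or the
logistic asymptote; the growth rate **r** is the OLS slope of log N on
year, reported wherever the exponential model has substantial support
(ΔAICc < 2).

**Model-averaged regression.** K and r (standardized) are regressed on 11
standardized predictors — invasion distance (great-circle km from the
introduction origin), population age, seven land-cover percentages, and
two climate variables — over all 2¹¹ = 2048 main-effects OLS subsets.
Each model m gets an Akaike weight w_m = exp(−Δ_m/2)/Σ exp(−Δ_j/2);
per-variable relative importance w_i₊ sums the weights of all models
containing the variable, and coefficients are model-averaged
(conditional or zero-substituted full averaging).

**Validation.** Leave-one-out cross-validation quantifies R² shrinkage
(overfitting); Moran's I correlograms over great-circle distance bands,
with permutation envelopes, check whether the averaged model accounts for
the spatial structure in K and r.

**Synthetic invasions.** A seeded generator produces datasets with known
ground truth: colonization spreading from an origin with occasional
long-distance jumps, per-site trajectories from the four families, count
noise, party-hour effort variation, and spatially autocorrelated
covariates that drive the true K and r. Every downstream stage is tested
against this truth.

## Worked example

```python
import invasionfit as iv

cfg = iv.PipelineConfig(
    simulation=iv.SimulationConfig(n_sites=300, seed=7),
    output_dir="example_out", seed=7,
)
report = iv.run_pipeline(cfg)
print(report.counts)
```

produces (about 30 s):

```
{'sites_total': 300, 'sites_with_series': 300, 'eligible_analyzed': 155,
 'too_few_years': 129, 'discarded_decreasing': 16, 'nonconvergent': 0,
 'k_analysis_sites': 84, 'r_analysis_sites': 82}
```

Of 300 simulated sites, 155 had ≥ 8 observed years and a usable
(non-decreasing, convergent) trajectory; 84 yielded a carrying capacity
and 82 a growth rate. Inspecting the averaged models:

```
K: model-averaged R2 = 0.46
   developed_med_pct        w+ = 0.98  beta = +0.30
   population_age_yr        w+ = 0.96  beta = +0.47
   precipitation_mm         w+ = 0.94  beta = -0.26
   LOOCV: R2_fit = 0.49, R2_cv = 0.28, shrinkage = 42.1%
r: model-averaged R2 = 0.78
   forest_pct               w+ = 1.00  beta = -0.44
   invasion_distance_km     w+ = 1.00  beta = +0.47
   developed_high_pct       w+ = 0.83  beta = -0.15
   LOOCV: R2_fit = 0.78, R2_cv = 0.69, shrinkage = 11.9%
```

The generator's true drivers (K: medium-intensity developed cover +,
high-intensity developed −, precipitation −; r: invasion distance +,
forest −) surface with high importance weights and correct signs; the
coefficients are in standard-deviation units of the standardized
response. Outputs land in `example_out/`: `growth_fits.csv`,
`site_parameters.csv`, `model_table.csv`, `averaged_model.csv`,
`cv_results.csv`, `correlogram.csv`, `prediction_grid.csv`, and
`run_report.json`.

The same stages are available from the shell:

```sh
invasionfit simulate --n-sites 300 --seed 7 --out data/
invasionfit run-all --seed 7 --out example_out/
invasionfit compare-windows --series data/series.csv
```

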