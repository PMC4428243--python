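# cyanorisk

County-level ecological analysis linking satellite-derived cyanobacterial
bloom coverage to liver-disease mortality.

Cyanobacterial blooms produce hepatotoxins (microcystins and relatives), so
chronic residential exposure to bloom-affected water bodies is a candidate
environmental risk factor for non-alcoholic liver disease. `cyanorisk`
implements the full analysis chain an epidemiologist needs to test that
hypothesis at county scale, from pigment remote sensing to Bayesian disease
mapping — and ships a synthetic-data generator with known ground truth, so
every stage runs and can be validated offline with no satellite archive or
vital-statistics extract.

## The analysis chain

1. **Pigment retrieval** (`cyanorisk.retrieval`). Phycocyanin (PC), the
   pigment specific to cyanobacteria, is estimated per pixel from four
   water-leaving reflectance bands B(λ) with the nested semi-empirical
   band-ratio model:

       a_chl(665) = { (B705/B665)·(a_w(709)+b_b) − b_b − a_w(665) } / γ
       a_pc(620)  = { (B705/B620)·(a_w(709)+b_b) − b_b − a_w(620) } / δ − ε·a_chl(665)

   with γ = 0.68, δ = 0.82, ε = 0.24 and b_b the particulate backscatter
   estimated from the 779 nm band. Multi-date scenes are combined by
   maximum-value compositing.
2. **Bloom mapping** (`cyanorisk.bloom_map`). The WHO recreational guideline
   of 20,000 cells/ml converts to PC through the log-linear calibration
   log10(cells) = 0.360·log10(PC) + 4.08, giving 4.11 μg/L; 4 μg/L is used
   as the operational threshold as a precaution. County bloom coverage is
   the percentage of county area covered by bloom pixels.
3. **Mortality standardization** (`cyanorisk.mortality`). Expected county
   deaths E_i by indirect standardization over gender × age strata;
   SMR_i = O_i/E_i; county totals of 0–9 deaths are suppressed and excluded.
4. **Spatial exploration** (`cyanorisk.spatial_stats`, `cyanorisk.cluster_scan`).
   Bivariate global Moran's I and LISA (Queen contiguity, 999 conditional
   permutations) relate SMR to neighboring bloom coverage; a flexible-shaped
   spatial scan statistic finds irregular excess-mortality clusters, and a
   rank-sum test compares coverage inside vs outside clusters.
5. **Association model** (`cyanorisk.nbcar`). The core estimator is a
   Bayesian negative-binomial regression with BYM-type convolution random
   effects:

       Y_i ~ NB(μ_i, r),   Var(Y_i) = μ_i + μ_i²/r
       log μ_i = log E_i + α + X_i β + e_i + φ_i

   with e_i ~ N(0, σ_e²) and φ an intrinsic CAR effect (neighbor-average
   conditional mean, conditional variance σ_φ²/m_i, sum-to-zero constraint).
   Fitting is by Metropolis-within-Gibbs MCMC; effects are reported as risk
   ratios exp(β·Δ) with 95% credible intervals — bloom coverage enters in
   percent, so its RR is per 1% of county coverage.

## Worked example

Simulate the default synthetic study system (a 20×20 county lattice with a
true bloom-coverage log-effect of 0.003 per 1%), standardize mortality, and
fit the NB-CAR model:

```python
import numpy as np
from cyanorisk import SyntheticScenario, make_county_grid, NegativeBinomialCAR
from cyanorisk.geo_synth import make_covariates, simulate_mortality
from cyanorisk import mortality as mort

scen = SyntheticScenario(seed=1)
counties = make_county_grid(scen.grid_nx, scen.grid_ny, scen.cell_size)
rng = np.random.default_rng(scen.seed)
cov = make_covariates(counties, scen, rng=rng)
sim = simulate_mortality(counties, cov, scen, rng=rng)
smr = mort.smr_table(sim.table)

df = smr.merge(cov, on="county_id")
model = NegativeBinomialCAR.from_dataframe(
    df, counties, covariates=["coverage_pct", "education", "race"])
post = model.fit(n_burn=5000, n_iter=10000, seed=1)
print(post.risk_ratios({"coverage_pct": 1.0}).round(4))
```

prints

```
              delta      rr  rr_2.5  rr_97.5
coverage_pct    1.0  1.0032  0.9989   1.0073
education       1.0  0.9520  0.9275   0.9767
race            1.0  1.0286  1.0018   1.0567
```

The bloom-coverage row says mortality risk rises an estimated 0.32% per 1%
of county bloom coverage (95% CrI −0.11% to +0.73%), consistent with the
generative 0.3%; `post.summary()` adds posterior sds, effective sample
sizes and split-chain R-hat per parameter.

The same chain runs end to end from one YAML config:

```bash
cyanorisk run --config config.yaml        # synth → retrieve → coverage →
                                          # smr → spatial → model
```

writing per-stage CSV/GeoJSON/raster outputs and a checksummed manifest
(rerunning with the same master seed reproduces them; `--resume` rebuilds
deleted intermediates).

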