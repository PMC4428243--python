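# Methods

This note documents the models, numerical choices and limitations behind
`cyanorisk`, in the order the pipeline runs them.

## Pigment retrieval

The band-ratio model treats each water pixel as a two-pigment absorption
problem. Reflectance ratios against the 705 nm band (where neither pigment
absorbs strongly) isolate total absorption at 665 nm (chlorophyll-a) and
620 nm (phycocyanin); subtracting pure-water absorption and backscatter and
applying the correction factors γ = 0.68, δ = 0.82 and the chlorophyll
cross-term ε = 0.24 yields pigment absorptions, which divide by
pigment-specific absorption coefficients to give concentrations (μg/L,
treated as identical to mg/m³).

Constants not fixed by the calibration itself use standard published
values, all overridable through `OpticalConstants`:

| constant | default | unit | role |
|---|---|---|---|
| a_w(620), a_w(665), a_w(709) | 0.281, 0.401, 0.727 | m⁻¹ | pure-water absorption |
| b_b estimator | 1.61·B779/(0.082 − 0.6·B779) | m⁻¹ | single-band backscatter |
| PC specific absorption | 0.007 | m²·mg⁻¹ | a_pc → concentration |
| chl specific absorption | 0.0153 | m²·mg⁻¹ | a_chl → concentration |

Numerical conventions: pixels with non-physical band ratios (zero bands,
backscatter outside its valid domain 0 ≤ B779 < 0.082/0.6) are flagged, not
propagated; negative retrieved concentrations are clamped to zero and
flagged, because the downstream threshold step requires physical values.
The model is a pure ratio form: scaling all four bands at a pixel leaves
retrievals unchanged *given* b_b — estimating b_b from a scaled B779 breaks
this, which is why `retrieve_pigments` accepts an explicit b_b override.
Maximum-value compositing is idempotent, commutative and associative;
flagged pixels are excluded from the maximum unless flagged in every scene.

## Bloom threshold and coverage

The cell-abundance calibration log10(cells/ml) = 0.360·log10(PC) + 4.08
inverts at the WHO recreational guideline (20,000 cells/ml) to 4.11 μg/L;
the operational threshold is lowered to 4 μg/L as a precaution, and the
comparison is `>=` so boundary pixels count as bloom. Coverage aggregation
assigns each pixel to the county containing its center (the standard zonal-
statistics default at ~300 m pixels) and divides bloom pixel area by total
county area; a water-area denominator is available but off by default.

## Standardization and suppression

Standard rates are pooled national stratum rates (gender × 10-year age
bands) computed from the same table ("closure mode"), so ΣE_i = ΣO_i holds
as an algebraic identity; rates are cumulative over the pooled study window
(a per-year constant cancels in the SMR). Counties with 0–9 total observed
deaths are suppressed and dropped from every downstream stage, exactly as
the confidentiality rule dictates; the resulting selection against small
rural counties is a documented bias, not corrected. Suppression is applied
at the county-total level.

## Spatial statistics

Conventions are the areal-analysis defaults: Queen contiguity from polygon
geometry, row-standardized weights, standardization by the population sd.
The bivariate statistic relates the focal variable (SMR) to the spatial lag
of the other (bloom coverage); the mean of the local values equals the
global I under this normalization, which the tests assert to 1e−12.

LISA inference is by conditional permutation — the focal value stays, the
remaining n−1 values are permuted into the neighborhood — with
pseudo-p = (more-extreme + 1)/(permutations + 1). The package uses the
**two-sided** |I| comparison rather than the directional variant: the
directional pseudo-p is anti-conservative (empirical type-I error near 2α),
while the two-sided version is valid, which the acceptance suite verifies
(≤ 6% rejections at α = 0.05 over 1,000 null maps). Quadrants (High-High,
Low-Low, High-Low, Low-High) come from the signs of the focal z-value and
the lag among significant regions; islands are reported Not-significant
with a flag. One permutation-index matrix is generated per map and reused
across regions (the standard implementation trick); results are seeded.

The cluster/non-cluster coverage comparison is a two-sample rank-sum test —
the groups are unpaired — exact when both groups have ≤ 10 observations and
no ties, otherwise normal approximation with tie correction. A signed-rank
variant on trimmed paired samples is available behind `paired=True` for
strict replication of analyses that name that test.

## Flexible spatial scan

Candidate windows are all connected subsets, containing the focal county,
of each county's K−1 nearest neighbors by centroid distance (ties broken by
county order); K defaults to 15 in the library (the reference default for
this scan family), while the pipeline config uses K = 5 to keep lattice
window counts proportionate. Windows score by the one-sided (high-rate)
Poisson log-likelihood ratio; the null distribution redraws county counts
multinomially with probabilities e_i/e_G conditional on the observed total,
and each reported cluster's p-value is the rank of its LLR among replicate
*maxima* (conservative for secondary clusters). Secondary clusters are
reported greedily by LLR among windows disjoint from all better-ranked
ones. With K unbounded the limited search is exhaustive, which the
acceptance suite exploits: on 6-region maps the scan must match brute force
over all connected subsets exactly.

## The NB-CAR model

Counts are negative-binomial with mean μ and dispersion r
(Var = μ + μ²/r; Poisson as r → ∞), the parameterization consistent with an
"over-dispersion parameter". The linear predictor adds the log expected
count as offset, an intercept, covariates (bloom coverage in percent, so β
is per 1% of coverage), an exchangeable effect e_i and an ICAR spatial
effect φ. The ICAR prior is improper; each draw is re-centered to sum to
zero with the removed mean absorbed into the intercept (a valid move on a
connected graph because the ICAR density and the likelihood are invariant
to that joint shift; disconnected components are centered per component).

Priors (all overridable via `Priors`): α, β ~ N(0, 10²);
r ~ Gamma(0.1, 0.1); σ_e, σ_φ ~ half-Normal(0, 5) — the weakly-informative
standard for convolution disease-mapping models; the analysis this package
reproduces did not state its priors.

Sampling is Metropolis-within-Gibbs with component-wise random-walk
proposals: scalar updates for α, each β_k, log r, log σ_e, log σ_φ;
vectorized element-wise updates for e (the likelihood factorizes); and
block updates for φ by graph coloring, so no two adjacent counties move
simultaneously and the ICAR full conditionals stay exact. Proposal scales
adapt multiplicatively toward ~35% acceptance during burn-in and are frozen
afterwards to preserve ergodicity. The gammaln terms of the NB likelihood
cancel for all location moves and are only evaluated in the dispersion
update. Defaults are a single chain of 5,000 burn-in + 10,000 retained
draws, with split-chain R-hat and ESS computed on chain halves (arviz).

Known mixing behavior: r and σ_e compete to explain overdispersion, so
their marginal chains move slowly (low ESS) even when α and β mix well;
β inference is robust to this, but variance-component summaries deserve a
longer chain or an R-hat check before being quoted. The GLM baseline
(`fit_glm`, statsmodels NB2) provides the collapse check: with σ_e and σ_φ
pinned near zero the posterior means reproduce the MLE.

## Synthetic study system

The generator emulates the *statistical structure* the analysis assumes,
not the sensing physics: a rectangular county lattice (default 20×20
counties of 10 km, 20 pixels per county side ≈ 500 m pixels), per-county
water masks (default 30% water), pigment fields in which a known fraction
of water pixels exceeds the bloom threshold (default prevalence 0.2; a Beta
spread across counties is available where cross-county variation is
needed), and reflectance scenes built by algebraically inverting the
retrieval equations so that retrieval recovers the pigments to floating
precision — the round trip is an identity check, not a radiative-transfer
simulation. Mortality tables come from the NB-CAR generative model itself
with defaults α = 0, β = (0.003, −0.05, 0.05) for (coverage %, education,
race), r = 20, σ_e = σ_φ = 0.05, 2 × 8 gender/age strata, county
populations log-normal around 50k and stratum rates shaped to rise with age
and scaled so mean county expected deaths ≈ 100 (a mid-size county over a
pooled 12-year window). County totals are drawn from the NB model and
allocated to strata multinomially in proportion to population × rate, so
the county-level model is exact and the stratified table is internally
consistent. ICAR fields are sampled exactly through the Laplacian
eigendecomposition restricted to its positive eigenspace.

What passing tests on this system does **not** show: robustness to
atmospheric-correction error, cloud gaps, mixed land/water pixels,
cross-boundary bloom exposure, non-lattice county geometries with highly
unequal areas, or real covariate confounding structure. Those belong to the
real-data mode, which consumes user-supplied GeoJSON/CSV/raster inputs
through the same interfaces.

## Test and verification sizes

The verification suite chooses problem sizes that make each check sharp but
quick: exhaustive-search scan comparisons on 6-region maps; LISA validity
on a 10×10 lattice over 1,000 null maps with 999 permutations; parameter
recovery over 50 replicates of the 20×20 scenario at 1,000 + 2,000 MCMC
iterations (the full 5,000 + 10,000 schedule is exercised once in the
acceptance script); end-to-end pipeline checks at 6×6–10×10 with
proportionally reduced Monte-Carlo settings.

## Known limitations

* The exact backscatter estimator, pure-water absorptions and PC specific
  absorption of the source processing chain are not published with the
  calibration; the defaults follow the cited algorithm lineage and are
  configurable, so absolute concentrations (not the round-trip identity)
  carry that uncertainty.
* Suppression-induced selection bias is reproduced, not corrected.
* The scan's K, null scheme and secondary-cluster rule follow the reference
  methodology's defaults; other choices change which secondary clusters are
  reported (the most-likely cluster is unaffected).
* Single-chain R-hat is computed on chain halves; it cannot detect a chain
  stuck in one mode from initialization.
* No proper-CAR (Leroux) alternative, no zero-inflation, no space–time
  scan.
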