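"""Synthetic study system: counties, pigment fields, reflectance, mortality.

This module generates data with the statistical structure the analysis
assumes, so the whole pipeline runs and can be validated without satellite
imagery or vital-statistics extracts:

* a rectangular lattice of square counties with Queen adjacency,
* per-pixel pigment fields with a known fraction of each county's water
  pixels above the bloom threshold (ground-truth coverage),
* reflectance scenes forward-modelled so the band-ratio retrieval recovers
  the pigments exactly (the forward model is the algebraic inverse of the
  retrieval equations),
* stratified mortality tables drawn from the negative-binomial spatial
  convolution model:  log μ_i = log E_i + α + X_i β + e_i + φ_i with
  Y_i ~ NB(μ_i, r), e_i ~ N(0, σ_e²) unstructured heterogeneity, and φ an
  intrinsic CAR (ICAR) spatial effect — conditional mean the neighbor
  average, conditional variance σ_φ²/m_i — centered to sum to zero per
  connected component.

Identical scenario (including seed) yields bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import box

from .rasters import GridSpec, PigmentRaster, ReflectanceScene
from .regions import CountyMap
from .retrieval import OpticalConstants

__all__ = [
    "SyntheticScenario",
    "make_county_grid",
    "make_pigment_field",
    "forward_reflectance",
    "make_covariates",
    "sample_icar",
    "simulate_mortality",
    "SimulatedMortality",
]


@dataclass
class SyntheticScenario:
    """Parameters of the synthetic study system.

    The mortality model parameters (``true_alpha``, ``true_beta``,
    ``true_r``, ``sigma_e``, ``sigma_phi``) are the generative values of
    the regression the analysis estimates; ``true_beta`` is per covariate
    on that covariate's own unit (bloom coverage in percent, so the default
    0.003 is a log-rate increase per 1% coverage — risk ratio ≈ 1.003).
    """

    grid_nx: int = 20
    grid_ny: int = 20
    cell_size: float = 10.0          # county side, km
    pixels_per_county: int = 20      # raster pixels per county side
    water_fraction: float = 0.3      # fraction of pixels flagged water
    bloom_prevalence: float | np.ndarray = 0.2   # fraction of water pixels above threshold
    bloom_heterogeneity: float = 0.0  # >0: per-county Beta spread around the mean
    true_alpha: float = 0.0
    true_beta: tuple[float, ...] = (0.003, -0.05, 0.05)
    true_r: float = 20.0             # NB dispersion, Var = mu + mu^2/r
    sigma_e: float = 0.05            # sd of unstructured effect
    sigma_phi: float = 0.05          # conditional sd of the ICAR effect
    n_strata: int = 16               # gender (2) x age bands
    mean_expected_deaths: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.grid_nx, self.grid_ny, self.pixels_per_county) < 1:
            raise ValueError("dimensions must be >= 1")
        if not (0 <= self.water_fraction <= 1):
            raise ValueError("water_fraction must be in [0, 1]")
        prev = np.asarray(self.bloom_prevalence, dtype=float)
        if np.any(prev < 0) or np.any(prev > 1):
            raise ValueError("bloom_prevalence must be in [0, 1]")
        if self.true_r <= 0:
            raise ValueError("true_r must be > 0")
        if self.sigma_e < 0 or self.sigma_phi < 0:
            raise ValueError("sigmas must be >= 0")
        if self.n_strata < 1:
            raise ValueError("n_strata must be >= 1")
        self.true_beta = tuple(float(b) for b in np.atleast_1d(self.true_beta))

    @property
    def n_counties(self) -> int:
        return self.grid_nx * self.grid_ny

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["bloom_prevalence"] = (np.asarray(self.bloom_prevalence).tolist())
        d["true_beta"] = list(self.true_beta)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticScenario":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def make_county_grid(nx: int, ny: int, cell_size: float = 10.0) -> CountyMap:
    """nx × ny lattice of square counties of side ``cell_size``.

    IDs are row-major ("C0000" at the lower-left).  Queen adjacency is
    computed from the polygon geometry, so corner-touching counties are
    neighbors.
    """
    if nx < 1 or ny < 1:
        raise ValueError("grid dimensions must be >= 1")
    if cell_size <= 0:
        raise ValueError("cell_size must be > 0")
    ids, polys = [], []
    for iy in range(ny):
        for ix in range(nx):
            ids.append(f"C{iy * nx + ix:04d}")
            polys.append(box(ix * cell_size, iy * cell_size,
                             (ix + 1) * cell_size, (iy + 1) * cell_size))
    return CountyMap(ids=ids, polygons=polys)


def _per_county_prevalence(scenario: SyntheticScenario, n: int,
                           rng: np.random.Generator) -> np.ndarray:
    prev = np.asarray(scenario.bloom_prevalence, dtype=float)
    if prev.ndim == 0:
        if scenario.bloom_heterogeneity > 0 and 0 < float(prev) < 1:
            kappa = scenario.bloom_heterogeneity
            return rng.beta(float(prev) * kappa, (1 - float(prev)) * kappa, size=n)
        return np.full(n, float(prev))
    if prev.shape != (n,):
        raise ValueError("per-county bloom_prevalence must align with counties")
    return prev


def make_pigment_field(counties: CountyMap, scenario: SyntheticScenario,
                       rng: np.random.Generator | None = None,
                       pc_threshold: float = 4.0
                       ) -> tuple[PigmentRaster, np.ndarray]:
    """Pigment raster with known per-county bloom coverage.

    Counties must form an axis-aligned lattice (as from
    :func:`make_county_grid`).  Each county gets ``pixels_per_county²``
    pixels; a ``water_fraction`` share is flagged water, and of those a
    ``bloom_prevalence`` share receives phycocyanin at or above
    ``pc_threshold`` (the rest strictly below).  Returns the raster and the
    exact ground-truth coverage percentage per county (bloom pixel area
    over county area).
    """
    if rng is None:
        rng = np.random.default_rng(scenario.seed)
    ppc = scenario.pixels_per_county
    minx, miny, maxx, maxy = counties.bounds
    n = len(counties)

    bnds = np.array([p.bounds for p in counties.polygons])
    cell_w = bnds[0, 2] - bnds[0, 0]
    cell_h = bnds[0, 3] - bnds[0, 1]
    dx, dy = cell_w / ppc, cell_h / ppc
    n_cols = int(round((maxx - minx) / dx))
    n_rows = int(round((maxy - miny) / dy))
    grid = GridSpec(origin_x=minx, origin_y=miny, dx=dx, dy=dy,
                    n_cols=n_cols, n_rows=n_rows)

    pc = np.zeros(grid.shape)
    chl = np.zeros(grid.shape)
    water = np.zeros(grid.shape, dtype=bool)
    coverage = np.zeros(n)
    prevalence = _per_county_prevalence(scenario, n, rng)

    n_pix = ppc * ppc
    n_water = int(round(scenario.water_fraction * n_pix))
    for c in range(n):
        c0 = int(round((bnds[c, 0] - minx) / dx))
        r0 = int(round((bnds[c, 1] - miny) / dy))
        flat = rng.permutation(n_pix)[:n_water]
        n_bloom = int(round(prevalence[c] * n_water))
        local_pc = np.zeros(n_pix)
        if n_water:
            bloom_idx = flat[:n_bloom]
            clear_idx = flat[n_bloom:]
            # at/above threshold for bloom pixels, strictly below for the rest
            local_pc[bloom_idx] = pc_threshold * (1.0 + 4.0 * rng.random(n_bloom))
            local_pc[clear_idx] = pc_threshold * 0.9 * rng.random(clear_idx.size)
        local_water = np.zeros(n_pix, dtype=bool)
        local_water[flat] = True
        local_chl = np.zeros(n_pix)
        local_chl[flat] = rng.lognormal(mean=np.log(2.0), sigma=0.5, size=n_water)

        sl = (slice(r0, r0 + ppc), slice(c0, c0 + ppc))
        pc[sl] = local_pc.reshape(ppc, ppc)
        chl[sl] = local_chl.reshape(ppc, ppc)
        water[sl] = local_water.reshape(ppc, ppc)
        coverage[c] = 100.0 * n_bloom * grid.pixel_area / counties.polygons[c].area

    qa = ~water
    raster = PigmentRaster(pc=pc, chl=chl, qa_mask=qa, water_mask=water, grid=grid)
    return raster, coverage


def forward_reflectance(pigments: PigmentRaster, b_b: float,
                        B705: float = 0.02,
                        consts: OpticalConstants | None = None
                        ) -> ReflectanceScene:
    """Forward-model a reflectance scene that inverts exactly.

    Emits the four bands such that applying the band-ratio retrieval with
    the same optical constants recovers the input pigments:

        B665 = B705·(a_w709+b_b) / (γ·a_chl + a_w665 + b_b)
        B620 = B705·(a_w709+b_b) / (δ·(a_pc + ε·a_chl) + a_w620 + b_b)
        B779 = c2·b_b / (c1 + c3·b_b)   (inverse of the b_b estimator)

    with a_pc and a_chl obtained from the concentrations through the
    pigment-specific absorption coefficients.  Land pixels get zero
    reflectance.
    """
    consts = consts or OpticalConstants()
    if not b_b > 0:
        raise ValueError("b_b must be > 0")
    if not B705 > 0:
        raise ValueError("B705 must be > 0")
    a_pc = pigments.pc * consts.pc_specific_absorption
    a_chl = pigments.chl * consts.chl_specific_absorption

    numer = B705 * (consts.a_w709 + b_b)
    den665 = consts.gamma * a_chl + consts.a_w665 + b_b
    den620 = consts.delta * (a_pc + consts.epsilon * a_chl) + consts.a_w620 + b_b
    if np.any(den665 <= 0) or np.any(den620 <= 0):
        raise ValueError("nonphysical pigment/backscatter combination")
    B665 = numer / den665
    B620 = numer / den620
    B779 = consts.bb_c2 * b_b / (consts.bb_c1 + consts.bb_c3 * b_b)

    water = pigments.water_mask
    z = np.zeros(pigments.grid.shape)
    return ReflectanceScene(
        B620=np.where(water, B620, z), B665=np.where(water, B665, z),
        B705=np.where(water, np.full_like(B620, B705), z),
        B779=np.where(water, np.full_like(B620, B779), z),
        water_mask=water, grid=pigments.grid)


def make_covariates(counties: CountyMap, scenario: SyntheticScenario,
                    rng: np.random.Generator | None = None,
                    coverage_pct: np.ndarray | None = None) -> pd.DataFrame:
    """Covariate table for the mortality regression.

    The bloom-coverage covariate is on the 0–100 percent scale (so the
    coefficient is per 1% of coverage); when not supplied it is drawn from
    a right-skewed Gamma distribution resembling county bloom coverages.
    Education and race enter standardized (mean 0, sd 1).
    """
    if rng is None:
        rng = np.random.default_rng(scenario.seed)
    n = len(counties)
    if coverage_pct is None:
        coverage_pct = np.clip(rng.gamma(shape=2.0, scale=5.0, size=n), 0, 100)
    else:
        coverage_pct = np.asarray(coverage_pct, dtype=float)
    edu = rng.standard_normal(n)
    race = rng.standard_normal(n)
    edu = (edu - edu.mean()) / edu.std()
    race = (race - race.mean()) / race.std()
    return pd.DataFrame({"county_id": counties.ids,
                         "coverage_pct": coverage_pct,
                         "education": edu, "race": race})


def sample_icar(counties: CountyMap, sigma_phi: float,
                rng: np.random.Generator) -> np.ndarray:
    """Exact draw from the centered intrinsic CAR prior.

    The ICAR precision is (D − A)/σ_φ² (graph Laplacian scaled by the
    conditional variance).  Sampling uses the Laplacian eigendecomposition
    restricted to its positive eigenspace, which is the proper Gaussian on
    the sum-to-zero subspace of each connected component — the standard
    way to make the improper ICAR usable for simulation.
    """
    n = len(counties)
    if sigma_phi == 0 or n == 1:
        return np.zeros(n)
    A = np.zeros((n, n))
    for i, nbrs in enumerate(counties.neighbors):
        A[i, nbrs] = 1.0
    L = np.diag(A.sum(axis=1)) - A
    evals, evecs = np.linalg.eigh(L)
    pos = evals > 1e-10 * max(evals.max(), 1.0)
    z = rng.standard_normal(int(pos.sum()))
    phi = sigma_phi * (evecs[:, pos] @ (z / np.sqrt(evals[pos])))
    # eigen-sampling already lives on the per-component sum-to-zero space;
    # re-center explicitly to remove floating-point drift
    for comp in counties.connected_components():
        phi[comp] -= phi[comp].mean()
    return phi


@dataclass
class SimulatedMortality:
    """Stratified death table plus the generative ground truth."""

    table: pd.DataFrame          # county_id, stratum_id, gender, age_band, population, deaths
    expected: np.ndarray         # true E_i used in the generative model
    mu: np.ndarray               # true NB means
    y: np.ndarray                # county death totals
    phi: np.ndarray
    e: np.ndarray
    standard_rates: pd.Series    # generative stratum rates


def _stratum_structure(scenario: SyntheticScenario):
    """Stratum ids, genders, age bands and deterministic rate/share shapes."""
    n_s = scenario.n_strata
    genders = ["F", "M"]
    n_age = max(1, n_s // 2) if n_s >= 2 else 1
    labels, gender_col, age_col = [], [], []
    for s in range(n_s):
        g = genders[s % 2] if n_s >= 2 else "A"
        a = (s // 2) * 10 if n_s >= 2 else 0
        labels.append(f"S{s:02d}")
        gender_col.append(g)
        age_col.append(f"{a}-{a + 9}")
    # mortality rises steeply with age; males somewhat higher
    age_idx = np.array([s // 2 if n_s >= 2 else 0 for s in range(n_s)], dtype=float)
    shape = 1.35 ** age_idx * np.where(np.array(gender_col) == "M", 1.3, 1.0)
    shares = np.full(n_s, 1.0 / n_s)
    return labels, gender_col, age_col, shape, shares


def simulate_mortality(counties: CountyMap, covariates: pd.DataFrame | np.ndarray,
                       scenario: SyntheticScenario,
                       rng: np.random.Generator | None = None
                       ) -> SimulatedMortality:
    """Draw a stratified mortality table from the NB spatial model.

    County totals follow Y_i ~ NB(μ_i, r) with
    log μ_i = log E_i + α + X_i β + e_i + φ_i, then are allocated to the
    gender × age strata multinomially in proportion to population × rate,
    which keeps the county-level model exact while producing the
    stratified table the standardization step consumes.
    """
    if rng is None:
        rng = np.random.default_rng(scenario.seed)
    n = len(counties)
    if isinstance(covariates, pd.DataFrame):
        X = covariates.drop(columns=["county_id"], errors="ignore").to_numpy(dtype=float)
    else:
        X = np.asarray(covariates, dtype=float)
    if X.shape[0] != n:
        raise ValueError("covariate rows must match counties")
    beta = np.asarray(scenario.true_beta, dtype=float)
    if X.shape[1] != beta.size:
        raise ValueError(f"covariates have {X.shape[1]} columns but true_beta "
                         f"has {beta.size}")

    labels, gender_col, age_col, shape, shares = _stratum_structure(scenario)
    n_s = scenario.n_strata

    # county populations: log-normal size spread around ~50k people
    county_pop = rng.lognormal(mean=np.log(5e4), sigma=0.5, size=n)
    pop = np.round(county_pop[:, None] * shares[None, :]).astype(float)
    pop = np.maximum(pop, 1.0)

    # scale the stratum rate shape so mean E_i hits the scenario target
    mean_E_unscaled = float(np.mean(pop @ shape))
    rates = shape * (scenario.mean_expected_deaths / mean_E_unscaled)
    E = pop @ rates

    phi = sample_icar(counties, scenario.sigma_phi, rng)
    e = rng.normal(0.0, scenario.sigma_e, size=n) if scenario.sigma_e > 0 \
        else np.zeros(n)
    log_mu = np.log(E) + scenario.true_alpha + X @ beta + e + phi
    mu = np.exp(log_mu)
    r = scenario.true_r
    y = rng.negative_binomial(n=r, p=r / (r + mu)).astype(float)

    # allocate county totals to strata in proportion to population x rate
    w = pop * rates[None, :]
    w = w / w.sum(axis=1, keepdims=True)
    deaths = np.vstack([rng.multinomial(int(y[i]), w[i]) for i in range(n)])
    deaths = np.minimum(deaths, pop).astype(float)

    rows = {
        "county_id": np.repeat(counties.ids, n_s),
        "stratum_id": np.tile(labels, n),
        "gender": np.tile(gender_col, n),
        "age_band": np.tile(age_col, n),
        "population": pop.ravel(),
        "deaths": deaths.ravel(),
    }
    table = pd.DataFrame(rows)
    return SimulatedMortality(
        table=table, expected=E, mu=mu, y=y, phi=phi, e=e,
        standard_rates=pd.Series(rates, index=labels, name="rate"))
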