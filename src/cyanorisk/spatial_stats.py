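"""Bivariate spatial association: global Moran's I, LISA, and a rank test.

Conventions follow the common areal-analysis defaults: Queen contiguity,
row-standardized weights, variables standardized with the population
standard deviation, and conditional-permutation inference for the local
statistics with pseudo-p = (more-extreme + 1) / (permutations + 1).

With z_x and z_y the standardized focal and lagged variables, the global
bivariate statistic is

    I = (1/n) Σ_i z_x,i · (Σ_j w_ij z_y,j)

and the local statistic is the i-th summand, so mean(local) = global.  The
permutation test holds z_x,i and the map fixed, permutes the z_y values of
the other n−1 regions into i's neighborhood, and compares |I_i| with its
permutation distribution (two-sided).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

from .regions import CountyMap

logger = logging.getLogger(__name__)

__all__ = [
    "SpatialWeights",
    "queen_weights",
    "standardize",
    "bivariate_moran",
    "local_moran_bv",
    "bivariate_lisa",
    "rank_test",
]

QUADRANTS = ("High-High", "Low-Low", "High-Low", "Low-High", "Not-significant")


@dataclass
class SpatialWeights:
    """Row-standardized contiguity weights.

    ``neighbors[i]`` lists the neighbor indices of region i; each neighbor
    receives weight 1/|neighbors[i]|, so row sums are 1 (or 0 for islands,
    which are allowed but logged).
    """

    neighbors: list[np.ndarray]

    def __post_init__(self) -> None:
        self.neighbors = [np.asarray(sorted(nb), dtype=int) for nb in self.neighbors]
        for i, nb in enumerate(self.neighbors):
            if i in nb:
                raise ValueError(f"region {i} listed as its own neighbor")
            for j in nb:
                if i not in self.neighbors[j]:
                    raise ValueError("adjacency must be symmetric")
        islands = [i for i, nb in enumerate(self.neighbors) if nb.size == 0]
        if islands:
            logger.info("weights contain %d island region(s): %s",
                        len(islands), islands[:10])

    @property
    def n(self) -> int:
        return len(self.neighbors)

    @property
    def cardinalities(self) -> np.ndarray:
        return np.array([nb.size for nb in self.neighbors])

    def sparse(self) -> sp.csr_matrix:
        rows, cols, vals = [], [], []
        for i, nb in enumerate(self.neighbors):
            if nb.size:
                rows.extend([i] * nb.size)
                cols.extend(nb.tolist())
                vals.extend([1.0 / nb.size] * nb.size)
        return sp.csr_matrix((vals, (rows, cols)), shape=(self.n, self.n))

    def lag(self, z: np.ndarray) -> np.ndarray:
        """Spatial lag: neighbor average of z (0 for islands)."""
        return self.sparse() @ np.asarray(z, dtype=float)


def queen_weights(counties: CountyMap) -> SpatialWeights:
    """Row-standardized Queen-contiguity weights from county polygons."""
    return SpatialWeights(neighbors=[np.array(nb) for nb in counties.neighbors])


def standardize(x: np.ndarray) -> np.ndarray:
    """(x − mean) / population sd; raises on a constant vector."""
    x = np.asarray(x, dtype=float)
    sd = x.std()  # population sd (ddof=0), the areal-analysis convention
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("cannot standardize a constant (or non-finite) vector")
    return (x - x.mean()) / sd


def bivariate_moran(x: np.ndarray, y: np.ndarray, W: SpatialWeights) -> float:
    """Global bivariate Moran's I of focal x against the spatial lag of y."""
    z_x = standardize(x)
    z_y = standardize(y)
    if z_x.size != W.n or z_y.size != W.n:
        raise ValueError("variable length must match the number of regions")
    return float(np.mean(z_x * W.lag(z_y)))


def local_moran_bv(x: np.ndarray, y: np.ndarray, W: SpatialWeights) -> np.ndarray:
    """Local bivariate Moran values I_i = z_x,i · lag(z_y)_i."""
    z_x = standardize(x)
    z_y = standardize(y)
    return z_x * W.lag(z_y)


def _conditional_permutation_index(rng: np.random.Generator, n: int,
                                   n_perm: int) -> np.ndarray:
    """(n_perm, n−1) matrix of permutations of 0..n−2.

    Reused across regions: for region i, entry v maps to the actual region
    index v + (v >= i), i.e. a permutation of "everyone but i".
    """
    return np.argsort(rng.random((n_perm, n - 1)), axis=1)


def bivariate_lisa(x: np.ndarray, y: np.ndarray, W: SpatialWeights,
                   n_perm: int = 999, alpha: float = 0.05,
                   seed: int | None = None,
                   rng: np.random.Generator | None = None,
                   ids: list[str] | None = None) -> pd.DataFrame:
    """Bivariate LISA with conditional-permutation significance.

    For each region the focal value z_x,i is held fixed while the z_y
    values of the remaining n−1 regions are permuted into its neighborhood;
    the two-sided pseudo-p is (1 + #{|I_perm| ≥ |I_i|}) / (1 + n_perm).
    Significant regions are classified by quadrant: High-High (z_x > 0,
    lag > 0), Low-Low, High-Low, Low-High; everything else — including
    islands, whose local statistic is undefined — is Not-significant.

    Returns a DataFrame with columns county_id (or index), local_I,
    pseudo_p, quadrant, island.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    z_x = standardize(x)
    z_y = standardize(y)
    n = W.n
    if z_x.size != n or z_y.size != n:
        raise ValueError("variable length must match the number of regions")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")

    lag = W.lag(z_y)
    local_I = z_x * lag
    cards = W.cardinalities
    perms = _conditional_permutation_index(rng, n, n_perm)

    pseudo_p = np.ones(n)
    island = cards == 0
    for i in range(n):
        k = cards[i]
        if k == 0:
            continue
        idx = perms[:, :k].copy()
        idx += idx >= i
        lag_perm = z_y[idx].mean(axis=1)
        I_perm = z_x[i] * lag_perm
        more_extreme = np.count_nonzero(np.abs(I_perm) >= abs(local_I[i]))
        pseudo_p[i] = (1 + more_extreme) / (1 + n_perm)

    quadrant = np.full(n, "Not-significant", dtype=object)
    sig = ~island & (pseudo_p <= alpha)
    hi_x = z_x > 0
    hi_lag = lag > 0
    quadrant[sig & hi_x & hi_lag] = "High-High"
    quadrant[sig & ~hi_x & ~hi_lag] = "Low-Low"
    quadrant[sig & hi_x & ~hi_lag] = "High-Low"
    quadrant[sig & ~hi_x & hi_lag] = "Low-High"

    out = pd.DataFrame({
        "county_id": ids if ids is not None else np.arange(n).astype(str),
        "local_I": np.where(island, np.nan, local_I),
        "pseudo_p": np.where(island, np.nan, pseudo_p),
        "quadrant": quadrant,
        "island": island,
    })
    return out


def rank_test(coverage_in: np.ndarray, coverage_out: np.ndarray,
              paired: bool = False) -> tuple[float, float]:
    """Compare bloom coverage between cluster and non-cluster counties.

    Default is the two-sample Wilcoxon rank-sum (Mann–Whitney) test —
    cluster membership defines unpaired groups — two-sided, exact when both
    groups have ≤ 10 observations and no ties, otherwise the normal
    approximation with tie correction.  ``paired=True`` switches to the
    signed-rank test on samples trimmed to equal length (strict
    replication of the test named for this comparison).

    Returns ``(statistic, p_value)``.
    """
    a = np.asarray(coverage_in, dtype=float)
    b = np.asarray(coverage_out, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")

    if paired:
        m = min(a.size, b.size)
        d = a[:m] - b[:m]
        if np.all(d == 0):
            return 0.0, 1.0
        res = stats.wilcoxon(a[:m], b[:m], alternative="two-sided")
        return float(res.statistic), float(res.pvalue)

    combined = np.concatenate([a, b])
    if np.all(combined == combined[0]):
        # identical constant groups: no evidence either way
        return float(a.size * b.size / 2.0), 1.0
    has_ties = np.unique(combined).size < combined.size
    method = "exact" if (max(a.size, b.size) <= 10 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)
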