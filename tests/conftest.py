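import itertools

import numpy as np
import pytest
from shapely.geometry import box

from cyanorisk.geo_synth import SyntheticScenario, make_county_grid
from cyanorisk.regions import CountyMap


@pytest.fixture
def grid3():
    """3x3 lattice of 10 km counties."""
    return make_county_grid(3, 3, 10.0)


@pytest.fixture
def grid2():
    return make_county_grid(2, 2, 10.0)


@pytest.fixture
def small_scenario():
    return SyntheticScenario(grid_nx=3, grid_ny=3, pixels_per_county=10,
                             water_fraction=1.0, bloom_prevalence=0.25, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def toy_maps_6():
    """Deterministic 6-region maps with observed/expected patterns, used to
    pit the limited scan against exhaustive search."""
    rng = np.random.default_rng(7)
    maps = []
    for counties in (make_county_grid(3, 2, 10.0), make_county_grid(6, 1, 10.0),
                     make_county_grid(2, 3, 10.0)):
        for _ in range(2):
            expected = rng.uniform(5.0, 15.0, size=6)
            observed = rng.poisson(expected * rng.uniform(0.5, 2.5, size=6)).astype(float)
            if observed.sum() == 0:
                observed[0] = 1.0
            maps.append((counties, observed, expected))
    return maps


def brute_force_best_cluster(counties: CountyMap, observed, expected):
    """Oracle: exhaustive search over ALL connected subsets of the map."""
    import networkx as nx

    from cyanorisk.cluster_scan import window_llr

    g = counties.adjacency_graph()
    n = len(counties)
    n_G, e_G = float(np.sum(observed)), float(np.sum(expected))
    best_llr, best_set = -1.0, None
    for size in range(1, n + 1):
        for combo in itertools.combinations(range(n), size):
            if size < n and not nx.is_connected(g.subgraph(combo)):
                continue
            if size == n:
                continue  # whole map has e_Z = e_G, not a valid window
            llr = window_llr(float(np.sum(observed[list(combo)])),
                             float(np.sum(expected[list(combo)])), n_G, e_G)
            if llr > best_llr:
                best_llr, best_set = llr, frozenset(combo)
    return best_set, best_llr
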