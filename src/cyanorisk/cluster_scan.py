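"""Flexible-shaped spatial scan statistic for excess-mortality clusters.

Candidate clusters are connected sets of counties built around each focal
county from its K−1 nearest neighbors (centroid distance), scored by the
Poisson log-likelihood ratio

    LLR(Z) = n_Z·ln(n_Z/e_Z) + (n_G−n_Z)·ln((n_G−n_Z)/(e_G−e_Z))

when the inside rate exceeds the outside rate, else 0 (high-rate scan
only).  Significance is by Monte-Carlo: null maps redraw the county counts
multinomially with probabilities proportional to the expected counts,
conditional on the observed total, and the observed maximum LLR is ranked
among the replicate maxima.  Secondary clusters are reported greedily by
LLR among windows disjoint from every better-ranked reported cluster.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .regions import CountyMap

logger = logging.getLogger(__name__)

__all__ = ["ScanWindow", "ScanResult", "enumerate_windows", "window_llr",
           "flex_scan"]


@dataclass(frozen=True)
class ScanWindow:
    """A scored candidate cluster: a connected set of counties."""

    region_ids: tuple[str, ...]
    n_Z: float
    e_Z: float
    llr: float
    p_value: float = float("nan")

    def __len__(self) -> int:
        return len(self.region_ids)


@dataclass
class ScanResult:
    """Ranked non-overlapping clusters with Monte-Carlo p-values."""

    clusters: list[ScanWindow] = field(default_factory=list)
    alpha: float = 0.01
    n_mc: int = 999

    @property
    def significant(self) -> list[ScanWindow]:
        return [c for c in self.clusters if c.p_value < self.alpha]

    @property
    def most_likely(self) -> ScanWindow | None:
        return self.clusters[0] if self.clusters else None


def _nearest_sets(counties: CountyMap, K: int) -> list[np.ndarray]:
    """For each focal county: itself plus its K−1 nearest neighbors.

    Distance is Euclidean between polygon centroids; ties are broken by
    positional (county-id) order, which np.lexsort makes deterministic.
    """
    cent = counties.centroids
    n = len(counties)
    sets = []
    for i in range(n):
        d = np.hypot(cent[:, 0] - cent[i, 0], cent[:, 1] - cent[i, 1])
        order = np.lexsort((np.arange(n), d))
        sets.append(np.sort(order[:K]))
    return sets


def _connected_subsets_containing(i: int, allowed: np.ndarray,
                                  neighbors: list[list[int]]):
    """Yield every connected subset of `allowed` that contains node i.

    Classic recursive enumeration: each call emits the current subset, then
    extends it through the frontier, forbidding already-branched vertices so
    each subset is produced exactly once.
    """
    allowed_set = set(int(a) for a in allowed)
    nbr = {v: sorted(set(neighbors[v]) & allowed_set) for v in allowed_set}

    def rec(current: frozenset, frontier: list[int], forbidden: set):
        yield current
        local_forbidden = set(forbidden)
        for v in frontier:
            new_current = current | {v}
            new_frontier = [u for u in nbr[v]
                            if u not in new_current and u not in local_forbidden
                            and u not in frontier]
            tail = [u for u in frontier if u != v and u not in local_forbidden]
            yield from rec(new_current, sorted(set(tail + new_frontier)),
                           set(local_forbidden))
            local_forbidden.add(v)

    yield from rec(frozenset({i}), sorted(nbr[i]), set())


def enumerate_windows(counties: CountyMap, K: int) -> list[tuple[int, ...]]:
    """All candidate windows for the limited exhaustive search.

    For every focal county, all connected subsets (of size ≤ K) of the set
    formed by the county and its K−1 nearest neighbors; duplicates arising
    from different focal counties are removed.  Returned as sorted tuples
    of positional indices, in a deterministic order.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    n = len(counties)
    if K > n:
        logger.warning("K=%d exceeds region count %d; clamped", K, n)
        K = n
    seen: set[tuple[int, ...]] = set()
    for i, allowed in enumerate(_nearest_sets(counties, K)):
        for subset in _connected_subsets_containing(i, allowed,
                                                    counties.neighbors):
            seen.add(tuple(sorted(subset)))
    return sorted(seen, key=lambda t: (len(t), t))


def window_llr(n_Z, e_Z, n_G: float, e_G: float):
    """Poisson log-likelihood ratio of a window; 0 unless the rate inside
    exceeds the rate outside (high-rate scan).  Vectorized over windows."""
    n_Z = np.asarray(n_Z, dtype=float)
    e_Z = np.asarray(e_Z, dtype=float)
    if np.any(e_Z <= 0) or not e_G > 0:
        raise ValueError("expected counts must be positive")
    if np.any(e_Z >= e_G):
        raise ValueError("window expected count must be < total expected")
    if np.any(n_Z < 0) or np.any(n_Z > n_G):
        raise ValueError("window observed count must lie in [0, total]")

    n_out = n_G - n_Z
    e_out = e_G - e_Z
    with np.errstate(divide="ignore", invalid="ignore"):
        t_in = np.where(n_Z > 0, n_Z * np.log(n_Z / e_Z), 0.0)
        t_out = np.where(n_out > 0, n_out * np.log(n_out / e_out), 0.0)
    high = n_Z * e_out > n_out * e_Z  # n_Z/e_Z > n_out/e_out without division
    llr = np.where(high, t_in + t_out, 0.0)
    return llr if llr.ndim else float(llr)


def flex_scan(counties: CountyMap, observed: np.ndarray, expected: np.ndarray,
              K: int = 15, n_mc: int = 999, alpha: float = 0.01,
              seed: int | None = None,
              rng: np.random.Generator | None = None,
              max_reported: int = 50) -> ScanResult:
    """Run the flexible scan and return ranked non-overlapping clusters.

    ``observed`` and ``expected`` are county-aligned vectors; ``expected``
    must be positive everywhere.  Monte-Carlo replicates are drawn
    conditional on the observed total, multinomially with probabilities
    e_i/e_G; each window's p-value is the rank of its LLR among the
    replicate *maximum* LLRs (so secondary p-values are conservative).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    observed = np.asarray(observed, dtype=float)
    expected = np.asarray(expected, dtype=float)
    n = len(counties)
    if observed.shape != (n,) or expected.shape != (n,):
        raise ValueError("observed/expected must align with counties")
    if np.any(expected <= 0):
        raise ValueError("expected must be positive everywhere")
    n_G = float(observed.sum())
    e_G = float(expected.sum())
    if n_G <= 0:
        logger.warning("all-zero observed counts: no clusters detectable")
        return ScanResult(clusters=[], alpha=alpha, n_mc=n_mc)

    # the whole map is not a window (its complement is empty)
    windows = [w for w in enumerate_windows(counties, K) if len(w) < n]
    if not windows:
        logger.warning("no candidate windows (single region?); empty result")
        return ScanResult(clusters=[], alpha=alpha, n_mc=n_mc)
    # membership matrix (windows x counties) for vectorized scoring
    rows = np.repeat(np.arange(len(windows)),
                     np.fromiter((len(w) for w in windows), dtype=int))
    cols = np.concatenate([np.asarray(w) for w in windows])
    M = sp.csr_matrix((np.ones(cols.size), (rows, cols)),
                      shape=(len(windows), n))
    e_Z = M @ expected
    n_Z = M @ observed
    llr = window_llr(n_Z, e_Z, n_G, e_G)

    # null distribution of the maximum LLR
    probs = expected / e_G
    max_llr_null = np.empty(n_mc)
    chunk = max(1, int(2e7 // max(len(windows), 1)))
    done = 0
    while done < n_mc:
        m = min(chunk, n_mc - done)
        counts = rng.multinomial(int(round(n_G)), probs, size=m)
        nZ_rep = (M @ counts.T).T  # (replicates, windows)
        llr_rep = window_llr(nZ_rep, e_Z[None, :], float(np.round(n_G)), e_G)
        max_llr_null[done:done + m] = llr_rep.max(axis=1)
        done += m

    # greedy non-overlapping reporting by decreasing LLR
    order = np.argsort(-llr, kind="stable")
    taken = np.zeros(n, dtype=bool)
    clusters: list[ScanWindow] = []
    for w_idx in order:
        if llr[w_idx] <= 0 or len(clusters) >= max_reported:
            break
        members = np.asarray(windows[w_idx])
        if taken[members].any():
            continue
        taken[members] = True
        p = (1 + np.count_nonzero(max_llr_null >= llr[w_idx])) / (1 + n_mc)
        clusters.append(ScanWindow(
            region_ids=tuple(counties.ids[j] for j in members),
            n_Z=float(n_Z[w_idx]), e_Z=float(e_Z[w_idx]),
            llr=float(llr[w_idx]), p_value=float(p)))
    return ScanResult(clusters=clusters, alpha=alpha, n_mc=n_mc)
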