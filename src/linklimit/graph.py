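"""Undirected simple graph model, random-graph generators, and perturbation
operations (shuffle, add/remove, combine, ring-lattice admixture).

All randomness flows through an explicit integer seed per call; there is no
global random state anywhere in the package.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "UndirectedGraph",
    "PerturbationSpec",
    "er_graph",
    "shuffle_links",
    "perturb_links",
    "combine",
    "circle_model",
    "chung_lu_q_matrix",
    "powerlaw_degree_sequence",
]


def _canon(u: int, v: int) -> tuple[int, int]:
    return (u, v) if u < v else (v, u)


@dataclass
class UndirectedGraph:
    """A simple undirected graph on nodes ``0..n-1``.

    Edges are stored as a set of ``(u, v)`` tuples with ``u < v``; no
    self-loops, no duplicates.  ``labels`` optionally maps the contiguous
    integer ids back to the original node labels of an input file.
    """

    n: int
    edges: set = field(default_factory=set)
    labels: Optional[list] = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("node count must be >= 1")
        canon = set()
        for u, v in self.edges:
            if u == v:
                raise ValueError(f"self-loop at node {u}")
            if not (0 <= u < self.n and 0 <= v < self.n):
                raise ValueError(f"edge ({u}, {v}) out of range for n={self.n}")
            canon.add(_canon(u, v))
        self.edges = canon

    # -- derived quantities -------------------------------------------------
    @property
    def num_edges(self) -> int:
        return len(self.edges)

    @property
    def max_edges(self) -> int:
        return self.n * (self.n - 1) // 2

    @property
    def density(self) -> float:
        return self.num_edges / self.max_edges if self.max_edges else 0.0

    @property
    def average_degree(self) -> float:
        return 2.0 * self.num_edges / self.n

    def degrees(self) -> np.ndarray:
        k = np.zeros(self.n, dtype=np.int64)
        for u, v in self.edges:
            k[u] += 1
            k[v] += 1
        return k

    def adjacency_matrix(self) -> np.ndarray:
        """Dense boolean adjacency matrix."""
        a = np.zeros((self.n, self.n), dtype=bool)
        if self.edges:
            e = np.array(sorted(self.edges), dtype=np.int64)
            a[e[:, 0], e[:, 1]] = True
            a[e[:, 1], e[:, 0]] = True
        return a

    def edge_array(self) -> np.ndarray:
        """Edges as an ``(E, 2)`` integer array in sorted order."""
        if not self.edges:
            return np.empty((0, 2), dtype=np.int64)
        return np.array(sorted(self.edges), dtype=np.int64)

    def has_edge(self, u: int, v: int) -> bool:
        return _canon(u, v) in self.edges

    def copy(self) -> "UndirectedGraph":
        return UndirectedGraph(self.n, set(self.edges), list(self.labels) if self.labels else None)

    def __eq__(self, other) -> bool:
        return isinstance(other, UndirectedGraph) and self.n == other.n and self.edges == other.edges

    def validity_band_warning(self) -> Optional[str]:
        """Warn when the graph is outside ``ln N << <k> << N - ln N``, the
        band where the compression-length normalization is meaningful."""
        k = self.average_degree
        ln_n = math.log(self.n) if self.n > 1 else 0.0
        if k <= ln_n or k >= self.n - ln_n:
            msg = (
                f"average degree {k:.2f} outside the validity band "
                f"ln N ({ln_n:.2f}) << <k> << N - ln N ({self.n - ln_n:.2f}); "
                "normalized quantities may be unreliable"
            )
            warnings.warn(msg)
            return msg
        return None


@dataclass
class PerturbationSpec:
    """Specification of a random perturbation of a graph's edge set.

    ``mode`` is one of ``shuffle``/``add``/``remove``.  The perturbation size
    is given either as a fraction ``f`` of the current edge count or as an
    absolute ``count``.
    """

    mode: str
    fraction: Optional[float] = None
    count: Optional[int] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("shuffle", "add", "remove"):
            raise ValueError(f"unknown perturbation mode {self.mode!r}")
        if (self.fraction is None) == (self.count is None):
            raise ValueError("exactly one of fraction/count must be given")
        if self.fraction is not None and not 0.0 <= self.fraction <= 1.0:
            raise ValueError("fraction must lie in [0, 1]")
        if self.count is not None and self.count < 0:
            raise ValueError("count must be >= 0")

    def resolve_count(self, g: UndirectedGraph) -> int:
        if self.count is not None:
            return self.count
        # round-half-up; fraction always refers to the current edge count
        return int(math.floor(self.fraction * g.num_edges + 0.5))


# ---------------------------------------------------------------------------
# pair-index helpers: bijection between upper-triangle pairs (i<j) and
# linear indices 0..C(n,2)-1 in row-major order.
# ---------------------------------------------------------------------------

def _pairs_to_indices(n: int, u: np.ndarray, v: np.ndarray) -> np.ndarray:
    u = np.asarray(u, dtype=np.int64)
    v = np.asarray(v, dtype=np.int64)
    return u * n - u * (u + 1) // 2 + (v - u - 1)


def _indices_to_pairs(n: int, idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    idx = np.asarray(idx, dtype=np.int64)
    row_start = np.concatenate(([0], np.cumsum(n - 1 - np.arange(n - 1, dtype=np.int64))))
    u = np.searchsorted(row_start, idx, side="right") - 1
    v = idx - row_start[u] + u + 1
    return u, v


def _sample_vacant(n: int, occupied: np.ndarray, m: int, rng: np.random.Generator) -> np.ndarray:
    """Sample ``m`` distinct vacant pair indices uniformly at random."""
    total = n * (n - 1) // 2
    vacant = total - occupied.size
    if m > vacant:
        raise ValueError(f"cannot place {m} new edges; only {vacant} vacant pairs")
    if m == 0:
        return np.empty(0, dtype=np.int64)
    if total <= 4_000_000:
        mask = np.ones(total, dtype=bool)
        mask[occupied] = False
        pool = np.nonzero(mask)[0]
        return rng.choice(pool, size=m, replace=False)
    # rejection sampling for very large graphs
    occ = set(int(i) for i in occupied)
    chosen: set[int] = set()
    while len(chosen) < m:
        draw = rng.integers(0, total, size=2 * (m - len(chosen)) + 16)
        for d in draw:
            d = int(d)
            if d not in occ and d not in chosen:
                chosen.add(d)
                if len(chosen) == m:
                    break
    return np.fromiter(chosen, dtype=np.int64, count=m)


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def er_graph(n: int, e: int, seed: int = 0) -> UndirectedGraph:
    """Erdős–Rényi graph in the fixed-edge-count G(n, M) convention:
    exactly ``e`` edges drawn uniformly without replacement."""
    total = n * (n - 1) // 2
    if not 0 <= e <= total:
        raise ValueError(f"edge count {e} out of range [0, {total}]")
    rng = np.random.default_rng(seed)
    idx = _sample_vacant(n, np.empty(0, dtype=np.int64), e, rng)
    u, v = _indices_to_pairs(n, idx)
    return UndirectedGraph(n, set(zip(u.tolist(), v.tolist())))


def circle_model(n: int, k_c: int) -> UndirectedGraph:
    """Ring lattice: node ``i`` linked to its ``k_c`` closest nodes, i.e.
    ``i +- 1 .. i +- k_c/2`` (mod n).  ``k_c`` must be even."""
    if k_c % 2 != 0:
        raise ValueError("k_c must be even")
    if not 2 <= k_c < n:
        raise ValueError("k_c must satisfy 2 <= k_c < n")
    edges = set()
    for i in range(n):
        for d in range(1, k_c // 2 + 1):
            edges.add(_canon(i, (i + d) % n))
    return UndirectedGraph(n, edges)


def chung_lu_q_matrix(degrees: Sequence[int]) -> np.ndarray:
    """Edge-probability matrix with ``q_ij = min(1, k_i k_j / sum(k))``,
    symmetric with zero diagonal."""
    k = np.asarray(degrees, dtype=np.float64)
    if np.any(k < 0):
        raise ValueError("degrees must be >= 0")
    s = k.sum()
    if s <= 0:
        raise ValueError("degree sequence sums to zero")
    if int(round(s)) % 2 != 0:
        raise ValueError("degree sequence must have an even sum")
    q = np.minimum(1.0, np.outer(k, k) / s)
    np.fill_diagonal(q, 0.0)
    return q


def powerlaw_degree_sequence(
    n: int,
    mean_degree: float,
    gamma: float = 2.5,
    k_max: Optional[int] = None,
    seed: int = 0,
) -> np.ndarray:
    """Heavy-tailed integer degree sequence with the given mean.

    Degrees are drawn from a Pareto tail with exponent ``gamma``, rescaled to
    the target mean, capped at ``k_max`` (default ``0.8*sqrt(n*mean_degree)``
    so that no Chung-Lu probability gets clipped at 1), and adjusted to an
    even sum.
    """
    rng = np.random.default_rng(seed)
    raw = rng.pareto(gamma - 1.0, size=n) + 1.0
    k = raw * (mean_degree / raw.mean())
    cap = k_max if k_max is not None else max(2.0, 0.8 * math.sqrt(n * mean_degree))
    k = np.clip(k, 1.0, cap)
    k = k * (mean_degree / k.mean())
    k = np.maximum(1, np.round(k)).astype(np.int64)
    if k.sum() % 2 != 0:
        k[int(np.argmin(k))] += 1
    return k


# ---------------------------------------------------------------------------
# perturbations
# ---------------------------------------------------------------------------

def shuffle_links(g: UndirectedGraph, f: float, seed: int = 0) -> UndirectedGraph:
    """Rewire a fraction ``f`` of links: remove ``round(f*E)`` edges at random
    and add the same number of edges uniformly among vacant pairs (replacement
    edges may coincide with removed ones).  ``n`` and ``E`` are preserved;
    at ``f = 1`` the result is distributed as G(n, E)."""
    if not 0.0 <= f <= 1.0:
        raise ValueError("shuffle fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    m = int(math.floor(f * g.num_edges + 0.5))
    edges = g.edge_array()
    if m == 0:
        return UndirectedGraph(g.n, set(g.edges))
    keep_mask = np.ones(g.num_edges, dtype=bool)
    keep_mask[rng.choice(g.num_edges, size=m, replace=False)] = False
    kept = edges[keep_mask]
    occupied = _pairs_to_indices(g.n, kept[:, 0], kept[:, 1])
    new_idx = _sample_vacant(g.n, occupied, m, rng)
    nu, nv = _indices_to_pairs(g.n, new_idx)
    es = set(zip(kept[:, 0].tolist(), kept[:, 1].tolist()))
    es.update(zip(nu.tolist(), nv.tolist()))
    return UndirectedGraph(g.n, es)


def perturb_links(g: UndirectedGraph, spec: PerturbationSpec) -> UndirectedGraph:
    """Apply a :class:`PerturbationSpec` (random addition or removal of links,
    or a shuffle) and return the perturbed graph."""
    if spec.mode == "shuffle":
        f = spec.fraction if spec.fraction is not None else spec.count / max(g.num_edges, 1)
        return shuffle_links(g, f, spec.seed)
    rng = np.random.default_rng(spec.seed)
    m = spec.resolve_count(g)
    if spec.mode == "remove":
        if m > g.num_edges:
            raise ValueError(f"cannot remove {m} edges from a graph with {g.num_edges}")
        edges = g.edge_array()
        keep_mask = np.ones(g.num_edges, dtype=bool)
        if m:
            keep_mask[rng.choice(g.num_edges, size=m, replace=False)] = False
        kept = edges[keep_mask]
        return UndirectedGraph(g.n, set(zip(kept[:, 0].tolist(), kept[:, 1].tolist())))
    # add
    edges = g.edge_array()
    occupied = _pairs_to_indices(g.n, edges[:, 0], edges[:, 1]) if g.num_edges else np.empty(0, dtype=np.int64)
    new_idx = _sample_vacant(g.n, occupied, m, rng)
    nu, nv = _indices_to_pairs(g.n, new_idx)
    es = set(g.edges)
    es.update(zip(nu.tolist(), nv.tolist()))
    return UndirectedGraph(g.n, es)


def combine(ga: UndirectedGraph, gb: UndirectedGraph) -> UndirectedGraph:
    """Union of two graphs on the same node set with disjoint edge sets.

    Overlapping edges are an error: the additivity argument for compression
    lengths assumes independent, non-overlapping link sets.
    """
    if ga.n != gb.n:
        raise ValueError(f"node counts differ: {ga.n} != {gb.n}")
    overlap = ga.edges & gb.edges
    if overlap:
        raise ValueError(f"edge sets overlap on {len(overlap)} pair(s), e.g. {next(iter(overlap))}")
    return UndirectedGraph(ga.n, ga.edges | gb.edges)
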