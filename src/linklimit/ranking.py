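"""Leave-one-out ranking of existing links.

For each edge ``e_i = (u, v)`` of the graph: remove it, score every unlinked
pair of the reduced graph (which now includes ``e_i`` itself; there are
``M = C(N,2) - E + 1`` candidates), and record the descending-score rank
``r_i`` of the removed edge with mid-rank tie correction.  The sequence
``D = (r_1, ..., r_E)`` is the raw material of all predictability measures.

Two drivers produce identical results: a naive one rescoring the full
matrix per removal, and a fast one using each index's exact incremental
updates.  They are cross-checked in the tests.

Tie handling matters: similarity scores are heavily tied (e.g. all pairs
without common neighbours score 0), and the rank of the removed edge inside
its tie block is unobservable.  The default draws it uniformly at random
(seeded), which reproduces the uniform rank distribution of uninformative
algorithms on Erdős–Rényi graphs; ``tie_break="midrank"`` gives the
deterministic expected rank instead.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .algorithms import SimilarityIndex, get_algorithm
from .graph import UndirectedGraph

__all__ = ["ScoreTable", "RankSequence", "score_pairs", "leave_one_out_ranks"]

# tie tolerance: floating-point scores assembled along different update paths
# can differ in the last couple of ulps
_REL_TOL = 1e-9
_ABS_TOL = 1e-12


@dataclass
class ScoreTable:
    algorithm: str
    params: dict
    scores: dict  # (u, v) canonical pair -> float


@dataclass
class RankSequence:
    """Ranks ``r_i`` (one per edge, in the order of ``edges``), with the
    candidate-set size ``M = C(N,2) - E + 1`` and node count ``n``."""

    ranks: np.ndarray
    m: int
    n: int
    edges: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.ranks = np.asarray(self.ranks, dtype=np.float64)
        if self.ranks.size and (self.ranks.min() < 1.0 or self.ranks.max() > self.m):
            raise ValueError("ranks must lie in [1, M]")


def _merged_params(alg: SimilarityIndex, params: Optional[dict]) -> dict:
    merged = dict(alg.default_params)
    if params:
        unknown = set(params) - set(alg.default_params)
        if unknown and alg.default_params:
            raise ValueError(f"unknown params for {alg.name}: {sorted(unknown)}")
        merged.update(params)
    return merged


def score_pairs(
    g: UndirectedGraph,
    pairs,
    algorithm: str,
    params: Optional[dict] = None,
    seed: int = 0,
) -> ScoreTable:
    """Score the given node pairs on ``g`` with the named index."""
    alg = get_algorithm(algorithm)
    p = _merged_params(alg, params)
    rng = np.random.default_rng(seed)
    s = alg.score_matrix(g.adjacency_matrix(), g.degrees(), p, rng)
    table = {}
    for u, v in pairs:
        if u == v:
            raise ValueError("cannot score a self-pair")
        key = (u, v) if u < v else (v, u)
        table[key] = float(s[key[0], key[1]])
    return ScoreTable(algorithm=alg.name, params=p, scores=table)


def _nonedge_pairs(adj: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mask = ~adj
    iu, iv = np.nonzero(np.triu(mask, k=1))
    return iu, iv


def _tol(s: float) -> float:
    return max(_ABS_TOL, _REL_TOL * abs(s))


def _rank(greater: int, ties_others: int, tie_rng: Optional[np.random.Generator]) -> float:
    if tie_rng is None:
        # mid-rank: (#strictly higher) + (#ties incl. the removed pair + 1)/2
        return greater + (ties_others + 2) / 2.0
    return greater + 1.0 + float(tie_rng.integers(ties_others + 1))


class _FastContext:
    """Shared state for the fast leave-one-out driver."""

    def __init__(self, g: UndirectedGraph, alg: SimilarityIndex, params: dict,
                 rng: np.random.Generator) -> None:
        self.adj = g.adjacency_matrix()
        self.deg = g.degrees()
        self.nbrs = [np.nonzero(self.adj[i])[0] for i in range(g.n)]
        self.s0 = alg.score_matrix(self.adj, self.deg, params, rng)
        a = self.adj.astype(np.float64)
        self.cn0 = a @ a
        iu, iv = _nonedge_pairs(self.adj)
        self.iu, self.iv = iu, iv
        self.vals = self.s0[iu, iv]
        self.sorted_vals = np.sort(self.vals)
        pair_pos = np.full((g.n, g.n), -1, dtype=np.int64)
        pair_pos[iu, iv] = np.arange(iu.size)
        pair_pos[iv, iu] = np.arange(iu.size)
        self.pair_pos = pair_pos


def _fast_loo(g: UndirectedGraph, alg: SimilarityIndex, params: dict,
              seed: int, edges: list, tie_rng) -> np.ndarray:
    ctx = _FastContext(g, alg, params, np.random.default_rng(seed))
    sv = ctx.sorted_vals
    n_all = sv.size
    ranks = np.empty(len(edges), dtype=np.float64)
    for i, (u, v) in enumerate(edges):
        (pos, new), s_e = alg.loo_updates(ctx, u, v)
        tol = _tol(s_e)
        hi, lo = s_e + tol, s_e - tol
        greater = n_all - int(np.searchsorted(sv, hi, side="right"))
        ties = int(np.searchsorted(sv, hi, side="right")) - int(np.searchsorted(sv, lo, side="left"))
        if pos.size:
            old = ctx.vals[pos]
            greater += int((new > hi).sum()) - int((old > hi).sum())
            ties += int(((new >= lo) & (new <= hi)).sum()) - int(((old >= lo) & (old <= hi)).sum())
        ranks[i] = _rank(greater, ties, tie_rng)
    return ranks


def _naive_loo(g: UndirectedGraph, alg: SimilarityIndex, params: dict,
               seed: int, edges: list, tie_rng) -> np.ndarray:
    adj = g.adjacency_matrix()
    deg = g.degrees()
    iu, iv = _nonedge_pairs(adj)
    ranks = np.empty(len(edges), dtype=np.float64)
    for i, (u, v) in enumerate(edges):
        adj[u, v] = adj[v, u] = False
        deg[u] -= 1
        deg[v] -= 1
        rng = np.random.default_rng([seed, i])
        try:
            s = alg.score_matrix(adj, deg, params, rng)
        except Exception as exc:  # noqa: BLE001 - re-raise with edge context
            raise RuntimeError(f"algorithm {alg.name} failed on removal of edge ({u}, {v}): {exc}") from exc
        finally:
            adj[u, v] = adj[v, u] = True
            deg[u] += 1
            deg[v] += 1
        s_e = float(s[u, v])
        others = s[iu, iv]
        tol = _tol(s_e)
        greater = int((others > s_e + tol).sum())
        ties = int((np.abs(others - s_e) <= tol).sum())
        ranks[i] = _rank(greater, ties, tie_rng)
    return ranks


def leave_one_out_ranks(
    g: UndirectedGraph,
    algorithm: str,
    params: Optional[dict] = None,
    seed: int = 0,
    tie_break: str = "random",
    force_naive: bool = False,
) -> RankSequence:
    """Compute the leave-one-out rank sequence ``D`` for all edges of ``g``
    (edges processed in sorted order).

    ``tie_break``: ``"random"`` (default) places the removed edge uniformly
    at random inside its score-tie block (seeded); ``"midrank"`` uses the
    deterministic expected position, which may be fractional.
    """
    if g.num_edges < 1:
        raise ValueError("graph has no edges to rank")
    if tie_break not in ("random", "midrank"):
        raise ValueError("tie_break must be 'random' or 'midrank'")
    alg = get_algorithm(algorithm)
    p = _merged_params(alg, params)
    edges = sorted(g.edges)
    m = g.max_edges - g.num_edges + 1
    tie_rng = np.random.default_rng([seed, 7]) if tie_break == "random" else None
    use_fast = alg.supports_fast_loo and not force_naive
    if use_fast:
        ranks = _fast_loo(g, alg, p, seed, edges, tie_rng)
    else:
        ranks = _naive_loo(g, alg, p, seed, edges, tie_rng)
    return RankSequence(ranks=ranks, m=m, n=g.n, edges=edges)
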