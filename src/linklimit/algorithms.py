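"""Similarity indices for link prediction.

Every index exposes ``score_matrix(adj, deg, params, rng)`` returning a full
symmetric score matrix (higher = more likely link).  The local indices
additionally implement exact incremental rescoring under single-edge removal
(``loo_updates``), which the leave-one-out driver uses to avoid recomputing
the full matrix for every removed edge; the incremental path is verified
against the naive one in the test suite.
"""
from __future__ import annotations

import math
from typing import Optional

import numpy as np

__all__ = ["get_algorithm", "registered_algorithms", "SimilarityIndex"]

_LN = np.log


def _safe_inv(x: np.ndarray) -> np.ndarray:
    out = np.zeros_like(x, dtype=np.float64)
    np.divide(1.0, x, out=out, where=x > 0)
    return out


def _inv_log(k: np.ndarray) -> np.ndarray:
    """1/ln(k) for k >= 2, else 0 (a common neighbour always has degree >= 2)."""
    out = np.zeros(k.shape, dtype=np.float64)
    mask = k >= 2
    out[mask] = 1.0 / _LN(k[mask].astype(np.float64))
    return out


class SimilarityIndex:
    name: str = "?"
    stochastic: bool = False
    supports_fast_loo: bool = False
    default_params: dict = {}

    def score_matrix(self, adj: np.ndarray, deg: np.ndarray, params: dict,
                     rng: Optional[np.random.Generator] = None) -> np.ndarray:
        raise NotImplementedError

    # fast leave-one-out interface -----------------------------------------
    def loo_updates(self, ctx: "object", u: int, v: int):
        """Return ``(positions, new_scores, s_e)``: the non-edge candidate
        positions whose score changes when edge (u, v) is removed, their new
        scores, and the score of the removed pair itself in G - e."""
        raise NotImplementedError


# ---------------------------------------------------------------------------
# local neighbourhood indices (all with exact fast LOO updates)
# ---------------------------------------------------------------------------

class CommonNeighbors(SimilarityIndex):
    name = "CN"
    supports_fast_loo = True

    def score_matrix(self, adj, deg, params, rng=None):
        a = adj.astype(np.float64)
        return a @ a

    def loo_updates(self, ctx, u, v):
        pos, delta = [], []
        for a, b in ((u, v), (v, u)):
            x = ctx.nbrs[b]
            x = x[x != a]
            if x.size:
                p = ctx.pair_pos[a, x]
                p = p[p >= 0]
                if p.size:
                    pos.append(p)
                    delta.append(np.full(p.size, -1.0))
        return _aggregate(ctx, pos, delta), float(ctx.s0[u, v])


def _weighted_cn_updates(ctx, u, v, w, w_after):
    """Shared fast-LOO logic for RA / AA style indices: score is a sum of a
    weight ``w(k_w)`` over common neighbours ``w``."""
    deg = ctx.deg
    pos, delta = [], []
    # v disappears from N(u): every non-edge (u, x) with x ~ v loses w(k_v)
    for a, b in ((u, v), (v, u)):
        x = ctx.nbrs[b]
        x = x[x != a]
        if x.size:
            p = ctx.pair_pos[a, x]
            keep = p >= 0
            if keep.any():
                pos.append(p[keep])
                delta.append(np.full(int(keep.sum()), -w[deg[b]]))
    # u's (and v's) degree drops: its weight changes wherever it stays a
    # common neighbour, i.e. for non-edge pairs inside N(u)\{v}
    for a, b in ((u, v), (v, u)):
        nb = ctx.nbrs[a]
        nb = nb[nb != b]
        if nb.size >= 2:
            sub = ~ctx.adj[np.ix_(nb, nb)]
            ii, jj = np.triu_indices(nb.size, k=1)
            keep = sub[ii, jj]
            if keep.any():
                p = ctx.pair_pos[nb[ii[keep]], nb[jj[keep]]]
                pos.append(p)
                delta.append(np.full(p.size, w_after[deg[a]] - w[deg[a]]))
    return _aggregate(ctx, pos, delta)


class ResourceAllocation(SimilarityIndex):
    name = "RA"
    supports_fast_loo = True

    def score_matrix(self, adj, deg, params, rng=None):
        a = adj.astype(np.float64)
        return (a * _safe_inv(deg.astype(np.float64))[None, :]) @ a

    def loo_updates(self, ctx, u, v):
        kmax = int(ctx.deg.max()) + 1
        w = _safe_inv(np.arange(kmax, dtype=np.float64))
        w_after = _safe_inv(np.arange(kmax, dtype=np.float64) - 1.0)
        upd = _weighted_cn_updates(ctx, u, v, w, w_after)
        return upd, float(ctx.s0[u, v])


class AdamicAdar(SimilarityIndex):
    name = "AA"
    supports_fast_loo = True

    def score_matrix(self, adj, deg, params, rng=None):
        a = adj.astype(np.float64)
        return (a * _inv_log(deg)[None, :]) @ a

    def loo_updates(self, ctx, u, v):
        kmax = int(ctx.deg.max()) + 1
        ks = np.arange(kmax)
        w = _inv_log(ks)
        w_after = _inv_log(ks - 1)
        upd = _weighted_cn_updates(ctx, u, v, w, w_after)
        return upd, float(ctx.s0[u, v])


class PreferentialAttachment(SimilarityIndex):
    name = "PA"
    supports_fast_loo = True

    def score_matrix(self, adj, deg, params, rng=None):
        k = deg.astype(np.float64)
        return np.outer(k, k)

    def loo_updates(self, ctx, u, v):
        deg = ctx.deg.astype(np.float64)
        pos, new = [], []
        for a in (u, v):
            p = ctx.pair_pos[a]
            keep = p >= 0
            x = np.nonzero(keep)[0]
            if x.size:
                pos.append(p[keep])
                new.append((deg[a] - 1.0) * deg[x])
        s_e = (deg[u] - 1.0) * (deg[v] - 1.0)
        return (np.concatenate(pos), np.concatenate(new)), s_e


class Jaccard(SimilarityIndex):
    name = "Jaccard"
    supports_fast_loo = True

    def score_matrix(self, adj, deg, params, rng=None):
        a = adj.astype(np.float64)
        cn = a @ a
        denom = deg[:, None] + deg[None, :] - cn
        return np.divide(cn, denom, out=np.zeros_like(cn), where=denom > 0)

    def loo_updates(self, ctx, u, v):
        return _ratio_updates(ctx, u, v, kind="jaccard")


class Salton(SimilarityIndex):
    name = "Salton"
    supports_fast_loo = True

    def score_matrix(self, adj, deg, params, rng=None):
        a = adj.astype(np.float64)
        cn = a @ a
        denom = np.sqrt(np.outer(deg, deg).astype(np.float64))
        return np.divide(cn, denom, out=np.zeros_like(cn), where=denom > 0)

    def loo_updates(self, ctx, u, v):
        return _ratio_updates(ctx, u, v, kind="salton")


def _ratio_updates(ctx, u, v, kind):
    """Fast LOO for CN-over-degree ratios: every non-edge touching u or v is
    affected (endpoint degree changes), nothing else."""
    deg = ctx.deg.astype(np.float64)
    adj = ctx.adj
    pos, new = [], []
    for a, b in ((u, v), (v, u)):
        p = ctx.pair_pos[a]
        keep = p >= 0
        x = np.nonzero(keep)[0]
        if not x.size:
            continue
        cn = ctx.cn0[a, x] - adj[b, x]  # b leaves N(a)
        ka = deg[a] - 1.0
        if kind == "jaccard":
            denom = ka + deg[x] - cn
        else:
            denom = np.sqrt(ka * deg[x])
        s = np.divide(cn, denom, out=np.zeros_like(cn), where=denom > 0)
        pos.append(p[keep])
        new.append(s)
    cn_e = float(ctx.cn0[u, v])
    ka, kb = deg[u] - 1.0, deg[v] - 1.0
    if kind == "jaccard":
        denom = ka + kb - cn_e
    else:
        denom = math.sqrt(ka * kb) if ka > 0 and kb > 0 else 0.0
    s_e = cn_e / denom if denom > 0 else 0.0
    return (np.concatenate(pos), np.concatenate(new)), s_e


def _aggregate(ctx, pos, delta):
    """Merge (position, delta) fragments into unique positions + new scores."""
    if not pos:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.float64)
    p = np.concatenate(pos)
    d = np.concatenate(delta)
    uniq, inv = np.unique(p, return_inverse=True)
    agg = np.bincount(inv, weights=d)
    return uniq, ctx.vals[uniq] + agg


# ---------------------------------------------------------------------------
# path / spectral indices (naive full-matrix rescoring only)
# ---------------------------------------------------------------------------

class LocalPath(SimilarityIndex):
    name = "LP"
    default_params = {"epsilon": 0.001}

    def score_matrix(self, adj, deg, params, rng=None):
        a = adj.astype(np.float64)
        a2 = a @ a
        return a2 + params["epsilon"] * (a2 @ a)


class Katz(SimilarityIndex):
    name = "Katz"
    default_params = {"beta": None}  # None -> 0.5 / lambda_max

    def score_matrix(self, adj, deg, params, rng=None):
        a = adj.astype(np.float64)
        n = a.shape[0]
        lam_max = float(np.linalg.eigvalsh(a)[-1]) if deg.sum() else 0.0
        beta = params.get("beta")
        if beta is None:
            beta = 0.5 / lam_max if lam_max > 0 else 0.0
        elif lam_max > 0 and beta >= 1.0 / lam_max:
            raise ValueError(f"Katz beta={beta} must be < 1/lambda_max = {1.0 / lam_max:.6g}")
        if beta == 0.0:
            return np.zeros_like(a)
        return np.linalg.inv(np.eye(n) - beta * a) - np.eye(n)


class AverageCommuteTime(SimilarityIndex):
    name = "ACT"

    def score_matrix(self, adj, deg, params, rng=None):
        a = adj.astype(np.float64)
        lap = np.diag(deg.astype(np.float64)) - a
        lp = np.linalg.pinv(lap)
        d = np.diag(lp)
        denom = d[:, None] + d[None, :] - 2.0 * lp
        return np.divide(1.0, denom, out=np.zeros_like(denom), where=denom > 1e-12)


class LocalRandomWalk(SimilarityIndex):
    name = "LRW"
    default_params = {"steps": 3}

    def score_matrix(self, adj, deg, params, rng=None):
        a = adj.astype(np.float64)
        e2 = float(deg.sum())
        if e2 == 0:
            return np.zeros_like(a)
        p = a * _safe_inv(deg.astype(np.float64))[:, None]
        pt = np.linalg.matrix_power(p, int(params["steps"]))
        q = deg.astype(np.float64) / e2
        half = q[:, None] * pt
        return half + half.T


class StructuralPerturbation(SimilarityIndex):
    """Structural perturbation method: remove a random fraction of links,
    perturb the spectrum of the reduced adjacency matrix to first order, and
    score pairs by the perturbed reconstruction, averaged over repetitions.

    Near-degenerate eigenvalues (relative gap < ``degeneracy_tol``) are
    handled as a block: the perturbation is projected onto the whole
    eigenspace rather than individual vectors.
    """

    name = "SPM"
    stochastic = True
    default_params = {"fraction": 0.1, "repetitions": 10, "degeneracy_tol": 1e-10}

    def score_matrix(self, adj, deg, params, rng=None):
        if rng is None:
            rng = np.random.default_rng(0)
        a = adj.astype(np.float64)
        n = a.shape[0]
        iu, iv = np.nonzero(np.triu(adj, k=1))
        n_edges = iu.size
        if n_edges == 0:
            return np.zeros_like(a)
        n_remove = max(1, int(math.ceil(params["fraction"] * n_edges)))
        tol = params["degeneracy_tol"]
        acc = np.zeros_like(a)
        for _ in range(int(params["repetitions"])):
            sel = rng.choice(n_edges, size=n_remove, replace=False)
            da = np.zeros_like(a)
            da[iu[sel], iv[sel]] = 1.0
            da[iv[sel], iu[sel]] = 1.0
            ar = a - da
            lam, x = np.linalg.eigh(ar)
            m = x.T @ da @ x
            # block-diagonal projection of the perturbation onto (near-)
            # degenerate eigenspaces
            gaps = np.diff(lam) > tol * np.maximum(1.0, np.abs(lam[:-1]))
            bounds = np.concatenate(([0], np.nonzero(gaps)[0] + 1, [n]))
            z = np.zeros_like(m)
            for b0, b1 in zip(bounds[:-1], bounds[1:]):
                z[b0:b1, b0:b1] = m[b0:b1, b0:b1]
            acc += ar + x @ z @ x.T
        return acc / float(params["repetitions"])


_REGISTRY: dict[str, SimilarityIndex] = {}
for _cls in (
    CommonNeighbors, Jaccard, ResourceAllocation, AdamicAdar,
    PreferentialAttachment, Salton, LocalPath, Katz,
    AverageCommuteTime, LocalRandomWalk, StructuralPerturbation,
):
    _inst = _cls()
    _REGISTRY[_inst.name.lower()] = _inst


def registered_algorithms() -> list[str]:
    return [a.name for a in _REGISTRY.values()]


def get_algorithm(name: str) -> SimilarityIndex:
    try:
        return _REGISTRY[name.lower()]
    except KeyError:
        raise ValueError(
            f"unknown algorithm {name!r}; registered: {registered_algorithms()}"
        ) from None
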