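"""Edge-independent random-graph theory.

For an artificial network generated from a symmetric probability matrix
``Q = (q_ij)``, the structural entropy, the entropy ``H_Q`` of the link
probabilities, its width-``N`` coarse-grained version, and the analytic
performance of the theoretical best predicting algorithm (which scores pairs
by ``q_ij`` itself) are all available in closed form; together they yield a
linear relation between normalized compression length and normalized
prediction entropy, with three variants of slope/intercept depending on the
level of approximation.

All logs are base 2; ``<k>`` is always derived from ``Q`` as an expectation,
``(2/N) * sum_{i>j} q_ij``.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .compress import binary_entropy, max_compression_length
from .graph import UndirectedGraph

__all__ = [
    "TheoryLine",
    "validate_q",
    "u_term",
    "structural_entropy",
    "q_entropy",
    "coarse_grained_entropy",
    "h_tbpa_analytic",
    "h_tbpa_numeric",
    "theory_line",
    "sample_from_q",
    "average_degree_from_q",
]


@dataclass
class TheoryLine:
    slope: float
    intercept: float
    variant: str
    n: int
    k: float


def validate_q(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=np.float64)
    if q.ndim != 2 or q.shape[0] != q.shape[1]:
        raise ValueError("Q must be a square matrix")
    if not np.allclose(q, q.T):
        raise ValueError("Q must be symmetric")
    if np.any(np.diag(q) != 0):
        raise ValueError("Q must have a zero diagonal")
    if q.min() < 0 or q.max() > 1:
        raise ValueError("Q entries must lie in [0, 1]")
    return q


def _upper(q: np.ndarray) -> np.ndarray:
    n = q.shape[0]
    iu, iv = np.triu_indices(n, k=1)
    return q[iu, iv]


def average_degree_from_q(q: np.ndarray) -> float:
    q = validate_q(q)
    return 2.0 * _upper(q).sum() / q.shape[0]


def u_term(q: np.ndarray) -> float:
    """``U = -sum_{i>j} q_ij log2 q_ij`` with ``0 log 0 = 0``."""
    vals = _upper(validate_q(q))
    nz = vals[vals > 0]
    return float(-(nz * np.log2(nz)).sum())


@dataclass
class StructuralEntropy:
    exact: float       # sum h(q_ij) - N log2 N
    approx: float      # U - N log2 N + N<k>/(2 ln 2)  (Taylor expansion)
    negative: bool     # exact <= 0: unusable for normalization


def structural_entropy(q: np.ndarray) -> StructuralEntropy:
    """Expected shortest compression length of a graph drawn from ``Q``."""
    q = validate_q(q)
    n = q.shape[0]
    vals = _upper(q)
    inner = vals[(vals > 0) & (vals < 1)]
    h_sum = float(-(inner * np.log2(inner) + (1 - inner) * np.log2(1 - inner)).sum())
    exact = h_sum - n * math.log2(n)
    k = 2.0 * vals.sum() / n
    approx = u_term(q) - n * math.log2(n) + n * k / (2.0 * math.log(2.0))
    negative = exact <= 0
    if negative:
        warnings.warn(f"structural entropy {exact:.2f} <= 0; Q is degenerate for normalization")
    return StructuralEntropy(exact=exact, approx=approx, negative=negative)


def q_entropy(q: np.ndarray) -> float:
    """Shannon entropy ``H_Q`` of the normalized upper-triangle of ``Q``."""
    vals = _upper(validate_q(q))
    total = vals.sum()
    if total <= 0:
        raise ValueError("Q has no mass")
    p = vals[vals > 0] / total
    return float(-(p * np.log2(p)).sum())


def coarse_grained_entropy(q: np.ndarray, n: Optional[int] = None) -> float:
    """Entropy of ``Q`` after replacing every ``n`` sorted values (descending)
    by their average -- equivalently, the entropy of the group masses.
    Approximately ``H_Q - log2 n``; exactly so for uniform ``Q``."""
    q = validate_q(q)
    n = q.shape[0] if n is None else n
    vals = np.sort(_upper(q))[::-1]
    total = vals.sum()
    if total <= 0:
        raise ValueError("Q has no mass")
    n_groups = int(math.ceil(vals.size / n))
    masses = np.add.reduceat(vals, np.arange(0, vals.size, n)) / total
    assert masses.size == n_groups
    nz = masses[masses > 0]
    return float(-(nz * np.log2(nz)).sum())


def h_tbpa_analytic(q: np.ndarray) -> tuple[float, float]:
    """Analytic TBPA entropy ``H_TBPA ~ (2/(N<k>)) U + log2(<k>/2)`` and its
    normalization ``H*_TBPA = H_TBPA / (log2 N - 1)``."""
    q = validate_q(q)
    n = q.shape[0]
    k = average_degree_from_q(q)
    if k <= 0:
        raise ValueError("average degree of Q is zero")
    h = (2.0 / (n * k)) * u_term(q) + math.log2(k / 2.0)
    return h, h / (math.log2(n) - 1.0)


def sample_from_q(q: np.ndarray, seed: int = 0) -> UndirectedGraph:
    """Independent Bernoulli(q_ij) draw for every pair."""
    q = validate_q(q)
    n = q.shape[0]
    rng = np.random.default_rng(seed)
    iu, iv = np.triu_indices(n, k=1)
    vals = q[iu, iv]
    hit = rng.random(vals.size) < vals
    edges = set(zip(iu[hit].tolist(), iv[hit].tolist()))
    return UndirectedGraph(n, edges)


def h_tbpa_numeric(q: np.ndarray, seed: int = 0, samples: int = 20,
                   max_retries: int = 100) -> float:
    """Monte-Carlo TBPA entropy: sample a graph from ``Q``, rank each sampled
    edge's ``q`` value among the ``q`` values of all non-links plus itself
    (edges placed uniformly at random within tie blocks), and bin with width
    ``N``.  The binned probabilities are averaged over ``samples`` draws
    before taking the entropy, which suppresses the finite-sample bias of the
    plug-in estimator."""
    q = validate_q(q)
    n = q.shape[0]
    iu, iv = np.triu_indices(n, k=1)
    vals = q[iu, iv]
    rng = np.random.default_rng(seed)
    dists = []
    attempts = 0
    while len(dists) < samples:
        attempts += 1
        if attempts > samples + max_retries:
            raise RuntimeError("too many empty samples from Q")
        hit = rng.random(vals.size) < vals
        e = int(hit.sum())
        if e == 0:
            continue
        nonlink = np.sort(vals[~hit])
        qe = vals[hit]
        m = nonlink.size + 1
        greater = nonlink.size - np.searchsorted(nonlink, qe, side="right")
        lower = np.searchsorted(nonlink, qe, side="left")
        ties_others = nonlink.size - lower - greater
        ranks = greater + 1 + rng.integers(0, ties_others + 1)
        n_bins = int(math.ceil(m / n))
        idx = np.ceil(ranks / n).astype(np.int64) - 1
        dists.append(np.bincount(idx, minlength=n_bins) / e)
    width = max(d.size for d in dists)
    p = np.zeros(width)
    for d in dists:
        p[: d.size] += d
    p /= len(dists)
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def theory_line(n: int, k: float, variant: str = "eq8") -> TheoryLine:
    """Slope/intercept of the theoretical ``H*_TBPA`` vs ``L*`` line.

    ``eq7``: full finite-size expression (needs a positive ceiling);
    ``eq8``: large-N simplification (slope ``1 - 2/k - log2 k / log2 N``);
    ``eq9``: thermodynamic limit (slope ``1 - 2/k``).
    For eq8/eq9, slope + intercept = 1 exactly.
    """
    if k <= 0:
        raise ValueError("average degree must be positive")
    if variant == "eq9":
        slope = 1.0 - 2.0 / k
        return TheoryLine(slope, 1.0 - slope, "eq9", n, k)
    if variant == "eq8":
        slope = 1.0 - 2.0 / k - math.log2(k) / math.log2(n)
        return TheoryLine(slope, 1.0 - slope, "eq8", n, k)
    if variant == "eq7":
        e = k * n / 2.0
        r = max_compression_length(n, e)  # raises if R <= 0
        log_half_n = math.log2(n / 2.0)
        slope = 2.0 * r / (k * n * log_half_n)
        intercept = (2.0 * math.log2(n) / k + math.log2(k / 2.0) - 1.0 / math.log(2.0)) / log_half_n
        return TheoryLine(slope, intercept, "eq7", n, k)
    raise ValueError(f"unknown variant {variant!r} (expected eq7|eq8|eq9)")
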