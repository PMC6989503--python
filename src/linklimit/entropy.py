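"""Rank-distribution entropy: the predictability measure.

Ranks are binned with width ``N`` into ``B = ceil(M/N)`` (about ``N/2``) bins
so that network size does not contribute to the entropy; the Shannon entropy
``H`` of the binned distribution, normalized by ``log2 N - 1`` (the value for
an Erdős–Rényi network of the same size), is the predictability ``H*``.
``bpaa`` takes the minimum over a suite of algorithms as the closest
available estimate of the theoretical best.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .constants import EMPIRICAL_INTERCEPT, EMPIRICAL_SLOPE
from .graph import UndirectedGraph
from .ranking import RankSequence, leave_one_out_ranks

__all__ = [
    "BinnedRankDistribution",
    "PredictabilityEstimate",
    "bin_ranks",
    "distribution_entropy",
    "normalized_entropy",
    "bpaa",
    "line_gap",
]


@dataclass
class BinnedRankDistribution:
    probabilities: np.ndarray
    bin_width: int
    m: int

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=np.float64)
        if p.size == 0 or np.any(p < 0) or not math.isclose(p.sum(), 1.0, rel_tol=1e-9):
            raise ValueError("probabilities must be non-negative and sum to 1")
        self.probabilities = p


@dataclass
class PredictabilityEstimate:
    algorithm: str
    h: float
    h_star: float
    table: dict = field(default_factory=dict)  # name -> {"H":, "H_star":} or {"error":}


def bin_ranks(d: RankSequence, n: Optional[int] = None) -> BinnedRankDistribution:
    """Bin the rank sequence with width ``n`` (default: the node count):
    rank ``r`` falls in bin ``ceil(r/n)``; the final partial bin is kept."""
    n = d.n if n is None else n
    ranks = d.ranks
    if ranks.size == 0:
        raise ValueError("empty rank sequence")
    if ranks.min() < 1.0 or ranks.max() > d.m:
        raise ValueError("rank out of range [1, M]")
    n_bins = int(math.ceil(d.m / n))
    idx = np.ceil(ranks / n).astype(np.int64) - 1
    counts = np.bincount(idx, minlength=n_bins)
    return BinnedRankDistribution(counts / ranks.size, bin_width=n, m=d.m)


def distribution_entropy(p) -> float:
    """Shannon entropy (bits) with the convention ``0 log 0 = 0``."""
    if isinstance(p, BinnedRankDistribution):
        p = p.probabilities
    p = np.asarray(p, dtype=np.float64)
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def normalized_entropy(h: float, n: int) -> float:
    """``H* = H / (log2 N - 1)``; requires ``N > 2``."""
    if n <= 2:
        raise ValueError("normalization requires N > 2")
    return h / (math.log2(n) - 1.0)


def bpaa(
    g: UndirectedGraph,
    algorithms: Optional[Sequence[str]] = None,
    seed: int = 0,
    params: Optional[dict] = None,
) -> PredictabilityEstimate:
    """Best-prediction-algorithm-available entropy: run the leave-one-out
    procedure for every algorithm and keep the minimum ``H``.

    ``params`` maps algorithm name to a parameter override dict.  Individual
    algorithm failures are recorded in the table; only total failure raises.
    """
    from .algorithms import registered_algorithms

    names = list(algorithms) if algorithms is not None else registered_algorithms()
    if not names:
        raise ValueError("no algorithms given")
    table: dict = {}
    best_name, best_h = None, math.inf
    for name in names:
        try:
            d = leave_one_out_ranks(g, name, params=(params or {}).get(name), seed=seed)
            h = distribution_entropy(bin_ranks(d))
            table[name] = {"H": h, "H_star": normalized_entropy(h, g.n)}
            if h < best_h:
                best_name, best_h = name, h
        except Exception as exc:  # noqa: BLE001 - recorded per algorithm
            table[name] = {"error": str(exc)}
    if best_name is None:
        raise RuntimeError(f"all algorithms failed: {table}")
    return PredictabilityEstimate(
        algorithm=best_name,
        h=best_h,
        h_star=normalized_entropy(best_h, g.n),
        table=table,
    )


def line_gap(l_star: float, h_star: float,
             slope: float = EMPIRICAL_SLOPE, intercept: float = EMPIRICAL_INTERCEPT) -> float:
    """Signed distance of an algorithm's performance from the empirical law
    ``H* = slope * L* + intercept``; positive means room for improvement."""
    return h_star - (slope * l_star + intercept)
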