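"""Entropy-constrained bounds on link-prediction precision, and the
dataset-value estimate.

Given a network's normalized compression length ``L*``, the empirical law
fixes the rank-distribution entropy ``H = (1.63 L* - 0.63)(log2 N - 1)``.
Over all decreasing probability vectors ``p_1 >= ... >= p_{N/2} >= 0`` with
that entropy, the extremal values of the top-``C`` mass ``P_C`` bound the
precision any algorithm can reach.  The upper bounds are roots of explicit
monotone equations (solved by bracketed root finding); the lower bound is a
direct numerical minimization validated against brute force in the tests.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import brentq, minimize

from .compress import max_compression_length
from .constants import EMPIRICAL_INTERCEPT, EMPIRICAL_SLOPE
from .entropy import bin_ranks
from .ranking import RankSequence

__all__ = [
    "PrecisionBounds",
    "ValueEstimate",
    "target_entropy",
    "upper_p1",
    "lower_p1",
    "upper_PC",
    "lower_PC",
    "precision_bounds",
    "commercial_value",
    "precision_from_ranks",
]

_TOL = 1e-10


@dataclass
class PrecisionBounds:
    h_target: float
    n: int
    c: int
    upper: float
    lower: float
    diagnostics: dict = field(default_factory=dict)


@dataclass
class ValueEstimate:
    value: float
    theta: float
    l: float
    ceiling: float
    n: int
    unit_cost: Optional[float] = None
    n_predictions: Optional[int] = None


def target_entropy(l_star: float, n: int,
                   slope: float = EMPIRICAL_SLOPE, intercept: float = EMPIRICAL_INTERCEPT) -> float:
    """Entropy implied by the law: ``(1.63 L* - 0.63)(log2 N - 1)``, clamped
    to 0 (with a warning) below the law's root."""
    h = (slope * l_star + intercept) * (math.log2(n) - 1.0)
    if h < 0:
        warnings.warn(
            f"target entropy {h:.4f} < 0 (L* below the law's root); clamping to 0"
        )
        return 0.0
    return h


def _upper_equation(p: float, c: float, b: float) -> float:
    """Entropy of the extremal distribution: top-``C`` mass ``p`` spread
    evenly over C bins, remainder uniform over ``b - C`` bins."""
    val = 0.0
    if p > 0:
        val -= p * math.log2(p / c)
    if p < 1 and b > c:
        val -= (1.0 - p) * math.log2((1.0 - p) / (b - c))
    return val


def upper_PC(h_target: float, n: int, c: int = 1) -> float:
    """Upper bound on ``P_C``: root of the implicit entropy equation on the
    branch ``P >= 2C/N`` (bisection/Brent to 1e-10)."""
    b = n / 2.0
    if not 1 <= c <= b:
        raise ValueError("C must satisfy 1 <= C <= N/2")
    if not 0.0 <= h_target <= math.log2(b) + _TOL:
        raise ValueError(f"H={h_target} outside [0, log2(N/2)={math.log2(b):.4f}]")
    if h_target <= _TOL:
        return 1.0
    if b - c < 1e-12:
        return 1.0  # degenerate: all bins inside the top block
    if h_target >= math.log2(b) - _TOL:
        return 2.0 * c / n
    lo = 2.0 * c / n
    f = lambda p: _upper_equation(p, float(c), b) - h_target
    if f(1.0) > 0:
        # even P_C = 1 admits entropy H inside the top block
        return 1.0
    return float(brentq(f, lo, 1.0, xtol=_TOL, maxiter=200))


def upper_p1(h_target: float, n: int) -> float:
    """Upper bound on ``p_1`` (the ``C = 1`` case)."""
    return upper_PC(h_target, n, c=1)


def lower_p1(h_target: float) -> float:
    """Explicit lower bound ``p_1 >= 2^(-H)``."""
    if h_target < 0:
        raise ValueError("entropy must be >= 0")
    return 2.0 ** (-h_target)


def _two_level_family(h_target: float, b_int: int, c: int) -> tuple[float, dict]:
    """Candidate minimizer: ``m`` bins at level ``a`` plus one residual bin.

    For entropy ``H`` in ``[log2 m, log2 (m+1)]`` there is a unique ``a`` in
    ``[1/(m+1), 1/m]``; the candidate value of ``P_C`` is ``C a`` (or 1 when
    the whole support fits inside the top ``C`` bins).
    """
    if h_target <= _TOL:
        return 1.0, {"m": 1, "a": 1.0}
    m = int(math.floor(2.0 ** h_target))
    if m >= b_int:
        return c / b_int, {"m": b_int, "a": 1.0 / b_int}

    def f(a: float) -> float:
        rest = 1.0 - m * a
        val = -m * a * math.log2(a)
        if rest > 0:
            val -= rest * math.log2(rest)
        return val - h_target

    lo, hi = 1.0 / (m + 1), 1.0 / m
    # entropy falls from log2(m+1) at a=lo to log2(m) at a=hi
    flo, fhi = f(lo + 1e-15), f(hi - 1e-15)
    if flo <= 0:
        a = lo
    elif fhi >= 0:
        a = hi
    else:
        a = float(brentq(f, lo + 1e-15, hi - 1e-15, xtol=1e-14, maxiter=200))
    pc = 1.0 if m < c else c * a
    return pc, {"m": m, "a": a}


def lower_PC(h_target: float, n: int, c: int = 1, polish: bool = True) -> tuple[float, dict]:
    """Lower bound on ``P_C``: numerical minimization of the top-``C`` mass
    over decreasing distributions with the target entropy.

    Returns ``(bound, diagnostics)``.  A constructive two-level family seeds
    the search; an SLSQP polish (skipped for very large N) can only lower it.
    """
    b = n / 2.0
    b_int = int(math.floor(b))
    if not 1 <= c <= b:
        raise ValueError("C must satisfy 1 <= C <= N/2")
    if h_target > math.log2(b) + _TOL:
        raise ValueError("infeasible: H exceeds log2(N/2)")
    pc, diag = _two_level_family(h_target, b_int, c)
    diag = {"method": "two-level family", **diag, "polished": False}
    if polish and b_int <= 200 and 0 < h_target < math.log2(b_int) - 1e-9:

        def entropy(p):
            nz = p[p > 1e-300]
            return -(nz * np.log2(nz)).sum()

        starts = []
        m, a = diag["m"], diag["a"]
        x0 = np.zeros(b_int)
        x0[: min(m, b_int)] = a
        if m < b_int:
            x0[m] = max(0.0, 1.0 - m * a)
        starts.append(x0)
        if b_int > c:
            # long-thin-tail start: relevant when H < log2 C
            x1 = np.full(b_int, 0.2 / (b_int - 1))
            x1[0] = 0.8
            x1[::-1].sort()
            starts.append(x1 / x1.sum())

        cons = [
            {"type": "eq", "fun": lambda p: p.sum() - 1.0},
            {"type": "eq", "fun": lambda p: entropy(p) - h_target},
            {"type": "ineq", "fun": lambda p: p[:-1] - p[1:]},
        ]
        for x0 in starts:
            res = minimize(
                lambda p: p[:c].sum(), x0, method="SLSQP", constraints=cons,
                bounds=[(0.0, 1.0)] * b_int, options={"maxiter": 300, "ftol": 1e-12},
            )
            if res.success and abs(entropy(res.x) - h_target) < 1e-6 and res.fun < pc:
                pc = float(res.fun)
                diag.update(polished=True, iterations=int(res.nit),
                            residual=float(abs(entropy(res.x) - h_target)))
    return pc, diag


def precision_bounds(h_target: float, n: int, c: int = 1) -> PrecisionBounds:
    upper = upper_PC(h_target, n, c)
    lower, diag = lower_PC(h_target, n, c)
    lower = min(lower, upper)
    return PrecisionBounds(h_target=h_target, n=n, c=c, upper=upper, lower=lower,
                           diagnostics=diag)


def commercial_value(l: float, n: int, e: int, theta: float,
                     unit_cost: Optional[float] = None,
                     n_predictions: Optional[int] = None) -> ValueEstimate:
    """Conservative dataset value ``V = Theta * 2^-(1.63 L/R - 0.63)(log2 N - 1)``."""
    if theta < 0:
        raise ValueError("Theta must be >= 0")
    r = max_compression_length(n, e)
    h = target_entropy(l / r, n)
    return ValueEstimate(value=theta * 2.0 ** (-h), theta=theta, l=l, ceiling=r,
                         n=n, unit_cost=unit_cost, n_predictions=n_predictions)


def precision_from_ranks(d: RankSequence, n: Optional[int] = None, c: int = 1) -> float:
    """Empirical ``P_C``: mass of the top ``C`` width-``N`` rank bins."""
    dist = bin_ranks(d, n)
    return float(dist.probabilities[:c].sum())
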