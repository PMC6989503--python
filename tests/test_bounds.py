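import math

import numpy as np
import pytest

import linklimit as ll
from linklimit.bounds import (
    commercial_value,
    lower_p1,
    lower_PC,
    precision_bounds,
    precision_from_ranks,
    target_entropy,
    upper_p1,
    upper_PC,
)
from linklimit.ranking import RankSequence


# --- independent oracles ----------------------------------------------------

def _entropy(p):
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def _max_entropy_given_pc(pc, b, c):
    """Entropy of the explicit extremal vector: P_C split evenly over the top
    C bins, remainder uniform over the rest (built and measured directly)."""
    p = np.empty(b)
    p[:c] = pc / c
    p[c:] = (1.0 - pc) / (b - c) if b > c else 0.0
    return _entropy(p)


def oracle_upper(h, n, c, grid=10_000, refine=True):
    """Grid-search the largest feasible P_C, optionally refined by bisection
    on the (directly measured) feasibility predicate."""
    b = n // 2
    ps = np.linspace(2 * c / n, 1.0, grid)
    feasible = [p for p in ps if _max_entropy_given_pc(p, b, c) >= h]
    best = feasible[-1]
    if not refine or best >= 1.0:
        return best
    lo, hi = best, min(1.0, best + (ps[1] - ps[0]))
    for _ in range(60):
        mid = (lo + hi) / 2
        if _max_entropy_given_pc(mid, b, c) >= h:
            lo = mid
        else:
            hi = mid
    return lo


def _random_decreasing(rng, b):
    p = rng.dirichlet(np.ones(b) * rng.uniform(0.05, 2.0))
    p[::-1].sort()
    return p


# --- target entropy ---------------------------------------------------------

class TestTargetEntropy:
    def test_er_point(self):
        n = 500
        assert target_entropy(1.0, n) == pytest.approx(math.log2(n) - 1)

    def test_root_of_law(self):
        assert target_entropy(0.63 / 1.63, 100) == pytest.approx(0.0, abs=1e-12)

    def test_arithmetic(self):
        assert target_entropy(0.8, 1024) == pytest.approx((1.63 * 0.8 - 0.63) * 9.0)

    def test_clamps_below_root(self):
        with pytest.warns(UserWarning, match="clamping"):
            assert target_entropy(0.1, 100) == 0.0


# --- p1 bounds --------------------------------------------------------------

class TestUpperP1:
    def test_zero_entropy(self):
        assert upper_p1(0.0, 100) == 1.0

    def test_uniform_entropy(self):
        n = 100
        assert upper_p1(math.log2(n / 2), n) == pytest.approx(2 / n)

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            upper_p1(10.0, 100)
        with pytest.raises(ValueError):
            upper_p1(-0.1, 100)

    def test_oracle_fine(self):
        assert upper_p1(3.0, 100) == pytest.approx(oracle_upper(3.0, 100, 1), abs=1e-6)

    def test_strictly_decreasing_in_h(self):
        hs = np.linspace(0.2, math.log2(50) - 0.1, 8)
        vals = [upper_p1(h, 100) for h in hs]
        assert all(a > b for a, b in zip(vals, vals[1:]))


class TestLowerP1:
    def test_zero_entropy(self):
        assert lower_p1(0.0) == 1.0

    def test_uniform(self):
        n = 100
        assert lower_p1(math.log2(n / 2)) == pytest.approx(2 / n)

    def test_never_violated_random_distributions(self):
        rng = np.random.default_rng(0)
        for _ in range(10_000):
            p = _random_decreasing(rng, int(rng.integers(3, 60)))
            assert p[0] >= lower_p1(_entropy(p)) * (1 - 1e-9)


# --- P_C bounds -------------------------------------------------------------

class TestUpperPC:
    def test_reduces_to_p1(self):
        for h in (0.5, 2.0, 4.0):
            assert upper_PC(h, 100, c=1) == pytest.approx(upper_p1(h, 100))

    def test_uniform_entropy(self):
        n, c = 100, 5
        assert upper_PC(math.log2(n / 2), n, c) == pytest.approx(2 * c / n)

    def test_oracle(self):
        assert upper_PC(3.0, 100, 5) == pytest.approx(oracle_upper(3.0, 100, 5), abs=1e-4)

    def test_increasing_in_c(self):
        # strictly increasing while unsaturated (H > log2 C) ...
        vals = [upper_PC(4.5, 100, c) for c in (1, 2, 5, 10, 20)]
        assert all(a < b for a, b in zip(vals, vals[1:]))
        # ... and non-decreasing through saturation at 1
        vals = [upper_PC(3.0, 100, c) for c in (1, 2, 5, 10, 20)]
        assert all(a <= b for a, b in zip(vals, vals[1:]))

    def test_degenerate_c_equals_half_n(self):
        assert upper_PC(2.0, 20, 10) == 1.0

    def test_small_h_large_c_saturates(self):
        # H < log2 C: entropy fits inside the top block
        assert upper_PC(1.5, 100, 10) == 1.0


class TestLowerPC:
    def test_c1_matches_lower_p1(self):
        for h in (2.0, 4.0, 5.5):
            val, _ = lower_PC(h, 100, c=1)
            assert val == pytest.approx(lower_p1(h), abs=1e-3)

    def test_c1_never_below_explicit_bound(self):
        # at small H the explicit 2^-H is not attained by any feasible
        # distribution; the minimizer must still dominate it
        for h in (0.3, 0.8, 1.5, 3.0, 5.0):
            val, _ = lower_PC(h, 100, c=1)
            assert val >= lower_p1(h) - 1e-9

    def test_zero_entropy(self):
        val, _ = lower_PC(0.0, 100, c=3)
        assert val == 1.0

    def test_consistency_with_explicit_formula(self):
        val, _ = lower_PC(3.0, 100, c=5)
        assert val >= 5 * lower_p1(3.0) * (1 - 1e-9)

    def test_uniform_boundary_coincides(self):
        n, c = 100, 5
        h = math.log2(n / 2)
        lo, _ = lower_PC(h, n, c)
        assert lo == pytest.approx(upper_PC(h, n, c), abs=1e-9)
        assert lo == pytest.approx(2 * c / n)

    def test_independent_minimizer(self):
        # SLSQP from random starts, fully independent of the two-level family
        from scipy.optimize import minimize

        h_target, n, c = 3.0, 100, 5
        b = n // 2
        rng = np.random.default_rng(1)
        cons = [
            {"type": "eq", "fun": lambda p: p.sum() - 1.0},
            {"type": "eq", "fun": lambda p: _entropy(p) - h_target},
            {"type": "ineq", "fun": lambda p: p[:-1] - p[1:]},
        ]
        best = 1.0
        for _ in range(30):
            x0 = _random_decreasing(rng, b)
            res = minimize(lambda p: p[:c].sum(), x0, method="SLSQP",
                           constraints=cons, bounds=[(0, 1)] * b,
                           options={"maxiter": 300, "ftol": 1e-12})
            if res.success and abs(_entropy(res.x) - h_target) < 1e-7:
                best = min(best, float(res.fun))
        val, diag = lower_PC(h_target, n, c)
        assert val == pytest.approx(best, abs=1e-3)

    def test_never_above_feasible_distributions(self):
        rng = np.random.default_rng(2)
        for _ in range(2000):
            p = _random_decreasing(rng, 50)
            val, _ = lower_PC(_entropy(p), 100, c=5)
            assert p[:5].sum() >= val - 1e-9

    def test_infeasible_entropy(self):
        with pytest.raises(ValueError, match="infeasible"):
            lower_PC(10.0, 100, c=1)


class TestPrecisionBoundsContainer:
    def test_invariants(self):
        pb = precision_bounds(3.0, 100, c=5)
        assert 2 * 5 / 100 <= pb.upper <= 1.0
        assert 0.0 <= pb.lower <= pb.upper
        assert pb.diagnostics


# --- value and empirical precision ------------------------------------------

class TestCommercialValue:
    def test_zero_exponent_gives_theta(self):
        n, e = 100, 495
        r = ll.max_compression_length(n, e)
        est = commercial_value(r * 0.63 / 1.63, n, e, theta=7.5)
        assert est.value == pytest.approx(7.5)

    def test_zero_theta(self):
        assert commercial_value(1000.0, 100, 495, theta=0.0).value == 0.0

    def test_identity_with_lower_p1(self):
        n, e, l = 200, 1500, 5000.0
        r = ll.max_compression_length(n, e)
        est = commercial_value(l, n, e, theta=3.0)
        assert est.value == pytest.approx(3.0 * lower_p1(target_entropy(l / r, n)))

    def test_negative_theta(self):
        with pytest.raises(ValueError):
            commercial_value(1000.0, 100, 495, theta=-1.0)


class TestPrecisionFromRanks:
    def test_all_ones(self):
        d = RankSequence(ranks=np.ones(10), m=100, n=20)
        assert precision_from_ranks(d, c=1) == 1.0

    def test_uniform(self):
        # ranks evenly spread: one per bin, width 20, M=100 -> 5 bins
        d = RankSequence(ranks=np.array([1.0, 21, 41, 61, 81]), m=100, n=20)
        assert precision_from_ranks(d, c=2) == pytest.approx(2 / 5)
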