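"""Connectivity models against analytic and brute-force oracles."""

import itertools

import numpy as np
import pytest

from landconn import circuit_current, cost_distance, factorial_lcp, resistant_kernels
from landconn.models import _CircuitSolver, build_cost_graph, effective_resistance
from landconn.walker import NEIGHBOURS, _SQRT2


def bellman_ford_oracle(surface, source):
    """Exhaustive edge relaxation on the Moore cost graph."""
    nrows, ncols = surface.shape
    dist = {(r, c): np.inf for r in range(nrows) for c in range(ncols)}
    dist[source] = 0.0
    for _ in range(nrows * ncols):
        changed = False
        for r in range(nrows):
            for c in range(ncols):
                for dr, dc in NEIGHBOURS:
                    r2, c2 = r + dr, c + dc
                    if 0 <= r2 < nrows and 0 <= c2 < ncols:
                        w = (_SQRT2 if dr and dc else 1.0) * (surface[r, c] + surface[r2, c2]) / 2
                        if dist[(r, c)] + w < dist[(r2, c2)] - 1e-15:
                            dist[(r2, c2)] = dist[(r, c)] + w
                            changed = True
        if not changed:
            break
    return np.array([[dist[(r, c)] for c in range(ncols)] for r in range(nrows)])


def dense_laplacian(surface):
    g = build_cost_graph(surface).toarray()
    with np.errstate(divide="ignore"):
        cond = np.where(g > 0, 1.0 / g, 0.0)
    return np.diag(cond.sum(axis=1)) - cond, cond


class TestCostDistance:
    def test_uniform_chain_cost(self):
        surf = np.ones((5, 9))
        cd = cost_distance(surf, np.array([[2, 2]]))
        assert cd[2, 5] == pytest.approx(3.0)
        assert cd[2, 2] == 0.0

    def test_matches_bellman_ford_oracle(self, rng):
        surf = np.exp(rng.normal(0, 1, (4, 4)))
        ours = cost_distance(surf, np.array([[1, 2]]))
        oracle = bellman_ford_oracle(surf, (1, 2))
        np.testing.assert_allclose(ours, oracle, atol=1e-10)

    def test_multi_source_is_pointwise_minimum(self, rng):
        surf = np.exp(rng.normal(0, 1, (5, 5)))
        srcs = np.array([[0, 0], [4, 4]])
        combined = cost_distance(surf, srcs)
        singles = np.minimum(
            cost_distance(surf, srcs[:1]), cost_distance(surf, srcs[1:])
        )
        np.testing.assert_allclose(combined, singles, atol=1e-12)

    def test_monotone_in_resistance(self, rng):
        surf = np.exp(rng.normal(0, 1, (6, 6)))
        base = cost_distance(surf, np.array([[0, 0]]))
        bumped = surf.copy()
        bumped[3, 3] *= 5.0
        raised = cost_distance(bumped, np.array([[0, 0]]))
        assert np.all(raised >= base - 1e-12)

    def test_empty_sources_rejected(self, uniform_surface):
        with pytest.raises(ValueError):
            cost_distance(uniform_surface, np.empty((0, 2)))


class TestFactorialLCP:
    def test_unique_geodesic_row_segment(self):
        surf = np.ones((7, 9))
        pred = factorial_lcp(surf, np.array([[3, 1], [3, 6]]))
        expected = np.zeros((7, 9))
        expected[3, 1:7] = 1
        np.testing.assert_array_equal(pred, expected)

    def test_pair_count_combinatorics(self, rng):
        surf = np.exp(rng.normal(0, 1, (8, 8)))
        pts = np.array([[0, 0], [7, 7], [0, 7], [7, 0], [3, 4]])
        pred = factorial_lcp(surf, pts)
        # every source terminates one path per other source (it may also lie
        # on further pairs' paths)
        k = len(pts)
        per_source = np.array([pred[r, c] for r, c in pts])
        assert np.all(per_source >= k - 1)

    def test_collinear_sources_exact_counts(self):
        surf = np.ones((7, 10))
        pts = np.array([[3, 1], [3, 4], [3, 8]])
        pred = factorial_lcp(surf, pts)
        # unique geodesics are the three row segments; counts superpose
        assert pred.sum() == 4 + 8 + 5  # path pixel counts over the 3 pairs
        assert pred[3, 2] == 2   # on paths 1-4 and 1-8
        assert pred[3, 4] == 3   # endpoint of two pairs, interior of 1-8
        assert pred[3, 6] == 2   # on paths 1-8 and 4-8

    def test_source_order_invariance(self, rng):
        surf = np.exp(rng.normal(0, 1, (8, 8)))
        pts = np.array([[0, 0], [7, 7], [2, 5], [6, 1]])
        a = factorial_lcp(surf, pts)
        b = factorial_lcp(surf, pts[::-1])
        np.testing.assert_array_equal(a, b)

    def test_single_source_rejected(self, uniform_surface):
        with pytest.raises(ValueError):
            factorial_lcp(uniform_surface, np.array([[1, 1]]))


class TestResistantKernels:
    def test_kernel_values_on_uniform_surface(self):
        surf = np.ones((7, 11))
        k = resistant_kernels(surf, np.array([[3, 2]]), threshold_T=5.0)
        assert k[3, 2] == pytest.approx(1.0)
        assert k[3, 5] == pytest.approx(0.4)  # 1 - 3/5
        assert k[3, 9] == 0.0  # cd=7 beyond threshold

    def test_superposition_over_sources(self, rng):
        surf = np.exp(rng.normal(0, 1, (6, 6)))
        a, b = np.array([[0, 0]]), np.array([[5, 5]])
        both = resistant_kernels(surf, np.vstack([a, b]), threshold_T=4.0)
        np.testing.assert_allclose(
            both,
            resistant_kernels(surf, a, 4.0) + resistant_kernels(surf, b, 4.0),
            atol=1e-12,
        )

    def test_nonpositive_threshold_rejected(self, uniform_surface):
        with pytest.raises(ValueError):
            resistant_kernels(uniform_surface, np.array([[0, 0]]), threshold_T=0.0)


class TestCircuitCurrent:
    def test_series_strip_carries_unit_current(self):
        strip = np.ones((1, 3))
        cur = circuit_current(strip, np.array([[0, 0], [0, 2]]))
        np.testing.assert_allclose(cur, [[1.0, 1.0, 1.0]], atol=1e-10)

    def test_effective_resistance_series_sum(self):
        strip = np.array([[1.0, 2.0, 4.0]])
        # edge resistances (1+2)/2 and (2+4)/2 in series
        assert effective_resistance(strip, (0, 0), (0, 2)) == pytest.approx(4.5, abs=1e-10)

    def test_parallel_corridors_split_evenly(self):
        # two identical disjoint corridors: a 3x3 grid cannot hold them, so
        # build a dumbbell explicitly with a dense oracle instead; here use
        # symmetry on a 3-column grid with an impassable-ish middle row
        surf = np.ones((3, 5))
        surf[1, 1:4] = 1e9  # middle corridor effectively blocked
        cur = circuit_current(surf, np.array([[1, 0], [1, 4]]))
        # symmetric top/bottom corridors carry equal current
        np.testing.assert_allclose(cur[0, 1:4], cur[2, 1:4], atol=1e-8)
        assert np.all(cur[0, 1:4] > 0.49)

    def test_kirchhoff_conservation(self, rng):
        surf = np.exp(rng.normal(0, 1, (6, 6)))
        lap, cond = dense_laplacian(surf)
        solver = _CircuitSolver(surf)
        a, b = 3, 31
        v = solver.potentials(a, b)
        net = lap @ v
        inj = np.zeros(36)
        inj[a], inj[b] = 1.0, -1.0
        np.testing.assert_allclose(net, inj, atol=1e-7)

    def test_matches_dense_direct_solve(self, rng):
        """Pairwise current density equals a dense pseudo-inverse oracle."""
        surf = np.exp(rng.normal(0, 1, (5, 5)))
        pts = np.array([[0, 0], [4, 4], [0, 4]])
        ours = circuit_current(surf, pts)
        lap, cond = dense_laplacian(surf)
        n = lap.shape[0]
        # truncate the Laplacian's null mode explicitly; the default cutoff
        # (1e-15) inverts it and destroys the oracle's accuracy
        linv = np.linalg.pinv(lap, rcond=1e-10)
        nodes = sorted(r * 5 + c for r, c in pts)
        expected = np.zeros(n)
        for a, b in itertools.combinations(nodes, 2):
            inj = np.zeros(n)
            inj[a], inj[b] = 1.0, -1.0
            v = linv @ inj
            flow = cond * np.abs(v[:, None] - v[None, :])
            cur = 0.5 * flow.sum(axis=1)
            cur[a] = cur[b] = 1.0
            expected += cur
        np.testing.assert_allclose(ours.ravel(), expected, atol=1e-8)

    def test_source_order_invariance(self, rng):
        surf = np.exp(rng.normal(0, 1, (5, 5)))
        pts = np.array([[0, 0], [4, 4], [2, 1]])
        np.testing.assert_allclose(
            circuit_current(surf, pts), circuit_current(surf, pts[::-1]), atol=1e-12
        )

    def test_all_to_one_mode_runs(self, rng):
        surf = np.exp(rng.normal(0, 1, (5, 5)))
        pts = np.array([[0, 0], [4, 4], [0, 4]])
        cur = circuit_current(surf, pts, mode="all-to-one")
        assert cur.shape == surf.shape
        assert np.all(cur >= 0) and np.all(np.isfinite(cur))
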