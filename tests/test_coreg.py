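"""Co-regulation curve and top-k overlap statistics.

The Fisher oracle computes the hypergeometric tail with exact rational
arithmetic at small universe sizes; curve behaviour is checked on
constructed data (collinear, constant, planted signal, global null).
"""

import math
from fractions import Fraction

import numpy as np
import pytest

from tfcoreg.coreg import (
    MODES,
    bagged_lowess,
    coreg_curve,
    overlap_significance_curve,
    quadrant_overlap_test,
    randomization_envelope,
)
from tfcoreg.rsa import score_genes
from tfcoreg.simulate import ExprSimSpec, simulate_expression


def exact_fisher_tail(n, k, overlap):
    """Oracle: P(X >= overlap), X ~ Hypergeom(n; k; k), exact rationals."""
    total = Fraction(0)
    for x in range(overlap, k + 1):
        total += Fraction(math.comb(k, x) * math.comb(n - k, k - x), math.comb(n, k))
    return float(total)


def make_rankings(n, seed=0):
    rng = np.random.default_rng(seed)
    genes = [f"g{i}" for i in range(n)]
    a = dict(zip(genes, rng.permutation(n) / n + 1e-9))
    b = dict(zip(genes, rng.permutation(n) / n + 1e-9))
    return genes, a, b


class TestLowess:
    def test_identity_recovered_exactly(self, rng):
        x = rng.normal(0, 1, 500)
        grid, bagged = bagged_lowess(x, x, n_boot=100, seed=0)
        np.testing.assert_allclose(bagged, grid, atol=1e-6)

    def test_constant_curve(self, rng):
        x = rng.normal(0, 1, 100)
        grid, bagged = bagged_lowess(x, np.full(100, 3.7), n_boot=20, seed=1)
        np.testing.assert_allclose(bagged, 3.7, atol=1e-9)

    def test_slope_two_recovered(self, rng):
        x = rng.normal(0, 1, 1000)
        y = 2 * x + rng.normal(0, 0.1, 1000)
        grid, bagged = bagged_lowess(x, y, n_boot=100, seed=3)
        slope = np.polyfit(grid, bagged, 1)[0]
        assert 1.9 <= slope <= 2.1

    def test_degenerate_x_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            bagged_lowess(np.ones(50), np.arange(50.0))

    def test_deterministic_under_seed(self, rng):
        x = rng.normal(size=200)
        y = x + rng.normal(0, 0.5, 200)
        g1, b1 = bagged_lowess(x, y, n_boot=10, seed=9)
        g2, b2 = bagged_lowess(x, y, n_boot=10, seed=9)
        np.testing.assert_array_equal(b1, b2)


class TestEnvelope:
    def test_constant_y_collapses_envelope(self, rng):
        x = rng.normal(size=100)
        grid, lo, hi = randomization_envelope(x, np.full(100, 2.5), n_perm=100, seed=0)
        np.testing.assert_allclose(lo, 2.5, atol=1e-9)
        np.testing.assert_allclose(hi, 2.5, atol=1e-9)

    def test_envelope_brackets_each_permuted_fit(self, rng):
        # min/max over permutations bound any single permuted fit drawn
        # from the same seed stream
        x = rng.normal(size=200)
        y = x + rng.normal(0, 0.3, 200)
        grid, lo, hi = randomization_envelope(x, y, n_perm=50, seed=4)
        grid2, lo2, hi2 = randomization_envelope(x, y, n_perm=10, seed=4)
        assert np.all(lo <= lo2 + 1e-12) and np.all(hi >= hi2 - 1e-12)

    def test_width_non_decreasing_in_n_perm(self, rng):
        x = rng.normal(size=150)
        y = rng.normal(size=150)
        _, lo_small, hi_small = randomization_envelope(x, y, n_perm=20, seed=2)
        _, lo_big, hi_big = randomization_envelope(x, y, n_perm=100, seed=2)
        assert np.all(hi_big - lo_big >= hi_small - lo_small - 1e-12)

    def test_planted_coactivation_exits_lower_left(self):
        t_mitf, t_yy1, _ = simulate_expression(ExprSimSpec(seed=11))
        x = t_mitf.values.mean(axis=1)
        y = t_yy1.values.mean(axis=1)
        curve = coreg_curve(x, y, n_boot=50, n_perm=200, seed=11)
        exits = curve.exits_envelope()
        lower_left = curve.grid < -1.0
        assert lower_left.any()
        assert exits[lower_left].mean() > 0.5

    def test_global_null_stays_inside(self):
        spec = ExprSimSpec(seed=21, effect=0.0)
        t_mitf, t_yy1, _ = simulate_expression(spec)
        x = t_mitf.values.mean(axis=1)
        y = t_yy1.values.mean(axis=1)
        curve = coreg_curve(x, y, n_boot=50, n_perm=200, seed=21)
        assert (~curve.exits_envelope()).mean() >= 0.95


class TestQuadrantOverlap:
    def test_worked_example_universe_100(self):
        genes = [f"g{i}" for i in range(100)]
        # construct rankings whose top-10 sets share exactly 5 genes
        a = {g: i + 1.0 for i, g in enumerate(genes)}
        b_order = genes[:5] + genes[50:55] + genes[5:50] + genes[55:]
        b = {g: i + 1.0 for i, g in enumerate(b_order)}
        pt = quadrant_overlap_test(a, b, k=10, mode="co_activated")
        assert pt.overlap == 5
        assert pt.fisher_p == pytest.approx(6.716e-4, rel=1e-3)
        assert pt.fisher_p == pytest.approx(exact_fisher_tail(100, 10, 5), rel=1e-12)

    @pytest.mark.parametrize("n,k,overlap", [(20, 5, 2), (50, 10, 4), (100, 10, 5),
                                             (200, 30, 10), (500, 50, 12)])
    def test_exact_rational_oracle(self, n, k, overlap):
        genes = [f"g{i}" for i in range(n)]
        a = {g: i + 1.0 for i, g in enumerate(genes)}
        b_order = (genes[:overlap] + genes[n - (k - overlap):]
                   + genes[overlap:n - (k - overlap)])
        b = {g: i + 1.0 for i, g in enumerate(b_order)}
        pt = quadrant_overlap_test(a, b, k=k, mode="co_activated")
        assert pt.overlap == overlap
        assert pt.fisher_p == pytest.approx(exact_fisher_tail(n, k, overlap), rel=1e-12)

    def test_identical_rankings_minimal_p(self):
        genes, a, _ = make_rankings(60)
        pt = quadrant_overlap_test(a, a, k=8, mode="co_activated")
        assert pt.overlap == 8
        assert pt.fisher_p == pytest.approx(exact_fisher_tail(60, 8, 8), rel=1e-12)
        # minimal achievable p for this k: 1 / C(60, 8)
        assert pt.fisher_p == pytest.approx(1 / math.comb(60, 8), rel=1e-9)

    def test_saturation_at_k_equal_universe(self):
        genes, a, b = make_rankings(40, seed=3)
        pt = quadrant_overlap_test(a, b, k=40, mode="co_activated")
        assert pt.overlap == 40
        assert pt.fisher_p == pytest.approx(1.0)

    def test_k_beyond_universe_rejected(self):
        genes, a, b = make_rankings(10)
        with pytest.raises(ValueError):
            quadrant_overlap_test(a, b, k=11)


@pytest.fixture(scope="module")
def planted_ranks():
    t_mitf, t_yy1, labels = simulate_expression(ExprSimSpec(seed=13))
    rm = score_genes(t_mitf)
    ry = score_genes(t_yy1)
    return ({r.gene_id: r.p_down for r in rm}, {r.gene_id: r.p_up for r in rm},
            {r.gene_id: r.p_down for r in ry}, {r.gene_id: r.p_up for r in ry})


class TestOverlapCurve:
    def test_fig_pattern_co_modes_significant_antagonistic_not(self, planted_ranks):
        """Planted co-activated/co-repressed truth: both co-modes highly
        significant at every k, antagonistic modes not."""
        dm, um, dy, uy = planted_ranks
        points = overlap_significance_curve(dm, dy, [100, 200, 300, 400],
                                            rank_a_up=um, rank_b_up=uy)
        for pt in points:
            if pt.mode in ("co_activated", "co_repressed"):
                assert pt.fisher_p < 1e-6, (pt.mode, pt.k, pt.fisher_p)
            else:
                assert pt.fisher_p > 0.01, (pt.mode, pt.k, pt.fisher_p)

    def test_permuted_labels_mostly_non_significant(self, planted_ranks):
        dm, um, dy, uy = planted_ranks
        genes = list(dm)
        rng = np.random.default_rng(99)
        n_null = 0
        n_runs = 20
        for _ in range(n_runs):
            perm = rng.permutation(genes)
            dy_p = {g: dy[p] for g, p in zip(genes, perm)}
            uy_p = {g: uy[p] for g, p in zip(genes, perm)}
            points = overlap_significance_curve(dm, dy_p, [100, 300],
                                                rank_a_up=um, rank_b_up=uy_p)
            if all(pt.fisher_p > 1e-4 for pt in points):
                n_null += 1
        assert n_null >= 0.95 * n_runs - 1

    def test_k_grid_at_universe_saturates(self):
        genes, a, b = make_rankings(30, seed=5)
        points = overlap_significance_curve(a, b, [30])
        assert all(pt.overlap == 30 and pt.fisher_p == pytest.approx(1.0)
                   for pt in points)

    def test_non_increasing_grid_rejected(self):
        genes, a, b = make_rankings(30, seed=5)
        with pytest.raises(ValueError):
            overlap_significance_curve(a, b, [10, 10])

    def test_all_four_modes_emitted(self):
        genes, a, b = make_rankings(30, seed=6)
        points = overlap_significance_curve(a, b, [5, 10])
        assert {(pt.k, pt.mode) for pt in points} == {
            (k, m) for k in (5, 10) for m in MODES}
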