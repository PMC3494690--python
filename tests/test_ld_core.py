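import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import brute_force_r2, make_table
from poolld import ld_core
from poolld.ld_core import (
    approx_mle_r2,
    direct_r2,
    effective_n,
    expected_haplotype_freqs,
    feasible_D_range,
)

probs = st.floats(0.02, 0.98)


class TestDirectR2:
    @pytest.mark.parametrize(
        "cells, r2, pa, pb, d",
        [
            ((5, 0, 0, 5), 1.0, 0.5, 0.5, 0.25),
            ((4, 4, 4, 4), 0.0, 0.5, 0.5, 0.0),
            ((6, 2, 1, 1), 0.0016 / 0.0336, 0.8, 0.7, 0.04),
        ],
    )
    def test_hand_computed_tables(self, cells, r2, pa, pb, d):
        res = direct_r2(make_table(*cells))
        assert res.r2 == pytest.approx(r2)
        assert (res.p_a, res.p_b) == (pa, pb)
        assert res.d == pytest.approx(d)

    def test_monomorphic_table_is_flagged_not_divided(self):
        res = direct_r2(make_table(5, 5, 0, 0))
        assert not res.defined and math.isnan(res.r2)

    def test_agrees_with_indicator_correlation(self, rng):
        """Independent oracle: squared correlation of expanded 0/1 vectors."""
        for _ in range(500):
            x = rng.integers(1, 40, size=4)
            res = direct_r2(make_table(*x))
            assert res.r2 == pytest.approx(brute_force_r2(*x), abs=1e-12)


class TestHaplotypeFreqs:
    def test_independence_gives_products(self):
        assert expected_haplotype_freqs(0.3, 0.6, 0.0) == pytest.approx(
            (0.18, 0.12, 0.42, 0.28)
        )

    def test_maximal_coupling(self):
        assert expected_haplotype_freqs(0.5, 0.5, 0.25) == pytest.approx(
            (0.5, 0.0, 0.0, 0.5)
        )

    def test_infeasible_d_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            expected_haplotype_freqs(0.5, 0.5, 0.3)

    @settings(max_examples=200, deadline=None)
    @given(probs, probs, st.floats(0.0, 1.0))
    def test_simplex_identities(self, pa, pb, frac):
        d_min, d_max = feasible_D_range(pa, pb)
        d = d_min + frac * (d_max - d_min)
        f = expected_haplotype_freqs(pa, pb, d)
        assert sum(f) == pytest.approx(1.0)
        assert f[0] + f[1] == pytest.approx(pa)  # marginals recovered
        assert f[0] + f[2] == pytest.approx(pb)
        assert min(f) >= -1e-12


class TestFeasibleRange:
    def test_symmetric_case(self):
        assert feasible_D_range(0.5, 0.5) == (-0.25, 0.25)

    def test_asymmetric_case_from_the_four_bounds(self):
        d_min, d_max = feasible_D_range(0.9, 0.1)
        assert d_min == pytest.approx(max(-0.9 * 0.1, -0.1 * 0.9))
        assert d_max == pytest.approx(min(0.9 * 0.9, 0.1 * 0.1))

    @settings(max_examples=200, deadline=None)
    @given(probs, probs)
    def test_all_cells_nonnegative_exactly_at_boundary(self, pa, pb):
        d_min, d_max = feasible_D_range(pa, pb)
        assert d_min <= 0 <= d_max
        for d in (d_min, d_max):
            assert min(expected_haplotype_freqs(pa, pb, d)) >= -1e-12


class TestEffectiveN:
    def test_formula_and_bounds(self):
        assert effective_n(100, 100) == pytest.approx(50.0)
        assert effective_n(40, 184) == pytest.approx(40 * 184 / 224)
        assert effective_n(40, 184) < 40

    def test_limit_is_pool_size(self):
        assert effective_n(1e12, 200) == pytest.approx(200, rel=1e-6)

    def test_monotone_in_both_arguments(self):
        assert effective_n(50, 100) < effective_n(60, 100) < effective_n(60, 120)

    def test_positive_inputs_required(self):
        with pytest.raises(ValueError):
            effective_n(0, 100)


class TestApproxMle:
    def test_perfect_table_at_coupling_bound(self):
        res = approx_mle_r2(make_table(5, 0, 0, 5), 0.5, 0.5, 1000)
        assert res.r2 == pytest.approx(1.0)
        assert res.boundary
        assert res.d_hat == pytest.approx(0.25)

    def test_independent_table(self):
        res = approx_mle_r2(make_table(4, 4, 4, 4), 0.5, 0.5, 1000)
        assert res.r2 == pytest.approx(0.0, abs=1e-6)
        assert not res.boundary

    def test_recovers_generating_d_from_proportional_table(self):
        f = expected_haplotype_freqs(0.6, 0.6, 0.12)
        cells = tuple(int(round(1000 * fi)) for fi in f)
        res = approx_mle_r2(make_table(*cells), 0.6, 0.6, 10**9)
        assert res.r2 == pytest.approx(0.12**2 / 0.24**2, abs=1e-4)
        assert res.d_hat == pytest.approx(0.12, abs=1e-4)

    def test_interior_mle_matches_direct_when_congruent(self, rng):
        """With pA'/pB' equal to the table marginals, D_hat = direct D."""
        for _ in range(50):
            x = rng.integers(1, 60, size=4)
            t = make_table(*x)
            d = direct_r2(t)
            res = approx_mle_r2(t, d.p_a, d.p_b, 10**9)
            assert res.d_hat == pytest.approx(d.d, abs=1e-6)
            assert res.r2 == pytest.approx(d.r2, abs=1e-5)

    def test_label_swap_symmetry(self, rng):
        """r^2 is invariant to which allele is called major at either locus."""
        for _ in range(20):
            x = tuple(int(v) for v in rng.integers(1, 40, size=4))
            pa, pb = rng.uniform(0.2, 0.8, size=2)
            base = approx_mle_r2(make_table(*x), pa, pb, 500)
            swapped_a = approx_mle_r2(
                make_table(x[2], x[3], x[0], x[1]), 1 - pa, pb, 500
            )
            swapped_b = approx_mle_r2(
                make_table(x[1], x[0], x[3], x[2]), pa, 1 - pb, 500
            )
            assert base.r2 == pytest.approx(swapped_a.r2, abs=1e-6)
            assert base.r2 == pytest.approx(swapped_b.r2, abs=1e-6)

    def test_count_scaling_changes_only_the_ci(self):
        small = approx_mle_r2(make_table(12, 6, 4, 8), 0.55, 0.5, 10**6)
        big = approx_mle_r2(make_table(120, 60, 40, 80), 0.55, 0.5, 10**6)
        assert big.d_hat == pytest.approx(small.d_hat, abs=1e-6)
        assert (big.ci_high - big.ci_low) < (small.ci_high - small.ci_low)

    def test_ci_contains_point_estimate(self, rng):
        for _ in range(100):
            x = rng.integers(0, 50, size=4)
            if x.sum() == 0:
                continue
            pa, pb = rng.uniform(0.05, 0.95, size=2)
            res = approx_mle_r2(make_table(*x), pa, pb, int(rng.integers(10, 1000)))
            assert res.ci_low - 1e-12 <= res.r2 <= res.ci_high + 1e-12
            assert 0.0 <= res.ci_low <= res.ci_high <= 1.0

    def test_ci_width_shrinks_with_pool_size(self):
        t = make_table(30, 10, 10, 10)
        widths = [
            (lambda r: r.ci_high - r.ci_low)(approx_mle_r2(t, 0.6, 0.6, n_chrom))
            for n_chrom in (20, 100, 1000)
        ]
        assert widths[0] > widths[1] > widths[2]

    def test_frequencies_must_be_interior(self):
        with pytest.raises(ValueError):
            approx_mle_r2(make_table(5, 5, 5, 5), 1.0, 0.5, 100)

    def test_grid_refinement_matches_fine_scan(self, rng):
        """Grid + local refinement agrees with a dense likelihood scan."""
        for _ in range(30):
            x = rng.integers(1, 80, size=4)
            pa, pb = rng.uniform(0.1, 0.9, size=2)
            n_chrom = int(rng.integers(50, 500))
            res = approx_mle_r2(make_table(*x), pa, pb, n_chrom)
            r2_scan = _fine_scan_r2(x, pa, pb, n_chrom)
            assert res.r2 == pytest.approx(r2_scan, abs=1e-4)


def _fine_scan_r2(x, pa, pb, n_chrom, points=100_001):
    """Brute-force likelihood maximization on a dense D grid."""
    x = np.asarray(x, dtype=float)
    n = x.sum()
    xe = x * (effective_n(n, n_chrom) / n)
    d_min, d_max = feasible_D_range(pa, pb)
    grid = np.linspace(d_min, d_max, points)
    signs = np.array([1.0, -1.0, -1.0, 1.0])
    f0 = np.array([pa * pb, pa * (1 - pb), (1 - pa) * pb, (1 - pa) * (1 - pb)])
    f = f0[None, :] + np.outer(grid, signs)
    np.clip(f, 0.0, None, out=f)
    with np.errstate(divide="ignore"):
        ll = np.where(f[:, xe > 0] > 0, np.log(f[:, xe > 0]), -np.inf) @ xe[xe > 0]
    d_hat = grid[int(np.argmax(ll))]
    denom = pa * (1 - pa) * pb * (1 - pb)
    return min(max(d_hat * d_hat / denom, 0.0), 1.0)
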