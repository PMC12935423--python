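import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bradyssa.exceptions import ParameterError
from bradyssa.ssa import (SSA, Grouping, decompose, diagonal_weights, embed)
from oracles import (antidiagonal_mean, hankel_entry, reconstruct_group,
                     ssa_via_gram)


class TestEmbed:
    def test_small_example(self):
        traj = embed([1, 2, 3, 4, 5], L=3)
        np.testing.assert_array_equal(
            traj.values, [[1, 2, 3], [2, 3, 4], [3, 4, 5]])
        assert (traj.L, traj.K, traj.N) == (3, 3, 5)

    def test_boundary_window_gives_two_columns(self):
        traj = embed(np.arange(10.0), L=9)
        assert traj.K == 2

    def test_entries_match_index_oracle(self, rng):
        x = rng.normal(size=50)
        traj = embed(x, L=17)
        for i in range(traj.L):
            for j in range(traj.K):
                assert traj.values[i, j] == hankel_entry(x, i, j)

    @pytest.mark.parametrize("L", [0, 1, 5, 99])
    def test_window_out_of_range_rejected(self, L):
        with pytest.raises(ParameterError):
            embed([1.0, 2.0, 3.0, 4.0, 5.0], L=L)


class TestDecompose:
    def test_constant_series_is_rank_one(self):
        m = decompose(np.full(40, 3.7), L=10)
        assert m.d >= 1
        assert np.all(m.sigma[1:] < 1e-10 * m.sigma[0])

    def test_zero_series_has_rank_zero(self):
        m = decompose(np.zeros(40), L=10)
        assert m.d == 0

    def test_sinusoid_is_rank_two_with_equal_pair(self):
        t = np.arange(500) / 250.0
        m = decompose(np.sin(2 * np.pi * 5 * t), L=250)
        assert m.d == 2
        assert abs(m.sigma[1] / m.sigma[0] - 1.0) < 0.01

    def test_two_tones_give_two_near_equal_pairs(self):
        t = np.arange(1000) / 250.0
        x = np.sin(2 * np.pi * 5 * t) + np.sin(2 * np.pi * 0.5 * t)
        m = decompose(x, L=250)
        dominant = m.sigma[m.sigma > 1e-6 * m.sigma[0]]
        assert dominant.size == 4
        assert dominant[1] / dominant[0] > 0.8
        assert dominant[3] / dominant[2] > 0.8

    def test_neig_caps_rank(self, rng):
        x = rng.normal(size=60)
        assert decompose(x, L=20, neig=5).d == 5

    def test_unit_norm_and_ordering(self, rng):
        m = decompose(rng.normal(size=80), L=25)
        np.testing.assert_allclose(np.linalg.norm(m.U, axis=0), 1, atol=1e-9)
        np.testing.assert_allclose(np.linalg.norm(m.V, axis=0), 1, atol=1e-9)
        assert np.all(np.diff(m.sigma) <= 1e-12)

    def test_energy_identity(self, rng):
        x = rng.normal(size=100)
        m = decompose(x, L=30)
        traj = embed(x, 30)
        np.testing.assert_allclose(np.sum(m.sigma**2),
                                   np.linalg.norm(traj.values, "fro") ** 2,
                                   rtol=1e-8)

    def test_deterministic_bit_identical(self, rng):
        x = rng.normal(size=120)
        a = decompose(x, L=40)
        b = decompose(x, L=40)
        assert np.array_equal(a.sigma, b.sigma)
        assert np.array_equal(a.U, b.U)
        assert np.array_equal(a.V, b.V)


class TestReconstruct:
    def test_full_group_identity(self, rng):
        x = rng.normal(size=70)
        m = decompose(x, L=20)
        comps = m.reconstruct(Grouping(groups={"all": range(1, m.d + 1)}))
        np.testing.assert_allclose(comps["all"], x,
                                   rtol=0, atol=1e-8 * np.abs(x).max())

    def test_geometric_series_rank_one_recovery(self):
        x = 2.0 ** -np.arange(20)
        m = decompose(x, L=8)
        comps = m.reconstruct(Grouping(groups={"g": (1,)}))
        np.testing.assert_allclose(comps["g"], x, rtol=1e-8)

    def test_matches_brute_force_antidiagonal_oracle(self, rng):
        x = rng.normal(size=50)
        L = 14
        m = decompose(x, L=L)
        idx_a = tuple(sorted(rng.choice(np.arange(1, m.d + 1), size=4,
                                        replace=False)))
        idx_b = tuple(i for i in range(1, m.d + 1) if i not in idx_a)
        comps = m.reconstruct(Grouping(groups={"a": idx_a, "b": idx_b}))
        np.testing.assert_allclose(comps["a"], reconstruct_group(x, L, idx_a),
                                   atol=1e-8)
        np.testing.assert_allclose(comps["b"], reconstruct_group(x, L, idx_b),
                                   atol=1e-8)

    def test_out_of_range_group_index_rejected(self, rng):
        m = decompose(rng.normal(size=30), L=10)
        with pytest.raises(ParameterError):
            m.reconstruct(Grouping(groups={"g": (m.d + 1,)}))

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(seed=st.integers(0, 10_000), n=st.integers(8, 40))
    def test_completeness_property(self, seed, n):
        """Components plus residual always sum back to the input."""
        x = np.random.default_rng(seed).normal(size=n)
        L = max(2, n // 3)
        m = decompose(x, L=L)
        if m.d < 2:
            return
        half = m.d // 2
        comps = m.reconstruct(Grouping(
            groups={"a": range(1, half + 1), "b": range(half + 1, m.d + 1)}))
        np.testing.assert_allclose(comps.total(), x,
                                   atol=1e-8 * max(1.0, np.abs(x).max()))


class TestGramOracleEquivalence:
    """decompose/reconstruct vs the explicit X X^T eigendecomposition."""

    @pytest.mark.parametrize("seed", range(8))
    def test_short_series_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 31))
        L = int(rng.integers(3, n - 1))
        x = rng.normal(size=n)
        m = decompose(x, L=L)
        sigma_o, U_o, V_o = ssa_via_gram(x, L)
        np.testing.assert_allclose(m.sigma, sigma_o[:m.d], rtol=1e-6,
                                   atol=1e-9)
        full = m.reconstruct(Grouping(groups={"all": range(1, m.d + 1)}))
        oracle_full = reconstruct_group(x, L, range(1, m.d + 1))
        np.testing.assert_allclose(full["all"], oracle_full, atol=1e-6)


class TestWCorrelation:
    def test_single_component_is_unit_matrix(self, rng):
        m = decompose(rng.normal(size=40), L=12)
        np.testing.assert_array_equal(m.w_correlation(1), [[1.0]])

    def test_separated_tones_nearly_w_orthogonal(self):
        # unequal amplitudes keep the two tones' singular subspaces distinct
        t = np.arange(2000) / 250.0
        x = 2.0 * np.sin(2 * np.pi * 10 * t) + np.sin(2 * np.pi * 40 * t)
        m = decompose(x, L=250)
        wcor = m.w_correlation(4)
        # components 1-2 and 3-4 belong to different tones
        assert abs(wcor[0, 2]) < 0.1
        assert abs(wcor[1, 3]) < 0.1

    def test_sine_pair_strongly_w_correlated(self):
        t = np.arange(500) / 250.0
        m = decompose(np.sin(2 * np.pi * 5 * t), L=250)
        assert m.w_correlation(2)[0, 1] > 0.7

    def test_symmetric_unit_diagonal_bounded(self, rng):
        m = decompose(rng.normal(size=100), L=30)
        wcor = m.w_correlation(8)
        np.testing.assert_allclose(wcor, wcor.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(wcor), 1.0)
        assert np.all(np.abs(wcor) <= 1.0)

    def test_k_beyond_rank_rejected(self, rng):
        m = decompose(rng.normal(size=30), L=10)
        with pytest.raises(ParameterError):
            m.w_correlation(m.d + 1)


def test_grouping_rejects_overlap_and_bad_indices():
    with pytest.raises(ParameterError):
        Grouping(groups={"a": (1, 2), "b": (2, 3)})
    with pytest.raises(ParameterError):
        Grouping(groups={"a": (0,)})


def test_diagonal_weights_count_antidiagonal_cells():
    np.testing.assert_array_equal(diagonal_weights(3, 4),
                                  [1, 2, 3, 3, 2, 1])
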