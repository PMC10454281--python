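import numpy as np
import pytest

from eegmotor.connectivity import (
    BandConnectivity,
    dwpli_cells,
    dwpli_from_coeffs,
    dwpli_matrix,
    global_efficiency,
    local_efficiency,
    node_strength,
    proportional_threshold,
)
from eegmotor.timefreq import TFDecomposition, make_frequency_grid
from graph_oracles import brute_global_efficiency, brute_local_efficiency


def _conn(W, band="theta"):
    return BandConnectivity(W=np.asarray(W, float), band=band, window_ms=(-150, 150),
                            n_trials=10, ch_names=[f"c{i}" for i in range(len(W))])


class TestDwpli:
    def _pair_coeffs(self, imags):
        """Coefficients for 2 channels whose cross-spectrum has Im = imags."""
        n = len(imags)
        F = np.zeros((n, 2, 1), complex)
        F[:, 0, 0] = 1.0
        F[:, 1, 0] = -1j * np.asarray(imags)  # Im(F_a conj F_b) = imags
        return F

    def test_constant_positive_imaginary_gives_one(self):
        val = dwpli_cells(self._pair_coeffs([0.5] * 6))
        assert np.isclose(val[0, 1, 0], 1.0)

    def test_zero_lag_gives_zero(self):
        F = np.ones((4, 2, 1), complex)  # identical signals, Im = 0
        assert dwpli_cells(F)[0, 1, 0] == 0.0

    def test_mixed_signs_give_negative_third(self):
        c = 0.7
        val = dwpli_cells(self._pair_coeffs([c, c, -c, -c]))
        assert np.isclose(val[0, 1, 0], -1.0 / 3.0)

    def test_clamping_policy(self):
        F = self._pair_coeffs([0.7, 0.7, -0.7, -0.7])
        W, W_raw = dwpli_from_coeffs(F, clamp_negative=True)
        assert W[0, 1] == 0.0
        assert np.isclose(W_raw[0, 1], -1.0 / 3.0)
        W2, _ = dwpli_from_coeffs(F, clamp_negative=False)
        assert np.isclose(W2[0, 1], -1.0 / 3.0)

    def test_needs_two_trials(self):
        with pytest.raises(ValueError):
            dwpli_cells(np.ones((1, 2, 1), complex))

    def test_invariance_to_trial_scaling_and_common_signal(self):
        rng = np.random.default_rng(0)
        n, cells = 40, 12
        a = rng.standard_normal((n, cells)) + 1j * rng.standard_normal((n, cells))
        b = np.exp(1j * np.pi / 2) * a + 0.3 * (rng.standard_normal((n, cells))
                                                + 1j * rng.standard_normal((n, cells)))
        F = np.stack([a, b], axis=1)
        W0, _ = dwpli_from_coeffs(F)
        # global amplitude rescaling (the estimator weights trials by their
        # imaginary cross-spectrum magnitude, so only a common scale cancels)
        W1, _ = dwpli_from_coeffs(F * 7.3)
        assert np.allclose(W0, W1, atol=1e-12)
        # adding a zero-lag common signal to both channels keeps Im unbiased:
        # dwPLI of purely common input is exactly 0
        common = rng.standard_normal((n, cells)) + 1j * rng.standard_normal((n, cells))
        Wc, _ = dwpli_from_coeffs(np.stack([common, common], axis=1))
        assert np.allclose(Wc, 0.0, atol=1e-12)

    def test_matrix_from_decomposition(self):
        rng = np.random.default_rng(1)
        grid = make_frequency_grid(4.0, 8.0 * 0.999, 1.1)
        n = 256
        coeffs = rng.standard_normal((20, 3, grid.n_freqs, n)) \
            + 1j * rng.standard_normal((20, 3, grid.n_freqs, n))
        times = (np.arange(n) - n // 2) / 256.0 * 1000
        tf = TFDecomposition(coeffs=coeffs, grid=grid, times=times, sfreq=256.0,
                             ch_names=["a", "b", "c"])
        conn = dwpli_matrix(tf, "theta", (-150.0, 150.0))
        assert conn.W.shape == (3, 3)
        assert np.allclose(conn.W, conn.W.T)
        assert np.all(np.diag(conn.W) == 0)
        assert conn.W.min() >= 0


class TestNodeStrength:
    def test_row_sums(self):
        W = np.array([[0, 0.2, 0.3], [0.2, 0, 0], [0.3, 0, 0]])
        assert np.allclose(node_strength(_conn(W)), [0.5, 0.2, 0.3])

    def test_zero_matrix(self):
        assert np.allclose(node_strength(_conn(np.zeros((4, 4)))), 0.0)

    def test_handshake_identity(self):
        rng = np.random.default_rng(2)
        W = rng.uniform(0, 1, (7, 7))
        W = np.triu(W, 1)
        W = W + W.T
        s = node_strength(_conn(W))
        assert np.isclose(s.sum(), 2 * np.triu(W, 1).sum())


class TestEfficiency:
    def test_three_node_hand_example(self):
        W = np.array([[0, 1.0, 0.5], [1.0, 0, 0], [0.5, 0, 0]])
        # lengths: d12=1, d13=2, d23=3 -> E = (1 + 1/2 + 1/3)/3
        assert np.isclose(global_efficiency(_conn(W)), (1 + 0.5 + 1 / 3) / 3)

    def test_complete_unit_graph(self):
        W = 1.0 - np.eye(5)
        assert np.isclose(global_efficiency(_conn(W)), 1.0)
        assert np.allclose(local_efficiency(_conn(W)), 1.0)

    def test_empty_graph(self):
        assert global_efficiency(_conn(np.zeros((4, 4)))) == 0.0

    def test_complete_triangle_local(self):
        W = 1.0 - np.eye(3)
        assert np.allclose(local_efficiency(_conn(W)), 1.0)

    def test_star_graph_local(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 1.0
        W[0, 2] = W[2, 0] = 1.0
        le = local_efficiency(_conn(W))
        assert le[0] == 0.0  # leaves disconnected from each other
        assert le[1] == 0.0 and le[2] == 0.0  # degree < 2

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_on_random_graphs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 7))
        W = rng.uniform(0, 1, (n, n)) * (rng.random((n, n)) < 0.7)
        W = np.triu(W, 1)
        W = W + W.T
        conn = _conn(W)
        assert np.isclose(global_efficiency(conn), brute_global_efficiency(W), atol=1e-10)
        assert np.allclose(local_efficiency(conn), brute_local_efficiency(W), atol=1e-10)

    def test_channel_permutation_consistency(self):
        rng = np.random.default_rng(5)
        n = 8
        W = rng.uniform(0, 1, (n, n))
        W = np.triu(W, 1)
        W = W + W.T
        perm = rng.permutation(n)
        Wp = W[np.ix_(perm, perm)]
        assert np.allclose(node_strength(_conn(Wp)), node_strength(_conn(W))[perm])
        assert np.allclose(local_efficiency(_conn(Wp)), local_efficiency(_conn(W))[perm])
        assert np.isclose(global_efficiency(_conn(Wp)), global_efficiency(_conn(W)))


class TestProportionalThreshold:
    def test_reference_edge_count(self):
        rng = np.random.default_rng(6)
        n = 128
        W = rng.uniform(0, 1, (n, n))
        W = np.triu(W, 1)
        W = W + W.T
        out = proportional_threshold(_conn(W), 0.02)
        kept = np.count_nonzero(np.triu(out.W, 1))
        assert kept == 163  # round-half-up of 0.02 * 8128 = 162.56

    def test_full_proportion_is_identity(self):
        rng = np.random.default_rng(7)
        W = rng.uniform(0, 1, (6, 6))
        W = np.triu(W, 1)
        W = W + W.T
        out = proportional_threshold(_conn(W), 1.0)
        assert np.allclose(out.W, W)

    def test_all_equal_weights_deterministic_tie_break(self):
        n = 5
        W = 0.5 * (1.0 - np.eye(n))
        out = proportional_threshold(_conn(W), 0.5)
        iu, ju = np.triu_indices(n, 1)
        kept = [(i, j) for i, j in zip(iu, ju) if out.W[i, j] > 0]
        assert len(kept) == 5  # round-half-up of 0.5 * 10
        # ties broken by (lower channel index, lower partner index)
        assert kept == [(0, 1), (0, 2), (0, 3), (0, 4), (1, 2)]

    def test_out_of_range_proportion(self):
        with pytest.raises(ValueError):
            proportional_threshold(_conn(np.zeros((3, 3))), 0.0)
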