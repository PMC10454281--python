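import numpy as np
import pytest

from eegmotor.ersp_itc import (
    ChannelFreqTimeMap,
    band_window_average,
    baseline_mean_power,
    ersp,
    itc,
    resultant_length,
    single_trial_gain,
)
from eegmotor.timefreq import TFDecomposition, make_frequency_grid


def _tf(coeffs, sfreq=256.0, t0_index=None, grid=None):
    coeffs = np.asarray(coeffs, dtype=complex)
    n = coeffs.shape[-1]
    if t0_index is None:
        t0_index = n // 2
    times = (np.arange(n) - t0_index) / sfreq * 1000.0
    if grid is None:
        grid = make_frequency_grid(1.0, 2.0 ** (coeffs.shape[2] - 1) + 1e-9, 2.0)
    return TFDecomposition(coeffs=coeffs, grid=grid, times=times, sfreq=sfreq,
                           ch_names=[f"c{i}" for i in range(coeffs.shape[1])])


class TestBaseline:
    def test_constant_power(self):
        tf = _tf(np.full((3, 2, 1, 2048), 2.0))  # |F|^2 = 4 everywhere
        base = baseline_mean_power(tf)
        assert base.shape == (3, 2, 1)
        assert np.allclose(base, 4.0)

    def test_mean_of_two_values(self):
        n = 2048
        coeffs = np.full((1, 1, 1, n), np.sqrt(2.0), dtype=complex)
        tf = _tf(coeffs)
        mask = tf.time_mask((-3500.0, -3000.0))
        idx = np.flatnonzero(mask)[:64]
        coeffs[0, 0, 0, idx] = np.sqrt(6.0)
        # half the baseline samples have power 6, half power 2 -> mean 4
        assert np.flatnonzero(mask).size == 128
        base = baseline_mean_power(_tf(coeffs))
        assert np.isclose(base[0, 0, 0], 4.0)

    def test_reference_window_sample_count(self):
        tf = _tf(np.ones((1, 1, 1, 2048)))
        assert tf.time_mask((-3500.0, -3000.0)).sum() == 128  # 0.5 s x 256 Hz

    def test_empty_window_rejected(self):
        tf = _tf(np.ones((1, 1, 1, 64)))
        with pytest.raises(ValueError):
            baseline_mean_power(tf, (-3500.0, -3000.0))


class TestSingleTrialGain:
    def test_power_equal_to_baseline_gives_unit_gain(self):
        tf = _tf(np.full((2, 1, 1, 2048), 3.0))
        gains = single_trial_gain(tf, baseline_mean_power(tf))
        assert np.allclose(gains, 1.0)

    def test_gain_ratio(self):
        base = np.full((1, 1, 1), 4.0)
        tf = _tf(np.full((1, 1, 1, 16), np.sqrt(40.0)))
        gains = single_trial_gain(tf, base)
        assert np.allclose(gains, 10.0)

    def test_equal_gains_from_different_baselines(self):
        n = 2048
        c1 = np.full((1, 1, 1, n), 1.0, dtype=complex)
        c2 = np.full((1, 1, 1, n), 5.0, dtype=complex)
        tf = _tf(np.concatenate([c1, c2]))
        gains = single_trial_gain(tf, baseline_mean_power(tf))
        assert np.allclose(gains[0], gains[1])


class TestErsp:
    def test_unit_gain_zero_db(self):
        assert np.allclose(ersp(np.ones((4, 1, 1, 8))), 0.0)

    def test_single_trial_ten_db(self):
        assert np.allclose(ersp(np.full((1, 1, 1, 1), 10.0)), 10.0)

    def test_two_trial_formula(self):
        gains = np.stack([np.full((1, 1, 1), 1.0), np.full((1, 1, 1), 100.0)])
        assert np.isclose(ersp(gains)[0, 0, 0], 10 * np.log10(50.5))

    def test_global_rescaling_invariance(self):
        rng = np.random.default_rng(0)
        coeffs = rng.standard_normal((5, 2, 3, 2048)) + 1j * rng.standard_normal((5, 2, 3, 2048))
        tf1 = _tf(coeffs, grid=make_frequency_grid(1, 4.1, 2))
        tf2 = _tf(7.3 * coeffs, grid=make_frequency_grid(1, 4.1, 2))
        e1 = ersp(single_trial_gain(tf1, baseline_mean_power(tf1)))
        e2 = ersp(single_trial_gain(tf2, baseline_mean_power(tf2)))
        assert np.allclose(e1, e2, atol=1e-10)


class TestItc:
    def test_identical_phases_give_one(self):
        coeffs = np.exp(1j * 0.9) * np.ones((50, 1, 1, 8))
        assert np.allclose(itc(_tf(coeffs)).values, 1.0)

    def test_uniform_phase_lattice_gives_zero(self):
        n = 8
        phases = 2 * np.pi * np.arange(n) / n
        coeffs = np.exp(1j * phases)[:, None, None, None] * np.ones((n, 1, 1, 4))
        assert np.all(itc(_tf(coeffs)).values < 1e-12)

    def test_two_trial_quadrature(self):
        coeffs = np.stack([np.ones((1, 1, 2)), 1j * np.ones((1, 1, 2))])
        assert np.allclose(itc(_tf(coeffs)).values, np.sqrt(2) / 2)

    def test_amplitude_invariance(self):
        rng = np.random.default_rng(1)
        phases = rng.uniform(0, 2 * np.pi, size=(20, 2, 3, 16))
        amps = rng.uniform(0.1, 10.0, size=(20, 1, 1, 1))
        v1 = itc(_tf(np.exp(1j * phases))).values
        v2 = itc(_tf(amps * np.exp(1j * phases))).values
        assert np.allclose(v1, v2, atol=1e-12)
        assert v1.min() >= 0 and v1.max() <= 1

    def test_needs_two_trials(self):
        with pytest.raises(ValueError):
            itc(_tf(np.ones((1, 1, 1, 4))))

    def test_resultant_length_matches_direct_formula(self):
        rng = np.random.default_rng(2)
        ph = rng.uniform(-np.pi, np.pi, size=(30, 5))
        direct = np.abs(np.exp(1j * ph).mean(axis=0))
        assert np.allclose(resultant_length(ph, axis=0), direct)


class TestBandWindowAverage:
    def _map(self, values, sfreq=256.0):
        grid = make_frequency_grid(0.32, 73.0, 1.1)
        n = values.shape[-1]
        times = (np.arange(n) - n // 2) / sfreq * 1000.0
        return ChannelFreqTimeMap(values=values, kind="ERSP_dB", grid=grid, times=times,
                                  sfreq=sfreq, ch_names=[f"c{i}" for i in range(values.shape[0])],
                                  n_trials=10)

    def test_constant_map(self):
        m = self._map(np.full((3, 57, 512), 0.5))
        vals, n_cells = band_window_average(m, "theta", (-150.0, 150.0))
        assert np.allclose(vals, 0.5)

    def test_window_cell_count(self):
        m = self._map(np.zeros((1, 57, 512)))
        _, n_cells = band_window_average(m, "theta", (-150.0, 150.0))
        grid = m.grid
        n_theta = sum(1 for f in grid.freqs if 4.0 <= f < 8.0)
        assert n_cells == n_theta * 76  # 300 ms at 256 Hz -> 76 on-grid samples

    def test_band_membership_against_scan(self):
        rng = np.random.default_rng(3)
        vals = rng.standard_normal((2, 57, 64))
        m = self._map(vals)
        got, _ = band_window_average(m, "theta", (-100.0, 100.0))
        fidx = [i for i, f in enumerate(m.grid.freqs) if 4.0 <= f < 8.0]
        tmask = m.time_mask((-100.0, 100.0))
        expected = vals[:, fidx][:, :, tmask].mean(axis=(1, 2))
        assert np.allclose(got, expected)

    def test_band_without_grid_support_errors(self):
        grid = make_frequency_grid(20.0, 60.0, 1.1)
        vals = np.zeros((1, grid.n_freqs, 64))
        times = (np.arange(64) - 32) / 256.0 * 1000
        m = ChannelFreqTimeMap(values=vals, kind="ERSP_dB", grid=grid, times=times,
                               sfreq=256.0, ch_names=["c0"], n_trials=2)
        with pytest.raises(ValueError, match="delta"):
            band_window_average(m, "delta", (-100.0, 100.0))
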