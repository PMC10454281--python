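import numpy as np
import pytest

from eegmotor.ersp_itc import itc
from eegmotor.synthetic import (
    GroupParams,
    SyntheticCohortConfig,
    generate_cohort,
    generate_subject,
    theoretical_itc,
)
from eegmotor.timefreq import make_frequency_grid, morlet_cwt


def small_config(n_trials=50, kappa=1.0, **kw):
    cfg = SyntheticCohortConfig.desk_scale(n_subjects=2, n_channels=8, n_trials=n_trials)
    cfg.noise_amplitude = 1.0
    cfg.groups["old"] = GroupParams(n_trials=n_trials, kappa=kappa,
                                    induced_gain=0.5, coupling_amplitude=12.0)
    for k, v in kw.items():
        setattr(cfg, k, v)
    return cfg


def estimated_itc_at_event(ep, f_pl, channel):
    grid = make_frequency_grid(f_pl / 1.1**2, f_pl * 1.1**2.5, 1.1)
    tf = morlet_cwt(ep, grid)
    m = itc(tf)
    fi = int(np.argmin(np.abs(grid.freqs - f_pl)))
    ti = int(np.argmin(np.abs(ep.times)))
    return m.values[ep.ch_names.index(channel), fi, ti]


class TestTheoreticalItc:
    def test_uniform_limit(self):
        assert theoretical_itc(0.0) == 0.0

    def test_point_mass_limit(self):
        assert theoretical_itc(np.inf) == 1.0
        assert theoretical_itc(1e6) > 0.999

    def test_bessel_ratio_value(self):
        assert np.isclose(theoretical_itc(2.0), 0.6978, atol=1e-4)

    def test_monotone_in_kappa(self):
        ks = np.linspace(0, 10, 30)
        vals = [theoretical_itc(k) for k in ks]
        assert np.all(np.diff(vals) > 0)

    def test_negative_kappa_rejected(self):
        with pytest.raises(ValueError):
            theoretical_itc(-0.5)


class TestGenerateSubject:
    def test_deterministic_given_seed(self):
        cfg = small_config(n_trials=5)
        a = generate_subject(cfg, "old", 123)
        b = generate_subject(cfg, "old", 123)
        assert np.array_equal(a.data, b.data)
        c = generate_subject(cfg, "old", 124)
        assert not np.array_equal(a.data, c.data)

    def test_identical_phase_limit_gives_full_coherence(self):
        cfg = small_config(n_trials=50, kappa=1e6)
        ep = generate_subject(cfg, "old", 0)
        est = estimated_itc_at_event(ep, cfg.pl_freq, cfg.pl_target_channels[0])
        assert est >= 0.99

    def test_uniform_phases_give_low_coherence(self):
        cfg = small_config(n_trials=100, kappa=0.0)
        ep = generate_subject(cfg, "old", 1)
        est = estimated_itc_at_event(ep, cfg.pl_freq, cfg.pl_target_channels[0])
        assert est < 0.2  # E[R] ~ 1/sqrt(n) under uniformity

    def test_shapes_and_metadata(self):
        cfg = small_config(n_trials=4)
        ep = generate_subject(cfg, "young", 2, subject_id="y00")
        assert ep.data.shape == (cfg.groups["young"].n_trials, 8, ep.n_samples)
        assert list(ep.metadata["group"].unique()) == ["young"]
        assert list(ep.metadata["subject"].unique()) == ["y00"]

    def test_unknown_group_rejected(self):
        with pytest.raises(KeyError):
            generate_subject(small_config(), "elderly", 0)


class TestConfigValidation:
    def test_trial_and_kappa_bounds(self):
        with pytest.raises(ValueError):
            GroupParams(n_trials=1, kappa=1.0, induced_gain=1.0, coupling_amplitude=0.0)
        with pytest.raises(ValueError):
            GroupParams(n_trials=10, kappa=-1.0, induced_gain=1.0, coupling_amplitude=0.0)
        with pytest.raises(ValueError):
            GroupParams(n_trials=10, kappa=1.0, induced_gain=0.0, coupling_amplitude=0.0)

    def test_event_window_must_lie_inside_epoch(self):
        with pytest.raises(ValueError):
            SyntheticCohortConfig(induced_window_ms=(-5000.0, 150.0))

    def test_phase_lag_range(self):
        with pytest.raises(ValueError):
            SyntheticCohortConfig(coupling_phase_lag=0.0)
        with pytest.raises(ValueError):
            SyntheticCohortConfig(coupling_phase_lag=np.pi)

    def test_target_channels_must_exist(self):
        with pytest.raises(ValueError):
            SyntheticCohortConfig(pl_target_channels=["ZZ9"])


class TestGenerateCohort:
    def test_group_sizes_and_determinism(self):
        cfg = small_config(n_trials=4)
        c1 = generate_cohort(cfg, master_seed=5)
        c2 = generate_cohort(cfg, master_seed=5)
        assert set(c1.groups) == {"young", "old"}
        assert len(c1.groups["old"]) == cfg.n_subjects
        assert np.array_equal(c1.groups["old"][0].data, c2.groups["old"][0].data)

    def test_ground_truth_matches_parameters(self):
        cfg = small_config(n_trials=4)
        c = generate_cohort(cfg, master_seed=0)
        gt = c.ground_truth
        for name, gp in cfg.groups.items():
            assert gt.itc[name] == pytest.approx(theoretical_itc(gp.kappa))
            assert gt.ersp_db[name] == pytest.approx(20 * np.log10(gp.induced_gain))
        assert 0 <= min(gt.itc.values()) and max(gt.itc.values()) <= 1

    def test_trial_equalization(self):
        cfg = small_config(n_trials=8)
        cfg.groups["young"] = GroupParams(n_trials=12, kappa=1.0, induced_gain=0.8,
                                          coupling_amplitude=6.0)
        cfg.equalize_trials = True
        c = generate_cohort(cfg, master_seed=3)
        assert all(ep.n_trials == 8 for subs in c.groups.values() for ep in subs)

    def test_group_itc_ordering_follows_kappa(self):
        """Higher phase concentration must produce higher estimated ITC."""
        cfg = small_config(n_trials=40)
        cfg.groups["young"] = GroupParams(n_trials=40, kappa=1.0, induced_gain=0.8,
                                          coupling_amplitude=6.0)
        cfg.groups["old"] = GroupParams(n_trials=40, kappa=4.0, induced_gain=0.5,
                                        coupling_amplitude=6.0)
        wins = 0
        for seed in range(5):
            c = generate_cohort(cfg, master_seed=seed)
            ch = cfg.pl_target_channels[0]
            old = np.mean([estimated_itc_at_event(ep, cfg.pl_freq, ch)
                           for ep in c.groups["old"]])
            young = np.mean([estimated_itc_at_event(ep, cfg.pl_freq, ch)
                             for ep in c.groups["young"]])
            wins += old > young
        assert wins == 5

    def test_no_coupling_gives_no_spurious_dwpli(self):
        from eegmotor.connectivity import dwpli_matrix

        cfg = small_config(n_trials=100)
        cfg.groups["old"] = GroupParams(n_trials=100, kappa=2.0, induced_gain=0.5,
                                        coupling_amplitude=0.0)
        ep = generate_subject(cfg, "old", 11)
        grid = make_frequency_grid(4.0, 7.99, 1.1)
        tf = morlet_cwt(ep, grid)
        conn = dwpli_matrix(tf, "theta", (-150.0, 150.0))
        assert conn.W.max() < 0.3

    def test_too_few_subjects_rejected(self):
        cfg = small_config()
        cfg.n_subjects = 1
        with pytest.raises(ValueError):
            generate_cohort(cfg, master_seed=0)
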