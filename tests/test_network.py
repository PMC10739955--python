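"""Network model: protocol construction, closed-form oracles, rule updates,
fast-vs-dense equivalence, and reproducibility."""

import numpy as np
import pytest
from scipy.signal import lfilter

from crhmem import network as nw


class TestProtocol:
    def test_aversive_defaults_have_ten_thirty_second_shocks(self):
        proto = nw.build_protocol("aversive")
        assert len(proto.fs_times_s) == 10
        assert np.allclose(np.diff(proto.fs_times_s), 30.0)
        assert proto.fs_times_s[0] == 900.0 and proto.fs_times_s[-1] == 1170.0

    def test_control_has_no_stimuli(self):
        proto = nw.build_protocol("control")
        assert proto.fs_times_s == () and proto.nut_time_s is None

    def test_appetitive_nut_time(self):
        proto = nw.build_protocol("appetitive")
        assert proto.nut_time_s == 930.0 and proto.fs_times_s == ()

    def test_invalid_overrides_rejected(self):
        with pytest.raises(ValueError):
            nw.build_protocol("aversive", fs_times_s=(100.0,))  # outside novel context
        with pytest.raises(ValueError):
            nw.build_protocol("aversive", nut_time_s=930.0)
        with pytest.raises(ValueError):
            nw.build_protocol("bogus")

    def test_shorten_scales_protocol_and_plasticity(self):
        p = nw.preset_params("fs_table1")
        proto = nw.build_protocol("aversive")
        ps, prs = nw.shorten(p, proto, 4)
        assert prs.total_duration_s == pytest.approx(547.5)
        assert prs.fs_times_s[0] == pytest.approx(225.0)
        assert ps.epsilon == pytest.approx(4 * p.epsilon)
        assert ps.tau_omega == pytest.approx(p.tau_omega / 4)
        assert prs.nut_width_s2 == pytest.approx(proto.nut_width_s2 / 16)

    def test_params_validation(self):
        with pytest.raises(ValueError):
            nw.NetworkParams(v_reset=-40, v_threshold=-40).validate()
        with pytest.raises(ValueError):
            nw.NetworkParams(tau_m=0).validate()
        with pytest.raises(ValueError):
            nw.NetworkParams(r_thresh="adaptive").validate()
        nw.NetworkParams(r_thresh="adaptive:90").validate()


class TestStimulusWaveforms:
    def test_fs_gaussian_values(self):
        times = tuple(900.0 + 30 * k for k in range(10))
        assert nw.fs_current(900.0, times) == pytest.approx(1.0, abs=1e-12)
        assert nw.fs_current(915.0, times) == pytest.approx(0.0, abs=1e-30)
        assert nw.fs_current(901.0, times) == pytest.approx(np.exp(-1), rel=1e-9)

    def test_nut_gaussian_values(self):
        assert nw.nut_current(930.0, 930.0) == pytest.approx(1.0)
        assert nw.nut_current(1030.0, 930.0) == pytest.approx(np.exp(-1))
        assert nw.nut_current(1e6, 930.0) == pytest.approx(0.0, abs=1e-12)
        assert nw.nut_current(100.0, None) == 0.0


class TestContextFilter:
    def test_single_spike_peak_time_matches_closed_form(self):
        td, tr = 20.0, 2.0
        p = nw.NetworkParams(n_neurons=1, n_context=1, dt=0.05)
        state = nw.NetworkState.initial(p, np.zeros((1, 1)))
        vals = []
        for k in range(1200):
            counts = np.array([1.0]) if k == 0 else np.array([0.0])
            vals.append(nw.context_filter_update(state, p, counts)[0])
        t_peak = (np.argmax(vals)) * p.dt   # spike lands at step 0
        closed = td * tr / (td - tr) * np.log(td / tr)
        assert t_peak == pytest.approx(closed, abs=0.1)

    def test_zero_rate_gives_zero_drive(self):
        p = nw.NetworkParams(n_neurons=1, n_context=4)
        state = nw.NetworkState.initial(p, np.zeros((1, 4)))
        for _ in range(100):
            r = nw.context_filter_update(state, p, np.zeros(4))
        assert np.all(r == 0)

    def test_poisson_time_average_matches_filter_integral(self):
        rate, dt_s = 8.0, 0.001
        rng = np.random.default_rng(0)
        counts = rng.poisson(rate * dt_s, 200000).astype(float)
        ad, ar = np.exp(-1 / 20.0), np.exp(-1 / 2.0)
        fd = lfilter([1.0], [1.0, -ad], counts)
        fr = lfilter([1.0], [1.0, -ar], counts)
        mean = (fd - fr).mean()
        expected = rate * (0.020 - 0.002)
        assert mean == pytest.approx(expected, rel=0.05)


class TestMembraneDynamics:
    def test_subthreshold_bias_never_spikes(self):
        p = nw.preset_params("fs_table1", n_neurons=2, n_context=1, noise_sd=0.0,
                             context_gain=0.0, fs_weight_mean=0.0, fs_weight_sd=0.0)
        proto = nw.StimulusProtocol(total_duration_s=20.0,
                                    novel_context_intervals_s=(),
                                    context_rate_home_hz=0.0, mode="control")
        res = nw.simulate(p, proto)
        assert all(len(s) == 0 for s in res.spike_times)
        assert np.all(res.r_slow == 0)

    @pytest.mark.parametrize("drive", [-30.0, -25.0, -20.0, -15.0, -10.0])
    def test_isi_matches_closed_form_within_one_step(self, drive):
        dt = 0.1
        p = nw.preset_params("fs_table1", n_neurons=1, n_context=1, noise_sd=0.0,
                             d=0.0, context_gain=0.0, fs_weight_mean=0.0,
                             fs_weight_sd=0.0, i_bias=drive, dt=dt)
        proto = nw.StimulusProtocol(total_duration_s=2.0,
                                    novel_context_intervals_s=(),
                                    context_rate_home_hz=0.0, mode="control")
        res = nw.simulate(p, proto)
        isis = np.diff(res.spike_times[0]) * 1000.0
        exact = p.tau_m * np.log((drive - p.v_reset) / (drive - p.v_threshold))
        assert np.abs(isis - exact).max() <= dt

    def test_adaptation_jump_and_decay(self):
        p = nw.NetworkParams(n_neurons=1, n_context=1, noise_sd=0.0)
        state = nw.NetworkState.initial(p, np.zeros((1, 1)))
        state.v[0] = p.v_threshold + 5.0   # force an immediate spike
        spiked = nw.step_network(state, p, np.zeros(1), 0.0, 0.0,
                                 np.zeros(1), np.zeros(1))
        assert spiked[0] and state.w_adapt[0] == pytest.approx(p.d)
        w0 = state.w_adapt[0]
        for _ in range(100):
            nw.step_network(state, p, np.zeros(1), 0.0, 0.0,
                            np.zeros(1), np.zeros(1))
        assert state.w_adapt[0] == pytest.approx(w0 * (1 - p.dt / p.tau_w) ** 100)


class TestLearningRules:
    def _state(self, p, s0=0.0, r_slow=0.0):
        st = nw.NetworkState.initial(p, np.full((1, p.n_context), s0 / p.n_context))
        st.slow_fd[0] = r_slow   # slow_fr = 0 -> r_slow = slow_fd
        return st

    def test_two_factor_hand_evaluated_step(self):
        p = nw.NetworkParams(n_neurons=1, n_context=10, epsilon=0.014,
                             omega_ceiling=0.0031)
        st = self._state(p, s0=0.0, r_slow=2.0)
        a_before = st.a.sum()
        nw.apply_two_factor_rule(st, p, r_thresh=1.0)
        assert st.a.sum() - a_before == pytest.approx(0.014 * 0.0031 * 2 * 0.001,
                                                      rel=1e-9)

    def test_two_factor_gate_and_ceiling_close_the_update(self):
        p = nw.NetworkParams(n_neurons=1, n_context=10, epsilon=0.014,
                             omega_ceiling=0.0031)
        st = self._state(p, s0=0.0031, r_slow=5.0)     # at ceiling
        a0 = st.a.copy()
        nw.apply_two_factor_rule(st, p, r_thresh=1.0)
        assert np.allclose(st.a, a0)
        st = self._state(p, s0=0.0, r_slow=0.5)        # below gate
        a0 = st.a.copy()
        nw.apply_two_factor_rule(st, p, r_thresh=1.0)
        assert np.allclose(st.a, a0)
        st = self._state(p, s0=0.0, r_slow=1.0)        # H(0) = 0: tie stays shut
        a0 = st.a.copy()
        nw.apply_two_factor_rule(st, p, r_thresh=1.0)
        assert np.allclose(st.a, a0)

    def test_one_factor_hand_evaluated_step(self):
        p = nw.NetworkParams(n_neurons=1, n_context=10, epsilon=2e-6,
                             omega_ceiling=-1.0, nut_thresh=0.5)
        st = self._state(p, s0=0.5)
        a_before = st.a.sum()
        nw.apply_one_factor_rule(st, p, nut_t=0.9)
        assert st.a.sum() - a_before == pytest.approx(2e-6 * (-1.5) * 0.001, rel=1e-9)
        st2 = self._state(p, s0=0.5)
        a0 = st2.a.copy()
        nw.apply_one_factor_rule(st2, p, nut_t=0.4)    # gate shut
        assert np.allclose(st2.a, a0)


class TestSimulate:
    def test_fast_path_matches_dense_reference(self):
        rng = np.random.default_rng(42)
        n, m = 4, 8
        proto = nw.StimulusProtocol(total_duration_s=30.0,
                                    novel_context_intervals_s=((5.0, 15.0), (20.0, 30.0)),
                                    fs_times_s=(10.0, 12.0), mode="aversive")
        p = nw.preset_params("fs_table1", n_neurons=n, n_context=m,
                             noise_sd=0.0, r_thresh=2.0, seed=0)
        n_steps = int(round(30.0 / p.dt_s))
        t = (np.arange(n_steps) + 1) * p.dt_s
        rate = np.full(n_steps, 1.0)
        for a, b in proto.novel_context_intervals_s:
            rate[(t >= a) & (t < b)] = 8.0
        counts = rng.poisson(rate[:, None] * p.dt_s, (n_steps, m)).astype(float)
        w_fs = rng.normal(2, 1, n)
        w_nut = rng.uniform(-0.09, 0.01, n)
        s0 = rng.uniform(0, 0.0031, n)
        fast = nw.simulate(p, proto, _inputs=(w_fs, w_nut, s0, counts.sum(axis=1)))
        dense = nw.simulate_dense(p, proto, counts,
                                  np.repeat((s0 / m)[:, None], m, axis=1),
                                  w_fs, w_nut, r_thresh=2.0)
        assert np.array_equal(fast.r_slow, dense.r_slow)
        assert np.allclose(fast.omega_sum, dense.omega_sum, atol=1e-15)
        for a, b in zip(fast.spike_times, dense.spike_times):
            assert np.allclose(a, b)

    def test_same_seed_identical_spike_trains(self):
        p = nw.preset_params("fs_table1", n_neurons=10, seed=5)
        proto = nw.build_protocol("aversive")
        ps, prs = nw.shorten(p, proto, 16)
        r1 = nw.simulate(ps, prs)
        r2 = nw.simulate(ps, prs)
        for a, b in zip(r1.spike_times, r2.spike_times):
            assert np.array_equal(a, b)
        assert np.array_equal(r1.r_slow, r2.r_slow)

    def test_spike_times_strictly_increasing(self):
        p = nw.preset_params("fs_table1", n_neurons=10, seed=5)
        ps, prs = nw.shorten(p, nw.build_protocol("aversive"), 16)
        res = nw.simulate(ps, prs)
        for sp in res.spike_times:
            assert np.all(np.diff(sp) > 0)

    def test_wall_budget_guard(self):
        p = nw.preset_params("fs_table1")
        proto = nw.build_protocol("aversive")
        with pytest.raises(ValueError, match="budget"):
            nw.simulate(p, proto, max_wall_s=0.001)

    def test_halving_dt_changes_population_epoch_means_little(self):
        means = {}
        for dt in (1.0, 0.5):
            p = nw.preset_params("fs_table1", seed=3, dt=dt, n_neurons=50)
            ps, prs = nw.shorten(p, nw.build_protocol("aversive"), 8)
            em = nw.simulate(ps, prs).epoch_means()
            means[dt] = em.mean()
        for epoch in ("home", "pre", "fs", "post"):
            assert means[0.5][epoch] == pytest.approx(means[1.0][epoch], rel=0.05)

    def test_epoch_means_oracle_values(self):
        p = nw.preset_params("fs_table1", n_neurons=2)
        proto = nw.build_protocol("control")
        n_samp = 100
        r_slow = np.vstack([np.full(n_samp, 2.5), np.linspace(0, 1, n_samp)])
        res = nw.SimulationResult([np.array([])] * 2, r_slow, np.zeros_like(r_slow),
                                  1.0, np.zeros(2), np.zeros(2), np.zeros(2),
                                  np.zeros(2), p, proto)
        em = nw.epoch_means(res, {"w": (0.0, 100.0), "one": (49.5, 50.5)})
        assert em["w"][0] == pytest.approx(2.5)
        assert em["w"][1] == pytest.approx(0.5, abs=0.01)
        assert em["one"][0] == pytest.approx(2.5)
        with pytest.raises(ValueError):
            nw.epoch_means(res, {"empty": (200.0, 300.0)})

    def test_result_h5_roundtrip(self, tmp_path):
        p = nw.preset_params("fs_table1", n_neurons=5, seed=1)
        ps, prs = nw.shorten(p, nw.build_protocol("control"), 16)
        res = nw.simulate(ps, prs)
        nw.save_result_h5(res, tmp_path / "run.h5")
        import h5py
        with h5py.File(tmp_path / "run.h5") as f:
            assert f["r_slow"].shape == res.r_slow.shape
            assert f["meta"].attrs["mode"] == "control"
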