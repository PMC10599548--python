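"""Dynamics: closed-form oracles, invariants, ablations, calibration."""

import dataclasses

import numpy as np
import pytest

from oddnet import (
    GenParams,
    ModelParams,
    SimState,
    calibrate_epsp,
    calibrate_stimulus,
    generate_network,
    make_sequence,
    run_sequence,
)
from oddnet.simulate import _Engine, epsp_peak, isolated_response_counts

from conftest import build_chain_network


def free_run(params, state, n_steps, scripted=None):
    """Step an isolated 2-neuron system (0 -> 1); ``scripted`` maps step
    index to presynaptic spikes delivered at that step."""
    net = build_chain_network(2)
    engine = _Engine(net, params)
    vs = []
    for s in range(n_steps):
        pending = scripted.get(s) if scripted else None
        engine.step(state, pending)
        vs.append(state.V.copy())
    return np.asarray(vs)


class TestClosedFormExamples:
    def test_membrane_decay_matches_exponential(self):
        """From -70 mV with no input, V relaxes to -60 - 10 e^{-t/tau_m}."""
        p = ModelParams(dt=0.1)
        state = SimState.recovered(2, p)
        state.V[:] = -70.0
        vs = free_run(p, state, n_steps=300)
        expected = -60.0 - 10.0 * np.exp(-1.0)
        assert vs[-1][0] == pytest.approx(expected, abs=0.02)

    def test_depression_recovery_is_exact(self):
        """x jumps to 1-U after a spike and recovers as 1 - U e^{-t/tau_x};
        the engine uses exact decay factors, so this holds to rounding."""
        p = ModelParams()
        net = build_chain_network(2)
        engine = _Engine(net, p)
        state = SimState.recovered(2, p)
        state.V[0] = -53.0  # above threshold: spikes at the first step
        engine.step(state, None)
        assert state.x[0] == pytest.approx(0.6, abs=1e-12)
        for _ in range(150):
            engine.step(state, None)
        assert state.x[0] == pytest.approx(1 - 0.4 * np.exp(-1.0), rel=1e-9)

    def test_threshold_adaptation_decay_is_exact(self):
        """theta jumps by 1 mV at a spike and decays with tau_theta = 1 s."""
        p = ModelParams()
        net = build_chain_network(2)
        engine = _Engine(net, p)
        state = SimState.recovered(2, p)
        state.V[0] = -53.0
        engine.step(state, None)
        assert state.theta[0] == 1.0
        for _ in range(1000):
            engine.step(state, None)
        assert state.theta[0] == pytest.approx(np.exp(-1.0), rel=1e-9)

    def test_rest_is_a_fixed_point(self):
        p = ModelParams()
        state = SimState.recovered(2, p)
        vs = free_run(p, state, 200)
        assert (vs == p.V_rest).all()
        assert (state.x == 1.0).all() and (state.theta == 0.0).all()

    @staticmethod
    def trajectory_error(dt: float) -> float:
        """Max deviation of a subthreshold scripted-input trajectory from the
        exact solution of the conductance-based membrane equation
        (independently integrated to high accuracy), as a fraction of the
        trajectory's range."""
        from scipy.integrate import solve_ivp

        p = ModelParams(dt=dt, epsp_scale=100.0)  # sizable yet subthreshold
        rm = p.R_m * 1e-3
        spikes_e = [5.0, 12.0]
        amt_e = p.U * p.w * p.epsp_scale
        scripted = {int(round(t / dt)): (np.array([0]), np.array([1.0])) for t in spikes_e}
        state = SimState.recovered(2, p)
        n_steps = int(round(80.0 / dt))
        vs = free_run(p, state, n_steps=n_steps, scripted=scripted)
        v_sim = vs[:, 1]

        def g_e(t):
            return sum(amt_e * np.exp(-(t - ts) / p.tau_e) for ts in spikes_e if t >= ts)

        def rhs(t, y):
            return ((p.V_rest - y[0]) + rm * g_e(t) * (p.E_e - y[0])) / p.tau_m

        sol = solve_ivp(
            rhs, (0, 80), [p.V_rest], t_eval=dt * np.arange(1, n_steps + 1),
            rtol=1e-10, atol=1e-12, max_step=0.25,
        )
        v_ref = sol.y[0]
        vrange = v_ref.max() - v_ref.min()
        assert vrange > 1.0  # the input actually moves the membrane
        return float(np.max(np.abs(v_sim - v_ref)) / vrange)

    def test_subthreshold_trajectory_matches_ode_oracle(self):
        """The discrete trajectory follows the exact membrane solution to
        within 1% of its range at fine step sizes, converging linearly in dt
        (forward Euler on the voltage)."""
        err_fine = self.trajectory_error(0.025)
        err_mid = self.trajectory_error(0.05)
        err_coarse = self.trajectory_error(0.1)
        assert err_fine < 0.01
        assert err_coarse < 0.025
        assert err_fine < 0.7 * err_mid < 0.5 * err_coarse  # first-order convergence


class TestInvariants:
    def test_state_bounds_throughout_a_run(self, calibrated_params):
        net = generate_network(GenParams(n_exc=120, n_inh=30, seed=5))
        p = dataclasses.replace(calibrated_params, stim_amplitude=1616.0)
        engine = _Engine(net, p)
        state = SimState.recovered(net.n_neurons, p)
        pending = None
        v_lo = min(p.E_i, p.V_reset)
        for s in range(400):
            ext = (net.stimulated_sets[0], p.stim_amplitude) if s % 100 == 0 else None
            ids, xv = engine.step(state, pending, external=ext)
            pending = (ids, xv)
            assert (state.x > 0).all() and (state.x <= 1).all()
            assert (state.theta >= 0).all()
            assert (state.V >= v_lo).all() and (state.V <= p.E_e).all()

    def test_monotone_recovery_between_spikes(self):
        """Without spikes, x is non-decreasing and theta non-increasing."""
        p = ModelParams()
        net = build_chain_network(2)
        engine = _Engine(net, p)
        state = SimState.recovered(2, p)
        state.x[:] = 0.3
        state.theta[:] = 2.5
        xs, ths = [], []
        for _ in range(500):
            engine.step(state, None)
            xs.append(state.x[0])
            ths.append(state.theta[0])
        assert (np.diff(xs) >= 0).all() and (np.diff(ths) <= 0).all()

    def test_run_sequence_is_deterministic(self, calibrated_params):
        net = generate_network(GenParams(n_exc=120, n_inh=30, seed=5))
        p = dataclasses.replace(calibrated_params, stim_amplitude=1616.0)
        seq = make_sequence("A-as-dev", 1, 2, n_trials=20, seed=3)
        a = run_sequence(net, seq, p)
        b = run_sequence(net, seq, p)
        assert np.array_equal(a.spike_neurons, b.spike_neurons)
        assert np.array_equal(a.spike_times, b.spike_times)
        assert np.array_equal(a.theta_at_onset, b.theta_at_onset)
        assert np.array_equal(a.x_at_onset, b.x_at_onset)

    def test_fast_forward_does_not_change_spikes(self, calibrated_params):
        net = generate_network(GenParams(n_exc=120, n_inh=30, seed=5))
        p = dataclasses.replace(calibrated_params, stim_amplitude=1616.0)
        seq = make_sequence("A-as-dev", 1, 2, n_trials=15, seed=3)
        a = run_sequence(net, seq, p, fast_forward=True)
        b = run_sequence(net, seq, p, fast_forward=False)
        assert np.array_equal(a.spike_neurons, b.spike_neurons)
        assert np.array_equal(a.spike_times, b.spike_times)
        assert np.allclose(a.theta_at_onset, b.theta_at_onset, atol=1e-9)
        assert np.allclose(a.x_at_onset, b.x_at_onset, atol=1e-9)


class TestAblations:
    def _tiny_setup(self, calibrated_params, **overrides):
        net = generate_network(GenParams(n_exc=120, n_inh=30, seed=5))
        p = dataclasses.replace(calibrated_params, stim_amplitude=1616.0, **overrides)
        seq = make_sequence("A-as-dev", 1, 2, n_trials=20, seed=8)
        return net, p, seq

    def test_std_off_equals_instant_recovery(self, calibrated_params):
        """Disabling STD reproduces the model with tau_x -> 0: x pinned to 1
        while the U factor in the increments is retained."""
        net, p_off, seq = self._tiny_setup(calibrated_params, std_enabled=False)
        p_fast = dataclasses.replace(p_off, std_enabled=True, tau_x=1e-9)
        a = run_sequence(net, seq, p_off)
        b = run_sequence(net, seq, p_fast)
        assert np.array_equal(a.spike_neurons, b.spike_neurons)
        assert np.array_equal(a.spike_times, b.spike_times)
        assert (a.x_at_onset == 1.0).all()

    def test_ta_off_equals_zero_increment(self, calibrated_params):
        """Disabling TA pins the threshold to theta0 exactly, matching a
        model whose adaptation increment is zero."""
        net, p_off, seq = self._tiny_setup(calibrated_params, ta_enabled=False)
        p_zero = dataclasses.replace(p_off, ta_enabled=True, theta_inc=0.0)
        a = run_sequence(net, seq, p_off)
        b = run_sequence(net, seq, p_zero)
        assert np.array_equal(a.spike_neurons, b.spike_neurons)
        assert np.array_equal(a.spike_times, b.spike_times)
        assert (a.theta_at_onset == 0.0).all()

    def test_no_plasticity_trials_are_identical_per_site(self, calibrated_params):
        """With both mechanisms off, no state survives the inter-trial gap:
        every trial of the same site yields the identical spike pattern."""
        # sparse connectivity so responses die out within the trial window
        net = generate_network(GenParams(n_exc=120, n_inh=30, out_degree=8, seed=5))
        p = dataclasses.replace(
            calibrated_params, stim_amplitude=1616.0, std_enabled=False, ta_enabled=False
        )
        seq = make_sequence("A-as-dev", 1, 2, n_trials=20, seed=8)
        rec = run_sequence(net, seq, p)
        counts = rec.trial_spike_counts()
        for site in (1, 2):
            site_counts = counts[rec.trial_mask(site)]
            assert (site_counts == site_counts[0]).all()

    def test_empty_sequence_leaves_state_recovered(self, calibrated_params):
        net, p, _ = self._tiny_setup(calibrated_params)
        seq = make_sequence("A-as-dev", 1, 2, n_trials=0)
        rec = run_sequence(net, seq, p)
        assert len(rec.spike_times) == 0 and rec.n_trials == 0


class TestEpspCalibration:
    def test_fitted_peak_hits_target_within_one_percent(self):
        peak, scale = calibrate_epsp(ModelParams())
        assert peak == pytest.approx(1.4, rel=0.01)
        assert scale > 1.0

    def test_zero_weight_gives_zero_epsp(self):
        assert epsp_peak(ModelParams(w=0.0)) == 0.0
        with pytest.raises(ValueError):
            calibrate_epsp(ModelParams(w=0.0))

    def test_small_signal_peak_matches_double_exponential(self):
        """In the linear regime the EPSP is a difference of exponentials;
        the simulated peak matches the analytic peak within 5%."""
        p = ModelParams(dt=0.01)
        scale = 0.05  # tiny increment: driving-force saturation negligible
        peak = epsp_peak(p, scale=scale)
        dg = p.U * p.w * scale
        rm = p.R_m * 1e-3
        a = rm * dg * (p.E_e - p.V_rest) * p.tau_e / (p.tau_m - p.tau_e)
        t_star = np.log(p.tau_m / p.tau_e) / (1 / p.tau_e - 1 / p.tau_m)
        v_star = a * (np.exp(-t_star / p.tau_m) - np.exp(-t_star / p.tau_e))
        assert peak == pytest.approx(v_star, rel=0.05)


class TestStimulusCalibration:
    def test_zero_amplitude_triggers_nothing(self):
        assert isolated_response_counts(ModelParams(), 0.0, is_exc=True) == 0

    def test_direct_response_monotone_in_amplitude(self, calibrated_params):
        grid = np.geomspace(1.0, 1e4, 25)
        for is_exc in (True, False):
            counts = [
                isolated_response_counts(calibrated_params, float(a), is_exc) for a in grid
            ]
            assert (np.diff(counts) >= 0).all()

    def test_calibrated_amplitude_in_band_for_both_types(self, calibrated_params):
        net = generate_network(GenParams(n_exc=60, n_inh=15, seed=1))
        amp = calibrate_stimulus(net, calibrated_params)
        for is_exc in (True, False):
            assert 2 <= isolated_response_counts(calibrated_params, amp, is_exc) <= 3

    def test_unreachable_band_raises(self, calibrated_params):
        net = generate_network(GenParams(n_exc=60, n_inh=15, seed=1))
        with pytest.raises(RuntimeError):
            calibrate_stimulus(net, calibrated_params, grid=np.array([1.0, 2.0]))


class TestSpikeRecordIO:
    def test_csv_json_roundtrip(self, calibrated_params, tmp_path):
        net = generate_network(GenParams(n_exc=60, n_inh=15, seed=2))
        p = dataclasses.replace(calibrated_params, stim_amplitude=1616.0)
        seq = make_sequence("A-in-con", 1, n_trials=10, seed=4)
        rec = run_sequence(net, seq, p)
        rec.save(tmp_path / "run")
        back = type(rec).load(tmp_path / "run")
        assert np.array_equal(rec.spike_neurons, back.spike_neurons)
        assert np.allclose(rec.spike_times, back.spike_times)
        assert np.array_equal(rec.sites, back.sites)
        assert np.allclose(rec.theta_at_onset, back.theta_at_onset)
        assert np.array_equal(rec.trial_spike_counts(), back.trial_spike_counts())
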