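"""Excitatory plasticity: event rules, drift curve, calibration, homeostatic LTD."""

import numpy as np
import pytest

from plastinet.kernel import Network
from plastinet.plasticity_exc import (
    ExcPlasticityParams,
    calibrate_amplitudes,
    drift_fixed_points,
    homeostatic_b,
    post_spike_update,
    pre_spike_update,
    rate_drift_curve,
    trace_third_moment,
)


class TestEventRules:
    def test_silent_post_gives_pure_transmitter_drift(self):
        # z-minus = 0: each presynaptic spike adds exactly delta
        w = pre_spike_update(np.array([0.3]), B=1e-3, zminus=0.0, delta=2e-5, w_max=5.0)
        assert w[0] == pytest.approx(0.3 + 2e-5)

    def test_pre_spike_with_active_post_and_no_delta_depresses(self):
        w = pre_spike_update(np.array([0.3]), B=1e-3, zminus=0.7, delta=0.0, w_max=5.0)
        assert w[0] < 0.3

    def test_heterosynaptic_term_vanishes_at_reference(self):
        w0 = np.array([0.4])
        out = post_spike_update(w0, w0.copy(), A=0.0, zplus=np.array([0.0]),
                                zslow=0.0, beta=10.0, zminus=5.0, w_max=5.0)
        np.testing.assert_allclose(out, w0)

    def test_isolated_post_spike_after_silence_changes_nothing(self):
        w0 = np.array([0.4])
        out = post_spike_update(w0, np.array([0.2]), A=1e-3, zplus=np.array([0.0]),
                                zslow=0.0, beta=0.45, zminus=0.0, w_max=5.0)
        np.testing.assert_allclose(out, w0)

    def test_clamping_to_bounds(self):
        w = pre_spike_update(np.array([0.01]), B=1.0, zminus=1.0, delta=0.0, w_max=5.0)
        assert w[0] == 0.0
        w = post_spike_update(np.array([4.999]), np.array([5.0]), A=1.0,
                              zplus=np.array([10.0]), zslow=10.0, beta=0.0,
                              zminus=0.0, w_max=5.0)
        assert w[0] == 5.0

    def test_transmitter_drift_count_oracle(self):
        # pre at 1 Hz, post silent, 100 s: total drift ~ n_spikes * delta
        p = ExcPlasticityParams()
        net = Network(1, 1, 0, W_in=np.array([[0.3]]), plasticity=p, seed=4)
        rr = net.run(100.0, rate_segments=[(0.0, 100.0, 1.0)])
        n_pre = 100  # expected spike count at 1 Hz over 100 s
        dw = net.W_in[0, 0] - 0.3
        # the post neuron never fires (one weak synapse), so dw = N_spk * delta
        assert dw / p.delta == pytest.approx(round(dw / p.delta))
        assert dw / p.delta == pytest.approx(n_pre, abs=3 * np.sqrt(n_pre))


class TestDriftCurve:
    def test_zero_post_rate_leaves_only_transmitter_term(self):
        p = ExcPlasticityParams()
        v = rate_drift_curve(p, nu_pre=10.0, nu_post=0.0)
        assert v == pytest.approx(p.delta * 10.0)

    def test_analytic_calibration_places_stable_zeros_at_1_and_30_hz(self):
        p = calibrate_amplitudes()
        fps = drift_fixed_points(p, nu_pre=10.0)
        stable = sorted(nu for nu, s in fps if s)
        unstable = [nu for nu, s in fps if not s]
        assert stable[0] == pytest.approx(1.0, abs=0.02)
        assert stable[-1] == pytest.approx(30.0, abs=0.1)
        assert len(unstable) == 1 and 1.0 < unstable[0] < 30.0

    def test_no_heterosynaptic_term_removes_elevated_fixed_point(self):
        # beta -> 0: the curve diverges upward, no stable high-rate zero
        p = calibrate_amplitudes()
        from dataclasses import replace

        p0 = replace(p, beta=0.0)
        fps = drift_fixed_points(p0, nu_pre=10.0, nu_range=(1e-3, 200.0))
        assert not any(s and nu > 5.0 for nu, s in fps)
        assert rate_drift_curve(p0, 10.0, 200.0) > 0

    def test_shot_noise_third_moment_against_brute_force(self, rng):
        # brute-force oracle: simulate a shot-noise trace and compare E[z^3]
        nu, tau, dt, T = 20.0, 0.015, 1e-4, 2000.0
        z, acc, n = 0.0, 0.0, 0
        f = np.exp(-dt / tau)
        spikes = rng.random(int(T / dt)) < nu * dt
        for s in spikes:
            z = z * f + (1.0 if s else 0.0)
            acc += z**3
            n += 1
        assert acc / n == pytest.approx(trace_third_moment(nu, tau), rel=0.05)


class TestMonteCarloDrift:
    @pytest.mark.parametrize("nu_pre,nu_post", [(10.0, 5.0), (10.0, 15.0), (20.0, 25.0)])
    def test_event_scheme_matches_rate_drift_curve(self, nu_pre, nu_post):
        """Frozen-weight Monte Carlo drift on Poisson pre/post trains vs analytic curve.

        The postsynaptic neuron is forced to fire a Poisson train (natural
        spiking suppressed by a 1-V threshold), weights are frozen and the
        would-be updates accumulated, so the measured dw/dt corresponds to
        the analytic expectation at fixed (w - wref).
        """
        from plastinet.neurons import NeuronParams

        p = ExcPlasticityParams()
        dw_gap = 0.2
        T, dt = 400.0, 1e-4
        n_steps = int(T / dt)
        rng = np.random.Generator(np.random.PCG64(99))
        net = Network(1, 1, 0, W_in=np.array([[0.5]]), plasticity=p,
                      neurons_e=NeuronParams(thr_rest=1.0), seed=11)
        net.wref_in = np.array([[0.5 - dw_gap]])
        net.consolidation.enabled = False
        net.enable_freeze()
        done = 0
        spc = net.kernel.steps_per_coarse
        while done < n_steps:
            n = min(spc, n_steps - done)
            in_spk = (rng.random((n, 1)) < nu_pre * dt).astype(np.uint8)
            forced = (rng.random((n, 1)) < nu_post * dt).astype(np.uint8)
            net.advance(n, in_spk, forced)
            done += n
        measured = net.acc_in[0, 0] / T
        expected = float(rate_drift_curve(p, nu_pre, nu_post, dw_gap))
        scale = abs(p.delta * nu_pre) + abs(p.A * nu_pre * nu_post**2 * p.tau_plus * p.tau_slow)
        assert measured == pytest.approx(expected, abs=max(0.15 * abs(expected), 0.1 * scale))


class TestHomeostaticLTD:
    def test_disabled_homeostasis_pins_b_at_a(self):
        p = ExcPlasticityParams(homeostasis=False)
        assert np.all(homeostatic_b(p, np.array([0.0, 1e5])) == p.A)

    def test_b_is_monotone_in_slow_trace_and_capped(self):
        p = ExcPlasticityParams(homeostasis=True)
        z = np.linspace(0, 3 * p.nu_ht * p.tau_ht, 50)
        b = homeostatic_b(p, z)
        assert np.all(np.diff(b) >= 0)
        assert b[-1] == p.A  # cap: LTD can never exceed A
        assert b[0] == p.A * p.b_floor

    def test_silent_neuron_b_decays_toward_floor(self):
        # as the slow trace decays, B follows monotonically down to the floor
        p = ExcPlasticityParams(homeostasis=True)
        z = p.nu_ht * p.tau_ht  # start at the cap
        bs = []
        for _ in range(200):
            z *= np.exp(-120.0 / p.tau_ht)  # 2 min of silence per step
            bs.append(float(homeostatic_b(p, z)))
        assert all(b2 <= b1 + 1e-15 for b1, b2 in zip(bs, bs[1:]))
        assert bs[-1] == p.A * p.b_floor

    def test_cap_preserves_elevated_fixed_point_of_drift(self):
        # at the cap B = A the drift still has its stable elevated zero
        p = calibrate_amplitudes()
        fps = drift_fixed_points(p, 10.0, B=p.A)
        assert any(s and nu > 25.0 for nu, s in fps)
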