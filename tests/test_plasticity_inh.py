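"""Inhibitory STDP gated by the global secreted factor H."""

import numpy as np
import pytest

from plastinet.kernel import Network
from plastinet.plasticity_inh import (
    GlobalFactor,
    InhPlasticityParams,
    inh_post_spike_update,
    inh_pre_spike_update,
)


class TestGlobalFactor:
    def test_analytic_decay_without_spikes(self):
        gf = GlobalFactor(InhPlasticityParams(tau_H=10.0), n_exc=100)
        gf.H = 1.0
        for _ in range(1000):
            gf.step(0, 0.01)  # 10 s total = one tau
        assert gf.H == pytest.approx(np.exp(-1.0), rel=1e-3)

    def test_steady_state_filter_reads_population_rate(self, rng):
        # at a steady population rate nu the filter converges to H ~ nu (Hz)
        nu, n_exc, dt = 7.0, 200, 1e-3
        gf = GlobalFactor(InhPlasticityParams(), n_exc=n_exc)
        for _ in range(int(60.0 / dt)):
            gf.step(rng.binomial(n_exc, nu * dt), dt)
        assert gf.H == pytest.approx(nu, rel=0.1)

    def test_g_sign_follows_target(self):
        gf = GlobalFactor(InhPlasticityParams(gamma=3.0), n_exc=10)
        gf.H = 1.0
        assert gf.G < 0  # depression-only regime
        gf.H = 5.0
        assert gf.G > 0  # Hebbian regime


class TestEventRules:
    def test_zero_g_gates_off_all_updates(self):
        w = np.array([0.5])
        assert inh_pre_spike_update(w, 1e-3, 0.0, np.array([2.0]))[0] == 0.5
        assert inh_post_spike_update(w, 1e-3, 0.0, np.array([2.0]))[0] == 0.5

    def test_negative_g_only_depresses_and_clamps_at_zero(self, rng):
        # sign audit over simulated trains: every update with G < 0 is <= 0
        w = np.full(30, 0.05)
        for _ in range(200):
            z = rng.random(30)
            w_new = inh_pre_spike_update(w, 0.01, -2.0, z)
            assert np.all(w_new <= w + 1e-15)
            w = w_new
        assert np.all(w >= 0.0)
        assert np.any(w == 0.0)  # lower clamp engaged

    def test_positive_g_with_correlated_firing_potentiates(self, rng):
        w = np.array([0.1])
        for _ in range(100):
            w = inh_post_spike_update(w, 0.01, +2.0, np.array([0.5]))
        assert w[0] > 0.1


class TestClosedLoop:
    def test_network_homeostasis_pulls_population_rate_toward_gamma(self):
        """A small E-I loop driven too hard relaxes toward the target rate.

        The learning rate is raised so the relaxation completes within a
        short simulation; no target is enforced per neuron, only the
        population filter H approaches gamma.
        """
        n_e, n_i, n_in = 80, 20, 120
        gamma = 3.0
        inh = InhPlasticityParams(eta=2e-3, gamma=gamma)
        rng = np.random.Generator(np.random.PCG64(8))
        W_in = (rng.random((n_in, n_e)) < 0.3) * 1.2   # strong external drive
        W_ei = (rng.random((n_e, n_i)) < 0.3) * 1.0
        W_ie = (rng.random((n_i, n_e)) < 0.3) * 0.2    # weak initial inhibition
        from plastinet.plasticity_exc import ExcPlasticityParams

        net = Network(n_in, n_e, n_i, W_in=W_in, W_ei=W_ei, W_ie=W_ie,
                      inh_plasticity=inh,
                      plasticity=ExcPlasticityParams(enabled=False),
                      plastic_in=False, plastic_ee=False, seed=21)
        rr = net.run(60.0, rate_segments=[(0.0, 60.0, 10.0)], max_rate_hint=500.0)
        sp = rr.spikes_e[:, 0]
        rate_early = ((sp > 2) & (sp < 10)).sum() / 8.0 / n_e
        rate_late = (sp > 45).sum() / 15.0 / n_e
        assert rate_early > 2.0 * gamma          # starts far above target
        assert abs(rate_late - gamma) < 0.5 * (rate_early - gamma)  # relaxes toward it
        assert net.W_ie.max() > 0.2              # inhibition grew

    def test_individual_rates_need_not_match_target(self):
        # after relaxation individual steady-state rates still differ widely
        n_e, n_i, n_in = 80, 20, 120
        inh = InhPlasticityParams(eta=2e-3, gamma=3.0)
        rng = np.random.Generator(np.random.PCG64(8))
        W_in = (rng.random((n_in, n_e)) < 0.3) * (0.6 + rng.random((n_in, n_e)))
        W_ei = (rng.random((n_e, n_i)) < 0.3) * 1.0
        W_ie = (rng.random((n_i, n_e)) < 0.3) * 0.2
        from plastinet.plasticity_exc import ExcPlasticityParams

        net = Network(n_in, n_e, n_i, W_in=W_in, W_ei=W_ei, W_ie=W_ie,
                      inh_plasticity=inh,
                      plasticity=ExcPlasticityParams(enabled=False),
                      plastic_in=False, plastic_ee=False, seed=22)
        rr = net.run(60.0, rate_segments=[(0.0, 60.0, 10.0)], max_rate_hint=500.0)
        sp = rr.spikes_e
        late = sp[sp[:, 0] > 40]
        per_neuron = np.bincount(late[:, 1].astype(int), minlength=n_e) / 20.0
        assert per_neuron.std() > 1.0  # broad distribution, no per-neuron target


def test_param_validation():
    with pytest.raises(ValueError):
        InhPlasticityParams(tau_H=0.0).validate()
    with pytest.raises(ValueError):
        InhPlasticityParams(eta=-1e-4).validate()
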