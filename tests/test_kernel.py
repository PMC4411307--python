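"""Clock, trace, spike-buffer and determinism contracts of the simulation core."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plastinet.kernel import KernelParams, Network, SimClock, SpikeBuffer, Trace
from plastinet.neurons import NeuronParams, lif_constant_drive_rate


class TestSimClock:
    def test_coarse_dt_must_be_multiple_of_dt(self):
        with pytest.raises(ValueError):
            SimClock(dt=1e-4, coarse_dt=1.25e-4)

    def test_time_advances_monotonically(self):
        c = SimClock()
        c.advance(10)
        assert c.t == pytest.approx(10 * c.dt)
        with pytest.raises(ValueError):
            c.advance(-1)


class TestTrace:
    def test_zero_is_a_fixed_point(self):
        tr = Trace(3, tau=0.02)
        tr.step(0.01)
        assert np.all(tr.value == 0.0)

    def test_analytic_exponential_decay(self):
        tr = Trace(1, tau=0.02)
        tr.value[:] = 1.0
        tr.step(0.02)
        assert tr.value[0] == pytest.approx(np.exp(-1.0))

    def test_nonpositive_tau_rejected(self):
        with pytest.raises(ValueError):
            Trace(1, tau=0.0)

    def test_poisson_long_run_mean_is_rate_times_tau(self, rng):
        # time-averaged trace of a Poisson-driven shot-noise filter -> r*tau
        r, tau, dt, T = 50.0, 0.02, 1e-3, 400.0
        tr = Trace(1, tau=tau)
        vals = []
        for _ in range(int(T / dt)):
            tr.step(dt, rng.random(1) < r * dt)
            vals.append(tr.value[0])
        assert np.mean(vals) == pytest.approx(r * tau, rel=0.05)

    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.integers(0, 1), min_size=5, max_size=40), st.lists(st.integers(0, 1), min_size=5, max_size=40))
    def test_linearity_in_spike_trains(self, train_a, train_b):
        # exact-decay mode: response to a superposition equals the sum of responses
        n = max(len(train_a), len(train_b))
        a = np.array(train_a + [0] * (n - len(train_a)), dtype=bool)
        b = np.array(train_b + [0] * (n - len(train_b)), dtype=bool)
        dt = 1e-3

        def respond(*trains):
            tr = Trace(1, tau=0.01)
            out = []
            for k in range(n):
                tr.value *= np.exp(-dt / tr.tau)
                for t in trains:
                    if t[k]:
                        tr.value += 1.0
                out.append(tr.value[0])
            return np.array(out)

        assert np.allclose(respond(a) + respond(b), respond(a, b), atol=1e-12)


class TestSpikeBuffer:
    def test_delivery_exactly_after_delay(self):
        buf = SpikeBuffer(delay_steps=5)
        buf.push(3, [7, 9])
        for step in range(4, 8):
            assert buf.pop_due(step).size == 0
        np.testing.assert_array_equal(buf.pop_due(8), [7, 9])
        assert buf.pop_due(9).size == 0  # not duplicated

    def test_delay_must_be_at_least_one_step(self):
        with pytest.raises(ValueError):
            SpikeBuffer(0)


class TestAdvance:
    def test_empty_network_advances_clock_without_spikes(self, tiny_feedforward):
        net = tiny_feedforward()
        es, _ = net.advance(10)
        assert net.step == 10
        assert es.shape == (0, 2)

    def test_same_seed_bit_identical_rasters(self):
        def run(seed):
            net = Network(20, 2, 1, W_in=np.full((20, 2), 1.5), W_ie=np.full((1, 2), 0.5),
                          W_ei=np.full((2, 1), 0.5), seed=seed)
            rr = net.run(6.0, rate_segments=[(0.0, 6.0, 30.0)])
            return rr.spikes_e

        a, b, c = run(5), run(5), run(6)
        np.testing.assert_array_equal(a, b)
        assert not (a.shape == c.shape and np.allclose(a, c))

    def test_constant_drive_isi_matches_closed_form(self):
        # static threshold + no adaptation -> closed-form LIF interspike interval
        par = NeuronParams(thr_jump=0.0, delta_a=0.0)
        g = 1.0
        net = Network(1, 1, 0, neurons_e=par, gbias_e=g)
        es, _ = net.advance(int(2.0 / net.kernel.dt))
        isi = np.diff(es[:, 0])
        expected = 1.0 / lif_constant_drive_rate(par, g)
        assert isi.mean() == pytest.approx(expected, abs=net.kernel.dt)

    def test_spike_first_visible_after_conduction_delay(self):
        # one strong E->E synapse: find minimal gap between pre spike and
        # postsynaptic conductance response via the post neuron's spike time
        k = KernelParams()
        par = NeuronParams(thr_jump=0.0, delta_a=0.0)
        net = Network(1, 2, 0, neurons_e=par,
                      W_ee=np.array([[0.0, 50.0], [0.0, 0.0]]), gbias_e=0.0)
        net.stp.enabled = False
        net.plastic_ee = False
        net.plastic_in = False
        # drive neuron 0 only, via a huge input weight
        net.W_in = np.array([[100.0, 0.0]])
        net.M_in = (net.W_in != 0).astype(np.uint8)
        net.plastic_in = False
        in_spk = np.zeros((3000, 1), dtype=np.uint8)
        in_spk[100, 0] = 1
        es, _ = net.advance(3000, in_spk)
        t0 = es[es[:, 1] == 0, 0]
        t1 = es[es[:, 1] == 1, 0]
        assert t0.size and t1.size
        # neuron 1 cannot fire earlier than neuron 0's spike + delay
        assert t1.min() >= t0.min() + k.delay - 1e-12


class TestKernelParams:
    def test_validation(self):
        with pytest.raises(ValueError):
            KernelParams(dt=0.0).validate()
        with pytest.raises(ValueError):
            KernelParams(coarse_dt=1.25e-4).validate()
        with pytest.raises(ValueError):
            KernelParams(delay=0.0).validate()
        assert KernelParams().delay_steps == 8
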