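"""Readout assignment, population activity, covariance, CV-ISI, PSTH on
synthetic rasters with known ground truth."""

import numpy as np
import pytest

from plastinet.analysis import (
    assign_readouts,
    evoked_covariance,
    evoked_rates,
    population_activity,
    psth,
    spike_stats,
)
from plastinet.stimulation import ScheduledStimulus


def make_raster(rng, rates, T, t0=0.0):
    """Poisson raster for n neurons with given rates over [t0, t0+T)."""
    rows = []
    for i, r in enumerate(rates):
        n = rng.poisson(r * T)
        rows.append(np.column_stack([rng.uniform(t0, t0 + T, n), np.full(n, i)]))
    out = np.vstack(rows)
    return out[np.argsort(out[:, 0])]


class TestEvokedRates:
    def test_silent_neuron_reads_zero_for_all_stimuli(self, rng):
        sched = [ScheduledStimulus(0, 1.0, 2.0), ScheduledStimulus(1, 3.0, 4.0)]
        r = evoked_rates(np.empty((0, 2)), sched, (0.0, 5.0), 3, 2)
        assert np.all(r == 0.0)

    def test_homogeneous_poisson_recovers_rate_for_every_stimulus(self, rng):
        sched = [ScheduledStimulus(k % 2, 10.0 * k, 10.0 * k + 5.0) for k in range(40)]
        raster = make_raster(rng, [8.0] * 5, 400.0)
        r = evoked_rates(raster, sched, (0.0, 400.0), 5, 2)
        assert r == pytest.approx(8.0, rel=0.15)

    def test_stimulus_locked_neuron_reads_zero_elsewhere(self):
        sched = [ScheduledStimulus(0, 0.0, 1.0), ScheduledStimulus(1, 2.0, 3.0)]
        raster = np.array([[0.5, 0.0], [0.6, 0.0]])
        r = evoked_rates(raster, sched, (0.0, 3.0), 1, 2)
        assert r[0, 0] == 2.0 and r[0, 1] == 0.0

    def test_zero_on_time_flagged_as_nan(self):
        sched = [ScheduledStimulus(0, 0.0, 1.0)]
        r = evoked_rates(np.empty((0, 2)), sched, (0.0, 3.0), 2, 2)
        assert np.isnan(r[:, 1]).all() and not np.isnan(r[:, 0]).any()


class TestReadouts:
    def test_all_silent_network_gives_empty_sets_full_reserve(self):
        rates = np.zeros((20, 3))
        ro = assign_readouts(rates)
        assert all(v.size == 0 for v in ro.members.values())
        assert ro.reserve_pool.size == 20

    def test_planted_assemblies_recovered_exactly(self, rng):
        # ground truth: neurons 0-9 code stimulus 0 at 30 Hz, 10-19 code 1;
        # everyone else at ~1 Hz background
        rates = rng.uniform(0.0, 2.0, size=(50, 2))
        rates[0:10, 0] = 30.0
        rates[10:20, 1] = 30.0
        ro = assign_readouts(rates)
        np.testing.assert_array_equal(ro.members[0], np.arange(10))
        np.testing.assert_array_equal(ro.members[1], np.arange(10, 20))
        np.testing.assert_array_equal(ro.reserve_pool, np.arange(20, 50))

    def test_infinite_threshold_empties_all_sets(self):
        rates = np.full((10, 2), 100.0)
        ro = assign_readouts(rates, threshold=np.inf)
        assert all(v.size == 0 for v in ro.members.values())


class TestPopulationActivity:
    def test_one_spike_per_member_in_a_50ms_bin_is_20_hz(self):
        members = np.arange(4)
        raster = np.column_stack([np.full(4, 0.51), np.arange(4)])
        t, act = population_activity(raster, members, (0.5, 0.6), 0.05)
        assert act[0] == pytest.approx(20.0)
        assert act[1] == 0.0

    def test_stationary_poisson_members_give_flat_series(self, rng):
        raster = make_raster(rng, [12.0] * 20, 50.0)
        t, act = population_activity(raster, np.arange(20), (0.0, 50.0), 1.0)
        assert act.mean() == pytest.approx(12.0, rel=0.1)
        assert act.std() < 0.5 * act.mean()

    def test_alternating_assemblies_anticorrelate(self):
        # constructed raster: set A fires in even seconds, B in odd seconds
        rows = []
        for s in range(20):
            ids = np.arange(0, 5) if s % 2 == 0 else np.arange(5, 10)
            for i in ids:
                rows.append([s + 0.5, i])
        raster = np.array(rows, dtype=float)
        _, a = population_activity(raster, np.arange(0, 5), (0.0, 20.0), 1.0)
        _, b = population_activity(raster, np.arange(5, 10), (0.0, 20.0), 1.0)
        assert np.corrcoef(a, b)[0, 1] < -0.9

    def test_empty_member_set_rejected(self):
        with pytest.raises(ValueError):
            population_activity(np.empty((0, 2)), np.array([]), (0.0, 1.0))


class TestCovariance:
    def test_identical_response_vectors_give_equal_entries(self, rng):
        v = rng.uniform(0, 10, 30)
        C = evoked_covariance(np.column_stack([v, v]))
        assert C[0, 0] == pytest.approx(C[0, 1]) == pytest.approx(C[1, 1])

    def test_orthogonal_centred_responses_have_zero_off_diagonal(self):
        a = np.array([1.0, -1.0, 1.0, -1.0])
        b = np.array([1.0, 1.0, -1.0, -1.0])
        C = evoked_covariance(np.column_stack([a, b]))
        assert C[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_always_symmetric_positive_semidefinite(self, rng):
        r = rng.uniform(0, 30, size=(40, 5))
        C = evoked_covariance(r)
        np.testing.assert_allclose(C, C.T)
        assert np.linalg.eigvalsh(C).min() >= -1e-10


class TestSpikeStats:
    def test_regular_train_has_zero_cv(self):
        t = np.arange(0.0, 10.0, 0.1)
        raster = np.column_stack([t, np.zeros_like(t)])
        df = spike_stats(raster, (0.0, 10.0), 1)
        assert df.loc[0, "cv_isi"] == pytest.approx(0.0, abs=1e-12)
        assert df.loc[0, "rate"] == pytest.approx(10.0)

    def test_poisson_train_cv_near_one(self, rng):
        raster = make_raster(rng, [20.0], 200.0)
        df = spike_stats(raster, (0.0, 200.0), 1)
        assert df.loc[0, "cv_isi"] == pytest.approx(1.0, abs=0.1)

    def test_gamma2_isi_cv_is_inverse_sqrt2(self, rng):
        isis = rng.gamma(2.0, 0.05, 8000)
        t = np.cumsum(isis)
        raster = np.column_stack([t, np.zeros_like(t)])
        df = spike_stats(raster, (0.0, t[-1]), 1)
        assert df.loc[0, "cv_isi"] == pytest.approx(1 / np.sqrt(2), abs=0.05)

    def test_sparse_neurons_excluded_from_cv(self):
        raster = np.array([[0.1, 0.0], [0.2, 0.0]])
        df = spike_stats(raster, (0.0, 1.0), 2)
        assert np.isnan(df.loc[0, "cv_isi"]) and np.isnan(df.loc[1, "cv_isi"])


class TestPSTH:
    def test_no_spikes_zero_everywhere(self):
        t, r = psth(np.empty((0, 2)), [1.0, 2.0], np.arange(3))
        assert np.all(r == 0.0)

    def test_delta_response_lands_in_single_bin(self):
        events = np.array([10.0, 20.0, 30.0])
        rows = [[ev + 0.021, 0] for ev in events]
        t, r = psth(np.array(rows), events, np.array([0]), window=(0.0, 0.1), bin_width=0.02)
        assert np.count_nonzero(r) == 1
        assert r[1] == pytest.approx(1.0 / 0.02)

    def test_planted_rate_step_recovered(self, rng):
        # 200 trials: rate steps from 0 to 50 Hz at t=0 for one neuron
        events = np.arange(0, 200.0, 1.0)
        rows = []
        for ev in events:
            n = rng.poisson(50.0 * 0.2)
            rows.append(np.column_stack([ev + rng.uniform(0.0, 0.2, n), np.zeros(n)]))
        raster = np.vstack(rows)
        t, r = psth(raster, events, np.array([0]), window=(-0.2, 0.4), bin_width=0.05)
        pre = r[t < 0].mean()
        during = r[(t > 0) & (t < 0.2)].mean()
        assert pre == pytest.approx(0.0, abs=1.0)
        assert during == pytest.approx(50.0, rel=0.1)

    def test_requires_at_least_one_event(self):
        with pytest.raises(ValueError):
            psth(np.empty((0, 2)), [], np.array([0]))
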