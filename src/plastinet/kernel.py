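"""Simulation clock, trace primitive, delayed spike delivery and the network driver.

The integration contract: neuron ODEs advance by forward Euler at ``dt``
(default 0.1 ms); synaptic traces use the exact exponential decay factor per
step, which removes any dt-dependence from trace calibration; the slow
reference-weight (consolidation) dynamics and homeostatic metaplasticity
update on the coarse clock (``coarse_dt``, default 1.2 s, an integer
multiple of ``dt``).  A fixed conduction delay (default 0.8 ms) applies to
all connections.  With a fixed root seed the spike output is bit-identical
across runs.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np

from . import _engine
from .consolidation import ConsolidationParams, step_reference_weights
from .neurons import NeuronParams
from .plasticity_exc import ExcPlasticityParams, homeostatic_b
from .plasticity_inh import InhPlasticityParams
from .stp import STPParams

__all__ = ["KernelParams", "SimClock", "Trace", "SpikeBuffer", "Network", "RunResult"]


@dataclass
class KernelParams:
    """Global integration parameters: time step, coarse step, delay, seed."""

    dt: float = 1.0e-4
    coarse_dt: float = 1.2
    delay: float = 8.0e-4
    seed: int = 1

    def validate(self) -> None:
        if self.dt <= 0:
            raise ValueError(f"kernel.dt must be positive, got {self.dt}")
        if self.coarse_dt <= 0:
            raise ValueError("kernel.coarse_dt must be positive")
        n = self.coarse_dt / self.dt
        if abs(n - round(n)) > 1e-9:
            raise ValueError("kernel.coarse_dt must be an integer multiple of dt")
        if self.delay < self.dt:
            raise ValueError("kernel.delay must be at least one time step")

    @property
    def steps_per_coarse(self) -> int:
        return int(round(self.coarse_dt / self.dt))

    @property
    def delay_steps(self) -> int:
        return int(round(self.delay / self.dt))


@dataclass
class SimClock:
    """Monotone simulation clock advancing in steps of dt."""

    dt: float = 1.0e-4
    coarse_dt: float = 1.2
    step: int = 0

    def __post_init__(self):
        KernelParams(dt=self.dt, coarse_dt=self.coarse_dt).validate()

    @property
    def t(self) -> float:
        return self.step * self.dt

    def advance(self, n_steps: int = 1) -> None:
        if n_steps < 0:
            raise ValueError("cannot advance the clock backwards")
        self.step += n_steps


class Trace:
    """Exponentially decaying spike trace for a vector of units.

    ``step`` first decays the value by exp(-dt/tau), then adds 1 for each
    spiking unit.  Callers needing the "triggering spike not yet counted"
    semantics must read :attr:`value` before calling ``step`` for that step.
    """

    def __init__(self, n: int, tau: float):
        if tau <= 0:
            raise ValueError(f"trace tau must be positive, got {tau}")
        self.tau = tau
        self.value = np.zeros(n, dtype=np.float64)

    def step(self, dt: float, spikes: np.ndarray | None = None) -> np.ndarray:
        if dt <= 0:
            raise ValueError("dt must be positive")
        self.value *= np.exp(-dt / self.tau)
        if spikes is not None:
            self.value[np.asarray(spikes, dtype=bool)] += 1.0
        return self.value


class SpikeBuffer:
    """FIFO of spike events delivered exactly ``delay_steps`` after emission."""

    def __init__(self, delay_steps: int):
        if delay_steps < 1:
            raise ValueError("delay must be at least one step")
        self.delay_steps = int(delay_steps)
        self._q: deque[tuple[int, np.ndarray]] = deque()

    def push(self, emit_step: int, ids: np.ndarray) -> None:
        self._q.append((emit_step, np.asarray(ids, dtype=np.int64)))

    def pop_due(self, step: int) -> np.ndarray:
        """Spikes emitted exactly delay_steps before ``step``; never early, never lost."""
        out = []
        while self._q and self._q[0][0] + self.delay_steps <= step:
            emit, ids = self._q.popleft()
            if emit + self.delay_steps == step:
                out.append(ids)
            else:  # pragma: no cover - delivery step was skipped by the caller
                raise RuntimeError("spike delivery step was skipped")
        if out:
            return np.concatenate(out)
        return np.empty(0, dtype=np.int64)


@dataclass
class RunResult:
    """Raw product of Network.run: spikes, coarse-clock statistics."""

    spikes_e: np.ndarray  # (n, 2) float64: time [s], neuron id
    spikes_i: np.ndarray
    weight_stats: dict[str, np.ndarray] = field(default_factory=dict)
    clamp_low: int = 0
    clamp_high: int = 0
    t_end: float = 0.0


class Network:
    """A complete simulated system: input layer, E and I populations, synapses.

    Weight matrices are dense float64 with rows = presynaptic unit and a
    parallel uint8 mask of realized synapses.  ``wref_in`` / ``wref_ee`` are
    the consolidation reference weights (initialized to the initial weights
    unless set otherwise before running).
    """

    def __init__(
        self,
        n_in: int,
        n_e: int,
        n_i: int,
        kernel: KernelParams | None = None,
        neurons_e: NeuronParams | None = None,
        neurons_i: NeuronParams | None = None,
        stp: STPParams | None = None,
        plasticity: ExcPlasticityParams | None = None,
        consolidation: ConsolidationParams | None = None,
        inh_plasticity: InhPlasticityParams | None = None,
        W_in: np.ndarray | None = None,
        M_in: np.ndarray | None = None,
        W_ee: np.ndarray | None = None,
        M_ee: np.ndarray | None = None,
        W_ei: np.ndarray | None = None,
        W_ie: np.ndarray | None = None,
        M_ie: np.ndarray | None = None,
        W_ii: np.ndarray | None = None,
        plastic_in: bool = True,
        plastic_ee: bool = True,
        delta_in: float | None = None,
        delta_ee: float | None = None,
        gbias_e: float = 0.0,
        seed: int | None = None,
    ):
        self.kernel = kernel or KernelParams()
        self.kernel.validate()
        self.neurons_e = neurons_e or NeuronParams()
        self.neurons_i = neurons_i or NeuronParams()
        self.neurons_e.validate()
        self.neurons_i.validate()
        self.stp = stp or STPParams()
        self.stp.validate()
        self.plasticity = plasticity or ExcPlasticityParams()
        self.plasticity.validate()
        self.consolidation = consolidation or ConsolidationParams()
        self.consolidation.validate()
        self.inh_plasticity = inh_plasticity or InhPlasticityParams()
        self.inh_plasticity.validate()

        self.n_in, self.n_e, self.n_i = int(n_in), int(n_e), int(n_i)
        if seed is not None:
            self.kernel.seed = int(seed)
        ss = np.random.SeedSequence(self.kernel.seed)
        self._rng_input, self._rng_aux = [np.random.Generator(np.random.PCG64(s)) for s in ss.spawn(2)]

        def _w(mat, shape):
            if mat is None:
                return np.zeros(shape, dtype=np.float64)
            mat = np.ascontiguousarray(np.asarray(mat, dtype=np.float64))
            if mat.shape != shape:
                raise ValueError(f"weight matrix shape {mat.shape} != expected {shape}")
            return mat

        def _m(mask, W):
            if mask is None:
                return np.ascontiguousarray((W != 0).astype(np.uint8))
            mask = np.ascontiguousarray(np.asarray(mask, dtype=np.uint8))
            if mask.shape != W.shape:
                raise ValueError("mask shape mismatch")
            return mask

        self.W_in = _w(W_in, (self.n_in, self.n_e))
        self.M_in = _m(M_in, self.W_in)
        self.W_ee = _w(W_ee, (self.n_e, self.n_e))
        self.M_ee = _m(M_ee, self.W_ee)
        if np.any(np.diagonal(self.M_ee)):
            raise ValueError("self-connections are not allowed")
        self.W_ei = _w(W_ei, (self.n_e, self.n_i))
        self.W_ie = _w(W_ie, (self.n_i, self.n_e))
        self.M_ie = _m(M_ie, self.W_ie)
        self.W_ii = _w(W_ii, (self.n_i, self.n_i))
        self.wref_in = self.W_in.copy()
        self.wref_ee = self.W_ee.copy()

        self.plastic_in = bool(plastic_in)
        self.plastic_ee = bool(plastic_ee)
        self.delta_in = self.plasticity.delta if delta_in is None else float(delta_in)
        self.delta_ee = self.plasticity.delta if delta_ee is None else float(delta_ee)
        self.gbias_e = float(gbias_e)
        self.freeze_w = False
        self.acc_in = np.zeros((0, 0))
        self.acc_ee = np.zeros((0, 0))

        # dynamic state
        ne, ni = self.n_e, self.n_i
        pe, pi = self.neurons_e, self.neurons_i
        self.v_e = np.full(ne, pe.u_rest)
        self.th_e = np.full(ne, pe.thr_rest)
        self.ga_e = np.zeros(ne)
        self.gn_e = np.zeros(ne)
        self.gg_e = np.zeros(ne)
        self.gad_e = np.zeros(ne)
        self.gad2_e = np.zeros(ne)
        self.v_i = np.full(ni, pi.u_rest)
        self.th_i = np.full(ni, pi.thr_rest)
        self.ga_i = np.zeros(ni)
        self.gn_i = np.zeros(ni)
        self.gg_i = np.zeros(ni)
        self.gad_i = np.zeros(ni)
        self.gad2_i = np.zeros(ni)
        self.u_in = np.full(self.n_in, self.stp.U)
        self.x_in = np.ones(self.n_in)
        self.u_e = np.full(ne, self.stp.U)
        self.x_e = np.ones(ne)
        self.zp_in = np.zeros(self.n_in)
        self.zp_e = np.zeros(ne)
        self.zm_e = np.zeros(ne)
        self.zs_e = np.zeros(ne)
        self.zht_e = np.zeros(ne)
        self.zi_e = np.zeros(ne)
        self.zi_i = np.zeros(ni)
        self.Hbox = np.zeros(1)
        self.B = np.full(ne, self.plasticity.A)

        D = self.kernel.delay_steps
        self.ring_e = np.zeros((D, max(ne, 1)), dtype=np.int64)
        self.cnt_e = np.zeros(D, dtype=np.int64)
        self.ring_i = np.zeros((D, max(ni, 1)), dtype=np.int64)
        self.cnt_i = np.zeros(D, dtype=np.int64)
        self._sc_del_e = np.zeros(max(ne, 1), dtype=np.int64)
        self._sc_del_i = np.zeros(max(ni, 1), dtype=np.int64)
        self._sc_emit_e = np.zeros(max(ne, 1), dtype=np.int64)
        self._sc_emit_i = np.zeros(max(ni, 1), dtype=np.int64)
        self._in_carry = np.zeros((D, self.n_in), dtype=np.uint8)

        self.step = 0
        self.clamp_low = 0
        self.clamp_high = 0

    # ------------------------------------------------------------------
    @property
    def t(self) -> float:
        return self.step * self.kernel.dt

    def enable_freeze(self) -> None:
        """Accumulate plasticity updates without applying them (drift measurement)."""
        self.freeze_w = True
        self.acc_in = np.zeros_like(self.W_in)
        self.acc_ee = np.zeros_like(self.W_ee)

    def _trace_factors(self) -> dict[str, float]:
        dt = self.kernel.dt
        p, q = self.plasticity, self.inh_plasticity
        return {
            "f_zp_in": np.exp(-dt / p.tau_plus),
            "f_zp_e": np.exp(-dt / p.tau_plus),
            "f_zm": np.exp(-dt / p.tau_minus),
            "f_zs": np.exp(-dt / p.tau_slow),
            "f_zht": np.exp(-dt / p.tau_ht),
            "f_zi": np.exp(-dt / q.tau_z),
            "f_H": np.exp(-dt / q.tau_H),
            "ffac": np.exp(-dt / self.stp.tau_f),
            "fdep": np.exp(-dt / self.stp.tau_d),
        }

    def advance(
        self,
        n_steps: int,
        in_spk: np.ndarray | None = None,
        forced: np.ndarray | None = None,
        max_rate_hint: float = 400.0,
    ) -> tuple[np.ndarray, np.ndarray]:
        """Advance n_steps with delivered input spikes ``in_spk`` (n_steps, n_in).

        Low-level entry point: the rows of ``in_spk`` are *delivery* times
        (already delay-aligned).  Returns (e_spikes, i_spikes) as (n, 2)
        arrays of (time [s], id); times are emission times.
        """
        k = self.kernel
        if in_spk is None:
            in_spk = np.zeros((n_steps, self.n_in), dtype=np.uint8)
        if in_spk.shape != (n_steps, self.n_in):
            raise ValueError("in_spk shape mismatch")
        if forced is None:
            forced = np.zeros((0, 0), dtype=np.uint8)
        elif forced.shape != (n_steps, self.n_e):
            raise ValueError("forced shape mismatch")
        fac = self._trace_factors()
        cap_e = max(10_000, int(self.n_e * n_steps * k.dt * max_rate_hint) + 1000)
        cap_i = max(10_000, int(max(self.n_i, 1) * n_steps * k.dt * max_rate_hint) + 1000)
        oe_step = np.empty(cap_e, dtype=np.int64)
        oe_id = np.empty(cap_e, dtype=np.int64)
        oi_step = np.empty(cap_i, dtype=np.int64)
        oi_id = np.empty(cap_i, dtype=np.int64)
        counters = np.zeros(_engine.CNT_LEN, dtype=np.int64)
        p = self.plasticity
        q = self.inh_plasticity
        _engine.run_chunk(
            n_steps, self.step, k.dt,
            np.ascontiguousarray(in_spk), np.ascontiguousarray(forced),
            self.v_e, self.th_e, self.ga_e, self.gn_e, self.gg_e, self.gad_e, self.gad2_e,
            self.v_i, self.th_i, self.ga_i, self.gn_i, self.gg_i, self.gad_i, self.gad2_i,
            self.neurons_e.to_array(), self.neurons_i.to_array(),
            self.gbias_e,
            self.stp.enabled, self.stp.U, fac["ffac"], fac["fdep"],
            self.u_in, self.x_in, self.u_e, self.x_e,
            self.W_in, self.M_in, self.wref_in,
            self.W_ee, self.M_ee, self.wref_ee,
            self.W_ei, self.W_ie, self.M_ie, self.W_ii,
            self.plastic_in and p.enabled, self.plastic_ee and p.enabled, self.freeze_w,
            p.A, p.beta, self.delta_in, self.delta_ee, p.w_max, self.B,
            self.acc_in, self.acc_ee,
            self.zp_in, fac["f_zp_in"], self.zp_e, fac["f_zp_e"],
            self.zm_e, fac["f_zm"], self.zs_e, fac["f_zs"], self.zht_e, fac["f_zht"],
            q.enabled, q.symmetric, q.eta, self.zi_e, self.zi_i, fac["f_zi"],
            self.Hbox, fac["f_H"], 1.0 / (max(self.n_e, 1) * q.tau_H), q.gamma,
            k.delay_steps, self.ring_e, self.cnt_e, self.ring_i, self.cnt_i,
            self._sc_del_e, self._sc_del_i, self._sc_emit_e, self._sc_emit_i,
            oe_step, oe_id, oi_step, oi_id, counters,
        )
        if counters[_engine.CNT_OVERFLOW]:
            raise RuntimeError(
                "spike output buffer overflow; pass a larger max_rate_hint to advance()"
            )
        self.clamp_low += int(counters[_engine.CNT_CLAMP_LO])
        self.clamp_high += int(counters[_engine.CNT_CLAMP_HI])
        self.step += n_steps
        ne = int(counters[_engine.CNT_OE])
        ni = int(counters[_engine.CNT_OI])
        dt = k.dt
        es = np.column_stack([oe_step[:ne] * dt, oe_id[:ne].astype(np.float64)])
        isp = np.column_stack([oi_step[:ni] * dt, oi_id[:ni].astype(np.float64)])
        return es, isp

    # ------------------------------------------------------------------
    def _input_spikes_for(self, t0: float, t1: float, segments) -> np.ndarray:
        """Generate emitted input spikes for [t0, t1) from piecewise-constant rates."""
        dt = self.kernel.dt
        s0, s1 = int(round(t0 / dt)), int(round(t1 / dt))
        n_steps = s1 - s0
        out = np.zeros((n_steps, self.n_in), dtype=np.uint8)
        if segments is None:
            return out
        sub = 2000  # limit the size of the float32 random blocks
        for seg_t0, seg_t1, rates in segments:
            a = max(s0, int(round(seg_t0 / dt)))
            b = min(s1, int(round(seg_t1 / dt)))
            if b <= a:
                continue
            pvec = (np.broadcast_to(np.asarray(rates, dtype=np.float64), (self.n_in,)) * dt).astype(
                np.float32
            )
            for c in range(a, b, sub):
                d = min(b, c + sub)
                blk = self._rng_input.random((d - c, self.n_in), dtype=np.float32) < pvec
                out[c - s0 : d - s0] = blk
        return out

    def run(
        self,
        T: float,
        rate_segments=None,
        forced_fn=None,
        record: bool = True,
        weight_probe=None,
        max_rate_hint: float = 400.0,
    ) -> RunResult:
        """Run for T seconds from the current time, on the coarse-clock loop.

        ``rate_segments`` is an iterable of (t_start, t_end, per-unit-rate
        vector or scalar) in absolute simulation time, driving the Poisson
        input layer.  ``forced_fn(t0, t1, n_steps)`` may return a uint8
        (n_steps, n_e) array forcing excitatory spikes (current injection).
        Every coarse step the consolidation dynamics advances the reference
        weights and (if enabled) homeostatic metaplasticity updates B_i.
        ``weight_probe(net)`` may return a dict of scalars recorded per
        coarse step.
        """
        k = self.kernel
        segments = list(rate_segments) if rate_segments is not None else None
        spc = k.steps_per_coarse
        D = k.delay_steps
        n_total = int(round(T / k.dt))
        done = 0
        se_all, si_all = [], []
        stats: dict[str, list] = {"t": [], "clamp_high": []}
        while done < n_total:
            n_steps = min(spc, n_total - done)
            t0, t1 = self.t, self.t + n_steps * k.dt
            emitted = self._input_spikes_for(t0, t1, segments)
            if n_steps >= D:
                delivered = np.vstack([self._in_carry, emitted[: n_steps - D]])
                self._in_carry = emitted[n_steps - D :].copy()
            else:  # short tail: shift through the carry buffer
                stacked = np.vstack([self._in_carry, emitted])
                delivered = stacked[:n_steps]
                self._in_carry = stacked[n_steps:].copy()
            forced = forced_fn(t0, t1, n_steps) if forced_fn is not None else None
            es, isp = self.advance(n_steps, delivered, forced, max_rate_hint=max_rate_hint)
            if record:
                se_all.append(es)
                si_all.append(isp)
            done += n_steps
            # ---- coarse-clock updates ----
            if self.consolidation.enabled:
                if self.plastic_in:
                    self.wref_in = np.where(
                        self.M_in.astype(bool),
                        step_reference_weights(self.W_in, self.wref_in, self.consolidation, n_steps * k.dt),
                        self.wref_in,
                    )
                if self.plastic_ee:
                    self.wref_ee = np.where(
                        self.M_ee.astype(bool),
                        step_reference_weights(self.W_ee, self.wref_ee, self.consolidation, n_steps * k.dt),
                        self.wref_ee,
                    )
            if self.plasticity.homeostasis:
                self.B = np.asarray(homeostatic_b(self.plasticity, self.zht_e), dtype=np.float64)
            if weight_probe is not None:
                for key, val in weight_probe(self).items():
                    stats.setdefault(key, []).append(val)
            stats["t"].append(self.t)
            stats["clamp_high"].append(self.clamp_high)
        spikes_e = np.vstack(se_all) if se_all else np.empty((0, 2))
        spikes_i = np.vstack(si_all) if si_all else np.empty((0, 2))
        return RunResult(
            spikes_e=spikes_e,
            spikes_i=spikes_i,
            weight_stats={kk: np.asarray(v) for kk, v in stats.items()},
            clamp_low=self.clamp_low,
            clamp_high=self.clamp_high,
            t_end=self.t,
        )
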