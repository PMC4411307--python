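"""Conductance-based leaky integrate-and-fire neurons and Poisson inputs.

The membrane voltage of neuron i obeys (forward Euler, dt = 0.1 ms)

    tau_mem * dU/dt = (U_rest - U) + g_exc*(E_exc - U) + g_gaba*(E_inh - U)
                      + (g_adapt + g_adapt2)*(E_adapt - U)

with all conductances dimensionless (units of the leak conductance).  The
excitatory conductance is a mix of a fast AMPA-like component and a slowly
rising and decaying NMDA-like component,

    g_exc = alpha * g_ampa + (1 - alpha) * g_nmda,
    d g_nmda/dt = (g_ampa - g_nmda) / tau_nmda,

where g_ampa jumps by w_ij * u_j * x_j on delivery of an excitatory spike
and decays with tau_ampa; the NMDA component low-pass filters it.  g_gaba
jumps by w_ij on delivery of inhibitory spikes.  Spike-triggered adaptation
g_adapt jumps by Delta_a at each emitted spike and decays with tau_adapt;
an optional second, much slower adaptation conductance (tau of tens of
seconds) makes sustained delay activity decay and promotes spontaneous
transitions between memory states.

A spike is emitted when U crosses the dynamic threshold theta; then U is
reset, and theta jumps up and relaxes back to its resting value with
tau_thr, implementing refractoriness.  The voltage is floored at E_inh to
prevent Euler overshoot at large conductances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["NeuronParams", "PoissonGroup", "poisson_spikes", "lif_constant_drive_rate"]

# index layout of the packed parameter vector consumed by the engine
NP_TAU_MEM = 0
NP_U_REST = 1
NP_U_RESET = 2
NP_THR_REST = 3
NP_THR_JUMP = 4
NP_TAU_THR = 5
NP_E_EXC = 6
NP_E_INH = 7
NP_E_ADAPT = 8
NP_TAU_AMPA = 9
NP_TAU_GABA = 10
NP_TAU_NMDA = 11
NP_TAU_ADAPT = 12
NP_DELTA_A = 13
NP_ALPHA = 14
NP_TAU_ADAPT2 = 15
NP_DELTA_A2 = 16
NP_ADAPT2_ON = 17
NP_LEN = 18


@dataclass
class NeuronParams:
    """Integrate-and-fire neuron constants.  Voltages in volts, times in seconds."""

    tau_mem: float = 0.020
    u_rest: float = -0.070
    u_reset: float = -0.070
    thr_rest: float = -0.050
    thr_jump: float = 0.100
    tau_thr: float = 0.005
    e_exc: float = 0.0
    e_inh: float = -0.080
    e_adapt: float = -0.080
    tau_ampa: float = 0.005
    tau_gaba: float = 0.010
    tau_nmda: float = 0.100
    tau_adapt: float = 0.100
    delta_a: float = 0.1
    # AMPA share of the excitatory conductance mix; the 0.2 NMDA share keeps
    # membrane fluctuations large enough for irregular firing at elevated rates
    alpha: float = 0.8
    # optional slow second adaptation conductance (delay-activity fatigue)
    tau_adapt2: float = 20.0
    delta_a2: float = 0.0
    adapt2_enabled: bool = False

    def validate(self) -> None:
        for name in ("tau_mem", "tau_thr", "tau_ampa", "tau_gaba", "tau_nmda", "tau_adapt", "tau_adapt2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"neurons.{name} must be positive")
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError("neurons.alpha must lie in [0, 1]")
        if self.thr_jump < 0 or self.delta_a < 0 or self.delta_a2 < 0:
            raise ValueError("neurons.thr_jump/delta_a/delta_a2 must be non-negative")

    def to_array(self) -> np.ndarray:
        a = np.empty(NP_LEN, dtype=np.float64)
        a[NP_TAU_MEM] = self.tau_mem
        a[NP_U_REST] = self.u_rest
        a[NP_U_RESET] = self.u_reset
        a[NP_THR_REST] = self.thr_rest
        a[NP_THR_JUMP] = self.thr_jump
        a[NP_TAU_THR] = self.tau_thr
        a[NP_E_EXC] = self.e_exc
        a[NP_E_INH] = self.e_inh
        a[NP_E_ADAPT] = self.e_adapt
        a[NP_TAU_AMPA] = self.tau_ampa
        a[NP_TAU_GABA] = self.tau_gaba
        a[NP_TAU_NMDA] = self.tau_nmda
        a[NP_TAU_ADAPT] = self.tau_adapt
        a[NP_DELTA_A] = self.delta_a
        a[NP_ALPHA] = self.alpha
        a[NP_TAU_ADAPT2] = self.tau_adapt2
        a[NP_DELTA_A2] = self.delta_a2
        a[NP_ADAPT2_ON] = 1.0 if self.adapt2_enabled else 0.0
        return a


def poisson_spikes(n: int, rate: float | np.ndarray, dt: float, n_steps: int, rng: np.random.Generator) -> np.ndarray:
    """Bernoulli thinning of Poisson processes: (n_steps, n) uint8 spike array.

    Each unit spikes independently with probability rate*dt per step; valid
    for rate*dt << 1.
    """
    r = np.broadcast_to(np.asarray(rate, dtype=np.float64), (n,))
    if np.any(r < 0):
        raise ValueError("Poisson rate must be non-negative")
    p = r * dt
    return (rng.random((n_steps, n), dtype=np.float32) < p).astype(np.uint8)


class PoissonGroup:
    """A population of independent Poisson units with a common or per-unit rate."""

    def __init__(self, n: int, rate: float | np.ndarray):
        self.n = int(n)
        self.rate = np.broadcast_to(np.asarray(rate, dtype=np.float64), (self.n,)).copy()
        if np.any(self.rate < 0):
            raise ValueError("Poisson rate must be non-negative")

    def spikes(self, dt: float, n_steps: int, rng: np.random.Generator) -> np.ndarray:
        return poisson_spikes(self.n, self.rate, dt, n_steps, rng)


def lif_constant_drive_rate(params: NeuronParams, g_exc: float) -> float:
    """Closed-form firing rate under a constant excitatory conductance.

    Valid for the reduced neuron with adaptation off and a static threshold
    (thr_jump = 0): the membrane relaxes toward
    U_inf = (u_rest + g_exc*e_exc) / (1 + g_exc) with effective time constant
    tau_mem/(1 + g_exc), and the interspike interval follows from the
    standard LIF threshold-crossing time.  Returns 0 for subthreshold drive.
    """
    g = float(g_exc)
    u_inf = (params.u_rest + g * params.e_exc) / (1.0 + g)
    if u_inf <= params.thr_rest:
        return 0.0
    tau_eff = params.tau_mem / (1.0 + g)
    isi = tau_eff * np.log((u_inf - params.u_reset) / (u_inf - params.thr_rest))
    return 1.0 / isi
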