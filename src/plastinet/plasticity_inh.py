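"""Inhibitory-to-excitatory STDP gated by a global secreted factor.

All excitatory spikes in the network feed a low-pass filter H(t) -- a
stand-in for a diffusing chemical signal that neurons secrete when they are
active.  With the per-spike increment 1/(N_exc * tau_H), H(t) is directly the
low-pass-filtered mean excitatory population rate in Hz.  The modulation
factor is G(t) = H(t) - gamma, where gamma is the target population rate.

Inhibitory synapses onto excitatory neurons update symmetrically on both
pre- and postsynaptic spikes, each term carrying the factor G:

    on inhibitory pre spike (delivery):   w_ij += eta * G * z_i   (post trace)
    on excitatory post spike (emission):  w_ij += eta * G * z_j   (pre trace)

with z_j / z_i exponential traces of common time constant tau_z, and weights
clamped at 0 from below.  For G > 0 (network too active) the rule is Hebbian
-- correlated firing potentiates inhibition, suppressing activity; for G < 0
it is a unidirectional depression-only rule that releases the network from
inhibition.  The closed loop regulates the *population* rate toward gamma
without enforcing a target rate for any individual neuron.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["InhPlasticityParams", "GlobalFactor", "inh_pre_spike_update", "inh_post_spike_update"]


@dataclass
class InhPlasticityParams:
    """Inhibitory STDP parameters.

    eta : learning rate (weight units per Hz of G per unit trace)
    tau_z : common pre/post trace time constant (s)
    tau_H : low-pass filter time constant of the secreted factor (s)
    gamma : target mean excitatory population rate (Hz)
    enabled : runtime blockade switch
    symmetric : if False, only the post-spike (pre-trace) term is applied
        (asymmetric variant; off by default because only the symmetric rule
        is depression-only for G<0 and Hebbian for G>0 on both event types)
    """

    eta: float = 1.0e-4
    tau_z: float = 0.020
    tau_H: float = 10.0
    gamma: float = 3.0
    enabled: bool = True
    symmetric: bool = True

    def validate(self) -> None:
        if self.eta < 0:
            raise ValueError("plasticity_inh.eta must be non-negative")
        if self.tau_z <= 0 or self.tau_H <= 0:
            raise ValueError("plasticity_inh time constants must be positive")
        if self.gamma < 0:
            raise ValueError("plasticity_inh.gamma must be non-negative")


class GlobalFactor:
    """Low-pass filter H of the excitatory population spike count, and G = H - gamma.

    ``step`` applies exact exponential decay over dt and then adds this
    step's excitatory spike count scaled by 1/(n_exc*tau_H), so that at a
    steady population rate nu the filter converges to H = nu (in Hz).
    """

    def __init__(self, params: InhPlasticityParams, n_exc: int):
        params.validate()
        self.params = params
        self.n_exc = int(n_exc)
        self.H = 0.0

    @property
    def G(self) -> float:
        return self.H - self.params.gamma

    def step(self, exc_spike_count: int, dt: float) -> tuple[float, float]:
        if dt <= 0:
            raise ValueError("dt must be positive")
        self.H *= np.exp(-dt / self.params.tau_H)
        self.H += exc_spike_count / (self.n_exc * self.params.tau_H)
        return self.H, self.G


def inh_pre_spike_update(
    w: np.ndarray, eta: float, G: float, z_post: np.ndarray
) -> np.ndarray:
    """Update of inhibitory weights w_:i triggered by an inhibitory presynaptic spike."""
    return np.maximum(w + eta * G * np.asarray(z_post), 0.0)


def inh_post_spike_update(
    w: np.ndarray, eta: float, G: float, z_pre: np.ndarray
) -> np.ndarray:
    """Update of inhibitory weights w_j: triggered by an excitatory postsynaptic spike."""
    return np.maximum(w + eta * G * np.asarray(z_pre), 0.0)
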