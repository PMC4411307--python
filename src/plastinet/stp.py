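"""Tsodyks-Markram short-term plasticity.

Every excitatory neuron (network neuron or external input unit) carries one
pair of state variables ``(u, x)`` shared by all of its outgoing synapses:
``u`` is the utilization (release probability) variable and ``x`` the fraction
of available synaptic resources.  Between spikes ``u`` relaxes to the baseline
utilization ``U`` with time constant ``tau_f`` and ``x`` recovers to 1 with
time constant ``tau_d``.  On a presynaptic spike the event update is applied
in the facilitation-then-release order

    u <- u + U * (1 - u)
    r  = u * x          (release factor)
    x <- x - r

and the postsynaptic conductance jump of synapse (j -> i) is ``w_ij * r_j``.
The saturation of ``r`` at high presynaptic rates supplies the curvature of
the effective transfer function that supports firing-rate bistability in a
cell assembly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["STPParams", "STPState", "step_stp", "stp_steady_state"]


@dataclass
class STPParams:
    """Short-term plasticity parameters (one set for all synapses).

    U : baseline utilization (dimensionless, in [0, 1])
    tau_f : facilitation time constant in seconds
    tau_d : depression (recovery) time constant in seconds
    enabled : if False, release factors are identically 1 (static synapses)
    """

    U: float = 0.2
    tau_f: float = 0.6
    tau_d: float = 0.2
    enabled: bool = True

    def validate(self) -> None:
        if not (0.0 <= self.U <= 1.0):
            raise ValueError(f"stp.U must lie in [0, 1], got {self.U}")
        if self.tau_f <= 0 or self.tau_d <= 0:
            raise ValueError(
                f"stp time constants must be positive, got tau_f={self.tau_f}, tau_d={self.tau_d}"
            )


class STPState:
    """Per-presynaptic-neuron (u, x) state for a population of n units."""

    def __init__(self, n: int, params: STPParams):
        params.validate()
        self.params = params
        self.u = np.full(n, params.U, dtype=np.float64)
        self.x = np.ones(n, dtype=np.float64)

    def step(self, dt: float, pre_spikes: np.ndarray) -> np.ndarray:
        """Advance one time step; returns release factors (0 for silent units).

        The relaxation uses the exact exponential solution of the linear
        inter-spike dynamics; the event update follows the
        facilitation-then-release order documented in the module docstring.
        """
        u, x, out = step_stp(self.u, self.x, self.params, dt, pre_spikes)
        self.u, self.x = u, x
        return out


def step_stp(
    u: np.ndarray,
    x: np.ndarray,
    params: STPParams,
    dt: float,
    pre_spikes: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One step of the (u, x) dynamics: event updates, then exact relaxation.

    Returns ``(u, x, release)`` where release[j] = u_j * x_j at the spike of
    unit j (after the facilitation update), else 0.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    p = params
    spk = np.asarray(pre_spikes, dtype=bool)
    release = np.zeros_like(u)
    if p.enabled:
        u = u.copy()
        x = x.copy()
        u[spk] += p.U * (1.0 - u[spk])
        release[spk] = u[spk] * x[spk]
        x[spk] -= release[spk]
        ff = np.exp(-dt / p.tau_f)
        fd = np.exp(-dt / p.tau_d)
        u = p.U + (u - p.U) * ff
        x = 1.0 + (x - 1.0) * fd
    else:
        release[spk] = 1.0
    return u, x, release


def stp_steady_state(rate: float, params: STPParams) -> dict[str, float]:
    """Closed-form fixed point of the deterministic event map at periodic firing.

    For a regular presynaptic train at ``rate`` (Hz) the pre-spike values
    (u-, x-) of the event map have the fixed point

        u- = U / (1 - (1 - U) * exp(-1/(rate*tau_f)))
        u+ = u- + U * (1 - u-)
        x- = (1 - e_d) / (1 - (1 - u+) * e_d),  e_d = exp(-1/(rate*tau_d))

    and the steady-state release factor is ``r = u+ * x-``.
    """
    p = params
    if rate <= 0:
        return {"u_pre": p.U, "u_post": p.U + p.U * (1 - p.U), "x_pre": 1.0, "release": p.U + p.U * (1 - p.U)}
    ef = np.exp(-1.0 / (rate * p.tau_f))
    ed = np.exp(-1.0 / (rate * p.tau_d))
    u_pre = p.U / (1.0 - (1.0 - p.U) * ef)
    u_post = u_pre + p.U * (1.0 - u_pre)
    x_pre = (1.0 - ed) / (1.0 - (1.0 - u_post) * ed)
    return {"u_pre": u_pre, "u_post": u_post, "x_pre": x_pre, "release": u_post * x_pre}
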