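"""Synaptic consolidation: slow bistable reference-weight dynamics.

Each plastic excitatory synapse carries, besides its weight ``w``, a hidden
reference weight ``w_ref`` toward which heterosynaptic plasticity pulls the
weight.  ``w_ref`` follows the negative gradient of a double-well potential
and is additionally driven by the difference between the current weight and
the reference:

    d w_ref / dt = [ (w - w_ref) - P * w_ref * (w_P/2 - w_ref) * (w_P - w_ref) ] / tau_cons

For ``w`` clamped to ``w_ref`` the drift has exactly three roots
{0, w_P/2, w_P}: the outer two are stable wells and the middle one is the
unstable separatrix.  ``w_P = 0.5`` places the upper stable fixed point.  If
``w`` is held slightly above ``w_ref`` both stable fixed points move up; for
sufficiently large ``w`` the lower well disappears in a saddle-node
bifurcation and only one high fixed point remains.  The dynamics is slow
(``tau_cons`` in the 20-60 min range) and is integrated on the coarse clock
(default 1.2 s steps), which makes induced weight changes revertible within
a consolidation window but durable beyond it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ConsolidationParams",
    "reference_drift",
    "step_reference_weights",
    "reference_equilibria",
]


@dataclass
class ConsolidationParams:
    """Parameters of the double-well reference-weight dynamics.

    P : strength of the double-well potential (dimensionless)
    w_P : location of the upper stable well (weight units)
    tau_cons : convergence time scale in seconds (20-60 min range)
    enabled : runtime switch; False freezes w_ref (consolidation blockade)
    """

    P: float = 20.0
    w_P: float = 0.5
    tau_cons: float = 1200.0
    enabled: bool = True

    def validate(self) -> None:
        if self.P <= 0:
            raise ValueError(f"consolidation.P must be positive, got {self.P}")
        if self.w_P <= 0:
            raise ValueError(f"consolidation.w_P must be positive, got {self.w_P}")
        if not (1200.0 <= self.tau_cons <= 3600.0):
            raise ValueError(
                "consolidation.tau_cons must lie in the 20-60 min range "
                f"[1200 s, 3600 s], got {self.tau_cons}"
            )


def reference_drift(w_ref: np.ndarray, w: np.ndarray, params: ConsolidationParams) -> np.ndarray:
    """Instantaneous drift d(w_ref)/dt * tau_cons (i.e. before the 1/tau factor)."""
    p = params
    return (w - w_ref) - p.P * w_ref * (p.w_P / 2.0 - w_ref) * (p.w_P - w_ref)


def step_reference_weights(
    w: np.ndarray,
    w_ref: np.ndarray,
    params: ConsolidationParams,
    coarse_dt: float,
) -> np.ndarray:
    """One coarse-clock Euler step of the reference weights.

    Called every ``coarse_dt`` seconds (default 1.2 s).  Returns the updated
    reference weights; the input array is not modified.  When consolidation is
    disabled (blockade) the references are returned unchanged.
    """
    if coarse_dt <= 0:
        raise ValueError("coarse_dt must be positive")
    if not params.enabled:
        return w_ref
    return w_ref + (coarse_dt / params.tau_cons) * reference_drift(w_ref, w, params)


def reference_equilibria(
    params: ConsolidationParams, w: float | None = None
) -> list[tuple[float, bool]]:
    """Real equilibria of the reference-weight drift, with stability flags.

    If ``w`` is None the weight is clamped to the reference (w = w_ref), in
    which case the roots are {0, w_P/2, w_P}.  Otherwise ``w`` is held fixed
    at the given value.  Returns a list of (root, is_stable) sorted by root.
    """
    p = params
    # drift(r) = (w - r) - P*r*(w_P/2 - r)*(w_P - r); with w=r the linear
    # coupling vanishes.  Build polynomial coefficients in r (descending).
    # -P*r*(w_P/2 - r)*(w_P - r) = -P*[r^3 - (3/2 w_P) r^2 + (w_P^2/2) r]
    coeffs = np.array(
        [-p.P, p.P * 1.5 * p.w_P, -p.P * 0.5 * p.w_P**2, 0.0], dtype=float
    )
    if w is not None:
        coeffs[2] += -1.0  # -r from (w - r)
        coeffs[3] += w
    roots = np.roots(coeffs[np.nonzero(coeffs)[0][0]:])
    out = []
    dcoeffs = np.polyder(coeffs)
    for r in roots:
        if abs(r.imag) > 1e-9:
            continue
        r = float(r.real)
        out.append((r, float(np.polyval(dcoeffs, r)) < 0.0))
    return sorted(out)
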