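"""Construction of the balanced recurrent network and its input layer.

The full-scale system has 4,096 excitatory and 1,024 inhibitory neurons with
random sparse recurrent connectivity at 10% probability, driven by a 64x64
grid of Poisson input units.  Afferents are wired either in receptive-field
mode -- every excitatory neuron receives all input units within a circular
patch of radius R = 8 around a uniformly random centre (clipped so the disc
fits inside the grid) -- or in unstructured mode at 5% random sparse
connectivity.

Desk-scale variants shrink the populations by a scale factor while keeping
connection probabilities and rates; recurrent and inhibitory weight
amplitudes are multiplied by the in-degree ratio so the mean synaptic drive
per neuron is preserved (afferent in-degree is unchanged when the input grid
is kept, so afferent weights are not rescaled).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .kernel import KernelParams, Network

__all__ = ["InitialWeights", "NetworkSpec", "BuiltConnectivity", "build_network", "embed_assembly", "desk_scale_spec"]

FULL_N_EXC = 4096
FULL_N_INH = 1024


@dataclass
class InitialWeights:
    """Initial weights per connection class (dimensionless, leak-conductance units)."""

    w_input: float = 0.2
    w_ee: float = 0.1
    w_ei: float = 0.5
    w_ie: float = 0.4
    w_ii: float = 0.3


@dataclass
class NetworkSpec:
    """Sizes, probabilities and wiring mode of the recurrent network.

    input_mode: 'rf' for circular receptive-field patches on the grid,
    'random' for unstructured sparse afferents at probability p_in.
    """

    n_exc: int = 1024
    n_inh: int = 256
    p_rec: float = 0.1
    grid: tuple[int, int] = (64, 64)
    input_mode: str = "rf"
    rf_radius: float = 8.0
    p_in: float = 0.05
    weights: InitialWeights = field(default_factory=InitialWeights)
    scale_weights_to_full: bool = True

    @property
    def n_input(self) -> int:
        return self.grid[0] * self.grid[1]

    def validate(self) -> None:
        if self.n_exc < 1 or self.n_inh < 0:
            raise ValueError("population sizes must be positive")
        if not (0.0 <= self.p_rec <= 1.0) or not (0.0 <= self.p_in <= 1.0):
            raise ValueError("connection probabilities must lie in [0, 1]")
        if self.input_mode not in ("rf", "random"):
            raise ValueError(f"unknown input_mode {self.input_mode!r}")
        if self.input_mode == "rf" and 2 * self.rf_radius >= min(self.grid):
            raise ValueError("rf_radius too large: the circular patch must fit inside the grid")

    @property
    def recurrent_weight_factor(self) -> float:
        """Recurrent in-degree ratio full/desk, applied to recurrent weight amplitudes.

        Full scale has in-degree 0.1 * 4096; a desk-scale network may both
        shrink the population and raise p_rec, and the weight factor keeps
        the product in-degree x weight (the mean recurrent drive) constant.
        """
        if not self.scale_weights_to_full or self.p_rec == 0.0:
            return 1.0
        return (0.1 * FULL_N_EXC) / (self.p_rec * self.n_exc)


def desk_scale_spec(scale: float = 0.25, **kw) -> NetworkSpec:
    """A spec scaled down from full size by ``scale`` (populations only)."""
    return NetworkSpec(
        n_exc=max(1, int(round(FULL_N_EXC * scale))),
        n_inh=max(1, int(round(FULL_N_INH * scale))),
        **kw,
    )


@dataclass
class BuiltConnectivity:
    """Masks, weights and receptive-field centres produced by build_network."""

    spec: NetworkSpec
    seed: int
    M_in: np.ndarray
    W_in: np.ndarray
    M_ee: np.ndarray
    W_ee: np.ndarray
    W_ei: np.ndarray
    M_ie: np.ndarray
    W_ie: np.ndarray
    W_ii: np.ndarray
    rf_centres: np.ndarray | None = None

    def to_network(self, **net_kwargs) -> Network:
        """Instantiate a simulatable Network around this connectivity."""
        s = self.spec
        return Network(
            s.n_input, s.n_exc, s.n_inh,
            W_in=self.W_in, M_in=self.M_in,
            W_ee=self.W_ee, M_ee=self.M_ee,
            W_ei=self.W_ei, W_ie=self.W_ie, M_ie=self.M_ie, W_ii=self.W_ii,
            **net_kwargs,
        )


def _sparse_mask(n_pre: int, n_post: int, p: float, rng: np.random.Generator, no_self: bool = False) -> np.ndarray:
    m = (rng.random((n_pre, n_post)) < p).astype(np.uint8)
    if no_self:
        np.fill_diagonal(m, 0)
    return m


def build_network(spec: NetworkSpec, seed: int) -> BuiltConnectivity:
    """Wire all five connection classes from a spec, reproducibly under seed.

    E->E, E->I, I->E and I->I are random sparse at p_rec with no
    self-connections; afferents follow spec.input_mode.  Every excitatory
    neuron is guaranteed at least one afferent (a uniformly random input
    unit is added if the draw left a neuron unconnected, which can only
    happen in 'random' mode).
    """
    spec.validate()
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence([seed, 0xB111])))
    ne, ni, n_in = spec.n_exc, spec.n_inh, spec.n_input
    w = spec.weights
    f = spec.recurrent_weight_factor

    M_ee = _sparse_mask(ne, ne, spec.p_rec, rng, no_self=True)
    M_ei = _sparse_mask(ne, ni, spec.p_rec, rng)
    M_ie = _sparse_mask(ni, ne, spec.p_rec, rng)
    M_ii = _sparse_mask(ni, ni, spec.p_rec, rng, no_self=True)

    rf_centres = None
    if spec.input_mode == "rf":
        gx, gy = spec.grid
        R = spec.rf_radius
        xs, ys = np.meshgrid(np.arange(gx), np.arange(gy), indexing="ij")
        coords = np.column_stack([xs.ravel(), ys.ravel()])  # input unit -> (x, y)
        lo, hix, hiy = int(np.ceil(R)), gx - 1 - int(np.ceil(R)), gy - 1 - int(np.ceil(R))
        cx = rng.integers(lo, hix + 1, size=ne)
        cy = rng.integers(lo, hiy + 1, size=ne)
        rf_centres = np.column_stack([cx, cy])
        M_in = np.zeros((n_in, ne), dtype=np.uint8)
        for i in range(ne):
            d2 = (coords[:, 0] - cx[i]) ** 2 + (coords[:, 1] - cy[i]) ** 2
            M_in[d2 <= R * R, i] = 1
    else:
        M_in = _sparse_mask(n_in, ne, spec.p_in, rng)
        empty = np.flatnonzero(M_in.sum(axis=0) == 0)
        for i in empty:
            M_in[rng.integers(0, n_in), i] = 1

    return BuiltConnectivity(
        spec=spec,
        seed=seed,
        M_in=M_in,
        W_in=M_in * w.w_input,
        M_ee=M_ee,
        W_ee=M_ee * (w.w_ee * f),
        W_ei=M_ei * (w.w_ei * f),
        M_ie=M_ie,
        W_ie=M_ie * (w.w_ie * f),
        W_ii=M_ii * (w.w_ii * f),
        rf_centres=rf_centres,
    )


def embed_assembly(built: BuiltConnectivity, member_ids: np.ndarray, w_strong: float) -> BuiltConnectivity:
    """Preset all existing E->E synapses among ``member_ids`` to ``w_strong``.

    Used by the working-memory failure demonstration: the cell assembly is
    defined by stronger-than-background intra-assembly recurrent weights.
    Returns a new BuiltConnectivity; the input is not modified.
    """
    member_ids = np.asarray(member_ids, dtype=np.int64)
    if member_ids.size and (member_ids.min() < 0 or member_ids.max() >= built.spec.n_exc):
        raise ValueError("assembly member ids outside the excitatory population")
    W = built.W_ee.copy()
    if member_ids.size:
        sub = np.ix_(member_ids, member_ids)
        W[sub] = np.where(built.M_ee[sub] != 0, w_strong, W[sub])
    return replace(built, W_ee=W)
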