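# plastinet

A spiking recurrent-network simulator for studying how several forms of
synaptic plasticity, orchestrated together, make Hebbian learning stable
enough to form and recall memories.  It is aimed at computational
neuroscientists who want to reproduce and probe the fixed-point structure
of "orchestrated" synaptic plasticity at desk scale: conductance-based
integrate-and-fire networks in which excitatory synapses combine triplet
spike-timing-dependent plasticity with burst-gated heterosynaptic
plasticity, transmitter-induced potentiation, slow double-well
consolidation of per-synapse reference weights and optional homeostatic
metaplasticity, while inhibitory synapses follow an STDP rule gated by a
global secreted factor, and all excitatory synapses show Tsodyks–Markram
short-term plasticity.

## The model in brief

The change of an excitatory weight w_ij is driven by four event-triggered
terms (traces z are exponential filters of the spike trains, read before
the triggering spike):

    on a presynaptic spike:    Δw = −B_i·z⁻_i + δ
    on a postsynaptic spike:   Δw = +A·z⁺_j·z_slow_i − β·(w_ij − w̃_ij)·(z⁻_i)³

i.e. schematically dw/dt ∝ A·pre·post² − B·pre·post − β(w−w̃)·post⁴ + δ·pre.
LTP is quadratic and LTD linear in the postsynaptic rate (triplet STDP);
the fourth-power term is a burst detector that pushes all synapses of a
bursting neuron toward their reference weights w̃; δ per presynaptic spike
keeps the network from falling silent.  For a 10-Hz Poisson pathway the
calibrated amplitudes give the weight drift two stable zeros, at ≈1 Hz and
≈30 Hz of postsynaptic rate — the low- and elevated-activity fixed points
of a cell assembly.  The reference weights follow a double-well potential
(wells at 0 and w_P = 0.5, timescale 20 min), so induced changes revert
within minutes but consolidate beyond.  Weights are hard-bounded to
[0, 5] but never reach the bound in default runs.

## Worked example

The central single-neuron experiment: 80 plastic synapses driven at 10 Hz
plus an 80-synapse control pathway at 1 Hz, plasticity switched on after
one minute.  Depending on the initial weight the output rate converges to
one of two stable states:

```python
from plastinet.protocols import run_single_neuron_bistability

hi = run_single_neuron_bistability(initial_w=0.35, duration=900.0, seed=1)
lo = run_single_neuron_bistability(initial_w=0.20, duration=1200.0, seed=1)
print(f"upper branch: {hi.summary['final_rate']:.1f} Hz, "
      f"mean active weight {hi.summary['w_active_final']:.2f}, "
      f"max weight {hi.summary['w_max_seen']:.2f}, "
      f"clamp events {hi.summary['clamp_high']}")
print(f"lower branch: {lo.summary['final_rate']:.2f} Hz")
```

prints

```
upper branch: 32.0 Hz, mean active weight 0.56, max weight 0.58, clamp events 0
lower branch: 1.03 Hz
```

Started above the separatrix (w = 0.35) the neuron converges to the
elevated fixed point near 30 Hz; started below (w = 0.20) it settles near
1 Hz.  The weights stop at intermediate, pathway-dependent values far
below the bound w_max = 5 — stability comes from the interplay of the
plasticity terms, not from the bound.

Other protocol drivers follow the same pattern:
`run_tetanization` (postsynaptic burst tetanization: synapses with
w > w̃ depress, w < w̃ potentiate, w ≈ w̃ stay), `run_pairing_curves`
(75 pre/post pairings at ±10 ms: indistinguishable from pure triplet STDP
below 40 Hz, heterosynaptic braking above), `run_triplet_instability_demo`
(triplet-only network: assembly rates explode; static control stationary),
`run_assembly_formation` (stochastic pattern stimulation forms assemblies
with selective delay activity and quarter-cue recall) and
`run_consolidation_blockade`.  A thin CLI wraps them:

```bash
plastinet run bistability --seed 1 --out out/
plastinet calibrate              # fixed-point calibration of (beta, delta)
plastinet fixtures --kind shapes # stimulus patterns as plain text
```

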