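"""Clock-driven simulation core (numba).

One njit function, :func:`run_chunk`, advances the whole network state by a
block of time steps.  Every step executes the documented global update
order:

  1. deliver due spikes to conductances (short-term-plasticity scaling on
     excitatory events) and apply presynaptic plasticity terms,
  2. integrate the neuron ODEs (forward Euler),
  3. detect threshold crossings (plus forced spikes, for current-injection
     protocols),
  4. apply resets / threshold jumps / adaptation increments,
  5. apply postsynaptic plasticity terms for the spikes emitted this step,
  6. decay all traces (exact exponential factors) and then add this step's
     spikes, so that every plasticity term in stages 1-5 reads traces that do
     not yet contain the triggering spike.

Conduction delay is a fixed number of steps D for all connections,
implemented with per-population ring buffers; presynaptic plasticity terms
and presynaptic traces use delivery times (emission + delay), postsynaptic
terms and traces use emission times.

Weight matrices are dense with rows = presynaptic unit; a parallel uint8
mask marks realized synapses (plasticity only ever touches masked entries;
unmasked entries stay exactly 0).  The Python wrappers in
:mod:`plastinet.kernel` own the arrays; this module holds no state.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .neurons import (
    NP_ALPHA,
    NP_DELTA_A,
    NP_DELTA_A2,
    NP_ADAPT2_ON,
    NP_E_ADAPT,
    NP_E_EXC,
    NP_E_INH,
    NP_TAU_ADAPT,
    NP_TAU_ADAPT2,
    NP_TAU_AMPA,
    NP_TAU_GABA,
    NP_TAU_MEM,
    NP_TAU_NMDA,
    NP_TAU_THR,
    NP_THR_JUMP,
    NP_THR_REST,
    NP_U_RESET,
    NP_U_REST,
)

# counters layout
CNT_OE = 0  # emitted excitatory spikes written
CNT_OI = 1  # emitted inhibitory spikes written
CNT_CLAMP_LO = 2
CNT_CLAMP_HI = 3
CNT_OVERFLOW = 4
CNT_LEN = 8


@njit(cache=False)
def run_chunk(  # noqa: PLR0913 - flat argument list is deliberate (numba)
    n_steps,
    step0,
    dt,
    in_spk,
    forced,
    # E neuron state
    v_e, th_e, ga_e, gn_e, gg_e, gad_e, gad2_e,
    # I neuron state
    v_i, th_i, ga_i, gn_i, gg_i, gad_i, gad2_i,
    np_e, np_i,
    gbias_e,
    # STP
    stp_on, U_stp, ffac, fdep, u_in, x_in, u_e, x_e,
    # weights (rows = pre)
    W_in, M_in, Wt_in,
    W_ee, M_ee, Wt_ee,
    W_ei, W_ie, M_ie, W_ii,
    # excitatory plasticity
    plastic_in, plastic_ee, freeze_w,
    A, beta, delta_in, delta_ee, w_max, B,
    acc_in, acc_ee,
    # traces + per-step exact decay factors
    zp_in, f_zp_in, zp_e, f_zp_e, zm_e, f_zm, zs_e, f_zs, zht_e, f_zht,
    # inhibitory plasticity
    inh_on, inh_sym, eta, zi_e, zi_i, f_zi, Hbox, f_H, h_inc, gamma,
    # delay rings
    D, ring_e, cnt_e, ring_i, cnt_i,
    # scratch (int64, length >= population size)
    sc_del_e, sc_del_i, sc_emit_e, sc_emit_i,
    # outputs
    oe_step, oe_id, oi_step, oi_id, counters,
):
    n_in = W_in.shape[0]
    n_e = v_e.shape[0]
    n_i = v_i.shape[0]
    use_forced = forced.shape[0] > 0

    # hoisted Euler coefficients, E population
    cmem_e = dt / np_e[NP_TAU_MEM]
    campa_e = dt / np_e[NP_TAU_AMPA]
    cgaba_e = dt / np_e[NP_TAU_GABA]
    cnmda_e = dt / np_e[NP_TAU_NMDA]
    cadapt_e = dt / np_e[NP_TAU_ADAPT]
    cadapt2_e = dt / np_e[NP_TAU_ADAPT2]
    cthr_e = dt / np_e[NP_TAU_THR]
    # I population
    cmem_i = dt / np_i[NP_TAU_MEM]
    campa_i = dt / np_i[NP_TAU_AMPA]
    cgaba_i = dt / np_i[NP_TAU_GABA]
    cnmda_i = dt / np_i[NP_TAU_NMDA]
    cadapt_i = dt / np_i[NP_TAU_ADAPT]
    cadapt2_i = dt / np_i[NP_TAU_ADAPT2]
    cthr_i = dt / np_i[NP_TAU_THR]

    cap_e = oe_step.shape[0]
    cap_i = oi_step.shape[0]

    for s in range(n_steps):
        t_abs = step0 + s
        slot = t_abs % D
        G = Hbox[0] - gamma

        # ---- stage 1: deliveries --------------------------------------
        # excitatory network spikes emitted D steps ago
        n_del_e = cnt_e[slot]
        for k in range(n_del_e):
            sc_del_e[k] = ring_e[slot, k]
        n_del_i = cnt_i[slot]
        for k in range(n_del_i):
            sc_del_i[k] = ring_i[slot, k]
        cnt_e[slot] = 0
        cnt_i[slot] = 0

        # external input spikes (rows already delay-aligned)
        for j in range(n_in):
            if in_spk[s, j] != 0:
                if stp_on:
                    u_in[j] += U_stp * (1.0 - u_in[j])
                    r = u_in[j] * x_in[j]
                    x_in[j] -= r
                else:
                    r = 1.0
                if plastic_in:
                    for i in range(n_e):
                        ga_e[i] += W_in[j, i] * r
                        if M_in[j, i] != 0:
                            dw = -B[i] * zm_e[i] + delta_in
                            if freeze_w:
                                acc_in[j, i] += dw
                            else:
                                nw = W_in[j, i] + dw
                                if nw < 0.0:
                                    nw = 0.0
                                    counters[CNT_CLAMP_LO] += 1
                                elif nw > w_max:
                                    nw = w_max
                                    counters[CNT_CLAMP_HI] += 1
                                W_in[j, i] = nw
                else:
                    for i in range(n_e):
                        ga_e[i] += W_in[j, i] * r

        # recurrent excitatory deliveries
        for k in range(n_del_e):
            j = sc_del_e[k]
            if stp_on:
                u_e[j] += U_stp * (1.0 - u_e[j])
                r = u_e[j] * x_e[j]
                x_e[j] -= r
            else:
                r = 1.0
            if plastic_ee:
                for i in range(n_e):
                    ga_e[i] += W_ee[j, i] * r
                    if M_ee[j, i] != 0:
                        dw = -B[i] * zm_e[i] + delta_ee
                        if freeze_w:
                            acc_ee[j, i] += dw
                        else:
                            nw = W_ee[j, i] + dw
                            if nw < 0.0:
                                nw = 0.0
                                counters[CNT_CLAMP_LO] += 1
                            elif nw > w_max:
                                nw = w_max
                                counters[CNT_CLAMP_HI] += 1
                            W_ee[j, i] = nw
            else:
                for i in range(n_e):
                    ga_e[i] += W_ee[j, i] * r
            for i2 in range(n_i):
                ga_i[i2] += W_ei[j, i2] * r

        # inhibitory deliveries
        for k in range(n_del_i):
            j = sc_del_i[k]
            if inh_on and inh_sym:
                for i in range(n_e):
                    gg_e[i] += W_ie[j, i]
                    if M_ie[j, i] != 0:
                        nw = W_ie[j, i] + eta * G * zi_e[i]
                        if nw < 0.0:
                            nw = 0.0
                        W_ie[j, i] = nw
            else:
                for i in range(n_e):
                    gg_e[i] += W_ie[j, i]
            for i2 in range(n_i):
                gg_i[i2] += W_ii[j, i2]

        # ---- stages 2-4: integrate, detect, reset ----------------------
        n_emit_e = 0
        for i in range(n_e):
            ge = np_e[NP_ALPHA] * ga_e[i] + (1.0 - np_e[NP_ALPHA]) * gn_e[i] + gbias_e
            v = v_e[i]
            v += cmem_e * (
                (np_e[NP_U_REST] - v)
                + ge * (np_e[NP_E_EXC] - v)
                + gg_e[i] * (np_e[NP_E_INH] - v)
                + (gad_e[i] + gad2_e[i]) * (np_e[NP_E_ADAPT] - v)
            )
            if v < np_e[NP_E_INH]:
                v = np_e[NP_E_INH]
            gn_e[i] += cnmda_e * (ga_e[i] - gn_e[i])
            ga_e[i] -= campa_e * ga_e[i]
            gg_e[i] -= cgaba_e * gg_e[i]
            gad_e[i] -= cadapt_e * gad_e[i]
            gad2_e[i] -= cadapt2_e * gad2_e[i]
            th_e[i] += cthr_e * (np_e[NP_THR_REST] - th_e[i])
            spike = v >= th_e[i]
            if use_forced and forced[s, i] != 0:
                spike = True
            if spike:
                v = np_e[NP_U_RESET]
                th_e[i] += np_e[NP_THR_JUMP]
                gad_e[i] += np_e[NP_DELTA_A]
                if np_e[NP_ADAPT2_ON] != 0.0:
                    gad2_e[i] += np_e[NP_DELTA_A2]
                sc_emit_e[n_emit_e] = i
                n_emit_e += 1
            v_e[i] = v

        n_emit_i = 0
        for i in range(n_i):
            ge = np_i[NP_ALPHA] * ga_i[i] + (1.0 - np_i[NP_ALPHA]) * gn_i[i]
            v = v_i[i]
            v += cmem_i * (
                (np_i[NP_U_REST] - v)
                + ge * (np_i[NP_E_EXC] - v)
                + gg_i[i] * (np_i[NP_E_INH] - v)
                + (gad_i[i] + gad2_i[i]) * (np_i[NP_E_ADAPT] - v)
            )
            if v < np_i[NP_E_INH]:
                v = np_i[NP_E_INH]
            gn_i[i] += cnmda_i * (ga_i[i] - gn_i[i])
            ga_i[i] -= campa_i * ga_i[i]
            gg_i[i] -= cgaba_i * gg_i[i]
            gad_i[i] -= cadapt_i * gad_i[i]
            gad2_i[i] -= cadapt2_i * gad2_i[i]
            th_i[i] += cthr_i * (np_i[NP_THR_REST] - th_i[i])
            if v >= th_i[i]:
                v = np_i[NP_U_RESET]
                th_i[i] += np_i[NP_THR_JUMP]
                gad_i[i] += np_i[NP_DELTA_A]
                sc_emit_i[n_emit_i] = i
                n_emit_i += 1
            v_i[i] = v

        # ---- stage 5: postsynaptic plasticity terms --------------------
        for k in range(n_emit_e):
            i = sc_emit_e[k]
            zs = zs_e[i]
            zm3 = zm_e[i] * zm_e[i] * zm_e[i]
            if plastic_in:
                for j in range(n_in):
                    if M_in[j, i] != 0:
                        dw = A * zp_in[j] * zs - beta * (W_in[j, i] - Wt_in[j, i]) * zm3
                        if freeze_w:
                            acc_in[j, i] += dw
                        else:
                            nw = W_in[j, i] + dw
                            if nw < 0.0:
                                nw = 0.0
                                counters[CNT_CLAMP_LO] += 1
                            elif nw > w_max:
                                nw = w_max
                                counters[CNT_CLAMP_HI] += 1
                            W_in[j, i] = nw
            if plastic_ee:
                for j in range(n_e):
                    if M_ee[j, i] != 0:
                        dw = A * zp_e[j] * zs - beta * (W_ee[j, i] - Wt_ee[j, i]) * zm3
                        if freeze_w:
                            acc_ee[j, i] += dw
                        else:
                            nw = W_ee[j, i] + dw
                            if nw < 0.0:
                                nw = 0.0
                                counters[CNT_CLAMP_LO] += 1
                            elif nw > w_max:
                                nw = w_max
                                counters[CNT_CLAMP_HI] += 1
                            W_ee[j, i] = nw
            if inh_on:
                for j in range(n_i):
                    if M_ie[j, i] != 0:
                        nw = W_ie[j, i] + eta * G * zi_i[j]
                        if nw < 0.0:
                            nw = 0.0
                        W_ie[j, i] = nw

        # ---- stage 6: trace decay, then spike increments ---------------
        for j in range(n_in):
            zp_in[j] *= f_zp_in
            if stp_on:
                u_in[j] = U_stp + (u_in[j] - U_stp) * ffac
                x_in[j] = 1.0 + (x_in[j] - 1.0) * fdep
        for i in range(n_e):
            zp_e[i] *= f_zp_e
            zm_e[i] *= f_zm
            zs_e[i] *= f_zs
            zht_e[i] *= f_zht
            zi_e[i] *= f_zi
            if stp_on:
                u_e[i] = U_stp + (u_e[i] - U_stp) * ffac
                x_e[i] = 1.0 + (x_e[i] - 1.0) * fdep
        for j in range(n_i):
            zi_i[j] *= f_zi
        Hbox[0] *= f_H

        for j in range(n_in):
            if in_spk[s, j] != 0:
                zp_in[j] += 1.0
        for k in range(n_del_e):
            zp_e[sc_del_e[k]] += 1.0
        for k in range(n_del_i):
            zi_i[sc_del_i[k]] += 1.0
        for k in range(n_emit_e):
            i = sc_emit_e[k]
            zm_e[i] += 1.0
            zs_e[i] += 1.0
            zht_e[i] += 1.0
            zi_e[i] += 1.0
            Hbox[0] += h_inc

        # ---- bookkeeping: rings and outputs ----------------------------
        for k in range(n_emit_e):
            ring_e[slot, cnt_e[slot]] = sc_emit_e[k]
            cnt_e[slot] += 1
            if counters[CNT_OE] < cap_e:
                oe_step[counters[CNT_OE]] = t_abs
                oe_id[counters[CNT_OE]] = sc_emit_e[k]
                counters[CNT_OE] += 1
            else:
                counters[CNT_OVERFLOW] = 1
        for k in range(n_emit_i):
            ring_i[slot, cnt_i[slot]] = sc_emit_i[k]
            cnt_i[slot] += 1
            if counters[CNT_OI] < cap_i:
                oi_step[counters[CNT_OI]] = t_abs
                oi_id[counters[CNT_OI]] = sc_emit_i[k]
                counters[CNT_OI] += 1
            else:
                counters[CNT_OVERFLOW] = 1
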