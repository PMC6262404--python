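"""Clock-driven simulation core, numba-compiled.

Implements exactly the per-neuron semantics of :mod:`seqwta.neurons` and
the synapse/plasticity semantics of :mod:`seqwta.synapses`, vectorised
over the whole network.  Update order per step ``t``:

1. exponential decay of the postsynaptic current (PSC) traces;
2. external drive: Poisson samples from the per-epoch rate profiles and
   any precomputed event-driven input (both enter via virtual-synapse
   weights);
3. delivery of the spikes emitted in step ``t-1`` (one-step transmission
   delay) through static and plastic weights, plus the plastic-weight
   jumps triggered by those presynaptic spikes;
4. membrane/adaptation/calcium integration and spike detection;
5. constant bistable drift of the learnable plastic block.

A finite-ness check runs every ``CHECK_EVERY`` steps; on failure the
kernel returns the offending step and neuron so the caller can raise a
diagnostic error.
"""

from __future__ import annotations

import numpy as np
from numba import njit

CHECK_EVERY = 1000


@njit(cache=True)
def simulate(  # noqa: C901 - single hot loop on purpose
    n_steps,
    dt,
    seed,
    # per-neuron parameter arrays
    tau_mem, v_rest, v_thr, slope, v_cut, v_reset, t_refr,
    b_adapt, dec_adapt, ca_inc, dec_ca,
    # state (in/out)
    v, w_adapt, ca, refr, psc,
    # connectivity
    w_static, w_plastic, plastic_gain, has_plastic_row,
    # plasticity
    plasticity_on, learn_row, c_lo, c_hi,
    th_mem, th1, th_max, dw_plus, dw_minus,
    c_drift, th_w, w_min, w_max, ltd_low_inclusive,
    drift_lo, drift_hi,
    # synapse time constant decay
    dec_syn,
    # rate-profile epochs
    ep_start, ep_end, ep_weight, ep_lo, ep_hi, ep_rates,
    # event-driven external input (sorted by step)
    ev_step, ev_neuron, ev_amount,
    # spike output
    out_t, out_i,
):
    n = v.shape[0]
    np.random.seed(seed)
    n_spikes = 0
    max_spikes = out_t.shape[0]
    n_ep = ep_start.shape[0]
    n_ev = ev_step.shape[0]
    ev_ptr = 0
    prev = np.empty(n, dtype=np.int64)
    n_prev = 0
    cur = np.empty(n, dtype=np.int64)
    rate_scale = dt * 1e-3  # Hz -> expected count per step
    drift_amt = c_drift * dt

    for t in range(n_steps):
        # 1. PSC decay
        for i in range(n):
            psc[i] *= dec_syn

        # 2a. Poisson drive from rate epochs
        for m in range(n_ep):
            if ep_start[m] <= t < ep_end[m]:
                wgt = ep_weight[m]
                for i in range(ep_lo[m], ep_hi[m]):
                    lam = ep_rates[m, i - ep_lo[m]] * rate_scale
                    if lam > 0.0:
                        cnt = np.random.poisson(lam)
                        if cnt > 0:
                            psc[i] += cnt * wgt

        # 2b. event-driven drive
        while ev_ptr < n_ev and ev_step[ev_ptr] == t:
            psc[ev_neuron[ev_ptr]] += ev_amount[ev_ptr]
            ev_ptr += 1

        # 3. deliver previous-step spikes; plastic jumps on pre arrival
        for s in range(n_prev):
            j = prev[s]
            if has_plastic_row[j]:
                for i in range(n):
                    psc[i] += w_static[j, i] + plastic_gain * w_plastic[j, i]
            else:
                for i in range(n):
                    psc[i] += w_static[j, i]
            if plasticity_on and learn_row[j]:
                for i in range(c_lo, c_hi):
                    wv = w_plastic[j, i]
                    cav = ca[i]
                    if v[i] > th_mem:
                        if th1 < cav < th_max:
                            wv += dw_plus
                    elif v[i] < th_mem:
                        if ltd_low_inclusive:
                            if cav < th_max:
                                wv -= dw_minus
                        else:
                            if th1 < cav < th_max:
                                wv -= dw_minus
                    if wv > w_max:
                        wv = w_max
                    elif wv < w_min:
                        wv = w_min
                    w_plastic[j, i] = wv

        # 4. integrate neurons
        n_cur = 0
        for i in range(n):
            w_adapt[i] *= dec_adapt[i]
            ca[i] *= dec_ca[i]
            if refr[i] > 0.0:
                refr[i] -= dt
                if refr[i] < 0.0:
                    refr[i] = 0.0
                v[i] = v_reset[i]
            else:
                vi = v[i]
                exp_term = 0.0
                if slope[i] > 0.0 and vi > v_thr[i] - 3.0 * slope[i]:
                    arg = (vi - v_thr[i]) / slope[i]
                    if arg > 16.0:
                        arg = 16.0
                    exp_term = slope[i] * np.exp(arg)
                vi += (
                    -(vi - v_rest[i]) + exp_term + psc[i] - w_adapt[i]
                ) * dt / tau_mem[i]
                if vi >= v_cut[i]:
                    v[i] = v_reset[i]
                    refr[i] = t_refr[i]
                    w_adapt[i] += b_adapt[i]
                    ca[i] += ca_inc[i]
                    if n_spikes < max_spikes:
                        out_t[n_spikes] = (t + 1) * dt
                        out_i[n_spikes] = i
                    n_spikes += 1
                    cur[n_cur] = i
                    n_cur += 1
                else:
                    v[i] = vi

        # 5. bistable drift on the learnable block
        if plasticity_on and drift_amt > 0.0:
            for j in range(drift_lo, drift_hi):
                for i in range(c_lo, c_hi):
                    wv = w_plastic[j, i]
                    if wv > th_w:
                        wv += drift_amt
                        if wv > w_max:
                            wv = w_max
                    elif wv < th_w:
                        wv -= drift_amt
                        if wv < w_min:
                            wv = w_min
                    w_plastic[j, i] = wv

        for s in range(n_cur):
            prev[s] = cur[s]
        n_prev = n_cur

        if (t + 1) % CHECK_EVERY == 0:
            for i in range(n):
                if not (np.isfinite(v[i]) and np.isfinite(psc[i])):
                    return n_spikes, t, i

    return n_spikes, -1, -1
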