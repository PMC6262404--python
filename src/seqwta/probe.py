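"""Probe readout of plastic synapse states.

The analog weight of a plastic synapse cannot be observed directly on
the emulated substrate; instead each synapse is read out by stimulating
it with a fixed spike burst and checking whether the postsynaptic neuron
fires within the observation window.  Probing happens with plasticity
turned off (probing with the rule active would corrupt the weights) and
each synapse is probed in isolation: the burst is injected into a fresh
copy of the postsynaptic neuron that receives no other input, so the
network state is left untouched.  The burst is regular (deterministic),
which makes the probe idempotent.

With the default neuron parameters and burst, the readout threshold sits
near the bistability threshold ``θ_w``: weights that have drifted to the
high state fire the neuron, depressed weights do not.
"""

from __future__ import annotations

import numpy as np

from .errors import ProbeError
from .network import Network

__all__ = ["probe_plastic_weights"]


def probe_plastic_weights(
    network: Network,
    pre_range: tuple[int, int] | None = None,
    post_range: tuple[int, int] | None = None,
    burst_rate: float = 1800.0,
    burst_duration: float = 200.0,
    dt: float = 0.1,
) -> np.ndarray:
    """Binary readout of the plastic matrix.

    Parameters
    ----------
    network : Network
        Must hold a plastic matrix with plasticity disabled.
    pre_range, post_range : (lo, hi) or None
        Sub-block to probe; defaults to the full matrix.  Entries
        outside the probed block are returned as 0.
    burst_rate : float
        Rate (Hz) of the regular probe burst.
    burst_duration : float
        Length of the burst and observation window, ms.

    Returns
    -------
    ndarray of int8, shape (n, n)
        1 where the probed synapse made its postsynaptic neuron spike.
    """
    if network.plastic is None:
        raise ProbeError("network has no plastic synapses to probe")
    if network.plastic.plasticity_enabled:
        raise ProbeError(
            "probing requires plasticity to be disabled first "
            "(probe bursts would corrupt the weights)"
        )
    n = network.n_neurons
    pre_lo, pre_hi = pre_range or (0, n)
    post_lo, post_hi = post_range or (0, n)
    w_eff = network.plastic.weights[pre_lo:pre_hi, post_lo:post_hi] \
        * network.plastic.gain
    n_pre, n_post = w_eff.shape
    amp = np.repeat(w_eff.ravel(), 1)  # flat drive amplitude per synapse
    m = amp.size

    p = network.params
    tau_syn = network.static.table.psc_time_constant
    dec_syn = np.exp(-dt / tau_syn)
    dec_ad = np.exp(-dt / p.adaptation_time_constant)
    n_steps = int(round(burst_duration / dt))
    isi = 1000.0 / burst_rate

    v = np.full(m, p.resting_potential)
    psc = np.zeros(m)
    adapt = np.zeros(m)
    refr = np.zeros(m)
    fired = np.zeros(m, dtype=bool)
    v_cut = p.cutoff_potential
    slope = p.exponential_slope
    next_spike = 0.0

    for t in range(n_steps):
        psc *= dec_syn
        adapt *= dec_ad
        now = t * dt
        while now + 1e-9 >= next_spike:
            psc += amp
            next_spike += isi
        in_refr = refr > 0
        refr[in_refr] -= dt
        v[in_refr] = p.reset_potential
        free = ~in_refr
        vi = v[free]
        drive = -(vi - p.resting_potential) + psc[free] - adapt[free]
        if slope > 0:
            hot = vi > p.spike_threshold - 3.0 * slope
            if hot.any():
                arg = np.minimum((vi[hot] - p.spike_threshold) / slope, 16.0)
                d2 = drive[hot] + slope * np.exp(arg)
                drive[hot] = d2
        vi = vi + drive * dt / p.membrane_time_constant
        v[free] = vi
        spk = v >= v_cut
        if spk.any():
            fired |= spk
            v[spk] = p.reset_potential
            refr[spk] = p.refractory_period
            adapt[spk] += p.adaptation_increment

    out = np.zeros((n, n), dtype=np.int8)
    out[pre_lo:pre_hi, post_lo:post_hi] = fired.reshape(n_pre, n_post)
    return out
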