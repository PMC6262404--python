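# seqwta

Spiking winner-take-all networks for serial-order sequence memory.

`seqwta` is a clock-driven simulator of a neuromorphic-style architecture
that learns, replays, and overwrites sequences of items using populations
of adaptive exponential integrate-and-fire (AdEx) neurons, soft
winner-take-all (WTA) attractor dynamics, and a bistable, calcium-gated
synaptic plasticity rule. It is aimed at researchers in neuromorphic
engineering and computational neuroscience who want a software testbed for
attractor-based sequence memory — the kind of architecture usually run on
mixed-signal neuromorphic processors with on-chip learning — without the
hardware.

## The model

**Neurons.** AdEx point neurons with membrane time constant τ_m, an
exponential spike-initiation term, subtractive spike-frequency adaptation,
and an absolute refractory period. Each neuron carries a calcium trace
`Ca`, a low-pass filter of its own spikes, used as the third factor of the
learning rule.

**Plasticity.** At each presynaptic spike arrival the analog weight
`w ∈ [w_min, w_max]` of a plastic synapse is updated from the state of the
*postsynaptic* neuron:

    w ← w + Δw⁺   if  V_mem > θ_mem  and  θ₁ < Ca < θ_max
    w ← w − Δw⁻   if  V_mem < θ_mem  and  Ca  in the depression window

Superimposed is a constant drift dw/dt = ±C_drift toward `w_max` or
`w_min` depending on the sign of `w − θ_w`, which makes every synapse
bistable — and hence binary in the long term. A presynaptic spike that is
not followed by postsynaptic activity depresses the synapse, which is what
lets a stored sequence be forgotten and overwritten.

**Architecture.** K *ordinal* groups (20 neurons each) are recurrent
attractors that represent "position k in the sequence" and inhibit each
other so only one can be active. Each ordinal group drives a *memory*
group (10 neurons) whose strong self-excitation keeps it firing for the
rest of the trial; memory k excites ordinal k+1 and slightly inhibits its
own ordinal group, biasing the competition toward the not-yet-visited
position. A *content* field (soft-WTA over 60 neurons for K=3) represents
the item itself as a localized activity bump. The sequence is stored in
the plastic ordinal→content block. A *condition-of-satisfaction* (CoS)
group transiently inhibits all ordinal groups to trigger each transition,
and a *reset* group silences the memories at the end of a trial. An
optional event-camera front end maps address events (t, x, y, polarity)
onto the content field by pixel column and gates the CoS through a
`dvs_on` population, so a blinking laser pointer can teach the sequence.

## Worked example

```python
from seqwta import (SerialOrderConfig, TeachingProtocol, build_serial_order,
                    run_teaching, run_replay, probe_plastic_weights, score_probe)

net = build_serial_order(SerialOrderConfig(n_items=3))
protocol = TeachingProtocol(items=("A", "B", "C"))

teach = run_teaching(net, protocol, seed=1)
print("teaching failures:", teach.failures)

net.set_plasticity(False)
probe = probe_plastic_weights(net, pre_range=net.layout.span_of("ordinal"),
                              post_range=net.layout.range_of("content_exc"))
score = score_probe(probe, net.layout, net.annotations["item_regions"])
print("learned associations:", score.winners)
print("I->A block fraction: %.2f" % score.block_fractions[("ordinal_1", "A")])

replay = run_replay(net, protocol=protocol, seed=2)
print("decoded replay:", replay.labels)
print("confidences:", [round(i.confidence, 2) for i in replay.decoded.items])
```

Output:

```
teaching failures: []
learned associations: {'ordinal_1': 'A', 'ordinal_2': 'B', 'ordinal_3': 'C'}
I->A block fraction: 0.35
decoded replay: ['A', 'B', 'C']
confidences: [1.0, 1.0, 1.0]
```

The teaching pass presents each item for 6 s as a Gaussian-profiled
Poisson input (peak 900 Hz, σ = 5 neurons) on top of ≤ 10 Hz background
noise, launches the sequence with a 3 s / 200 Hz "go" signal to the first
ordinal group, and ends each item with a 500 ms / 800 Hz CoS trigger.
`score.winners` is the association read out of the plastic matrix by the
burst-probe protocol (each synapse stimulated in isolation, plasticity
off); the block fraction is the share of potentiated synapses in the
20 × 20 ordinal-I → item-A block. During replay the content field receives
no external input — the decoded bumps are driven purely through the
learned synapses — and `confidence` is the fraction of each bump's spike
mass inside the decoded item's region.

The same protocols are available from the command line:

```sh
seqwta teach --items A,B,C --seed 1 --out run_teach
seqwta replay --weights run_teach/plastic_weights.csv --seed 2
seqwta unlearn --old-items C,A,B --new-items B,A,C
seqwta dvs-demo --columns 20,100,64
```

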