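"""End-to-end protocol behaviour: teaching, replay, probing, unlearning."""

import numpy as np
import pytest

from seqwta.analysis import score_probe
from seqwta.builder import SerialOrderConfig, build_serial_order
from seqwta.errors import ConfigurationError, ProbeError
from seqwta.probe import probe_plastic_weights
from seqwta.protocols import (
    TeachingProtocol,
    default_cos_schedule,
    run_replay,
    run_teaching,
    run_unlearning,
)


def ordinal_block_means(net):
    wp = net.plastic.weights
    c_lo, c_hi = net.layout.range_of("content_exc")
    out = {}
    for name in net.layout.group_names("ordinal"):
        lo, hi = net.layout.range_of(name)
        out[name] = wp[lo:hi, c_lo:c_hi].mean(axis=0)
    return out


class TestTeaching:
    def test_teaching_abc_potentiates_the_three_diagonal_blocks(self, taught_k3):
        net, _, result = taught_k3
        assert result.ok
        probe = probe_plastic_weights(
            net, pre_range=net.layout.span_of("ordinal"),
            post_range=net.layout.range_of("content_exc"))
        score = score_probe(probe, net.layout,
                            net.annotations["item_regions"])
        assert score.winners == {"ordinal_1": "A", "ordinal_2": "B",
                                 "ordinal_3": "C"}
        for g, lab in score.winners.items():
            assert score.block_fractions[(g, lab)] > 0.2
        off_diag = [v for (g, lab), v in score.block_fractions.items()
                    if lab != score.winners[g]]
        assert max(off_diag) < 0.05

    def test_memory_groups_persist_until_reset(self, taught_k3):
        """Each memory group, once activated, stays above threshold
        until the reset epoch at the end of the trial."""
        net, protocol, result = taught_k3
        raster = result.raster
        K = len(protocol.items)
        reset_start = K * protocol.item_duration - protocol.cos_duration
        for k in range(1, K + 1):
            lo, hi = net.layout.range_of(f"memory_{k}")
            activation = (k - 1) * protocol.item_duration + 1500.0
            for t in np.arange(activation, reset_start - 500.0, 500.0):
                assert raster.population_rate(lo, hi, t, t + 500.0) > 20.0, (
                    f"memory_{k} silent at {t} ms")
            # and silenced after the reset
            assert raster.population_rate(
                lo, hi, reset_start + 600.0, reset_start + 900.0) < 10.0

    def test_ordinal_mutual_exclusion(self, taught_k3):
        """Outside CoS windows, at most one ordinal group is active at a
        time."""
        net, protocol, result = taught_k3
        raster = result.raster
        K = len(protocol.items)
        cos_windows = [((i + 1) * protocol.item_duration
                        - protocol.cos_duration - 100.0,
                        (i + 1) * protocol.item_duration + 200.0)
                       for i in range(K)]
        ranges = [net.layout.range_of(f"ordinal_{k}")
                  for k in range(1, K + 1)]
        for t in np.arange(0.0, raster.duration - 200.0, 200.0):
            if any(a <= t <= b for a, b in cos_windows):
                continue
            active = sum(
                raster.population_rate(lo, hi, t, t + 200.0) > 40.0
                for lo, hi in ranges)
            assert active <= 1, f"two ordinal groups active at {t} ms"

    def test_single_item_sequence_learns_one_block(self):
        net = build_serial_order(SerialOrderConfig(n_items=1))
        res = run_teaching(net, TeachingProtocol(items=("A",)), seed=0)
        assert res.ok
        blocks = ordinal_block_means(net)
        assert (blocks["ordinal_1"] > 0.5).sum() > 3

    def test_repeated_item_blocks_are_independent(self):
        """Teaching A-A-C potentiates ordinal_1->A and ordinal_2->A as
        two separate blocks of plastic synapses."""
        net = build_serial_order(SerialOrderConfig())
        res = run_teaching(net, TeachingProtocol(items=("A", "A", "C")),
                           seed=5)
        assert res.ok
        blocks = ordinal_block_means(net)
        a_lo, a_hi = net.annotations["item_regions"]["A"]
        c_lo0 = net.layout.range_of("content_exc")[0]
        rel = slice(a_lo - c_lo0, a_hi - c_lo0)
        assert (blocks["ordinal_1"][rel] > 0.5).sum() > 3
        assert (blocks["ordinal_2"][rel] > 0.5).sum() > 3
        # distinct synapse populations: rows differ
        o1 = net.layout.range_of("ordinal_1")
        o2 = net.layout.range_of("ordinal_2")
        assert o1 != o2

    def test_unknown_item_label_rejected(self, k3_network):
        with pytest.raises(ConfigurationError):
            run_teaching(k3_network, TeachingProtocol(items=("A", "Z")),
                         seed=0)


class TestReplay:
    def test_replay_decodes_taught_sequence(self, taught_k3):
        net, protocol, _ = taught_k3
        rep = run_replay(net, protocol=protocol, seed=21)
        assert rep.labels == ["A", "B", "C"]
        assert not rep.failures

    def test_replay_with_irregular_cos_spacing(self, taught_k3):
        """The decoded sequence does not depend on when the transitions
        are triggered (spacing drawn from [1, 5] s)."""
        net, protocol, _ = taught_k3
        for seed in (0, 1):
            rng = np.random.default_rng(seed)
            times = list(3200.0 + np.cumsum(rng.uniform(1000, 5000, 3)))
            rep = run_replay(net, cos_times=times, protocol=protocol,
                             seed=seed)
            assert rep.labels == ["A", "B", "C"]

    def test_untaught_network_reports_recall_failures(self):
        net = build_serial_order(SerialOrderConfig())
        rep = run_replay(net, seed=0)
        assert rep.labels == [None, None, None]
        assert len(rep.failures) == 3  # reported, not raised

    def test_replay_does_not_change_weights(self, taught_k3):
        net, protocol, _ = taught_k3
        before = net.plastic.weights.copy()
        run_replay(net, protocol=protocol, seed=33)
        assert np.array_equal(before, net.plastic.weights)

    def test_cos_before_go_end_rejected(self, taught_k3):
        net, protocol, _ = taught_k3
        with pytest.raises(ConfigurationError):
            run_replay(net, cos_times=[1000.0, 5000.0, 9000.0],
                       protocol=protocol)

    def test_protocol_determinism(self):
        """Identical (protocol, seed) give identical rasters and
        identical learned weights."""
        def one():
            net = build_serial_order(SerialOrderConfig())
            res = run_teaching(net, TeachingProtocol(items=("A", "B", "C")),
                               seed=3)
            return res.raster, net.plastic.weights.copy()

        (r1, w1), (r2, w2) = one(), one()
        assert np.array_equal(r1.times, r2.times)
        assert np.array_equal(r1.indices, r2.indices)
        assert np.array_equal(w1, w2)


class TestProbe:
    def test_probe_refused_while_plasticity_enabled(self, k3_network):
        k3_network.set_plasticity(True)
        with pytest.raises(ProbeError):
            probe_plastic_weights(k3_network)

    def test_probe_single_potentiated_entry(self, k3_network):
        net = k3_network
        net.set_plasticity(False)
        olo, _ = net.layout.range_of("ordinal_1")
        clo, chi = net.layout.range_of("content_exc")
        net.plastic.weights[:, clo:chi] = net.plastic.params.w_min
        net.plastic.weights[olo + 2, clo + 7] = net.plastic.params.w_max
        probe = probe_plastic_weights(net, pre_range=(olo, olo + 20),
                                      post_range=(clo, chi))
        hits = np.argwhere(probe)
        assert hits.tolist() == [[olo + 2, clo + 7]]

    def test_probe_idempotent(self, taught_k3):
        net, _, _ = taught_k3
        span = net.layout.span_of("ordinal")
        crange = net.layout.range_of("content_exc")
        a = probe_plastic_weights(net, pre_range=span, post_range=crange)
        b = probe_plastic_weights(net, pre_range=span, post_range=crange)
        assert np.array_equal(a, b)

    def test_probe_all_depressed_is_all_low(self, k3_network):
        net = k3_network
        net.set_plasticity(False)
        clo, chi = net.layout.range_of("content_exc")
        probe = probe_plastic_weights(
            net, pre_range=net.layout.span_of("ordinal"),
            post_range=(clo, chi))
        assert probe.sum() == 0


class TestUnlearning:
    def test_reteaching_same_sequence_is_a_fixed_point(self):
        net = build_serial_order(SerialOrderConfig())
        protocol = TeachingProtocol(items=("A", "B", "C"))
        run_teaching(net, protocol, seed=2)
        res = run_unlearning(net, ("A", "B", "C"), n_trials=1, seed=2)
        assert res.first_success_trial == 1

    def test_overwriting_depresses_old_and_potentiates_new(self):
        """Re-teaching B-A-C over C-A-B depresses the old-only
        associations (I->C, III->B) and potentiates the new ones."""
        net = build_serial_order(SerialOrderConfig())
        run_teaching(net, TeachingProtocol(items=("C", "A", "B")), seed=4)
        net.set_plasticity(False)
        span = net.layout.span_of("ordinal")
        crange = net.layout.range_of("content_exc")
        regions = net.annotations["item_regions"]
        before = score_probe(
            probe_plastic_weights(net, pre_range=span, post_range=crange),
            net.layout, regions)
        net.set_plasticity(True)
        assert before.winners["ordinal_1"] == "C"

        res = run_unlearning(net, ("B", "A", "C"), n_trials=1, seed=4)
        after = score_probe(res.probes[0], net.layout, regions)
        assert after.block_fractions[("ordinal_1", "C")] < \
            before.block_fractions[("ordinal_1", "C")]
        assert after.block_fractions[("ordinal_1", "B")] > 0.2
        assert after.winners["ordinal_1"] == "B"


def test_default_cos_schedule_is_regular():
    assert default_cos_schedule(3, spacing=2000.0) == [2000.0, 4000.0, 6000.0]
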