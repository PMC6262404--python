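"""Synapse delivery, the three-factor plasticity rule, and bistable drift."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from seqwta.builder import SerialOrderConfig, _make_layout
from seqwta.errors import ConfigurationError
from seqwta.synapses import (
    PlasticityParams,
    PlasticSynapseMatrix,
    StaticSynapseMatrix,
    StaticWeightTable,
    deliver_spikes,
    drift_step,
    initialize_plastic_matrix,
    plastic_update_on_pre,
)


def three_branch_oracle(w, v_post, ca_post, p):
    """Literal brute-force restatement of the update rule's three branches."""
    ltp = p.theta_1 < ca_post < p.theta_max
    ltd = (ca_post < p.theta_max) if p.ltd_gate == "low_inclusive" else ltp
    if v_post > p.theta_mem and ltp:
        out = w + p.delta_w_plus
    elif v_post < p.theta_mem and ltd:
        out = w - p.delta_w_minus
    else:
        out = w
    return min(max(out, p.w_min), p.w_max)


class TestDeliverSpikes:
    def setup_method(self):
        table = StaticWeightTable()
        w = np.zeros((4, 4))
        w[0, 1] = table.excitatory_levels[2]
        w[2, 3] = table.inhibitory_levels[1]
        self.m = StaticSynapseMatrix(weights=w, table=table)

    def test_no_spikes_no_current(self):
        assert np.all(deliver_spikes(np.array([], dtype=int), self.m) == 0)

    def test_single_spike_proportional_to_weight(self):
        out = deliver_spikes(np.array([0]), self.m)
        assert out[1] == self.m.table.excitatory_levels[2]
        assert out[[0, 2, 3]].sum() == 0

    def test_inhibitory_weight_gives_negative_current(self):
        out = deliver_spikes(np.array([2]), self.m)
        assert out[3] < 0

    def test_simultaneous_spikes_superpose_linearly(self):
        single = deliver_spikes(np.array([0]), self.m)
        double = deliver_spikes(np.array([0, 0]), self.m)
        assert np.allclose(double, 2 * single)

    def test_out_of_range_index_rejected(self):
        with pytest.raises(ConfigurationError):
            deliver_spikes(np.array([7]), self.m)

    def test_plastic_delivery_scales_with_gain(self):
        w = np.zeros((2, 2))
        w[0, 1] = 1.0
        pm = PlasticSynapseMatrix(weights=w, learnable=np.ones((2, 2), bool),
                                  gain=0.03)
        out = deliver_spikes(np.array([0]), pm)
        assert out[1] == pytest.approx(0.03)


class TestPlasticUpdate:
    @given(
        w=st.floats(0.0, 1.0),
        v=st.floats(-2.0, 3.0),
        ca=st.floats(0.0, 30.0),
        gate=st.sampled_from(["low_inclusive", "shared"]),
    )
    def test_matches_three_branch_oracle(self, w, v, ca, gate):
        p = PlasticityParams(ltd_gate=gate)
        assert plastic_update_on_pre(w, v, ca, p) == three_branch_oracle(
            w, v, ca, p
        )

    def test_calcium_gate_blocks_potentiation_for_silent_neuron(self):
        p = PlasticityParams(ltd_gate="shared")
        # Ca below theta_1: no change regardless of membrane potential
        for v in (-1.0, 0.0, 0.2, 0.9, 2.0):
            assert plastic_update_on_pre(0.4, v, 0.0, p) == 0.4

    def test_potentiation_branch(self):
        p = PlasticityParams()
        ca = (p.theta_1 + p.theta_max) / 2
        assert plastic_update_on_pre(0.4, p.theta_mem + 0.1, ca, p) == \
            pytest.approx(0.4 + p.delta_w_plus)

    def test_depression_branch(self):
        p = PlasticityParams()
        ca = (p.theta_1 + p.theta_max) / 2
        assert plastic_update_on_pre(0.4, p.theta_mem - 0.1, ca, p) == \
            pytest.approx(0.4 - p.delta_w_minus)

    def test_silent_post_neuron_depresses_with_default_gate(self):
        """A presynaptic spike not followed by postsynaptic activity
        (V at rest, Ca = 0) depresses the synapse — the forgetting
        mechanism that lets a stored sequence be overwritten."""
        p = PlasticityParams()
        assert plastic_update_on_pre(1.0, 0.0, 0.0, p) == \
            pytest.approx(1.0 - p.delta_w_minus)

    @given(
        start=st.floats(0.0, 1.0),
        events=st.lists(
            st.tuples(st.floats(-1.0, 2.0), st.floats(0.0, 30.0)),
            max_size=40,
        ),
    )
    def test_weight_never_leaves_bounds(self, start, events):
        p = PlasticityParams()
        w = start
        for v, ca in events:
            w = plastic_update_on_pre(w, v, ca, p)
            assert p.w_min <= w <= p.w_max

    @given(n_pre=st.integers(1, 200))
    def test_silent_post_never_potentiates(self, n_pre):
        """Weights never increase while the postsynaptic neuron stays
        silent, whatever the starting weight."""
        p = PlasticityParams()
        w = 0.8
        for _ in range(n_pre):
            w_new = plastic_update_on_pre(w, 0.0, 0.0, p)
            assert w_new <= w
            w = w_new


class TestDrift:
    def test_at_w_max_no_change(self):
        p = PlasticityParams()
        assert drift_step(p.w_max, 0.1, p) == p.w_max

    def test_at_threshold_exactly_no_change(self):
        p = PlasticityParams()
        assert drift_step(p.theta_w, 0.1, p) == p.theta_w

    def test_reaches_w_max_in_predicted_step_count(self):
        """Integrating the constant-rate drift from just above theta_w
        hits w_max after exactly ceil((w_max - theta_w - eps)/(C dt))
        steps."""
        p = PlasticityParams()
        dt, eps = 0.5, 1e-4
        w = p.theta_w + eps
        expected = math.ceil((p.w_max - p.theta_w - eps) / (p.c_drift * dt))
        steps = 0
        while w < p.w_max:
            w = drift_step(w, dt, p)
            steps += 1
        # accumulated float rounding may cost one extra step
        assert expected <= steps <= expected + 1

    def test_drift_down_floors_at_w_min(self):
        p = PlasticityParams()
        w = p.theta_w - 1e-4
        for _ in range(int(2 * (p.theta_w - p.w_min) / (p.c_drift * 0.5))):
            w = drift_step(w, 0.5, p)
        assert w == p.w_min

    def test_bistability_after_long_drift(self):
        """After T = 10 (w_max - w_min) / C_drift of input-free drift,
        every weight sits within 1e-9 of one of the two stable states."""
        p = PlasticityParams()
        rng = np.random.default_rng(0)
        ws = rng.uniform(p.w_min, p.w_max, size=500)
        ws = ws[np.abs(ws - p.theta_w) > 1e-6]
        dt = 1.0
        n = int(10 * (p.w_max - p.w_min) / p.c_drift / dt)
        up = ws > p.theta_w
        ws = np.where(up, np.minimum(ws + n * p.c_drift * dt, p.w_max),
                      np.maximum(ws - n * p.c_drift * dt, p.w_min))
        # closed-form fast-forward above agrees with drift_step stepping
        w_check = p.theta_w + 1e-3
        for _ in range(n):
            w_check = drift_step(w_check, dt, p)
        assert w_check == p.w_max
        assert np.all(
            (np.abs(ws - p.w_min) < 1e-9) | (np.abs(ws - p.w_max) < 1e-9)
        )


class TestInitializePlasticMatrix:
    def setup_method(self):
        self.layout = _make_layout(SerialOrderConfig())

    def test_zero_fraction_all_depressed(self):
        m = initialize_plastic_matrix(self.layout, 0.0, seed=0)
        assert np.all(m.weights == m.params.w_min)

    def test_fraction_count_per_recurrent_block(self):
        """30% of a 20x20 ordinal recurrent block is 120 potentiated
        entries exactly."""
        m = initialize_plastic_matrix(self.layout, 0.3, seed=0)
        lo, hi = self.layout.range_of("ordinal_1")
        block = m.weights[lo:hi, lo:hi]
        assert (block == m.params.w_max).sum() == round(0.3 * 400)
        mlo, mhi = self.layout.range_of("memory_2")
        mblock = m.weights[mlo:mhi, mlo:mhi]
        assert (mblock == m.params.w_max).sum() == round(0.3 * 100)

    def test_ordinal_to_content_block_depressed_and_learnable(self):
        m = initialize_plastic_matrix(self.layout, 0.3, seed=0)
        olo, ohi = self.layout.range_of("ordinal_1")
        clo, chi = self.layout.range_of("content_exc")
        assert np.all(m.weights[olo:ohi, clo:chi] == m.params.w_min)
        assert np.all(m.learnable[olo:ohi, clo:chi])

    def test_recurrent_potentiated_entries_not_learnable(self):
        m = initialize_plastic_matrix(self.layout, 0.3, seed=0)
        assert not m.learnable[m.weights == m.params.w_max].any()

    def test_same_seed_same_matrix(self):
        a = initialize_plastic_matrix(self.layout, 0.3, seed=42)
        b = initialize_plastic_matrix(self.layout, 0.3, seed=42)
        assert np.array_equal(a.weights, b.weights)

    def test_bad_fraction_rejected(self):
        with pytest.raises(ConfigurationError):
            initialize_plastic_matrix(self.layout, 1.5, seed=0)


class TestWeightTable:
    def test_exactly_four_excitatory_levels_required(self):
        with pytest.raises(ConfigurationError):
            StaticWeightTable(excitatory_levels=(0.1, 0.2, 0.3))
        with pytest.raises(ConfigurationError):
            StaticWeightTable(excitatory_levels=(0.1, 0.2, 0.2, 0.3))

    def test_matrix_entries_validated_against_levels(self):
        table = StaticWeightTable()
        with pytest.raises(ConfigurationError):
            StaticSynapseMatrix(weights=np.full((2, 2), 0.123), table=table)
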