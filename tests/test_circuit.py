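"""Spinal circuit: connectivity structure and spiking dynamics."""

import math
from collections import Counter

import numpy as np
import pytest

from spindlearm.circuit import (DEFAULT_RELATIONS, NeuronParams,
                                apply_weight_vector, build_connectome,
                                simulate_window)


class TestConnectivity:
    def test_connection_counts(self, complete, simple):
        assert len(complete.connections) == 150
        assert len(simple.connections) == 42

    def test_unit_counts(self, complete, simple):
        assert complete.n_neurons == 36
        assert len(complete.encoders) == 12
        assert simple.n_neurons == 12
        assert len(simple.encoders) == 0

    def test_initial_weights_by_sign_class(self, complete):
        for c in complete.connections:
            assert c.weight == {"excitatory": 5.0, "inhibitory": -5.0,
                                "flexible": 2.0}[c.sign_class]
            assert c.bounds == {"excitatory": (0.0, 10.0),
                                "inhibitory": (-10.0, 0.0),
                                "flexible": (-10.0, 10.0)}[c.sign_class]
            assert c.delay == 1.0

    def test_simple_is_renshaw_core_of_complete(self, complete, simple):
        core = {(c.pre, c.post, c.scope, c.sign_class)
                for c in complete.connections
                if {c.pre.split("_")[0], c.post.split("_")[0]} <= {"alpha", "R"}}
        assert {(c.pre, c.post, c.scope, c.sign_class)
                for c in simple.connections} == core

    def test_afferent_routing(self, complete):
        """Alpha and PN receive Ia + II; Ia interneurons receive Ia only."""
        by_post_type = Counter()
        for c in complete.connections:
            pre_t, post_t = c.pre.split("_")[0], c.post.split("_")[0]
            if pre_t in ("Ia", "II"):
                by_post_type[(pre_t, post_t)] += 1
        assert by_post_type[("Ia", "alpha")] == 14   # HOM x6 + SYN x8
        assert by_post_type[("II", "alpha")] == 6
        assert by_post_type[("Ia", "IaIN")] == 6
        assert by_post_type[("II", "IaIN")] == 0
        assert by_post_type[("Ia", "PN")] == 6
        assert by_post_type[("II", "PN")] == 6

    def test_syn_ant_sign_opposition(self, complete):
        """Where a connection type exists in both SYN and ANT scope, the
        sign classes must be opposite (synergist/antagonist opposition)."""
        signs = {}
        for c in complete.connections:
            key = (c.pre.split("_")[0], c.post.split("_")[0], c.scope)
            signs.setdefault(key, set()).add(c.sign_class)
        for (pre_t, post_t, scope), s in signs.items():
            assert len(s) == 1  # each (type pair, scope) has one sign class
            if scope == "SYN":
                other = signs.get((pre_t, post_t, "ANT"))
                if other:
                    assert {next(iter(s)), next(iter(other))} == \
                        {"excitatory", "inhibitory"}

    def test_inconsistent_relations_rejected(self):
        bad = dict(DEFAULT_RELATIONS)
        bad["SYN"] = bad["SYN"] + [("MEF", "MEE")]  # already antagonists
        with pytest.raises(ValueError):
            build_connectome("complete", relations=bad)
        with pytest.raises(ValueError):
            build_connectome("complete",
                             relations={"ANT": [("MEF", "MEF")]})


class TestWeightVector:
    def test_identity_roundtrip(self, complete):
        w = complete.weight_vector()
        c2 = apply_weight_vector(complete, w)
        assert np.array_equal(c2.weight_vector(), w)

    def test_out_of_bounds_clamped(self, complete):
        i_inh = next(i for i, c in enumerate(complete.connections)
                     if c.sign_class == "inhibitory")
        w = complete.weight_vector()
        w[i_inh] = +20.0
        c2 = apply_weight_vector(complete, w)
        assert c2.connections[i_inh].weight == 0.0

    def test_sign_discipline_after_any_update(self, complete, rng):
        w = rng.uniform(-30, 30, size=150)
        c2 = apply_weight_vector(complete, w)
        for c in c2.connections:
            if c.sign_class == "excitatory":
                assert c.weight >= 0.0
            elif c.sign_class == "inhibitory":
                assert c.weight <= 0.0
            assert c.bounds[0] <= c.weight <= c.bounds[1]

    def test_length_mismatch_rejected(self, complete):
        with pytest.raises(ValueError):
            apply_weight_vector(complete, np.zeros(42))


def _silent(connectome):
    return apply_weight_vector(connectome, np.zeros(len(connectome.connections)))


class TestSpiking:
    def test_tonic_isi_matches_lif_closed_form(self, complete):
        """I_e = 380 pA, no synaptic input: ISI = t_ref + tau ln(dV/(dV-th))."""
        c = _silent(complete)
        sp, _ = simulate_window(c, np.zeros(12), 0.0, 0.8,
                                np.random.default_rng(0))
        times = sorted(t for u, t in sp if u == "alpha_MEF")
        p = c.neuron_params
        dv = p.I_e * p.tau_m / p.C_m          # 15.2 mV
        theta = p.V_th - p.E_L                # 15 mV
        isi_ms = p.t_ref + p.tau_m * math.log(dv / (dv - theta))
        assert isi_ms == pytest.approx(45.31, abs=0.01)
        measured = np.diff(times) * 1e3
        assert np.allclose(measured, isi_ms, atol=0.15)
        assert len(times) == 17                # ~17 spikes in 0.8 s

    def test_rheobase(self, complete):
        """375 pA is the rheobase: 374 pA silent, 380 pA fires."""
        c374 = _silent(build_connectome(
            "complete", neuron_params=NeuronParams(I_e=374.0)))
        sp, _ = simulate_window(c374, np.zeros(12), 0.0, 0.8,
                                np.random.default_rng(0))
        assert len(sp) == 0
        sp380, _ = simulate_window(_silent(complete), np.zeros(12), 0.0, 0.1,
                                   np.random.default_rng(0))
        assert len(sp380) > 0

    def test_silent_without_drive(self, complete):
        c = _silent(build_connectome(
            "complete", neuron_params=NeuronParams(I_e=0.0)))
        sp, _ = simulate_window(c, np.zeros(12), 0.0, 0.2,
                                np.random.default_rng(3))
        assert sp == []

    def test_poisson_encoder_statistics(self, complete):
        """Encoder spike counts are Poisson: mean = rate x duration."""
        c = _silent(build_connectome(
            "complete", neuron_params=NeuronParams(I_e=0.0)))
        rate, duration, n_rep = 100.0, 0.1, 3000
        rates = np.zeros(12)
        rates[0] = rate
        rng = np.random.default_rng(42)
        counts = []
        for _ in range(n_rep):
            sp, _ = simulate_window(c, rates, 0.0, duration, rng)
            counts.append(sum(1 for u, t in sp if u == "Ia_MEF"))
        mean = np.mean(counts)
        expect = rate * duration
        sigma = math.sqrt(expect)
        assert abs(mean - expect) < 3 * sigma / math.sqrt(n_rep)

    def test_refractoriness_respected(self, complete, rng):
        c = apply_weight_vector(complete, rng.uniform(-10, 10, 150))
        sp, _ = simulate_window(c, np.full(12, 80.0), 0.0, 0.3,
                                np.random.default_rng(5))
        per_unit = {}
        for u, t in sp:
            per_unit.setdefault(u, []).append(t)
        p = c.neuron_params
        for u, times in per_unit.items():
            if u.split("_")[0] in ("Ia", "II"):
                continue  # encoders are not refractory
            gaps = np.diff(times) * 1e3
            assert np.all(gaps >= p.t_ref - 1e-9)

    def test_exact_and_euler_integrators_agree_on_spike_counts(self, complete):
        c = _silent(complete)
        sp_a, _ = simulate_window(c, np.zeros(12), 0.0, 0.4,
                                  np.random.default_rng(0))
        sp_b, _ = simulate_window(c, np.zeros(12), 0.0, 0.4,
                                  np.random.default_rng(0),
                                  integrator="euler")
        assert len(sp_a) == len(sp_b)

    def test_determinism(self, complete):
        c = apply_weight_vector(complete, complete.weight_vector())
        runs = []
        for _ in range(2):
            sp, _ = simulate_window(c, np.full(12, 40.0), 0.0, 0.2,
                                    np.random.default_rng(7))
            runs.append(sp)
        assert runs[0] == runs[1]

    def test_negative_rates_rejected(self, complete):
        with pytest.raises(ValueError):
            simulate_window(complete, np.full(12, -1.0), 0.0, 0.1,
                            np.random.default_rng(0))
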