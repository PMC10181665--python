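"""Network construction, simplification transforms, and simulation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lso_ssl import (
    ConnectionKernel,
    Network,
    NetworkSpec,
    binomial_kernel,
    build_network,
    build_network_with_relays,
    eliminate_relays,
    quantize_kernel,
    simulate,
    validate_network,
    ws_weights,
)
from lso_ssl.network import Edge, Unit
from lso_ssl.neurons import activation, rate_equilibrium


class TestWsWeights:
    def test_seven_tuning_ladder(self):
        ipsi, contra = ws_weights(7)
        assert np.allclose(ipsi, np.arange(1, 8) / 8)
        assert np.allclose(contra, np.arange(7, 0, -1) / 8)

    def test_single_tuning(self):
        ipsi, contra = ws_weights(1)
        assert ipsi.tolist() == [0.5] and contra.tolist() == [0.5]

    @settings(derandomize=True, max_examples=30)
    @given(p=st.integers(1, 50))
    def test_ladders_are_complementary(self, p):
        ipsi, contra = ws_weights(p)
        assert len(ipsi) == len(contra) == p
        assert np.allclose(ipsi + contra, 1.0)

    def test_rejects_non_positive(self):
        with pytest.raises(ValueError):
            ws_weights(0)


class TestBinomialKernel:
    @pytest.mark.parametrize(
        "width,expected",
        [(1, [1.0]), (3, [0.25, 0.5, 0.25]), (5, [1 / 16, 4 / 16, 6 / 16, 4 / 16, 1 / 16])],
    )
    def test_pascal_rows(self, width, expected):
        k = binomial_kernel(width)
        assert np.allclose(k.weights, expected)

    @settings(derandomize=True, max_examples=20)
    @given(half=st.integers(0, 10))
    def test_symmetric_and_normalized(self, half):
        k = binomial_kernel(2 * half + 1)
        assert np.allclose(k.weights, k.weights[::-1])
        assert k.weights.sum() == pytest.approx(1.0)

    def test_even_width_rejected(self):
        with pytest.raises(ValueError):
            binomial_kernel(4)


class TestQuantizeKernel:
    def test_width3_binomial_at_level2(self):
        q, scale = quantize_kernel(binomial_kernel(3), max_level=2)
        assert q.weights.tolist() == [1.0, 2.0, 1.0]
        assert scale == pytest.approx(0.25)

    def test_single_weight_maps_to_full_scale(self):
        q, _ = quantize_kernel(ConnectionKernel(np.array([1.0])), max_level=7)
        assert q.weights.tolist() == [7.0]

    @settings(derandomize=True, max_examples=30)
    @given(
        a=st.floats(0.01, 1.0),
        b=st.floats(0.01, 1.0),
        level=st.integers(1, 16),
    )
    def test_dequantization_error_bound(self, a, b, level):
        """Optimal rescaling never exceeds the rounding bound 0.5*max(w)/level."""
        w = np.array([a, b, a])
        w = w / w.sum()
        q, scale = quantize_kernel(ConnectionKernel(w), max_level=level)
        err = np.max(np.abs(q.weights * scale - w))
        assert err <= 0.5 * w.max() / level + 1e-12

    def test_zero_kernel_rejected(self):
        with pytest.raises(ValueError):
            quantize_kernel(ConnectionKernel(np.zeros(3)), max_level=2)


class TestBuildNetwork:
    def test_default_census_is_1024(self):
        net = build_network(NetworkSpec(n_freq=64, n_tunings=7))
        assert net.n_units == 1024
        per_hemi_st = sum(1 for u in net.units if u.kind == "st" and u.hemisphere == "L")
        per_hemi_ws = sum(1 for u in net.units if u.kind == "ws" and u.hemisphere == "L")
        assert per_hemi_st == 64 and per_hemi_ws == 448
        validate_network(net)

    def test_minimal_network_by_hand(self):
        net = build_network(NetworkSpec(n_freq=1, n_tunings=1))
        assert net.n_units == 4
        kernel_edges = [e for e in net.edges if e.conn == "kernel"]
        one_to_one = [e for e in net.edges if e.conn == "one_to_one"]
        assert len(kernel_edges) == 2 and len(one_to_one) == 4
        validate_network(net)

    @pytest.mark.parametrize("n_freq,n_tunings", [(2, 1), (4, 3), (8, 7)])
    def test_validator_accepts_built_networks(self, n_freq, n_tunings):
        validate_network(build_network(NetworkSpec(n_freq=n_freq, n_tunings=n_tunings)))

    def test_validator_catches_tampering(self, small_network):
        small_network.edges = [e for e in small_network.edges
                               if not (e.sign == "inh" and e.dst == "L:ws:0:0")]
        with pytest.raises(ValueError):
            validate_network(small_network)

    def test_construction_is_mirror_symmetric(self, small_network):
        def flip(uid):
            return {"L": "R", "R": "L"}[uid[0]] + uid[1:]

        edges = {(e.src, e.dst, e.weight, e.sign) for e in small_network.edges}
        flipped = {(flip(s), flip(d), w, sign) for s, d, w, sign in edges}
        assert edges == flipped

    def test_json_round_trip(self, small_network):
        restored = Network.from_json(small_network.to_json())
        assert restored.spec == small_network.spec
        assert restored.units == small_network.units
        assert restored.edges == small_network.edges


class TestRelayElimination:
    def _relay_net(self):
        return build_network_with_relays(NetworkSpec(n_freq=2, n_tunings=2, mode="rate"))

    def test_mntb_relay_subsumed_into_inhibitory_edge(self):
        net = self._relay_net()
        n_before = net.n_units
        simplified = eliminate_relays(net)
        assert simplified.n_units == n_before - 2 * 2 * 2  # one relay per W-S unit
        validate_network(simplified)
        direct = build_network(net.spec)
        assert {(e.src, e.dst, e.weight, e.sign) for e in simplified.edges} == \
               {(e.src, e.dst, e.weight, e.sign) for e in direct.edges}

    def test_identity_on_relay_free_network(self, small_network):
        out = eliminate_relays(small_network)
        assert out.units == small_network.units
        assert len(out.edges) == len(small_network.edges)

    def test_chain_of_two_relays_composes_weights(self):
        spec = NetworkSpec(n_freq=1, n_tunings=1, mode="rate")
        units = [
            Unit("src_n", "L", "st", 0),
            Unit("r1", "L", "relay", 0, transfer="linear"),
            Unit("r2", "L", "relay", 0, transfer="linear"),
            Unit("dst_n", "L", "ws", 0, tuning=0),
        ]
        edges = [
            Edge("src_n", "r1", 0.5, "exc", "one_to_one"),
            Edge("r1", "r2", 0.4, "exc", "one_to_one"),
            Edge("r2", "dst_n", 0.25, "inh", "one_to_one"),
        ]
        net = Network(spec=spec, inputs=[], units=units, edges=edges)
        out = eliminate_relays(net)
        assert [u.id for u in out.units] == ["src_n", "dst_n"]
        (edge,) = out.edges
        assert (edge.src, edge.dst, edge.sign) == ("src_n", "dst_n", "inh")
        assert edge.weight == pytest.approx(0.5 * 0.4 * 0.25)

    def test_multi_input_unit_left_untouched(self):
        spec = NetworkSpec(n_freq=1, n_tunings=1, mode="rate")
        units = [Unit("a", "L", "st", 0), Unit("b", "L", "st", 0),
                 Unit("r", "L", "relay", 0, transfer="linear"),
                 Unit("c", "L", "ws", 0, tuning=0)]
        edges = [Edge("a", "r", 1.0, "exc", "one_to_one"),
                 Edge("b", "r", 1.0, "exc", "one_to_one"),
                 Edge("r", "c", 1.0, "inh", "one_to_one")]
        net = Network(spec=spec, inputs=[], units=units, edges=edges)
        out = eliminate_relays(net)
        assert len(out.units) == 4 and len(out.edges) == 3

    def test_functional_equivalence_in_rate_mode(self):
        """Eliminating linear relays leaves all W-S equilibria unchanged."""
        spec = NetworkSpec(n_freq=4, n_tunings=3, mode="rate")
        with_relays = build_network_with_relays(spec)
        direct = build_network(spec)
        inputs = np.concatenate([np.array([0.3, 1.2, 0.7, 0.1]),
                                 np.array([0.9, 0.2, 0.5, 1.0])])
        r1 = simulate(with_relays, inputs, duration=400.0, dt=0.1)
        r2 = simulate(direct, inputs, duration=400.0, dt=0.1)
        for uid in direct.unit_ids():
            if ":ws:" in uid:
                assert r1.rates[r1.index(uid)] == pytest.approx(
                    r2.rates[r2.index(uid)], abs=1e-6
                )


class TestSimulate:
    def test_zero_input_gives_no_spikes(self):
        net = build_network(NetworkSpec(n_freq=2, n_tunings=2, mode="spiking"))
        res = simulate(net, np.zeros(4), duration=100.0, dt=0.1, seed=0)
        assert res.spikes.sum() == 0

    def test_same_seed_bitwise_reproducible(self):
        net = build_network(NetworkSpec(n_freq=2, n_tunings=2, mode="spiking"))
        inputs = np.array([800.0, 100.0, 50.0, 400.0])
        a = simulate(net, inputs, duration=500.0, dt=0.1, seed=42)
        b = simulate(net, inputs, duration=500.0, dt=0.1, seed=42)
        assert np.array_equal(a.spikes, b.spikes)

    def test_input_contract_errors(self, small_network):
        with pytest.raises(ValueError):
            simulate(small_network, np.zeros(3), duration=10.0)  # missing channels
        with pytest.raises(ValueError):
            simulate(small_network, np.zeros(8), duration=10.05, dt=0.1)

    def test_rate_mode_matches_hand_iterated_equilibria(self):
        """One band: input -> S-T -> W-S equilibria agree with the closed form."""
        spec = NetworkSpec(n_freq=1, n_tunings=3, mode="rate")
        net = build_network(spec)
        left_in, right_in = 1.4, 0.6
        res = simulate(net, np.array([left_in, right_in]), duration=600.0, dt=0.1)
        base = spec.rate_params
        # with a single band only the kernel's centre coefficient survives
        # the zero padding, so the S-T drive is 0.5 * input
        k_center = binomial_kernel(spec.kernel_width).weights[1]
        g_st = {h: activation(rate_equilibrium(k_center * x, 0.0, base))
                for h, x in (("L", left_in), ("R", right_in))}
        ipsi, contra = ws_weights(3)
        for j in range(3):
            expected = activation(rate_equilibrium(
                ipsi[j] * g_st["L"], contra[j] * g_st["R"], base))
            assert res.rates[res.index(f"L:ws:0:{j}")] == pytest.approx(
                expected, abs=1e-6
            )

    def test_rate_mode_mirror_symmetry_is_exact(self, small_network):
        inputs = np.concatenate([np.array([0.2, 1.0, 0.4, 0.8]),
                                 np.array([0.6, 0.1, 0.9, 0.3])])
        swapped = np.concatenate([inputs[4:], inputs[:4]])
        a = simulate(small_network, inputs, duration=300.0, dt=0.1)
        b = simulate(small_network, swapped, duration=300.0, dt=0.1)
        for uid in small_network.unit_ids():
            other = {"L": "R", "R": "L"}[uid[0]] + uid[1:]
            assert a.rates[a.index(uid)] == b.rates[b.index(other)]

    def test_tuning_monotone_in_ipsilateral_drive(self, small_network):
        """Left W-S equilibria never decrease as the left drive grows."""
        right = 0.8
        drives = [0.0, 0.4, 0.8, 1.2, 1.6, 2.0]
        responses = []
        for left in drives:
            inputs = np.concatenate([np.full(4, left), np.full(4, right)])
            res = simulate(small_network, inputs, duration=300.0, dt=0.1)
            responses.append([res.rates[res.index(f"L:ws:1:{j}")]
                              for j in range(3)])
        responses = np.array(responses)
        assert np.all(np.diff(responses, axis=0) >= -1e-9)
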