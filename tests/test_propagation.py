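"""Signal propagation: the node rule, circuit evaluation, cycles, properties."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pathsig.errors import DomainError, NonConvergenceWarning
from pathsig.pathways import INHIBITION, extract_circuits
from pathsig.propagation import PropagationConfig, node_signal, propagate_all, propagate_circuit

from conftest import build_graph, oracle_propagate

unit = st.floats(0, 1, allow_nan=False)


class TestNodeSignal:
    @pytest.mark.parametrize(
        "v,acts,inhs,expected",
        [
            (1.0, [1.0], [], 1.0),
            (0.8, [0.5], [0.3], 0.28),
            (1.0, [0.5, 0.5], [], 0.75),
            (0.3, [1.0], [1.0], 0.0),
            (0.9, [], [], 0.9),  # receptor: incoming signal is 1
            (0.0, [0.7], [0.1], 0.0),
        ],
    )
    def test_hand_evaluated_cases(self, v, acts, inhs, expected):
        assert node_signal(v, acts, inhs) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("bad", [(-0.1, [], []), (0.5, [1.2], []), (0.5, [], [np.nan])])
    def test_domain_enforced(self, bad):
        with pytest.raises(DomainError):
            node_signal(*bad)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(unit, st.lists(unit, max_size=4), st.lists(unit, max_size=4))
    def test_bounded_in_unit_interval(self, v, acts, inhs):
        assert 0.0 <= node_signal(v, acts, inhs) <= 1.0


def series(graph, values):
    return pd.Series({n: values.get(n, values.get("*", 0.5)) for n in graph.nodes})


class TestPropagateCircuit:
    def test_lossless_chain(self):
        g = build_graph([("R", "M"), ("M", "E")])
        (c,) = extract_circuits(g)
        assert propagate_circuit(c, series(g, {"*": 1.0})) == 1.0

    def test_chain_attenuated_by_middle_node(self):
        g = build_graph([("R", "M"), ("M", "E")])
        (c,) = extract_circuits(g)
        v = pd.Series({"R": 1.0, "M": 0.5, "E": 1.0})
        assert propagate_circuit(c, v) == pytest.approx(0.5, abs=1e-12)

    def test_inhibition_attenuates(self):
        g = build_graph([("R", "E"), ("I", "E", INHIBITION)])
        (c,) = extract_circuits(g)
        v = pd.Series({"R": 0.8, "I": 0.4, "E": 1.0})
        # S_E = 1 · (1−(1−0.8)) · (1−0.4)
        assert propagate_circuit(c, v) == pytest.approx(0.8 * 0.6, abs=1e-12)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_independent_recursion_on_random_dags(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 16))
        names = [f"N{i}" for i in range(n)]
        edges = []
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < 0.35:
                    sign = INHIBITION if rng.random() < 0.3 else "activation"
                    edges.append((names[i], names[j], sign))
        if not edges:
            pytest.skip("empty draw")
        g = build_graph(edges)
        values = {node: float(rng.random()) for node in g.nodes}
        for c in extract_circuits(g):
            got = propagate_circuit(c, pd.Series(values))
            want = oracle_propagate(c, values)
            assert got == pytest.approx(want, abs=1e-12)

    def test_activation_monotonicity(self, rng):
        g = build_graph([("R", "A"), ("R", "B"), ("A", "E"), ("B", "E")])
        (c,) = extract_circuits(g)
        base = {n: float(rng.uniform(0.2, 0.8)) for n in g.nodes}
        s0 = propagate_circuit(c, pd.Series(base))
        for node in g.nodes:
            bumped = dict(base)
            bumped[node] = min(1.0, base[node] + 0.1)
            assert propagate_circuit(c, pd.Series(bumped)) >= s0 - 1e-12

    def test_cut_node_annihilates(self):
        g = build_graph([("R", "M"), ("M", "A"), ("M", "B"), ("A", "E"), ("B", "E")])
        (c,) = extract_circuits(g)
        v = series(g, {"*": 0.9, "M": 0.0})
        assert propagate_circuit(c, v) == 0.0

    def test_inhibition_monotone_decreasing(self):
        g = build_graph([("R", "E"), ("I", "E", INHIBITION)])
        (c,) = extract_circuits(g)
        lo = propagate_circuit(c, pd.Series({"R": 0.9, "I": 0.2, "E": 1.0}))
        hi = propagate_circuit(c, pd.Series({"R": 0.9, "I": 0.8, "E": 1.0}))
        assert hi < lo


class TestCycles:
    def _cyclic(self):
        g = build_graph([("R", "B"), ("B", "M"), ("M", "B"), ("B", "E")])
        (c,) = extract_circuits(g)
        return g, c

    def test_converges_and_is_bounded(self):
        g, c = self._cyclic()
        v = series(g, {"*": 0.9})
        s = propagate_circuit(c, v, PropagationConfig(tol=1e-10))
        assert 0.0 <= s <= 1.0

    def test_tightening_tol_changes_little(self):
        g, c = self._cyclic()
        v = series(g, {"*": 0.9})
        a = propagate_circuit(c, v, PropagationConfig(tol=1e-6))
        b = propagate_circuit(c, v, PropagationConfig(tol=1e-12))
        assert a == pytest.approx(b, abs=1e-5)

    def test_nonconvergence_warns_but_returns(self):
        g, c = self._cyclic()
        v = series(g, {"*": 0.9})
        with pytest.warns(NonConvergenceWarning):
            s = propagate_circuit(c, v, PropagationConfig(tol=1e-12, max_iter=2))
        assert 0.0 <= s <= 1.0

    def test_fixed_point_satisfies_node_rule(self):
        """The converged signals are a genuine fixed point of the node rule."""
        g, c = self._cyclic()
        v = series(g, {"*": 0.8})
        s_e = propagate_circuit(c, v, PropagationConfig(tol=1e-12))
        # solve the 2-cycle analytically: S_B = v_B·(1−(1−S_R)(1−S_M)), S_M = v_M·S_B
        v_r, v_b, v_m, v_e = 0.8, 0.8, 0.8, 0.8
        s_b = 0.0
        for _ in range(10000):
            s_m = v_m * s_b
            s_b = v_b * (1 - (1 - v_r) * (1 - s_m))
        assert s_e == pytest.approx(v_e * s_b, abs=1e-9)


class TestPropagateAll:
    def test_shape_and_order(self, rng):
        g = build_graph([("A", "B"), ("B", "C"), ("B", "D")])
        circuits = extract_circuits(g)
        nv = pd.DataFrame(rng.random((4, 3)), index=list("ABCD"), columns=["s1", "s2", "s3"])
        act = propagate_all(circuits, nv)
        assert act.shape == (2, 3)
        assert list(act.index) == [c.circuit_id for c in circuits]

    def test_zero_values_give_zero_activity(self):
        g = build_graph([("A", "B"), ("B", "C")])
        nv = pd.DataFrame(np.zeros((3, 2)), index=list("ABC"), columns=["x", "y"])
        act = propagate_all(extract_circuits(g), nv)
        assert (act.to_numpy() == 0).all()

    def test_duplicate_sample_columns_give_duplicate_activities(self, rng):
        g = build_graph([("A", "B"), ("B", "C")])
        col = rng.random(3)
        nv = pd.DataFrame({"x": col, "y": col}, index=list("ABC"))
        act = propagate_all(extract_circuits(g), nv)
        np.testing.assert_array_equal(act["x"].to_numpy(), act["y"].to_numpy())
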