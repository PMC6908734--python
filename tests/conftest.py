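"""Shared test helpers: tiny graph builders and independent oracles."""

from __future__ import annotations

import numpy as np
import pytest

from pathsig.pathways import ACTIVATION, NodeSpec, PathwayGraph, validate_pathway


def build_graph(
    edges: list[tuple[str, str, str] | tuple[str, str]],
    pathway_id: str = "P",
    genes: dict[str, list[str]] | None = None,
    extra_nodes: list[str] = (),
) -> PathwayGraph:
    """Build a validated PathwayGraph from shorthand edges.

    Two-tuples default to activation.  Each node gets a single gene
    ``g_<node>`` unless overridden via ``genes``.
    """
    full = [(e[0], e[1], e[2] if len(e) == 3 else ACTIVATION) for e in edges]
    node_ids = sorted({n for e in full for n in e[:2]} | set(extra_nodes))
    nodes = {
        n: NodeSpec(node_id=n, genes=tuple((genes or {}).get(n, [f"g_{n}"])))
        for n in node_ids
    }
    graph, _ = validate_pathway(pathway_id, nodes, full)
    return graph


def oracle_propagate(circuit, values: dict[str, float]) -> float:
    """Independent straight-line evaluation of the propagation rule.

    Memoized recursion over the circuit DAG: S(n) = v_n for receptors, else
    v_n · (1 − ∏(1−S_a)) · ∏(1−S_i).  Only valid for acyclic circuits.
    """
    in_edges: dict[str, list[tuple[str, str]]] = {n: [] for n in circuit.member_nodes}
    for src, dst, sign in circuit.member_edges:
        in_edges[dst].append((src, sign))
    memo: dict[str, float] = {}

    def s(node: str) -> float:
        if node in memo:
            return memo[node]
        incoming = in_edges[node]
        if not incoming:
            memo[node] = values[node]
            return memo[node]
        act = 1.0
        inh = 1.0
        for src, sign in incoming:
            if sign == ACTIVATION:
                act *= 1.0 - s(src)
            else:
                inh *= 1.0 - s(src)
        memo[node] = values[node] * (1.0 - act) * inh
        return memo[node]

    return s(circuit.effector)


def pick_cutting_gene(graph) -> tuple[str, set[str], set[str]]:
    """Ground-truth target choice for recovery fixtures.

    Returns ``(gene, cut_ids, containing_ids)`` for the first gene (sorted)
    whose every containing circuit it also cuts; the effector genes guarantee
    one always exists (an effector belongs only to its own circuit).
    """
    from pathsig.pathways import extract_circuits, gene_cuts_circuit

    circuits = extract_circuits(graph)
    for gene in sorted(graph.gene_universe()):
        containing = {
            c.circuit_id
            for c in circuits
            if any(gene in graph.nodes[n].genes for n in c.member_nodes)
        }
        cut = {c.circuit_id for c in circuits if gene_cuts_circuit(graph, c, gene)}
        if containing and cut == containing:
            return gene, cut, containing
    raise AssertionError("unreachable: effector genes always qualify")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
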