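"""Signed pathway topologies and receptor→effector circuit extraction.

A signaling pathway is modeled as a directed graph whose nodes house one or
more genes and whose edges carry a sign (``activation`` or ``inhibition``).
Signal enters at *receptors* (nodes with no incoming edges), flows along the
edges, and is read out at *effectors* (nodes with no outgoing edges).  The
unit of quantification is the *circuit*: the subgraph of all directed paths
from any receptor to one effector.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx

from .errors import EmptyRoleError, MalformedPathwayError

logger = logging.getLogger(__name__)

ACTIVATION = "activation"
INHIBITION = "inhibition"
_SIGNS = (ACTIVATION, INHIBITION)


@dataclass(frozen=True)
class NodeSpec:
    """A pathway node: an identifier plus the genes whose expression proxies it.

    Duplicate gene IDs are collapsed; an empty gene list is rejected.
    """

    node_id: str
    genes: tuple[str, ...]
    label: str | None = None

    def __post_init__(self) -> None:
        if not self.node_id:
            raise ValueError("node_id must be a non-empty string")
        if not self.genes:
            raise ValueError(f"node {self.node_id!r} declares no genes")
        deduped = tuple(dict.fromkeys(self.genes))
        object.__setattr__(self, "genes", deduped)

    @property
    def display(self) -> str:
        return self.label if self.label else self.node_id


@dataclass
class PathwayGraph:
    """A validated signed digraph for one pathway.

    ``edges`` holds ``(source, target, sign)`` triples with
    ``sign in {"activation", "inhibition"}``.  Construct via
    :func:`validate_pathway` (or the ``.sif``/``.att`` loader in
    :mod:`pathsig.io`) so the invariants hold.
    """

    pathway_id: str
    nodes: dict[str, NodeSpec] = field(default_factory=dict)
    edges: list[tuple[str, str, str]] = field(default_factory=list)

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph(pathway_id=self.pathway_id)
        for node_id, spec in self.nodes.items():
            g.add_node(node_id, genes=spec.genes, label=spec.display)
        for src, dst, sign in self.edges:
            g.add_edge(src, dst, sign=sign)
        return g

    def gene_universe(self) -> set[str]:
        return {g for spec in self.nodes.values() for g in spec.genes}


@dataclass(frozen=True)
class Circuit:
    """All directed receptor→effector paths ending at one effector.

    ``member_edges`` excludes out-edges of the effector and in-edges of the
    receptors, so within the circuit the effector is a pure sink and every
    receptor a pure source.
    """

    circuit_id: str
    pathway_id: str
    effector: str
    receptors: frozenset[str]
    member_nodes: frozenset[str]
    member_edges: tuple[tuple[str, str, str], ...]

    def subgraph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.member_nodes)
        for src, dst, sign in self.member_edges:
            g.add_edge(src, dst, sign=sign)
        return g


def validate_pathway(
    pathway_id: str,
    nodes: dict[str, NodeSpec],
    edges: list[tuple[str, str, str]],
) -> tuple[PathwayGraph, list[str]]:
    """Validate raw parsed content and return a clean graph plus diagnostics.

    Self-loops are removed, duplicate edges collapsed (first sign wins, sign
    conflicts are reported), isolated nodes reported as warnings.  An edge
    referencing an undeclared node raises :class:`MalformedPathwayError`.
    """
    diagnostics: list[str] = []
    seen: dict[tuple[str, str], str] = {}
    clean: list[tuple[str, str, str]] = []
    for src, dst, sign in edges:
        if sign not in _SIGNS:
            raise MalformedPathwayError(
                f"{pathway_id}: edge {src}->{dst} has unknown relation {sign!r}"
            )
        if src not in nodes or dst not in nodes:
            missing = src if src not in nodes else dst
            raise MalformedPathwayError(
                f"{pathway_id}: edge {src}->{dst} references undeclared node {missing!r}"
            )
        if src == dst:
            diagnostics.append(f"self-loop on {src} removed")
            continue
        key = (src, dst)
        if key in seen:
            if seen[key] != sign:
                diagnostics.append(
                    f"duplicate edge {src}->{dst} with conflicting sign; kept {seen[key]}"
                )
            else:
                diagnostics.append(f"duplicate edge {src}->{dst} collapsed")
            continue
        seen[key] = sign
        clean.append((src, dst, sign))

    touched = {n for e in clean for n in e[:2]}
    for node_id in nodes:
        if node_id not in touched:
            diagnostics.append(f"isolated node {node_id}")

    for msg in diagnostics:
        logger.warning("%s: %s", pathway_id, msg)
    return PathwayGraph(pathway_id=pathway_id, nodes=dict(nodes), edges=clean), diagnostics


def identify_roles(graph: PathwayGraph) -> tuple[set[str], set[str]]:
    """Return (receptors, effectors): nodes of in-degree 0 and out-degree 0.

    Raises :class:`EmptyRoleError` when either set is empty (e.g. a pure
    cycle), since no circuit can then be defined.
    """
    g = graph.to_networkx()
    receptors = {n for n, d in g.in_degree() if d == 0}
    effectors = {n for n, d in g.out_degree() if d == 0}
    if not receptors or not effectors:
        raise EmptyRoleError(
            f"{graph.pathway_id}: receptors={sorted(receptors)} effectors={sorted(effectors)}; "
            "both must be non-empty"
        )
    return receptors, effectors


def extract_circuits(graph: PathwayGraph) -> list[Circuit]:
    """Extract one circuit per effector, ordered by effector node ID.

    A node is a member when it is reachable from some receptor and reaches the
    effector (reachability through cycles included, so feedback loops sitting
    on a receptor→effector walk are retained).  Effectors no receptor can
    reach yield no circuit and are logged.
    """
    receptors, effectors = identify_roles(graph)
    g = graph.to_networkx()

    reachable_from_receptor: set[str] = set(receptors)
    for r in receptors:
        reachable_from_receptor |= nx.descendants(g, r)

    # Disambiguate duplicate effector labels by appending the node id.
    labels = [g.nodes[e]["label"] for e in effectors]
    dup = {lbl for lbl in labels if labels.count(lbl) > 1}

    circuits: list[Circuit] = []
    for eff in sorted(effectors):
        upstream = nx.ancestors(g, eff) | {eff}
        members = upstream & reachable_from_receptor
        circuit_receptors = members & receptors
        if not circuit_receptors:
            logger.warning(
                "%s: effector %s unreachable from any receptor; circuit dropped",
                graph.pathway_id,
                eff,
            )
            continue
        member_edges = tuple(
            (src, dst, sign)
            for src, dst, sign in graph.edges
            if src in members and dst in members and src != eff and dst not in circuit_receptors
        )
        lbl = g.nodes[eff]["label"]
        name = f"{lbl}({eff})" if lbl in dup else lbl
        circuits.append(
            Circuit(
                circuit_id=f"{graph.pathway_id}:{name}",
                pathway_id=graph.pathway_id,
                effector=eff,
                receptors=frozenset(circuit_receptors),
                member_nodes=frozenset(members),
                member_edges=member_edges,
            )
        )
    return circuits


def gene_cuts_circuit(graph: PathwayGraph, circuit: Circuit, gene: str) -> bool:
    """True when removing every member node housing ``gene`` severs all
    receptor→effector paths of the circuit (a total LoF annihilates it)."""
    hit = {n for n in circuit.member_nodes if gene in graph.nodes[n].genes}
    if not hit:
        return False
    if circuit.effector in hit:
        return True
    g = circuit.subgraph()
    g.remove_nodes_from(hit)
    live_receptors = circuit.receptors - hit
    return not any(
        nx.has_path(g, r, circuit.effector) for r in live_receptors if r in g
    )


def circuit_gene_sets(circuits: list[Circuit], graphs: dict[str, PathwayGraph]) -> dict[str, set[str]]:
    """Map circuit_id → set of member genes (union over member nodes)."""
    out: dict[str, set[str]] = {}
    for c in circuits:
        nodes = graphs[c.pathway_id].nodes
        out[c.circuit_id] = {g for n in c.member_nodes for g in nodes[n].genes}
    return out
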