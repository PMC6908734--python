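"""Signal propagation over circuits.

The signal intensity at a node n is

    S_n = v_n · (1 − ∏_{a∈A} (1 − s_a)) · ∏_{i∈I} (1 − s_i)

where v_n ∈ [0,1] is the node's expression proxy, A the signals arriving on
activation edges and I those arriving on inhibition edges.  Receptors (no
incoming edges) receive a constant incoming signal of 1, so S_receptor =
v_receptor.  A circuit's activity is the signal reaching its effector.

Acyclic circuits are evaluated exactly in one topological pass.  Circuits
with feedback loops are solved by Jacobi fixed-point iteration started from
zero signals; for activation-only circuits the iteration is monotone
non-decreasing and bounded by 1, hence convergent.
"""

from __future__ import annotations

import warnings
from collections.abc import Sequence
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .errors import DomainError, NonConvergenceWarning
from .pathways import ACTIVATION, Circuit

__all__ = ["PropagationConfig", "node_signal", "propagate_circuit", "propagate_all"]


@dataclass(frozen=True)
class PropagationConfig:
    """Fixed-point solver settings for cyclic circuits.

    tol: convergence threshold on the max per-node signal change.
    max_iter: iteration cap; hitting it emits :class:`NonConvergenceWarning`.
    """

    tol: float = 1e-6
    max_iter: int = 1000

    def __post_init__(self) -> None:
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


def node_signal(
    v_n: float,
    activations: Sequence[float] = (),
    inhibitions: Sequence[float] = (),
) -> float:
    """Evaluate the propagation rule at one node.

    With no activation inputs the node is treated as a receptor whose
    incoming signal is the constant 1, so the activation term is 1.
    """
    act = np.asarray(activations, dtype=float)
    inh = np.asarray(inhibitions, dtype=float)
    vals = np.concatenate(([v_n], act, inh))
    if ((vals < 0) | (vals > 1)).any() or not np.isfinite(vals).all():
        raise DomainError("node_signal inputs must lie in [0, 1]")
    act_term = 1.0 - np.prod(1.0 - act) if act.size else 1.0
    inh_term = np.prod(1.0 - inh) if inh.size else 1.0
    return float(v_n * act_term * inh_term)


def _signals_vectorized(
    circuit: Circuit,
    values: np.ndarray,
    node_order: list[str],
    config: PropagationConfig,
) -> tuple[dict[str, np.ndarray], bool]:
    """Signals for every member node, vectorized over samples.

    ``values`` is nodes × samples aligned to ``node_order``.  Returns the
    signal map and a convergence flag (False only when a cyclic circuit hit
    max_iter).
    """
    g = circuit.subgraph()
    idx = {n: i for i, n in enumerate(node_order)}
    v = {n: values[idx[n], :] for n in circuit.member_nodes}
    n_samples = values.shape[1]

    in_edges: dict[str, list[tuple[str, str]]] = {n: [] for n in circuit.member_nodes}
    for src, dst, sign in circuit.member_edges:
        in_edges[dst].append((src, sign))

    def evaluate(node: str, signals: dict[str, np.ndarray]) -> np.ndarray:
        incoming = in_edges[node]
        if not incoming:  # receptor: incoming signal is the constant 1
            return v[node] * np.ones(n_samples)
        acts = [signals[src] for src, sign in incoming if sign == ACTIVATION]
        inhs = [signals[src] for src, sign in incoming if sign != ACTIVATION]
        # empty product over an empty activation set is 1, so a node fed only
        # by inhibition edges transmits nothing
        act_term = 1.0 - np.prod([1.0 - a for a in acts], axis=0) if acts else 0.0
        inh_term = np.prod([1.0 - i for i in inhs], axis=0) if inhs else 1.0
        return v[node] * act_term * inh_term

    if nx.is_directed_acyclic_graph(g):
        signals: dict[str, np.ndarray] = {}
        for node in nx.topological_sort(g):
            signals[node] = evaluate(node, signals)
        return signals, True

    # Feedback present: Jacobi iteration from zero signals (receptors start at v).
    signals = {
        n: (v[n].copy() if n in circuit.receptors else np.zeros(n_samples))
        for n in circuit.member_nodes
    }
    for _ in range(config.max_iter):
        new = {n: evaluate(n, signals) for n in circuit.member_nodes}
        delta = max(np.max(np.abs(new[n] - signals[n])) for n in circuit.member_nodes)
        signals = new
        if delta < config.tol:
            return signals, True
    warnings.warn(
        f"circuit {circuit.circuit_id}: fixed-point iteration did not reach "
        f"tol={config.tol} within {config.max_iter} iterations",
        NonConvergenceWarning,
        stacklevel=2,
    )
    return signals, False


def propagate_circuit(
    circuit: Circuit,
    node_values: pd.Series | pd.DataFrame,
    config: PropagationConfig | None = None,
) -> float | np.ndarray:
    """Signal reaching the circuit's effector for one sample (Series) or all
    samples at once (DataFrame, nodes × samples)."""
    config = config or PropagationConfig()
    single = isinstance(node_values, pd.Series)
    frame = node_values.to_frame() if single else node_values
    missing = [n for n in circuit.member_nodes if n not in frame.index]
    if missing:
        raise KeyError(f"circuit {circuit.circuit_id}: node values missing for {sorted(missing)}")
    order = sorted(circuit.member_nodes)
    values = frame.loc[order].to_numpy(dtype=float)
    if ((values < 0) | (values > 1)).any():
        raise DomainError("node values must lie in [0, 1]")
    signals, _ = _signals_vectorized(circuit, values, order, config)
    out = signals[circuit.effector]
    return float(out[0]) if single else out


def propagate_all(
    circuits: Sequence[Circuit],
    node_values: pd.DataFrame,
    config: PropagationConfig | None = None,
) -> pd.DataFrame:
    """Circuit-activity matrix (circuits × samples) for every circuit.

    ``node_values`` may pool the nodes of several pathways; each circuit only
    reads its own member rows.  Row order follows the input circuit order.
    """
    if not circuits:
        raise ValueError("no circuits supplied")
    config = config or PropagationConfig()
    rows = {c.circuit_id: propagate_circuit(c, node_values, config) for c in circuits}
    return pd.DataFrame.from_dict(rows, orient="index", columns=node_values.columns)
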