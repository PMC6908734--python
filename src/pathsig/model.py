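"""End-to-end estimator: gene expression in, circuit activity out.

:class:`PathwayActivityModel` chains the frozen-reference preprocessing with
circuit extraction and signal propagation.  ``fit`` learns the normalization
reference from a (control) expression matrix and extracts the circuits of the
supplied pathways; ``transform`` maps any matrix over the same genes — the
fitted one, new samples, or an in-silico perturbed copy — to a circuits ×
samples activity matrix on the frozen scale.
"""

from __future__ import annotations

from collections.abc import Sequence

import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .pathways import Circuit, PathwayGraph, circuit_gene_sets, extract_circuits
from .preprocessing import ExpressionPreprocessor, compute_node_values
from .propagation import PropagationConfig, propagate_all


class PathwayActivityModel(BaseEstimator, TransformerMixin):
    """Transform expression matrices into signaling-circuit activities.

    Parameters
    ----------
    pathways : sequence of PathwayGraph
        Validated pathway topologies; circuits are extracted at ``fit``.
    preprocess : bool
        When False the input is taken as already [0,1]-scaled gene values and
        only node aggregation + propagation run.
    q_low, q_high, rescale_mode, log_transform
        Passed to :class:`ExpressionPreprocessor`.
    aggregator, missing_default
        Gene→node aggregation rule and the value for unmeasured nodes.
    tol, max_iter
        Fixed-point settings for cyclic circuits.

    Attributes
    ----------
    preprocessor_ : fitted ExpressionPreprocessor (when ``preprocess``).
    circuits_ : list of Circuit, deterministic order (pathway, then effector).
    circuit_genes_ : dict circuit_id → member gene set.
    """

    def __init__(
        self,
        pathways: Sequence[PathwayGraph],
        preprocess: bool = True,
        q_low: float = 0.01,
        q_high: float = 0.99,
        rescale_mode: str = "global",
        log_transform: bool = True,
        aggregator: str = "percentile90",
        missing_default: float = 0.5,
        tol: float = 1e-6,
        max_iter: int = 1000,
    ):
        self.pathways = pathways
        self.preprocess = preprocess
        self.q_low = q_low
        self.q_high = q_high
        self.rescale_mode = rescale_mode
        self.log_transform = log_transform
        self.aggregator = aggregator
        self.missing_default = missing_default
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X: pd.DataFrame, y=None) -> "PathwayActivityModel":
        if not self.pathways:
            raise ValueError("at least one pathway is required")
        graphs = {g.pathway_id: g for g in self.pathways}
        if len(graphs) != len(self.pathways):
            raise ValueError("duplicate pathway_id among supplied pathways")
        circuits: list[Circuit] = []
        for pid in sorted(graphs):
            circuits.extend(extract_circuits(graphs[pid]))
        if not circuits:
            raise ValueError("no receptor→effector circuit could be extracted")
        self.graphs_ = graphs
        self.circuits_ = circuits
        self.circuit_genes_ = circuit_gene_sets(circuits, graphs)
        if self.preprocess:
            self.preprocessor_ = ExpressionPreprocessor(
                q_low=self.q_low,
                q_high=self.q_high,
                rescale_mode=self.rescale_mode,
                log_transform=self.log_transform,
            ).fit(X)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "circuits_"):
            raise RuntimeError("PathwayActivityModel is not fitted")
        scaled = self.preprocessor_.transform(X) if self.preprocess else X
        config = PropagationConfig(tol=self.tol, max_iter=self.max_iter)
        frames = []
        # node IDs are namespaced per pathway, so propagate pathway by pathway
        for pid in sorted(self.graphs_):
            graph = self.graphs_[pid]
            circuits = [c for c in self.circuits_ if c.pathway_id == pid]
            node_values = compute_node_values(
                scaled, graph, aggregator=self.aggregator, missing_default=self.missing_default
            )
            frames.append(propagate_all(circuits, node_values, config))
        return pd.concat(frames, axis=0)

    def node_values(self, X: pd.DataFrame) -> dict[str, pd.DataFrame]:
        """Per-pathway node-value matrices for a given expression matrix."""
        if not hasattr(self, "circuits_"):
            raise RuntimeError("PathwayActivityModel is not fitted")
        scaled = self.preprocessor_.transform(X) if self.preprocess else X
        return {
            pid: compute_node_values(
                scaled, g, aggregator=self.aggregator, missing_default=self.missing_default
            )
            for pid, g in sorted(self.graphs_.items())
        }
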