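"""Seeded synthetic fixtures: pathways, expression matrices, tissue panels.

Everything downstream (preprocessing, propagation, contrasts) is testable
offline with these generators.  They emulate the *shape* of real inputs —
signed pathway DAGs with optional feedback, log-normal expression with
multiplicative noise, per-tissue baseline shifts — not real topologies or
transcriptome covariance.  Identical configs produce identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import GenerationError
from .pathways import ACTIVATION, INHIBITION, NodeSpec, PathwayGraph, extract_circuits, validate_pathway

__all__ = [
    "FixtureConfig",
    "make_pathway",
    "make_expression",
    "make_tissue_panel",
    "two_group_design",
]

_MAX_RETRIES = 50


@dataclass(frozen=True)
class FixtureConfig:
    """Knobs of the synthetic generators.

    effect, when set, is an injected LoF: group B columns of the expression
    matrix are copies of group A with the target gene's rows multiplied by
    ``effect_factor``.
    """

    seed: int = 0
    n_nodes: int = 12
    n_genes_per_node: int = 2
    n_samples: int = 20
    edge_density: float = 0.35
    inhibition_fraction: float = 0.2
    cycle: bool = False
    effect_gene: str | None = None
    effect_factor: float = 0.01
    n_tissues: int = 3
    tissue_offset_sd: float = 0.5
    baseline_log_mean: float = 4.0
    baseline_log_sd: float = 1.0
    noise_log_sd: float = 0.4

    def __post_init__(self) -> None:
        if not 0 < self.edge_density <= 1:
            raise ValueError("edge_density must lie in (0, 1]")
        if not 0 <= self.inhibition_fraction <= 1:
            raise ValueError("inhibition_fraction must lie in [0, 1]")
        for name in ("n_nodes", "n_genes_per_node", "n_samples"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")


def _random_dag(rng: np.random.Generator, config: FixtureConfig) -> tuple[list[str], list[tuple[str, str, str]]]:
    n = config.n_nodes
    names = [f"N{i + 1:02d}" for i in range(n)]
    pairs: list[tuple[int, int]] = []
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < config.edge_density:
                pairs.append((i, j))
    # attach stranded nodes so the graph has no isolates
    touched = {x for p in pairs for x in p}
    for i in range(n):
        if i not in touched:
            if i == 0:
                pairs.append((0, int(rng.integers(1, n))))
            else:
                pairs.append((int(rng.integers(0, i)), i))
            touched.add(i)
    # signs: each target keeps >= 1 activating input (a node fed only by
    # inhibitors would transmit nothing and its circuits would be dead)
    edges: list[tuple[str, str, str]] = []
    by_target: dict[int, list[int]] = {}
    for i, j in sorted(pairs):
        by_target.setdefault(j, []).append(i)
    for j, sources in by_target.items():
        for k, i in enumerate(sources):
            if k == 0:
                sign = ACTIVATION
            else:
                sign = INHIBITION if rng.random() < config.inhibition_fraction else ACTIVATION
            edges.append((names[i], names[j], sign))
    return names, edges


def make_pathway(config: FixtureConfig, pathway_id: str = "P1", gene_offset: int = 0) -> PathwayGraph:
    """Random signed DAG (plus one feedback edge when ``cycle``) with at
    least one receptor→effector circuit; genes G0001… assigned per node.
    ``gene_offset`` shifts the gene numbering so several pathways can carry
    disjoint gene universes."""
    rng = np.random.default_rng(config.seed)
    for _ in range(_MAX_RETRIES):
        names, edges = _random_dag(rng, config)
        if config.cycle:
            in_deg = {n: 0 for n in names}
            for _, dst, _ in edges:
                in_deg[dst] += 1
            # close a loop back into a non-receptor node to keep roles intact
            candidates = [(src, dst) for src, dst, _ in edges if in_deg[src] >= 1]
            if not candidates:
                continue
            src, dst = candidates[int(rng.integers(len(candidates)))]
            edges.append((dst, src, ACTIVATION))
        gene_counter = gene_offset
        nodes = {}
        for name in names:
            genes = tuple(
                f"G{gene_counter + k + 1:04d}" for k in range(config.n_genes_per_node)
            )
            gene_counter += config.n_genes_per_node
            nodes[name] = NodeSpec(node_id=name, genes=genes, label=name)
        graph, _ = validate_pathway(pathway_id, nodes, edges)
        try:
            if extract_circuits(graph):
                return graph
        except Exception:
            continue
    raise GenerationError(
        f"could not generate a pathway with a receptor→effector circuit in {_MAX_RETRIES} tries"
    )


def _gene_baseline(config: FixtureConfig, genes: list[str]) -> np.ndarray:
    rng = np.random.default_rng(config.seed + 1)
    return rng.lognormal(config.baseline_log_mean, config.baseline_log_sd, size=len(genes))


def make_expression(
    config: FixtureConfig,
    graph: PathwayGraph,
    baseline: np.ndarray | None = None,
    noise_seed: int | None = None,
) -> pd.DataFrame:
    """Log-normal expression for the graph's genes.

    Without an effect: samples S01…  With ``effect_gene`` set: columns
    A01…A<n>, B01…B<n>, where B is a copy of A with the LoF factor applied to
    the target gene — the deterministic two-group recovery fixture.
    ``baseline``/``noise_seed`` let the tissue panel share per-gene baselines
    while drawing tissue-specific noise.
    """
    genes = sorted(graph.gene_universe())
    if baseline is None:
        baseline = _gene_baseline(config, genes)
    rng = np.random.default_rng(config.seed + 3 if noise_seed is None else noise_seed)
    n = config.n_samples
    values = baseline[:, None] * rng.lognormal(0.0, config.noise_log_sd, size=(len(genes), n))
    if config.effect_gene is None:
        return pd.DataFrame(values, index=genes, columns=[f"S{i + 1:02d}" for i in range(n)])
    if config.effect_gene not in genes:
        raise GenerationError(f"effect gene {config.effect_gene!r} not in pathway gene universe")
    a = pd.DataFrame(values, index=genes, columns=[f"A{i + 1:02d}" for i in range(n)])
    b = a.copy()
    b.columns = [f"B{i + 1:02d}" for i in range(n)]
    b.loc[config.effect_gene] *= config.effect_factor
    return pd.concat([a, b], axis=1)


def two_group_design(matrix: pd.DataFrame, case_prefix: str = "B") -> pd.Series:
    """Design labeling columns by prefix: ``case_prefix`` → case, rest → control."""
    return pd.Series(
        {c: ("case" if str(c).startswith(case_prefix) else "control") for c in matrix.columns}
    )


def make_tissue_panel(config: FixtureConfig, graph: PathwayGraph) -> dict[str, pd.DataFrame]:
    """Control matrices for ``n_tissues`` tissues over a shared gene universe.

    Each tissue draws fresh noise and applies a tissue-specific log-scale
    baseline shift of standard deviation ``tissue_offset_sd`` (0 makes the
    tissues statistically exchangeable)."""
    panel: dict[str, pd.DataFrame] = {}
    offset_rng = np.random.default_rng(config.seed + 2)
    genes = sorted(graph.gene_universe())
    baseline = _gene_baseline(config, genes)
    for t in range(config.n_tissues):
        offset = float(offset_rng.normal(0.0, config.tissue_offset_sd)) if config.tissue_offset_sd else 0.0
        sub = replace(config, effect_gene=None)
        matrix = make_expression(
            sub, graph, baseline=baseline * np.exp(offset), noise_seed=config.seed + 100 + t
        )
        matrix.columns = [f"T{t + 1}_{c}" for c in matrix.columns]
        panel[f"tissue{t + 1:02d}"] = matrix
    return panel
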