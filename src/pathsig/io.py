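"""Readers and writers for the on-disk dialects.

Pathways travel as two tab-separated files: ``<id>.sif`` with
``source<TAB>relation<TAB>target`` (relation ``activation``/``inhibition``,
no header) and ``<id>.att`` with ``node_id<TAB>label<TAB>genes`` (one header
line, genes comma-separated).  Expression matrices are CSV or TSV with gene
IDs in the first column and sample IDs in the header.  Lines starting with
``#`` are metadata comments and are skipped everywhere.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from .errors import MalformedPathwayError
from .pathways import Circuit, NodeSpec, PathwayGraph, validate_pathway

logger = logging.getLogger(__name__)


def _data_lines(path: Path) -> list[str]:
    lines = path.read_text(encoding="utf-8").splitlines()
    return [ln for ln in lines if ln.strip() and not ln.startswith("#")]


# --------------------------------------------------------------------------
# pathways


def read_pathway(sif_path: str | Path, att_path: str | Path) -> PathwayGraph:
    """Parse and validate one pathway from its .sif/.att pair."""
    sif_path, att_path = Path(sif_path), Path(att_path)
    pathway_id = sif_path.stem

    nodes: dict[str, NodeSpec] = {}
    att_lines = _data_lines(att_path)
    if not att_lines:
        raise MalformedPathwayError(f"{att_path}: empty attribute file")
    for ln in att_lines[1:]:  # first data line is the header
        parts = ln.split("\t")
        if len(parts) != 3:
            raise MalformedPathwayError(f"{att_path}: expected 3 tab-separated fields: {ln!r}")
        node_id, label, genes = parts
        if node_id in nodes:
            raise MalformedPathwayError(f"{att_path}: duplicate node {node_id!r}")
        gene_list = tuple(g.strip() for g in genes.split(",") if g.strip())
        if not gene_list:
            raise MalformedPathwayError(f"{att_path}: node {node_id!r} has no genes")
        nodes[node_id] = NodeSpec(node_id=node_id, genes=gene_list, label=label or None)

    edges = []
    for ln in _data_lines(sif_path):
        parts = ln.split("\t")
        if len(parts) != 3:
            raise MalformedPathwayError(f"{sif_path}: expected 3 tab-separated fields: {ln!r}")
        src, relation, dst = parts
        edges.append((src, dst, relation))

    graph, _ = validate_pathway(pathway_id, nodes, edges)
    return graph


def read_pathway_dir(directory: str | Path) -> list[PathwayGraph]:
    """Load every ``*.sif`` with its matching ``*.att`` from a directory."""
    directory = Path(directory)
    graphs = []
    for sif in sorted(directory.glob("*.sif")):
        att = sif.with_suffix(".att")
        if not att.exists():
            raise MalformedPathwayError(f"{sif}: missing attribute file {att.name}")
        graphs.append(read_pathway(sif, att))
    if not graphs:
        raise MalformedPathwayError(f"no *.sif pathway files found in {directory}")
    return graphs


def write_pathway(graph: PathwayGraph, directory: str | Path, comment: str | None = None) -> tuple[Path, Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    sif = directory / f"{graph.pathway_id}.sif"
    att = directory / f"{graph.pathway_id}.att"
    header = f"# {comment}\n" if comment else ""
    sif.write_text(
        header + "".join(f"{s}\t{sign}\t{t}\n" for s, t, sign in graph.edges),
        encoding="utf-8",
    )
    att_rows = "".join(
        f"{n.node_id}\t{n.display}\t{','.join(n.genes)}\n" for n in graph.nodes.values()
    )
    att.write_text(header + "node_id\tlabel\tgenes\n" + att_rows, encoding="utf-8")
    return sif, att


def write_circuit_table(circuits: list[Circuit], path: str | Path) -> Path:
    path = Path(path)
    rows = [
        {
            "circuit_id": c.circuit_id,
            "pathway_id": c.pathway_id,
            "effector": c.effector,
            "receptors": ",".join(sorted(c.receptors)),
            "n_nodes": len(c.member_nodes),
            "n_edges": len(c.member_edges),
        }
        for c in circuits
    ]
    pd.DataFrame.from_records(rows).to_csv(path, sep="\t", index=False)
    return path


# --------------------------------------------------------------------------
# matrices, designs, gene lists


def _sniff_sep(path: Path) -> str:
    for ln in path.read_text(encoding="utf-8").splitlines():
        if ln.strip() and not ln.startswith("#"):
            return "\t" if "\t" in ln else ","
    raise ValueError(f"{path}: empty file")


def read_expression(path: str | Path, aggregate_duplicates: str | None = None) -> pd.DataFrame:
    """Load a genes × samples matrix (CSV or TSV, autodetected).

    Duplicate gene rows are rejected unless ``aggregate_duplicates`` is
    ``"max"`` or ``"mean"``.  Negative or non-finite values are rejected.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path), index_col=0, comment="#")
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        if aggregate_duplicates == "max":
            df = df.groupby(level=0, sort=False).max()
        elif aggregate_duplicates == "mean":
            df = df.groupby(level=0, sort=False).mean()
        else:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValueError(f"{path}: duplicate gene rows {dups[:5]}; pass aggregate_duplicates")
    values = df.to_numpy(dtype=float)
    if not pd.notna(values).all():
        raise ValueError(f"{path}: matrix contains missing values")
    if (values < 0).any():
        raise ValueError(f"{path}: matrix contains negative values")
    return df.astype(float)


def write_matrix(df: pd.DataFrame, path: str | Path, comment: str | None = None, digits: int = 10) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        df.to_csv(fh, sep="\t", float_format=f"%.{digits}g")
    return path


def write_result_table(df: pd.DataFrame, path: str | Path, index: bool = True) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", float_format="%.6g", index=index)
    return path


def read_design(path: str | Path) -> pd.Series:
    """TSV ``sample_id<TAB>group`` (no header) → Series sample → group."""
    path = Path(path)
    design = {}
    for ln in _data_lines(path):
        parts = ln.split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}: expected 'sample<TAB>group': {ln!r}")
        design[parts[0]] = parts[1]
    if not design:
        raise ValueError(f"{path}: empty design file")
    return pd.Series(design)


def read_gene_list(path: str | Path) -> list[str]:
    """Plain text, one gene ID per line."""
    genes = [ln.strip() for ln in _data_lines(Path(path))]
    if not genes:
        raise ValueError(f"{path}: empty gene list")
    return genes


def read_tissue_panel(directory: str | Path) -> dict[str, pd.DataFrame]:
    """Directory of expression files; filename stem = tissue label."""
    directory = Path(directory)
    panel = {}
    for f in sorted(directory.iterdir()):
        if f.suffix.lower() in (".csv", ".tsv", ".txt") and f.name != "manifest.tsv":
            panel[f.stem] = read_expression(f)
    if not panel:
        raise ValueError(f"no expression files found in {directory}")
    return panel


def write_run_metadata(path: str | Path, config: dict, warnings_list: list[str] | None = None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {"config": config, "warnings": warnings_list or []}
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=str) + "\n", encoding="utf-8")
    return path
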