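"""In-silico perturbations: loss-of-function and over-expression simulation.

A loss-of-function (LoF) mutation is simulated by multiplying the target
genes' expression by a small factor (default 0.01) in every sample — an
inactive gene product and an absent one are equivalent for signal
transduction.  Setting the value to 0 models total loss of function;
multiplying by a factor > 1 models over-expression (clamped to the fitted
scale ceiling downstream).  The perturbed matrix is renormalized with the
parameters fitted on the ORIGINAL matrix, so untouched genes keep exactly
their original node values and only the targeted signal changes.
"""

from __future__ import annotations

import logging
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import NoTargetResolvedError
from .model import PathwayActivityModel
from .pathways import PathwayGraph
from .stats import wilcoxon_contrast

logger = logging.getLogger(__name__)

#: default LoF expression multiplier
LOF_FACTOR = 0.01
#: pseudo-count guarding the fold-change ratio of near-zero activities
FC_EPSILON = 1e-10


@dataclass(frozen=True)
class PerturbationSpec:
    """What to perturb and how.

    mode "lof_scale": multiply target rows by ``factor`` (0 < factor <= 1).
    mode "set_value": overwrite target rows with ``value``.
    mode "overexpress": multiply target rows by ``factor`` (> 1).
    """

    targets: tuple[str, ...]
    mode: str = "lof_scale"
    factor: float = LOF_FACTOR
    value: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "targets", tuple(self.targets))
        if not self.targets:
            raise ValueError("targets must be non-empty")
        if self.mode == "lof_scale":
            if not 0 < self.factor <= 1:
                raise ValueError("lof_scale factor must lie in (0, 1]")
        elif self.mode == "overexpress":
            if self.factor <= 1:
                raise ValueError("overexpress factor must be > 1")
        elif self.mode == "set_value":
            if self.value < 0:
                raise ValueError("set_value must be nonnegative")
        else:
            raise ValueError(f"unknown perturbation mode {self.mode!r}")


def apply_perturbation(matrix: pd.DataFrame, spec: PerturbationSpec) -> pd.DataFrame:
    """Return a copy of the matrix with target gene rows transformed in all
    samples; every other row is bit-identical.  Unresolved targets are
    logged; if none resolves, :class:`NoTargetResolvedError` is raised."""
    resolved = [g for g in spec.targets if g in matrix.index]
    unresolved = [g for g in spec.targets if g not in matrix.index]
    if unresolved:
        logger.warning("perturbation targets not in matrix: %s", unresolved)
    if not resolved:
        raise NoTargetResolvedError(f"no perturbation target resolved: {list(spec.targets)}")
    out = matrix.copy()
    if spec.mode in ("lof_scale", "overexpress"):
        out.loc[resolved] = out.loc[resolved] * spec.factor
    else:
        out.loc[resolved] = spec.value
    return out


@dataclass
class PerturbationEffect:
    """Result bundle of :func:`perturbation_effect`."""

    table: pd.DataFrame
    activity_original: pd.DataFrame
    activity_perturbed: pd.DataFrame
    resolved_targets: list[str] = field(default_factory=list)


def perturbation_effect(
    matrix: pd.DataFrame,
    spec: PerturbationSpec,
    pathways: Sequence[PathwayGraph] | None = None,
    model: PathwayActivityModel | None = None,
    **model_kwargs,
) -> PerturbationEffect:
    """Contrast circuit activities before and after a perturbation.

    The model (normalization reference included) is fitted on the original
    matrix; the perturbed matrix reuses it frozen.  The table reports, per
    circuit, the mean original and perturbed activity, their log2 fold change
    (with pseudo-count) and whether the circuit contains a target gene.
    """
    if model is None:
        if pathways is None:
            raise ValueError("supply either pathways or a fitted model")
        model = PathwayActivityModel(pathways, **model_kwargs).fit(matrix)
    elif not hasattr(model, "circuits_"):
        model = model.fit(matrix)
    perturbed = apply_perturbation(matrix, spec)
    act_orig = model.transform(matrix)
    act_pert = model.transform(perturbed)
    targets = set(spec.targets)
    mean_orig = act_orig.mean(axis=1)
    mean_pert = act_pert.mean(axis=1)
    table = pd.DataFrame(
        {
            "mean_original": mean_orig,
            "mean_perturbed": mean_pert,
            "log2_fc": np.log2((mean_pert + FC_EPSILON) / (mean_orig + FC_EPSILON)),
            "contains_target": [
                bool(model.circuit_genes_[cid] & targets) for cid in act_orig.index
            ],
        }
    )
    table.index.name = "circuit_id"
    return PerturbationEffect(
        table=table,
        activity_original=act_orig,
        activity_perturbed=act_pert,
        resolved_targets=[g for g in spec.targets if g in matrix.index],
    )


def variant_interpreter(
    panel: Mapping[str, pd.DataFrame],
    gene_list: Sequence[str],
    pathways: Sequence[PathwayGraph],
    lof_factor: float = LOF_FACTOR,
    fdr: float = 0.05,
    **model_kwargs,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Simulate a gene list's LoF across tissue control matrices.

    For each tissue, a case matrix is simulated by applying LoF (×``lof_factor``)
    to every control sample; circuit activities of cases and controls (both on
    the normalization fitted to the controls) are contrasted with the
    rank-sum test and BH adjustment.  A failing tissue is logged and skipped;
    the others are still produced.

    Returns ``(per-tissue result tables, tissue × circuit summary)`` where the
    summary holds the signed significance: −1/+1 when fdr_p < ``fdr`` (down/up),
    0 otherwise.
    """
    spec = PerturbationSpec(targets=tuple(gene_list), mode="lof_scale", factor=lof_factor)
    results: dict[str, pd.DataFrame] = {}
    summary_rows: dict[str, pd.Series] = {}
    for tissue in sorted(panel):
        control = panel[tissue]
        try:
            model = PathwayActivityModel(pathways, **model_kwargs).fit(control)
            case = apply_perturbation(control, spec)
            act_control = model.transform(control)
            act_case = model.transform(case)
            act_case.columns = [f"{s}__case" for s in act_case.columns]
            combined = pd.concat([act_case, act_control], axis=1)
            design = pd.Series(
                {**{s: "case" for s in act_case.columns},
                 **{s: "control" for s in act_control.columns}}
            )
            table = wilcoxon_contrast(combined, design)
            results[tissue] = table
            sig = (table["fdr_p"] < fdr).astype(int)
            sign = table["direction"].map({"up": 1, "down": -1, "none": 0})
            summary_rows[tissue] = sig * sign
        except Exception:
            logger.exception("variant interpreter failed for tissue %r; skipping", tissue)
    summary = pd.DataFrame(summary_rows).T
    summary.index.name = "tissue"
    return results, summary


def lof_scan(
    matrix: pd.DataFrame,
    pathways: Sequence[PathwayGraph],
    lof_factor: float = LOF_FACTOR,
    breadth_threshold: float = 0.5,
    genes: Sequence[str] | None = None,
    **model_kwargs,
) -> tuple[pd.DataFrame, pd.Series]:
    """Systematic single-gene LoF scan over the pathway gene universe.

    Every gene appearing in any circuit (or the explicit ``genes`` list) is
    knocked down in turn and the per-circuit log2 fold change recorded.
    Returns ``(impact, breadth)``: a gene × circuit log2FC matrix and the
    per-gene count of circuits with \\|log2FC\\| above ``breadth_threshold``
    across all loaded pathways — genes of broad impact touch many circuits.
    """
    model = PathwayActivityModel(pathways, **model_kwargs).fit(matrix)
    universe = sorted(set().union(*model.circuit_genes_.values())) if genes is None else list(genes)
    act_orig = model.transform(matrix)
    mean_orig = act_orig.mean(axis=1)
    rows = {}
    for gene in universe:
        if gene not in matrix.index:
            rows[gene] = pd.Series(0.0, index=act_orig.index)
            continue
        spec = PerturbationSpec(targets=(gene,), mode="lof_scale", factor=lof_factor)
        mean_pert = model.transform(apply_perturbation(matrix, spec)).mean(axis=1)
        rows[gene] = np.log2((mean_pert + FC_EPSILON) / (mean_orig + FC_EPSILON))
    impact = pd.DataFrame(rows).T
    impact.index.name = "gene"
    breadth = (impact.abs() > breadth_threshold).sum(axis=1)
    breadth.name = "n_circuits_affected"
    return impact, breadth
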