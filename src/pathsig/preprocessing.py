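"""Expression-matrix preprocessing: probe summarization, log/truncate/quantile
normalization, [0,1] rescaling and gene→node aggregation.

The chain turns an already library-normalized expression matrix (genes ×
samples, nonnegative) into the node-value matrix ``v`` consumed by signal
propagation:

    log(x+1) → truncate at the global 0.01/0.99 quantiles → quantile
    normalization across samples → min-max rescale to [0,1] → aggregate the
    genes of each pathway node (default: 90th percentile).

:class:`ExpressionPreprocessor` is the sklearn-style transformer form of the
chain: ``fit`` learns the truncation bounds, the quantile-normalization
reference distribution and the min-max scale from a reference matrix;
``transform`` applies them frozen.  That freezing is what keeps an in-silico
perturbation from leaking into untouched genes through renormalization.
"""

from __future__ import annotations

import logging
import warnings
from collections.abc import Mapping

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import DegenerateMatrixError, DegenerateScaleWarning, EmptyMappingError
from .pathways import PathwayGraph

logger = logging.getLogger(__name__)

#: Aggregators available for multi-gene nodes (and the probe→gene default).
AGGREGATORS = ("percentile90", "mean", "min", "max")


def _aggregate(values: np.ndarray, how: str) -> np.ndarray:
    """Collapse a genes × samples block to one row. Percentiles interpolate linearly."""
    if how == "percentile90":
        return np.percentile(values, 90, axis=0, method="linear")
    if how == "mean":
        return values.mean(axis=0)
    if how == "min":
        return values.min(axis=0)
    if how == "max":
        return values.max(axis=0)
    raise ValueError(f"unknown aggregator {how!r}; choose from {AGGREGATORS}")


def aggregate_probes(
    probe_matrix: pd.DataFrame,
    probe_to_gene: Mapping[str, list[str]] | pd.DataFrame,
) -> pd.DataFrame:
    """Summarize a probe-level matrix to gene level.

    Per gene the 90th percentile of its uniquely-mapping probes is taken.
    Probes mapping to more than one gene are discarded — unless they are the
    only probes a gene has, in which case the median of those probes is used.

    Parameters
    ----------
    probe_matrix : DataFrame, probes × samples.
    probe_to_gene : mapping probe → list of gene IDs, or a two-column
        DataFrame ``(probe_id, gene_id)`` with one row per mapping.
    """
    if isinstance(probe_to_gene, pd.DataFrame):
        mapping: dict[str, list[str]] = {}
        for probe, gene in probe_to_gene.itertuples(index=False):
            mapping.setdefault(str(probe), []).append(str(gene))
    else:
        mapping = {p: list(gs) for p, gs in probe_to_gene.items()}

    unique_probes: dict[str, list[str]] = {}
    all_probes: dict[str, list[str]] = {}
    for probe, genes in mapping.items():
        if probe not in probe_matrix.index:
            continue
        genes = list(dict.fromkeys(genes))
        for gene in genes:
            all_probes.setdefault(gene, []).append(probe)
            if len(genes) == 1:
                unique_probes.setdefault(gene, []).append(probe)

    if not all_probes:
        raise EmptyMappingError("no probe in the matrix maps to any gene")

    rows = {}
    for gene in sorted(all_probes):
        if gene in unique_probes:
            block = probe_matrix.loc[unique_probes[gene]].to_numpy(dtype=float)
            rows[gene] = np.percentile(block, 90, axis=0, method="linear")
        else:  # only multi-mapping probes: fall back to their median
            block = probe_matrix.loc[all_probes[gene]].to_numpy(dtype=float)
            rows[gene] = np.median(block, axis=0)
    return pd.DataFrame.from_dict(rows, orient="index", columns=probe_matrix.columns)


def _check_constant_columns(arr: np.ndarray, context: str) -> bool:
    """Return True if ALL columns are constant; raise if only some are."""
    col_const = np.all(arr == arr[0:1, :], axis=0)
    if col_const.all():
        warnings.warn(
            f"{context}: every column is constant; quantile normalization is the identity",
            DegenerateScaleWarning,
            stacklevel=3,
        )
        return True
    if col_const.any():
        bad = int(col_const.sum())
        raise DegenerateMatrixError(
            f"{context}: {bad} constant column(s) among varying ones; "
            "quantile normalization is undefined for them"
        )
    return False


def _quantile_normalize_to_ref(arr: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Map each column onto the reference order statistics ``ref`` (sorted,
    length = n rows).  Ties receive the mean of their rank positions via
    average ranks and linear interpolation between reference values."""
    n = arr.shape[0]
    positions = np.arange(1, n + 1, dtype=float)
    out = np.empty_like(arr, dtype=float)
    for j in range(arr.shape[1]):
        ranks = rankdata(arr[:, j], method="average")
        out[:, j] = np.interp(ranks, positions, ref)
    return out


def log_truncate_quantile_normalize(
    matrix: pd.DataFrame,
    q_high: float = 0.99,
    q_low: float = 0.01,
) -> pd.DataFrame:
    """Apply log(x+1), clamp at the global [q_low, q_high] quantiles of the
    transformed matrix, then quantile-normalize columns against the mean
    order-statistic reference of this same matrix."""
    arr = np.log1p(matrix.to_numpy(dtype=float))
    lo, hi = np.quantile(arr, [q_low, q_high])
    arr = np.clip(arr, lo, hi)
    if _check_constant_columns(arr, "quantile normalization"):
        return pd.DataFrame(arr, index=matrix.index, columns=matrix.columns)
    ref = np.sort(arr, axis=0).mean(axis=1)
    out = _quantile_normalize_to_ref(arr, ref)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def rescale_unit_interval(matrix: pd.DataFrame, mode: str = "global") -> pd.DataFrame:
    """Affine rescale to [0,1].

    ``global`` (default) uses a single min/max over the whole matrix, keeping
    values comparable across genes; ``per_gene`` rescales each row on its own.
    Constant input maps to 0.5 with a warning.
    """
    arr = matrix.to_numpy(dtype=float)
    if mode == "global":
        lo, hi = arr.min(), arr.max()
        if hi == lo:
            warnings.warn("constant matrix: rescaled to 0.5", DegenerateScaleWarning, stacklevel=2)
            out = np.full_like(arr, 0.5)
        else:
            out = (arr - lo) / (hi - lo)
    elif mode == "per_gene":
        lo = arr.min(axis=1, keepdims=True)
        hi = arr.max(axis=1, keepdims=True)
        span = hi - lo
        const = (span == 0).ravel()
        if const.any():
            warnings.warn(
                f"{int(const.sum())} constant gene row(s) rescaled to 0.5",
                DegenerateScaleWarning,
                stacklevel=2,
            )
        span[span == 0] = 1.0
        out = (arr - lo) / span
        out[const, :] = 0.5
    else:
        raise ValueError(f"unknown rescale mode {mode!r}")
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def compute_node_values(
    matrix: pd.DataFrame,
    graph: PathwayGraph,
    aggregator: str = "percentile90",
    missing_default: float = 0.5,
) -> pd.DataFrame:
    """Aggregate [0,1]-scaled gene rows into per-node values ``v_n``.

    Nodes with several measured genes are collapsed with ``aggregator``
    (default 90th percentile).  A node none of whose genes was measured gets
    the signal-neutral ``missing_default`` and is logged.
    """
    rows = {}
    for node_id, spec in graph.nodes.items():
        present = [g for g in spec.genes if g in matrix.index]
        if not present:
            logger.info(
                "%s: node %s has no measured genes; defaulting to %g",
                graph.pathway_id, node_id, missing_default,
            )
            rows[node_id] = np.full(matrix.shape[1], float(missing_default))
        else:
            rows[node_id] = _aggregate(matrix.loc[present].to_numpy(dtype=float), aggregator)
    return pd.DataFrame.from_dict(rows, orient="index", columns=matrix.columns)


class ExpressionPreprocessor(BaseEstimator, TransformerMixin):
    """Fit-once/apply-frozen form of the preprocessing chain.

    ``fit`` learns, from a reference matrix: the global truncation bounds on
    the log scale, the quantile-normalization reference distribution (mean
    order statistics across samples), and the min-max rescaling bounds.
    ``transform`` then maps any matrix over the same genes through a single
    monotone value→quantile map — the pooled empirical CDF of the fitted
    matrix composed with the quantile function of the reference distribution.
    Because the map depends only on the value (never on the ranks within the
    matrix being transformed), perturbing one gene leaves every other gene's
    transformed values exactly unchanged, which is what keeps an in-silico
    LoF simulation "all else equal".

    Parameters
    ----------
    q_low, q_high : float
        Global truncation quantiles applied to the log-transformed matrix.
    rescale_mode : {"global", "per_gene"}
        How the final [0,1] rescaling is computed (fitted, then frozen).
    log_transform : bool
        Apply log(x+1) first; disable when the input is already on log scale.

    Attributes (after ``fit``)
    --------------------------
    gene_index_ : the gene order the transformer is bound to.
    lo_, hi_ : truncation bounds on the log scale.
    ref_ : mean order-statistic reference distribution (length = n genes).
    pooled_ : sorted pooled fitted values backing the empirical CDF.
    scale_min_, scale_max_ : min-max bounds of the transformed fitted matrix.
    """

    def __init__(
        self,
        q_low: float = 0.01,
        q_high: float = 0.99,
        rescale_mode: str = "global",
        log_transform: bool = True,
    ):
        self.q_low = q_low
        self.q_high = q_high
        self.rescale_mode = rescale_mode
        self.log_transform = log_transform

    # -- internals ---------------------------------------------------------
    def _validate(self, X: pd.DataFrame) -> np.ndarray:
        if not isinstance(X, pd.DataFrame):
            raise TypeError("expected a genes × samples DataFrame")
        arr = X.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise ValueError("expression matrix contains non-finite values")
        if self.log_transform and (arr < 0).any():
            raise ValueError("expression matrix contains negative values")
        return np.log1p(arr) if self.log_transform else arr

    def _map_values(self, arr: np.ndarray) -> np.ndarray:
        """Monotone value map: pooled fitted ECDF (midpoint convention)
        composed with the quantile function of the reference distribution."""
        pooled = self.pooled_
        u = 0.5 * (
            np.searchsorted(pooled, arr, side="left")
            + np.searchsorted(pooled, arr, side="right")
        ) / pooled.size
        g = self.ref_.size
        grid = (np.arange(g) + 0.5) / g
        return np.interp(u, grid, self.ref_)

    # -- sklearn API -------------------------------------------------------
    def fit(self, X: pd.DataFrame, y=None) -> "ExpressionPreprocessor":
        if not 0 <= self.q_low < self.q_high <= 1:
            raise ValueError("need 0 <= q_low < q_high <= 1")
        arr = self._validate(X)
        self.gene_index_ = X.index.copy()
        self.lo_, self.hi_ = np.quantile(arr, [self.q_low, self.q_high])
        arr = np.clip(arr, self.lo_, self.hi_)
        self.all_constant_ = _check_constant_columns(arr, "ExpressionPreprocessor.fit")
        if self.all_constant_:
            self.ref_ = np.sort(arr[:, 0])
        else:
            self.ref_ = np.sort(arr, axis=0).mean(axis=1)
        self.pooled_ = np.sort(arr, axis=None)
        mapped = arr if self.all_constant_ else self._map_values(arr)
        if self.rescale_mode == "global":
            self.scale_min_ = mapped.min()
            self.scale_max_ = mapped.max()
        elif self.rescale_mode == "per_gene":
            self.scale_min_ = mapped.min(axis=1, keepdims=True)
            self.scale_max_ = mapped.max(axis=1, keepdims=True)
        else:
            raise ValueError(f"unknown rescale mode {self.rescale_mode!r}")
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "ref_"):
            raise RuntimeError("ExpressionPreprocessor is not fitted")
        if not X.index.equals(self.gene_index_):
            raise ValueError("gene index differs from the fitted reference matrix")
        arr = self._validate(X)
        arr = np.clip(arr, self.lo_, self.hi_)
        if not self.all_constant_:
            arr = self._map_values(arr)
        span = self.scale_max_ - self.scale_min_
        degenerate = span == 0
        span = np.where(degenerate, 1.0, span)
        out = (arr - self.scale_min_) / span
        out = np.where(np.broadcast_to(degenerate, out.shape), 0.5, out)
        out = np.clip(out, 0.0, 1.0)  # perturbed values may fall outside the fitted scale
        return pd.DataFrame(out, index=X.index, columns=X.columns)
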