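"""Differential signaling: per-circuit case/control contrasts.

Two-sided Wilcoxon rank-sum (Mann–Whitney U) per circuit, exact null
distribution when the smaller group has fewer than 8 samples and no ties are
present, normal approximation with continuity and tie correction otherwise;
Benjamini–Hochberg control of the FDR across circuits.  Direction and effect
are reported from group medians, independently of the two-sided p-value.
"""

from __future__ import annotations

from collections.abc import Mapping

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .errors import DesignError, DomainError

#: below this smaller-group size the exact rank-sum null is enumerated
EXACT_THRESHOLD = 8


def _split_design(
    activity: pd.DataFrame,
    design: Mapping[str, str] | pd.Series,
    case: str = "case",
    control: str = "control",
) -> tuple[list[str], list[str]]:
    design = pd.Series(dict(design)) if not isinstance(design, pd.Series) else design
    labels = set(design.unique())
    if labels != {case, control}:
        raise DesignError(f"design labels {sorted(labels)} != expected {{{case!r}, {control!r}}}")
    missing = [s for s in design.index if s not in activity.columns]
    if missing:
        raise DesignError(f"design samples absent from activity matrix: {missing}")
    cases = [s for s in activity.columns if design.get(s) == case]
    controls = [s for s in activity.columns if design.get(s) == control]
    if len(cases) < 2 or len(controls) < 2:
        raise DesignError(
            f"each group needs >= 2 samples (case={len(cases)}, control={len(controls)})"
        )
    return cases, controls


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise DomainError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def wilcoxon_contrast(
    activity: pd.DataFrame,
    design: Mapping[str, str] | pd.Series,
    case: str = "case",
    control: str = "control",
) -> pd.DataFrame:
    """Per-circuit two-sided rank-sum contrast of case vs control activities.

    Returns a DataFrame indexed by circuit_id with columns ``statistic`` (the
    Mann–Whitney U of the case group), ``p_value``, ``fdr_p``, ``direction``
    (up/down/none by median difference case − control), ``effect`` (that
    median difference) and the two group medians.  Circuits with all values
    tied get p = 1 and direction "none".
    """
    cases, controls = _split_design(activity, design, case, control)
    x_all = activity[cases].to_numpy(dtype=float)
    y_all = activity[controls].to_numpy(dtype=float)
    n1, n2 = len(cases), len(controls)

    records = []
    for i, circuit_id in enumerate(activity.index):
        x, y = x_all[i], y_all[i]
        med_x, med_y = float(np.median(x)), float(np.median(y))
        pooled = np.concatenate([x, y])
        if np.all(pooled == pooled[0]):
            stat, p = n1 * n2 / 2.0, 1.0
        else:
            has_ties = np.unique(pooled).size < pooled.size
            method = "exact" if (min(n1, n2) < EXACT_THRESHOLD and not has_ties) else "asymptotic"
            res = mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True)
            stat, p = float(res.statistic), float(res.pvalue)
        effect = med_x - med_y
        direction = "none" if effect == 0 else ("up" if effect > 0 else "down")
        records.append(
            {
                "circuit_id": circuit_id,
                "statistic": stat,
                "p_value": min(p, 1.0),
                "direction": direction,
                "effect": effect,
                f"median_{case}": med_x,
                f"median_{control}": med_y,
            }
        )
    out = pd.DataFrame.from_records(records).set_index("circuit_id")
    out.insert(2, "fdr_p", bh_adjust(out["p_value"].to_numpy()))
    return out


def summarize_activity(
    activity: pd.DataFrame,
    design: Mapping[str, str] | pd.Series,
    case: str = "case",
    control: str = "control",
) -> pd.DataFrame:
    """Per-circuit, per-group median, mean and IQR of activity values."""
    cases, controls = _split_design(activity, design, case, control)
    frames = []
    for label, cols in ((case, cases), (control, controls)):
        block = activity[cols]
        q3 = block.quantile(0.75, axis=1)
        q1 = block.quantile(0.25, axis=1)
        frames.append(
            pd.DataFrame(
                {
                    "circuit_id": activity.index,
                    "group": label,
                    "median": block.median(axis=1).to_numpy(),
                    "mean": block.mean(axis=1).to_numpy(),
                    "iqr": (q3 - q1).to_numpy(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
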