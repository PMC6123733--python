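"""Group-specific feature selection by one-way ANOVA and fold change.

For every feature a one-way ANOVA across the observation groups gives a
p-value, and the fold change is the ratio of the largest to the smallest
group mean (on linear-scale data) or 2**(max - min) when the input is
log2-scale.  Features pass when p < p_threshold AND FC > fc_threshold;
both statistics are reported for all features.  An optional
Benjamini–Hochberg correction can replace the raw p-values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ..exceptions import ValidationError
from .embed import DataMatrix

__all__ = ["FeatureFilterResult", "anova_feature_filter"]


@dataclass
class FeatureFilterResult:
    selected: list              # feature ids passing both thresholds
    table: pd.DataFrame         # per-feature: p_value, (q_value), fold_change
    p_threshold: float
    fc_threshold: float


def anova_feature_filter(matrix: DataMatrix, group_labels, p_threshold: float = 0.05,
                         fc_threshold: float = 2.0, log2_scale: bool = False,
                         fdr: bool = False) -> FeatureFilterResult:
    """Select features with a significant group effect and a large fold change.

    Parameters
    ----------
    matrix : DataMatrix
        n observations × p features.
    group_labels : array-like of length n
        Group of each observation; >= 2 groups, each with >= 2 members.
    p_threshold, fc_threshold : float
        Raw ANOVA p-value and fold-change cutoffs (p < threshold, FC > threshold).
    log2_scale : bool
        If True values are log2 expression and FC = 2**(max mean - min mean);
        otherwise FC = max group mean / min group mean (requires positive means).
    fdr : bool
        Apply Benjamini–Hochberg correction and threshold the q-values instead.
    """
    groups = np.asarray(group_labels)
    if groups.shape != (matrix.n,):
        raise ValidationError("group_labels length must match observation count")
    uniq, counts = np.unique(groups, return_counts=True)
    if uniq.size < 2:
        raise ValidationError("need at least 2 groups")
    if counts.min() < 2:
        small = uniq[counts.argmin()]
        raise ValidationError(f"group {small!r} has < 2 observations")
    X = matrix.values
    pvals = np.empty(matrix.p)
    fold = np.empty(matrix.p)
    masks = [groups == g for g in uniq]
    for j in range(matrix.p):
        cols = [X[m, j] for m in masks]
        if all(np.ptp(c) == 0 for c in cols) and np.ptp(X[:, j]) == 0:
            pvals[j] = 1.0
        else:
            with np.errstate(invalid="ignore", divide="ignore"):
                _, p = stats.f_oneway(*cols)
            pvals[j] = 1.0 if not np.isfinite(p) else float(p)
        means = np.array([c.mean() for c in cols])
        if log2_scale:
            fold[j] = float(2.0 ** (means.max() - means.min()))
        else:
            mn = means.min()
            fold[j] = float(means.max() / mn) if mn > 0 else np.inf
    table = pd.DataFrame({"feature": matrix.column_ids, "p_value": pvals,
                          "fold_change": fold}).set_index("feature")
    crit = pvals
    if fdr:
        table["q_value"] = multipletests(pvals, method="fdr_bh")[1]
        crit = table["q_value"].to_numpy()
    keep = (crit < p_threshold) & (fold > fc_threshold)
    selected = [matrix.column_ids[j] for j in np.where(keep)[0]]
    return FeatureFilterResult(selected, table, p_threshold, fc_threshold)
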