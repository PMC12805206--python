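"""ROC/AUC evaluation of inclusion scores against ground truth.

The AUC is computed with the Mann-Whitney identity (probability that a
randomly chosen true-difference pair scores above a randomly chosen null
pair, ties counted half), which equals the trapezoidal area under the ROC
staircase.  Inclusion probabilities are used directly as scores — no cutoff
is imposed, so the comparison is threshold-free.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = ["RocResult", "roc_auc", "auc_summary_table"]


@dataclass
class RocResult:
    """ROC staircase and its area."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def roc_auc(scores, labels) -> RocResult:
    """ROC curve and AUC of real-valued scores against binary labels.

    Requires at least one positive and one negative label; ties in the
    scores are handled by midranks in the AUC and by vertical/horizontal
    jumps merged into diagonal segments in the staircase.
    """
    s = np.asarray(scores, dtype=float).ravel()
    y = np.asarray(labels).ravel().astype(int)
    if s.shape != y.shape:
        raise ValueError("scores and labels must have equal length")
    if np.any((y != 0) & (y != 1)):
        raise ValueError("labels must be binary")
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: need both classes present")

    # Mann-Whitney with midrank ties
    ranks = rankdata(s)
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)

    # staircase: sweep thresholds from high to low, tied scores jointly
    order = np.argsort(-s, kind="mergesort")
    s_sorted = s[order]
    y_sorted = y[order]
    distinct = np.r_[np.nonzero(np.diff(s_sorted))[0], s_sorted.size - 1]
    tp = np.cumsum(y_sorted)[distinct]
    fp = np.cumsum(1 - y_sorted)[distinct]
    tpr = np.r_[0.0, tp / n_pos]
    fpr = np.r_[0.0, fp / n_neg]
    thresholds = np.r_[np.inf, s_sorted[distinct]]
    return RocResult(thresholds=thresholds, fpr=fpr, tpr=tpr, auc=float(auc))


def auc_summary_table(cell_tables: dict) -> pd.DataFrame:
    """Mean AUC and its standard error per condition cell.

    ``cell_tables`` maps a condition label to a tidy harness table with
    columns ``replicate``, ``true_diff``, ``pip``; the AUC is computed per
    replicate and averaged.
    """
    rows = []
    for label, table in cell_tables.items():
        aucs = []
        for _, grp in table.groupby("replicate"):
            if grp["true_diff"].nunique() < 2:
                continue  # replicate with a single class carries no AUC
            aucs.append(roc_auc(grp["pip"].values, grp["true_diff"].values).auc)
        aucs = np.asarray(aucs)
        rows.append({
            "condition": label,
            "n_replicates": aucs.size,
            "mean_auc": float(aucs.mean()) if aucs.size else np.nan,
            "se_auc": float(aucs.std(ddof=1) / np.sqrt(aucs.size))
            if aucs.size > 1 else np.nan,
        })
    return pd.DataFrame(rows)
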