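"""Two-group differential expression on an FPKM-like matrix.

The upstream count model of alignment-based pipelines is out of scope
here; differential testing is a two-sided Welch t-test on log2(x+1)
abundances, followed by Benjamini-Hochberg adjustment.  Genes are called
up/down with the strict thresholds |FC| > 1.5 and q < 0.05 (fold change on
the linear scale, with a small pseudocount for stability near zero).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .dmr import adjust_fdr

__all__ = ["fold_change", "de_test", "filter_degs", "coefficient_of_variation"]

logger = logging.getLogger(__name__)


def fold_change(mean_A, mean_B, eps: float = 0.01):
    """log2((mean_B + eps) / (mean_A + eps)); antisymmetric under group swap."""
    if eps <= 0:
        raise ValueError("eps must be > 0")
    return np.log2((np.asarray(mean_B, dtype=float) + eps) / (np.asarray(mean_A, dtype=float) + eps))


def de_test(values_A, values_B) -> float:
    """Two-sided Welch t-test on log2(x+1)-transformed abundances."""
    a = np.log2(np.asarray(values_A, dtype=float) + 1.0)
    b = np.log2(np.asarray(values_B, dtype=float) + 1.0)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 values per group")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        return 1.0 if a[0] == b[0] else 0.0
    p = stats.ttest_ind(a, b, equal_var=False).pvalue
    return 1.0 if np.isnan(p) else float(p)


def filter_degs(
    matrix: pd.DataFrame,
    groups: dict[str, str],
    fc_thresh: float = 1.5,
    q_thresh: float = 0.05,
    eps: float = 0.01,
    group_order: list[str] | None = None,
) -> pd.DataFrame:
    """Per-gene fold change + Welch test + BH, with strict DEG thresholds.

    ``matrix`` is genes x samples (index = gene ids).  Returns a table with
    mean_A, mean_B, log2_fc, p_value, q_value and status in {up, down, ns};
    "up" means higher in group B.  All-zero genes are excluded (logged).
    """
    labels = sorted(set(groups.values())) if group_order is None else list(group_order)
    if len(labels) != 2:
        raise ValueError(f"exactly two groups required, got {labels}")
    a_cols = [s for s, g in groups.items() if g == labels[0]]
    b_cols = [s for s, g in groups.items() if g == labels[1]]
    if len(a_cols) < 2 or len(b_cols) < 2:
        raise ValueError("need >= 2 samples per group")

    X = matrix[a_cols + b_cols]
    if (X.to_numpy() < 0).any():
        raise ValueError("negative abundances")
    nonzero = X.sum(axis=1) > 0
    n_dropped = int((~nonzero).sum())
    if n_dropped:
        logger.info("filter_degs: excluded %d all-zero genes", n_dropped)
    X = X[nonzero]
    if len(X) == 0:
        return pd.DataFrame(columns=["gene_id", "mean_A", "mean_B", "log2_fc", "p_value", "q_value", "status"])

    A = X[a_cols].to_numpy(dtype=float)
    B = X[b_cols].to_numpy(dtype=float)
    mean_A, mean_B = A.mean(axis=1), B.mean(axis=1)
    lfc = fold_change(mean_A, mean_B, eps)
    la, lb = np.log2(A + 1.0), np.log2(B + 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(la, lb, axis=1, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    # zero variance in both groups: p undefined; equal means carry no signal
    p = np.where(np.isnan(p), np.where(la.mean(axis=1) == lb.mean(axis=1), 1.0, np.finfo(float).tiny), p)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    q = adjust_fdr(p)

    lfc_cut = np.log2(fc_thresh)
    status = np.full(len(X), "ns", dtype=object)
    status[(lfc > lfc_cut) & (q < q_thresh)] = "up"
    status[(lfc < -lfc_cut) & (q < q_thresh)] = "down"
    return pd.DataFrame(
        {
            "gene_id": X.index,
            "mean_A": mean_A,
            "mean_B": mean_B,
            "log2_fc": lfc,
            "p_value": p,
            "q_value": q,
            "status": status,
        }
    ).reset_index(drop=True)


def coefficient_of_variation(values) -> float:
    """Sample standard deviation (n-1) divided by the mean."""
    x = np.asarray(values, dtype=float)
    m = x.mean()
    if m == 0:
        raise ValueError("CV undefined for zero mean")
    return float(x.std(ddof=1) / m)
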