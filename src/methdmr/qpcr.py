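"""Comparative-CT (delta-delta-CT) relative quantification.

Per sample, dCT = CT(target) - CT(reference gene); ddCT subtracts a
calibrator dCT (by default the control group's mean dCT, optionally a
named sample); relative expression = 2^(-ddCT).  Group comparison is a
two-sided Wilcoxon rank-sum test, exact for small tie-free groups.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["ddct", "group_compare", "qpcr_report"]

logger = logging.getLogger(__name__)

CT_COLUMNS = ["sample", "group", "gene", "ct_target", "ct_ref"]


def ddct(records: pd.DataFrame, calibrator: str = "control-mean", control_group: str | None = None) -> pd.DataFrame:
    """Relative expression 2^(-ddCT) per sample and target gene.

    ``records`` is a long-format table with columns sample, group, gene,
    ct_target, ct_ref.  Technical replicates (repeated sample/gene rows)
    are averaged on the CT scale first.  ``calibrator`` is either
    ``"control-mean"`` (mean dCT of the control group, per gene) or a
    sample name whose dCT is used as calibrator.  ``control_group``
    defaults to the lexicographically first group label.
    """
    df = records.copy()
    missing = df["ct_target"].isna() | df["ct_ref"].isna()
    if missing.any():
        logger.info("ddct: skipped %d records missing a CT value", int(missing.sum()))
        df = df[~missing]
    if (df[["ct_target", "ct_ref"]].to_numpy() <= 0).any():
        raise ValueError("CT values must be finite and > 0")
    df = df.groupby(["sample", "group", "gene"], as_index=False)[["ct_target", "ct_ref"]].mean()
    df["dct"] = df["ct_target"] - df["ct_ref"]

    if control_group is None:
        control_group = sorted(df["group"].unique())[0]

    out = []
    for gene, g in df.groupby("gene", sort=True):
        if calibrator == "control-mean":
            cal = g.loc[g["group"] == control_group, "dct"].mean()
            if np.isnan(cal):
                raise ValueError(f"no control-group records for gene {gene!r}")
        else:
            sel = g.loc[g["sample"] == calibrator, "dct"]
            if len(sel) != 1:
                raise ValueError(f"calibrator sample {calibrator!r} not found (or ambiguous) for gene {gene!r}")
            cal = float(sel.iloc[0])
        gg = g.copy()
        gg["ddct"] = gg["dct"] - cal
        gg["rel_expr"] = np.power(2.0, -gg["ddct"])
        out.append(gg)
    return pd.concat(out, ignore_index=True)


def group_compare(values_A, values_B) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) p-value.

    Exact when both groups have n <= 8 and there are no ties; otherwise
    the normal approximation with tie correction.  All-tied input returns
    p = 1.0.
    """
    a = np.asarray(values_A, dtype=float)
    b = np.asarray(values_B, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need >= 3 samples per group")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        return 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(a) <= 8 and len(b) <= 8 and not has_ties) else "asymptotic"
    return float(stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)


def qpcr_report(records: pd.DataFrame, calibrator: str = "control-mean", control_group: str | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample relative expression plus per-gene group-comparison p-values."""
    rel = ddct(records, calibrator=calibrator, control_group=control_group)
    if control_group is None:
        control_group = sorted(rel["group"].unique())[0]
    rows = []
    for gene, g in rel.groupby("gene", sort=True):
        ctrl = g.loc[g["group"] == control_group, "rel_expr"].to_numpy()
        trt = g.loc[g["group"] != control_group, "rel_expr"].to_numpy()
        rows.append(
            {
                "gene": gene,
                "mean_control": float(ctrl.mean()),
                "mean_treated": float(trt.mean()),
                "p_value": group_compare(ctrl, trt),
            }
        )
    return rel, pd.DataFrame(rows)
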