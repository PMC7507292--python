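"""Gene-lipid Pearson correlation networks.

Every (differential gene, differential lipid) pair is tested across the
shared samples; pairs with |r| strictly above 0.50 and two-sided p below
0.05 (t-distribution with n-2 df) become network edges, signed by the
correlation's direction.  No multiple-testing correction is applied by
default (matching the published raw-p filter; an FDR option is provided
and documented as the conservative alternative).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .dmr import adjust_fdr

__all__ = ["correlate", "build_network", "write_cytoscape_edges", "write_sif", "node_table"]

logger = logging.getLogger(__name__)


class ConstantProfileError(ValueError):
    """Correlation undefined for a constant profile."""


def correlate(x, y) -> tuple[float, float, int]:
    """Pearson r, two-sided p and n for two paired per-sample profiles."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired samples")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantProfileError("constant profile: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), len(x)


def _corr_pvalues(R: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p for Pearson r via the exact t transform (n-2 df)."""
    R = np.clip(R, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = R * np.sqrt((n - 2) / (1.0 - R**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    return np.where(np.abs(R) >= 1.0, 0.0, p)


def build_network(
    deg_matrix: pd.DataFrame,
    lipid_matrix: pd.DataFrame,
    r_thresh: float = 0.50,
    alpha: float = 0.05,
    log_transform: bool = False,
    fdr: bool = False,
) -> pd.DataFrame:
    """All-pairs gene x lipid correlation edges with strict thresholds.

    Both matrices are features x samples with identical sample columns
    (order may differ; a mismatch raises with the offending names).
    Constant profiles are skipped with a log entry.  Returns the edge
    table: gene_id, lipid_id, r, p_value (q_value when ``fdr``), sign, n,
    weight = |r|.
    """
    g_cols, l_cols = set(deg_matrix.columns), set(lipid_matrix.columns)
    if g_cols != l_cols:
        raise ValueError(
            f"sample mismatch: only-genes {sorted(g_cols - l_cols)}, only-lipids {sorted(l_cols - g_cols)}"
        )
    samples = list(deg_matrix.columns)
    G = deg_matrix[samples].to_numpy(dtype=float)
    L = lipid_matrix[samples].to_numpy(dtype=float)
    if log_transform:
        G, L = np.log2(G + 1.0), np.log2(L + 1.0)
    n = len(samples)
    if n < 3:
        raise ValueError("need >= 3 shared samples")

    g_ok = np.ptp(G, axis=1) > 0
    l_ok = np.ptp(L, axis=1) > 0
    if (~g_ok).any() or (~l_ok).any():
        logger.info("build_network: skipped %d constant genes, %d constant lipids",
                    int((~g_ok).sum()), int((~l_ok).sum()))
    Gz = (G[g_ok] - G[g_ok].mean(axis=1, keepdims=True))
    Lz = (L[l_ok] - L[l_ok].mean(axis=1, keepdims=True))
    Gz /= np.linalg.norm(Gz, axis=1, keepdims=True)
    Lz /= np.linalg.norm(Lz, axis=1, keepdims=True)
    R = Gz @ Lz.T
    P = _corr_pvalues(R, n)

    gi, li = np.nonzero(np.ones_like(R, dtype=bool))
    edges = pd.DataFrame(
        {
            "gene_id": deg_matrix.index[g_ok][gi],
            "lipid_id": lipid_matrix.index[l_ok][li],
            "r": R.ravel(),
            "p_value": P.ravel(),
            "n": n,
        }
    )
    if fdr:
        edges["q_value"] = adjust_fdr(edges["p_value"].to_numpy())
        keep = (edges["r"].abs() > r_thresh) & (edges["q_value"] < alpha)
    else:
        keep = (edges["r"].abs() > r_thresh) & (edges["p_value"] < alpha)
    edges = edges[keep].reset_index(drop=True)
    edges["sign"] = np.where(edges["r"] > 0, "positive", "negative")
    edges["weight"] = edges["r"].abs()
    return edges


def write_cytoscape_edges(edges: pd.DataFrame, path: str, header_comment: str | None = None) -> None:
    tab = pd.DataFrame(
        {
            "source": edges["gene_id"],
            "target": edges["lipid_id"],
            "interaction": np.where(edges["sign"] == "positive", "pos", "neg"),
            "r": edges["r"],
            "p": edges["p_value"],
            "abs_r": edges["weight"],
        }
    )
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        tab.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def write_sif(edges: pd.DataFrame, path: str) -> None:
    with open(path, "w") as fh:
        for _, e in edges.iterrows():
            rel = "pos" if e["sign"] == "positive" else "neg"
            fh.write(f"{e['gene_id']}\t{rel}\t{e['lipid_id']}\n")


def node_table(edges: pd.DataFrame) -> pd.DataFrame:
    genes = pd.DataFrame({"node": sorted(edges["gene_id"].unique()), "type": "gene"})
    lipids = pd.DataFrame({"node": sorted(edges["lipid_id"].unique()), "type": "lipid"})
    return pd.concat([genes, lipids], ignore_index=True)
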