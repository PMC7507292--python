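"""Promoter windows and DMR-to-gene assignment.

Promoters are defined strand-aware as TSS -2000 bp to +1000 bp.  A DMR is
associated with a gene when it overlaps the promoter window or the gene
body by at least one base; genes hit in both contexts yield a single link
with context "both" so that DMR-associated genes (DMRGs) are not double
counted.  All internal interval arithmetic is 0-based half-open; gene
tables and TSS coordinates are 1-based inclusive on input.
"""

from __future__ import annotations

import re
import warnings
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "promoter_window",
    "read_gene_table",
    "read_gtf_genes",
    "associate_dmrs",
    "dmrg_genes",
]

GENE_COLUMNS = ["gene_id", "chrom", "strand", "tss", "start", "end"]


def promoter_window(tss: int, strand: str, up: int = 2000, down: int = 1000) -> tuple[int, int]:
    """0-based half-open promoter interval around a 1-based TSS.

    On '+' the window runs ``up`` bp upstream to ``down`` bp downstream of
    the TSS; on '-' the genomic interval is mirrored. Clamped at 0.
    """
    if tss < 1:
        raise ValueError("tss must be >= 1")
    t0 = tss - 1  # 0-based
    if strand == "+":
        lo, hi = t0 - up, t0 + down
    elif strand == "-":
        lo, hi = t0 - down + 1, t0 + up + 1
    else:
        raise ValueError(f"bad strand {strand!r}")
    return max(0, lo), max(0, hi)


def read_gene_table(path: str) -> pd.DataFrame:
    """Read a 6-column gene TSV: gene_id, chrom, strand, tss, start, end (1-based)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(GENE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"gene table missing columns: {sorted(missing)}")
    return df[GENE_COLUMNS].copy()


_GENE_ID_RE = re.compile(r'gene_id "?([^";]+)"?')


def read_gtf_genes(path: str) -> pd.DataFrame:
    """Extract gene features from a GTF into the 6-column gene table.

    Only rows with feature type ``gene`` are used; when a gene id appears
    on several rows the most upstream TSS is kept.
    """
    raw = pd.read_csv(path, sep="\t", comment="#", header=None,
                      names=["chrom", "source", "feature", "start", "end", "score", "strand", "frame", "attr"],
                      dtype={"chrom": str})
    raw = raw[raw["feature"] == "gene"].copy()
    raw["gene_id"] = raw["attr"].map(lambda s: m.group(1) if (m := _GENE_ID_RE.search(s)) else None)
    if raw["gene_id"].isna().any():
        raise ValueError("GTF gene rows without gene_id attribute")
    raw["tss"] = np.where(raw["strand"] == "+", raw["start"], raw["end"])
    rows = []
    for gid, g in raw.groupby("gene_id", sort=True):
        strand = g["strand"].iloc[0]
        tss = int(g["tss"].min() if strand == "+" else g["tss"].max())
        rows.append((gid, g["chrom"].iloc[0], strand, tss, int(g["start"].min()), int(g["end"].max())))
    return pd.DataFrame(rows, columns=GENE_COLUMNS)


def _overlaps(starts_a, ends_a, start_b, end_b) -> np.ndarray:
    return (starts_a < end_b) & (start_b < ends_a)


def associate_dmrs(
    dmrs: pd.DataFrame,
    genes: pd.DataFrame,
    up: int = 2000,
    down: int = 1000,
    min_overlap: int = 1,
) -> pd.DataFrame:
    """Link DMRs to genes via promoter or gene-body overlap.

    Returns a links table (dmr_id, gene_id, context) with one row per
    (DMR, gene) pair overlapping by >= ``min_overlap`` bp in at least one
    context; context is "promoter", "gene_body" or "both".
    """
    shared = set(dmrs["chrom"]).intersection(set(genes["chrom"]))
    only_d = set(dmrs["chrom"]) - shared
    only_g = set(genes["chrom"]) - shared
    if len(dmrs) and len(genes) and (only_d or only_g):
        warnings.warn(
            f"chromosome namespaces differ: DMR-only {sorted(only_d)}, gene-only {sorted(only_g)}",
            stacklevel=2,
        )

    prom = genes.apply(lambda g: promoter_window(int(g["tss"]), g["strand"], up, down), axis=1) if len(genes) else []
    gene_iv = []
    for i, g in genes.reset_index(drop=True).iterrows():
        p_lo, p_hi = prom.iloc[i]
        gene_iv.append((g["gene_id"], g["chrom"], p_lo, p_hi, int(g["start"]) - 1, int(g["end"])))

    records = []
    d = dmrs.reset_index(drop=True)
    dmr_ids = d["name"] if "name" in d.columns else pd.Series([f"DMR_{k + 1}" for k in range(len(d))])
    for k, row in d.iterrows():
        ds, de, dc = int(row["start"]), int(row["end"]), row["chrom"]
        for gid, gc, p_lo, p_hi, b_lo, b_hi in gene_iv:
            if gc != dc:
                continue
            in_prom = min(de, p_hi) - max(ds, p_lo) >= min_overlap
            in_body = min(de, b_hi) - max(ds, b_lo) >= min_overlap
            if in_prom and in_body:
                ctx = "both"
            elif in_prom:
                ctx = "promoter"
            elif in_body:
                ctx = "gene_body"
            else:
                continue
            records.append((dmr_ids.iloc[k], gid, ctx))
    return pd.DataFrame(records, columns=["dmr_id", "gene_id", "context"])


def dmrg_genes(links: pd.DataFrame) -> list[str]:
    """Deduplicated DMR-associated gene list."""
    return sorted(links["gene_id"].unique())
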