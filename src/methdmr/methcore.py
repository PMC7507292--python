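"""Per-cytosine bisulfite call handling.

Parses methratio-style call tables, computes per-site methylation levels,
pools read counts across samples within groups, applies the candidate-site
coverage filter, and estimates bisulfite conversion efficiency from an
unmethylated spike-in contig (lambda-DNA style control).

A methylation level is simply the fraction of sequenced reads that support
methylation at a cytosine: meth_reads / total_reads.  Candidate sites for
differential testing are CpGs commonly covered in every sample of both
groups at a minimum depth (default 5x).
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import IO, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CALL_COLUMNS",
    "SpikeInSummary",
    "MethcallParseError",
    "parse_methcall_table",
    "methylation_level",
    "conversion_rate",
    "pool_and_select_candidates",
    "write_grouped_sites",
    "read_grouped_sites",
]

#: canonical column order for a parsed call table
CALL_COLUMNS = ["chrom", "pos", "strand", "context", "meth_reads", "total_reads"]


class MethcallParseError(ValueError):
    """Raised for malformed or invariant-violating call-table rows."""


@dataclass(frozen=True)
class SpikeInSummary:
    """Conversion-rate QC from an unmethylated control contig.

    ``conversion_rate = 1 - retained_c_calls / total_c_calls`` where a
    "retained" call is a read that still reports the cytosine as methylated
    (i.e. bisulfite failed to convert it).
    """

    n_unmeth_c_sites: int
    retained_c_calls: int
    total_c_calls: int

    @property
    def conversion_rate(self) -> float:
        return 1.0 - self.retained_c_calls / self.total_c_calls


def parse_methcall_table(source: str | IO[str], sample_id: str | None = None) -> pd.DataFrame:
    """Parse a methratio-style TSV of per-cytosine bisulfite calls.

    Parameters
    ----------
    source
        Path or open text handle. Expected columns (tab- or
        whitespace-delimited): chrom, pos (1-based), strand, context, then
        either ``meth_reads, total_reads`` or ``ratio, meth_reads,
        total_reads`` (the methratio dialect; the ratio column is ignored).
        A header line and ``#`` comment lines are tolerated.
    sample_id
        Optional label stored in a ``sample`` column.

    Returns
    -------
    DataFrame with columns :data:`CALL_COLUMNS` (plus ``sample``), restricted
    to CpG-context rows and sorted by (chrom, pos, strand).

    Raises
    ------
    MethcallParseError
        On a malformed row (naming its line number) or when
        ``meth_reads > total_reads``.
    """
    try:
        if isinstance(source, (str, bytes)):
            raw = pd.read_csv(source, sep=r"\s+", header=None, comment="#", dtype=str)
        else:
            raw = pd.read_csv(io.StringIO(source.read()), sep=r"\s+", header=None, comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        raw = pd.DataFrame()
    if raw.empty:
        out = pd.DataFrame(columns=CALL_COLUMNS)
        out = out.astype({"pos": int, "meth_reads": int, "total_reads": int})
        if sample_id is not None:
            out["sample"] = pd.Series(dtype=str)
        return out

    # drop a header line only if it looks like one throughout (a single
    # non-numeric position field is a malformed data row, not a header)
    first_pos = str(raw.iloc[0, 1])
    first_last = str(raw.iloc[0, raw.shape[1] - 1])
    if not first_pos.lstrip("-").isdigit() and not first_last.lstrip("-").isdigit():
        raw = raw.iloc[1:].reset_index(drop=True)
        line_offset = 2  # 1-based line numbers, header consumed
    else:
        line_offset = 1

    ncol = raw.shape[1]
    if ncol == 6:
        raw.columns = CALL_COLUMNS
    elif ncol >= 7:
        raw = raw.iloc[:, :7]
        raw.columns = ["chrom", "pos", "strand", "context", "ratio", "meth_reads", "total_reads"]
    else:
        raise MethcallParseError(f"expected 6 or 7 columns, found {ncol}")

    df = raw[CALL_COLUMNS].copy()
    for col in ("pos", "meth_reads", "total_reads"):
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna()
        if bad.any():
            line = int(np.flatnonzero(bad.to_numpy())[0]) + line_offset
            raise MethcallParseError(f"line {line}: non-numeric value in column '{col}'")
        df[col] = numeric.astype(int)

    invalid = (df["meth_reads"] > df["total_reads"]) | (df["meth_reads"] < 0) | (df["total_reads"] < 1) | (df["pos"] < 1)
    if invalid.any():
        line = int(np.flatnonzero(invalid.to_numpy())[0]) + line_offset
        raise MethcallParseError(
            f"line {line}: invalid counts or position "
            "(need 0 <= meth_reads <= total_reads, total_reads >= 1, pos >= 1)"
        )

    df = df[df["context"].str.upper().isin({"CPG", "CG"})].reset_index(drop=True)
    df = df.sort_values(["chrom", "pos", "strand"], kind="mergesort").reset_index(drop=True)
    if sample_id is not None:
        df["sample"] = sample_id
    return df


def methylation_level(meth_reads, total_reads):
    """Fraction of covering reads that support methylation.

    Accepts scalars or arrays; ``total_reads`` must be >= 1 everywhere.
    """
    total = np.asarray(total_reads)
    if np.any(total < 1):
        raise ValueError("methylation level undefined at zero coverage; exclude the site upstream")
    level = np.asarray(meth_reads) / total
    return float(level) if level.ndim == 0 else level


def conversion_rate(spikein_calls: pd.DataFrame, contig: str | None = None) -> SpikeInSummary:
    """Bisulfite conversion rate from an unmethylated control contig.

    All cytosine contexts on the control are used (the spike-in carries no
    methylation, so any read calling a C methylated is a conversion
    failure).  ``contig`` optionally restricts to one chromosome name.
    """
    calls = spikein_calls
    if contig is not None:
        calls = calls[calls["chrom"] == contig]
    if len(calls) == 0:
        raise ValueError("no control-contig calls: conversion-rate QC unavailable")
    return SpikeInSummary(
        n_unmeth_c_sites=int(len(calls)),
        retained_c_calls=int(calls["meth_reads"].sum()),
        total_c_calls=int(calls["total_reads"].sum()),
    )


def pool_and_select_candidates(
    samples: Mapping[str, pd.DataFrame],
    groups: Mapping[str, str],
    min_depth: int = 5,
    depth_mode: str = "per-sample",
    group_order: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Pool counts by group and select candidate CpG sites.

    A site is a candidate when it is covered (>=1 read) in *every* sample of
    both groups and the depth criterion holds.  ``depth_mode="per-sample"``
    (default, strict) requires depth >= ``min_depth`` in every sample;
    ``"per-group-pool"`` requires only the pooled per-group depth to reach
    ``min_depth``.

    Returns a grouped-site table: chrom, pos, strand, meth_A, total_A,
    level_A, meth_B, total_B, level_B — group A is the first of
    ``group_order`` (default: sorted group labels).
    """
    if depth_mode not in ("per-sample", "per-group-pool"):
        raise ValueError(f"unknown depth_mode {depth_mode!r}")
    unknown = set(groups) - set(samples)
    if unknown:
        raise ValueError(f"groups map names unknown samples: {sorted(unknown)}")
    labels = sorted(set(groups.values())) if group_order is None else list(group_order)
    if len(labels) != 2:
        raise ValueError(f"exactly two groups required, got {labels}")

    frames = []
    for sid, grp in groups.items():
        df = samples[sid]
        frames.append(
            pd.DataFrame(
                {
                    "chrom": df["chrom"],
                    "pos": df["pos"],
                    "strand": df["strand"],
                    "meth": df["meth_reads"],
                    "total": df["total_reads"],
                    "sample": sid,
                    "group": grp,
                }
            )
        )
    longf = pd.concat(frames, ignore_index=True)

    key = ["chrom", "pos", "strand"]
    n_samples = len(groups)
    per_site = longf.groupby(key, sort=True)
    counts = per_site["sample"].nunique()
    min_total = per_site["total"].min()
    covered = counts[counts == n_samples].index
    if depth_mode == "per-sample":
        deep = min_total[min_total >= min_depth].index
        keep = covered.intersection(deep)
        longf = longf.set_index(key).loc[keep].reset_index()
    else:
        longf = longf.set_index(key).loc[covered].reset_index()

    cols = ["chrom", "pos", "strand", "meth_A", "total_A", "level_A", "meth_B", "total_B", "level_B"]
    if len(longf) == 0:
        empty = pd.DataFrame(columns=cols)
        return empty.astype({c: int for c in ("pos", "meth_A", "total_A", "meth_B", "total_B")})

    pooled = longf.groupby(key + ["group"], sort=True)[["meth", "total"]].sum().unstack("group")
    a, b = labels
    out = pd.DataFrame(
        {
            "meth_A": pooled[("meth", a)],
            "total_A": pooled[("total", a)],
            "meth_B": pooled[("meth", b)],
            "total_B": pooled[("total", b)],
        }
    ).reset_index()
    if depth_mode == "per-group-pool":
        out = out[(out["total_A"] >= min_depth) & (out["total_B"] >= min_depth)].reset_index(drop=True)
    out[["meth_A", "total_A", "meth_B", "total_B"]] = out[["meth_A", "total_A", "meth_B", "total_B"]].astype(int)
    out["level_A"] = out["meth_A"] / out["total_A"]
    out["level_B"] = out["meth_B"] / out["total_B"]
    return out[cols].sort_values(["chrom", "pos", "strand"], kind="mergesort").reset_index(drop=True)


def write_grouped_sites(sites: pd.DataFrame, path: str, header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        sites.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def read_grouped_sites(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
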