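"""Sliding-window DMR calling on grouped CpG sites.

The caller follows a seed-and-merge strategy over candidate CpG sites
ordered along each chromosome:

1. every candidate site gets a two-sided Fisher's exact test on its pooled
   2x2 (methylated/unmethylated x group) table;
2. the first significant site (p < 0.05) seeds a chain that extends over
   subsequent significant sites sharing its methylation direction while
   consecutive members are <= 300 bp apart; a non-significant candidate,
   a direction flip or a larger gap closes the chain;
3. chains with >= 5 member CpGs become candidate regions; member counts are
   pooled per group and the region must pass a chi-square screen
   (p <= 0.05) and show an absolute group-mean methylation difference
   >= 0.20;
4. region p-values are Benjamini-Hochberg adjusted and regions with
   q < 0.01 are the final DMRs.

Direction is relative to group B minus group A ("hyper" = higher
methylation in group B, the treatment group in a treatment/control design).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DmrParams",
    "fisher_exact_2x2",
    "site_test",
    "region_chi2",
    "call_dmrs",
    "adjust_fdr",
    "finalize_dmrs",
    "write_dmr_bed",
    "chromosome_summary",
]

# relative slack when deciding which tables are "as extreme as" the observed
# one: large enough to absorb float error in log-gamma pmf evaluation, small
# enough never to merge genuinely distinct hypergeometric probabilities
# (distinct pmfs at total <= a few hundred differ by far more than this).
_TIE_REL_TOL = 1e-11


@dataclass(frozen=True)
class DmrParams:
    """Thresholds of the merge-and-filter procedure (defaults as published)."""

    alpha_site: float = 0.05
    max_gap: int = 300
    min_sites: int = 5
    min_delta: float = 0.20
    alpha_region: float = 0.05
    allow_nonsig_gaps: bool = False


def fisher_exact_2x2(a, b, c, d):
    """Vectorized two-sided Fisher's exact test.

    Tables are ``[[a, b], [c, d]]`` given as equal-length integer arrays
    (or scalars).  The two-sided p-value is the hypergeometric probability
    mass of all tables with the observed margins whose point probability
    does not exceed the observed one (the standard "sum of small p"
    definition, as in R's ``fisher.test``).

    Returns an array (or scalar) of p-values in (0, 1].
    """
    a = np.atleast_1d(np.asarray(a, dtype=np.int64))
    b = np.atleast_1d(np.asarray(b, dtype=np.int64))
    c = np.atleast_1d(np.asarray(c, dtype=np.int64))
    d = np.atleast_1d(np.asarray(d, dtype=np.int64))
    if np.any((a < 0) | (b < 0) | (c < 0) | (d < 0)):
        raise ValueError("negative cell count")

    row1 = a + b  # draws
    col1 = a + c  # successes in population
    n = a + b + c + d
    lo = np.maximum(0, col1 - (c + d))
    hi = np.minimum(col1, row1)
    length = hi - lo + 1

    # flat support: for site i, k runs over [lo_i, hi_i]
    offsets = np.concatenate(([0], np.cumsum(length)))
    total = int(offsets[-1])
    idx = np.repeat(np.arange(len(a)), length)
    k = np.arange(total) - np.repeat(offsets[:-1], length) + lo[idx]

    # log hypergeometric pmf: C(col1, k) C(n-col1, row1-k) / C(n, row1)
    col1_i, n_i, row1_i = col1[idx], n[idx], row1[idx]

    def _lchoose(nn, kk):
        return gammaln(nn + 1) - gammaln(kk + 1) - gammaln(nn - kk + 1)

    logpmf = _lchoose(col1_i, k) + _lchoose(n_i - col1_i, row1_i - k) - _lchoose(n_i, row1_i)
    pmf = np.exp(logpmf)

    obs_flat = offsets[:-1] + (a - lo)
    pmf_obs = pmf[obs_flat]
    include = pmf <= pmf_obs[idx] * (1.0 + _TIE_REL_TOL)
    p = np.bincount(idx, weights=np.where(include, pmf, 0.0), minlength=len(a))
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return p if p.size > 1 else float(p[0])


def site_test(sites: pd.DataFrame) -> pd.DataFrame:
    """Per-site differential test on pooled group counts.

    Adds ``p_value``, ``delta`` (level_B - level_A) and ``direction``
    ({hyper, hypo, none}) columns to a grouped-site table.
    """
    if np.any(sites["total_A"].to_numpy() < 1) or np.any(sites["total_B"].to_numpy() < 1):
        raise ValueError("pooled totals must be >= 1 in both groups")
    out = sites.copy()
    a = sites["meth_A"].to_numpy()
    b = (sites["total_A"] - sites["meth_A"]).to_numpy()
    c = sites["meth_B"].to_numpy()
    d = (sites["total_B"] - sites["meth_B"]).to_numpy()
    out["p_value"] = np.atleast_1d(fisher_exact_2x2(a, b, c, d))
    out["delta"] = out["level_B"] - out["level_A"]
    out["direction"] = np.where(out["delta"] > 0, "hyper", np.where(out["delta"] < 0, "hypo", "none"))
    return out


def region_chi2(meth_A: int, unmeth_A: int, meth_B: int, unmeth_B: int) -> float:
    """Region-level chi-square p on pooled member-site counts.

    Pearson chi-square without continuity correction; falls back to
    Fisher's exact test when any expected cell count is below 5.  A
    degenerate table (zero margin) carries no information and returns 1.0
    with a warning.
    """
    table = np.array([[meth_A, unmeth_A], [meth_B, unmeth_B]], dtype=float)
    if np.any(table < 0) or table[0].sum() < 1 or table[1].sum() < 1:
        raise ValueError("invalid region table")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        warnings.warn("degenerate 2x2 table (zero margin); p set to 1.0", stacklevel=2)
        return 1.0
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    if np.any(expected < 5):
        return float(fisher_exact_2x2(meth_A, unmeth_A, meth_B, unmeth_B))
    _, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(p)


def _close_chain(chain: list[int], tested: pd.DataFrame, params: DmrParams, records: list[dict]) -> None:
    if len(chain) < params.min_sites:
        return
    sub = tested.iloc[chain]
    mA, tA = int(sub["meth_A"].sum()), int(sub["total_A"].sum())
    mB, tB = int(sub["meth_B"].sum()), int(sub["total_B"].sum())
    level_A, level_B = mA / tA, mB / tB
    delta = level_B - level_A
    if abs(delta) < params.min_delta:
        return
    p = region_chi2(mA, tA - mA, mB, tB - mB)
    if p > params.alpha_region:
        return
    pos = sub["pos"].to_numpy()
    records.append(
        {
            "chrom": sub["chrom"].iloc[0],
            "start": int(pos[0]) - 1,  # 0-based half-open
            "end": int(pos[-1]),
            "n_sites": len(chain),
            "direction": sub["direction"].iloc[0],
            "level_A": level_A,
            "level_B": level_B,
            "delta": delta,
            "chi2_p": p,
        }
    )


def call_dmrs(tested_sites: pd.DataFrame, params: DmrParams = DmrParams()) -> pd.DataFrame:
    """Merge tested candidate sites into candidate DMRs (pre-FDR).

    ``tested_sites`` must be the output of :func:`site_test`, sorted by
    (chrom, pos).  Returns one row per candidate region passing the site
    count, gap, direction, chi-square and effect-size criteria; q-values
    are attached later by :func:`finalize_dmrs`.
    """
    t = tested_sites.reset_index(drop=True)
    pos_sorted = t.groupby("chrom", sort=False)["pos"].apply(lambda s: bool(s.is_monotonic_increasing))
    if not pos_sorted.all():
        raise ValueError("sites must be sorted by (chrom, pos)")

    records: list[dict] = []
    for _, chrom_df in t.groupby("chrom", sort=True):
        cd = chrom_df.reset_index(drop=True)
        sig = (cd["p_value"] < params.alpha_site).to_numpy()
        direction = cd["direction"].to_numpy()
        pos = cd["pos"].to_numpy()
        n = len(cd)
        i = 0
        while i < n:
            if not sig[i] or direction[i] == "none":
                i += 1
                continue
            # seed a chain at i
            chain = [i]
            j = i + 1
            while j < n:
                if pos[j] - pos[j - 1] > params.max_gap:
                    break
                if not sig[j]:
                    if params.allow_nonsig_gaps:
                        j += 1
                        continue
                    break
                if direction[j] != direction[i]:
                    break
                chain.append(j)
                j += 1
            _close_chain(chain, cd, params, records)
            # resume at the breaking site (it may itself seed a new chain)
            i = max(j, chain[-1] + 1)

    cols = ["chrom", "start", "end", "n_sites", "direction", "level_A", "level_B", "delta", "chi2_p"]
    if not records:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame.from_records(records)[cols]


def adjust_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([])
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def finalize_dmrs(dmrs: pd.DataFrame, q_threshold: float = 0.01) -> pd.DataFrame:
    """Attach BH q-values to candidate regions and keep q < threshold."""
    if len(dmrs) == 0:
        out = dmrs.copy()
        out["q_value"] = pd.Series(dtype=float)
        return out
    out = dmrs.copy()
    out["q_value"] = adjust_fdr(out["chi2_p"].to_numpy())
    out = out[out["q_value"] < q_threshold].reset_index(drop=True)
    return out


def write_dmr_bed(dmrs: pd.DataFrame, path: str, header_comment: str | None = None) -> None:
    """Write DMRs as BED6+ (score = -10*log10 q, capped at 1000)."""
    bed = pd.DataFrame(
        {
            "chrom": dmrs["chrom"],
            "start": dmrs["start"].astype(int),
            "end": dmrs["end"].astype(int),
            "name": [f"DMR_{k + 1}" for k in range(len(dmrs))],
            "score": np.minimum(1000, np.round(-10 * np.log10(np.maximum(dmrs.get("q_value", pd.Series(np.ones(len(dmrs)))), 1e-100)))).astype(int),
            "strand": ".",
            "n_sites": dmrs["n_sites"].astype(int),
            "level_A": dmrs["level_A"],
            "level_B": dmrs["level_B"],
            "delta": dmrs["delta"],
            "chi2_p": dmrs["chi2_p"],
            "q_value": dmrs.get("q_value", np.nan),
        }
    )
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        bed.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def chromosome_summary(dmrs: pd.DataFrame) -> pd.DataFrame:
    """Per-chromosome DMR counts, split by direction."""
    if len(dmrs) == 0:
        return pd.DataFrame(columns=["chrom", "n_dmrs", "n_hyper", "n_hypo"])
    g = dmrs.groupby("chrom")
    return pd.DataFrame(
        {
            "n_dmrs": g.size(),
            "n_hyper": g.apply(lambda d: int((d["direction"] == "hyper").sum()), include_groups=False),
            "n_hypo": g.apply(lambda d: int((d["direction"] == "hypo").sum()), include_groups=False),
        }
    ).reset_index()
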