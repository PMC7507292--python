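"""Synthetic multi-omics inputs with planted ground truth.

Generates all pipeline inputs — per-sample bisulfite call tables, a gene
annotation table, group assignments, an expression matrix, a lipid
feature matrix, a qPCR CT table and an unmethylated spike-in contig —
with known planted signals, so that every analysis stage can be verified
end to end without any external data.

The default configuration mirrors a two-group animal study: 16 animals
per group (treatment vs control), of which 4 per group are profiled by
targeted bisulfite sequencing at ~30x depth; clustered CpGs with
beta-distributed baseline methylation and binomial read counts; planted
contiguous differentially methylated regions (8 CpGs, 100 bp spacing,
methylation shift 0.3); log-normal expression with 2-fold planted genes;
log-normal lipid intensities with 3-fold planted features; gene-lipid
pairs coupled through a latent factor; a 7+7 qPCR design with a 2-fold
true effect; and a spike-in with a 1.23% conversion-failure rate (i.e. a
98.77% conversion rate).

Every generator draws from its own RNG stream derived from the master
seed, so adding or re-running one generator never perturbs the others.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "GroundTruth",
    "simulate_methylomes",
    "simulate_genes",
    "simulate_expression",
    "simulate_lipidome",
    "simulate_links",
    "simulate_spikein",
    "simulate_qpcr",
    "simulate_all",
    "write_inputs",
]

_STREAMS = {
    "methylome": 1,
    "genes": 2,
    "expression": 3,
    "lipidome": 4,
    "links": 5,
    "spikein": 6,
    "qpcr": 7,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STREAMS[stream]])


@dataclass
class GenomeConfig:
    n_chroms: int = 2
    chrom_length: int = 5_000_000


@dataclass
class CpGConfig:
    n_sites: int = 20_000
    spacing_mean: float = 80.0        # geometric inter-CpG gap, bp
    beta_a: float = 2.0               # baseline methylation Beta(a, b)
    beta_b: float = 2.0
    depth_mean: float = 30.0          # Poisson sequencing depth per sample
    n_planted_dmrs: int = 20
    dmr_n_sites: int = 8
    dmr_spacing: int = 100            # bp between planted CpGs
    dmr_delta: float = 0.3            # group-B methylation shift


@dataclass
class ExprConfig:
    n_genes: int = 2000
    log_mean: float = 2.0             # natural-log FPKM location
    log_sd: float = 1.2
    n_planted_degs: int = 100
    planted_fc: float = 2.0
    noise_cv: float = 0.3


@dataclass
class LipidConfig:
    n_features: int = 500
    log_mean: float = 12.0            # natural-log intensity location
    log_sd: float = 1.0
    n_planted: int = 20
    planted_fc: float = 3.0
    noise_cv: float = 0.3


@dataclass
class LinkConfig:
    n_pairs: int = 10
    latent_r: float = 0.9


@dataclass
class SpikeInConfig:
    contig: str = "lambda_spike"
    n_sites: int = 5000
    depth_mean: float = 30.0
    failure_prob: float = 0.0123      # -> 98.77% conversion rate


@dataclass
class QpcrConfig:
    genes: tuple[str, ...] = ("ALOX15", "CXCL10", "NNMT")
    true_fc: float = 2.0
    ct_sd: float = 0.3
    n_per_group: int = 7
    ref_gene: str = "GAPDH"


@dataclass
class SimConfig:
    seed: int = 0
    n_samples_per_group: int = 16     # whole-cohort size (expression, lipids)
    meth_samples_per_group: int = 4   # bisulfite-profiled subset
    n_genes_annot: int = 400          # annotated gene models on the genome
    group_labels: tuple[str, str] = ("CON", "LDA")
    genome: GenomeConfig = field(default_factory=GenomeConfig)
    cpg: CpGConfig = field(default_factory=CpGConfig)
    expr: ExprConfig = field(default_factory=ExprConfig)
    lipid: LipidConfig = field(default_factory=LipidConfig)
    links: LinkConfig = field(default_factory=LinkConfig)
    spikein: SpikeInConfig = field(default_factory=SpikeInConfig)
    qpcr: QpcrConfig = field(default_factory=QpcrConfig)


@dataclass
class GroundTruth:
    """Planted signals, consistent with the emitted data files."""

    dmrs: pd.DataFrame = None          # chrom, start, end, direction, delta (0-based half-open)
    degs: pd.DataFrame = None          # gene_id, fc
    lipids: pd.DataFrame = None        # feature_id, fc
    pairs: pd.DataFrame = None         # gene_id, lipid_id, latent_r
    qpcr_fc: dict = None

    def to_json(self) -> str:
        def df(d):
            return [] if d is None else d.to_dict(orient="records")
        return json.dumps(
            {
                "dmrs": df(self.dmrs),
                "degs": df(self.degs),
                "lipids": df(self.lipids),
                "pairs": df(self.pairs),
                "qpcr_fc": self.qpcr_fc or {},
            },
            indent=1,
        )


def _sample_names(config: SimConfig, n_per_group: int | None = None) -> tuple[list[str], dict[str, str]]:
    n = config.n_samples_per_group if n_per_group is None else n_per_group
    a, b = config.group_labels
    names = [f"{a}_{i + 1}" for i in range(n)] + [f"{b}_{i + 1}" for i in range(n)]
    groups = {s: (a if s.startswith(a + "_") else b) for s in names}
    return names, groups


def simulate_methylomes(config: SimConfig) -> tuple[dict[str, pd.DataFrame], GroundTruth]:
    """Per-sample CpG call tables with planted DMRs.

    Site positions follow geometric spacing (mean ~80 bp, so <=300 bp
    merge gaps arise naturally); baseline methylation pi_i ~ Beta(a, b)
    shared by all samples; depth ~ Poisson(mean); methylated reads ~
    Binomial(depth, pi).  Inside planted regions group B's pi is shifted
    by +/- delta; baselines there are drawn uniformly away from the [0,1]
    boundary so the full shift is realised without clipping.
    """
    cfg = config.cpg
    rng = _rng(config.seed, "methylome")
    n_chroms = config.genome.n_chroms
    sites_per_chrom = [cfg.n_sites // n_chroms] * n_chroms
    sites_per_chrom[-1] += cfg.n_sites - sum(sites_per_chrom)

    # distribute planted DMRs across chromosomes
    planted_per_chrom = rng.multinomial(cfg.n_planted_dmrs, [1 / n_chroms] * n_chroms)

    chroms, positions, pi_A, pi_B = [], [], [], []
    truth_rows = []
    for ci in range(n_chroms):
        chrom = f"chr{ci + 1}"
        n_sites = sites_per_chrom[ci]
        n_planted = int(planted_per_chrom[ci])
        # choose which site indices start a planted block, leaving room
        block = cfg.dmr_n_sites
        starts = []
        if n_planted > 0:
            slots = np.sort(rng.choice(n_sites // (3 * block), size=n_planted, replace=False))
            starts = list(slots * 3 * block + block)  # block starts, >=2 blocks apart
        gaps = rng.geometric(1.0 / cfg.spacing_mean, size=n_sites)
        pos = 1000 + np.cumsum(gaps)
        base = rng.beta(cfg.beta_a, cfg.beta_b, size=n_sites)
        pa = base.copy()
        pb = base.copy()
        for s in starts:
            idx = np.arange(s, s + block)
            # rewrite the block's positions to the planted spacing
            pos[idx] = pos[s] + np.arange(block) * cfg.dmr_spacing
            # shift everything after so coordinates stay increasing
            if s + block < n_sites:
                delta_pos = pos[s + block - 1] + gaps[s + block] - pos[s + block]
                pos[s + block:] += max(0, delta_pos)
            direction = rng.choice(["hyper", "hypo"])
            lo, hi = (0.15, 0.85 - cfg.dmr_delta) if direction == "hyper" else (0.15 + cfg.dmr_delta, 0.85)
            b0 = rng.uniform(lo, hi, size=block)
            pa[idx] = b0
            pb[idx] = b0 + cfg.dmr_delta if direction == "hyper" else b0 - cfg.dmr_delta
            truth_rows.append(
                {
                    "chrom": chrom,
                    "start": int(pos[idx[0]]) - 1,
                    "end": int(pos[idx[-1]]),
                    "direction": direction,
                    "delta": cfg.dmr_delta if direction == "hyper" else -cfg.dmr_delta,
                    "n_sites": block,
                }
            )
        chroms.append(np.full(n_sites, chrom, dtype=object))
        positions.append(pos)
        pi_A.append(pa)
        pi_B.append(pb)

    chrom_arr = np.concatenate(chroms)
    pos_arr = np.concatenate(positions)
    pa_arr = np.concatenate(pi_A)
    pb_arr = np.concatenate(pi_B)

    names, _ = _sample_names(config, config.meth_samples_per_group)
    a_label = config.group_labels[0]
    tables: dict[str, pd.DataFrame] = {}
    for s in names:
        pi = pa_arr if s.startswith(a_label + "_") else pb_arr
        depth = rng.poisson(cfg.depth_mean, size=len(pos_arr))
        covered = depth > 0
        meth = rng.binomial(depth[covered], pi[covered])
        tables[s] = pd.DataFrame(
            {
                "chrom": chrom_arr[covered],
                "pos": pos_arr[covered].astype(int),
                "strand": "+",
                "context": "CpG",
                "meth_reads": meth,
                "total_reads": depth[covered],
            }
        )

    truth = GroundTruth(dmrs=pd.DataFrame(truth_rows, columns=["chrom", "start", "end", "direction", "delta", "n_sites"]))
    return tables, truth


def simulate_genes(config: SimConfig) -> pd.DataFrame:
    """Random gene models tiled along the simulated chromosomes."""
    rng = _rng(config.seed, "genes")
    rows = []
    per_chrom = config.n_genes_annot // config.genome.n_chroms
    for ci in range(config.genome.n_chroms):
        chrom = f"chr{ci + 1}"
        starts = np.sort(rng.choice(np.arange(5000, config.genome.chrom_length - 60_000), size=per_chrom, replace=False))
        lengths = rng.integers(2_000, 50_000, size=per_chrom)
        strands = rng.choice(["+", "-"], size=per_chrom)
        for k in range(per_chrom):
            start, end = int(starts[k]), int(starts[k] + lengths[k])
            strand = strands[k]
            tss = start if strand == "+" else end
            rows.append((f"GENE_{chrom}_{k + 1}", chrom, strand, tss, start, end))
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "strand", "tss", "start", "end"])


def simulate_expression(config: SimConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """FPKM-like genes x samples matrix with planted fold changes."""
    cfg = config.expr
    rng = _rng(config.seed, "expression")
    names, _ = _sample_names(config)
    n = len(names)
    gene_ids = [f"G{i + 1:05d}" for i in range(cfg.n_genes)]
    base = np.exp(rng.normal(cfg.log_mean, cfg.log_sd, size=cfg.n_genes))
    fc = np.ones(cfg.n_genes)
    planted_idx = rng.choice(cfg.n_genes, size=cfg.n_planted_degs, replace=False) if cfg.planted_fc != 1.0 and cfg.n_planted_degs > 0 else np.array([], dtype=int)
    if planted_idx.size:
        up = rng.random(planted_idx.size) < 0.5
        fc[planted_idx] = np.where(up, cfg.planted_fc, 1.0 / cfg.planted_fc)
    sigma = np.sqrt(np.log1p(cfg.noise_cv**2))
    b_label = config.group_labels[1]
    cols = {}
    for s in names:
        mult = fc if s.startswith(b_label + "_") else np.ones(cfg.n_genes)
        noise = np.exp(rng.normal(-sigma**2 / 2, sigma, size=cfg.n_genes))
        cols[s] = base * mult * noise
    mat = pd.DataFrame(cols, index=gene_ids)
    truth = GroundTruth(degs=pd.DataFrame({"gene_id": np.array(gene_ids)[planted_idx], "fc": fc[planted_idx]}))
    return mat, truth


def simulate_lipidome(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Lipid intensities (features x samples) + feature metadata (m/z, RT, mode)."""
    cfg = config.lipid
    rng = _rng(config.seed, "lipidome")
    names, _ = _sample_names(config)
    ids = [f"L{i + 1:04d}" for i in range(cfg.n_features)]
    meta = pd.DataFrame(
        {
            "feature_id": ids,
            "mz": rng.uniform(200, 1200, size=cfg.n_features),
            "rt": rng.uniform(0, 26, size=cfg.n_features),
            "mode": rng.choice(["ESI+", "ESI-"], size=cfg.n_features),
        }
    )
    base = np.exp(rng.normal(cfg.log_mean, cfg.log_sd, size=cfg.n_features))
    fc = np.ones(cfg.n_features)
    planted_idx = rng.choice(cfg.n_features, size=cfg.n_planted, replace=False) if cfg.n_planted > 0 and cfg.planted_fc != 1.0 else np.array([], dtype=int)
    if planted_idx.size:
        # mostly down in the treated group, as in serum lipid depletion
        down = rng.random(planted_idx.size) < 0.7
        fc[planted_idx] = np.where(down, 1.0 / cfg.planted_fc, cfg.planted_fc)
    sigma = np.sqrt(np.log1p(cfg.noise_cv**2))
    b_label = config.group_labels[1]
    cols = {}
    for s in names:
        mult = fc if s.startswith(b_label + "_") else np.ones(cfg.n_features)
        noise = np.exp(rng.normal(-sigma**2 / 2, sigma, size=cfg.n_features))
        cols[s] = base * mult * noise
    mat = pd.DataFrame(cols, index=ids)
    truth = GroundTruth(lipids=pd.DataFrame({"feature_id": np.array(ids)[planted_idx], "fc": fc[planted_idx]}))
    return mat, meta, truth


def simulate_links(
    config: SimConfig, expr: pd.DataFrame, lipids: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Couple selected gene-lipid pairs through a shared latent factor.

    Both members of a pair are rebuilt on the log scale as
    sqrt(r)*z + sqrt(1-r)*e with a shared standard-normal latent z, giving
    expected pairwise correlation ~= latent_r, then mapped back to the
    original log-mean/SD.  Returns modified copies of both matrices.
    """
    cfg = config.links
    rng = _rng(config.seed, "links")
    names = list(expr.columns)
    n = len(names)
    genes = rng.choice(expr.index.to_numpy(), size=cfg.n_pairs, replace=False)
    feats = rng.choice(lipids.index.to_numpy(), size=cfg.n_pairs, replace=False)
    expr2, lipids2 = expr.copy(), lipids.copy()
    a = np.sqrt(cfg.latent_r)
    b = np.sqrt(max(0.0, 1.0 - cfg.latent_r))
    for g, f in zip(genes, feats):
        z = rng.standard_normal(n)
        for mat, key in ((expr2, g), (lipids2, f)):
            logv = np.log(mat.loc[key].to_numpy(dtype=float) + 1e-9)
            mu, sd = logv.mean(), logv.std()
            sd = sd if sd > 0 else 0.3
            e = rng.standard_normal(n)
            mat.loc[key] = np.exp(mu + sd * (a * z + b * e))
    truth = GroundTruth(pairs=pd.DataFrame({"gene_id": genes, "lipid_id": feats, "latent_r": cfg.latent_r}))
    return expr2, lipids2, truth


def simulate_spikein(config: SimConfig) -> pd.DataFrame:
    """Unmethylated control contig: residual methylated calls = conversion failures."""
    cfg = config.spikein
    rng = _rng(config.seed, "spikein")
    pos = 100 + np.cumsum(rng.integers(5, 40, size=cfg.n_sites))
    depth = np.maximum(1, rng.poisson(cfg.depth_mean, size=cfg.n_sites))
    meth = rng.binomial(depth, cfg.failure_prob)
    context = rng.choice(["CpG", "CHG", "CHH"], size=cfg.n_sites, p=[0.2, 0.3, 0.5])
    return pd.DataFrame(
        {
            "chrom": cfg.contig,
            "pos": pos.astype(int),
            "strand": "+",
            "context": context,
            "meth_reads": meth,
            "total_reads": depth,
        }
    )


def simulate_qpcr(config: SimConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """CT table for a 7+7 design with a reference gene and true fold changes."""
    cfg = config.qpcr
    rng = _rng(config.seed, "qpcr")
    a, b = config.group_labels
    rows = []
    for gene in cfg.genes:
        base_dct = rng.uniform(3, 8)  # target minus reference, control scale
        for grp in (a, b):
            for i in range(cfg.n_per_group):
                ct_ref = rng.normal(18.0, cfg.ct_sd)
                shift = -np.log2(cfg.true_fc) if grp == b else 0.0
                ct_t = ct_ref + base_dct + shift + rng.normal(0, cfg.ct_sd)
                rows.append((f"{grp}_{i + 1}", grp, gene, round(ct_t, 4), round(ct_ref, 4)))
    table = pd.DataFrame(rows, columns=["sample", "group", "gene", "ct_target", "ct_ref"])
    truth = GroundTruth(qpcr_fc={g: cfg.true_fc for g in cfg.genes})
    return table, truth


def simulate_all(config: SimConfig) -> dict:
    """Run every generator; returns a dict of all inputs plus merged truth."""
    meth, t_dmr = simulate_methylomes(config)
    genes = simulate_genes(config)
    expr, t_deg = simulate_expression(config)
    lipids, lipid_meta, t_lip = simulate_lipidome(config)
    expr, lipids, t_links = simulate_links(config, expr, lipids)
    spike = simulate_spikein(config)
    ct, t_q = simulate_qpcr(config)
    truth = GroundTruth(dmrs=t_dmr.dmrs, degs=t_deg.degs, lipids=t_lip.lipids, pairs=t_links.pairs, qpcr_fc=t_q.qpcr_fc)
    _, meth_groups = _sample_names(config, config.meth_samples_per_group)
    _, all_groups = _sample_names(config)
    return {
        "methylomes": meth,
        "meth_groups": meth_groups,
        "genes": genes,
        "expression": expr,
        "lipids": lipids,
        "lipid_meta": lipid_meta,
        "groups": all_groups,
        "spikein": spike,
        "qpcr": ct,
        "truth": truth,
    }


def write_inputs(data: dict, outdir: str | Path) -> None:
    """Emit all simulated inputs as plain-text files plus truth.json."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    calls = out / "calls"
    calls.mkdir(exist_ok=True)
    for s, df in data["methylomes"].items():
        df.to_csv(calls / f"{s}.tsv", sep="\t", index=False)
    data["spikein"].to_csv(out / "spikein.tsv", sep="\t", index=False)
    data["genes"].to_csv(out / "genes.tsv", sep="\t", index=False)
    pd.DataFrame(
        {"sample": list(data["groups"]), "group": list(data["groups"].values())}
    ).to_csv(out / "groups.tsv", sep="\t", index=False)
    data["expression"].rename_axis("gene_id").to_csv(out / "fpkm.tsv", sep="\t", float_format="%.6g")
    lip = data["lipid_meta"].set_index("feature_id").join(data["lipids"]).reset_index()
    lip.to_csv(out / "lipids.csv", index=False, float_format="%.6g")
    data["qpcr"].to_csv(out / "ct.tsv", sep="\t", index=False)
    (out / "truth.json").write_text(data["truth"].to_json())
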