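"""End-to-end orchestration: simulate -> pool -> call -> annotate -> DEG ->
lipids -> network -> qPCR, from one configuration object.

`run_pipeline` writes every stage's output under one run directory and a
machine-readable `summary.json` with per-stage counts and all thresholds
used.  Outputs embed the configuration hash and package version in a
header comment, so a run directory is self-describing.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotate import associate_dmrs, dmrg_genes
from .deg import filter_degs
from .dmr import DmrParams, call_dmrs, chromosome_summary, finalize_dmrs, site_test, write_dmr_bed
from .lipidomics import filter_lipids, fit_oplsda, preprocess
from .methcore import conversion_rate, pool_and_select_candidates, write_grouped_sites
from .network import build_network, node_table, write_cytoscape_edges, write_sif
from .qpcr import qpcr_report
from .simulate import SimConfig, simulate_all, write_inputs

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All stage thresholds (defaults are the published values) plus the seed."""

    seed: int = 0
    min_depth: int = 5
    depth_mode: str = "per-sample"
    alpha_site: float = 0.05
    max_gap: int = 300
    min_sites: int = 5
    min_delta: float = 0.20
    alpha_region: float = 0.05
    dmr_fdr: float = 0.01
    promoter_up: int = 2000
    promoter_down: int = 1000
    fc_thresh: float = 1.5
    deg_fdr: float = 0.05
    vip_thresh: float = 1.0
    lipid_alpha: float = 0.05
    lipid_adjust: str = "fdr"
    n_orthogonal: int = 1
    scaling: str = "pareto"
    r_thresh: float = 0.50
    edge_alpha: float = 0.05
    sim: SimConfig = field(default_factory=SimConfig)

    def __post_init__(self):
        if isinstance(self.sim, dict):
            self.sim = SimConfig(**self.sim)
        if self.sim.seed != self.seed:
            self.sim = dataclasses.replace(self.sim, seed=self.seed)
        for name, lo, hi in [
            ("alpha_site", 0, 1), ("alpha_region", 0, 1), ("dmr_fdr", 0, 1),
            ("deg_fdr", 0, 1), ("lipid_alpha", 0, 1), ("edge_alpha", 0, 1),
            ("min_delta", 0, 1),
        ]:
            v = getattr(self, name)
            if not (lo < v <= hi):
                raise ValueError(f"{name}={v} out of range ({lo}, {hi}]")

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run every stage in dependency order; returns the summary dict.

    The run directory receives the simulated inputs (under ``inputs/``),
    each stage's output table, and ``summary.json``.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    tag = f"methdmr v{__version__} config={config.config_hash()} seed={config.seed}"
    logger.info("pipeline start: %s", tag)

    # --- simulate all inputs
    data = simulate_all(config.sim)
    write_inputs(data, out / "inputs")
    a_label, b_label = config.sim.group_labels

    # --- spike-in conversion QC
    qc = conversion_rate(data["spikein"])

    # --- methylation: pool, test, call, finalize
    sites = pool_and_select_candidates(
        data["methylomes"], data["meth_groups"], min_depth=config.min_depth,
        depth_mode=config.depth_mode, group_order=[a_label, b_label],
    )
    write_grouped_sites(sites, str(out / "sites.tsv"), header_comment=tag)
    tested = site_test(sites)
    params = DmrParams(
        alpha_site=config.alpha_site, max_gap=config.max_gap, min_sites=config.min_sites,
        min_delta=config.min_delta, alpha_region=config.alpha_region,
    )
    candidates = call_dmrs(tested, params)
    dmrs = finalize_dmrs(candidates, q_threshold=config.dmr_fdr)
    dmrs = dmrs.assign(name=[f"DMR_{k + 1}" for k in range(len(dmrs))])
    write_dmr_bed(dmrs, str(out / "dmrs.bed"), header_comment=tag)
    chromosome_summary(dmrs).to_csv(out / "dmr_by_chrom.tsv", sep="\t", index=False)

    # --- annotation
    links = associate_dmrs(dmrs, data["genes"], up=config.promoter_up, down=config.promoter_down)
    links.to_csv(out / "dmr_gene_links.tsv", sep="\t", index=False)
    dmrgs = dmrg_genes(links)
    (out / "dmrg_genes.txt").write_text("\n".join(dmrgs) + ("\n" if dmrgs else ""))

    # --- differential expression
    degs = filter_degs(
        data["expression"], data["groups"], fc_thresh=config.fc_thresh,
        q_thresh=config.deg_fdr, group_order=[a_label, b_label],
    )
    degs.to_csv(out / "degs.tsv", sep="\t", index=False, float_format="%.6g")
    deg_ids = degs.loc[degs["status"] != "ns", "gene_id"].tolist()

    # --- lipidomics: OPLS-DA + VIP filter
    y = np.array([1.0 if g == b_label else -1.0 for g in data["groups"].values()])
    scaled = preprocess(data["lipids"], scaling=config.scaling, log_transform=True)
    model = fit_oplsda(scaled.to_numpy(), y, n_orthogonal=config.n_orthogonal)
    lipid_table = filter_lipids(
        data["lipids"], data["groups"], model.vip, alpha=config.lipid_alpha,
        vip_thresh=config.vip_thresh, adjust=config.lipid_adjust,
        group_order=[a_label, b_label],
    )
    lipid_table.to_csv(out / "lipids_diff.tsv", sep="\t", index=False, float_format="%.6g")
    pd.DataFrame(
        {"sample": list(data["groups"]), "t_pred": model.t_pred,
         "t_orth1": model.t_orth[:, 0] if model.n_orthogonal else np.nan}
    ).to_csv(out / "oplsda_scores.tsv", sep="\t", index=False, float_format="%.6g")
    diff_lipids = lipid_table.loc[lipid_table["significant"], "feature_id"].tolist()

    # --- correlation network on DEG x differential-lipid profiles
    if deg_ids and diff_lipids:
        edges = build_network(
            data["expression"].loc[deg_ids], data["lipids"].loc[diff_lipids],
            r_thresh=config.r_thresh, alpha=config.edge_alpha,
        )
    else:
        edges = pd.DataFrame(columns=["gene_id", "lipid_id", "r", "p_value", "n", "sign", "weight"])
    write_cytoscape_edges(edges, str(out / "network_edges.tsv"), header_comment=tag)
    write_sif(edges, str(out / "network.sif"))
    node_table(edges).to_csv(out / "network_nodes.tsv", sep="\t", index=False)

    # --- qPCR
    rel, gene_p = qpcr_report(data["qpcr"], control_group=a_label)
    rel.to_csv(out / "qpcr_rel_expr.tsv", sep="\t", index=False, float_format="%.6g")
    gene_p.to_csv(out / "qpcr_group_tests.tsv", sep="\t", index=False, float_format="%.6g")

    summary = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "conversion_rate": round(qc.conversion_rate, 6),
        "n_candidate_sites": int(len(sites)),
        "n_candidate_dmrs": int(len(candidates)),
        "n_dmrs": int(len(dmrs)),
        "n_dmr_gene_links": int(len(links)),
        "n_dmrgs": int(len(dmrgs)),
        "n_degs": int(len(deg_ids)),
        "n_degs_up": int((degs["status"] == "up").sum()),
        "n_degs_down": int((degs["status"] == "down").sum()),
        "n_diff_lipids": int(len(diff_lipids)),
        "n_edges": int(len(edges)),
        "oplsda": {"r2x": round(float(model.r2x), 4), "r2y": round(float(model.r2y), 4),
                   "q2": round(float(model.q2), 4)},
        "qpcr_p": {r["gene"]: round(float(r["p_value"]), 6) for _, r in gene_p.iterrows()},
        "thresholds": {
            k: getattr(config, k)
            for k in ("min_depth", "alpha_site", "max_gap", "min_sites", "min_delta",
                      "alpha_region", "dmr_fdr", "fc_thresh", "deg_fdr", "vip_thresh",
                      "lipid_alpha", "r_thresh", "edge_alpha")
        },
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=1))
    logger.info("pipeline done: %d DMRs, %d DEGs, %d lipids, %d edges",
                summary["n_dmrs"], summary["n_degs"], summary["n_diff_lipids"], summary["n_edges"])
    return summary
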