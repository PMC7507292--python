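"""Assign DMRs to genes through promoter windows and gene bodies.

Promoters are TSS -2000 bp to +1000 bp, strand-aware; a DMR links to a
gene when it overlaps the promoter or the gene body by at least 1 bp.
"""

from methdmr.annotate import associate_dmrs, dmrg_genes
from methdmr.dmr import call_dmrs, finalize_dmrs, site_test
from methdmr.methcore import pool_and_select_candidates
from methdmr.simulate import SimConfig, simulate_genes, simulate_methylomes

cfg = SimConfig(seed=42)
tables, _ = simulate_methylomes(cfg)
genes = simulate_genes(cfg)
groups = {s: s.split("_")[0] for s in tables}

tested = site_test(pool_and_select_candidates(tables, groups, group_order=["CON", "LDA"]))
dmrs = finalize_dmrs(call_dmrs(tested), q_threshold=0.01)

links = associate_dmrs(dmrs, genes, up=2000, down=1000)
print(f"DMRs: {len(dmrs)}   gene models: {len(genes)}")
print(f"DMR-gene links: {len(links)}   DMR-associated genes (DMRGs): {len(dmrg_genes(links))}")
print(links.head().to_string(index=False))
# context says where the DMR falls: the promoter window, the gene body,
# or both; a gene counts once as a DMRG however many DMRs hit it.
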