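"""Gene-lipid Pearson correlation network with |r| > 0.50 and p < 0.05.

Couples a few gene-lipid pairs through a latent factor, then tests all
pairs across the 32 shared samples and keeps the strict-threshold edges.
"""

from methdmr.network import build_network, node_table
from methdmr.simulate import SimConfig, simulate_expression, simulate_lipidome, simulate_links

cfg = SimConfig(seed=42)
expr, _ = simulate_expression(cfg)
lip, _, _ = simulate_lipidome(cfg)
expr, lip, truth = simulate_links(cfg, expr, lip)

# restrict to a small panel: the coupled genes/lipids plus some bystanders
genes = list(truth.pairs["gene_id"]) + list(expr.index[:10])
lipids = list(truth.pairs["lipid_id"]) + list(lip.index[:10])
edges = build_network(expr.loc[genes], lip.loc[lipids], r_thresh=0.50, alpha=0.05)

nodes = node_table(edges)
print(f"pairs tested: {len(genes) * len(lipids)}   edges kept: {len(edges)}")
print(f"nodes: {(nodes['type'] == 'gene').sum()} genes, {(nodes['type'] == 'lipid').sum()} lipids")
planted = set(zip(truth.pairs["gene_id"], truth.pairs["lipid_id"]))
found = planted & set(zip(edges["gene_id"], edges["lipid_id"]))
print(f"planted coupled pairs recovered: {len(found)} / {len(planted)}")
print(edges[["gene_id", "lipid_id", "r", "p_value", "sign"]].head().to_string(index=False))
# Edge sign records whether gene expression and lipid abundance rise
# together (positive) or in opposition (negative); |r| is the edge weight.
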