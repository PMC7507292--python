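"""Run the whole pipeline from one configuration and print the summary.

Simulates all inputs, then runs pooling, DMR calling, annotation,
differential expression, OPLS-DA lipid filtering, the correlation network
and qPCR, writing every stage's table under the run directory.
"""

import json

from methdmr.pipeline import PipelineConfig, run_pipeline

summary = run_pipeline(PipelineConfig(seed=42), "scratch/example_run")
print(json.dumps(summary, indent=1))
# Stage outputs (sites.tsv, dmrs.bed, dmr_gene_links.tsv, degs.tsv,
# lipids_diff.tsv, network_edges.tsv, qpcr_*.tsv) and summary.json are in
# scratch/example_run/; counts above are line counts of those files.
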