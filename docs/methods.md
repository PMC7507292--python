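# Methods

## Scope and data model

The package analyses a two-group design (labelled CON and LDA by default,
i.e. control vs low-dose-antibiotic treatment; any two labels work). Its
inputs are plain-text tables: per-sample, per-cytosine bisulfite call
tables (chrom, 1-based position, strand, context, methylated reads, total
reads; the methratio 7-column dialect with a ratio column is accepted), a
6-column gene table or gene-feature GTF, a sample→group map, a genes ×
samples FPKM-like matrix, a lipid feature matrix with m/z, retention-time
and ion-mode metadata, and a long-format qPCR CT table. Input coordinates
are 1-based; all internal interval arithmetic is 0-based half-open, and
writers convert back (BED output is natively half-open).

## Methylation and candidate sites

The methylation level of a cytosine is methylated reads / total reads.
Candidate sites for differential testing must be covered in *every*
sample of both groups with per-sample depth ≥ `min_depth` (default 5).
The per-sample reading of the depth rule is deliberate — it is stricter
and makes the pooled counts well supported; `depth_mode="per-group-pool"`
implements the laxer reading (common coverage plus pooled group depth
≥ 5). Opposite-strand CpGs are independent sites; no dyad merging is
performed. Non-CpG contexts are parsed but dropped — nothing downstream
consumes them.

Bisulfite conversion rate is computed on an unmethylated spike-in contig
as 1 − Σmeth/Σtotal over all cytosine contexts (CpG and non-CpG alike),
the usual λ-DNA convention: on fully unmethylated DNA every methylated
call is a conversion failure.

## DMR calling

Per-site test: two-sided Fisher's exact test on the pooled 2×2 table.
The test is unspecified in the procedure this implements; Fisher is exact
at the low per-site depths the 5× threshold admits, where the chi-square
approximation is anti-conservative. The implementation is vectorised
(log-gamma hypergeometric pmf over each table's support, "sum of small
p" two-sided rule) with a 1e-11 relative tie tolerance — wide enough to
absorb float error on genuinely tied probabilities, orders of magnitude
below the spacing of distinct hypergeometric masses at realistic depths.

Merging: chains are built left to right per chromosome. A significant
site (p < `alpha_site`, default 0.05) seeds a chain; the chain extends
over subsequent significant sites with the same direction while the gap
to the previous member is ≤ `max_gap` (300 bp). A non-significant
candidate closes the chain and is not a member (the merge criteria are
stated over significant candidate sites only); `allow_nonsig_gaps=True`
enables a skip-over variant. A direction flip closes the chain, and the
flip site may seed the next chain; scanning resumes at whichever site
broke the chain, so members of a failed chain are not re-used — any
restart inside it would close at the same break with fewer members, and
re-pooling sub-chains of a region that failed the downstream filters
would amount to data dredging.

Region filters: chains with ≥ `min_sites` (5) members are tested on
pooled member counts — Pearson chi-square without continuity correction,
falling back to Fisher's exact test whenever any expected cell is < 5;
degenerate tables (zero margin) carry no information and return p = 1
with a warning. Regions are kept when the region p ≤ `alpha_region`
(0.05) and |Δ| ≥ `min_delta` (0.20), where Δ is the difference of
group-pooled means (Σmeth/Σtotal), which weights deep sites more than a
mean of per-site levels. The "< 20% average difference" filter-out rule
is read as a group-mean (not per-sample-pair) criterion. Both
significance statements are applied in sequence: the chi-square screen
at 0.05, then Benjamini–Hochberg across surviving regions at q < 0.01 —
the only reading consistent with a per-region p filter *and* a final FDR
cut. The caller is idempotent on each emitted region's member sites, and
counts are monotone non-increasing in `min_sites` and `min_delta` (both
property-tested).

## Annotation

Promoter windows: on '+', [tss−1−up, tss−1+down) around the 0-based TSS;
on '−' the genomic mirror; clamped at zero; defaults up = 2000,
down = 1000. Association requires ≥ 1 bp overlap (`min_overlap`
configurable) with the promoter window or the 0-based gene body; a DMR
hitting both contexts of one gene yields a single link with context
"both", so DMRG counts never double-count. Multi-row GTF genes collapse
to the most upstream TSS and the union body span.

## Differential expression

The alignment-level count model of FPKM pipelines is out of scope, so the
two-group test is a two-sided Welch t on log2(x+1) values — a deliberate,
documented substitution; DEG lists are therefore not expected to match
any specific count-model output. Fold change is
log2((mean_B+ε)/(mean_A+ε)) with ε = 0.01 FPKM for stability near zero.
Thresholds are strict: |FC| > 1.5 and BH q < 0.05. All-zero genes are
excluded (logged); zero-variance/equal-mean genes get p = 1. The
coefficient of variation uses the sample SD (n−1); the choice of
denominator was unspecified.

## Lipidomics (OPLS-DA + VIP)

Preprocessing centres features and applies Pareto scaling by default
(centered values divided by √SD — the metabolomics convention, damping
high-intensity dominance without inflating near-constant features);
unit-variance scaling is available and drops zero-variance features.

The OPLS fit is the standard single-response orthogonal deflation: from
the current X, w ∝ X'y; the orthogonal weight is the part of the loading
p orthogonal to w; its score/loading pair is removed from X; after k
such deflations (default k = 1, the convention for a binary class) a
single predictive component t = Xw is fitted. With k = 0 this is exactly
the first NIPALS PLS1 component (tested against an independent NIPALS
implementation and scikit-learn). Orthogonal scores have zero sample
covariance with the response by construction (asserted to 1e-8). R2X and
R2Y are fractions of explained variation; Q2 = 1 − PRESS/SS(y) by 7-fold
cross-validation with a seeded permutation of sample order. The CV folds
re-fit the model but reuse the globally scaled matrix; per-fold
re-scaling would be slightly more conservative and is a known
simplification.

VIP with one predictive component reduces to √p·|w_j|/‖w‖, so
mean(VIP²) = 1 exactly; VIP > 1 marks above-average influence. The
differential-lipid filter takes VIP > 1 (strict) AND Welch-t p on log2
intensities below 0.05 — BH-adjusted by default, with `adjust="none"`
reproducing the raw-p variant; both readings exist in practice and both
are supported. ESI+ and ESI− features are analysed jointly with the mode
recorded per feature.

## Correlation network

All (differential gene, differential lipid) pairs are tested across the
shared samples on raw abundances (a log option exists); Pearson r with
the exact t-transform p (n−2 df). Edges need |r| strictly above 0.50 and
p < 0.05 with *no* multiple-testing correction — a liberal choice made
deliberately to match the stated filter; `fdr=True` gives the
conservative variant. Edge weight is |r|; sign records the direction.
Constant profiles are skipped and logged. Outputs are a Cytoscape-ready
edge table, SIF, and a node-type table.

## qPCR (ΔΔCT)

Technical replicates are averaged on the CT scale. ΔCT = CT(target) −
CT(reference); the calibrator is the control group's mean ΔCT per gene
(the "calibrator sample" was unspecified, and the group mean is the
stable choice) or a named sample; RQ = 2^(−ΔΔCT), hence the calibrator
sample's RQ is exactly 1 and RQ is invariant to any constant added to
both of a sample's CTs. Group comparison: two-sided Wilcoxon rank-sum,
exact when both n ≤ 8 with no ties, otherwise the normal approximation
with tie correction; all-tied input returns p = 1.

## Synthetic data

The generator emulates the study design it is meant to exercise: 16
animals per group, of which 4 per group carry methylomes; 2 chromosomes
with ~20,000 clustered CpGs (geometric spacing, mean 80 bp, so ≤300 bp
merge gaps arise naturally); baseline methylation Beta(2,2) shared
across samples (bimodality is not modelled — intermediate levels are the
hardest case for the tests, and promoter-targeted data is depleted of
fully methylated sites anyway); depth Poisson(30) per sample per site
(within the 5–50× band of targeted captures); planted DMRs of 8 CpGs at
100 bp spacing with a ±0.3 shift applied to group B only, baselines
drawn Uniform away from the unit-interval boundary so the full shift is
realisable without clipping. Expression: log-normal baselines, 100 of
2000 genes at 2-fold (random direction), multiplicative log-normal noise
at CV 0.3. Lipids: 500 features, 20 planted at 3-fold (mostly down in
the treated group, as in serum lipid depletion), m/z ∈ [200, 1200], RT ∈
[0, 26] min, random ESI mode. Gene–lipid links: pairs rebuilt on the log
scale as √r·z + √(1−r)·e with a shared latent z, so the sample
correlation approaches the target r (±0.15 at n = 32). Spike-in:
per-read conversion-failure probability 0.0123, i.e. a 98.77% conversion
rate. qPCR: 7 per group, CT noise SD 0.3 cycles, true fold change 2.

Every generator draws from its own RNG stream (`default_rng([seed,
offset])`), so outputs are deterministic per seed and adding a generator
never perturbs the others; emitted files are byte-identical across runs.

What a green test does *not* establish: the generator has no coverage
biases, no correlated errors along reads, no batch effects, no missing
values, no bimodal methylation landscape, no realistic lipid-class
structure, and FPKM noise is log-normal rather than count-based — real
data will be harder on every stage than these simulations are.

## Numerical choices and degenerate inputs

Fisher tie tolerance 1e-11 (above); p-values clipped to [tiny, 1];
BH via statsmodels with q ≥ p guaranteed; zero-coverage sites are a
caller error upstream of the level formula; empty inputs return empty
outputs rather than raising wherever a downstream stage can proceed.
The pipeline embeds the package version and a SHA-256 prefix of its
configuration in every main output's header comment and writes a
summary JSON whose counts equal the line counts of the stage files
(tested).

## Known limitations

No BAM/CX-report ingestion (call tables only); no smoothing or
segmentation-based DMR statistics; no pathway enrichment or lipid
identification (they depend on external database versions); the DEG test
is a documented substitute for count-model machinery; network p-values
are uncorrected by default by design. Headline counts from any real
study (e.g. numbers of DMRs or DEGs) depend on the raw data and
annotation versions and are not reproduced by the synthetic world; the
test suite verifies the *rules*, not those counts.
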