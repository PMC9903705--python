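# Methods

`mptseq` analyses targeted single-cell DNA sequencing of tumors profiled
with a pooled multi-patient amplicon panel: a few hundred amplicons, each
centered on a somatic mutation found by bulk exome sequencing in at least
one patient of a cohort, sequenced to high depth (~100-200x per cell per
amplicon) in thousands of cells per sample. From the per-cell genotype and
read-count matrices it reconstructs the sample's clonal substructure,
per-clone copy-number states, and the mutational lineage tree. This note
describes the models and the numerical choices; nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Data model

Two matrices describe one sample. The genotype bundle holds, per cell and
variant, the genotype code NGT (0 reference, 1 heterozygous, 2 homozygous
alternate, plus a distinct missing sentinel written as `NA` on disk), read
depth DP, genotype quality GQ, and alternate allele fraction AF. The count
bundle holds non-negative integer read counts per cell and amplicon.
Intervals are 0-based half-open internally; VCF positions are converted on
ingest, so a VCF position `p` lies in amplicon `[s, e)` iff `s < p <= e`.

## Quality control

Barcodes are kept as cells when at least 80% of amplicons have nonzero
reads and the total read count exceeds 0.2x the median per-cell total (the
absolute cutoff is unpublished for this assay class; the scale-free form
mirrors the 0.2x rule used for amplicon success).

The genotype cascade then (1) masks entries to missing where GQ < 30,
DP < 10, or an alternate call has AF < 20% (reference calls are not
AF-masked); (2) drops variants genotyped in < 50% of cells; (3) drops cells
genotyped at < 50% of variants; (4) drops variants mutated in < 1% of
genotyped cells; (5) drops germline heterozygous SNPs; (6) drops any
remaining row/column with > 50% missing. Percentage filters are computed
over genotyped entries. Because removing variants changes per-cell
completeness and vice versa, the row/column stages iterate to a fixed
point; this also makes the cascade idempotent, and an audit ledger records
every masked entry count and removed row/column with its stage and rule.

Stage 5 deserves a note. At ~9% allelic dropout a true germline SNP is
heterozygous in only ~91% of cells, so a literal "heterozygous in > 95% of
cells" test can never fire at the assay's own dropout rate. The rule is
therefore implemented as: alternate allele present (NGT 1 or 2) in > 95% of
genotyped cells with heterozygous the dominant mutant state. This removes
germline SNPs robustly to dropout while leaving truncal somatic mutations
(present in at most the tumor fraction of cells) untouched, provided tumor
purity is below the 95% threshold.

Bulk variant tables get the standard consensus filters: at least 3
supporting reads, removal of every member of any mutation cluster within a
10-bp window (the conservative reading of the clustered-region rule), and
NA-flagging of sites under 10x coverage. A mapping-quality floor of 40
applies only when read-level evidence is ingested; with VCF input it is a
no-op.

## Clustering and consensus

Cells are clustered in genotype space with complete-linkage agglomerative
clustering on Euclidean distances, with missing genotypes imputed as
reference for distance purposes only. When the cluster count is not fixed,
k in [2, 8] is chosen by maximum mean silhouette. Clusters smaller than
max(20, 1% of cells) are labeled outliers. The mutation-poorest cluster is
labeled the normal (diploid reference) population when it is clearly poorer
than the richest cluster (zero mutant consensus calls, or fewer than half
of the maximum); otherwise all real clusters are tumor. A PCA -> UMAP
(n_neighbors = 15, a = b = 1; an a = b = 1.2 preset for inter-patient maps)
embedding is produced for reporting only — cluster assignment never
depends on it, because the 2-D projection adds technical dispersion in
highly clonal samples.

Per-cluster consensus genotypes are the modal non-missing code per variant
(ties toward the lower code), with the mutated fraction per variant
reported alongside.

## Copy number

The two-step copy-ratio normalization divides each cell's counts by the
cell's total reads, then each amplicon by the median of that composition
over the normal cells. The result is 1.0 when an amplicon is represented as
in a diploid cell. Two caveats are inherent and documented rather than
hidden: (a) the scale is compositional, so a clone whose efficiency-weighted
mean copy number differs from 2 carries a clone-constant bias (small when
CNA amplicons are a minor panel fraction — with the default 330-amplicon
panel and a handful of events the bias is ~2%); (b) total-content signals
cancel exactly, so doublets are invisible on this scale. For doublet
screening the package therefore also computes a depth-preserving ratio
(per-amplicon normalization against the normal cells' median raw counts,
no per-cell rescaling), on which a doublet sits near 2x.

Cluster medians of the composition ratios, thresholded at |log2| >= 0.32
(~1.25x / 0.8x, configurable; the threshold is a package choice, not a
published constant), give gain/loss calls. Integer copy number for
pseudo-bulk references multiplies segment ratios by a FACS-derived ploidy
(2x the aneuploid-to-diploid peak ratio) and rounds half away from zero;
the consensus is the per-segment median over cells. Segmentation itself is
out of scope: the function accepts precomputed segment ratios.

## Doublet screening

Each non-outlier cluster is summarised by its per-variant mean
depth-preserving ratio and the log2 of its grand mean. The highest cluster
is compared against the cell-count-weighted mean of the remaining tumor
clusters with a one-sided paired t-test across variants. A cluster is
re-labeled doublet when three conditions hold: p below alpha/k (alpha =
0.05 family-wise; the Bonferroni factor k accounts for selecting the
maximum of k clusters), a positive mean difference, and a log2 elevation of
at least 0.5. The effect floor exists because cluster means over hundreds
of cells are so precise that percent-level depth drifts (e.g. same-clone
doublets hiding inside a genuine cluster) are statistically significant;
doublets are a discrete ~2x (log2 = 1) phenomenon, and half that effect is
the natural boundary. The screen runs iteratively (doublets of different
clone pairs can form several clusters) and, because silhouette model
selection can sit at the edge of resolving a small doublet cluster, it also
probes clusterings at k+1..k+3 and keeps the resolution that isolates the
most doublet cells. Under the null every probe fails the effect floor and
the screen is a no-op; the type-I rate of the full procedure is checked by
simulation in the test suite.

Same-clone doublets are genuinely undetectable on the compositional
genotype side and are only caught when they separate by depth; the reported
doublet percentage is therefore an underestimate of the generative rate
(cluster-level screens share this property).

## Lineage reconstruction

Neighbor joining (classical Saitou-Nei) runs on pairwise L1 distances over
cluster consensus genotype codes, with missing entries handled
pairwise-complete (observed distance rescaled by the fraction of
co-observed sites). L1 is used rather than Euclidean because under a
perfect phylogeny the summed genotype-code difference is an additive tree
metric, which NJ provably recovers; Euclidean distances on the same
profiles are not additive and can invert short internal branches. An
ancestor-like clone with no private mutations produces an exactly
zero-length internal branch and a fully tied Q matrix; the implementation
breaks ties deterministically toward the lowest-index pair, which is why NJ
is implemented in-package (~40 lines) rather than delegated — the tree
container, rooting and Newick output use scikit-bio, and scikit-bio's `nj`
serves as an independent cross-check in tests. Negative branch-length
estimates are clamped to zero.

The unrooted tree is rooted on the branch to the normal cluster; the MRCA
is the most rootward node ancestral to all tumor leaves, and deeper
tumor-side ancestors are named A1, A2, ... Mutations and CNA calls are
placed on the branch above the smallest clade containing all carrier
clusters; events carried by every tumor cluster land on the root-to-MRCA
branch (truncal). Carrier sets that are not clades are placed at their LCA
and flagged as conflicts. Within-branch event order is not modeled.

Deleteriousness ranking follows the standard annotation rule: a variant
passes when PolyPhen > 0.8 or (1 - SIFT) > 0.8 (missing scores fail);
passers are ranked by CADD descending, the top 30 retained, and each is
annotated with its phred-scaled CADD percentile band (> 10 top 10%, > 20
top 1%, > 30 top 0.1%).

## Coverage metrics and downsampling

The Gini index uses the mean-absolute-difference form
`sum_ij |x_i - x_j| / (2 n^2 mean)`, computed by the O(n log n) sorted
identity and tested against the O(n^2) oracle. Per-amplicon Gini/CV are
computed across cells and per-cell Gini/CV across amplicons, each averaged
over the sample; CV uses the sample (n-1) SD and is reported in percent.
Allelic dropout is the fraction of genotyped entries at known heterozygous
SNPs called homozygous. An amplicon succeeds when its mean reads exceed
0.2x the grand mean reads per cell per amplicon.

Read-level FASTQ downsampling is replaced by binomial thinning of the count
matrix — the one intentional mechanical substitution in the package, exact
for independent reads. The sensitivity harness downsamples depth, mutations
or cells, reruns the full QC -> cluster -> doublet pipeline at each (level,
seed), and records the number of detected (non-doublet, non-outlier)
clusters; medians over seeds summarise each level.

## Synthetic data

The generator's defaults are the study conditions the pipeline targets:
330 amplicons, 69 somatic variants (15 truncal + 0/8/28 private across
three tumor subclones, i.e. clone totals 15/23/43), 20 germline
heterozygous SNPs, 20% diploid cells, 164x mean depth, 9% allelic dropout,
0.5% genotype error, 8% doublets. Counts are negative-binomial
(Gamma-Poisson, size 10) around mean_depth x amplicon efficiency x CN/2 x
per-cell capture factor. Amplicon efficiencies are lognormal with sigma
0.95 — chosen once because it reproduces the cell-level coverage
inequality characteristic of targeted panels (per-cell Gini ~0.5, CV
~125%) and leaves ~85-90% of amplicons above the success threshold — and
per-cell capture is lognormal sigma 0.3, which drives amplicon-level
inequality (Gini ~0.28, CV ~45%). Doublets sum their two parents'
expected counts (~2x content). ADO converts heterozygous sites to a random
homozygous call symmetrically; errors shift the call to a random other
code and are given low GQ so that roughly half are caught by the GQ mask.
All tumor clones beyond the first are children of the first tumor clone,
which gives nested mutation sets (perfect phylogeny, no back mutation).

What the generator does not emulate — and hence what green tests do not
certify on real data: locus-specific amplification bias beyond a static
efficiency, allele-specific amplification correlated across cells, barcode
collisions/ambient DNA, CNA breakpoints inside amplicons, and vendor
pipeline idiosyncrasies in genotype-quality calibration. The benchmark
quantities (ARI, copy-ratio error, flag rates) therefore measure the
implementation under its own generative assumptions.

## Problem sizes and tolerances

Benchmark fits use 4,000 cells x 330 amplicons; the doublet screen's
operating characteristics use 20 simulated samples of 2,000 cells per
condition; downsampling uses 10 seeds per level in the test suite and 5 in
the acceptance script. Copy-ratio recovery is asserted to ±0.15 of CN/2
for clusters of >= 200 cells; the ADO estimate to ±0.02 at a true rate of
0.09; Gini to 1e-12 of the pairwise oracle; noise-free VAF concordance to
Pearson r >= 0.999. Stochastic stages all derive their seeds from a master
seed (SHA-256 of seed + stage name, below 2^31), making pipeline reruns
bit-identical.
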