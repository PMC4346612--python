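# Methods

This note records the models behind each stage, the parameters that matter,
what the synthetic data does and does not emulate, and the numerical choices
made where the design was genuinely open.

## Coordinates and formats

All internal coordinates are 0-based half-open; GTF I/O converts from the
format's 1-based closed convention. The TSS of a gene model is the
strand-aware 5′ end of the merged-exon span (for a minus-strand gene, the
0-based exclusive end coordinate). Chromosome names are normalized by
stripping any `chr` prefix on read, and writers emit the stripped
(Ensembl-style) names; we deliberately do not track the input dialect per
object. Coverage is carried as dense per-base float arrays per chromosome;
bedGraph/fixed-step-wiggle readers refuse unsorted or negative input rather
than silently repairing it, and the writers round-trip float depths
bit-identically (values are placed, not re-accumulated, when records do not
overlap).

## Expression quantification

Read counts per feature are estimated as (per-base coverage sum) /
(read length, default 75 bp). This keeps the pipeline alignment-free while
preserving the proportionality RPKM needs; duplicate and multi-mapped reads
are whatever the upstream track contains. The RPKM normalizer for a library
is the coding-exon read total after removing, in order, mitochondrial-genome
exons, ribosomal-protein-gene exons, and the top ceil(0.005·n) of the
remaining coding exons ranked by provisional RPKM (ties broken by
chromosome and start for determinism). Gene RPKM uses the merged-exon count
over the total exonic length; exon and intron RPKM are analogous over their
own lengths; `normalized_coverage` is mean per-base depth per million
included reads, and `breadth` the fraction of bases covered at least once.
Junction RPKM uses a configurable effective length, defaulting to the read
length (the span a junction-crossing read can occupy); the original effective
length is not published, so the default is ours and exposed.

## Differential expression and isoforms

The two-library test is an Audic–Claverie-style conditional binomial: for
counts x_A, x_B with included-read totals N_A, N_B, x_A is referred to
Binomial(x_A + x_B, N_A/(N_A + N_B)) with a doubled-tail two-sided p-value,
followed by Benjamini–Hochberg correction. The upper tail is evaluated as
the mirrored lower tail of the complementary count so that swapping the two
samples is bitwise symmetric. The statistic of the original in-house tool is
unpublished; this is the standard substitute for count data conditioned on
library totals, and whether its FDR was BH or empirical is likewise
unstated — BH is used. Defaults: FDR 0.015, min RPKM 0.005, min reads 25.

Cassette-exon isoform events are DE exons expressed in exactly one of the
two samples by the gene-relative bands: expressed ≥ 10% of gene RPKM,
silent ≤ 1%, with the 1–10% band discarded as a false-positive filter. DE
genes are removed from the isoform list. Junction support marks a call when
any junction touching the exon has RPKM > 0.1 on the expressed side and
< 0.1 on the silent side. Multi-donor overlaps use the upper-tail
hypergeometric probability with the universe = features tested in all pairs.

## Intron retention

Retained introns pass four joint rules in one sample: RPKM > 1 (expression
prefilter), RPKM > 5% of the (protein-coding) gene RPKM, normalized
coverage > 30% of the flanking merged exons', and breadth ≥ 0.90. The
flanking reference is the arithmetic mean of the two adjacent exons
(`cov_ratio_mode="both"` requires each flank individually instead; the
original tool's choice is unknowable, so both are exposed); a first/last
intron uses its single flank. Introns overlapping an antisense exon by
≥ 1 bp are excluded up front, which normalizes strand-specific against
non-strand-specific libraries. Note that on the toy synthetic genome the
RPKM > 1 prefilter is nearly vacuous — the library is small, so RPKM values
are inflated roughly two orders of magnitude relative to a real library —
and the discriminating rules are the 5%/30%/90% ones; on real data the
prefilter carries weight.

NMD prediction uses the classic 50-nt rule on explicit sequence: the
retained-intron mRNA is translated from the start codon, and the transcript
is NMD-sensitive iff the first stop ends more than 50 nt upstream of the
final exon–exon junction (the retained boundary itself is not a junction).
No rule is published for the original analysis; this is the standard one and
is labelled a substitute. The generator does not produce sequence, so NMD is
exercised on directly constructed transcripts.

The boundary statistic for Fig-style metaprofiles is max(exon-side 20-bp-bin
mean methylation) − min(intron-side bin mean) over ± 200 bp at each intron
boundary, strand-oriented; a window without CpGs leaves the statistic
undefined rather than zero.

## Entropy specificity

H, F and Q are exactly the printed formulas, with 0·log2 0 := 0 and
zero-total features excluded (H = NaN). The 2-D threshold keeps features
with max expression ≥ `expr_min` and H ≤ `h_max` + `slope`·log10(max
expression / `expr_min`): a linear-in-log-expression relaxation of the
entropy bound, respecting the stated monotone coupling between the two
thresholds without inventing unpublished constants. Defaults (ours,
exposed): h_max = 1.0 bit, expr_min = 1 RPKM/RPM, slope = 0.25 bits per
decade. Infinite Q (zero expression in a type) is a "not expressed here"
sentinel clipped to the maximum finite Q for clustering, which is average
linkage on Euclidean distances and deterministic for a fixed input order.

## Methylome

UMR detection: the background is the genome-wide coverage-weighted mean
fractional methylation; each CpG's methylated-read count is tested against
it with a binomial lower tail; significant CpGs (p < 0.0005, the same value
as the region cutoff) within 500 bp merge into regions whose p-value is the
Fisher combination of member-CpG p-values; regions need ≥ 4 significant
CpGs and combined p < 0.0005. The upstream segmentation tool is cited but
not restated in the source material, so this is a re-implementation in
spirit, parameterized to be consistent with the reported medians (~270 bp,
5 CpGs per region); no cross-region FDR correction is applied, matching the
printed cutoff. Reported regions are asserted below background,
non-overlapping and sorted.

MeDIP calibration: background = mean signal over bases ≥ 500 bp from any
CpG (non-specific pulldown); CpGs with mappability < 0.5 are dropped and
signal is divided by mappability in [0.5, 1). Because an IP fragment carries
every CpG it spans, enrichment scales with local CpG density as well as
methylation, so enrichment is divided by a Gaussian-smoothed local CpG
density (coupling factor, sd 100 bp at the fragment scale) before the final
step: empirical quantile mapping onto a WGBS fractional-methylation
reference — the minimal transform guaranteeing the score distribution
matches WGBS. Classes: < 0.35 hypomethylated, > 0.8 hypermethylated.

Metaprofiles average fractional methylation in 20-bp bins over ± 200 bp
around junctions, strand-oriented, with per-group means and Welch two-sided
t-tests between groups (group sizes and variances differ); H3K36me3 exon
enrichment is the group mean of per-exon mean signal over the genome-wide
mean.

## Regulatory association

A UMR links to every gene whose TSS ± 2 kb (proximal) or ± 20 kb (distal)
window overlaps the UMR interval; every proximal link is by construction
also a distal link. Directionality is reported under both defensible
denominators — per UMR, using the nearest linked DE gene, and per
(UMR, DE-gene) pair — since "proximal UMRs associated with increased
transcription" does not fix one. TF asymmetry counts sites overlapping each
cell type's UMRs; the ratio takes a +1 pseudocount on both counts only when
either is zero (flagged), and is otherwise exactly antisymmetric under
swapping the cell types. The permutation null redraws UMR-length intervals
uniformly per chromosome (default 1,000 permutations, seeded) — the
simplest null consistent with "expected by chance". SNP overlap is half-open
containment.

## Synthetic data: what it emulates and what it does not

The default genome is 200 genes on two 2-Mb chromosomes with three cell
types, exon lengths 100–300 bp, introns 300–1,500 bp, lognormal per-gene
exonic depth (mean 30 reads/base, σ = 0.6) shared across cell types, and
per-base Poisson sampling. Planted events: 30 cassette exons (full depth in
one cell type, 0.2% elsewhere, with the silent cell's remaining exons scaled
by L/(L − L_exon) so the gene is not DE — exon skipping at constant
transcript abundance), 50 retained introns at retention fraction 0.5, and
50 UMRs per cell type (300 bp, ≥ 10 CpGs, methylation 0.05) against a
Beta-concentrated background at 0.85, CpG density 2/100 bp with 10% of the
genome as 5-kb CpG-free deserts, and Poisson(30) CpG coverage. Planted
splicing events are restricted to adequately expressed genes (a cassette
exon must carry ≥ 50 expected reads, a retained intron ≥ 4 expected
reads/base) so their detectability reflects splicing, not expression noise.
All randomness flows from one seed; a fixed seed gives byte-identical
outputs. The full pipeline on this genome runs in well under a minute on
one CPU, which is the problem size the test suite and the acceptance script
use.

`simulate_medip` smooths per-CpG methylation with a Gaussian at the IP
fragment scale (sd 100 bp), scales so an isolated methylated CpG peaks at
the configured depth, adds a uniform non-specific floor (2 reads/base) and
Poisson noise, and emits a mappability track with planted low-mappability
patches. `simulate_regional_methylome` assigns methylation per 1-kb block
from a low/intermediate/high mixture: it provides the rank-resolvable
dynamic range that MeDIP calibration is meaningful over, whereas the
planted-UMR genome keeps its background deliberately uniform (a two-level
methylome caps any method's rank correlation with truth at 0.75, so
calibration accuracy is assessed on the regional methylome and UMR
recovery on the planted genome).

What passing tests do **not** show about real data: the generator produces
no sequence content, no alignment artefacts, no duplicate/multimap
structure, no CpG-island/shore geography beyond deserts and planted
regions, no batch or donor variation, and expression differences between
cell types only where planted. Recall/precision measured here characterize
the callers under their stated assumptions, not their behaviour on tissue
libraries.

## Known limitations

- The DE statistic and the UMR segmentation are standard substitutes for
  unpublished in-house tools; calls on real data will differ in detail.
- RPKM magnitudes on the toy genome are inflated (small library), so
  absolute-RPKM thresholds (intron prefilter, entropy `expr_min`) bind
  differently than on genome-scale data.
- `calibrate_medip` assumes the reference WGBS distribution and the MeDIP
  library come from the same cell population; quantile mapping transfers
  distribution shape, not locus-level accuracy, where coverage is low.
- Trans-spliced or multi-chromosome genes are rejected rather than modelled;
  variable-step wiggle is not supported; bigWig is out of scope.
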