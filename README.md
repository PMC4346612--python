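# epilineage

Tools for characterizing differentiated cell types — such as the luminal and
myoepithelial lineages of the human mammary epithelium — from matched
transcriptomic and epigenomic profiles. The package takes per-base coverage
tracks (RNA-seq, H3K36me3 ChIP-seq, MeDIP-seq) and per-CpG bisulfite
methylation calls, and implements the bespoke computational procedures such
studies rely on:

- **Modified RPKM quantification** of genes, merged exons, introns and
  exon–exon junctions, where the per-library normalizer is the number of
  reads in coding exons after excluding the mitochondrial genome,
  ribosomal-protein genes and the top 0.5% expressed exons.
- **Differential expression and cassette-exon isoform calling** between two
  samples: an Audic–Claverie-style conditional binomial test with
  Benjamini–Hochberg FDR (default 0.015, minimum RPKM 0.005, minimum
  25 reads), and the gene-relative isoform bands — an exon is *expressed* at
  ≥ 10% of gene RPKM, *silent* at ≤ 1%, and the 1–10% band is discarded —
  with optional junction-read support (junction RPKM > 0.1 / < 0.1).
- **Intron-retention calling** by four joint rules: intron RPKM > 1,
  intron RPKM > 5% of gene RPKM, intron normalized coverage > 30% of the
  flanking exons', and ≥ 90% of the intron covered; introns overlapping
  antisense exons are excluded. Includes cell-type-specificity
  partitioning, 50-nt-rule NMD prediction for retained-intron transcripts,
  and the exon–intron boundary methylation "peak minus valley" statistic.
- **Entropy-based specificity scoring** for any feature × cell-type
  expression matrix: `H = −Σ F_i log2 F_i` with fractions
  `F_i = E_i / Σ E_j`, the per-type specificity `Q_i = H − log2 F_i`, a 2-D
  (entropy, expression) gate, and hierarchical clustering of Q.
- **Methylome analysis**: unmethylated-region (UMR) segmentation from WGBS
  CpG calls (per-CpG binomial test against the genome background, merge,
  Fisher combination, p < 0.0005), MeDIP-seq calibration to absolute
  [0, 1] methylation scores by quantile mapping onto a WGBS reference (with
  mappability and CpG-density correction; classes < 0.35 hypomethylated,
  > 0.8 hypermethylated), binned methylation metaprofiles at exon
  junctions, and per-exon-group H3K36me3 fold enrichment.
- **Regulatory association**: UMR-to-gene linkage at TSS ± 2 kb (proximal)
  and ± 20 kb (distal), directionality of UMRs versus differential
  expression, TF-binding-site asymmetry between cell types (flagged at
  ≥ 2× and ≥ 8×) with a seeded permutation null, and SNP–UMR intersection.

A first-class **synthetic-genome module** generates gene models, per-cell-type
coverage tracks and methylomes with planted cassette exons, retained introns
and UMRs, recorded in truth tables — so the whole pipeline is testable on a
desk without any external data.

## Worked example

```python
from epilineage import expression, genomic_io, retention
from epilineage.synthetic import SimulationConfig, simulate_genome

ds = simulate_genome(SimulationConfig(rng_seed=42))   # 200 genes, 3 cell types
track = ds.tracks["luminal"]
norm = expression.compute_normalization(track, ds.genes)
expr = expression.quantify(track, ds.genes, norm)
flags = genomic_io.flag_opposite_strand_introns(ds.genes)
coding = {g.gene_id for g in ds.genes.values() if g.biotype == "protein_coding"}
calls = retention.call_retained_introns(expr, flags, cell_type="luminal",
                                        coding_gene_ids=coding)
print(len(calls), "retained introns;",
      len(set(calls.intron_id) & set(ds.truth_retention.intron_id)), "planted")
```

prints

```
17 retained introns; 17 planted
```

— the caller recovers exactly the 17 retention events planted for the
luminal cell type in this genome, with no false positives. The narrative
scripts in `examples/` walk through each capability the same way
(quantification, isoform calls, retention, entropy specificity, UMR/MeDIP,
regulatory asymmetry) and print what the numbers mean.

A thin CLI mirrors the library (`epilineage simulate|quant|de|isoform|
retention|entropy|umr|medip-score|profile|regnet|run-all`); run
`epilineage run-all --show-defaults` to see every threshold in one place.

## Layout

```
src/epilineage/      genomic_io, synthetic, expression, differential,
                     retention, entropy, methylome, regulatory,
                     pipeline, cli
examples/            one narrative script per capability
tests/               pytest suite (unit, property and acceptance tests)
docs/methods.md      models, assumptions, parameter defaults, limitations
```
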