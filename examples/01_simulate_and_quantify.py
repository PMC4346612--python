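"""Simulate the synthetic genome and quantify expression with modified RPKM.

Builds the default 200-gene, 3-cell-type genome, computes the bespoke
normalization factor (coding-exon reads minus mitochondrial, ribosomal and
top-0.5%-exon reads) and prints gene/exon/intron RPKM summaries.
"""

from epilineage import expression
from epilineage.synthetic import SimulationConfig, simulate_genome

ds = simulate_genome(SimulationConfig(rng_seed=42))
print(f"genes: {len(ds.genes)}; cell types: {list(ds.tracks)}")

track = ds.tracks["luminal"]
norm = expression.compute_normalization(track, ds.genes)
print(f"total_included_reads = {norm.total_included_reads:.0f} "
      f"(top-exon excluded: {norm.excluded_top_exon_reads:.0f} reads)")

expr = expression.quantify(track, ds.genes, norm)
for ft in ("gene", "exon", "intron"):
    sub = expr[expr.feature_type == ft]
    print(f"{ft:7s} n={len(sub):5d}  median RPKM={sub.rpkm.median():9.2f}  "
          f"expressed (RPKM>1): {(sub.rpkm > 1).sum()}")
# Gene and exon RPKM are high and comparable (exons carry the reads); intron
# RPKM is ~1% of gene level except where retention was planted.
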