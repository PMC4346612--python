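"""Call retained introns and partition them by cell-type specificity.

A retained intron passes four joint rules: RPKM > 1, > 5% of gene RPKM,
normalized coverage > 30% of the flanking exons', and >= 90% of its bases
covered. Introns overlapping antisense exons are excluded first.
"""

from epilineage import expression, genomic_io, retention
from epilineage.synthetic import SimulationConfig, simulate_genome

ds = simulate_genome(SimulationConfig(rng_seed=42))
flags = genomic_io.flag_opposite_strand_introns(ds.genes)
coding = {g.gene_id for g in ds.genes.values() if g.biotype == "protein_coding"}

calls_by_type = {}
for ct, track in ds.tracks.items():
    norm = expression.compute_normalization(track, ds.genes)
    expr = expression.quantify(track, ds.genes, norm)
    calls_by_type[ct] = retention.call_retained_introns(
        expr, flags, cell_type=ct, coding_gene_ids=coding)
    truth = set(ds.truth_retention.loc[ds.truth_retention.cell_type == ct, "intron_id"])
    got = set(calls_by_type[ct]["intron_id"])
    print(f"{ct:14s} called {len(got):3d}  planted {len(truth):3d}  "
          f"recovered {len(truth & got):3d}")

part = retention.specificity_partition(calls_by_type)
frac = (part["status"] == "specific").mean()
print(f"cell-type-specific retained introns: {100 * frac:.0f}% of {len(part)}")
# Each planted event targets one cell type, so specificity approaches 100%
# here; in tissue data shared events pull this fraction down.
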