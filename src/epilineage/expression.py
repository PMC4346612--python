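"""Modified-RPKM quantification of genes, exons, introns and junctions.

RPKM here uses a bespoke normalization factor: the total number of reads in
coding exons after excluding the mitochondrial genome, ribosomal-protein
genes, and the top 0.5% expressed exons. Read counts are estimated from
per-base coverage sums divided by a configured read length (default 75 bp),
which preserves the proportionality RPKM needs while keeping the pipeline
alignment-free; duplicate/multimap handling is upstream of the tracks and
taken at face value.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from epilineage.genomic_io import CoverageTrack, GeneModel, normalize_chrom

log = logging.getLogger(__name__)

DEFAULT_READ_LENGTH = 75
DEFAULT_TOP_EXON_FRACTION = 0.005


class EmptyLibraryError(ValueError):
    pass


@dataclass
class NormalizationFactor:
    """Reads retained for the RPKM denominator, with the excluded components."""

    total_included_reads: float
    excluded_mito_reads: float = 0.0
    excluded_ribosomal_reads: float = 0.0
    excluded_top_exon_reads: float = 0.0
    top_exon_fraction: float = DEFAULT_TOP_EXON_FRACTION
    read_length: int = DEFAULT_READ_LENGTH

    def __post_init__(self):
        if self.total_included_reads <= 0:
            raise EmptyLibraryError("empty library")


def _exon_frame(genes: dict[str, GeneModel]) -> pd.DataFrame:
    rows = []
    for g in genes.values():
        for i, (s, e) in enumerate(g.merged_exons):
            rows.append((g.gene_id, i, g.chrom, s, e, g.strand, g.biotype))
    return pd.DataFrame(rows, columns=["gene_id", "exon_index", "chrom", "start",
                                       "end", "strand", "biotype"])


def compute_normalization(track: CoverageTrack, genes: dict[str, GeneModel],
                          mito_chrom: str = "MT",
                          ribosomal_gene_ids: frozenset | set = frozenset(),
                          read_length: int = DEFAULT_READ_LENGTH,
                          top_exon_fraction: float = DEFAULT_TOP_EXON_FRACTION,
                          ) -> NormalizationFactor:
    """Compute the modified-RPKM normalization factor for one library.

    Per-exon read counts are (base-coverage sum / read_length) over coding
    (protein_coding) merged exons. Mitochondrial-genome and ribosomal-gene
    exon reads are removed, then the top ceil(f * n) remaining exons ranked
    by provisional RPKM (computed with the all-coding-exon total; ties broken
    by (chrom, start)) are removed. The remaining coding-exon reads are
    total_included_reads.
    """
    mito_chrom = normalize_chrom(mito_chrom)
    exons = _exon_frame(genes)
    exons = exons[exons["biotype"] == "protein_coding"].reset_index(drop=True)
    if exons.empty:
        raise EmptyLibraryError("empty library")
    counts = np.array([track.sum(r.chrom, r.start, r.end) / read_length
                       for r in exons.itertuples(index=False)])
    provisional_total = counts.sum()
    if provisional_total <= 0:
        raise EmptyLibraryError("empty library")
    lengths = (exons["end"] - exons["start"]).to_numpy()
    prov_rpkm = counts / (lengths / 1e3) / (provisional_total / 1e6)
    is_mito = (exons["chrom"] == mito_chrom).to_numpy()
    is_ribo = exons["gene_id"].isin(ribosomal_gene_ids).to_numpy()
    remaining = ~(is_mito | is_ribo)
    n_top = math.ceil(top_exon_fraction * int(remaining.sum()))
    order = sorted(np.flatnonzero(remaining),
                   key=lambda i: (-prov_rpkm[i], exons["chrom"].iat[i], exons["start"].iat[i]))
    top_idx = np.zeros(len(exons), dtype=bool)
    top_idx[order[:n_top]] = True
    included = remaining & ~top_idx
    total = counts[included].sum()
    return NormalizationFactor(
        total_included_reads=float(total),
        excluded_mito_reads=float(counts[is_mito].sum()),
        excluded_ribosomal_reads=float(counts[is_ribo & ~is_mito].sum()),
        excluded_top_exon_reads=float(counts[top_idx].sum()),
        top_exon_fraction=top_exon_fraction,
        read_length=read_length,
    )


def _feature_row(track, norm, feature_id, feature_type, gene_id, chrom, intervals, strand):
    length = sum(e - s for s, e in intervals)
    if length <= 0:
        raise ValueError(f"zero-length feature {feature_id}")
    cov_sum = sum(track.sum(chrom, s, e) for s, e in intervals)
    covered = sum((track.depth(chrom, s, e) >= 1).sum() for s, e in intervals)
    read_count = cov_sum / norm.read_length
    per_million = norm.total_included_reads / 1e6
    rpkm = read_count / (length / 1e3) / per_million
    normalized_coverage = (cov_sum / length) / per_million
    start = min(s for s, _ in intervals)
    end = max(e for _, e in intervals)
    return (feature_id, feature_type, gene_id, chrom, start, end, strand, length,
            read_count, rpkm, normalized_coverage, covered / length)


QUANT_COLUMNS = ["feature_id", "feature_type", "gene_id", "chrom", "start", "end",
                 "strand", "length", "read_count", "rpkm", "normalized_coverage",
                 "breadth"]


def quantify(track: CoverageTrack, genes: dict[str, GeneModel],
             norm: NormalizationFactor) -> pd.DataFrame:
    """Per-gene, per-exon and per-intron expression features.

    Gene RPKM = merged-exon read count / (exonic_length/1e3) /
    (total_included_reads/1e6); exon and intron RPKM are analogous over their
    own lengths. normalized_coverage = mean per-base depth /
    (total_included_reads/1e6); breadth = fraction of bases with depth >= 1.
    """
    rows = []
    for g in genes.values():
        rows.append(_feature_row(track, norm, g.gene_id, "gene", g.gene_id,
                                 g.chrom, g.merged_exons, g.strand))
        for i, (s, e) in enumerate(g.merged_exons):
            rows.append(_feature_row(track, norm, f"{g.gene_id}:exon{i}", "exon",
                                     g.gene_id, g.chrom, [(s, e)], g.strand))
        for i, (s, e) in enumerate(g.introns):
            rows.append(_feature_row(track, norm, f"{g.gene_id}:intron{i}", "intron",
                                     g.gene_id, g.chrom, [(s, e)], g.strand))
    df = pd.DataFrame(rows, columns=QUANT_COLUMNS)
    assert (df["rpkm"] >= 0).all() and df["breadth"].between(0, 1).all()
    return df


def junction_rpkm(junction_counts: pd.DataFrame, norm: NormalizationFactor,
                  effective_length: int | None = None) -> pd.DataFrame:
    """RPKM for exon-exon junction read counts over a fixed effective length.

    ``junction_counts`` needs columns junction_id, count. The effective
    length defaults to the configured read length (the span a junction read
    can occupy).
    """
    if (junction_counts["count"] < 0).any():
        raise ValueError("negative junction count")
    eff = effective_length if effective_length is not None else norm.read_length
    out = junction_counts.copy()
    out["rpkm"] = out["count"] / (eff / 1e3) / (norm.total_included_reads / 1e6)
    return out
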