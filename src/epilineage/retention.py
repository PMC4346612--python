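"""Intron-retention calling, cell-type specificity, NMD prediction and
boundary-methylation statistics.

A retained intron must pass four joint rules against a single sample's
expression features: intron RPKM > 1 (expression prefilter); intron RPKM
> 5% of the protein-coding gene's RPKM; intron normalized coverage > 30% of
the flanking merged exons' normalized coverage (mean of the two flanks); and
>= 90% of the intron covered by at least one read. Introns overlapping an
exon on the opposite strand are excluded beforehand, which normalizes across
strand-specific and non-strand-specific libraries.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from epilineage.methylome import MethylomeTrack

log = logging.getLogger(__name__)

MIN_INTRON_RPKM = 1.0
MIN_GENE_FRACTION = 0.05
MIN_COVERAGE_RATIO = 0.30
MIN_BREADTH = 0.90
NMD_RULE_NT = 50


def call_retained_introns(expr: pd.DataFrame, opposite_strand_flags: dict,
                          cell_type: str = "",
                          coding_gene_ids: set | None = None,
                          min_intron_rpkm: float = MIN_INTRON_RPKM,
                          gene_fraction: float = MIN_GENE_FRACTION,
                          coverage_ratio: float = MIN_COVERAGE_RATIO,
                          min_breadth: float = MIN_BREADTH,
                          cov_ratio_mode: str = "mean") -> pd.DataFrame:
    """Call retained introns from one sample's quantify() output.

    ``coding_gene_ids`` restricts calling to protein-coding genes (None means
    the table was already restricted, e.g. via filter_protein_coding).
    ``cov_ratio_mode`` selects whether the >30% coverage rule compares the
    intron with the mean of the two flanking exons ("mean") or must hold
    against each flank individually ("both"); first/last introns with a
    missing flank use the single available flank (logged once).
    """
    if cov_ratio_mode not in ("mean", "both"):
        raise ValueError("cov_ratio_mode must be 'mean' or 'both'")
    genes = expr[expr["feature_type"] == "gene"].set_index("gene_id")
    exons = expr[expr["feature_type"] == "exon"]
    exon_cov = {}  # (gene_id, exon_index) -> normalized_coverage
    for r in exons.itertuples(index=False):
        idx = int(r.feature_id.rsplit("exon", 1)[1])
        exon_cov[(r.gene_id, idx)] = r.normalized_coverage
    rows = []
    for r in expr[expr["feature_type"] == "intron"].itertuples(index=False):
        gid = r.gene_id
        i = int(r.feature_id.rsplit("intron", 1)[1])
        if opposite_strand_flags.get((gid, i), False):
            continue
        if coding_gene_ids is not None and gid not in coding_gene_ids:
            continue
        g = genes.loc[gid]
        flanks = [exon_cov.get((gid, i)), exon_cov.get((gid, i + 1))]
        flanks = [f for f in flanks if f is not None]
        if len(flanks) == 1:
            log.debug("intron %s has a single flank; using it", r.feature_id)
        if not flanks:
            continue
        if cov_ratio_mode == "mean":
            denom = float(np.mean(flanks))
            ratio = r.normalized_coverage / denom if denom > 0 else np.inf
            ratio_ok = ratio > coverage_ratio
        else:
            ratios = [r.normalized_coverage / f if f > 0 else np.inf for f in flanks]
            ratio = float(np.mean(ratios))
            ratio_ok = all(x > coverage_ratio for x in ratios)
        if (r.rpkm > min_intron_rpkm
                and r.rpkm > gene_fraction * g["rpkm"]
                and ratio_ok
                and r.breadth >= min_breadth):
            rows.append((gid, r.feature_id, r.chrom, r.start, r.end, r.strand,
                         r.rpkm, g["rpkm"], ratio, r.breadth, cell_type))
    df = pd.DataFrame(rows, columns=["gene_id", "intron_id", "chrom", "start", "end",
                                     "strand", "intron_rpkm", "gene_rpkm",
                                     "coverage_ratio", "breadth", "cell_type"])
    # emission-time invariants of a RetentionCall
    if len(df):
        assert (df["intron_rpkm"] > min_intron_rpkm).all()
        assert (df["intron_rpkm"] > gene_fraction * df["gene_rpkm"]).all()
        assert (df["breadth"] >= min_breadth).all()
    return df


def filter_protein_coding(expr: pd.DataFrame, genes: dict) -> pd.DataFrame:
    """Restrict an expression table to features of protein-coding genes."""
    coding = {gid for gid, g in genes.items() if g.biotype == "protein_coding"}
    return expr[expr["gene_id"].isin(coding)].reset_index(drop=True)


def specificity_partition(calls_by_type: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Partition retention calls into shared vs cell-type-specific.

    An intron is "specific" iff called in exactly one cell type with identical
    thresholds. Returns intron_id, n_types, cell_types, status.
    """
    membership: dict[str, list[str]] = {}
    for ct, calls in calls_by_type.items():
        for iid in calls["intron_id"]:
            membership.setdefault(iid, []).append(ct)
    rows = [(iid, len(cts), ",".join(sorted(cts)),
             "specific" if len(cts) == 1 else "shared")
            for iid, cts in sorted(membership.items())]
    return pd.DataFrame(rows, columns=["intron_id", "n_types", "cell_types", "status"])


def predict_nmd(exon_sequences: list[str], retained_intron_index: int,
                intron_sequence: str, cds_start: int | None,
                rule_nt: int = NMD_RULE_NT) -> bool | None:
    """Predict nonsense-mediated decay of a retained-intron transcript.

    The retained-intron mRNA is the exon sequence with ``intron_sequence``
    inserted after exon ``retained_intron_index``. Translation starts at
    ``cds_start`` (offset of the start codon in the fully spliced transcript;
    None means no CDS -> indeterminate, returns None). The transcript is
    predicted NMD-sensitive iff the first in-frame stop codon ends more than
    ``rule_nt`` nt upstream of the final exon-exon junction of the
    retained-intron transcript (the classic 50-nt rule). The retained
    boundary itself is not a spliced junction; a transcript with no remaining
    junction downstream of the stop is NMD-insensitive.
    """
    if cds_start is None:
        return None
    if not (0 <= retained_intron_index < len(exon_sequences) - 1):
        raise ValueError("retained_intron_index out of range")
    lens = [len(s) for s in exon_sequences]
    insert_at = sum(lens[: retained_intron_index + 1])
    mrna = "".join(exon_sequences[: retained_intron_index + 1]) + intron_sequence \
        + "".join(exon_sequences[retained_intron_index + 1:])
    # junction positions in retained-mRNA coordinates (retained one excluded)
    junctions = []
    acc = 0
    for j, L in enumerate(lens[:-1]):
        acc += L
        pos = acc + (len(intron_sequence) if j >= retained_intron_index else 0)
        if j != retained_intron_index:
            junctions.append(pos)
    start = cds_start + (len(intron_sequence) if cds_start >= insert_at else 0)
    coding = mrna[start:]
    coding = coding[: len(coding) - len(coding) % 3]
    aa = str(Seq(coding).translate())
    stop_idx = aa.find("*")
    if stop_idx < 0 or not junctions:
        return False
    stop_end = start + 3 * (stop_idx + 1)
    last_junction = max(junctions)
    return stop_end < last_junction - rule_nt


def boundary_methylation_delta(methylome: MethylomeTrack, chrom: str, start: int,
                               end: int, strand: str, window: int = 200,
                               bin_size: int = 20) -> dict:
    """Binned methylation around both intron boundaries and the peak-valley delta.

    For each boundary (5' and 3' of the intron, strand-oriented) the exon-side
    and intron-side ``window`` bp are averaged in ``bin_size`` bp bins over
    CpGs; the statistic is max(exon-side bin means) - min(intron-side bin
    means). A boundary whose exon- or intron-side window holds no CpG has an
    undefined (NaN) delta. Retained introns show shallower deltas: boundary
    methylation steps accompany splicing, which is attenuated when the intron
    persists.
    """
    nb = window // bin_size

    def binned(lo: int, hi: int, reverse: bool) -> np.ndarray:
        pos, meth, _ = methylome.query(chrom, lo, hi)
        out = np.full(nb, np.nan)
        if len(pos):
            b = (pos - lo) // bin_size
            for k in range(nb):
                sel = b == k
                if sel.any():
                    out[k] = meth[sel].mean()
        return out[::-1] if reverse else out

    if strand == "+":
        b5_exon = binned(start - window, start, False)
        b5_intron = binned(start, start + window, False)
        b3_intron = binned(end - window, end, False)
        b3_exon = binned(end, end + window, False)
    else:
        b5_exon = binned(end, end + window, True)
        b5_intron = binned(end - window, end, True)
        b3_intron = binned(start, start + window, True)
        b3_exon = binned(start - window, start, True)

    def delta(exon_bins, intron_bins):
        if np.all(np.isnan(exon_bins)) or np.all(np.isnan(intron_bins)):
            return np.nan
        return float(np.nanmax(exon_bins) - np.nanmin(intron_bins))

    return {
        "five_prime": {"exon_bins": b5_exon, "intron_bins": b5_intron,
                       "delta": delta(b5_exon, b5_intron)},
        "three_prime": {"exon_bins": b3_exon, "intron_bins": b3_intron,
                        "delta": delta(b3_exon, b3_intron)},
    }


def expressed_feature_summary(expr: pd.DataFrame, min_rpkm: float = 1.0) -> dict:
    """Counts of expressed genes/introns/exons (RPKM > 1) and the intron/exon ratio."""
    out = {}
    for ft in ("gene", "exon", "intron"):
        out[f"expressed_{ft}s"] = int((expr.loc[expr["feature_type"] == ft, "rpkm"]
                                       > min_rpkm).sum())
    out["intron_exon_ratio"] = (out["expressed_introns"] / out["expressed_exons"]
                                if out["expressed_exons"] else np.nan)
    return out
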