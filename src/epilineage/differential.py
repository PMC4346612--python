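"""Differential expression and cassette-exon isoform calling between two samples.

The two-library count test is an Audic–Claverie-style conditional binomial:
given feature counts x_A, x_B with library totals N_A, N_B, x_A is tested
against Binomial(x_A + x_B, N_A/(N_A+N_B)) with a doubled-tail two-sided
p-value, then Benjamini–Hochberg corrected. This is a standard substitute
for the unpublished statistic of the original in-house tool and is exactly
symmetric under swapping the two samples.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

DEFAULT_FDR = 0.015
DEFAULT_MIN_RPKM = 0.005
DEFAULT_MIN_READS = 25
EXPRESSED_REL = 0.10   # exon RPKM >= 10% of gene RPKM: expressed
SILENT_REL = 0.01      # exon RPKM <= 1% of gene RPKM: unexpressed
JUNCTION_RPKM_MIN = 0.1


def binomial_two_library_pvalues(x_a: np.ndarray, x_b: np.ndarray,
                                 total_a: float, total_b: float) -> np.ndarray:
    """Vectorized doubled-tail two-sided binomial p-values for count pairs."""
    x_a = np.asarray(x_a, dtype=np.int64)
    x_b = np.asarray(x_b, dtype=np.int64)
    n = x_a + x_b
    p0 = total_a / (total_a + total_b)
    lower = stats.binom.cdf(x_a, n, p0)
    # P(X_a >= x_a) written as the mirrored lower tail so that swapping the
    # samples evaluates the identical expressions (bitwise-exact symmetry)
    upper = stats.binom.cdf(x_b, n, 1.0 - p0)
    p = np.minimum(1.0, 2.0 * np.minimum(lower, upper))
    return np.where(n > 0, p, 1.0)


def de_call(expr_a: pd.DataFrame, expr_b: pd.DataFrame, norm_a, norm_b,
            level: str = "gene", fdr: float = DEFAULT_FDR,
            min_rpkm: float = DEFAULT_MIN_RPKM,
            min_reads: float = DEFAULT_MIN_READS) -> pd.DataFrame:
    """Call differentially expressed features at gene or exon level.

    Features are retained iff BH q <= fdr AND max(rpkm) > min_rpkm AND
    max(read_count) > min_reads. Returns feature_id, gene_id, direction
    (up_in_A / up_in_B), p_value, q_value, rpkm_A, rpkm_B, count_A, count_B.
    """
    a = expr_a[expr_a["feature_type"] == level].set_index("feature_id")
    b = expr_b[expr_b["feature_type"] == level].set_index("feature_id")
    if not a.index.equals(b.index):
        if set(a.index) != set(b.index):
            raise ValueError("samples quantified against different annotations")
        b = b.loc[a.index]
    x_a = np.rint(a["read_count"].to_numpy()).astype(np.int64)
    x_b = np.rint(b["read_count"].to_numpy()).astype(np.int64)
    p = binomial_two_library_pvalues(
        x_a, x_b, norm_a.total_included_reads, norm_b.total_included_reads)
    _, q, _, _ = multipletests(p, method="fdr_bh")
    df = pd.DataFrame({
        "feature_id": a.index,
        "gene_id": a["gene_id"].to_numpy(),
        "p_value": p,
        "q_value": q,
        "rpkm_A": a["rpkm"].to_numpy(),
        "rpkm_B": b["rpkm"].to_numpy(),
        "count_A": x_a,
        "count_B": x_b,
    })
    keep = ((df["q_value"] <= fdr)
            & (df[["rpkm_A", "rpkm_B"]].max(axis=1) > min_rpkm)
            & (df[["count_A", "count_B"]].max(axis=1) > min_reads))
    df = df[keep].copy()
    df["direction"] = np.where(df["rpkm_A"] > df["rpkm_B"], "up_in_A", "up_in_B")
    return df.reset_index(drop=True)


def isoform_call(expr_a: pd.DataFrame, expr_b: pd.DataFrame,
                 de_exons: pd.DataFrame, de_genes: pd.DataFrame,
                 expressed_rel: float = EXPRESSED_REL,
                 silent_rel: float = SILENT_REL) -> pd.DataFrame:
    """Cassette-exon isoform events: DE exons expressed in only one sample.

    For each DE exon the gene-relative expression (exon RPKM / gene RPKM) must
    be >= 10% on the expressed side and <= 1% on the silent side; exons in the
    1–10% band on either side are discarded as likely false positives. Genes
    that are themselves DE are excluded. Genes with zero RPKM in both samples
    are skipped with a warning.
    """
    gene_a = expr_a[expr_a["feature_type"] == "gene"].set_index("feature_id")["rpkm"]
    gene_b = expr_b[expr_b["feature_type"] == "gene"].set_index("feature_id")["rpkm"]
    exon_a = expr_a[expr_a["feature_type"] == "exon"].set_index("feature_id")["rpkm"]
    exon_b = expr_b[expr_b["feature_type"] == "exon"].set_index("feature_id")["rpkm"]
    de_gene_ids = set(de_genes["gene_id"]) if len(de_genes) else set()
    rows = []
    for rec in de_exons.itertuples(index=False):
        gid = rec.gene_id
        if gid in de_gene_ids:
            continue
        ga, gb = gene_a.get(gid, 0.0), gene_b.get(gid, 0.0)
        if ga == 0 and gb == 0:
            log.warning("gene %s has zero RPKM in both samples; exon %s skipped",
                        gid, rec.feature_id)
            continue
        rel_a = exon_a[rec.feature_id] / ga if ga > 0 else np.inf
        rel_b = exon_b[rec.feature_id] / gb if gb > 0 else np.inf
        if rel_a >= expressed_rel and rel_b <= silent_rel:
            side = "A"
        elif rel_b >= expressed_rel and rel_a <= silent_rel:
            side = "B"
        else:
            continue  # includes the 1-10% discard band
        rows.append((gid, rec.feature_id, side, rel_a, rel_b))
    out = pd.DataFrame(rows, columns=["gene_id", "exon_id", "expressed_in",
                                      "exon_rel_A", "exon_rel_B"])
    assert not set(out["gene_id"]) & de_gene_ids
    return out


def junction_support(calls: pd.DataFrame, junctions_a: pd.DataFrame,
                     junctions_b: pd.DataFrame, junction_exon_map: pd.DataFrame,
                     threshold: float = JUNCTION_RPKM_MIN) -> pd.DataFrame:
    """Annotate isoform calls with exon-junction read support.

    A call is supported iff >=1 junction touching the exon has junction RPKM
    > threshold in the expressed sample and < threshold in the silent one.
    ``junction_exon_map`` needs columns junction_id, exon_id; ``junctions_*``
    need junction_id, rpkm. Calls whose exon has no mapped junction are
    flagged no_junction.
    """
    ja = junctions_a.set_index("junction_id")["rpkm"]
    jb = junctions_b.set_index("junction_id")["rpkm"]
    by_exon = junction_exon_map.groupby("exon_id")["junction_id"].apply(list)
    supported, flags = [], []
    for rec in calls.itertuples(index=False):
        juncs = by_exon.get(rec.exon_id, [])
        if not juncs:
            supported.append(False)
            flags.append("no_junction")
            continue
        ok = False
        for j in juncs:
            ra, rb = ja.get(j, 0.0), jb.get(j, 0.0)
            hi, lo = (ra, rb) if rec.expressed_in == "A" else (rb, ra)
            if hi > threshold and lo < threshold:
                ok = True
                break
        supported.append(ok)
        flags.append("" if ok else "unsupported")
    out = calls.copy()
    out["junction_supported"] = supported
    out["junction_flag"] = flags
    return out


def overlap_significance(size_a: int, size_b: int, overlap: int, universe: int) -> float:
    """Upper-tail hypergeometric probability P[X >= overlap] of a set overlap."""
    if not (0 <= overlap <= min(size_a, size_b)) or max(size_a, size_b) > universe:
        raise ValueError("inconsistent set sizes")
    if overlap < size_a + size_b - universe:
        raise ValueError("overlap below the forced minimum")
    return float(stats.hypergeom.sf(overlap - 1, universe, size_a, size_b))


def multi_sample_overlap(call_sets: list[set], universes: list[set]) -> tuple[set, int]:
    """Intersection of per-pair call sets; universe = features tested in all pairs."""
    common = set.intersection(*call_sets) if call_sets else set()
    universe = set.intersection(*universes) if universes else set()
    return common, len(universe)
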