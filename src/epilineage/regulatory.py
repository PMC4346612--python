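"""UMR-based regulatory association: gene linkage, directionality, TF/SNP overlap.

UMRs (hypomethylated regions, a proxy for actively bound enhancers) are
linked to genes whose TSS lies within +/-2 kb (proximal) or +/-20 kb
(distal); directionality asks how often a cell-type-specific UMR's nearest
linked DE gene is upregulated in the UMR's own cell type. TF-binding
asymmetry counts sites inside each cell type's UMR set, with a seeded
permutation null (uniform placement of length-matched intervals per
chromosome) for the chance expectation.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from epilineage.genomic_io import GenomeInterval

log = logging.getLogger(__name__)

PROXIMAL_BP = 2_000
DISTAL_BP = 20_000
RATIO_FLAG = 2.0
RATIO_FLAG_STRONG = 8.0


def link_umrs_to_genes(umrs: pd.DataFrame, genes: dict, window_proximal: int = PROXIMAL_BP,
                       window_distal: int = DISTAL_BP) -> pd.DataFrame:
    """Link each UMR to every gene whose TSS window overlaps the UMR interval.

    Emits one row per (umr, gene, class); every proximal pair also appears as
    a distal pair. Columns: umr_id, gene_id, distance_class, distance
    (|UMR midpoint - TSS| in bp), umr_cell_type.
    """
    gene_list = [(g.chrom, g.tss, g.gene_id) for g in genes.values()]
    by_chrom: dict[str, tuple[np.ndarray, list[str]]] = {}
    for chrom in {c for c, _, _ in gene_list}:
        items = sorted((t, gid) for c, t, gid in gene_list if c == chrom)
        by_chrom[chrom] = (np.array([t for t, _ in items]), [gid for _, gid in items])
    rows = []
    for u in umrs.itertuples(index=False):
        if u.chrom not in by_chrom:
            continue
        tss_arr, gids = by_chrom[u.chrom]
        mid = (u.start + u.end) // 2
        for cls, w in (("proximal", window_proximal), ("distal", window_distal)):
            # TSS window [tss-w, tss+w) overlaps UMR [start, end)
            i = np.searchsorted(tss_arr, u.start - w + 1)
            j = np.searchsorted(tss_arr, u.end + w)
            for k in range(i, j):
                rows.append((u.umr_id, gids[k], cls, abs(mid - int(tss_arr[k])),
                             getattr(u, "cell_type", "")))
    df = pd.DataFrame(rows, columns=["umr_id", "gene_id", "distance_class",
                                     "distance", "umr_cell_type"])
    prox = set(map(tuple, df.loc[df.distance_class == "proximal", ["umr_id", "gene_id"]].to_numpy()))
    dist = set(map(tuple, df.loc[df.distance_class == "distal", ["umr_id", "gene_id"]].to_numpy()))
    assert prox <= dist, "every proximal link must also be a distal link"
    return df


def directionality_summary(links: pd.DataFrame, de_genes: pd.DataFrame) -> pd.DataFrame:
    """Fraction of cell-type-specific UMRs whose nearest linked DE gene is up
    in the UMR's own cell type.

    ``de_genes`` needs columns gene_id, up_in (cell-type label). Reported per
    distance class with two denominators: per UMR (nearest linked DE gene)
    and per (UMR, DE gene) pair, since either reading of "proximal UMRs
    associated with increased transcription" is defensible. Fractions of
    up_in_same_type + up_in_other_type + not_de sum to 1 within each row
    of the per-UMR accounting.
    """
    up_in = de_genes.set_index("gene_id")["up_in"] if len(de_genes) else pd.Series(dtype=object)
    rows = []
    for cls, sub in links.groupby("distance_class"):
        # per-UMR: nearest linked DE gene decides the direction
        same = other = notde = 0
        for (umr, ct), g in sub.groupby(["umr_id", "umr_cell_type"]):
            de_links = g[g["gene_id"].isin(up_in.index)]
            if de_links.empty:
                notde += 1
                continue
            nearest = de_links.sort_values("distance").iloc[0]
            if up_in[nearest.gene_id] == ct:
                same += 1
            else:
                other += 1
        n_umr = same + other + notde
        # per-pair accounting over all linked DE genes
        pair_same = pair_other = 0
        for rec in sub.itertuples(index=False):
            if rec.gene_id in up_in.index:
                if up_in[rec.gene_id] == rec.umr_cell_type:
                    pair_same += 1
                else:
                    pair_other += 1
        n_de_umr = same + other
        rows.append({
            "distance_class": cls,
            "n_umrs": n_umr,
            "frac_up_same_type": same / n_de_umr if n_de_umr else np.nan,
            "frac_up_other_type": other / n_de_umr if n_de_umr else np.nan,
            "frac_umrs_up_same": same / n_umr if n_umr else np.nan,
            "frac_umrs_up_other": other / n_umr if n_umr else np.nan,
            "frac_umrs_not_de": notde / n_umr if n_umr else np.nan,
            "frac_pairs_up_same": pair_same / (pair_same + pair_other)
                                  if (pair_same + pair_other) else np.nan,
        })
    return pd.DataFrame(rows)


def _overlap_any(starts: np.ndarray, ends: np.ndarray,
                 site_starts: np.ndarray, site_ends: np.ndarray) -> np.ndarray:
    """Boolean per query interval: overlaps >=1 bp of any (sorted) site."""
    if len(site_starts) == 0:
        return np.zeros(len(starts), dtype=bool)
    # site i overlaps [s, e) iff site_start < e and site_end > s
    idx = np.searchsorted(site_starts, ends)  # first site with start >= e
    prev_end_max = np.maximum.accumulate(site_ends)
    has_prev = idx > 0
    out = np.zeros(len(starts), dtype=bool)
    out[has_prev] = prev_end_max[idx[has_prev] - 1] > starts[has_prev]
    return out


def tf_overlap_asymmetry(umrs_a: pd.DataFrame, umrs_b: pd.DataFrame,
                         tf_sites: dict[str, list[GenomeInterval]],
                         chrom_sizes: dict[str, int], n_permutations: int = 1000,
                         seed: int = 0, labels: tuple[str, str] = ("A", "B"),
                         ) -> pd.DataFrame:
    """Per-TF site counts inside each UMR set, the A/B ratio and a permutation null.

    ratio = n_A / n_B, with pseudocount +1 on both counts when either is 0;
    flagged at ratio >= 2 and >= 8 (and the reciprocal for B-enrichment).
    expected_by_chance_* = mean over permutations of the fraction of
    length-matched, uniformly placed UMR intervals overlapping >=1 site of
    the TF; observed_frac_* is the corresponding observed fraction.
    """
    rng = np.random.default_rng(seed)
    sites_by_tf: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]] = {}
    for tf, ivs in tf_sites.items():
        if not ivs:
            log.warning("TF %s has no sites; skipped", tf)
            continue
        per_chrom: dict[str, tuple[list, list]] = {}
        for iv in ivs:
            per_chrom.setdefault(iv.chrom, ([], []))[0].append(iv.start)
            per_chrom[iv.chrom][1].append(iv.end)
        sites_by_tf[tf] = {
            c: (np.array(sorted(ss)), np.array([e for _, e in sorted(zip(ss, ee))]))
            for c, (ss, ee) in per_chrom.items()}

    def umr_arrays(umrs):
        return {c: (sub["start"].to_numpy(), sub["end"].to_numpy())
                for c, sub in umrs.groupby("chrom")}

    arr_a, arr_b = umr_arrays(umrs_a), umr_arrays(umrs_b)
    rows = []
    for tf in sorted(sites_by_tf):
        sites = sites_by_tf[tf]

        def count_sites_in(umr_arr):
            n = 0
            for c, (ss, ee) in sites.items():
                if c not in umr_arr:
                    continue
                us, ue = umr_arr[c]
                order = np.argsort(us)
                n += int(_overlap_any(ss, ee, us[order], ue[order]).sum())
            return n

        def overlap_fraction(umr_arr):
            tot = hit = 0
            for c, (us, ue) in umr_arr.items():
                tot += len(us)
                if c in sites:
                    ss, se = sites[c]
                    hit += int(_overlap_any(us, ue, ss, se).sum())
            return hit / tot if tot else np.nan

        def permuted_fraction(umr_arr):
            fracs = np.zeros(n_permutations)
            lengths = {c: ue - us for c, (us, ue) in umr_arr.items()}
            for p in range(n_permutations):
                tot = hit = 0
                for c, lens in lengths.items():
                    size = chrom_sizes[c]
                    starts = rng.integers(0, np.maximum(size - lens, 1))
                    tot += len(lens)
                    if c in sites:
                        ss, se = sites[c]
                        hit += int(_overlap_any(starts, starts + lens, ss, se).sum())
                fracs[p] = hit / tot if tot else np.nan
            return float(np.nanmean(fracs))

        n_a, n_b = count_sites_in(arr_a), count_sites_in(arr_b)
        if n_a == 0 or n_b == 0:
            ratio = (n_a + 1) / (n_b + 1)
            pseudocount = True
        else:
            ratio = n_a / n_b
            pseudocount = False
        rows.append({
            "tf": tf,
            f"n_sites_in_{labels[0]}_umrs": n_a,
            f"n_sites_in_{labels[1]}_umrs": n_b,
            "ratio": ratio,
            "pseudocount": pseudocount,
            "flag_2x": ratio >= RATIO_FLAG or ratio <= 1 / RATIO_FLAG,
            "flag_8x": ratio >= RATIO_FLAG_STRONG or ratio <= 1 / RATIO_FLAG_STRONG,
            f"observed_frac_{labels[0]}": overlap_fraction(arr_a),
            f"observed_frac_{labels[1]}": overlap_fraction(arr_b),
            f"expected_by_chance_{labels[0]}": permuted_fraction(arr_a),
            f"expected_by_chance_{labels[1]}": permuted_fraction(arr_b),
        })
    return pd.DataFrame(rows)


def snp_overlap(umrs: pd.DataFrame, snps: pd.DataFrame) -> pd.DataFrame:
    """SNPs whose position falls inside a UMR (half-open containment).

    ``snps`` needs columns chrom, pos and optionally name. One row per
    (SNP, UMR) pair.
    """
    rows = []
    for c, sub in umrs.groupby("chrom"):
        s = snps[snps["chrom"] == c]
        if s.empty:
            continue
        for u in sub.itertuples(index=False):
            inside = s[(s["pos"] >= u.start) & (s["pos"] < u.end)]
            for snp in inside.itertuples(index=False):
                rows.append((getattr(snp, "name_", getattr(snp, "name", "")), snp.chrom,
                             snp.pos, u.umr_id, u.start, u.end))
    return pd.DataFrame(rows, columns=["snp", "chrom", "pos", "umr_id",
                                       "umr_start", "umr_end"])
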