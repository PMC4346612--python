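"""WGBS methylome handling: UMR detection, MeDIP calibration, boundary metaprofiles.

A MethylomeTrack holds per-CpG fractional-methylation calls (position of the
C on the + strand; symmetric CG calls are assumed already folded). UMRs —
runs of significantly unmethylated CpGs — are the regulatory-element unit of
the downstream association analysis. MeDIP enrichment is calibrated onto the
WGBS fractional-methylation scale by empirical quantile mapping.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import gaussian_filter1d

log = logging.getLogger(__name__)

# methylation-score class boundaries on the [0,1] scale
HYPO_MAX = 0.35
HYPER_MIN = 0.8


@dataclass
class MethylomeTrack:
    """Per-CpG (position, fractional methylation, coverage) for one sample.

    ``chroms`` maps chromosome -> (positions int64 sorted strictly increasing,
    methylation float in [0,1], coverage int >= 1).
    """

    chroms: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = field(default_factory=dict)

    def __post_init__(self):
        for chrom, (pos, meth, cov) in self.chroms.items():
            if len(pos) and np.any(np.diff(pos) <= 0):
                raise ValueError(f"{chrom}: CpG positions not strictly increasing")
            if np.any((meth < 0) | (meth > 1)):
                raise ValueError(f"{chrom}: fractional methylation outside [0,1]")
            if np.any(cov < 1):
                raise ValueError(f"{chrom}: coverage < 1")

    @classmethod
    def from_arrays(cls, chroms):
        return cls({c: (np.asarray(p, dtype=np.int64), np.asarray(m, dtype=float),
                        np.asarray(v, dtype=np.int64)) for c, (p, m, v) in chroms.items()})

    def query(self, chrom: str, start: int, end: int):
        """(positions, methylation, coverage) of CpGs with start <= pos < end."""
        if chrom not in self.chroms:
            z = np.array([], dtype=np.int64)
            return z, z.astype(float), z
        pos, meth, cov = self.chroms[chrom]
        i, j = np.searchsorted(pos, [start, end])
        return pos[i:j], meth[i:j], cov[i:j]

    def n_cpgs(self) -> int:
        return sum(len(p) for p, _, _ in self.chroms.values())

    def background(self) -> float:
        """Genome-wide coverage-weighted mean fractional methylation."""
        num = sum(float((m * v).sum()) for _, m, v in self.chroms.values())
        den = sum(float(v.sum()) for _, _, v in self.chroms.values())
        if den == 0:
            raise ValueError("empty methylome")
        return num / den

    def all_fractions(self) -> np.ndarray:
        if not self.chroms:
            return np.array([])
        return np.concatenate([m for _, m, _ in self.chroms.values()])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for chrom in sorted(self.chroms):
            pos, meth, cov = self.chroms[chrom]
            rows.append(pd.DataFrame({"chrom": chrom, "pos": pos,
                                      "fraction": meth, "coverage": cov}))
        return pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
            columns=["chrom", "pos", "fraction", "coverage"])

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "MethylomeTrack":
        df = pd.read_csv(path, sep="\t")
        from epilineage.genomic_io import normalize_chrom
        df["chrom"] = df["chrom"].astype(str).map(normalize_chrom)
        chroms = {}
        for chrom, sub in df.groupby("chrom", sort=True):
            sub = sub.sort_values("pos")
            chroms[chrom] = (sub["pos"].to_numpy(np.int64),
                             sub["fraction"].to_numpy(float),
                             sub["coverage"].to_numpy(np.int64))
        return cls(chroms)


def call_umrs(methylome: MethylomeTrack, p_cutoff: float = 0.0005, min_cpgs: int = 4,
              merge_gap: int = 500, cpg_alpha: float | None = None,
              background: float | None = None, cell_type: str = "") -> pd.DataFrame:
    """Detect unmethylated regions (UMRs) from per-CpG WGBS calls.

    Each CpG is tested for hypomethylation against the genome-wide
    coverage-weighted background rate with a binomial lower-tail test on
    (methylated reads, coverage). Significant CpGs (p < cpg_alpha, default
    = p_cutoff) within ``merge_gap`` bp are merged; a region's p-value is the
    Fisher combination of its significant-CpG p-values, and regions are kept
    iff combined p < p_cutoff and they contain >= min_cpgs significant CpGs.

    Returns a DataFrame with columns umr_id, chrom, start, end, n_cpgs,
    mean_methylation (coverage-weighted over all CpGs in the span), p_value,
    cell_type — sorted and pairwise non-overlapping.
    """
    if methylome.n_cpgs() < 1000:
        log.warning("fewer than 1000 CpGs; background estimate will be noisy")
    if cpg_alpha is None:
        cpg_alpha = p_cutoff
    bg = methylome.background() if background is None else background
    if bg < 0.5:
        log.warning("globally hypomethylated input (background %.3f < 0.5)", bg)
    rows = []
    for chrom in sorted(methylome.chroms):
        pos, meth, cov = methylome.chroms[chrom]
        if len(pos) == 0:
            continue
        m_reads = np.rint(meth * cov).astype(np.int64)
        pvals = stats.binom.cdf(m_reads, cov, bg)
        sig = pvals < cpg_alpha
        idx = np.flatnonzero(sig)
        if len(idx) == 0:
            continue
        # merge significant CpGs within merge_gap
        breaks = np.flatnonzero(np.diff(pos[idx]) > merge_gap)
        starts = np.concatenate(([0], breaks + 1))
        ends = np.concatenate((breaks, [len(idx) - 1]))
        for a, b in zip(starts, ends):
            members = idx[a:b + 1]
            if len(members) < min_cpgs:
                continue
            stat, p_comb = stats.combine_pvalues(pvals[members], method="fisher")
            if not (p_comb < p_cutoff):
                continue
            lo, hi = int(pos[members[0]]), int(pos[members[-1]]) + 2  # CpG dinucleotide
            i, j = np.searchsorted(pos, [lo, hi])
            span_m, span_c = meth[i:j], cov[i:j]
            mean_meth = float((span_m * span_c).sum() / span_c.sum())
            assert mean_meth < bg, "reported UMR must be below background"
            rows.append((chrom, lo, hi, int(len(members)), mean_meth, float(p_comb)))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "n_cpgs",
                                     "mean_methylation", "p_value"])
    df = df.sort_values(["chrom", "start"]).reset_index(drop=True)
    df.insert(0, "umr_id", [f"umr_{cell_type or 'x'}_{i}" for i in range(len(df))])
    df["cell_type"] = cell_type
    # non-overlap: merged runs are separated by > merge_gap by construction
    same = df["chrom"].to_numpy()[1:] == df["chrom"].to_numpy()[:-1]
    assert np.all(df["start"].to_numpy()[1:][same] >= df["end"].to_numpy()[:-1][same])
    return df


def calibrate_medip(signal, methylome_reference: np.ndarray, mappability: dict[str, np.ndarray],
                    cpg_positions: dict[str, np.ndarray], cpg_distance: int = 500,
                    min_mappability: float = 0.5, coupling_sd: float | None = 100.0,
                    ) -> pd.DataFrame:
    """Calibrate MeDIP enrichment at CpGs to fractional-methylation scores.

    Background = mean signal over all bases >= ``cpg_distance`` bp from any
    CpG (non-specific pulldown level). Per-CpG raw enrichment =
    (signal - background) / background, with CpGs at mappability < 0.5
    dropped and signal divided by mappability where 0.5 <= m < 1. Because
    immunoprecipitated fragments carry all CpGs they span, enrichment scales
    with local CpG density as well as methylation; when ``coupling_sd`` is
    set, enrichment is divided by a Gaussian-smoothed local CpG density
    (coupling factor, sd in bp at the fragment scale) before calibration.
    The density-normalized enrichments are quantile-mapped onto the sorted
    WGBS reference fractional-methylation distribution, giving a score in
    [0,1] classified as hypomethylated (<0.35), intermediate, or
    hypermethylated (>0.8).
    """
    ref = np.sort(np.asarray(methylome_reference, dtype=float))
    if len(ref) == 0:
        raise ValueError("empty WGBS reference distribution")
    # background: bases far from any CpG
    bg_sum = 0.0
    bg_n = 0
    for chrom, arr in signal.data.items():
        pos = cpg_positions.get(chrom)
        mask = np.ones(len(arr), dtype=bool)
        if pos is not None and len(pos):
            lo = np.maximum(pos - cpg_distance, 0)
            hi = np.minimum(pos + 1 + cpg_distance, len(arr))
            delta = np.zeros(len(arr) + 1, dtype=np.int64)
            np.add.at(delta, lo, 1)
            np.add.at(delta, hi, -1)
            mask = np.cumsum(delta[:-1]) == 0
        bg_sum += float(arr[mask].sum())
        bg_n += int(mask.sum())
    if bg_n == 0 or bg_sum == 0:
        raise ValueError("zero MeDIP background (no CpG-free bases with signal)")
    background = bg_sum / bg_n
    recs = []
    for chrom in sorted(cpg_positions):
        pos = np.asarray(cpg_positions[chrom], dtype=np.int64)
        arr = signal.data.get(chrom)
        if arr is None or len(pos) == 0:
            continue
        pos = pos[pos < len(arr)]
        sig = arr[pos].astype(float)
        mp = mappability.get(chrom)
        m = mp[pos] if mp is not None else np.ones(len(pos))
        coupling_all = None
        if coupling_sd is not None and len(arr):
            dens = np.zeros(len(arr))
            np.add.at(dens, pos, 1.0)  # density over all CpGs, pre-filter
            coupling_all = gaussian_filter1d(dens, sigma=coupling_sd)
        keep = m >= min_mappability
        pos, sig, m = pos[keep], sig[keep], m[keep]
        corr = np.where(m < 1, sig / m, sig)
        enrich = np.maximum(corr - background, 0.0) / background
        if coupling_all is not None:
            coupling = coupling_all[pos]
            floor = np.median(coupling[coupling > 0]) * 0.05 if np.any(coupling > 0) else 1.0
            enrich = enrich / np.maximum(coupling, floor)
        recs.append(pd.DataFrame({"chrom": chrom, "pos": pos,
                                  "raw_enrichment": enrich,
                                  "mappability": m}))
    if not recs:
        return pd.DataFrame(columns=["chrom", "pos", "raw_enrichment", "mappability",
                                     "score", "meth_class"])
    df = pd.concat(recs, ignore_index=True)
    ranks = stats.rankdata(df["raw_enrichment"], method="average")
    q = (ranks - 0.5) / len(df)
    df["score"] = np.quantile(ref, q)
    df["meth_class"] = np.select(
        [df["score"] < HYPO_MAX, df["score"] > HYPER_MIN],
        ["hypomethylated", "hypermethylated"], default="intermediate")
    return df


def _bin_edges(window: int, bin_size: int) -> np.ndarray:
    if window % bin_size:
        raise ValueError("window must be a multiple of bin_size")
    return np.arange(-window, window + 1, bin_size)


def boundary_profile_matrix(methylome: MethylomeTrack, junctions: pd.DataFrame,
                            window: int = 200, bin_size: int = 20):
    """Per-feature binned mean methylation around junction positions.

    ``junctions`` needs columns chrom, pos, strand. Bins are strand-oriented
    5'->3': bin b covers transcript-direction offsets [b*bin_size,
    (b+1)*bin_size) for b in -window/bin_size .. window/bin_size - 1.
    Returns (meth_matrix, count_matrix, bin_labels); matrix entries are NaN
    where a bin holds no CpG.
    """
    nb = window // bin_size
    bins = np.arange(-nb, nb)
    meth_mat = np.full((len(junctions), 2 * nb), np.nan)
    count_mat = np.zeros((len(junctions), 2 * nb))
    for r, row in enumerate(junctions.itertuples(index=False)):
        pos, meth, _ = methylome.query(row.chrom, row.pos - window, row.pos + window)
        if len(pos) == 0:
            continue
        off = pos - row.pos  # genomic offset in [-window, window)
        if row.strand == "-":
            off = -off - 1  # orient 5'->3'
        b = np.floor_divide(off, bin_size)
        for k, bb in enumerate(bins):
            sel = b == bb
            count_mat[r, k] = sel.sum()
            if sel.any():
                meth_mat[r, k] = meth[sel].mean()
    return meth_mat, count_mat, bins


def boundary_profile(methylome: MethylomeTrack, junctions: pd.DataFrame,
                     window: int = 200, bin_size: int = 20) -> pd.DataFrame:
    """Group-averaged methylation/CpG-count metaprofile at exon junctions.

    ``junctions`` needs columns chrom, pos, strand, group. Returns a
    long-format frame (group, bin, mean_methylation, mean_cpg_count,
    n_features); empty groups are omitted with a warning.
    """
    out = []
    for group, sub in junctions.groupby("group", sort=True):
        if len(sub) == 0:
            log.warning("group %s is empty; omitted", group)
            continue
        meth_mat, count_mat, bins = boundary_profile_matrix(methylome, sub, window, bin_size)
        n_obs = (~np.isnan(meth_mat)).sum(axis=0)
        mean_meth = np.where(n_obs > 0,
                             np.nansum(meth_mat, axis=0) / np.maximum(n_obs, 1),
                             np.nan)
        out.append(pd.DataFrame({
            "group": group, "bin": bins,
            "mean_methylation": mean_meth,
            "mean_cpg_count": count_mat.mean(axis=0),
            "n_features": len(sub),
        }))
    return pd.concat(out, ignore_index=True) if out else pd.DataFrame(
        columns=["group", "bin", "mean_methylation", "mean_cpg_count", "n_features"])


def compare_profile_groups(methylome: MethylomeTrack, junctions: pd.DataFrame,
                           group_a: str, group_b: str, window: int = 200,
                           bin_size: int = 20) -> tuple[float, float]:
    """Welch two-sided t-test on per-feature mean window methylation between groups."""
    vals = {}
    for g in (group_a, group_b):
        sub = junctions[junctions["group"] == g]
        meth_mat, _, _ = boundary_profile_matrix(methylome, sub, window, bin_size)
        with np.errstate(invalid="ignore"):
            per_feature = np.nanmean(meth_mat, axis=1)
        vals[g] = per_feature[~np.isnan(per_feature)]
    a, b = vals[group_a], vals[group_b]
    if np.var(a) == 0 and np.var(b) == 0 and a.mean() == b.mean():
        return 0.0, 1.0  # identical constant groups: no difference
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def exon_signal_enrichment(track, exon_groups: pd.DataFrame) -> pd.DataFrame:
    """Fold enrichment of mean per-base signal within exons, per exon group.

    ``exon_groups`` needs columns chrom, start, end, group. Fold = group mean
    of (mean per-base signal over the exon) / genome-wide mean signal.
    Intended for H3K36me3, whose exonic enrichment tracks transcription.
    """
    genome_len = sum(len(a) for a in track.data.values())
    genome_mean = track.total() / genome_len if genome_len else 0.0
    if genome_mean == 0:
        raise ValueError("zero genome-wide signal")
    rows = []
    for group, sub in exon_groups.groupby("group", sort=True):
        means = [track.sum(r.chrom, r.start, r.end) / (r.end - r.start)
                 for r in sub.itertuples(index=False)]
        rows.append((group, float(np.mean(means)) / genome_mean, len(sub)))
    return pd.DataFrame(rows, columns=["group", "fold_enrichment", "n_exons"])


def write_umr_bed(umrs: pd.DataFrame, path) -> None:
    from epilineage.genomic_io import GenomeInterval, write_bed
    ivs = [GenomeInterval(r.chrom, r.start, r.end, name=r.umr_id)
           for r in umrs.itertuples(index=False)]
    write_bed(ivs, path)
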