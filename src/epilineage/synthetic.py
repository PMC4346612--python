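"""Synthetic genome, coverage and methylome generator with planted ground truth.

Emulates the statistical structure of the real inputs — gene models with
merged exons and introns, cell-type-shared expression with planted cassette
exons and retained introns, bimodal CpG methylation with planted
hypomethylated regions, and MeDIP signal derived from methylation by
fragment-scale smoothing — at a desk scale (200 genes, two 2-Mb
chromosomes, 3 cell types) so the full pipeline runs in well under a
minute. Every planted event is recorded in a truth table, which is the
oracle for all caller modules.

Expression in a cassette gene's silent cell type is compensated (remaining
exons scaled by L/(L - L_exon)) so isoform genes are not differentially
expressed at the gene level, mirroring exon skipping at constant transcript
abundance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from epilineage.genomic_io import CoverageTrack, GeneModel
from epilineage.methylome import MethylomeTrack

log = logging.getLogger(__name__)


@dataclass
class SimulationConfig:
    """All knobs of the synthetic genome; a fixed seed gives identical outputs."""

    n_genes: int = 200
    chrom_sizes: dict = field(default_factory=lambda: {"1": 2_000_000, "2": 2_000_000})
    cell_types: tuple = ("luminal", "myoepithelial", "stemlike")
    exons_per_gene: tuple = (4, 9)       # inclusive range
    exon_length: tuple = (100, 300)      # bp, inclusive
    intron_length: tuple = (300, 1500)   # bp, inclusive
    intergenic_gap: tuple = (3000, 8000)  # bp between gene spans
    frac_noncoding: float = 0.1
    mean_depth: float = 30.0             # mean exonic reads per base
    depth_sigma: float = 0.6             # lognormal sigma of per-gene depth
    read_length: int = 75
    intron_background: float = 0.01      # pre-mRNA background, fraction of gene depth
    silent_exon_depth: float = 0.002     # cassette exon depth in silent cells, x gene depth
    n_cassette_exons: int = 30
    n_retained_introns: int = 50
    retention_fraction: float = 0.5
    # planted events go into adequately expressed genes, so that detecting
    # them is a property of splicing, not of expression noise: a cassette
    # exon must carry >= plant_min_exon_reads expected reads (2x the DE
    # count-evidence filter) and a retained intron >= plant_min_intron_depth
    # expected reads per base (coverage breadth ~1-exp(-depth)).
    plant_min_exon_reads: float = 50.0
    plant_min_intron_depth: float = 4.0
    n_umrs_per_cell_type: int = 50
    umr_width: int = 300
    umr_n_cpgs: int = 10
    umr_methylation: float = 0.05
    methylation_background: float = 0.85
    beta_concentration: float = 20.0
    cpg_per_100bp: float = 2.0
    cpg_coverage: float = 30.0           # mean per-CpG WGBS depth (Poisson)
    # CpG deserts: CpG-free blocks emulating the uneven CpG landscape of a
    # real genome; they also provide the CpG-distal background regions the
    # MeDIP calibration needs.
    cpg_desert_fraction: float = 0.10
    cpg_desert_block: int = 5000
    planted_cassette_exons: list | None = None   # [(gene_id, exon_idx, cell_type)]
    planted_retained_introns: list | None = None  # [(gene_id, intron_idx, cell_type, fraction)]
    planted_umrs: list | None = None     # [(cell_type, chrom, start, end)]
    rng_seed: int = 42

    def validate(self, genes=None):
        if not (0 <= self.retention_fraction <= 1):
            raise ValueError("retention fraction must be in [0, 1]")
        if self.planted_umrs:
            for ct, chrom, s, e in self.planted_umrs:
                if chrom not in self.chrom_sizes or not (0 <= s < e <= self.chrom_sizes[chrom]):
                    raise ValueError(f"planted UMR ({chrom}:{s}-{e}) outside chromosomes")
                if ct not in self.cell_types:
                    raise ValueError(f"planted UMR cell type {ct!r} unknown")


@dataclass
class SimulatedDataset:
    """Everything simulate_genome produces, plus the planted truth."""

    config: SimulationConfig
    genes: dict[str, GeneModel]
    depths: dict[str, float]                    # gene_id -> exonic reads/base
    tracks: dict[str, CoverageTrack]            # cell type -> RNA coverage
    methylomes: dict[str, MethylomeTrack]       # cell type -> WGBS calls
    cpg_positions: dict[str, np.ndarray]        # shared CpG coordinates
    truth_cassette: pd.DataFrame
    truth_retention: pd.DataFrame
    truth_umrs: pd.DataFrame


def _place_genes(cfg: SimulationConfig, rng) -> tuple[dict[str, GeneModel], list]:
    genes: dict[str, GeneModel] = {}
    gaps: list[tuple[str, int, int]] = []  # intergenic gaps for UMR placement
    chroms = list(cfg.chrom_sizes)
    cursors = {c: 1000 for c in chroms}
    n_noncoding = int(round(cfg.frac_noncoding * cfg.n_genes))
    for gi in range(cfg.n_genes):
        chrom = chroms[gi % len(chroms)]
        n_ex = int(rng.integers(cfg.exons_per_gene[0], cfg.exons_per_gene[1] + 1))
        ex_lens = rng.integers(cfg.exon_length[0], cfg.exon_length[1] + 1, n_ex)
        in_lens = rng.integers(cfg.intron_length[0], cfg.intron_length[1] + 1, n_ex - 1)
        span = int(ex_lens.sum() + in_lens.sum())
        gap = int(rng.integers(cfg.intergenic_gap[0], cfg.intergenic_gap[1] + 1))
        start = cursors[chrom] + gap
        if start + span + 1000 > cfg.chrom_sizes[chrom]:
            log.warning("chromosome %s full after %d genes", chrom, gi)
            break
        gaps.append((chrom, cursors[chrom], start))
        exons = []
        pos = start
        for k in range(n_ex):
            exons.append((pos, pos + int(ex_lens[k])))
            pos += int(ex_lens[k])
            if k < n_ex - 1:
                pos += int(in_lens[k])
        strand = "+" if rng.random() < 0.5 else "-"
        biotype = "noncoding" if gi < n_noncoding else "protein_coding"
        gid = f"G{gi:04d}"
        genes[gid] = GeneModel(gid, chrom, strand, biotype, exons)
        cursors[chrom] = pos
    for c in chroms:
        gaps.append((c, cursors[c], cfg.chrom_sizes[c] - 500))
    return genes, gaps


def _pick_events(cfg: SimulationConfig, genes: dict[str, GeneModel],
                 depths: dict[str, float], rng):
    coding = [g for g in genes.values() if g.biotype == "protein_coding"]
    cassette = cfg.planted_cassette_exons
    if cassette is None:
        eligible = []  # (gene, [internal exon indices with enough expected reads])
        for g in coding:
            if g.n_exons < 4:
                continue
            d = depths[g.gene_id]
            idx = [i for i in range(1, g.n_exons - 1)
                   if (g.merged_exons[i][1] - g.merged_exons[i][0]) * d / cfg.read_length
                   >= cfg.plant_min_exon_reads]
            if idx:
                eligible.append((g, idx))
        if len(eligible) < cfg.n_cassette_exons:
            raise ValueError("not enough expressed genes to plant cassette exons")
        chosen = rng.choice(len(eligible), size=cfg.n_cassette_exons, replace=False)
        cassette = []
        for j, gi in enumerate(chosen):
            g, idx = eligible[gi]
            exon_idx = int(idx[rng.integers(0, len(idx))])
            ct = cfg.cell_types[j % len(cfg.cell_types)]
            cassette.append((g.gene_id, exon_idx, ct))
    used = {gid for gid, _, _ in cassette}
    retention = cfg.planted_retained_introns
    if retention is None:
        eligible = [g for g in coding
                    if g.gene_id not in used and g.n_exons >= 2
                    and cfg.retention_fraction * depths[g.gene_id]
                    >= cfg.plant_min_intron_depth]
        if len(eligible) < cfg.n_retained_introns:
            raise ValueError("not enough expressed genes to plant retained introns")
        chosen = rng.choice(len(eligible), size=cfg.n_retained_introns, replace=False)
        retention = []
        for j, gi in enumerate(chosen):
            g = eligible[gi]
            intron_idx = int(rng.integers(0, len(g.introns)))
            ct = cfg.cell_types[j % len(cfg.cell_types)]
            retention.append((g.gene_id, intron_idx, ct, cfg.retention_fraction))
    return cassette, retention


def _place_umrs(cfg: SimulationConfig, gaps: list, rng) -> list[tuple[str, str, int, int]]:
    if cfg.planted_umrs is not None:
        return list(cfg.planted_umrs)
    # slot candidates inside intergenic gaps, spaced > merge distance apart
    margin, spacing = 600, 1200
    slots = []
    for chrom, lo, hi in gaps:
        pos = lo + margin
        while pos + cfg.umr_width + margin <= hi:
            slots.append((chrom, pos, pos + cfg.umr_width))
            pos += cfg.umr_width + spacing
    need = cfg.n_umrs_per_cell_type * len(cfg.cell_types)
    if need > len(slots):
        raise ValueError(f"cannot place {need} UMRs in {len(slots)} intergenic slots")
    order = rng.permutation(len(slots))
    umrs = []
    for j in range(need):
        chrom, s, e = slots[order[j]]
        ct = cfg.cell_types[j % len(cfg.cell_types)]
        umrs.append((ct, chrom, s, e))
    return umrs


def simulate_genome(config: SimulationConfig | None = None) -> SimulatedDataset:
    """Generate gene models, per-cell-type RNA coverage and WGBS methylomes.

    RNA coverage over an expressed gene's exons is per-base Poisson around
    the gene's depth; a planted retained intron receives retention_fraction
    x that depth across its whole length in its target cell type; a planted
    cassette exon receives full depth in its target cell type and
    ~silent_exon_depth x gene depth elsewhere. CpG methylation is
    Beta-concentrated near methylation_background except inside planted
    UMRs (near umr_methylation); per-CpG coverage is Poisson(cpg_coverage),
    zero-coverage CpGs dropped.
    """
    cfg = config or SimulationConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.rng_seed)
    genes, gaps = _place_genes(cfg, rng)
    depths = {gid: float(rng.lognormal(np.log(cfg.mean_depth) - cfg.depth_sigma ** 2 / 2,
                                       cfg.depth_sigma)) for gid in genes}
    cassette, retention = _pick_events(cfg, genes, depths, rng)
    umrs = _place_umrs(cfg, gaps, rng)

    cassette_by_gene = {}
    for gid, ei, ct in cassette:
        cassette_by_gene.setdefault(gid, []).append((ei, ct))
    retention_by_gene = {}
    for gid, ii, ct, frac in retention:
        retention_by_gene.setdefault(gid, []).append((ii, ct, frac))

    tracks: dict[str, CoverageTrack] = {}
    for ct in cfg.cell_types:
        data = {c: np.zeros(n) for c, n in cfg.chrom_sizes.items()}
        for gid, g in genes.items():
            d = depths[gid]
            cass = dict((ei, cct) for ei, cct in cassette_by_gene.get(gid, []))
            # compensate silent cells so cassette genes stay gene-level equal
            silent_lens = sum(g.merged_exons[ei][1] - g.merged_exons[ei][0]
                              for ei, cct in cass.items() if cct != ct)
            scale = (g.exonic_length / (g.exonic_length - silent_lens)
                     if silent_lens else 1.0)
            arr = data[g.chrom]
            for ei, (s, e) in enumerate(g.merged_exons):
                if ei in cass and cass[ei] != ct:
                    mu = cfg.silent_exon_depth * d
                else:
                    mu = d * scale
                arr[s:e] += rng.poisson(mu, e - s)
            for ii, (s, e) in enumerate(g.introns):
                mu = cfg.intron_background * d
                for rii, rct, frac in retention_by_gene.get(gid, []):
                    if rii == ii and rct == ct:
                        mu = frac * d
                arr[s:e] += rng.poisson(mu, e - s)
        track = CoverageTrack(data, assay="rnaseq")
        track.library_total = track.total() / cfg.read_length
        tracks[ct] = track

    # shared CpG positions, with CpGs forced into every planted UMR interval
    # and CpG-free desert blocks carved out
    cpg_positions: dict[str, np.ndarray] = {}
    for chrom, size in cfg.chrom_sizes.items():
        n_cpg = int(size * cfg.cpg_per_100bp / 100)
        pos = rng.choice(size - 1, size=n_cpg, replace=False)
        n_desert = int(size * cfg.cpg_desert_fraction / cfg.cpg_desert_block)
        if n_desert:
            desert_starts = rng.choice(size - cfg.cpg_desert_block, size=n_desert,
                                       replace=False)
            in_desert = np.zeros(size, dtype=bool)
            for s in desert_starts:
                in_desert[s: s + cfg.cpg_desert_block] = True
            pos = pos[~in_desert[pos]]
        forced = []
        for ct, c, s, e in umrs:
            if c == chrom:
                forced.append(np.linspace(s + 5, e - 5, cfg.umr_n_cpgs).astype(np.int64))
        allpos = np.concatenate([pos] + forced) if forced else pos
        cpg_positions[chrom] = np.unique(allpos)

    kappa = cfg.beta_concentration

    def beta(mean, n):
        return rng.beta(mean * kappa, (1 - mean) * kappa, n)

    methylomes: dict[str, MethylomeTrack] = {}
    umr_truth_rows = []
    for ct in cfg.cell_types:
        chroms = {}
        for chrom, pos in cpg_positions.items():
            meth = beta(cfg.methylation_background, len(pos))
            for uct, c, s, e in umrs:
                if uct == ct and c == chrom:
                    i, j = np.searchsorted(pos, [s, e])
                    meth[i:j] = beta(cfg.umr_methylation, j - i)
            cov = rng.poisson(cfg.cpg_coverage, len(pos))
            keep = cov >= 1
            chroms[chrom] = (pos[keep], meth[keep], cov[keep])
        methylomes[ct] = MethylomeTrack(chroms)
    for uct, c, s, e in umrs:
        i, j = np.searchsorted(cpg_positions[c], [s, e])
        umr_truth_rows.append((uct, c, s, e, int(j - i), cfg.umr_methylation))

    truth_cassette = pd.DataFrame(
        [(gid, ei, f"{gid}:exon{ei}", ct) for gid, ei, ct in cassette],
        columns=["gene_id", "exon_index", "exon_id", "cell_type"])
    truth_retention = pd.DataFrame(
        [(gid, ii, f"{gid}:intron{ii}", ct, frac) for gid, ii, ct, frac in retention],
        columns=["gene_id", "intron_index", "intron_id", "cell_type", "retention_fraction"])
    truth_umrs = pd.DataFrame(umr_truth_rows, columns=["cell_type", "chrom", "start",
                                                       "end", "n_cpgs", "target_methylation"])
    return SimulatedDataset(cfg, genes, depths, tracks, methylomes, cpg_positions,
                            truth_cassette, truth_retention, truth_umrs)


def simulate_medip(methylome: MethylomeTrack, chrom_sizes: dict[str, int],
                   fragment_sd: float = 100.0, depth: float = 30.0,
                   nonspecific_depth: float = 2.0,
                   n_low_map_patches: int = 4, patch_width: int = 2000,
                   patch_mappability: float = 0.3, seed: int = 0,
                   ) -> tuple[CoverageTrack, dict[str, np.ndarray]]:
    """MeDIP-like enrichment signal generated from a methylome.

    Expected signal per base = Gaussian-smoothed (sd = fragment_sd, the
    immunoprecipitated fragment scale) sum of nearby CpG methylation,
    scaled so an isolated fully methylated CpG peaks at ``depth`` reads,
    plus a uniform non-specific pulldown floor (``nonspecific_depth``, the
    signal observed far from any CpG); the observed track adds per-base
    Poisson noise. Also returns a mappability track of ones with
    ``n_low_map_patches`` patches at ``patch_mappability`` placed over
    CpG-bearing sequence.
    """
    rng = np.random.default_rng(seed)
    scale = depth * fragment_sd * np.sqrt(2 * np.pi)
    data, mappability = {}, {}
    for chrom, size in chrom_sizes.items():
        expect = np.full(size, float(nonspecific_depth))
        if chrom in methylome.chroms:
            pos, meth, _ = methylome.chroms[chrom]
            delta = np.zeros(size)
            np.add.at(delta, pos, meth)
            expect = expect + gaussian_filter1d(delta, sigma=fragment_sd) * scale
        data[chrom] = rng.poisson(expect).astype(float)
        mp = np.ones(size)
        if chrom in methylome.chroms and n_low_map_patches:
            pos = methylome.chroms[chrom][0]
            centers = rng.choice(pos, size=min(n_low_map_patches, len(pos)), replace=False)
            for c in centers:
                lo = max(0, int(c) - patch_width // 2)
                mp[lo: int(c) + patch_width // 2] = patch_mappability
        mappability[chrom] = mp
    track = CoverageTrack(data, assay="medip")
    track.library_total = track.total()
    return track, mappability


def simulate_regional_methylome(chrom_sizes: dict[str, int], cpg_per_100bp: float = 2.0,
                                block: int = 1000, p_low: float = 0.25,
                                p_mid: float = 0.35, low: float = 0.1,
                                mid_range: tuple = (0.2, 0.8), high: float = 0.85,
                                concentration: float = 50.0, coverage: float = 30.0,
                                desert_fraction: float = 0.10, desert_block: int = 5000,
                                seed: int = 0) -> MethylomeTrack:
    """A methylome with regionally varying methylation spanning the full range.

    Methylation is assigned per ``block`` bp: a low mode (fraction p_low,
    CpG-island-like), a continuous intermediate stratum (p_mid, uniform over
    mid_range, shore/partially-methylated-domain-like) and a high somatic
    mode; CpGs scatter tightly (Beta, ``concentration``) around their block
    level. This regional structure carries the rank-resolvable dynamic range
    that MeDIP-seq calibration is meaningful over — unlike the planted-UMR
    genome, whose background is deliberately uniform. CpG deserts are carved
    out as in the main generator.
    """
    rng = np.random.default_rng(seed)
    chroms = {}
    for chrom, size in chrom_sizes.items():
        n_cpg = int(size * cpg_per_100bp / 100)
        pos = np.sort(rng.choice(size - 1, size=n_cpg, replace=False))
        n_desert = int(size * desert_fraction / desert_block)
        if n_desert:
            starts = rng.choice(size - desert_block, size=n_desert, replace=False)
            in_desert = np.zeros(size, dtype=bool)
            for s in starts:
                in_desert[s: s + desert_block] = True
            pos = pos[~in_desert[pos]]
        n_blocks = size // block + 1
        u = rng.random(n_blocks)
        levels = np.where(u < p_low, rng.beta(low * 20, (1 - low) * 20, n_blocks),
                          np.where(u < p_low + p_mid,
                                   rng.uniform(*mid_range, n_blocks),
                                   rng.beta(high * 20, (1 - high) * 20, n_blocks)))
        mu = np.clip(levels[pos // block], 0.02, 0.98)
        meth = rng.beta(mu * concentration, (1 - mu) * concentration)
        cov = rng.poisson(coverage, len(pos))
        keep = cov >= 1
        chroms[chrom] = (pos[keep], meth[keep], cov[keep])
    return MethylomeTrack(chroms)


def simulate_h3k36me3(genes: dict[str, GeneModel], depths: dict[str, float],
                      chrom_sizes: dict[str, int], expressed: set[str],
                      enrichment: float = 5.0, background: float = 0.2,
                      seed: int = 0) -> CoverageTrack:
    """H3K36me3-like track: exonic enrichment over expressed gene bodies.

    Exons of expressed genes get Poisson(background * enrichment * depth
    scale); everything else Poisson(background).
    """
    rng = np.random.default_rng(seed)
    data = {c: rng.poisson(background, n).astype(float) for c, n in chrom_sizes.items()}
    for gid, g in genes.items():
        if gid not in expressed:
            continue
        arr = data[g.chrom]
        for s, e in g.merged_exons:
            arr[s:e] += rng.poisson(background * enrichment, e - s)
    track = CoverageTrack(data, assay="h3k36me3")
    track.library_total = track.total()
    return track
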