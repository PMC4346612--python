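"""End-to-end orchestration of the analysis stages with deterministic seeding.

``run_all`` executes quantification -> DE/isoform -> retention & entropy on
the RNA side and UMR calling -> gene association on the methylome side,
writing TSV outputs plus a provenance manifest (config hash, version,
per-stage row counts) under a run directory. All stage thresholds live in
RunConfig with their standard defaults so every cutoff is inspectable in
one place.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from epilineage import differential, entropy, expression, regulatory, retention
from epilineage import genomic_io, methylome as methylome_mod
from epilineage.synthetic import SimulationConfig, SimulatedDataset, simulate_genome

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """Every stage threshold, with its standard default, in one place."""

    # differential expression / isoform
    fdr: float = 0.015
    min_rpkm: float = 0.005
    min_reads: float = 25
    expressed_rel: float = 0.10
    silent_rel: float = 0.01
    junction_rpkm_min: float = 0.1
    # intron retention
    min_intron_rpkm: float = 1.0
    gene_fraction: float = 0.05
    coverage_ratio: float = 0.30
    min_breadth: float = 0.90
    cov_ratio_mode: str = "mean"
    # entropy gate
    h_max: float = 1.0
    expr_min: float = 1.0
    slope: float = 0.25
    # methylome
    umr_p_cutoff: float = 0.0005
    umr_min_cpgs: int = 4
    umr_merge_gap: int = 500
    medip_hypo_max: float = 0.35
    medip_hyper_min: float = 0.8
    # regulatory association
    window_proximal: int = 2_000
    window_distal: int = 20_000
    n_permutations: int = 1000
    # profiles
    profile_window: int = 200
    profile_bin: int = 20
    # execution
    read_length: int = 75
    stages: tuple = ("rna", "methylome")
    rng_seed: int = 42
    simulation: SimulationConfig | None = None

    def to_dict(self) -> dict:
        d = asdict(self)
        d["stages"] = list(self.stages)
        if self.simulation is not None:
            d["simulation"]["cell_types"] = list(self.simulation.cell_types)
            for k in ("exons_per_gene", "exon_length", "intron_length", "intergenic_gap"):
                d["simulation"][k] = list(d["simulation"][k])
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()).hexdigest()[:16]


def show_defaults() -> str:
    cfg = RunConfig()
    lines = [f"{f.name} = {getattr(cfg, f.name)!r}" for f in dataclasses.fields(cfg)
             if f.name != "simulation"]
    return "\n".join(lines)


def _write(df: pd.DataFrame, path: Path, manifest: dict, key: str) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    manifest["row_counts"][key] = int(len(df))


def run_all(config: RunConfig, outdir, dataset: SimulatedDataset | None = None) -> dict:
    """Run all requested stages on a (simulated) dataset and write outputs.

    With no ``dataset``, the synthetic genome from ``config.simulation``
    (default SimulationConfig seeded by config.rng_seed) is generated. Any
    stage failure aborts with the stage name. Returns the manifest dict.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if config.simulation is None:
        config.simulation = SimulationConfig(rng_seed=config.rng_seed)
    manifest = {"config_hash": config.config_hash(), "row_counts": {},
                "stages_run": [], "stages_skipped": []}
    from epilineage import __version__
    manifest["version"] = __version__

    stage = "simulate"
    try:
        if dataset is None:
            dataset = simulate_genome(config.simulation)
        genes = dataset.genes
        cell_types = list(dataset.tracks)
        coding = {gid for gid, g in genes.items() if g.biotype == "protein_coding"}

        if "rna" in config.stages:
            stage = "quant"
            norms, quants = {}, {}
            for ct in cell_types:
                norms[ct] = expression.compute_normalization(
                    dataset.tracks[ct], genes, read_length=config.read_length)
                quants[ct] = expression.quantify(dataset.tracks[ct], genes, norms[ct])
                _write(quants[ct], outdir / f"quant_{ct}.tsv", manifest, f"quant_{ct}")
            manifest["stages_run"].append("quant")

            stage = "de_isoform"
            a, b = cell_types[0], cell_types[1]
            de_genes = differential.de_call(quants[a], quants[b], norms[a], norms[b],
                                            level="gene", fdr=config.fdr,
                                            min_rpkm=config.min_rpkm,
                                            min_reads=config.min_reads)
            de_exons = differential.de_call(quants[a], quants[b], norms[a], norms[b],
                                            level="exon", fdr=config.fdr,
                                            min_rpkm=config.min_rpkm,
                                            min_reads=config.min_reads)
            isoforms = differential.isoform_call(quants[a], quants[b], de_exons, de_genes,
                                                 expressed_rel=config.expressed_rel,
                                                 silent_rel=config.silent_rel)
            _write(de_genes, outdir / f"de_genes_{a}_vs_{b}.tsv", manifest, "de_genes")
            _write(de_exons, outdir / f"de_exons_{a}_vs_{b}.tsv", manifest, "de_exons")
            _write(isoforms, outdir / f"isoforms_{a}_vs_{b}.tsv", manifest, "isoforms")
            manifest["stages_run"].append("de_isoform")

            stage = "retention"
            flags = genomic_io.flag_opposite_strand_introns(genes)
            calls_by_type = {}
            for ct in cell_types:
                calls_by_type[ct] = retention.call_retained_introns(
                    quants[ct], flags, cell_type=ct, coding_gene_ids=coding,
                    min_intron_rpkm=config.min_intron_rpkm,
                    gene_fraction=config.gene_fraction,
                    coverage_ratio=config.coverage_ratio,
                    min_breadth=config.min_breadth,
                    cov_ratio_mode=config.cov_ratio_mode)
                _write(calls_by_type[ct], outdir / f"retention_{ct}.tsv",
                       manifest, f"retention_{ct}")
            partition = retention.specificity_partition(calls_by_type)
            _write(partition, outdir / "retention_partition.tsv", manifest,
                   "retention_partition")
            manifest["stages_run"].append("retention")

            stage = "entropy"
            matrix = pd.DataFrame({ct: quants[ct][quants[ct].feature_type == "gene"]
                                   .set_index("feature_id")["rpkm"] for ct in cell_types})
            scores = entropy.entropy_scores(matrix)
            specific = entropy.specificity_threshold(scores, h_max=config.h_max,
                                                     expr_min=config.expr_min,
                                                     slope=config.slope)
            _write(specific, outdir / "entropy_specific.tsv", manifest, "entropy_specific")
            manifest["stages_run"].append("entropy")

        if "methylome" in config.stages:
            if not dataset.methylomes:
                log.warning("no methylomes available; methylome stages skipped")
                manifest["stages_skipped"].append("methylome")
            else:
                stage = "umr"
                umrs_by_type = {}
                for ct, meth in dataset.methylomes.items():
                    umrs_by_type[ct] = methylome_mod.call_umrs(
                        meth, p_cutoff=config.umr_p_cutoff,
                        min_cpgs=config.umr_min_cpgs,
                        merge_gap=config.umr_merge_gap, cell_type=ct)
                    _write(umrs_by_type[ct], outdir / f"umrs_{ct}.tsv",
                           manifest, f"umrs_{ct}")
                manifest["stages_run"].append("umr")

                if "rna" in config.stages:
                    stage = "regulatory"
                    a, b = cell_types[0], cell_types[1]
                    de_dir = pd.DataFrame({
                        "gene_id": de_genes["gene_id"],
                        "up_in": np.where(de_genes["direction"] == "up_in_A", a, b)})
                    umrs_ab = pd.concat([umrs_by_type[a], umrs_by_type[b]],
                                        ignore_index=True)
                    links = regulatory.link_umrs_to_genes(
                        umrs_ab, genes, window_proximal=config.window_proximal,
                        window_distal=config.window_distal)
                    summary = regulatory.directionality_summary(links, de_dir)
                    _write(links, outdir / "umr_gene_links.tsv", manifest, "umr_gene_links")
                    _write(summary, outdir / "directionality.tsv", manifest,
                           "directionality")
                    manifest["stages_run"].append("regulatory")

                stage = "profiles"
                ct0 = cell_types[0]
                junctions = _intron_boundary_junctions(dataset, ct0)
                profile = methylome_mod.boundary_profile(
                    dataset.methylomes[ct0], junctions,
                    window=config.profile_window, bin_size=config.profile_bin)
                _write(profile, outdir / f"boundary_profile_{ct0}.tsv",
                       manifest, "boundary_profile")
                manifest["stages_run"].append("profiles")
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    manifest_json = json.dumps(manifest, indent=2, sort_keys=True)
    (outdir / "manifest.json").write_text(manifest_json + "\n")
    return manifest


def _intron_boundary_junctions(dataset: SimulatedDataset, cell_type: str) -> pd.DataFrame:
    """Intron 5' boundaries grouped retained / not_retained by the planted truth."""
    retained = set(dataset.truth_retention.loc[
        dataset.truth_retention.cell_type == cell_type, "intron_id"])
    rows = []
    for g in dataset.genes.values():
        for i, (s, e) in enumerate(g.introns):
            pos = s if g.strand == "+" else e
            iid = f"{g.gene_id}:intron{i}"
            rows.append((g.chrom, pos, g.strand,
                         "retained" if iid in retained else "not_retained"))
    return pd.DataFrame(rows, columns=["chrom", "pos", "strand", "group"])
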