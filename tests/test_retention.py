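"""Retained-intron calling, NMD prediction and boundary-methylation deltas."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from epilineage.methylome import MethylomeTrack
from epilineage.retention import (
    boundary_methylation_delta,
    call_retained_introns,
    expressed_feature_summary,
    predict_nmd,
    specificity_partition,
)


def _expr_rows(gene_rpkm=20.0, intron_rpkm=1.5, intron_cov=0.4, flank_cov=1.0,
               breadth=0.95, gid="G"):
    rows = [
        dict(feature_id=gid, feature_type="gene", gene_id=gid, chrom="1", start=0,
             end=1000, strand="+", rpkm=gene_rpkm, normalized_coverage=flank_cov,
             breadth=1.0, read_count=100),
        dict(feature_id=f"{gid}:exon0", feature_type="exon", gene_id=gid, chrom="1",
             start=0, end=100, strand="+", rpkm=gene_rpkm,
             normalized_coverage=flank_cov, breadth=1.0, read_count=50),
        dict(feature_id=f"{gid}:exon1", feature_type="exon", gene_id=gid, chrom="1",
             start=400, end=500, strand="+", rpkm=gene_rpkm,
             normalized_coverage=flank_cov, breadth=1.0, read_count=50),
        dict(feature_id=f"{gid}:intron0", feature_type="intron", gene_id=gid,
             chrom="1", start=100, end=400, strand="+", rpkm=intron_rpkm,
             normalized_coverage=intron_cov, breadth=breadth, read_count=10),
    ]
    return pd.DataFrame(rows)


class TestFourRuleCaller:
    def test_all_thresholds_met_gives_call(self):
        calls = call_retained_introns(_expr_rows(), {})
        assert list(calls["intron_id"]) == ["G:intron0"]
        assert calls.iloc[0]["coverage_ratio"] == pytest.approx(0.4)

    @pytest.mark.parametrize("kwargs", [
        dict(intron_rpkm=0.9),                 # fails the RPKM>1 prefilter
        dict(gene_rpkm=40.0, intron_rpkm=1.5),  # 1.5 < 5% of 40
        dict(intron_cov=0.25),                  # coverage ratio below 30%
        dict(breadth=0.85),                     # breadth below 90%
    ])
    def test_each_rule_individually_blocks(self, kwargs):
        assert len(call_retained_introns(_expr_rows(**kwargs), {})) == 0

    def test_opposite_strand_intron_never_called(self):
        # saturated coverage cannot rescue a flagged intron
        expr = _expr_rows(intron_rpkm=100.0, intron_cov=1.0, breadth=1.0)
        flags = {("G", 0): True}
        assert len(call_retained_introns(expr, flags)) == 0

    def test_noncoding_genes_excluded(self):
        expr = _expr_rows()
        assert len(call_retained_introns(expr, {}, coding_gene_ids=set())) == 0

    def test_matches_brute_force_filter_on_synthetic_genome(
            self, default_dataset, default_quants, opposite_strand_flags):
        """Caller equals an independent four-rule filter over the full table."""
        _, quants = default_quants
        expr = quants["luminal"]
        coding = {g.gene_id for g in default_dataset.genes.values()
                  if g.biotype == "protein_coding"}
        calls = call_retained_introns(expr, opposite_strand_flags,
                                      coding_gene_ids=coding)
        # oracle: plain pandas filter, flanks averaged by hand
        gene_rpkm = expr[expr.feature_type == "gene"].set_index("gene_id")["rpkm"]
        exon_cov = expr[expr.feature_type == "exon"].set_index("feature_id")[
            "normalized_coverage"]
        expect = set()
        for r in expr[expr.feature_type == "intron"].itertuples(index=False):
            gid = r.gene_id
            i = int(r.feature_id.rsplit("intron", 1)[1])
            if opposite_strand_flags.get((gid, i)) or gid not in coding:
                continue
            flanks = [exon_cov.get(f"{gid}:exon{i}"), exon_cov.get(f"{gid}:exon{i+1}")]
            flanks = [f for f in flanks if f is not None]
            mean_flank = np.mean(flanks)
            if (r.rpkm > 1 and r.rpkm > 0.05 * gene_rpkm[gid]
                    and (r.normalized_coverage / mean_flank if mean_flank > 0 else np.inf) > 0.30
                    and r.breadth >= 0.90):
                expect.add(r.feature_id)
        assert set(calls["intron_id"]) == expect

    def test_emitted_calls_satisfy_invariants(self, default_quants,
                                              opposite_strand_flags, default_dataset):
        _, quants = default_quants
        coding = {g.gene_id for g in default_dataset.genes.values()
                  if g.biotype == "protein_coding"}
        calls = call_retained_introns(quants["myoepithelial"], opposite_strand_flags,
                                      coding_gene_ids=coding)
        assert (calls["intron_rpkm"] > 1).all()
        assert (calls["intron_rpkm"] > 0.05 * calls["gene_rpkm"]).all()
        assert (calls["coverage_ratio"] > 0.30).all()
        assert (calls["breadth"] >= 0.90).all()


class TestSpecificityPartition:
    def test_shared_and_specific(self):
        a = pd.DataFrame({"intron_id": ["i1", "i2"]})
        b = pd.DataFrame({"intron_id": ["i2", "i3"]})
        part = specificity_partition({"A": a, "B": b}).set_index("intron_id")
        assert part.loc["i1", "status"] == "specific"
        assert part.loc["i2", "status"] == "shared"
        assert part.loc["i3", "status"] == "specific"

    def test_disjoint_sets_all_specific(self):
        a = pd.DataFrame({"intron_id": ["i1"]})
        b = pd.DataFrame({"intron_id": ["i2"]})
        part = specificity_partition({"A": a, "B": b})
        assert (part["status"] == "specific").all()

    def test_partition_conserves_union(self):
        rng = np.random.default_rng(0)
        ids = [f"i{k}" for k in range(50)]
        sets = {ct: pd.DataFrame({"intron_id": rng.choice(ids, 20, replace=False)})
                for ct in ("A", "B", "C")}
        part = specificity_partition(sets)
        union = set().union(*(set(s["intron_id"]) for s in sets.values()))
        assert len(part) == len(union)
        assert ((part["status"] == "shared") == (part["n_types"] > 1)).all()


def _codon_walk_oracle(exons, idx, intron, cds_start, rule_nt=50):
    """Independent naive codon scan implementing the 50-nt junction rule."""
    mrna = "".join(exons[: idx + 1]) + intron + "".join(exons[idx + 1:])
    insert_at = sum(len(e) for e in exons[: idx + 1])
    start = cds_start + (len(intron) if cds_start >= insert_at else 0)
    junctions = []
    acc = 0
    for j in range(len(exons) - 1):
        acc += len(exons[j])
        if j != idx:
            junctions.append(acc + (len(intron) if j >= idx else 0))
    stop_codons = {"TAA", "TAG", "TGA"}
    pos = start
    stop_end = None
    while pos + 3 <= len(mrna):
        if mrna[pos:pos + 3] in stop_codons:
            stop_end = pos + 3
            break
        pos += 3
    if stop_end is None or not junctions:
        return False
    return stop_end < max(junctions) - rule_nt


class TestPredictNmd:
    def test_stop_near_last_junction_is_insensitive(self):
        # stop inside the retained last intron, < 50 nt from the last junction
        exons = ["ATGAAA", "GGGGGG", "CCCCCC"]
        intron = "TAAGG"  # immediate in-frame stop
        # retained intron is the last one; the only remaining junction is
        # upstream of the stop -> no NMD
        assert predict_nmd(exons, 1, intron, cds_start=0) is False

    def test_early_frameshift_stop_is_sensitive(self):
        # long downstream exons keep the last junction far from the stop
        exons = ["ATGAAA", "G" * 90, "C" * 90, "ATCGATCG"]
        intron = "TTAACC"  # in-frame TAA at offset 1? -> codons TTA ACC: no stop
        intron = "TAATTT"  # codon TAA immediately
        assert predict_nmd(exons, 0, intron, cds_start=0) is True

    def test_no_cds_is_indeterminate(self):
        assert predict_nmd(["ATG", "CCC"], 0, "TAA", cds_start=None) is None

    def test_matches_codon_walk_oracle_on_random_cases(self):
        rng = np.random.default_rng(17)
        bases = np.array(list("ACGT"))
        for _ in range(300):
            n_ex = int(rng.integers(2, 6))
            exons = ["".join(rng.choice(bases, int(rng.integers(6, 60))))
                     for _ in range(n_ex)]
            exons[0] = "ATG" + exons[0]
            intron = "".join(rng.choice(bases, int(rng.integers(4, 80))))
            idx = int(rng.integers(0, n_ex - 1))
            got = predict_nmd(exons, idx, intron, cds_start=0)
            assert got == _codon_walk_oracle(exons, idx, intron, 0)


class TestBoundaryMethylationDelta:
    @staticmethod
    def _methylome(pos, meth):
        pos = np.asarray(pos, dtype=np.int64)
        return MethylomeTrack({"1": (pos, np.asarray(meth, float),
                                     np.full(len(pos), 30, dtype=np.int64))})

    def test_flat_methylation_zero_delta(self):
        pos = np.arange(0, 2000, 25)
        m = self._methylome(pos, np.full(len(pos), 0.8))
        out = boundary_methylation_delta(m, "1", 600, 1400, "+")
        assert out["five_prime"]["delta"] == pytest.approx(0.0)
        assert out["three_prime"]["delta"] == pytest.approx(0.0)

    def test_constructed_dip_gives_expected_delta(self):
        pos = np.arange(0, 2000, 20)
        meth = np.where((pos >= 600) & (pos < 800), 0.3, 0.9)  # intron-side dip
        m = self._methylome(pos, meth)
        out = boundary_methylation_delta(m, "1", 600, 1400, "+")
        assert out["five_prime"]["delta"] == pytest.approx(0.6)

    def test_empty_window_is_undefined(self):
        m = self._methylome([50], [0.8])
        out = boundary_methylation_delta(m, "1", 600, 1400, "+")
        assert np.isnan(out["five_prime"]["delta"])

    def test_minus_strand_orientation_swaps_boundaries(self):
        pos = np.arange(0, 2000, 20)
        meth = np.where((pos >= 1200) & (pos < 1400), 0.3, 0.9)
        m = self._methylome(pos, meth)
        # on the minus strand the intron 5' end is the genomic end coordinate
        out = boundary_methylation_delta(m, "1", 600, 1400, "-")
        assert out["five_prime"]["delta"] == pytest.approx(0.6)

    def test_retained_introns_show_shallower_deltas(self):
        """Planted cohort: retained-intron boundaries dip less -> smaller delta."""
        rng = np.random.default_rng(23)
        deltas = {"retained": [], "spliced": []}
        for group, dip in (("retained", 0.15), ("spliced", 0.45)):
            for k in range(100):
                base = k * 3000
                pos = np.arange(base, base + 2000, 25)
                meth = np.clip(0.85 + rng.normal(0, 0.05, len(pos)), 0, 1)
                inside = (pos >= base + 600) & (pos < base + 800)
                meth[inside] = np.clip(0.85 - dip + rng.normal(0, 0.05, inside.sum()),
                                       0, 1)
                m = self._methylome(pos - base, meth)
                out = boundary_methylation_delta(m, "1", 600, 1400, "+")
                deltas[group].append(out["five_prime"]["delta"])
        t, p = stats.ttest_ind(deltas["retained"], deltas["spliced"],
                               equal_var=False, alternative="less")
        assert p < 0.01


def test_expressed_feature_summary_counts():
    expr = pd.DataFrame({
        "feature_type": ["gene", "gene", "exon", "intron", "intron"],
        "rpkm": [5.0, 0.5, 2.0, 1.5, 0.2],
    })
    out = expressed_feature_summary(expr)
    assert out["expressed_genes"] == 1
    assert out["expressed_introns"] == 1
    assert out["intron_exon_ratio"] == pytest.approx(1.0)
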