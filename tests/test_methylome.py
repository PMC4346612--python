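"""UMR segmentation, MeDIP calibration and exon/intron metaprofiles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from epilineage.genomic_io import CoverageTrack
from epilineage.methylome import (
    MethylomeTrack,
    boundary_profile,
    boundary_profile_matrix,
    calibrate_medip,
    call_umrs,
    compare_profile_groups,
    exon_signal_enrichment,
)
from epilineage.synthetic import simulate_medip, simulate_regional_methylome

from conftest import make_track


def _flat_methylome(n=5000, level=0.85, cov=30, spacing=50, seed=0):
    rng = np.random.default_rng(seed)
    pos = np.arange(0, n * spacing, spacing, dtype=np.int64)
    meth = np.clip(rng.beta(level * 20, (1 - level) * 20, n), 0, 1)
    return MethylomeTrack({"1": (pos, meth, np.full(n, cov, dtype=np.int64))})


class TestMethylomeTrack:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            MethylomeTrack({"1": (np.array([5, 5]), np.array([0.5, 0.5]),
                                  np.array([3, 3]))})
        with pytest.raises(ValueError):
            MethylomeTrack({"1": (np.array([1]), np.array([1.5]), np.array([3]))})
        with pytest.raises(ValueError):
            MethylomeTrack({"1": (np.array([1]), np.array([0.5]), np.array([0]))})

    def test_tsv_roundtrip(self, tmp_path):
        m = _flat_methylome(100)
        p = tmp_path / "m.tsv"
        m.write_tsv(p)
        m2 = MethylomeTrack.read_tsv(p)
        pos1, meth1, cov1 = m.chroms["1"]
        pos2, meth2, cov2 = m2.chroms["1"]
        assert np.array_equal(pos1, pos2) and np.array_equal(cov1, cov2)
        np.testing.assert_allclose(meth1, meth2)


class TestCallUmrs:
    def test_flat_methylome_yields_no_umrs(self):
        assert len(call_umrs(_flat_methylome())) == 0

    def test_planted_region_found_and_cpgwise_significant(self):
        # 300 bp, 10 CpGs at 0.05 against a 0.85 background, coverage 30
        m = _flat_methylome(3000)
        pos, meth, cov = m.chroms["1"]
        lo, hi = 75_000, 75_300
        inside = (pos >= lo) & (pos < hi)
        assert inside.sum() >= 4
        meth[inside] = 0.05
        umrs = call_umrs(m)
        assert len(umrs) == 1
        u = umrs.iloc[0]
        assert u.start < hi and u.end > lo
        # per-CpG binomial oracle: every interior CpG individually significant
        bg = m.background()
        for p_, me, cv in zip(pos[inside], meth[inside], cov[inside]):
            assert stats.binom.cdf(round(me * cv), cv, bg) < 0.0005

    def test_region_statistics_invariants(self, default_dataset):
        meth = default_dataset.methylomes["luminal"]
        umrs = call_umrs(meth)
        bg = meth.background()
        assert (umrs["p_value"] < 0.0005).all()
        assert (umrs["mean_methylation"] < bg).all()
        assert (umrs["n_cpgs"] >= 4).all()
        # sorted and pairwise non-overlapping
        for c, sub in umrs.groupby("chrom"):
            starts, ends = sub["start"].to_numpy(), sub["end"].to_numpy()
            assert (starts[1:] >= ends[:-1]).all()

    def test_planted_umr_recovery(self, default_dataset):
        """Recall, precision and width on the 50 planted regions per cell type."""
        ds = default_dataset
        for ct in ds.config.cell_types:
            umrs = call_umrs(ds.methylomes[ct], cell_type=ct)
            truth = ds.truth_umrs[ds.truth_umrs.cell_type == ct]
            hit = sum(((umrs.chrom == r.chrom) & (umrs.start < r.end)
                       & (umrs.end > r.start)).any() for r in truth.itertuples())
            tp = sum(((truth.chrom == r.chrom) & (truth.start < r.end)
                      & (truth.end > r.start)).any() for r in umrs.itertuples())
            assert hit >= 0.96 * len(truth)
            assert tp >= 0.95 * len(umrs)
            width = (umrs["end"] - umrs["start"]).median()
            planted = ds.config.umr_width
            assert 0.6 * planted <= width <= 1.4 * planted

    def test_hypomethylated_background_warns(self, caplog):
        m = _flat_methylome(2000, level=0.3)
        with caplog.at_level("WARNING"):
            call_umrs(m)
        assert any("globally hypomethylated" in r.message for r in caplog.records)


@pytest.fixture(scope="module")
def medip_fixture():
    sizes = {"1": 1_000_000}
    meth = simulate_regional_methylome(sizes, seed=11)
    signal, mappability = simulate_medip(meth, sizes, seed=12)
    cpg_pos = {c: p for c, (p, _, _) in meth.chroms.items()}
    scores = calibrate_medip(signal, meth.all_fractions(), mappability, cpg_pos)
    return meth, signal, mappability, scores


class TestCalibrateMedip:
    def test_low_mappability_cpgs_absent(self, medip_fixture):
        meth, _, mappability, scores = medip_fixture
        pos = meth.chroms["1"][0]
        low = pos[mappability["1"][pos] < 0.5]
        assert len(low) > 0
        assert not set(low) & set(scores["pos"])
        assert (scores["mappability"] >= 0.5).all()

    def test_quantile_map_is_monotone(self):
        # without density normalization, higher enrichment never lowers the score
        rng = np.random.default_rng(1)
        n = 2000
        pos = np.arange(0, n * 100, 100, dtype=np.int64)
        size = n * 100 + 50_000  # CpG-free tail provides the background
        arr = np.zeros(size)
        arr[pos] = rng.gamma(3, 5, n)
        sig = CoverageTrack({"1": arr + 1.0})
        mp = {"1": np.ones(size)}
        ref = rng.beta(2, 2, 5000)
        out = calibrate_medip(sig, ref, mp, {"1": pos}, coupling_sd=None)
        order = np.argsort(out["raw_enrichment"].to_numpy())
        assert (np.diff(out["score"].to_numpy()[order]) >= -1e-12).all()

    def test_score_distribution_matches_reference(self, medip_fixture):
        meth, _, _, scores = medip_fixture
        assert len(scores) >= 10_000
        ks = stats.ks_2samp(scores["score"], meth.all_fractions()).statistic
        assert ks <= 0.05

    def test_scores_track_true_methylation(self, medip_fixture):
        meth, _, _, scores = medip_fixture
        truth = meth.to_frame().merge(scores, on=["chrom", "pos"])
        rho = stats.spearmanr(truth["fraction"], truth["score"]).statistic
        assert rho >= 0.8
        wgbs_class = np.select([truth["fraction"] < 0.35, truth["fraction"] > 0.8],
                               ["hypomethylated", "hypermethylated"], "intermediate")
        assert (wgbs_class == truth["meth_class"]).mean() >= 0.8

    def test_class_boundaries_exact(self, medip_fixture):
        _, _, _, scores = medip_fixture
        assert (scores.loc[scores["score"] < 0.35, "meth_class"]
                == "hypomethylated").all()
        assert (scores.loc[scores["score"] > 0.8, "meth_class"]
                == "hypermethylated").all()

    def test_empty_reference_rejected(self):
        sig = CoverageTrack({"1": np.ones(1000)})
        with pytest.raises(ValueError):
            calibrate_medip(sig, np.array([]), {"1": np.ones(1000)},
                            {"1": np.array([500])})


class TestBoundaryProfile:
    @staticmethod
    def _methylome_and_junctions(n_junc=200, seed=0):
        rng = np.random.default_rng(seed)
        pos = np.sort(rng.choice(2_000_000, 60_000, replace=False)).astype(np.int64)
        meth = rng.beta(5, 2, len(pos))
        m = MethylomeTrack({"1": (pos, meth, np.full(len(pos), 20, dtype=np.int64))})
        junc = pd.DataFrame({
            "chrom": "1",
            "pos": rng.integers(1000, 1_999_000, n_junc),
            "strand": rng.choice(["+", "-"], n_junc),
            "group": rng.choice(["expressed", "silent"], n_junc),
        })
        return m, junc

    def test_bin_count_is_window_over_bin_both_sides(self):
        m, junc = self._methylome_and_junctions(20)
        prof = boundary_profile(m, junc, window=200, bin_size=20)
        for _, sub in prof.groupby("group"):
            assert len(sub) == 20  # 10 bins per side
            assert set(sub["bin"]) == set(range(-10, 10))

    def test_bin_means_match_brute_force_per_cpg_average(self):
        """Bit-match against a naive per-junction, per-CpG averaging oracle."""
        m, junc = self._methylome_and_junctions(300, seed=3)
        meth_mat, count_mat, bins = boundary_profile_matrix(m, junc)
        pos, meth, _ = m.chroms["1"]
        for r in range(0, len(junc), 37):
            row = junc.iloc[r]
            for k, b in enumerate(bins):
                if row.strand == "+":
                    lo = row.pos + b * 20
                    hi = lo + 20
                else:
                    hi = row.pos - b * 20
                    lo = hi - 20
                sel = (pos >= lo) & (pos < hi)
                assert count_mat[r, k] == sel.sum()
                if sel.any():
                    assert meth_mat[r, k] == meth[sel].mean()
                else:
                    assert np.isnan(meth_mat[r, k])

    def test_uniform_methylome_flat_profiles_and_null_ttest(self):
        rng = np.random.default_rng(5)
        pos = np.arange(0, 500_000, 25, dtype=np.int64)
        m = MethylomeTrack({"1": (pos, np.full(len(pos), 0.8),
                                  np.full(len(pos), 20, dtype=np.int64))})
        junc = pd.DataFrame({"chrom": "1", "pos": rng.integers(1000, 499_000, 100),
                             "strand": "+",
                             "group": ["a"] * 50 + ["b"] * 50})
        prof = boundary_profile(m, junc)
        assert np.allclose(prof["mean_methylation"], 0.8)
        _, p = compare_profile_groups(m, junc, "a", "b")
        assert p > 0.9

    def test_planted_group_difference_detected(self):
        """Boundary enrichment planted only in the expressed group: p < 1e-6."""
        rng = np.random.default_rng(7)
        rows = []
        chrom_pos, chrom_meth = [], []
        cursor = 0
        for i in range(1000):
            group = "expressed" if i < 500 else "not_expressed"
            center = cursor + 500
            pos = np.arange(cursor, cursor + 1000, 25)
            meth = np.clip(rng.normal(0.55, 0.05, len(pos)), 0, 1)
            if group == "expressed":
                near = np.abs(pos - center) <= 200
                meth[near] = np.clip(rng.normal(0.85, 0.05, near.sum()), 0, 1)
            chrom_pos.append(pos)
            chrom_meth.append(meth)
            rows.append(("1", center, "+", group))
            cursor += 1000
        m = MethylomeTrack({"1": (np.concatenate(chrom_pos),
                                  np.concatenate(chrom_meth),
                                  np.full(40_000, 20, dtype=np.int64))})
        junc = pd.DataFrame(rows, columns=["chrom", "pos", "strand", "group"])
        _, p = compare_profile_groups(m, junc, "expressed", "not_expressed")
        assert p < 1e-6

    def test_empty_group_omitted_with_warning(self, caplog):
        m, junc = self._methylome_and_junctions(10)
        junc["group"] = "only"
        prof = boundary_profile(m, junc)
        assert set(prof["group"]) == {"only"}


class TestExonSignalEnrichment:
    def _groups(self):
        return pd.DataFrame({
            "chrom": "1",
            "start": [100, 1000, 5000, 9000],
            "end": [300, 1200, 5200, 9200],
            "group": ["expressed", "expressed", "silent", "silent"],
        })

    def test_uniform_signal_fold_one(self):
        track = make_track({"1": np.ones(10_000)}, assay="h3k36me3")
        out = exon_signal_enrichment(track, self._groups())
        assert np.allclose(out["fold_enrichment"], 1.0)

    def test_fold_invariant_under_doubling(self):
        rng = np.random.default_rng(2)
        arr = rng.poisson(3.0, 10_000).astype(float) + 0.5
        t1 = make_track({"1": arr}, assay="h3k36me3")
        t2 = make_track({"1": arr * 2}, assay="h3k36me3")
        o1 = exon_signal_enrichment(t1, self._groups())
        o2 = exon_signal_enrichment(t2, self._groups())
        np.testing.assert_allclose(o1["fold_enrichment"], o2["fold_enrichment"])

    def test_planted_enrichment_recovered_within_10pct(self):
        rng = np.random.default_rng(4)
        arr = rng.poisson(2.0, 100_000).astype(float)
        groups = pd.DataFrame({
            "chrom": "1",
            "start": np.arange(0, 50_000, 1000),
            "end": np.arange(200, 50_200, 1000),
            "group": "expressed",
        })
        for s, e in zip(groups["start"], groups["end"]):
            arr[s:e] += rng.poisson(8.0, e - s)  # 5x enrichment over mean 2
        silent = pd.DataFrame({"chrom": "1", "start": np.arange(60_000, 80_000, 1000),
                               "end": np.arange(60_200, 80_200, 1000),
                               "group": "silent"})
        track = make_track({"1": arr}, assay="h3k36me3")
        out = exon_signal_enrichment(track, pd.concat([groups, silent]))\
            .set_index("group")
        genome_mean = arr.mean()
        expect_expr = (2 + 8) / genome_mean
        assert out.loc["expressed", "fold_enrichment"] == pytest.approx(
            expect_expr, rel=0.1)
        assert out.loc["expressed", "fold_enrichment"] > out.loc[
            "silent", "fold_enrichment"]

    def test_zero_signal_rejected(self):
        track = make_track({"1": np.zeros(1000)}, library_total=1)
        with pytest.raises(ValueError):
            exon_signal_enrichment(track, self._groups())
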