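"""Expression binning, site counting and chromosome fold changes."""

import numpy as np
import pandas as pd
import pytest

from m6adosage import m6amap
from m6adosage.annotation import TranscriptModel


class TestExpressionBins:
    @pytest.mark.parametrize(
        "tpm,expected",
        [
            (0.5, 0),    # TPM <= 1 unassigned
            (1.0, 0),    # floor is strict
            (1.5, 1),    # log10 ~ 0.176 -> bin 1
            (10.0, 4),   # log10 = 1.0 -> bin 4
            (10 ** 0.49, 1),
            (10 ** 0.5, 2),   # lower edge of bin 2
            (10 ** 2.99, 11),
            (1000.0, 12),     # log10 = 3 collected into outer bin
            (10 ** 5, 12),
        ],
    )
    def test_edge_enumeration(self, tpm, expected):
        assert m6amap.expression_bin(np.array([tpm]))[0] == expected

    def test_partition_every_expressed_transcript_in_one_bin(self, rng):
        tpm = rng.lognormal(3, 2, size=2000)
        bins = m6amap.expression_bin(tpm)
        assert ((bins == 0) == (tpm <= 1.0)).all()
        assert set(np.unique(bins[bins > 0])) <= set(range(1, 13))

    def test_assign_bins_averages_replicates(self):
        tab = pd.DataFrame(
            {"tpm_1": [5.0, 0.5], "tpm_2": [15.0, 0.9]},
            index=pd.Index(["g1", "g2"], name="gene_id"),
        )
        out = m6amap.assign_bins(tab)
        assert out.loc["g1", "tpm_mean"] == 10.0
        assert out.loc["g1", "bin"] == 4
        assert out.loc["g2", "bin"] == 0


def _stop_window_transcript(strand="+"):
    """utr5 20 nt, cds 60 nt, utr3 220 nt on a 300 nt exon."""
    if strand == "+":
        regions = {"utr5": [(0, 20)], "cds": [(20, 80)], "utr3": [(80, 300)]}
    else:
        regions = {"utr5": [(280, 300)], "cds": [(220, 280)], "utr3": [(0, 220)]}
    return TranscriptModel(
        gene_id="g1", transcript_id="t1", chrom="chr1", strand=strand,
        exons=[(0, 300)], regions=regions,
    )


class TestStopWindowCounting:
    # stop codon first base at transcript offset 77 (cds ends at 80)

    @pytest.mark.parametrize("offset,included", [
        (0, True), (-50, True), (150, True), (-51, False), (151, False),
    ])
    def test_window_is_inclusive_201_nt(self, offset, included):
        t = _stop_window_transcript()
        stop = t.stop_codon_offset
        assert stop == 77
        pos = stop + offset  # plus strand: transcript == genomic offset
        sites = pd.DataFrame(
            [{"chrom": "chr1", "pos": pos, "strand": "+", "gene_id": "g1"}]
        )
        counts, ledger = m6amap.count_sites_per_transcript(
            sites, [t], region_filter="stop_window"
        )
        assert counts["g1"] == (1 if included else 0)
        assert ledger["outside_window"] == (0 if included else 1)

    def test_minus_strand_offsets(self):
        t = _stop_window_transcript(strand="-")
        stop = t.stop_codon_offset
        assert stop == 77
        gpos = t.transcript_to_genomic(stop)  # first base of stop codon
        sites = pd.DataFrame(
            [{"chrom": "chr1", "pos": gpos, "strand": "-", "gene_id": "g1"}]
        )
        counts, _ = m6amap.count_sites_per_transcript(
            sites, [t], region_filter="stop_window"
        )
        assert counts["g1"] == 1

    def test_no_filter_counts_all(self):
        t = _stop_window_transcript()
        sites = pd.DataFrame(
            [{"chrom": "chr1", "pos": p, "strand": "+", "gene_id": "g1"}
             for p in (5, 100, 299)]
        )
        counts, _ = m6amap.count_sites_per_transcript(sites, [t])
        assert counts["g1"] == 3

    def test_unknown_gene_is_orphan(self):
        t = _stop_window_transcript()
        sites = pd.DataFrame(
            [{"chrom": "chr1", "pos": 5, "strand": "+", "gene_id": "nope"}]
        )
        counts, ledger = m6amap.count_sites_per_transcript(sites, [t])
        assert ledger["orphans"] == 1


class TestBinProfile:
    def test_identical_counts_zero_width_ci(self):
        counts = pd.Series([1, 1, 1], index=list("abc"))
        bins = pd.Series([4, 4, 4], index=list("abc"))
        out = m6amap.bin_profile(counts, bins)
        row = out.iloc[0]
        assert row["mean"] == 1.0
        assert row["ci_low"] == row["ci_high"] == 1.0

    def test_sem_arithmetic(self):
        counts = pd.Series([0, 2, 4], index=list("abc"))
        bins = pd.Series([4, 4, 4], index=list("abc"))
        row = m6amap.bin_profile(counts, bins).iloc[0]
        sem = 2.0 / np.sqrt(3)
        assert row["mean"] == pytest.approx(2.0)
        assert row["ci_high"] == pytest.approx(2 + 1.959963984540054 * sem)

    def test_singleton_bin_reports_no_ci(self):
        counts = pd.Series([3], index=["a"])
        bins = pd.Series([5], index=["a"])
        row = m6amap.bin_profile(counts, bins).iloc[0]
        assert np.isnan(row["ci_low"])

    def test_weighted_chromosome_means_match_overall(self, rng):
        idx = [f"g{i}" for i in range(60)]
        counts = pd.Series(rng.poisson(2, 60), index=idx)
        bins = pd.Series(4, index=idx)
        chrom = pd.Series([f"chr{i % 3}" for i in range(60)], index=idx)
        out = m6amap.bin_profile(counts, bins, chrom)
        overall = out[out["group"] == "all"].iloc[0]["mean"]
        per = out[out["group"] != "all"]
        weighted = (per["mean"] * per["n"]).sum() / per["n"].sum()
        assert weighted == pytest.approx(overall, rel=1e-12)


class TestChromFoldChange:
    def test_toy_single_bin_hand_arithmetic(self):
        idx = list("abcd")
        counts = pd.Series([2, 2, 1, 1], index=idx)
        bins = pd.Series([4, 4, 4, 4], index=idx)
        chrom = pd.Series(["chrA", "chrA", "chrX", "chrX"], index=idx)
        res = m6amap.chrom_fold_change(
            counts, bins, chrom, bin_range=(4, 4), n_boot=50, seed=0
        )
        pb = res["per_bin"].set_index("chrom")
        assert pb.loc["chrA", "fc"] == pytest.approx(4 / 3)
        assert pb.loc["chrX", "fc"] == pytest.approx(2 / 3)
        w = (res["per_bin"]["n"] * res["per_bin"]["fc"]).sum() / res["per_bin"]["n"].sum()
        assert w == pytest.approx(1.0, abs=1e-12)

    def test_identical_distributions_zero_summaries(self):
        idx = [f"g{i}" for i in range(200)]
        counts = pd.Series(2, index=idx)
        bins = pd.Series([3 + i % 4 for i in range(200)], index=idx)
        chrom = pd.Series([f"chr{i % 5}" for i in range(200)], index=idx)
        res = m6amap.chrom_fold_change(counts, bins, chrom, bin_range=(3, 6), n_boot=50)
        assert np.allclose(res["summary"]["summary_log2fc"], 0.0)

    def test_per_bin_weighted_mean_fc_is_one_exactly(self, default_dataset):
        tr = default_dataset.truth[~default_dataset.truth.is_spikein]
        counts = default_dataset.sites.groupby("gene_id").size().reindex(
            tr.index, fill_value=0
        )
        res = m6amap.chrom_fold_change(
            counts, tr["expression_bin"], tr["chrom"], n_boot=10, seed=0
        )
        for b, g in res["per_bin"].groupby("bin"):
            w = (g["n"] * g["fc"]).sum() / g["n"].sum()
            assert w == pytest.approx(1.0, abs=1e-12)

    def test_missing_stratum_recorded(self):
        idx = list("abcd")
        counts = pd.Series([1, 1, 1, 1], index=idx)
        bins = pd.Series([3, 3, 3, 4], index=idx)
        chrom = pd.Series(["chrA", "chrA", "chrX", "chrA"], index=idx)
        res = m6amap.chrom_fold_change(counts, bins, chrom, bin_range=(3, 4), n_boot=10)
        assert ("chrX", 4) in res["skipped_strata"]


class TestSubsampleFoldChange:
    def _data(self, rng, n=600):
        idx = [f"g{i}" for i in range(n)]
        counts = pd.Series(rng.poisson(2, n), index=idx)
        bins = pd.Series([3 + i % 3 for i in range(n)], index=idx)
        chrom = pd.Series([f"chr{i % 4}" for i in range(n)], index=idx)
        return counts, bins, chrom

    def test_identical_chromosomes_centered_at_zero(self, rng):
        counts, bins, chrom = self._data(rng)
        res = m6amap.subsample_fold_change(counts, bins, chrom, reps=50, seed=3)
        assert res["distribution"]["median"].abs().max() < 0.25

    def test_fixed_seed_reproducible(self, rng):
        counts, bins, chrom = self._data(rng)
        a = m6amap.subsample_fold_change(counts, bins, chrom, reps=20, seed=9)
        b = m6amap.subsample_fold_change(counts, bins, chrom, reps=20, seed=9)
        pd.testing.assert_frame_equal(a["distribution"], b["distribution"])

    def test_short_strata_flagged(self, rng):
        counts, bins, chrom = self._data(rng, n=40)
        res = m6amap.subsample_fold_change(
            counts, bins, chrom, n_per_bin=30, reps=5, seed=1
        )
        assert len(res["short_strata"]) > 0

    def test_consistent_with_full_data_summary(self, default_dataset):
        tr = default_dataset.truth[~default_dataset.truth.is_spikein]
        counts = default_dataset.sites.groupby("gene_id").size().reindex(
            tr.index, fill_value=0
        )
        full = m6amap.chrom_fold_change(
            counts, tr["expression_bin"], tr["chrom"],
            bin_range=(3, 5), n_boot=10, seed=0
        )
        sub = m6amap.subsample_fold_change(
            counts, tr["expression_bin"], tr["chrom"],
            bin_range=(3, 5), reps=100, seed=0
        )
        x_full = full["summary"].set_index("chrom").loc["chrX", "summary_log2fc"]
        dist = sub["distribution"].set_index("chrom")
        assert dist.loc["chrX", "iqr_low"] - 0.5 < x_full < dist.loc["chrX", "iqr_high"] + 0.5


class TestFractionMethylated:
    def _motifs(self):
        return pd.DataFrame(
            {
                "gene_id": ["g1"] * 10,
                "chrom": ["chr1"] * 10,
                "strand": ["+"] * 10,
                "pos": list(range(10, 110, 10)),
            }
        )

    def test_counting(self):
        motifs = self._motifs()
        sites = motifs.iloc[:3][["chrom", "pos", "strand", "gene_id"]]
        out = m6amap.fraction_motifs_methylated(sites, motifs)
        assert out.loc[0, "fraction"] == pytest.approx(0.3)

    def test_no_sites_zero(self):
        motifs = self._motifs()
        sites = pd.DataFrame(columns=["chrom", "pos", "strand", "gene_id"])
        out = m6amap.fraction_motifs_methylated(sites, motifs)
        assert out.loc[0, "fraction"] == 0.0

    def test_all_methylated_one(self):
        motifs = self._motifs()
        sites = motifs[["chrom", "pos", "strand", "gene_id"]]
        out = m6amap.fraction_motifs_methylated(sites, motifs)
        assert out.loc[0, "fraction"] == 1.0

    def test_round_trip_on_synthetic_truth(self, small_dataset):
        ds = small_dataset
        motifs = ds.motifs
        out = m6amap.fraction_motifs_methylated(
            ds.sites, motifs[["gene_id", "chrom", "strand", "pos"]]
        )
        expected = ds.sites.groupby("chrom").size() / motifs.groupby("chrom").size()
        for row in out.itertuples():
            assert row.fraction == pytest.approx(expected[row.chrom])


class TestPeakDensityRatio:
    def test_uniform_density_all_ones(self):
        counts = {"chr1": 10, "chr2": 20, "chr3": 30}
        lengths = {"chr1": 1000, "chr2": 2000, "chr3": 3000}
        out = m6amap.peak_density_ratio(counts, lengths)
        assert np.allclose(out, 1.0)

    def test_double_density_ratio_two(self):
        counts = {"chr1": 10, "chr2": 10, "chr3": 20}
        lengths = {"chr1": 1000, "chr2": 1000, "chr3": 1000}
        out = m6amap.peak_density_ratio(counts, lengths)
        assert out["chr3"] == pytest.approx(2.0)

    def test_zero_peaks_zero_ratio(self):
        counts = {"chr1": 10, "chr2": 0, "chr3": 10}
        lengths = {"chr1": 1000, "chr2": 1000, "chr3": 1000}
        assert m6amap.peak_density_ratio(counts, lengths)["chr2"] == 0.0

    def test_positive_length_required(self):
        with pytest.raises(ValueError):
            m6amap.peak_density_ratio({"chr1": 1}, {"chr1": 0})
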