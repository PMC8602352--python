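import numpy as np
import pandas as pd
import pytest

from k27tools.chip import (FragmentSet, bin_counts, filter_fragments,
                           h3k27me3_level, promoter_rpkm, scaled_metagene,
                           tss_profile)
from k27tools.annotation import promoter_windows
from conftest import frags


class TestFiltering:
    def test_mapq_threshold_inclusive(self):
        fs = filter_fragments(frags([("chr1", 0, 150, 19), ("chr1", 200, 350, 20)]))
        assert fs.library_size == 1 and fs.n_lowmapq == 1
        assert fs.df.iloc[0]["start"] == 200

    def test_exact_duplicates_collapsed(self):
        fs = filter_fragments(frags([("chr1", 0, 150, 30)] * 3))
        assert fs.library_size == 1 and fs.n_duplicates == 2

    def test_empty_input(self):
        fs = filter_fragments(pd.DataFrame(columns=["chrom", "start", "end", "mapq"]))
        assert fs.library_size == 0

    def test_malformed_rejected_with_count(self):
        fs = filter_fragments(frags([("chr1", 100, 100, 30), ("chr1", 0, 150, 30)]))
        assert fs.n_malformed == 1 and fs.library_size == 1

    def test_missing_mapq_column_passes_all(self):
        fs = filter_fragments(frags([("chr1", 0, 150), ("chr1", 10, 160)]))
        assert fs.library_size == 2 and fs.n_lowmapq == 0


class TestBinning:
    sizes = {"chr1": 1000}

    def test_midpoint_assignment(self):
        fs = filter_fragments(frags([("chr1", 0, 150, 30), ("chr1", 190, 340, 30)]))
        track = bin_counts(fs, self.sizes, w=200)
        assert track.counts["chr1"][0] == 1  # midpoint 75
        assert track.counts["chr1"][1] == 1  # midpoint 265

    def test_conservation(self, rng):
        starts = rng.integers(0, 800, size=200)
        fs = filter_fragments(pd.DataFrame(
            {"chrom": "chr1", "start": starts, "end": starts + 150,
             "mapq": 30 + np.arange(200) % 2}))
        track = bin_counts(fs, self.sizes, w=200)
        assert track.counts["chr1"].sum() == fs.library_size

    def test_fragment_beyond_chrom_end_raises(self):
        fs = FragmentSet(frags([("chr1", 900, 1050)]))
        with pytest.raises(ValueError, match="beyond"):
            bin_counts(fs, self.sizes, w=200)


class TestPromoterRPKM:
    def test_direct_formula(self):
        starts = np.arange(100) * 50 + 20_000
        fs = FragmentSet(pd.DataFrame({"chrom": "chr1", "start": starts, "end": starts + 100}))
        windows = pd.DataFrame({"chrom": ["chr1"], "start": [20_000], "end": [30_000]},
                               index=["g1"])
        # fake a 10^7 library by padding far-away fragments
        pad = pd.DataFrame({"chrom": "chr2",
                            "start": np.zeros(10**4 - 100, dtype=int),
                            "end": np.ones(10**4 - 100, dtype=int)})
        fs_full = FragmentSet(pd.concat([fs.df, pad], ignore_index=True))
        # RPKM = 100 / (10 kb * 0.01 M) with a 10^4 library
        assert promoter_rpkm(fs_full, windows)["g1"] == pytest.approx(
            100 / (10 * (10**4 / 1e6)))

    def test_empty_window_and_scaling(self):
        fs = FragmentSet(frags([("chr1", 0, 100), ("chr1", 50_000, 50_100)]))
        windows = pd.DataFrame({"chrom": ["chr1"], "start": [20_000], "end": [30_000]},
                               index=["g1"])
        assert promoter_rpkm(fs, windows)["g1"] == 0.0
        double = FragmentSet(pd.concat([fs.df, frags([("chr2", 0, 100), ("chr2", 5, 105)])],
                                       ignore_index=True))
        windows2 = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [10_000]},
                                index=["g1"])
        r1 = promoter_rpkm(fs, windows2)["g1"]
        r2 = promoter_rpkm(double, windows2)["g1"]
        assert r2 == pytest.approx(r1 / 2)

    def test_order_invariance(self, rng):
        starts = rng.integers(0, 90_000, size=500)
        df = pd.DataFrame({"chrom": "chr1", "start": starts, "end": starts + 150})
        windows = pd.DataFrame({"chrom": ["chr1"], "start": [40_000], "end": [50_000]},
                               index=["g1"])
        a = promoter_rpkm(FragmentSet(df), windows)
        b = promoter_rpkm(FragmentSet(df.iloc[::-1].reset_index(drop=True)), windows)
        pd.testing.assert_series_equal(a, b)

    def test_empty_library_raises(self):
        fs = FragmentSet(pd.DataFrame(columns=["chrom", "start", "end"]))
        with pytest.raises(ValueError):
            promoter_rpkm(fs, pd.DataFrame({"chrom": [], "start": [], "end": []}))


class TestLevel:
    def test_equal_channels_give_unity(self):
        ip = pd.DataFrame({"r1": [1.0], "r2": [2.0]}, index=["g1"])
        assert h3k27me3_level(ip, ip)["g1"] == pytest.approx(1.0)

    def test_ratio_then_average(self):
        ip = pd.DataFrame({"r1": [1.9], "r2": [3.9]}, index=["g1"])
        inp = pd.DataFrame({"r1": [0.9], "r2": [0.9]}, index=["g1"])
        assert h3k27me3_level(ip, inp, eps=0.1)["g1"] == pytest.approx(3.0)

    def test_average_then_ratio_mode(self):
        ip = pd.DataFrame({"r1": [1.9], "r2": [3.9]}, index=["g1"])
        inp = pd.DataFrame({"r1": [0.9], "r2": [0.9]}, index=["g1"])
        lvl = h3k27me3_level(ip, inp, eps=0.1, mode="average_then_ratio")
        assert lvl["g1"] == pytest.approx((2.9 + 0.1) / (0.9 + 0.1))

    def test_zero_signal_stabilised(self):
        z = pd.DataFrame({"r1": [0.0], "r2": [0.0]}, index=["g1"])
        assert h3k27me3_level(z, z)["g1"] == pytest.approx(1.0)

    def test_replicate_mismatch_raises(self):
        ip = pd.DataFrame({"r1": [1.0]}, index=["g1"])
        inp = pd.DataFrame({"r1": [1.0], "r2": [1.0]}, index=["g1"])
        with pytest.raises(ValueError):
            h3k27me3_level(ip, inp)


class TestProfiles:
    def test_identical_channels_flat_zero(self, toy_genome, rng):
        starts = rng.integers(0, 99_000, size=2000)
        fs = FragmentSet(pd.DataFrame({"chrom": "chr1", "start": starts, "end": starts + 150}))
        strata = pd.Series({"gA": "high", "gB": "low"})
        prof = tss_profile([fs], [fs], toy_genome, strata, flank=5000, profile_bin=500)
        assert np.allclose(prof.to_numpy(), 0.0)

    def test_minus_strand_orientation(self, toy_genome):
        # gB: minus strand, TSS at 69,999; spike 1 kb genomically downstream
        spike = 69_999 + 1000
        ip = FragmentSet(pd.DataFrame({"chrom": "chr1",
                                       "start": np.full(200, spike - 75),
                                       "end": np.full(200, spike + 75)}))
        inp_starts = np.linspace(0, 99_000, 400).astype(int)
        inp = FragmentSet(pd.DataFrame({"chrom": "chr1", "start": inp_starts,
                                        "end": inp_starts + 150}))
        strata = pd.Series({"gB": "low"})
        prof = tss_profile([ip], [inp], toy_genome, strata, flank=5000, profile_bin=200)
        peak_pos = prof.loc["low"].idxmax()
        assert -1200 <= peak_pos <= -800  # appears upstream on the oriented axis

    def test_scaled_metagene_shape_and_flatness(self, toy_genome, rng):
        starts = rng.integers(0, 99_000, size=3000)
        fs = FragmentSet(pd.DataFrame({"chrom": "chr1", "start": starts, "end": starts + 150}))
        curve, n_skip = scaled_metagene([fs], [fs], toy_genome, flank=2000,
                                        profile_bin=100, n_body_bins=30)
        assert len(curve) == 2 * (2000 // 100) + 30
        assert n_skip == 0
        assert np.allclose(curve.to_numpy(), 0.0)

    def test_short_genes_skipped(self, toy_genome, rng):
        starts = rng.integers(0, 99_000, size=500)
        fs = FragmentSet(pd.DataFrame({"chrom": "chr1", "start": starts, "end": starts + 150}))
        curve, n_skip = scaled_metagene([fs], [fs], toy_genome, n_body_bins=30_000)
        assert n_skip == 2


def test_promoter_window_consistency_across_modules(toy_genome):
    """The promoter windows used for RPKM are the same objects used for
    promoter-modified gene sets (one definition, one midpoint rule)."""
    windows = promoter_windows(toy_genome, flank=5000)
    tssA = toy_genome.by_id["gA"].tss
    assert windows.loc["gA", "start"] == tssA - 5000
    assert windows.loc["gA", "end"] == tssA + 5000
    mid = (windows.loc["gA", "start"] + windows.loc["gA", "end"]) // 2
    fs = FragmentSet(frags([("chr1", int(mid) - 75, int(mid) + 75)]))
    assert promoter_rpkm(fs, windows)["gA"] > 0


def test_bedgraph_writer_round_trips_counts(tmp_path, rng):
    starts = rng.integers(0, 800, size=120)
    fs = filter_fragments(pd.DataFrame(
        {"chrom": "chr1", "start": starts, "end": starts + 150,
         "mapq": np.full(120, 30)}))
    track = bin_counts(fs, {"chr1": 1000}, w=200)
    path = tmp_path / "sig.bedgraph"
    from k27tools.chip import write_bedgraph
    write_bedgraph(track, {"chr1": 1000}, path, normalise=False)
    rows = [l.split("\t") for l in path.read_text().splitlines()]
    assert sum(float(r[3]) for r in rows) == fs.library_size
    assert all(int(r[2]) <= 1000 for r in rows)
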