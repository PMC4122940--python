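"""Window pairing, masking, binomial discordance and flanking profiles."""

import numpy as np
import pandas as pd
import pytest

from paradiverge import chromdiv, io
from paradiverge.chromdiv import (
    MappabilityTrack,
    WindowPair,
    classify_discordant_windows,
    count_reads_in_windows,
    flanking_read_profile,
    make_window_pairs,
)
from paradiverge.chromdiv import test_window_discordance as window_binomial
from paradiverge.dupmap import CpGSite
from paradiverge.methdiv import MethylCounts, ParalogousCpGPair

from conftest import build_alignment


def full_mappability(*chroms, length=100_000):
    return MappabilityTrack({c: np.array([[0, length]]) for c in chroms})


def reads_df(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])


class TestWindowPairs:
    def test_fully_mappable_2kb_duplicon(self):
        rng = np.random.default_rng(0)
        aln, _ = build_alignment(rng, n_match=2000, start_a=0, start_b=10_000)
        windows = make_window_pairs(aln, full_mappability("cA", "cB"))
        assert len(windows) == 4
        assert all(w.mask_size == 500 for w in windows)

    def test_trailing_partial_window_dropped(self):
        rng = np.random.default_rng(1)
        aln, _ = build_alignment(rng, n_match=1750)
        windows = make_window_pairs(aln, full_mappability("cA", "cB"))
        assert len(windows) == 3

    def test_one_sided_nonunique_position_excluded_from_both(self):
        rng = np.random.default_rng(2)
        aln, _ = build_alignment(rng, n_match=1500, start_a=0, start_b=10_000)
        # mask out 100 bp of copy B only
        mapp = MappabilityTrack(
            {"cA": np.array([[0, 100_000]]),
             "cB": np.array([[0, 10_100], [10_200, 100_000]])}
        )
        windows = make_window_pairs(aln, mapp)
        assert windows[0].mask_size == 400  # symmetric exclusion
        assert not np.isin(np.arange(10_100, 10_200), windows[0].mask_b).any()

    def test_gap_columns_never_in_mask(self):
        rng = np.random.default_rng(3)
        aln, _ = build_alignment(rng, n_match=1500, n_del_b=30)
        windows = make_window_pairs(aln, full_mappability("cA", "cB"))
        total_mask = sum(w.mask_size for w in windows)
        n_windows = len(windows)
        assert total_mask < n_windows * 500  # deletions removed from masks

    def test_mask_symmetry_under_copy_swap(self):
        rng = np.random.default_rng(4)
        aln, _ = build_alignment(rng, n_match=1500, n_ins_b=20, n_del_b=20)
        mapp = full_mappability("cA", "cB")
        fwd = make_window_pairs(aln, mapp)
        pos_pairs_fwd = {
            (int(a), int(b)) for w in fwd for a, b in zip(w.mask_a, w.mask_b)
        }
        # every masked (a, b) position pair is kept iff unique in both copies
        for a, b in pos_pairs_fwd:
            assert mapp.is_mappable("cA", np.array([a]))[0]
            assert mapp.is_mappable("cB", np.array([b]))[0]


class TestBinomial:
    def test_balanced_window_not_significant(self):
        w = WindowPair("c", "c", 0, 500, np.arange(500), np.arange(500),
                       count_a=7, count_b=7)
        assert window_binomial(w) == 1.0

    def test_one_copy_zero(self):
        w = WindowPair("c", "c", 0, 500, np.arange(500), np.arange(500),
                       count_a=10, count_b=0)
        assert window_binomial(w) == pytest.approx(2 * 0.5**10, abs=1e-15)

    def test_untestable_window_raises(self):
        w = WindowPair("c", "c", 0, 500, np.arange(500), np.arange(500))
        with pytest.raises(ValueError):
            window_binomial(w)

    def test_significant_but_nonzero_not_discordant(self):
        # (40, 2) is deeply significant yet both copies have reads
        windows = [
            WindowPair("c", "c", i * 500, (i + 1) * 500, np.arange(500), np.arange(500))
            for i in range(3)
        ]
        windows[0].count_a, windows[0].count_b = 40, 2
        windows[1].count_a, windows[1].count_b = 30, 0
        windows[2].count_a, windows[2].count_b = 5, 6
        disc = classify_discordant_windows(windows)
        assert disc == [windows[1]]
        assert windows[0].p_value < 0.05 / 3 and not windows[0].discordant


class TestCounting:
    def test_count_conservation_across_windows(self):
        rng = np.random.default_rng(5)
        aln, _ = build_alignment(rng, n_match=2000, start_a=0, start_b=10_000)
        windows = make_window_pairs(aln, full_mappability("cA", "cB"))
        positions = rng.integers(0, 2000, size=300)
        rows = [("cA", int(p), int(p) + 36, "m", 0, "+") for p in positions]
        count_reads_in_windows(windows, reads_df(rows))
        assert sum(w.count_a for w in windows) == len(positions)
        assert sum(w.count_b for w in windows) == 0

    def test_five_prime_assignment_for_minus_strand(self):
        rng = np.random.default_rng(6)
        aln, _ = build_alignment(rng, n_match=1500, start_a=0, start_b=10_000)
        windows = make_window_pairs(aln, full_mappability("cA", "cB"))
        # minus-strand read ending at 499 -> 5' position 498 -> first window
        rows = [("cA", 463, 499, "m", 0, "-")]
        count_reads_in_windows(windows, reads_df(rows))
        assert windows[0].count_a == 1

    def test_planted_one_copy_zero_windows_recovered(self, bundle):
        out, cfg, truth = bundle
        from paradiverge import dupmap

        alignments = dupmap.parse_duplication_alignments(out / "alignments.txt")
        mapp = MappabilityTrack.from_bed(io.read_bed(out / "mappability.bed"))
        windows = []
        for idx, aln in enumerate(alignments):
            windows.extend(make_window_pairs(aln, mapp, alignment_index=idx))
        reads = io.read_bed(out / "reads_H3K4me3.bed")
        count_reads_in_windows(windows, reads)
        disc = classify_discordant_windows(windows)
        planted = {(w["chrom_a"], w["a_start"]) for w in truth.planted_windows}
        called = {(w.chrom_a, w.a_start) for w in disc}
        assert len(called & planted) / len(planted) >= 0.9
        # the zero-copy rule is never violated
        for w in disc:
            assert min(w.count_a, w.count_b) == 0


class TestFlankProfile:
    def _disc_pair(self, pos_a, pos_b, hyper="a"):
        p = ParalogousCpGPair(
            site_a=CpGSite("cA", pos_a), site_b=CpGSite("cB", pos_b),
            counts_a=MethylCounts(9, 1), counts_b=MethylCounts(1, 9),
        )
        p.hyper = hyper
        return p

    def test_no_reads_gives_na(self):
        pairs = [self._disc_pair(1000, 2000)]
        res = flanking_read_profile(pairs, reads_df([]))
        assert np.isnan(res["wilcoxon_p"])
        assert res["hyper_counts"].sum() == 0

    def test_symmetric_reads_give_no_signal(self):
        pairs = [self._disc_pair(1000 * i, 1000 * i) for i in range(2, 12)]
        rows = []
        for i in range(2, 12):
            rows += [("cA", 1000 * i - 50, 1000 * i - 14, "m", 0, "+"),
                     ("cB", 1000 * i - 50, 1000 * i - 14, "m", 0, "+")]
        res = flanking_read_profile(pairs, reads_df(rows))
        assert np.isnan(res["wilcoxon_p"])  # all differences zero

    def test_planted_enrichment_at_hypo_copies_detected(self):
        rng = np.random.default_rng(7)
        pairs = [self._disc_pair(5000 * (i + 1), 5000 * (i + 1)) for i in range(50)]
        rows = []
        for i in range(50):
            center = 5000 * (i + 1)
            for _ in range(int(rng.poisson(20))):  # 10x enrichment at hypo copy
                p = int(rng.integers(center - 400, center + 400))
                rows.append(("cB", p, p + 36, "m", 0, "+"))
            for _ in range(int(rng.poisson(2))):
                p = int(rng.integers(center - 400, center + 400))
                rows.append(("cA", p, p + 36, "m", 0, "+"))
        res = flanking_read_profile(pairs, reads_df(rows))
        assert res["wilcoxon_p"] < 0.01
        assert res["hypo_counts"].mean() > res["hyper_counts"].mean()
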