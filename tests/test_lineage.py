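"""Ancestral assignment, insertion detection, profiles and expression links."""

import numpy as np
import pandas as pd
import pytest

from paradiverge import io, lineage
from paradiverge.dupmap import CpGSite
from paradiverge.io import Chain
from paradiverge.lineage import (
    ChainMap,
    InsertionEvent,
    OrthologousCpG,
    assign_ancestral_derived,
    detect_lineage_specific_insertions,
    expression_linkage,
    flanking_methylation_profile,
    match_orthologous_cpgs,
    paired_flank_test,
    select_remodeled_sites,
)
from paradiverge.methdiv import MethylCounts, ParalogousCpGPair
from paradiverge.simulate import simulate_ortho_sites


def chain(t_name, q_name, blocks, t_start=0, q_start=0, t_size=10**6, q_size=10**6,
          cid=1, q_strand="+"):
    t_end = t_start + sum(s + dt for s, dt, _ in blocks)
    q_end = q_start + sum(s + dq for s, _, dq in blocks)
    return Chain(score=1000, t_name=t_name, t_size=t_size, t_start=t_start,
                 t_end=t_end, q_name=q_name, q_size=q_size, q_strand=q_strand,
                 q_start=q_start, q_end=q_end, chain_id=cid, blocks=blocks)


class TestChainMap:
    def test_simple_projection_and_gap(self):
        cm = ChainMap([chain("chr1", "q1", [(100, 50, 0), (100, 0, 0)])])
        assert cm.project("chr1", 10) == ("q1", 10)
        assert cm.project("chr1", 120) is None  # inside the dt gap
        assert cm.project("chr1", 160) == ("q1", 110)

    def test_round_trip_through_chain_file(self, tmp_path):
        ch = chain("chr1", "q1", [(100, 10, 5), (200, 0, 0)])
        io.write_chain_file([ch], tmp_path / "c.chain")
        back = io.read_chain_file(tmp_path / "c.chain")
        assert len(back) == 1 and back[0].blocks == ch.blocks
        assert ChainMap(back).project("chr1", 115) == ("q1", 110)

    def test_coverage_fraction(self):
        cm = ChainMap([chain("chr1", "q1", [(100, 100, 0), (100, 0, 0)])])
        assert cm.coverage_fraction("chr1", 0, 100) == 1.0
        assert cm.coverage_fraction("chr1", 100, 200) == 0.0
        assert cm.coverage_fraction("chr1", 50, 150) == 0.5

    def test_minus_strand_query(self):
        cm = ChainMap([chain("chr1", "q1", [(100, 0, 0)], q_strand="-", q_size=1000)])
        assert cm.project("chr1", 0) == ("q1", 999)
        assert cm.project("chr1", 99) == ("q1", 900)


def _pair(chrom_a, pos_a, chrom_b, pos_b):
    return ParalogousCpGPair(
        site_a=CpGSite(chrom_a, pos_a), site_b=CpGSite(chrom_b, pos_b),
        counts_a=MethylCounts(5, 5), counts_b=MethylCounts(5, 5),
    )


class TestAncestral:
    def setup_method(self):
        # chr1 maps to og_chr1; a redirect lifts chr2:5000-8000 onto og_chr1
        self.cmap = ChainMap([
            chain("chr1", "og_chr1", [(100_000, 0, 0)], cid=1),
            chain("chr2", "og_chr1", [(3000, 0, 0)], t_start=5000, q_start=2000, cid=2),
        ])
        self.synteny = {"chr1": "og_chr1", "chr2": "og_chr2"}

    def test_syntenic_copy_is_ancestral(self):
        pair = _pair("chr1", 2500, "chr2", 6000)
        assert assign_ancestral_derived(pair, self.cmap, self.synteny) == "a"
        pair_swapped = _pair("chr2", 6000, "chr1", 2500)
        assert assign_ancestral_derived(pair_swapped, self.cmap, self.synteny) == "b"

    def test_failed_lift_is_undetermined(self):
        pair = _pair("chr1", 2500, "chr2", 50_000)  # outside the redirect
        assert assign_ancestral_derived(pair, self.cmap, self.synteny) == "undetermined"

    def test_intrachromosomal_pair_rejected(self):
        with pytest.raises(ValueError):
            assign_ancestral_derived(_pair("chr1", 100, "chr1", 5000), self.cmap, {})

    def test_bundle_truth_agreement(self, bundle, bundle_retained):
        out, cfg, truth = bundle
        retained, _ = bundle_retained
        polarity = ChainMap(io.read_chain_file(out / "polarity.chain"))
        syn = pd.read_csv(out / "synteny.tsv", sep="\t")
        synteny = dict(zip(syn["chrom"], syn["outgroup_chrom"]))
        agree = total = 0
        for p in retained:
            if p.site_a.chrom == p.site_b.chrom:
                continue
            want = truth.ancestral_copy_per_pair.get(p.key)
            if want is None:
                continue
            got = assign_ancestral_derived(p, polarity, synteny)
            if got == "undetermined":
                continue
            total += 1
            agree += got == want
        assert total > 0
        assert agree / total >= 0.95


def _repeats(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])


class TestInsertionDetection:
    def test_covered_element_not_called(self):
        m_cov = ChainMap([chain("chr1", "q1", [(10_000, 0, 0)])])
        m_gap = ChainMap([chain("chr1", "q2", [(4000, 300, 0), (5700, 0, 0)])])
        reps = _repeats([("chr1", 4000, 4300, "AluY", 0, "+")])
        # present in outgroup1 (fully covered) -> not lineage-specific
        assert detect_lineage_specific_insertions(reps, m_cov, m_gap) == []

    def test_absent_with_syntenic_flanks_called(self):
        m1 = ChainMap([chain("chr1", "q1", [(4000, 300, 0), (5700, 0, 0)])])
        m2 = ChainMap([chain("chr1", "q2", [(4000, 300, 0), (5700, 0, 0)])])
        reps = _repeats([("chr1", 4000, 4300, "AluYa5", 0, "+")])
        events = detect_lineage_specific_insertions(reps, m1, m2)
        assert len(events) == 1
        assert events[0].family == "AluYa5" and events[0].start == 4000

    def test_unaligned_flank_suppresses_call(self):
        # nothing aligns around the element: an alignment hole, not an insertion
        m1 = ChainMap([chain("chr1", "q1", [(3000, 2000, 0), (5000, 0, 0)])])
        m2 = ChainMap([chain("chr1", "q2", [(3000, 2000, 0), (5000, 0, 0)])])
        reps = _repeats([("chr1", 4000, 4300, "AluY", 0, "+")])
        assert detect_lineage_specific_insertions(reps, m1, m2) == []

    def test_bundle_detection_is_exact(self, bundle):
        out, cfg, truth = bundle
        m1 = ChainMap(io.read_chain_file(out / "outgroup1.chain"))
        m2 = ChainMap(io.read_chain_file(out / "outgroup2.chain"))
        reps = io.read_bed(out / "repeats.bed")
        events = detect_lineage_specific_insertions(reps, m1, m2, families=("Alu",))
        detected = {(e.chrom, e.start, e.end) for e in events}
        planted = {
            (e["chrom"], e["start"], e["end"])
            for e in truth.insertion_events
            if e["lineage"] == "human"
        }
        assert detected == planted


def _sites(levels_x, levels_y, positions, depth=100):
    out = []
    for lx, ly, p in zip(levels_x, levels_y, positions):
        mx, my = round(lx * depth), round(ly * depth)
        out.append(OrthologousCpG("chr1", p, p, MethylCounts(mx, depth - mx),
                                  MethylCounts(my, depth - my)))
    return out


class TestProfilesAndTests:
    def test_null_profile_species_agree(self):
        events, sites, _ = simulate_ortho_sites(max_elevation=0.0, seed=0)
        prof = flanking_methylation_profile(events, sites)
        filled = prof.dropna()
        overlap = (filled["ci_lo_x"] <= filled["ci_hi_y"]) & (
            filled["ci_lo_y"] <= filled["ci_hi_x"]
        )
        assert overlap.mean() > 0.9

    def test_planted_elevation_decays_with_distance(self):
        events, sites, _ = simulate_ortho_sites(max_elevation=0.2, decay=300, seed=1)
        prof = flanking_methylation_profile(events, sites).dropna()
        gain = prof["mean_x"] - prof["mean_y"]
        center = gain[(prof["win_start"] >= -250) & (prof["win_end"] <= 250 + 500)]
        far = gain[np.abs(prof["win_start"]) >= 1500]
        assert center.mean() > far.mean() + 0.05

    def test_max_dist_smaller_than_window_rejected(self):
        with pytest.raises(ValueError):
            flanking_methylation_profile([], [], window=500, max_dist=400)

    def test_empty_window_is_na(self):
        ev = [InsertionEvent("human", "AluY", "chr1", 10_000, 10_300)]
        sites = _sites([0.5], [0.5], [10_500])
        prof = flanking_methylation_profile(ev, sites)
        assert prof["mean_x"].isna().any()

    def test_paired_t_identical_levels(self):
        ev = [InsertionEvent("human", "AluY", "chr1", 1000, 1300)]
        sites = _sites([0.2, 0.4, 0.6], [0.2, 0.4, 0.6], [900, 1500, 1800])
        res = paired_flank_test(ev, sites)
        assert res["t"] == 0.0 and res["p"] == 1.0

    def test_paired_t_closed_form_on_five_site_fixture(self):
        ev = [InsertionEvent("human", "AluY", "chr1", 1000, 1300)]
        lx = [0.30, 0.45, 0.52, 0.61, 0.70]
        ly = [0.20, 0.40, 0.50, 0.55, 0.58]
        sites = _sites(lx, ly, [600, 800, 1400, 1600, 1800], depth=100)
        res = paired_flank_test(ev, sites)
        d = np.array([s.level_x - s.level_y for s in sites])
        t_hand = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        assert res["t"] == pytest.approx(t_hand, rel=1e-12)

    def test_planted_shift_power(self):
        events, sites, _ = simulate_ortho_sites(
            max_elevation=0.0, shift=0.15, n_events=10, sites_per_event=50, seed=2
        )
        res = paired_flank_test(events, sites, radius=1000)
        assert res["p"] < 1e-6

    def test_insufficient_sites_na(self):
        ev = [InsertionEvent("human", "AluY", "chr1", 1000, 1300)]
        res = paired_flank_test(ev, _sites([0.5], [0.5], [1500]))
        assert np.isnan(res["p"])


class TestRemodeling:
    def _event(self):
        return [InsertionEvent("human", "AluY", "chr1", 10_000, 10_300)]

    def test_threshold_boundaries(self):
        ev = self._event()
        fg_site = _sites([0.99], [0.39], [10_500])  # low outgroup, big gain
        bg_site = _sites([0.50], [0.39], [10_600])  # low outgroup, small gain
        out_site = _sites([0.99], [0.41], [10_700])  # outgroup not low
        bg, fg = select_remodeled_sites(fg_site + bg_site + out_site, ev)
        assert fg == fg_site
        assert set(map(id, bg)) == set(map(id, fg_site + bg_site))

    def test_distance_cut(self):
        ev = self._event()
        near = _sites([0.99], [0.10], [11_000])
        far = _sites([0.99], [0.10], [20_000])
        bg, fg = select_remodeled_sites(near + far, ev)
        assert fg == near

    def test_expression_tally_sign_test(self):
        fg = _sites([0.9, 0.9], [0.1, 0.1], [10_500, 30_000])
        genes = pd.DataFrame(
            {
                "gene": ["g1", "g2", "g3"],
                "chrom": ["chr1"] * 3,
                "tss": [10_600, 30_200, 90_000],
                "expr_x": [1.0, 2.0, 5.0],
                "expr_y": [3.0, 6.0, 5.0],
            }
        )
        res = expression_linkage(genes, fg)
        assert res["lower"] == 2 and res["higher"] == 0
        assert res["sign_test_p"] == pytest.approx(2 * 0.5**2)

    def test_empty_foreground_empty_tally(self):
        genes = pd.DataFrame(
            {"gene": ["g"], "chrom": ["chr1"], "tss": [100],
             "expr_x": [1.0], "expr_y": [2.0]}
        )
        res = expression_linkage(genes, [])
        assert res["lower"] == res["higher"] == 0
        assert np.isnan(res["sign_test_p"])


class TestOrthologMatching:
    def test_depth_filter_and_lift(self, bundle):
        out, cfg, truth = bundle
        m1 = ChainMap(io.read_chain_file(out / "outgroup1.chain"))
        cov_h = io.coverage_dict(io.read_coverage(out / "coverage_human_brain.tsv"))
        cov_o = io.coverage_dict(io.read_coverage(out / "coverage_outgroup_brain.tsv"))
        sites = match_orthologous_cpgs(cov_h, cov_o, m1, min_depth=5)
        assert len(sites) > 0
        for s in sites[:200]:
            assert s.counts_x.depth >= 5 and s.counts_y.depth >= 5

    def test_profile_invariant_to_site_order(self, bundle):
        out, cfg, truth = bundle
        m1 = ChainMap(io.read_chain_file(out / "outgroup1.chain"))
        cov_h = io.coverage_dict(io.read_coverage(out / "coverage_human_brain.tsv"))
        cov_o = io.coverage_dict(io.read_coverage(out / "coverage_outgroup_brain.tsv"))
        sites = match_orthologous_cpgs(cov_h, cov_o, m1)
        events = [
            InsertionEvent(e["lineage"], e["family"], e["chrom"], e["start"], e["end"])
            for e in truth.insertion_events
            if e["lineage"] == "human"
        ]
        p1 = flanking_methylation_profile(events, sites)
        rng = np.random.default_rng(0)
        shuffled = [sites[i] for i in rng.permutation(len(sites))]
        p2 = flanking_methylation_profile(events, shuffled)
        pd.testing.assert_frame_equal(p1, p2)
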