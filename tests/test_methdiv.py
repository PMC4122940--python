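"""Filters, discordance calls, concordance and the permutation null."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from paradiverge import methdiv
from paradiverge.dupmap import CpGSite
from paradiverge.methdiv import (
    FilterPolicy,
    IntervalSet,
    MethylCounts,
    ParalogousCpGPair,
    classify_discordant,
    concordance_summary,
    dedupe_within_1kb,
    filter_pairs,
    permutation_null,
    sequence_divergence_association,
)
from paradiverge.methdiv import test_discordance as fisher_discordance
from paradiverge.simulate import simulate_pair_set

from conftest import build_alignment


def make_pair(
    counts_a=(10, 10),
    counts_b=(10, 10),
    pos_a=1000,
    pos_b=5000,
    chrom_a="c1",
    chrom_b="c2",
    **kwargs,
):
    return ParalogousCpGPair(
        site_a=CpGSite(chrom_a, pos_a),
        site_b=CpGSite(chrom_b, pos_b),
        counts_a=MethylCounts(*counts_a),
        counts_b=MethylCounts(*counts_b),
        **kwargs,
    )


class TestFilters:
    def test_min_depth_boundary(self):
        low = make_pair(counts_a=(2, 3), counts_b=(10, 10))  # depth 5
        edge = make_pair(counts_a=(3, 3), counts_b=(3, 3))  # depth 6 both
        retained, rej = filter_pairs([low, edge])
        assert retained == [edge]
        assert rej["min_depth"] == 1

    def test_total_depth_cap(self):
        over = make_pair(counts_a=(30, 30), counts_b=(25, 25))  # total 110
        at_cap = make_pair(counts_a=(25, 25), counts_b=(25, 25))  # total 100
        retained, rej = filter_pairs([over, at_cap])
        assert retained == [at_cap]
        assert rej["max_total_depth"] == 1

    def test_snp_overlap_at_c_and_flanks(self):
        snps = IntervalSet.from_bed(
            pd.DataFrame({"chrom": ["c1"], "start": [999], "end": [1000]})
        )  # flanking base of the C at 1000
        pair = make_pair()
        retained, rej = filter_pairs(
            [pair], FilterPolicy(snp_intervals=snps)
        )
        assert retained == [] and rej["snp_overlap"] == 1

    def test_flag_based_rejections(self):
        alt = make_pair(alt_allele_b=True)
        noev = make_pair(cytosine_evidence_a=False)
        ok = make_pair()
        retained, rej = filter_pairs([alt, noev, ok])
        assert retained == [ok]
        assert rej["alt_allele"] == 1 and rej["no_cytosine_evidence"] == 1

    def test_rejection_counts_sum_to_input(self):
        pairs = [make_pair(counts_a=(i, 2)) for i in range(12)]
        retained, rej = filter_pairs(pairs)
        assert len(retained) + sum(rej.values()) == len(pairs)

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(min_depth=st.integers(1, 20), bump=st.integers(1, 10))
    def test_raising_min_depth_is_monotone(self, min_depth, bump):
        rng = np.random.default_rng(min_depth * 31 + bump)
        pairs = [
            make_pair(
                counts_a=(int(rng.integers(0, 25)), int(rng.integers(0, 25))),
                counts_b=(int(rng.integers(0, 25)), int(rng.integers(0, 25))),
            )
            for _ in range(50)
        ]
        lo, _ = filter_pairs(pairs, FilterPolicy(min_depth_per_site=min_depth,
                                                 max_total_depth=200))
        hi, _ = filter_pairs(pairs, FilterPolicy(min_depth_per_site=min_depth + bump,
                                                 max_total_depth=200))
        assert len(hi) <= len(lo)

    def test_policy_invariants(self):
        with pytest.raises(ValueError):
            FilterPolicy(min_depth_per_site=0)
        with pytest.raises(ValueError):
            FilterPolicy(min_depth_per_site=6, max_total_depth=12)


class TestDiscordance:
    def test_zero_depth_raises(self):
        pair = make_pair(counts_a=(0, 0))
        with pytest.raises(ValueError):
            fisher_discordance(pair)

    def test_site_swap_symmetry(self):
        p1 = make_pair(counts_a=(12, 3), counts_b=(2, 14))
        p2 = make_pair(counts_a=(2, 14), counts_b=(12, 3))
        assert fisher_discordance(p1) == fisher_discordance(p2)

    def test_strict_alpha_cutoff(self):
        just_below = make_pair(p_value=4.9e-7)
        at_alpha = make_pair(p_value=5e-7)
        disc = classify_discordant([just_below, at_alpha])
        assert disc == [just_below]
        assert just_below.discordant and not at_alpha.discordant

    def test_recomputed_bonferroni_alpha(self):
        # 0.05 / 82,692 ~ 6.05e-7, consistent with the fixed 5e-7 default
        assert 0.05 / 82_692 == pytest.approx(6.05e-7, rel=1e-3)
        pairs = [make_pair(p_value=6e-4) for _ in range(100)]  # above 0.05/100
        assert classify_discordant(pairs, recompute_alpha=True) == []
        pairs = [make_pair(p_value=4e-4) for _ in range(100)]  # below 0.05/100
        assert len(classify_discordant(pairs, recompute_alpha=True)) == 100

    def test_hyper_hypo_labels(self):
        pair = make_pair(counts_a=(19, 1), counts_b=(1, 19), p_value=1e-9)
        classify_discordant([pair])
        assert pair.hyper == "a"

    def test_empty_input(self):
        assert classify_discordant([]) == []


class TestConcordance:
    def test_identical_levels(self):
        pairs = [make_pair(counts_a=(5, 5), counts_b=(5, 5)) for _ in range(5)]
        res = concordance_summary(pairs)
        assert res["proportion_within_delta"] == 1.0
        assert np.isnan(res["spearman_rho"])  # constant levels: rho undefined

    def test_perfectly_matched_distinct_levels(self):
        pairs = [make_pair(counts_a=(m, 10 - m), counts_b=(m, 10 - m)) for m in range(1, 9)]
        res = concordance_summary(pairs)
        assert res["spearman_rho"] == pytest.approx(1.0)

    def test_requires_two_pairs(self):
        with pytest.raises(ValueError):
            concordance_summary([make_pair()])

    def test_high_depth_null_approaches_full_concordance(self):
        pairs = simulate_pair_set(400, depth_model=(2000, 0.0), correlated=True,
                                  correlation_noise=0.005, seed=0)
        res = concordance_summary(pairs)
        assert res["proportion_within_delta"] > 0.99


class TestPermutation:
    def test_correlated_data_gives_minimal_p(self):
        pairs = simulate_pair_set(300, correlated=True, seed=3)
        res = permutation_null(pairs, n_perm=100, seed=0)
        assert res["p_value"] == pytest.approx(1 / 101)

    def test_reproducible_under_seed(self):
        pairs = simulate_pair_set(100, seed=4)
        r1 = permutation_null(pairs, n_perm=50, seed=9)
        r2 = permutation_null(pairs, n_perm=50, seed=9)
        assert np.array_equal(r1["perm_stats"], r2["perm_stats"])

    def test_zero_permutations_rejected(self):
        with pytest.raises(ValueError):
            permutation_null([make_pair()], n_perm=0)

    def test_partner_scheme_also_supported(self):
        pairs = simulate_pair_set(200, correlated=True, seed=5)
        res = permutation_null(pairs, n_perm=50, seed=1, scheme="partners")
        assert res["p_value"] == pytest.approx(1 / 51)


class TestDedupe:
    def _pair_at(self, pa, pb):
        return make_pair(pos_a=pa, pos_b=pb)

    def test_close_pairs_thinned_to_one(self):
        pairs = [self._pair_at(1000, 5000), self._pair_at(1500, 5500)]
        assert len(dedupe_within_1kb(pairs)) == 1

    def test_distant_pairs_both_kept(self):
        pairs = [self._pair_at(1000, 5000), self._pair_at(2500, 8000)]
        assert len(dedupe_within_1kb(pairs)) == 2

    def test_conflict_through_either_member(self):
        # far on the a side, close on the b side
        pairs = [self._pair_at(1000, 5000), self._pair_at(9000, 5400)]
        assert len(dedupe_within_1kb(pairs)) == 1

    def test_bundle_cluster_count_matches_truth(self, bundle, bundle_retained):
        out, cfg, truth = bundle
        retained, _ = bundle_retained
        disc = classify_discordant(retained)
        assert len(dedupe_within_1kb(disc)) <= len(disc)
        # thinning the full planted set reproduces the generator's
        # independently computed cluster count
        planted = []
        for pid in truth.discordant_pair_ids:
            first, second = pid.split("|")
            ca, pa = first.split(":")
            cb, pb = second.split(":")
            planted.append(make_pair(pos_a=int(pa), pos_b=int(pb),
                                     chrom_a=ca, chrom_b=cb))
        assert len(dedupe_within_1kb(planted)) == truth.n_discordant_loci_after_1kb


class TestSequenceDivergence:
    def test_identical_flanks_have_zero_substitutions(self):
        rng = np.random.default_rng(0)
        aln, genome = build_alignment(rng, n_match=1500, sub_rate=0.0)
        pair = make_pair(pos_a=aln.copy_a.start + 700, chrom_a="cA",
                         alignment_index=0)
        res = sequence_divergence_association([pair], [aln])
        assert res["substitutions"][0] == 0

    def test_flank_truncated_at_duplicon_edge(self):
        rng = np.random.default_rng(1)
        aln, _ = build_alignment(rng, n_match=1500, sub_rate=0.5)
        near_edge = make_pair(pos_a=aln.copy_a.start + 200, alignment_index=0)
        center = make_pair(pos_a=aln.copy_a.start + 750, alignment_index=0)
        res = sequence_divergence_association([near_edge, center], [aln])
        # the truncated window spans 200 + 501 bases, the full one 1001
        assert res["substitutions"][0] < res["substitutions"][1]

    def test_null_association_in_bundle(self, bundle_pairs, bundle_retained):
        # methylation noise is independent of flanking substitutions in the
        # generator, so the Kruskal-Wallis association should be null
        _, alignments, _ = bundle_pairs
        retained, _ = bundle_retained
        res = sequence_divergence_association(retained, alignments)
        assert len(res["substitutions"]) == len(retained)
        assert res["kruskal_p"] > 1e-4


def test_bundle_planted_discordance_recovery(bundle, bundle_retained):
    """Planted large-delta pairs are recovered; false calls essentially absent."""
    out, cfg, truth = bundle
    retained, rejections = bundle_retained
    disc = classify_discordant(retained)
    truth_ids = set(truth.discordant_pair_ids)
    called = {p.key for p in disc}
    retained_truth = truth_ids & {p.key for p in retained}
    assert len(called & truth_ids) / len(retained_truth) >= 0.9
    assert len(called - truth_ids) <= 1


def test_bundle_filter_truth(bundle, bundle_retained):
    """SNP-masked, alt-allele and no-evidence planted pairs are all rejected."""
    out, cfg, truth = bundle
    retained, rejections = bundle_retained
    keys = {p.key for p in retained}
    for pid in truth.snp_masked_pair_ids + truth.alt_allele_pair_ids + truth.no_evidence_pair_ids:
        assert pid not in keys
    assert rejections["snp_overlap"] >= len(truth.snp_masked_pair_ids)
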