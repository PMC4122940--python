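"""Methylation divergence between paralogous CpG sites.

Quantities and procedures:

* a pair's methylation *level* is the plug-in proportion
  methylated / (methylated + unmethylated) at each copy;
* pairs are stringently filtered (SNP overlap at the C or a flanking
  base, alt-allele reads, missing cytosine evidence, per-site depth < 6,
  total depth across both sites > 100);
* discordance is called with a two-sided Fisher exact test on the 2x2
  read-count table at alpha = 5e-7 (approximately Bonferroni 0.05 at
  genome scale), the discordant copy with the higher level being the
  hypermethylated one;
* overall concordance is summarised as the proportion of pairs with an
  absolute level difference <= 0.20 plus a Spearman rank correlation,
  and is calibrated against a null in which CpG sites are randomly
  re-paired across all duplicated regions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .dupmap import CpGPairing, CpGSite
from .exact_tests import fisher_exact_two_sided

log = logging.getLogger(__name__)

DEFAULT_ALPHA = 5e-7
DEFAULT_DELTA = 0.20

FILTER_ORDER = [
    "snp_overlap",
    "alt_allele",
    "no_cytosine_evidence",
    "min_depth",
    "max_total_depth",
]


@dataclass(frozen=True)
class MethylCounts:
    methylated: int
    unmethylated: int

    def __post_init__(self):
        if self.methylated < 0 or self.unmethylated < 0:
            raise ValueError("read counts must be non-negative")

    @property
    def depth(self) -> int:
        return self.methylated + self.unmethylated

    @property
    def level(self) -> float:
        if self.depth == 0:
            return float("nan")
        return self.methylated / self.depth


@dataclass
class ParalogousCpGPair:
    site_a: CpGSite
    site_b: CpGSite
    counts_a: MethylCounts
    counts_b: MethylCounts
    alignment_index: int | None = None
    alt_allele_a: bool = False
    alt_allele_b: bool = False
    cytosine_evidence_a: bool = True
    cytosine_evidence_b: bool = True
    p_value: float | None = None
    discordant: bool = False
    hyper: str | None = None  # 'a' or 'b' once discordant
    flags: dict = field(default_factory=dict)

    @property
    def level_a(self) -> float:
        return self.counts_a.level

    @property
    def level_b(self) -> float:
        return self.counts_b.level

    @property
    def abs_difference(self) -> float:
        return abs(self.level_a - self.level_b)

    @property
    def key(self) -> str:
        return f"{self.site_a.key}|{self.site_b.key}"


class IntervalSet:
    """Sorted, per-chromosome interval set with overlap queries."""

    def __init__(self, intervals: dict[str, np.ndarray] | None = None):
        # chrom -> (n, 2) array of [start, end)
        self._by_chrom: dict[str, np.ndarray] = {}
        if intervals:
            for chrom, arr in intervals.items():
                self._add(chrom, np.asarray(arr, dtype=np.int64))

    def _add(self, chrom: str, arr: np.ndarray) -> None:
        arr = arr[np.argsort(arr[:, 0], kind="mergesort")]
        self._by_chrom[chrom] = arr

    @classmethod
    def from_bed(cls, df) -> "IntervalSet":
        obj = cls()
        for chrom, grp in df.groupby("chrom", sort=True):
            obj._add(str(chrom), grp[["start", "end"]].to_numpy(dtype=np.int64))
        return obj

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        arr = self._by_chrom.get(chrom)
        if arr is None or len(arr) == 0:
            return False
        i = int(np.searchsorted(arr[:, 0], end, side="left"))
        # any interval starting before `end` may still overlap; check the
        # closest few (intervals are not guaranteed non-overlapping)
        j = i - 1
        while j >= 0 and j >= i - 64:
            if arr[j, 1] > start:
                return True
            j -= 1
        return bool((arr[max(0, i - 64) : i, 1] > start).any())


def attach_counts(
    pairings: list[CpGPairing],
    coverage: dict[tuple[str, int], tuple[int, int]],
    site_flags: dict[tuple[str, int], tuple[bool, bool]] | None = None,
) -> list[ParalogousCpGPair]:
    """Join coordinate-level pairings with read counts and per-site flags.

    Sites absent from the coverage table get zero counts; the depth
    filter removes them downstream.
    """
    site_flags = site_flags or {}
    out = []
    for pg in pairings:
        ka = (pg.site_a.chrom, pg.site_a.pos)
        kb = (pg.site_b.chrom, pg.site_b.pos)
        ma, ua = coverage.get(ka, (0, 0))
        mb, ub = coverage.get(kb, (0, 0))
        alt_a, ev_a = site_flags.get(ka, (False, True))
        alt_b, ev_b = site_flags.get(kb, (False, True))
        out.append(
            ParalogousCpGPair(
                site_a=pg.site_a,
                site_b=pg.site_b,
                counts_a=MethylCounts(ma, ua),
                counts_b=MethylCounts(mb, ub),
                alignment_index=pg.alignment_index,
                alt_allele_a=alt_a,
                alt_allele_b=alt_b,
                cytosine_evidence_a=ev_a,
                cytosine_evidence_b=ev_b,
            )
        )
    return out


@dataclass
class FilterPolicy:
    min_depth_per_site: int = 6
    max_total_depth: int = 100
    snp_intervals: IntervalSet | None = None
    require_cytosine_evidence: bool = True
    exclude_alt_allele_sites: bool = True

    def __post_init__(self):
        if self.min_depth_per_site < 1:
            raise ValueError("min_depth_per_site must be >= 1")
        if self.max_total_depth <= 2 * self.min_depth_per_site:
            raise ValueError("max_total_depth must exceed twice the per-site minimum")


def _snp_hits_site(snps: IntervalSet, site: CpGSite) -> bool:
    # the C itself or either flanking base
    return snps.overlaps(site.chrom, site.pos - 1, site.pos + 2)


def filter_pairs(
    pairs: list[ParalogousCpGPair], policy: FilterPolicy | None = None
) -> tuple[list[ParalogousCpGPair], dict[str, int]]:
    """Apply the stringent site filters; returns (retained, rejection counts).

    A pair is rejected by the *first* failing rule in FILTER_ORDER, so the
    per-filter counts plus the retained count sum to the input count.
    """
    policy = policy or FilterPolicy()
    rejected = {name: 0 for name in FILTER_ORDER}
    retained: list[ParalogousCpGPair] = []
    for pair in pairs:
        if policy.snp_intervals is not None and (
            _snp_hits_site(policy.snp_intervals, pair.site_a)
            or _snp_hits_site(policy.snp_intervals, pair.site_b)
        ):
            rejected["snp_overlap"] += 1
            pair.flags["rejected"] = "snp_overlap"
            continue
        if policy.exclude_alt_allele_sites and (pair.alt_allele_a or pair.alt_allele_b):
            rejected["alt_allele"] += 1
            pair.flags["rejected"] = "alt_allele"
            continue
        if policy.require_cytosine_evidence and not (
            pair.cytosine_evidence_a and pair.cytosine_evidence_b
        ):
            rejected["no_cytosine_evidence"] += 1
            pair.flags["rejected"] = "no_cytosine_evidence"
            continue
        if min(pair.counts_a.depth, pair.counts_b.depth) < policy.min_depth_per_site:
            rejected["min_depth"] += 1
            pair.flags["rejected"] = "min_depth"
            continue
        if pair.counts_a.depth + pair.counts_b.depth > policy.max_total_depth:
            rejected["max_total_depth"] += 1
            pair.flags["rejected"] = "max_total_depth"
            continue
        retained.append(pair)
    return retained, rejected


def test_discordance(pair: ParalogousCpGPair) -> float:
    """Two-sided Fisher exact p on [[meth_a, unmeth_a], [meth_b, unmeth_b]].

    Symmetric under swapping the two sites.  Zero-depth sites should have
    been removed by the depth filter and raise here.
    """
    if pair.counts_a.depth == 0 or pair.counts_b.depth == 0:
        raise ValueError(f"zero-depth site in pair {pair.key}; filter first")
    p = fisher_exact_two_sided(
        pair.counts_a.methylated,
        pair.counts_a.unmethylated,
        pair.counts_b.methylated,
        pair.counts_b.unmethylated,
    )
    pair.p_value = p
    return p


def classify_discordant(
    pairs: list[ParalogousCpGPair],
    alpha: float = DEFAULT_ALPHA,
    recompute_alpha: bool = False,
) -> list[ParalogousCpGPair]:
    """Label pairs with p < alpha (strict) as discordant.

    With ``recompute_alpha`` the cutoff becomes a Bonferroni 0.05 / n over
    the tested pairs.  Each discordant pair is annotated with its hyper-
    and hypomethylated copy.
    """
    if recompute_alpha and pairs:
        alpha = 0.05 / len(pairs)
    discordant = []
    for pair in pairs:
        if pair.p_value is None:
            test_discordance(pair)
        pair.discordant = pair.p_value < alpha
        if pair.discordant:
            pair.hyper = "a" if pair.level_a > pair.level_b else "b"
            discordant.append(pair)
        else:
            pair.hyper = None
    return discordant


def concordance_summary(
    pairs: list[ParalogousCpGPair], delta: float = DEFAULT_DELTA
) -> dict:
    """Proportion of pairs within ``delta`` plus Spearman rho of the levels."""
    if len(pairs) < 2:
        raise ValueError("need at least 2 pairs")
    la = np.array([p.level_a for p in pairs])
    lb = np.array([p.level_b for p in pairs])
    prop = float((np.abs(la - lb) <= delta).mean())
    if np.all(la == la[0]) or np.all(lb == lb[0]):
        rho, rho_p = float("nan"), float("nan")
    else:
        rho, rho_p = stats.spearmanr(la, lb)
        rho, rho_p = float(rho), float(rho_p)
    return {
        "proportion_within_delta": prop,
        "delta": delta,
        "spearman_rho": rho,
        "spearman_p": rho_p,
        "n": len(pairs),
    }


def _proportion_within(la: np.ndarray, lb: np.ndarray, delta: float) -> float:
    return float((np.abs(la - lb) <= delta).mean())


def permutation_null(
    pairs: list[ParalogousCpGPair],
    n_perm: int = 100,
    delta: float = DEFAULT_DELTA,
    seed: int | None = None,
    scheme: str = "pool",
) -> dict:
    """Empirical p for the observed concordance against a shuffled null.

    Under the default ``pool`` scheme the second member of every pair is
    replaced by a site drawn without replacement from the pooled set of
    all paired sites, i.e. CpG sites are randomly re-paired across all
    duplicated regions.  The alternative ``partners`` scheme permutes the
    second members among the pairs.  The statistic is the proportion of
    pairs within ``delta``; p = (#{perm >= observed} + 1) / (n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if scheme not in ("pool", "partners"):
        raise ValueError(f"unknown permutation scheme {scheme!r}")
    rng = np.random.default_rng(seed)
    la = np.array([p.level_a for p in pairs])
    lb = np.array([p.level_b for p in pairs])
    observed = _proportion_within(la, lb, delta)
    pool = np.concatenate([la, lb]) if scheme == "pool" else lb
    n = len(pairs)
    perm_stats = np.empty(n_perm)
    for i in range(n_perm):
        drawn = rng.choice(pool, size=n, replace=False)
        perm_stats[i] = _proportion_within(la, drawn, delta)
    n_ge = int((perm_stats >= observed).sum())
    return {
        "observed": observed,
        "perm_stats": perm_stats,
        "p_value": (n_ge + 1) / (n_perm + 1),
        "n_perm": n_perm,
    }


def dedupe_within_1kb(
    pairs: list[ParalogousCpGPair], max_dist: int = 1000, seed: int | None = None
) -> list[ParalogousCpGPair]:
    """Thin a discordant set so no two retained pairs sit within 1 kb.

    Two pairs conflict when either corresponding member (a-vs-a or
    b-vs-b, same chromosome) lies within ``max_dist`` bp of the other.
    The survivor within a cluster is an arbitrary but fixed choice:
    greedy in genome order by default, or in a seeded shuffled order when
    ``seed`` is given.
    """
    order = sorted(
        range(len(pairs)),
        key=lambda i: (pairs[i].site_a.chrom, pairs[i].site_a.pos, pairs[i].site_b.pos),
    )
    if seed is not None:
        rng = np.random.default_rng(seed)
        order = [order[int(i)] for i in rng.permutation(len(order))]
    retained: list[ParalogousCpGPair] = []
    for idx in order:
        cand = pairs[int(idx)]
        ok = True
        for kept in retained:
            if (
                cand.site_a.chrom == kept.site_a.chrom
                and abs(cand.site_a.pos - kept.site_a.pos) <= max_dist
            ) or (
                cand.site_b.chrom == kept.site_b.chrom
                and abs(cand.site_b.pos - kept.site_b.pos) <= max_dist
            ):
                ok = False
                break
        if ok:
            retained.append(cand)
    retained.sort(key=lambda p: (p.site_a.chrom, p.site_a.pos, p.site_b.pos))
    return retained


def sequence_divergence_association(
    pairs: list[ParalogousCpGPair],
    alignments: list,
    flank: int = 500,
) -> dict:
    """Relate |level difference| to flanking single-base substitutions.

    For each pair, substitutions are counted over non-gap alignment
    columns within ``flank`` bp either side of the copy-a CpG (truncated
    at the duplicated-region edge), then a Kruskal-Wallis test asks
    whether |level difference| varies across substitution-count groups.
    """
    subs = []
    diffs = []
    for pair in pairs:
        if pair.alignment_index is None:
            continue
        aln = alignments[pair.alignment_index]
        cmap = aln.coordinate_map
        lo = max(aln.copy_a.start, pair.site_a.pos - flank)
        hi = min(aln.copy_a.end, pair.site_a.pos + flank + 1)
        cols = cmap._col_of_a[lo - aln.copy_a.start : hi - aln.copy_a.start]
        a = np.frombuffer(aln.seq_a.upper().encode(), dtype="S1")[cols]
        b = np.frombuffer(aln.seq_b.upper().encode(), dtype="S1")[cols]
        non_gap = b != b"-"
        subs.append(int((a[non_gap] != b[non_gap]).sum()))
        diffs.append(pair.abs_difference)
    subs_arr = np.array(subs)
    diffs_arr = np.array(diffs)
    groups = [diffs_arr[subs_arr == v] for v in np.unique(subs_arr)]
    groups = [g for g in groups if len(g) > 0]
    if len(groups) < 2:
        kw_stat, kw_p = float("nan"), float("nan")
    else:
        kw_stat, kw_p = stats.kruskal(*groups)
        kw_stat, kw_p = float(kw_stat), float(kw_p)
    return {
        "substitutions": subs_arr,
        "abs_difference": diffs_arr,
        "kruskal_stat": kw_stat,
        "kruskal_p": kw_p,
    }
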