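"""Lineage-polarised analyses through outgroup orthology maps.

Covers four related procedures:

* ancestral/derived assignment for interchromosomal duplicon pairs --
  both sites are lifted through an outgroup chain map and, when they land
  on the same outgroup chromosome, the copy residing on the human
  chromosome syntenic with that outgroup chromosome is the ancestral one;
* detection of lineage-specific repeat insertions: elements present in
  the reference genome but essentially absent from the orthologous
  region of *both* outgroups, with syntenic flanks so that unaligned
  junk is not mistaken for an insertion;
* mean methylation profiles in sliding windows (500 bp wide, 100-bp
  offset) of distance from an insertion breakpoint, per species, with a
  paired t-test over orthologous CpG sites within 1 kb of any event;
* selection of "remodeled" sites (low in the outgroup, large absolute
  gain in the reference) near insertions, and their linkage to
  interspecies expression differences at nearby promoters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exact_tests import binom_two_sided_half
from .io import Chain
from .methdiv import MethylCounts, ParalogousCpGPair

log = logging.getLogger(__name__)

ALU_FAMILIES = ("AluY", "AluYa5", "AluYb8", "AluJ", "AluS")


class ChainMap:
    """Position-level liftover built from UCSC-style chains.

    Blocks are indexed per target chromosome; within a map, blocks must
    not overlap on the target side, so a position projects through at
    most one chain.
    """

    def __init__(self, chains: list[Chain]):
        self.chains = chains
        self._blocks: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = {}
        per_chrom: dict[str, list[tuple[int, int, int, int]]] = {}
        self._chain_list: list[Chain] = []
        for ci, ch in enumerate(chains):
            self._chain_list.append(ch)
            t = ch.t_start
            q = ch.q_start
            for size, dt, dq in ch.blocks:
                per_chrom.setdefault(ch.t_name, []).append((t, t + size, q, ci))
                t += size + dt
                q += size + dq
        for chrom, blocks in per_chrom.items():
            blocks.sort()
            starts = np.array([b[0] for b in blocks], dtype=np.int64)
            ends = np.array([b[1] for b in blocks], dtype=np.int64)
            if (starts[1:] < ends[:-1]).any():
                raise ValueError(f"chain blocks overlap on target {chrom}")
            self._blocks[chrom] = (
                starts,
                ends,
                np.array([b[2] for b in blocks], dtype=np.int64),
                np.array([b[3] for b in blocks], dtype=np.int64),
            )

    def project(self, chrom: str, pos: int) -> tuple[str, int] | None:
        """Lift one target position; None when it falls in a gap."""
        entry = self._blocks.get(chrom)
        if entry is None:
            return None
        starts, ends, q_starts, chain_idx = entry
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        if i < 0 or pos >= ends[i]:
            return None
        ch = self._chain_list[int(chain_idx[i])]
        offset = pos - int(starts[i])
        q = int(q_starts[i]) + offset
        if ch.q_strand == "-":
            q = ch.q_size - 1 - q
        return ch.q_name, q

    def covered_bases(self, chrom: str, start: int, end: int) -> int:
        """Number of bases of [start, end) covered by aligning blocks."""
        entry = self._blocks.get(chrom)
        if entry is None:
            return 0
        starts, ends, _, _ = entry
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        if hi <= lo:
            return 0
        s = np.maximum(starts[lo:hi], start)
        e = np.minimum(ends[lo:hi], end)
        return int(np.maximum(e - s, 0).sum())

    def coverage_fraction(self, chrom: str, start: int, end: int) -> float:
        if end <= start:
            return 0.0
        return self.covered_bases(chrom, start, end) / (end - start)

    def query_gaps(self, min_dq: int = 1):
        """Yield (t_name, t_pos, dq) for query-side gaps (insertions in
        the query genome relative to the target)."""
        for ch in self.chains:
            t = ch.t_start
            for size, dt, dq in ch.blocks:
                t += size
                if dq >= min_dq:
                    yield ch.t_name, t, dq
                t += dt


@dataclass(frozen=True)
class InsertionEvent:
    lineage: str  # "human" (reference) or "outgroup1"
    family: str
    chrom: str
    start: int
    end: int
    flank_syntenic: bool = True

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("insertion end must exceed start")

    def breakpoint_distance(self, pos: int) -> int:
        """Signed distance from the nearest breakpoint; 0 inside the span."""
        if pos < self.start:
            return pos - self.start
        if pos >= self.end:
            return pos - self.end + 1
        return 0


@dataclass
class OrthologousCpG:
    """A CpG conserved across two genomes with per-genome counts."""

    chrom_x: str
    pos_x: int
    pos_y: int
    counts_x: MethylCounts
    counts_y: MethylCounts

    @property
    def level_x(self) -> float:
        return self.counts_x.level

    @property
    def level_y(self) -> float:
        return self.counts_y.level


def assign_ancestral_derived(
    pair: ParalogousCpGPair,
    outgroup_map: ChainMap,
    synteny: dict[str, str],
) -> str:
    """Ancestral copy of an interchromosomal pair via outgroup synteny.

    Returns 'a', 'b' or 'undetermined'.  Both sites are lifted through
    the outgroup map; if they land on the same outgroup chromosome, the
    copy whose own chromosome is syntenic with it (per ``synteny``) is
    the ancestral one.  Never determined when either lift fails.
    """
    if pair.site_a.chrom == pair.site_b.chrom:
        raise ValueError("ancestral/derived rule applies to interchromosomal pairs only")
    qa = outgroup_map.project(pair.site_a.chrom, pair.site_a.pos)
    qb = outgroup_map.project(pair.site_b.chrom, pair.site_b.pos)
    if qa is None or qb is None or qa[0] != qb[0]:
        return "undetermined"
    target = qa[0]
    a_syntenic = synteny.get(pair.site_a.chrom) == target
    b_syntenic = synteny.get(pair.site_b.chrom) == target
    if a_syntenic and not b_syntenic:
        return "a"
    if b_syntenic and not a_syntenic:
        return "b"
    return "undetermined"


def detect_lineage_specific_insertions(
    repeats: pd.DataFrame,
    map_outgroup1: ChainMap,
    map_outgroup2: ChainMap,
    min_absent_fraction: float = 0.1,
    flank: int = 200,
    min_flank_coverage: float = 0.5,
    families: tuple[str, ...] | None = None,
    lineage: str = "human",
) -> list[InsertionEvent]:
    """Reference-lineage-specific insertions from two outgroup maps.

    An annotated element is lineage-specific iff the fraction of its span
    covered by aligning blocks is below ``min_absent_fraction`` in BOTH
    outgroups while both 200-bp flanks align syntenically (coverage >=
    ``min_flank_coverage`` in both outgroups) -- the orthologous region
    exists but the element does not.
    """
    events: list[InsertionEvent] = []
    for row in repeats.itertuples(index=False):
        family = str(row.name)
        if families is not None and not any(family.startswith(f) for f in families):
            continue
        chrom, start, end = str(row.chrom), int(row.start), int(row.end)
        cov1 = map_outgroup1.coverage_fraction(chrom, start, end)
        cov2 = map_outgroup2.coverage_fraction(chrom, start, end)
        if cov1 >= min_absent_fraction or cov2 >= min_absent_fraction:
            continue
        flank_ok = True
        for m in (map_outgroup1, map_outgroup2):
            left = m.coverage_fraction(chrom, start - flank, start)
            right = m.coverage_fraction(chrom, end, end + flank)
            if left < min_flank_coverage or right < min_flank_coverage:
                flank_ok = False
                break
        if not flank_ok:
            continue
        events.append(
            InsertionEvent(
                lineage=lineage, family=family, chrom=chrom, start=start, end=end
            )
        )
    return events


def detect_outgroup_insertions(
    map_outgroup1: ChainMap,
    map_outgroup2: ChainMap,
    min_length: int = 100,
    tolerance: int = 50,
) -> list[InsertionEvent]:
    """Outgroup1-specific insertions from query-side chain gaps.

    A dq gap of at least ``min_length`` in the reference->outgroup1 map
    marks sequence present in outgroup1 but absent from the reference; it
    is outgroup1-specific (rather than a reference-lineage deletion) when
    the reference->outgroup2 map is contiguous around the same reference
    point.  Events are reported as 1-bp breakpoints in reference
    coordinates.
    """
    gap2_points = [
        (chrom, t) for chrom, t, _ in map_outgroup2.query_gaps(min_dq=min_length)
    ]
    events = []
    for chrom, t_pos, dq in map_outgroup1.query_gaps(min_dq=min_length):
        near_gap2 = any(
            c == chrom and abs(p - t_pos) <= tolerance for c, p in gap2_points
        )
        if near_gap2:
            continue
        if map_outgroup2.coverage_fraction(chrom, t_pos - tolerance, t_pos + tolerance) < 0.9:
            continue
        events.append(
            InsertionEvent(
                lineage="outgroup1", family="other", chrom=chrom,
                start=t_pos, end=t_pos + 1,
            )
        )
    return events


def match_orthologous_cpgs(
    coverage_x: dict[tuple[str, int], tuple[int, int]],
    coverage_y: dict[tuple[str, int], tuple[int, int]],
    chain_map: ChainMap,
    min_depth: int = 5,
) -> list[OrthologousCpG]:
    """Pair reference CpGs with their outgroup orthologs through a chain.

    Sites failing to lift, missing from the outgroup coverage, or with a
    depth below ``min_depth`` in either species are excluded.
    """
    sites = []
    for (chrom, pos), (mx, ux) in sorted(coverage_x.items()):
        if mx + ux < min_depth:
            continue
        lifted = chain_map.project(chrom, pos)
        if lifted is None:
            continue
        q_chrom, q_pos = lifted
        cy = coverage_y.get((q_chrom, q_pos))
        if cy is None or cy[0] + cy[1] < min_depth:
            continue
        sites.append(
            OrthologousCpG(
                chrom_x=chrom, pos_x=pos, pos_y=q_pos,
                counts_x=MethylCounts(mx, ux), counts_y=MethylCounts(*cy),
            )
        )
    return sites


def _nearest_breakpoint_distances(
    sites: list[OrthologousCpG], events: list[InsertionEvent]
) -> np.ndarray:
    """Signed distance from each site to its nearest event breakpoint."""
    by_chrom: dict[str, list[InsertionEvent]] = {}
    for ev in events:
        by_chrom.setdefault(ev.chrom, []).append(ev)
    out = np.full(len(sites), np.iinfo(np.int64).max, dtype=np.int64)
    for i, s in enumerate(sites):
        best = None
        for ev in by_chrom.get(s.chrom_x, ()):  # event lists are short
            d = ev.breakpoint_distance(s.pos_x)
            if best is None or abs(d) < abs(best):
                best = d
        if best is not None:
            out[i] = best
    return out


def flanking_methylation_profile(
    events: list[InsertionEvent],
    sites: list[OrthologousCpG],
    window: int = 500,
    offset: int = 100,
    max_dist: int = 2000,
) -> pd.DataFrame:
    """Per-species mean methylation in sliding windows of insertion distance.

    Sites are grouped into windows of width ``window`` advanced by
    ``offset`` bp along the signed distance from the nearest insertion
    breakpoint, out to +/- ``max_dist``.  Each row carries the window
    bounds, site count, and the mean level with a normal-approximation
    95% CI per species; empty windows are NaN.
    """
    if max_dist < window:
        raise ValueError("max_dist must be at least one window wide")
    dists = _nearest_breakpoint_distances(sites, events)
    lx = np.array([s.level_x for s in sites])
    ly = np.array([s.level_y for s in sites])
    rows = []
    start = -max_dist
    while start + window <= max_dist:
        sel = (dists >= start) & (dists < start + window)
        n = int(sel.sum())
        row = {"win_start": start, "win_end": start + window, "n": n}
        for label, vals in (("x", lx[sel]), ("y", ly[sel])):
            if n == 0:
                mean = lo = hi = float("nan")
            else:
                mean = float(vals.mean())
                se = float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
                lo, hi = mean - 1.96 * se, mean + 1.96 * se
            row[f"mean_{label}"] = mean
            row[f"ci_lo_{label}"] = lo
            row[f"ci_hi_{label}"] = hi
        rows.append(row)
        start += offset
    return pd.DataFrame(rows)


def paired_flank_test(
    events: list[InsertionEvent],
    sites: list[OrthologousCpG],
    radius: int = 1000,
) -> dict:
    """Paired t-test of species' methylation within 1 kb of any event.

    Pairs level_x against level_y at every orthologous site whose
    distance to the nearest insertion breakpoint is within ``radius``.
    Degenerate cases (fewer than 2 sites) return NaN; identical levels in
    both species give t = 0, p = 1.
    """
    dists = _nearest_breakpoint_distances(sites, events)
    sel = np.abs(dists) <= radius
    x = np.array([s.level_x for s in sites])[sel]
    y = np.array([s.level_y for s in sites])[sel]
    n = len(x)
    if n < 2:
        return {"t": float("nan"), "p": float("nan"), "n": n}
    d = x - y
    if np.all(d == d[0]):
        if d[0] == 0:
            return {"t": 0.0, "p": 1.0, "n": n}
        return {"t": float("inf") * np.sign(d[0]), "p": 0.0, "n": n}
    t, p = stats.ttest_rel(x, y)
    return {"t": float(t), "p": float(p), "n": n}


def select_remodeled_sites(
    sites: list[OrthologousCpG],
    events: list[InsertionEvent],
    proximity: int = 2000,
    low_threshold: float = 0.4,
    min_gain: float = 0.6,
) -> tuple[list[OrthologousCpG], list[OrthologousCpG]]:
    """Foreground/background sets for external enrichment tools.

    Background: orthologous sites with outgroup methylation < 0.4 (strict)
    lying within 2 kb of an insertion event.  Foreground: the background
    subset whose reference methylation exceeds the outgroup level by an
    absolute proportion of at least 0.6 (low -> high remodeling).
    """
    dists = _nearest_breakpoint_distances(sites, events)
    background, foreground = [], []
    for s, d in zip(sites, dists):
        if abs(d) > proximity:
            continue
        if not s.level_y < low_threshold:
            continue
        background.append(s)
        if s.level_x - s.level_y >= min_gain:
            foreground.append(s)
    return background, foreground


def expression_linkage(
    genes: pd.DataFrame,
    foreground_sites: list[OrthologousCpG],
    promoter_window: int = 2000,
) -> dict:
    """Tally interspecies expression at genes with a remodeled promoter.

    Genes whose promoter window (TSS +/- ``promoter_window``) contains a
    foreground remodeled site are tallied by the sign of
    (reference - outgroup) expression; a two-sided exact sign test asks
    whether lower-in-reference genes predominate.  Genes with missing
    expression are excluded and logged.
    """
    positions: dict[str, list[int]] = {}
    for s in foreground_sites:
        positions.setdefault(s.chrom_x, []).append(s.pos_x)
    fg_by_chrom = {c: np.sort(np.array(v)) for c, v in positions.items()}
    lower = higher = tied = 0
    selected = []
    for row in genes.itertuples(index=False):
        arr = fg_by_chrom.get(str(row.chrom))
        if arr is None or len(arr) == 0:
            continue
        tss = int(row.tss)
        lo = np.searchsorted(arr, tss - promoter_window, side="left")
        hi = np.searchsorted(arr, tss + promoter_window + 1, side="left")
        if hi <= lo:
            continue
        ex, ey = row.expr_x, row.expr_y
        if pd.isna(ex) or pd.isna(ey):
            log.info("gene %s missing expression; excluded", row.gene)
            continue
        selected.append(str(row.gene))
        if ex < ey:
            lower += 1
        elif ex > ey:
            higher += 1
        else:
            tied += 1
    n = lower + higher
    p = binom_two_sided_half(lower, n) if n > 0 else float("nan")
    return {
        "lower": lower,
        "higher": higher,
        "tied": tied,
        "genes": selected,
        "sign_test_p": p,
    }
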