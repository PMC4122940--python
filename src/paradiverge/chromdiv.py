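"""Chromatin-feature divergence between duplicon copies.

Reads from each ChIP-seq / DNase-seq track are counted in nonoverlapping
500-bp windows tiled along copy A of each duplicon and projected onto
copy B; a position contributes to a window only when it is uniquely
mappable (35-bp uniqueness) in *both* copies and not a gap column.  A
two-sided exact binomial test (success probability 0.5 -- both windows
come from the same library, so no normalisation is needed) flags
windows with unequal counts; a window pair is called discordant only
when its Bonferroni-corrected p is < 0.05 AND one copy has a read count
of zero, restricting to complete loss of the mark on one copy.

A read is assigned to a window by its 5'-most mapped position, which
keeps window counts additive across nonoverlapping tiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .dupmap import DupliconAlignment, GAP
from .exact_tests import binom_two_sided_half

DEFAULT_WINDOW = 500


class MappabilityTrack:
    """Uniquely mappable positions as sorted, non-overlapping intervals."""

    def __init__(self, intervals: dict[str, np.ndarray]):
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, arr in intervals.items():
            arr = np.asarray(arr, dtype=np.int64)
            arr = arr[np.argsort(arr[:, 0], kind="mergesort")]
            if len(arr) > 1 and (arr[1:, 0] < arr[:-1, 1]).any():
                raise ValueError(f"mappability intervals overlap on {chrom}")
            self._by_chrom[chrom] = (arr[:, 0].copy(), arr[:, 1].copy())

    @classmethod
    def from_bed(cls, df: pd.DataFrame) -> "MappabilityTrack":
        return cls(
            {
                str(chrom): grp[["start", "end"]].to_numpy(dtype=np.int64)
                for chrom, grp in df.groupby("chrom", sort=True)
            }
        )

    def is_mappable(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        entry = self._by_chrom.get(chrom)
        if entry is None:
            return np.zeros(len(positions), dtype=bool)
        starts, ends = entry
        idx = np.searchsorted(starts, positions, side="right") - 1
        ok = idx >= 0
        res = np.zeros(len(positions), dtype=bool)
        res[ok] = positions[ok] < ends[idx[ok]]
        return res


@dataclass
class WindowPair:
    """Two aligned 500-bp windows with a joint mappability mask."""

    chrom_a: str
    chrom_b: str
    a_start: int
    a_end: int
    mask_a: np.ndarray  # masked positions in copy-a coordinates
    mask_b: np.ndarray  # their aligned partners in copy-b coordinates
    count_a: int = 0
    count_b: int = 0
    p_value: float | None = None
    discordant: bool = False
    alignment_index: int | None = None
    flags: dict = field(default_factory=dict)

    @property
    def mask_size(self) -> int:
        return len(self.mask_a)

    @property
    def b_span(self) -> tuple[int, int]:
        if len(self.mask_b) == 0:
            return (0, 0)
        return int(self.mask_b.min()), int(self.mask_b.max()) + 1

    @property
    def testable(self) -> bool:
        return self.count_a + self.count_b > 0


def make_window_pairs(
    alignment: DupliconAlignment,
    mappability: MappabilityTrack,
    size: int = DEFAULT_WINDOW,
    alignment_index: int | None = None,
) -> list[WindowPair]:
    """Tile copy A with nonoverlapping windows and project them to copy B.

    A position enters the joint mask iff it is uniquely mappable in both
    copies and its alignment column is not gapped; the trailing partial
    window is dropped.
    """
    ca, cb = alignment.copy_a, alignment.copy_b
    cmap = alignment.coordinate_map
    # aligned partner of every copy-a position (or -1 at gaps)
    partners = cmap._pos_b[cmap._col_of_a]
    pos_a = np.arange(ca.start, ca.end, dtype=np.int64)
    valid = partners >= 0
    map_a = mappability.is_mappable(ca.chrom, pos_a)
    map_b = np.zeros(len(pos_a), dtype=bool)
    map_b[valid] = mappability.is_mappable(cb.chrom, partners[valid])
    joint = valid & map_a & map_b
    windows = []
    for w_start in range(ca.start, ca.end - size + 1, size):
        lo = w_start - ca.start
        sel = joint[lo : lo + size]
        mask_a = pos_a[lo : lo + size][sel]
        mask_b = partners[lo : lo + size][sel]
        windows.append(
            WindowPair(
                chrom_a=ca.chrom,
                chrom_b=cb.chrom,
                a_start=w_start,
                a_end=w_start + size,
                mask_a=mask_a,
                mask_b=mask_b.astype(np.int64),
                alignment_index=alignment_index,
            )
        )
    return windows


def read_positions(reads: pd.DataFrame) -> pd.DataFrame:
    """5'-most mapped position of each read (start on +, end-1 on -)."""
    pos = np.where(
        reads["strand"].to_numpy() == "-",
        reads["end"].to_numpy() - 1,
        reads["start"].to_numpy(),
    )
    return pd.DataFrame({"chrom": reads["chrom"].to_numpy(), "pos": pos})


def count_reads_in_windows(windows: list[WindowPair], reads: pd.DataFrame) -> None:
    """Fill count_a / count_b for every window from a read track (BED).

    Reads are placed by their 5'-most position; a read is counted in a
    window when that position belongs to the window's joint mask on
    either copy.
    """
    assign: dict[str, dict[int, list[tuple[int, str]]]] = {}
    for i, w in enumerate(windows):
        for pos in w.mask_a:
            assign.setdefault(w.chrom_a, {}).setdefault(int(pos), []).append((i, "a"))
        for pos in w.mask_b:
            assign.setdefault(w.chrom_b, {}).setdefault(int(pos), []).append((i, "b"))
        w.count_a = 0
        w.count_b = 0
    rp = read_positions(reads)
    for chrom, grp in rp.groupby("chrom", sort=False):
        lookup = assign.get(str(chrom))
        if not lookup:
            continue
        for pos in grp["pos"].to_numpy():
            hits = lookup.get(int(pos))
            if not hits:
                continue
            for i, side in hits:
                if side == "a":
                    windows[i].count_a += 1
                else:
                    windows[i].count_b += 1


def test_window_discordance(pair: WindowPair) -> float:
    """Two-sided exact binomial p of count_a given n = count_a + count_b."""
    n = pair.count_a + pair.count_b
    if n == 0:
        raise ValueError("window untestable: both counts zero")
    p = binom_two_sided_half(pair.count_a, n)
    pair.p_value = p
    return p


def classify_discordant_windows(
    windows: list[WindowPair], alpha: float = 0.05
) -> list[WindowPair]:
    """Bonferroni-corrected binomial calls restricted to one-copy-zero loss.

    The correction denominator is the number of testable windows (count
    sum > 0) in the supplied set, i.e. per mark when called per track.  A
    window significant after correction but with reads on both copies is
    *not* discordant.
    """
    testable = [w for w in windows if w.testable]
    m = len(testable)
    discordant = []
    for w in windows:
        w.discordant = False
        if not w.testable:
            w.p_value = None
            continue
        p = test_window_discordance(w)
        if p * m < alpha and min(w.count_a, w.count_b) == 0:
            w.discordant = True
            discordant.append(w)
    return discordant


def flanking_read_profile(
    discordant_pairs,
    reads: pd.DataFrame,
    flank: int = 500,
) -> dict:
    """Read counts within +/-flank of each copy of discordant CpG pairs.

    Counts the reads (by 5'-most position) around the hypermethylated and
    hypomethylated copies, then runs a paired Wilcoxon signed-rank test of
    the per-pair counts across pairs.  Returns NaN when there is no
    signal to rank (all differences zero, or no reads at all).
    """
    rp = read_positions(reads)
    by_chrom = {
        str(chrom): np.sort(grp["pos"].to_numpy())
        for chrom, grp in rp.groupby("chrom", sort=False)
    }

    def count_near(chrom: str, pos: int) -> int:
        arr = by_chrom.get(chrom)
        if arr is None:
            return 0
        lo = np.searchsorted(arr, pos - flank, side="left")
        hi = np.searchsorted(arr, pos + flank + 1, side="left")
        return int(hi - lo)

    hyper_counts, hypo_counts = [], []
    for pair in discordant_pairs:
        if pair.hyper is None:
            continue
        hyper_site = pair.site_a if pair.hyper == "a" else pair.site_b
        hypo_site = pair.site_b if pair.hyper == "a" else pair.site_a
        hyper_counts.append(count_near(hyper_site.chrom, hyper_site.pos))
        hypo_counts.append(count_near(hypo_site.chrom, hypo_site.pos))
    hyper_arr = np.array(hyper_counts, dtype=float)
    hypo_arr = np.array(hypo_counts, dtype=float)
    diffs = hyper_arr - hypo_arr
    if len(diffs) < 2 or np.all(diffs == 0):
        w_stat, w_p = float("nan"), float("nan")
    else:
        w_stat, w_p = stats.wilcoxon(hyper_arr, hypo_arr)
        w_stat, w_p = float(w_stat), float(w_p)
    return {
        "hyper_counts": hyper_arr,
        "hypo_counts": hypo_arr,
        "wilcoxon_stat": w_stat,
        "wilcoxon_p": w_p,
        "n": len(diffs),
    }
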