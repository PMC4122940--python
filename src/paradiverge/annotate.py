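"""Contextual annotation and proximity statistics for discordant sites.

Distances are edge-to-point (0 when the point overlaps the feature).
CpG sites are classified as island (overlap), shore (strictly less than
2 kb from an island edge) or open sea.  "Paired Mann-Whitney" tests in
this module are Wilcoxon signed-rank tests, the standard paired
analogue.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .dupmap import CpGSite

SHORE_WIDTH = 2000


class FeatureTrack:
    """A named interval track with fast nearest-distance queries."""

    def __init__(self, df: pd.DataFrame, name: str = "track"):
        self.name = name
        self.df = df
        self._edges: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, grp in df.groupby("chrom", sort=True):
            starts = np.sort(grp["start"].to_numpy(dtype=np.int64))
            ends = np.sort(grp["end"].to_numpy(dtype=np.int64))
            self._edges[str(chrom)] = (starts, ends)

    def __len__(self) -> int:
        return len(self.df)

    def distance(self, chrom: str, pos: int) -> float:
        """Minimal edge-to-point distance; 0 when inside a feature."""
        entry = self._edges.get(chrom)
        if entry is None:
            return float("nan")
        starts, ends = entry
        # inside any feature? count of starts <= pos vs ends <= pos
        n_started = int(np.searchsorted(starts, pos, side="right"))
        n_ended = int(np.searchsorted(ends, pos, side="right"))
        if n_started > n_ended:
            return 0.0
        best = np.inf
        if n_started < len(starts):  # nearest feature to the right
            best = min(best, starts[n_started] - pos)
        if n_ended > 0:  # nearest feature to the left; end is half-open
            best = min(best, pos - ends[n_ended - 1] + 1)
        return float(best)

    def subset(self, cls: str) -> "FeatureTrack":
        sel = self.df[self.df["name"].astype(str).str.startswith(cls)]
        return FeatureTrack(sel, name=cls)


def distance_to_nearest(sites: list[CpGSite], track: FeatureTrack) -> np.ndarray:
    """Distance from each site to the nearest feature (NaN off-track)."""
    if len(track) == 0:
        return np.full(len(sites), np.nan)
    return np.array([track.distance(s.chrom, s.pos) for s in sites])


def classify_island_shore(
    sites: list[CpGSite], islands: FeatureTrack, shore_width: int = SHORE_WIDTH
) -> list[str]:
    """island | shore | open_sea per site (shore: 0 < distance < 2 kb)."""
    classes = []
    for s in sites:
        d = islands.distance(s.chrom, s.pos)
        if d == 0:
            classes.append("island")
        elif d < shore_width:
            classes.append("shore")
        else:
            classes.append("open_sea")
    return classes


def repeat_proximity_test(
    discordant_pairs,
    repeats: FeatureTrack,
    classes: tuple[str, ...] = ("Alu", "LINE", "LTR", "Simple_repeat"),
) -> dict[str, dict]:
    """Per repeat class, a paired signed-rank test of distances.

    Compares distance-to-nearest-element at the hypermethylated vs the
    hypomethylated copy across discordant pairs.  Classes absent from the
    track, or with fewer than 2 informative pairs, yield NaN.
    """
    results: dict[str, dict] = {}
    for cls in classes:
        sub = repeats.subset(cls)
        if len(sub) == 0:
            results[cls] = {"p": float("nan"), "n": 0, "median_hyper": float("nan"),
                            "median_hypo": float("nan")}
            continue
        d_hyper, d_hypo = [], []
        for pair in discordant_pairs:
            if pair.hyper is None:
                continue
            hyper_site = pair.site_a if pair.hyper == "a" else pair.site_b
            hypo_site = pair.site_b if pair.hyper == "a" else pair.site_a
            dh = sub.distance(hyper_site.chrom, hyper_site.pos)
            dl = sub.distance(hypo_site.chrom, hypo_site.pos)
            if np.isfinite(dh) and np.isfinite(dl):
                d_hyper.append(dh)
                d_hypo.append(dl)
        d_hyper_arr = np.array(d_hyper)
        d_hypo_arr = np.array(d_hypo)
        diffs = d_hyper_arr - d_hypo_arr
        if len(diffs) < 2 or np.all(diffs == 0):
            p = 1.0 if len(diffs) >= 2 else float("nan")
        else:
            _, p = stats.wilcoxon(d_hyper_arr, d_hypo_arr)
            p = float(p)
        results[cls] = {
            "p": p,
            "n": len(diffs),
            "median_hyper": float(np.median(d_hyper_arr)) if len(diffs) else float("nan"),
            "median_hypo": float(np.median(d_hypo_arr)) if len(diffs) else float("nan"),
        }
    return results


def junction_distance_test(
    discordant_sites: list[CpGSite],
    concordant_sites: list[CpGSite],
    duplicons,
) -> dict:
    """Distance to the nearest duplicated-region junction, by group.

    The junction set is the boundary positions of all duplicon intervals;
    groups are compared with an unpaired two-sided Mann-Whitney U test.
    """
    edges: dict[str, np.ndarray] = {}
    pts: dict[str, list[int]] = {}
    for d in duplicons:
        pts.setdefault(d.chrom, []).extend([d.start, d.end - 1])
    edges = {c: np.sort(np.array(v)) for c, v in pts.items()}

    def dist(site: CpGSite) -> float:
        arr = edges.get(site.chrom)
        if arr is None:
            return float("nan")
        i = int(np.searchsorted(arr, site.pos))
        cands = []
        if i < len(arr):
            cands.append(arr[i] - site.pos)
        if i > 0:
            cands.append(site.pos - arr[i - 1])
        return float(min(cands))

    d_disc = np.array([dist(s) for s in discordant_sites])
    d_conc = np.array([dist(s) for s in concordant_sites])
    d_disc = d_disc[np.isfinite(d_disc)]
    d_conc = d_conc[np.isfinite(d_conc)]
    if len(d_disc) == 0 or len(d_conc) == 0:
        return {"median_discordant": float("nan"), "median_concordant": float("nan"),
                "p": float("nan"), "n_discordant": len(d_disc), "n_concordant": len(d_conc)}
    _, p = stats.mannwhitneyu(d_disc, d_conc, alternative="two-sided")
    return {
        "median_discordant": float(np.median(d_disc)),
        "median_concordant": float(np.median(d_conc)),
        "p": float(p),
        "n_discordant": len(d_disc),
        "n_concordant": len(d_conc),
    }


def tss_distance_table(pairs, tss_track: FeatureTrack) -> pd.DataFrame:
    """Per-pair distances of both copies to the nearest TSS.

    The returned frame carries the discordance label; the summary of
    interest downstream is the fraction of discordant pairs with both
    distances greater than 1 kb.
    """
    rows = []
    for pair in pairs:
        rows.append(
            {
                "chrom_a": pair.site_a.chrom,
                "pos_a": pair.site_a.pos,
                "chrom_b": pair.site_b.chrom,
                "pos_b": pair.site_b.pos,
                "dist_a": tss_track.distance(pair.site_a.chrom, pair.site_a.pos),
                "dist_b": tss_track.distance(pair.site_b.chrom, pair.site_b.pos),
                "discordant": pair.discordant,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["chrom_a", "pos_a", "chrom_b", "pos_b", "dist_a", "dist_b", "discordant"],
    )


def fraction_distal(table: pd.DataFrame, min_dist: int = 1000) -> float:
    """Fraction of discordant pairs with both TSS distances > min_dist."""
    disc = table[table["discordant"]]
    if len(disc) == 0:
        return float("nan")
    return float(((disc["dist_a"] > min_dist) & (disc["dist_b"] > min_dist)).mean())


def export_flank_fasta(
    groups: dict[str, list[CpGSite]],
    genome: dict[str, str],
    out_dir: str | Path,
    flank: int = 500,
) -> dict[str, Path]:
    """Write one FASTA of +/- flank sequence per site group.

    Each record covers [pos - flank, pos + flank + 1), truncated (and
    flagged in the header) at chromosome ends.  Ready for motif tools
    such as MEME or HOMER.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for group, sites in groups.items():
        path = out_dir / f"flanks_{group}.fasta"
        with open(path, "w") as fh:
            for site in sites:
                seq = genome[site.chrom]
                start = max(0, site.pos - flank)
                end = min(len(seq), site.pos + flank + 1)
                truncated = (start != site.pos - flank) or (end != site.pos + flank + 1)
                header = f">{site.chrom}:{start}-{end} site={site.pos}"
                if truncated:
                    header += " truncated"
                fh.write(header + "\n")
                fh.write(seq[start:end] + "\n")
        paths[group] = path
    return paths
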