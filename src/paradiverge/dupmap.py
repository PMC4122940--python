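"""Segmental-duplication alignments, coordinate maps, paralogous CpG pairs.

A duplicon is a pair of genomic regions >1 kb long aligning at >90%
identity; the two copies are paralogous.  The alignment file format is::

    >chrA:startA-endA strandA chrB:startB-endB strandB identity
    GATTACA-GGC...        (gapped sequence of copy A, always + strand)
    GATCACATGGC...        (gapped sequence of copy B, in alignment
                           orientation: reverse-complemented when strandB
                           is '-')

Coordinates are 0-based half-open genome coordinates on the plus strand.
Every CpG site is keyed by the position of the C on the plus strand of
the CpG dinucleotide; reads from both strands of the symmetric
dinucleotide are summed upstream (see io.read_coverage).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

log = logging.getLogger(__name__)

#: Sentinel returned by projections that land on a gap column.
GAP = None

MIN_DUPLICON_LENGTH = 1000
MIN_IDENTITY = 0.90

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Duplicon:
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if self.end - self.start <= MIN_DUPLICON_LENGTH:
            raise ValueError(
                f"duplicon {self.chrom}:{self.start}-{self.end} is <= {MIN_DUPLICON_LENGTH} bp"
            )
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class CpGSite:
    """A CpG dinucleotide, keyed by the plus-strand C position."""

    chrom: str
    pos: int

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}"


class CoordinateMap:
    """Base-level lookup between the two copies of a duplicon alignment.

    The map is an involution on non-gap positions: projecting a position
    to the other copy and back returns the original position.
    """

    def __init__(self, alignment: "DupliconAlignment"):
        self.alignment = alignment
        a = np.frombuffer(alignment.seq_a.encode(), dtype="S1")
        b = np.frombuffer(alignment.seq_b.encode(), dtype="S1")
        if a.shape != b.shape:
            raise ValueError("gapped sequences differ in length")
        non_a = a != b"-"
        non_b = b != b"-"
        ca, cb = alignment.copy_a, alignment.copy_b
        if int(non_a.sum()) != len(ca) or int(non_b.sum()) != len(cb):
            raise ValueError("ungapped sequence length does not match interval")
        # genome coordinate per column (-1 at gaps)
        off_a = np.cumsum(non_a) - 1
        off_b = np.cumsum(non_b) - 1
        pos_a = np.where(non_a, ca.start + off_a, -1)
        if cb.strand == "+":
            pos_b = np.where(non_b, cb.start + off_b, -1)
        else:
            pos_b = np.where(non_b, cb.end - 1 - off_b, -1)
        self._pos_a = pos_a
        self._pos_b = pos_b
        # column index for each position offset within each copy
        self._col_of_a = np.flatnonzero(non_a)
        self._col_of_b = np.flatnonzero(non_b)

    def project(self, pos: int, from_copy: str) -> int | None:
        """Project a genome position in one copy to the other copy.

        Returns the aligned genome coordinate, or GAP (None) when the
        column is gapped in the other copy.  Raises for positions outside
        the source duplicon.
        """
        aln = self.alignment
        if from_copy == "a":
            ca = aln.copy_a
            if not ca.start <= pos < ca.end:
                raise ValueError(f"position {pos} outside copy_a {ca.start}-{ca.end}")
            col = self._col_of_a[pos - ca.start]
            other = int(self._pos_b[col])
        elif from_copy == "b":
            cb = aln.copy_b
            if not cb.start <= pos < cb.end:
                raise ValueError(f"position {pos} outside copy_b {cb.start}-{cb.end}")
            offset = pos - cb.start if cb.strand == "+" else cb.end - 1 - pos
            col = self._col_of_b[offset]
            other = int(self._pos_a[col])
        else:
            raise ValueError("from_copy must be 'a' or 'b'")
        return GAP if other < 0 else other


@dataclass
class DupliconAlignment:
    copy_a: Duplicon
    copy_b: Duplicon
    seq_a: str
    seq_b: str
    identity: float
    _map: CoordinateMap | None = field(default=None, repr=False, compare=False)

    @property
    def coordinate_map(self) -> CoordinateMap:
        if self._map is None:
            self._map = CoordinateMap(self)
        return self._map

    @property
    def columns(self) -> list[tuple[int | None, int | None]]:
        """Ordered aligned-position pairs; None marks a gap."""
        m = self.coordinate_map
        out = []
        for pa, pb in zip(m._pos_a, m._pos_b):
            out.append((int(pa) if pa >= 0 else None, int(pb) if pb >= 0 else None))
        return out

    def empirical_identity(self) -> float:
        """Fraction of non-gap columns whose bases match (case-folded)."""
        a = np.frombuffer(self.seq_a.upper().encode(), dtype="S1")
        b = np.frombuffer(self.seq_b.upper().encode(), dtype="S1")
        both = (a != b"-") & (b != b"-")
        n = int(both.sum())
        return float((a[both] == b[both]).sum() / n) if n else 0.0


def project_position(cmap: CoordinateMap, pos: int, from_copy: str) -> int | None:
    """Functional wrapper around CoordinateMap.project."""
    return cmap.project(pos, from_copy)


def _parse_header(line: str):
    fields = line[1:].split()
    if len(fields) != 5:
        raise ValueError("header needs 5 fields")

    def region(token: str):
        chrom, rng = token.rsplit(":", 1)
        s, e = rng.split("-")
        return chrom, int(s), int(e)

    ca = region(fields[0])
    cb = region(fields[2])
    return ca, fields[1], cb, fields[3], float(fields[4])


def parse_duplication_alignments(path: str | Path) -> list[DupliconAlignment]:
    """Parse a pairwise duplication-alignment file.

    Records whose alignment span is <= 1 kb or whose identity is <= 0.90
    (the standard segmental-duplication inclusion rule) are rejected with
    a logged warning, as are structurally malformed records; the line
    number of every rejected record is reported.
    """
    alignments: list[DupliconAlignment] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        if not lines[i].startswith(">"):
            log.warning("%s:%d: expected header line, skipping", path, i + 1)
            i += 1
            continue
        header_no = i + 1
        try:
            (ca_c, ca_s, ca_e), strand_a, (cb_c, cb_s, cb_e), strand_b, ident = _parse_header(
                lines[i]
            )
            seq_a, seq_b = lines[i + 1].strip(), lines[i + 2].strip()
        except (ValueError, IndexError) as exc:
            log.warning("%s:%d: malformed record (%s)", path, header_no, exc)
            i += 1
            continue
        i += 3
        span = min(ca_e - ca_s, cb_e - cb_s)
        if span <= MIN_DUPLICON_LENGTH:
            log.warning("%s:%d: rejected, span %d bp <= 1 kb", path, header_no, span)
            continue
        if ident <= MIN_IDENTITY:
            log.warning("%s:%d: rejected, identity %.4f <= 0.90", path, header_no, ident)
            continue
        if strand_a != "+":
            log.warning("%s:%d: copy_a strand must be '+', skipping", path, header_no)
            continue
        try:
            aln = DupliconAlignment(
                copy_a=Duplicon(ca_c, ca_s, ca_e, strand_a),
                copy_b=Duplicon(cb_c, cb_s, cb_e, strand_b),
                seq_a=seq_a,
                seq_b=seq_b,
                identity=ident,
            )
            aln.coordinate_map  # validates lengths against intervals
        except ValueError as exc:
            log.warning("%s:%d: rejected (%s)", path, header_no, exc)
            continue
        alignments.append(aln)
    return alignments


def write_duplication_alignments(alignments: list[DupliconAlignment], path: str | Path) -> None:
    with open(path, "w") as fh:
        for aln in alignments:
            ca, cb = aln.copy_a, aln.copy_b
            fh.write(
                f">{ca.chrom}:{ca.start}-{ca.end} {ca.strand} "
                f"{cb.chrom}:{cb.start}-{cb.end} {cb.strand} {aln.identity:.4f}\n"
            )
            fh.write(aln.seq_a + "\n")
            fh.write(aln.seq_b + "\n")


@dataclass(frozen=True)
class CpGPairing:
    """Two CpG sites occupying aligned positions in a duplicon pair."""

    site_a: CpGSite
    site_b: CpGSite
    alignment_index: int

    @property
    def key(self) -> str:
        return f"{self.site_a.key}|{self.site_b.key}"


def find_paralogous_cpg_pairs(
    alignments: list[DupliconAlignment], genome: dict[str, str]
) -> list[CpGPairing]:
    """Enumerate paralogous CpG site pairs across all duplicon alignments.

    A pair is emitted when both aligned positions carry an intact CG
    dinucleotide in their own copy, with no gap column in between; a CpG
    maps onto a CpG under reverse complement, so inverted duplicons are
    handled by keying the partner site at the aligned G's left neighbour.
    Each site appears at most once per alignment; a site participating in
    several duplicon alignments yields one pair per alignment.
    """
    pairs: list[CpGPairing] = []
    for idx, aln in enumerate(alignments):
        ca, cb = aln.copy_a, aln.copy_b
        seq_a_gen = genome[ca.chrom]
        seq_b_gen = genome[cb.chrom]
        cmap = aln.coordinate_map
        inverted = cb.strand == "-"
        for p in range(ca.start, ca.end - 1):
            if seq_a_gen[p : p + 2] != "CG":
                continue
            q1 = cmap.project(p, "a")
            q2 = cmap.project(p + 1, "a")
            if q1 is GAP or q2 is GAP:
                continue
            if not inverted:
                if q2 != q1 + 1:
                    continue
                c_pos_b = q1
            else:
                if q2 != q1 - 1:
                    continue
                c_pos_b = q2  # the aligned G's left neighbour on the + strand
            if c_pos_b < cb.start or c_pos_b + 2 > cb.end:
                continue
            if seq_b_gen[c_pos_b : c_pos_b + 2] != "CG":
                continue
            pairs.append(
                CpGPairing(CpGSite(ca.chrom, p), CpGSite(cb.chrom, c_pos_b), idx)
            )
    return pairs
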