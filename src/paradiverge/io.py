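"""Readers and writers for the plain-text formats the pipeline consumes.

All genomic intervals are 0-based, half-open.  Conversions for formats
that use other conventions happen here and nowhere else.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]
COVERAGE_COLUMNS = ["chrom", "pos", "strand", "methylated_reads", "unmethylated_reads"]


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a genome FASTA into a dict of upper-case sequences."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# BED

def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED3..BED6 file; missing optional columns are filled."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    df.columns = BED_COLUMNS[: df.shape[1]]
    for col, default in (("name", "."), ("score", 0), ("strand", "+")):
        if col not in df.columns:
            df[col] = default
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    return df


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in BED_COLUMNS if c in df.columns]
    df.to_csv(path, sep="\t", header=False, index=False, columns=cols)


# ---------------------------------------------------------------------------
# Bisulfite coverage tables

def read_coverage(path: str | Path, combine_strands: bool = True) -> pd.DataFrame:
    """Read a per-CpG coverage TSV (chrom, pos, strand, meth, unmeth).

    With ``combine_strands`` (the default), reads from the G on the minus
    strand of the symmetric CpG dinucleotide (reported at ``pos`` with
    strand '-') are folded onto the plus-strand C at ``pos - 1`` and the
    two strands summed, so each CpG site appears once, keyed by its
    plus-strand C position.
    """
    df = pd.read_csv(path, sep="\t", header=0, dtype={"chrom": str})
    missing = set(COVERAGE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"coverage file {path} missing columns {sorted(missing)}")
    if not combine_strands:
        return df
    pos = df["pos"].to_numpy().copy()
    minus = (df["strand"] == "-").to_numpy()
    pos[minus] -= 1
    out = (
        df.assign(pos=pos)
        .groupby(["chrom", "pos"], as_index=False)[["methylated_reads", "unmethylated_reads"]]
        .sum()
        .sort_values(["chrom", "pos"], kind="mergesort")
        .reset_index(drop=True)
    )
    return out


def write_coverage(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, columns=COVERAGE_COLUMNS)


def coverage_dict(df: pd.DataFrame) -> dict[tuple[str, int], tuple[int, int]]:
    """Index a strand-combined coverage table by (chrom, pos)."""
    return {
        (c, int(p)): (int(m), int(u))
        for c, p, m, u in zip(
            df["chrom"], df["pos"], df["methylated_reads"], df["unmethylated_reads"]
        )
    }


# ---------------------------------------------------------------------------
# Per-site flags (alt-allele reads, cytosine evidence)

def read_site_flags(path: str | Path) -> dict[tuple[str, int], tuple[bool, bool]]:
    """Read per-site flags: (chrom, pos) -> (alt_allele, cytosine_evidence)."""
    df = pd.read_csv(path, sep="\t", header=0, dtype={"chrom": str})
    return {
        (c, int(p)): (bool(a), bool(e))
        for c, p, a, e in zip(df["chrom"], df["pos"], df["alt_allele"], df["cytosine_evidence"])
    }


def write_site_flags(rows: Iterable[tuple[str, int, bool, bool]], path: str | Path) -> None:
    df = pd.DataFrame(rows, columns=["chrom", "pos", "alt_allele", "cytosine_evidence"])
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# UCSC chain format (subset: header + block lines)

@dataclass
class Chain:
    """One chained alignment between a target and a query genome.

    ``blocks`` is a list of (size, dt, dq) triples as in the UCSC chain
    format; the final block has dt = dq = 0.
    """

    score: float
    t_name: str
    t_size: int
    t_start: int
    t_end: int
    q_name: str
    q_size: int
    q_strand: str
    q_start: int
    q_end: int
    chain_id: int
    blocks: list[tuple[int, int, int]] = field(default_factory=list)


def read_chain_file(path: str | Path) -> list[Chain]:
    chains: list[Chain] = []
    current: Chain | None = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                current = None
                continue
            if line.startswith("chain"):
                f = line.split()
                if len(f) != 13:
                    raise ValueError(f"{path}:{lineno}: malformed chain header")
                if f[4] != "+":
                    raise ValueError(f"{path}:{lineno}: target strand must be '+'")
                current = Chain(
                    score=float(f[1]),
                    t_name=f[2], t_size=int(f[3]), t_start=int(f[5]), t_end=int(f[6]),
                    q_name=f[7], q_size=int(f[8]), q_strand=f[9],
                    q_start=int(f[10]), q_end=int(f[11]), chain_id=int(f[12]),
                )
                chains.append(current)
            else:
                if current is None:
                    raise ValueError(f"{path}:{lineno}: block line outside a chain")
                f = line.split()
                if len(f) == 1:
                    current.blocks.append((int(f[0]), 0, 0))
                elif len(f) == 3:
                    current.blocks.append((int(f[0]), int(f[1]), int(f[2])))
                else:
                    raise ValueError(f"{path}:{lineno}: malformed block line")
    return chains


def write_chain_file(chains: list[Chain], path: str | Path) -> None:
    with open(path, "w") as fh:
        for ch in chains:
            fh.write(
                f"chain {ch.score:g} {ch.t_name} {ch.t_size} + {ch.t_start} {ch.t_end} "
                f"{ch.q_name} {ch.q_size} {ch.q_strand} {ch.q_start} {ch.q_end} {ch.chain_id}\n"
            )
            for i, (size, dt, dq) in enumerate(ch.blocks):
                if i == len(ch.blocks) - 1:
                    fh.write(f"{size}\n")
                else:
                    fh.write(f"{size} {dt} {dq}\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# Truth / JSON helpers

def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)
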