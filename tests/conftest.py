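"""Shared fixtures: a session-scoped synthetic bundle and alignment builders."""

from __future__ import annotations

import numpy as np
import pytest

from paradiverge import dupmap, io, methdiv
from paradiverge.dupmap import Duplicon, DupliconAlignment
from paradiverge.simulate import SimulationConfig, simulate_dataset

BASES = "ACGT"


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """Default synthetic bundle (seed 1) shared across the session."""
    out = tmp_path_factory.mktemp("bundle")
    cfg = SimulationConfig(seed=1)
    truth = simulate_dataset(cfg, out)
    return out, cfg, truth


@pytest.fixture(scope="session")
def bundle_pairs(bundle):
    """Parsed genome, alignments and enumerated CpG pairings for the bundle."""
    out, cfg, truth = bundle
    genome = io.read_fasta(out / "genome.fasta")
    alignments = dupmap.parse_duplication_alignments(out / "alignments.txt")
    pairings = dupmap.find_paralogous_cpg_pairs(alignments, genome)
    return genome, alignments, pairings


@pytest.fixture(scope="session")
def bundle_retained(bundle, bundle_pairs):
    """Filtered, Fisher-tested pair set for the bundle."""
    out, cfg, truth = bundle
    genome, alignments, pairings = bundle_pairs
    coverage = io.coverage_dict(io.read_coverage(out / "coverage_base.tsv"))
    flags = io.read_site_flags(out / "site_flags.tsv")
    snps = methdiv.IntervalSet.from_bed(io.read_bed(out / "snps.bed"))
    pairs = methdiv.attach_counts(pairings, coverage, flags)
    retained, rejections = methdiv.filter_pairs(
        pairs, methdiv.FilterPolicy(snp_intervals=snps)
    )
    for p in retained:
        methdiv.test_discordance(p)
    return retained, rejections


def random_dna(rng: np.random.Generator, n: int, no_cg: bool = False) -> str:
    s = list(rng.choice(list(BASES), size=n))
    if no_cg:
        for i in range(n - 1):
            if s[i] == "C" and s[i + 1] == "G":
                s[i + 1] = "A"
    return "".join(s)


def build_alignment(
    rng: np.random.Generator,
    n_match: int = 1500,
    n_ins_b: int = 0,
    n_del_b: int = 0,
    sub_rate: float = 0.0,
    inverted: bool = False,
    chrom_a: str = "cA",
    chrom_b: str = "cB",
    start_a: int = 1000,
    start_b: int = 4000,
) -> tuple[DupliconAlignment, dict[str, str]]:
    """Random gapped alignment plus a genome dict embedding both copies.

    Columns are match columns (possibly substituted), insertions in copy B
    (gap in A) and deletions from copy B (gap in B), shuffled together.
    """
    cols = []
    for _ in range(n_match):
        a = rng.choice(list(BASES))
        b = a if rng.random() >= sub_rate else rng.choice([x for x in BASES if x != a])
        cols.append((a, b))
    cols += [("-", rng.choice(list(BASES))) for _ in range(n_ins_b)]
    cols += [(rng.choice(list(BASES)), "-") for _ in range(n_del_b)]
    order = rng.permutation(len(cols))
    cols = [cols[i] for i in order]
    seq_a = "".join(a for a, _ in cols)
    seq_b = "".join(b for _, b in cols)
    ungapped_a = seq_a.replace("-", "")
    ungapped_b = seq_b.replace("-", "")
    genome_b_seq = dupmap.revcomp(ungapped_b) if inverted else ungapped_b
    copy_a = Duplicon(chrom_a, start_a, start_a + len(ungapped_a), "+")
    copy_b = Duplicon(chrom_b, start_b, start_b + len(ungapped_b), "-" if inverted else "+")
    aln = DupliconAlignment(copy_a, copy_b, seq_a, seq_b, identity=0.99)
    genome = {
        chrom_a: "A" * start_a + ungapped_a + "A" * 50,
        chrom_b: "A" * start_b + genome_b_seq + "A" * 50,
    }
    if chrom_a == chrom_b:
        pad = "A" * (start_b - (start_a + len(ungapped_a)))
        genome = {
            chrom_a: "A" * start_a + ungapped_a + pad + genome_b_seq + "A" * 50
        }
    return aln, genome
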