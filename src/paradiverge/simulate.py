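"""Synthetic dataset generator with planted ground truth.

The generator emulates every input the pipeline consumes -- genome,
segmental-duplication alignments, per-CpG bisulfite counts for two cell
types and two species, chromatin read tracks, mappability, SNPs,
annotation tracks, orthology chains, and an expression table -- without
any external downloads, and writes a truth file recording exactly what
was planted.

Geometry.  Each chromosome is built on an ancestral *backbone*.  Three
genomes share it: the reference ("human"), outgroup1 and outgroup2.
Lineage-specific sequence (Alu-like insertions specific to human or to
outgroup1, and the derived copies of segmental duplications, which are
human-specific) is spliced into the backbone per genome; chains between
genomes then fall out of the segment model with target gaps (dt) at
human-specific segments and query gaps (dq) at outgroup1-specific ones.
Shared Alu elements are plain backbone intervals, present everywhere.

Methylation.  Every CpG is planted explicitly (the backbone contains no
other CG dinucleotides), with a true level drawn from a two-component
low/high mixture.  Paralogous copies of a duplicon share the source
site's level, displaced by an interaction-model-driven divergence (see
diffmodel) except for the planted discordant pairs, which differ by a
fixed large delta.  Read counts are beta-binomial at a negative-binomial
sampled depth, split across the two strands of the symmetric
dinucleotide.  Brain methylation in each species is elevated near that
lineage's insertions with an exponentially decaying spread effect.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io
from .dupmap import (
    Duplicon,
    DupliconAlignment,
    revcomp,
    write_duplication_alignments,
)
from .methdiv import MethylCounts

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_A, _C, _G, _T = 0, 1, 2, 3

HUMAN, OG1, OG2 = "H", "P", "O"

HUMAN_ALU_FAMILIES = ("AluY", "AluYa5", "AluYb8")
SHARED_ALU_FAMILIES = ("AluJ", "AluS")


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic bundle.

    All fractions lie in [0, 1]; duplicon lengths must exceed 1 kb (the
    segmental-duplication definition) and identity must exceed 0.90.  A
    fixed seed makes the emitted bundle byte-identical across runs.
    """

    n_chromosomes: int = 2
    chrom_length: int = 600_000
    n_duplicons: int = 20
    duplicon_length_range: tuple[int, int] = (2000, 5000)
    sequence_identity: float = 0.96
    cpg_density: float = 10.0  # sites per kb
    depth_mean: float = 30.0
    depth_dispersion: float = 0.02
    meth_dispersion: float = 0.02  # beta-binomial overdispersion
    mixture_weights: tuple[float, float] = (0.35, 0.65)
    mixture_means: tuple[float, float] = (0.08, 0.88)
    mixture_concentration: float = 20.0
    n_planted_discordant: int = 30
    planted_discordance_delta: float = 0.9
    n_planted_insertions: int = 25  # per lineage
    insertion_max_elevation: float = 0.2
    insertion_decay_length: float = 300.0
    model_coefficients: tuple[float, float, float, float] = (0.05, -0.04, 0.35, -0.20)
    noise_sd: float = 0.05
    inversion_prob: float = 0.3
    n_shared_elements: int = 25
    alu_length: int = 300
    n_genes: int = 30
    n_remodeled_promoters: int = 8
    n_planted_discordant_windows: int = 12
    window_read_rate: float = 8.0
    planted_window_rate: float = 25.0
    flank_enrichment_reads: float = 20.0
    flank_base_reads: float = 2.0
    n_other_repeats: int = 30
    n_islands: int = 8
    island_width: int = 400
    n_snp_masked: int = 3
    n_alt_allele: int = 2
    n_no_evidence: int = 2
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.duplicon_length_range
        if lo <= 1000:
            raise ValueError("duplicon lengths must exceed 1 kb")
        if hi < lo:
            raise ValueError("bad duplicon_length_range")
        if not 0.90 < self.sequence_identity <= 1.0:
            raise ValueError("sequence_identity must lie in (0.90, 1.0]")
        for frac in (
            self.planted_discordance_delta,
            self.insertion_max_elevation,
            self.noise_sd,
            self.inversion_prob,
            *self.mixture_weights,
            *self.mixture_means,
        ):
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"fraction {frac} outside [0, 1]")
        if abs(sum(self.mixture_weights) - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d = {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        fields = {f.name: f for f in dataclasses.fields(cls)}
        kwargs = {}
        for k, v in d.items():
            if k not in fields:
                raise ValueError(f"unknown config key {k!r}")
            if isinstance(v, list):
                v = tuple(v)
            kwargs[k] = v
        return cls(**kwargs)


@dataclass
class SyntheticTruth:
    """Everything that was planted, for downstream recovery checks."""

    seed: int
    n_pairs_emitted: int
    discordant_pair_ids: list[str]
    n_discordant_loci_after_1kb: int
    ancestral_copy_per_pair: dict[str, str]
    insertion_events: list[dict]
    true_model_coefficients: list[float]
    planted_windows: list[dict]
    snp_masked_pair_ids: list[str]
    alt_allele_pair_ids: list[str]
    no_evidence_pair_ids: list[str]
    pair_site_classes: dict[str, str]
    remodeled_genes: list[str]
    remodeled_sites: list[str]
    pair_true_levels: dict[str, list[float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticTruth":
        return cls(**{f.name: d[f.name] for f in dataclasses.fields(cls)})


def write_truth(truth: SyntheticTruth, path: str | Path) -> None:
    io.write_json(truth.to_dict(), path)


def read_truth(path: str | Path) -> SyntheticTruth:
    return SyntheticTruth.from_dict(io.read_json(path))


# ---------------------------------------------------------------------------
# Sequence primitives

def _random_seq_no_cg(rng: np.random.Generator, length: int) -> np.ndarray:
    """Random base indices with every CG dinucleotide removed.

    G -> A replacement cannot create a new CG, so one pass suffices; the
    genome then contains exactly the CpGs planted afterwards.
    """
    arr = rng.integers(0, 4, size=length, dtype=np.int8)
    cg = np.flatnonzero((arr[:-1] == _C) & (arr[1:] == _G))
    arr[cg + 1] = _A
    return arr


def _plant_cpgs(arr: np.ndarray, rng: np.random.Generator, density_per_kb: float) -> np.ndarray:
    """Write CG dinucleotides at ~density_per_kb spaced >= 4 bp apart."""
    n_target = int(len(arr) * density_per_kb / 1000)
    lo, hi = 5, len(arr) - 6
    cand = np.sort(rng.choice(np.arange(lo, hi), size=min(n_target, hi - lo), replace=False))
    # drop candidates closer than 4 bp to their predecessor so the planted
    # dinucleotides stay disjoint; the realised density is slightly below
    # the requested one, uniformly along the chromosome
    keep = np.concatenate([[True], np.diff(cand) >= 4])
    pos = cand[keep].astype(np.int64)
    arr[pos] = _C
    arr[pos + 1] = _G
    return pos


def _indices_to_str(arr: np.ndarray) -> str:
    return _BASES[arr].tobytes().decode()


def _mutate(
    seq: np.ndarray, rng: np.random.Generator, identity: float, protected: np.ndarray
) -> np.ndarray:
    """Substitute bases at rate 1 - identity, never inside protected positions."""
    n_sub = int(round((1.0 - identity) * len(seq)))
    allowed = np.setdiff1d(np.arange(len(seq)), protected, assume_unique=False)
    positions = rng.choice(allowed, size=min(n_sub, len(allowed)), replace=False)
    out = seq.copy()
    out[positions] = (out[positions] + rng.integers(1, 4, size=len(positions))) % 4
    return out


# ---------------------------------------------------------------------------
# Count simulation

def sample_depths(rng: np.random.Generator, n: int, mean: float, dispersion: float) -> np.ndarray:
    """Per-site depths: Poisson when dispersion is 0, gamma-Poisson otherwise
    (variance = mean + dispersion * mean^2)."""
    if dispersion <= 0:
        return rng.poisson(mean, n)
    lam = rng.gamma(1.0 / dispersion, mean * dispersion, n)
    return rng.poisson(lam)


def sample_meth_counts(
    rng: np.random.Generator, levels: np.ndarray, depths: np.ndarray, rho: float
) -> np.ndarray:
    """Beta-binomial methylated read counts (binomial when rho -> 0).

    Levels of exactly 0 or 1 stay degenerate: the per-read methylation
    probability is the level itself, so a fully unmethylated site never
    yields a methylated read.
    """
    levels = np.asarray(levels, dtype=float)
    p = levels
    if rho > 0:
        interior = (levels > 0) & (levels < 1)
        p = levels.copy()
        a = levels[interior] * (1 - rho) / rho
        b = (1 - levels[interior]) * (1 - rho) / rho
        p[interior] = rng.beta(a, b)
    return rng.binomial(depths, p)


def simulate_bisulfite_counts(
    true_level: float,
    depth_model: tuple[float, float],
    rng: np.random.Generator | int | None = None,
    meth_dispersion: float = 0.0,
) -> MethylCounts:
    """Simulate the read counts of a single CpG site.

    ``depth_model`` is (mean, dispersion) of the per-site depth.  A depth
    of zero yields (0, 0).
    """
    if not 0.0 <= true_level <= 1.0:
        raise ValueError("true_level must lie in [0, 1]")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    depth = int(sample_depths(rng, 1, depth_model[0], depth_model[1])[0])
    if depth == 0:
        return MethylCounts(0, 0)
    m = int(sample_meth_counts(rng, np.array([true_level]), np.array([depth]), meth_dispersion)[0])
    return MethylCounts(m, depth - m)


def _mixture_levels(rng: np.random.Generator, n: int, cfg: SimulationConfig) -> np.ndarray:
    comp = rng.choice(len(cfg.mixture_weights), size=n, p=list(cfg.mixture_weights))
    means = np.array(cfg.mixture_means)[comp]
    k = cfg.mixture_concentration
    return rng.beta(means * k, (1 - means) * k)


# ---------------------------------------------------------------------------
# Layout machinery

@dataclass(eq=False)
class _Event:
    """A lineage-specific segment spliced into the backbone at ``bpos``."""

    bpos: int
    length: int
    present: frozenset
    kind: str  # "alu" or "dup"
    family: str | None = None
    payload: np.ndarray | None = None
    dup_idx: int | None = None


class _Coords:
    """Backbone -> genome coordinate transform for one chromosome."""

    def __init__(self, events: list[_Event], tag: str):
        mine = [e for e in events if tag in e.present]
        self.bpos = np.array([e.bpos for e in mine], dtype=np.int64)
        lens = np.array([e.length for e in mine], dtype=np.int64)
        self.cum = np.concatenate([[0], np.cumsum(lens)])
        self._starts = {id(e): int(e.bpos + self.cum[i]) for i, e in enumerate(mine)}

    def to_genome(self, b):
        idx = np.searchsorted(self.bpos, np.asarray(b), side="right")
        return np.asarray(b) + self.cum[idx]

    def event_start(self, e: _Event) -> int:
        return self._starts[id(e)]

    @property
    def added(self) -> int:
        return int(self.cum[-1])


def _layout_items(rng: np.random.Generator, cfg: SimulationConfig, items: list[tuple[str, int, int]]):
    """Place items (kind, index, width) sequentially with random gaps.

    Items are shuffled and distributed across chromosomes by filling the
    least-loaded chromosome first; raises when the planted counts exceed
    the available space.
    """
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chromosomes)]
    cursors = {c: 2000 for c in chroms}
    order = rng.permutation(len(items))
    placed = []
    for idx in order:
        kind, i, width = items[int(idx)]
        chrom = min(chroms, key=lambda c: cursors[c])
        gap = int(rng.integers(500, 2000))
        start = cursors[chrom] + gap
        if start + width + 300 > cfg.chrom_length - 2000:
            raise ValueError(
                "planted items exceed available genome space; increase "
                "chrom_length or reduce planted counts"
            )
        cursors[chrom] = start + width + 300
        placed.append((kind, i, chrom, start, width))
    return placed


def _build_chain(
    chrom: str,
    backbone_len: int,
    events: list[_Event],
    q_name: str,
    t_tag: str,
    q_tag: str,
    t_len: int,
    q_len: int,
    chain_id: int,
) -> io.Chain:
    """Chain between two genomes of one chromosome from the segment model."""
    blocks: list[tuple[int, int, int]] = []
    prev = 0
    size_acc = 0
    for e in sorted(events, key=lambda e: e.bpos):
        in_t = t_tag in e.present
        in_q = q_tag in e.present
        if not (in_t or in_q):
            continue
        size_acc += e.bpos - prev
        prev = e.bpos
        dt = e.length if in_t else 0
        dq = e.length if in_q else 0
        if in_t and in_q:
            size_acc += e.length  # aligned in both: extend the block
            continue
        if size_acc == 0 and blocks:
            s, pdt, pdq = blocks[-1]
            blocks[-1] = (s, pdt + dt, pdq + dq)
        else:
            blocks.append((size_acc, dt, dq))
        size_acc = 0
    blocks.append((size_acc + backbone_len - prev, 0, 0))
    return io.Chain(
        score=1000.0,
        t_name=chrom, t_size=t_len, t_start=0, t_end=t_len,
        q_name=q_name, q_size=q_len, q_strand="+", q_start=0, q_end=q_len,
        chain_id=chain_id, blocks=blocks,
    )


# ---------------------------------------------------------------------------
# Main generator

def simulate_dataset(config: SimulationConfig, out_dir: str | Path) -> SyntheticTruth:
    """Generate the full synthetic bundle under ``out_dir``.

    Writes the genome FASTA, the duplication-alignment file, coverage
    TSVs for a base and a differentiated cell type and for two species'
    brain samples, chromatin read BEDs, mappability/SNP/island/TSS/repeat
    BEDs, three chain files plus a synteny table, an expression table,
    the truth JSON, and a manifest.  Returns the truth object.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    cfg = config
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chromosomes)]

    # --- backbone sequence and CpGs -------------------------------------
    backbone: dict[str, np.ndarray] = {}
    cpg_pos: dict[str, np.ndarray] = {}
    cpg_set: dict[str, set] = {}
    for chrom in chroms:
        arr = _random_seq_no_cg(rng, cfg.chrom_length)
        pos = _plant_cpgs(arr, rng, cfg.cpg_density)
        backbone[chrom] = arr
        cpg_pos[chrom] = pos
        cpg_set[chrom] = set(pos.tolist())

    # --- layout ----------------------------------------------------------
    dup_lengths = rng.integers(
        cfg.duplicon_length_range[0], cfg.duplicon_length_range[1] + 1, cfg.n_duplicons
    )
    items: list[tuple[str, int, int]] = []
    items += [("dup_src", i, int(dup_lengths[i])) for i in range(cfg.n_duplicons)]
    items += [("dup_tgt", i, 0) for i in range(cfg.n_duplicons)]
    items += [("alu_h", i, cfg.alu_length) for i in range(cfg.n_planted_insertions)]
    items += [("alu_o", i, cfg.alu_length) for i in range(cfg.n_planted_insertions)]
    items += [("alu_shared", i, cfg.alu_length) for i in range(cfg.n_shared_elements)]
    items += [("gene", i, 0) for i in range(cfg.n_genes)]
    items += [("island", i, cfg.island_width) for i in range(cfg.n_islands)]
    placed = _layout_items(rng, cfg, items)
    by_kind: dict[str, dict[int, tuple[str, int, int]]] = {}
    for kind, i, chrom, start, width in placed:
        by_kind.setdefault(kind, {})[i] = (chrom, start, width)

    def _avoid_cpg_split(chrom: str, bpos: int) -> int:
        # never split a CG dinucleotide by inserting between C and G
        while (bpos - 1) in cpg_set[chrom]:
            bpos += 1
        return bpos

    # --- duplicons: derived payloads and pair truth ----------------------
    # gather per-duplicon source CpGs, select planted discordant pairs
    dup_info = []
    for i in range(cfg.n_duplicons):
        chrom_s, s, L = by_kind["dup_src"][i]
        e = s + L
        src_cpgs = [p for p in cpg_pos[chrom_s] if s <= p <= e - 2]
        dup_info.append({"chrom_s": chrom_s, "s": s, "e": e, "L": L, "src_cpgs": src_cpgs})
    all_candidates = [
        (i, p) for i, info in enumerate(dup_info) for p in info["src_cpgs"]
    ]
    if cfg.n_planted_discordant > len(all_candidates):
        raise ValueError("planted discordant count exceeds available CpG pairs")
    sel = rng.choice(len(all_candidates), size=cfg.n_planted_discordant, replace=False)
    planted = {all_candidates[int(k)] for k in sel}

    events: dict[str, list[_Event]] = {c: [] for c in chroms}
    for i in range(cfg.n_duplicons):
        info = dup_info[i]
        chrom_t, t_b, _ = by_kind["dup_tgt"][i]
        t_b = _avoid_cpg_split(chrom_t, t_b)
        src_seq = backbone[info["chrom_s"]][info["s"] : info["e"]]
        protected = []
        for p in info["src_cpgs"]:
            if (i, p) in planted:
                protected += [p - info["s"], p - info["s"] + 1]
        payload_aligned = _mutate(
            src_seq, rng, cfg.sequence_identity, np.array(protected, dtype=np.int64)
        )
        inverted = bool(rng.random() < cfg.inversion_prob)
        swapped = bool(rng.random() < 0.5)
        payload_genome = payload_aligned
        if inverted:
            # genome carries the reverse complement of the aligned copy
            comp = np.array([3, 2, 1, 0], dtype=np.int8)
            payload_genome = comp[payload_aligned][::-1]
        ev = _Event(
            bpos=t_b, length=info["L"], present=frozenset({HUMAN}),
            kind="dup", payload=payload_genome, dup_idx=i,
        )
        events[chrom_t].append(ev)
        info.update(
            chrom_t=chrom_t, t_b=t_b, payload_aligned=payload_aligned,
            payload_genome=payload_genome, inverted=inverted, swapped=swapped,
            event=ev,
            identity=1.0 - float((payload_aligned != src_seq).sum()) / info["L"],
        )

    # --- Alu insertion events --------------------------------------------
    insertion_truth: list[dict] = []
    alu_events: dict[str, list[_Event]] = {HUMAN: [], OG1: []}
    for kind, tag, fams in (("alu_h", HUMAN, HUMAN_ALU_FAMILIES), ("alu_o", OG1, HUMAN_ALU_FAMILIES)):
        for i in sorted(by_kind.get(kind, {})):
            chrom, bpos, width = by_kind[kind][i]
            bpos = _avoid_cpg_split(chrom, bpos)
            family = str(rng.choice(fams, p=[0.5, 0.25, 0.25]))
            payload = _random_seq_no_cg(rng, width) if tag == HUMAN else None
            ev = _Event(
                bpos=bpos, length=width, present=frozenset({tag}),
                kind="alu", family=family, payload=payload,
            )
            events[chrom].append(ev)
            alu_events[tag].append(ev)
            ev_chrom = chrom
            insertion_truth.append(
                {
                    "lineage": "human" if tag == HUMAN else "outgroup1",
                    "family": family,
                    "chrom": ev_chrom,
                    "bpos": int(bpos),
                    "length": int(width),
                    "max_elevation": cfg.insertion_max_elevation,
                    "decay": cfg.insertion_decay_length,
                }
            )
    for chrom in chroms:
        events[chrom].sort(key=lambda e: e.bpos)

    # --- coordinate transforms and genome assembly -----------------------
    coords_h = {c: _Coords(events[c], HUMAN) for c in chroms}
    coords_p = {c: _Coords(events[c], OG1) for c in chroms}
    # record genome coordinates of the insertion events in the truth:
    # human-lineage events occupy [start, end) in human coordinates; an
    # outgroup1-specific event is a 1-bp breakpoint on the human side
    ev_by_key = {
        (rec["chrom"], rec["bpos"], rec["lineage"]): rec for rec in insertion_truth
    }
    for chrom in chroms:
        for e in events[chrom]:
            if e.kind != "alu":
                continue
            lineage_label = "human" if HUMAN in e.present else "outgroup1"
            rec = ev_by_key[(chrom, e.bpos, lineage_label)]
            if HUMAN in e.present:
                hs = coords_h[chrom].event_start(e)
                rec["start"], rec["end"] = int(hs), int(hs + e.length)
            else:
                hp = int(coords_h[chrom].to_genome(e.bpos))
                rec["start"], rec["end"] = hp, hp + 1
    genome_idx: dict[str, np.ndarray] = {}
    for chrom in chroms:
        pieces = []
        prev = 0
        for e in events[chrom]:
            if HUMAN not in e.present:
                continue
            pieces.append(backbone[chrom][prev : e.bpos])
            pieces.append(e.payload)
            prev = e.bpos
        pieces.append(backbone[chrom][prev:])
        genome_idx[chrom] = np.concatenate(pieces)
    genome = {c: _indices_to_str(genome_idx[c]) for c in chroms}
    human_len = {c: len(genome_idx[c]) for c in chroms}

    # fill in human coordinates of duplicon copies and write alignments
    alignments: list[DupliconAlignment] = []
    ancestral_truth: dict[str, str] = {}
    pair_rows = []  # per emitted pair: id, sites, levels (filled below)
    for i, info in enumerate(dup_info):
        hs = int(coords_h[info["chrom_s"]].to_genome(info["s"]))
        ts = coords_h[info["chrom_t"]].event_start(info["event"])
        te = ts + info["L"]
        info.update(hs=hs, he=hs + info["L"], ts=ts, te=te)
        src_str = _indices_to_str(backbone[info["chrom_s"]][info["s"] : info["e"]])
        pay_aln_str = _indices_to_str(info["payload_aligned"])
        if not info["swapped"]:
            copy_a = Duplicon(info["chrom_s"], hs, hs + info["L"], "+")
            copy_b = Duplicon(info["chrom_t"], ts, te, "-" if info["inverted"] else "+")
            seq_a, seq_b = src_str, pay_aln_str
        else:
            copy_a = Duplicon(info["chrom_t"], ts, te, "+")
            copy_b = Duplicon(info["chrom_s"], hs, hs + info["L"], "-" if info["inverted"] else "+")
            seq_a = _indices_to_str(info["payload_genome"])
            seq_b = revcomp(src_str) if info["inverted"] else src_str
        alignments.append(
            DupliconAlignment(copy_a, copy_b, seq_a, seq_b, identity=info["identity"])
        )
    write_duplication_alignments(alignments, out / "alignments.txt")

    # --- methylation levels ----------------------------------------------
    # backbone sites: base level, differentiation change, brain levels
    site_levels: dict[tuple[str, int], float] = {}  # base cell type, human coords later
    site_x2: dict[tuple[str, int], float] = {}
    brain_base: dict[tuple[str, int], float] = {}
    for chrom in chroms:
        n = len(cpg_pos[chrom])
        lv = _mixture_levels(rng, n, cfg)
        x2_wide = rng.random(n) < 0.3
        x2 = np.where(x2_wide, rng.uniform(-0.6, 0.6, n), rng.normal(0, 0.05, n))
        x2 = np.clip(x2, -1, 1)
        bb = _mixture_levels(rng, n, cfg)
        for p, l, x, b in zip(cpg_pos[chrom], lv, x2, bb):
            site_levels[(chrom, int(p))] = float(l)
            site_x2[(chrom, int(p))] = float(x)
            brain_base[(chrom, int(p))] = float(b)

    # paralogous pairs: survived CpGs, truth levels, planted discordance
    b0, b1, b2, b3 = cfg.model_coefficients
    discordant_ids: list[str] = []
    pair_true_levels: dict[str, list[float]] = {}
    derived_site_levels: dict[tuple[str, int], tuple[float, float]] = {}  # (level_b, x2)
    pair_records = []  # (pair_id, site_src, site_der, dup_idx, hyper_side)
    for i, info in enumerate(dup_info):
        L = info["L"]
        for p in info["src_cpgs"]:
            off = p - info["s"]
            pa = info["hs"] + off
            if info["payload_aligned"][off] != _C or info["payload_aligned"][off + 1] != _G:
                continue  # dinucleotide destroyed by substitution
            if not info["inverted"]:
                pb = info["ts"] + off
            else:
                pb = info["ts"] + (L - 2 - off)
            key_src = (info["chrom_s"], p)  # backbone key
            level_a = site_levels[key_src]
            x2 = site_x2[key_src]
            if (i, p) in planted:
                lo = float(rng.uniform(0.02, 0.08))
                hi = lo + cfg.planted_discordance_delta
                if rng.random() < 0.5:
                    level_a, level_b = lo, hi
                else:
                    level_a, level_b = hi, lo
                site_levels[key_src] = level_a
                is_planted = True
            else:
                y = b0 + b1 * level_a + b2 * x2 + b3 * level_a * x2
                y += float(rng.normal(0, cfg.noise_sd))
                y = float(np.clip(y, 0, 1))
                sign = 1.0 if rng.random() < 0.5 else -1.0
                level_b = float(np.clip(level_a + sign * y, 0, 1))
                is_planted = False
            if not info["swapped"]:
                pair_id = f"{info['chrom_s']}:{pa}|{info['chrom_t']}:{pb}"
                anc = "a"
            else:
                pair_id = f"{info['chrom_t']}:{pb}|{info['chrom_s']}:{pa}"
                anc = "b"
            derived_site_levels[(info["chrom_t"], pb)] = (level_b, x2)
            pair_true_levels[pair_id] = [level_a, level_b]
            if is_planted:
                discordant_ids.append(pair_id)
            if info["chrom_s"] != info["chrom_t"]:
                ancestral_truth[pair_id] = anc
            hyper_on_src = level_a > level_b
            pair_records.append(
                {
                    "pair_id": pair_id,
                    "chrom_src": info["chrom_s"], "pos_src": pa,
                    "chrom_der": info["chrom_t"], "pos_der": pb,
                    "dup_idx": i, "planted": is_planted,
                    "hyper_site": (info["chrom_s"], pa) if hyper_on_src else (info["chrom_t"], pb),
                    "hypo_site": (info["chrom_t"], pb) if hyper_on_src else (info["chrom_s"], pa),
                }
            )

    # expected count after 1-kb thinning of the planted set: independent
    # greedy brute force in genome order of the emitted first member, with
    # the same <= 1000 bp conflict rule on corresponding members
    planted_recs = [r for r in pair_records if r["planted"]]

    def _emitted(rec):
        first, second = rec["pair_id"].split("|")
        ca, pa = first.split(":")
        cb, pb = second.split(":")
        return ca, int(pa), cb, int(pb)

    kept: list[tuple] = []
    for r in sorted(planted_recs, key=lambda r: _emitted(r)[:2] + _emitted(r)[3:]):
        ca, pa, cb, pb = _emitted(r)
        ok = True
        for kca, kpa, kcb, kpb in kept:
            if (ca == kca and abs(pa - kpa) <= 1000) or (cb == kcb and abs(pb - kpb) <= 1000):
                ok = False
                break
        if ok:
            kept.append((ca, pa, cb, pb))
    n_loci = len(kept)

    # --- brain methylation with insertion spread (vectorised per chrom) ---
    brain_h: dict[tuple[str, int], float] = {}
    brain_p: dict[tuple[str, int], float] = {}
    for chrom in chroms:
        pos = cpg_pos[chrom].astype(np.int64)
        base = np.array([brain_base[(chrom, int(p))] for p in pos])
        elev = {HUMAN: np.zeros(len(pos)), OG1: np.zeros(len(pos))}
        for tag in (HUMAN, OG1):
            bps = np.array(
                [e.bpos for e in events[chrom] if tag in e.present and e.kind == "alu"],
                dtype=np.int64,
            )
            if len(bps) and cfg.insertion_max_elevation > 0:
                d = np.abs(pos[:, None] - bps[None, :]).min(axis=1)
                elev[tag] = cfg.insertion_max_elevation * np.exp(
                    -d / cfg.insertion_decay_length
                )
        hv = np.clip(base + elev[HUMAN], 0, 1)
        pv = np.clip(base + elev[OG1], 0, 1)
        for p, h, q in zip(pos, hv, pv):
            brain_h[(chrom, int(p))] = float(h)
            brain_p[(chrom, int(p))] = float(q)

    # --- remodeled promoters ----------------------------------------------
    remodeled_genes: list[str] = []
    remodeled_sites: list[str] = []
    gene_rows = []
    gene_ids = sorted(by_kind.get("gene", {}))
    human_alu_list = list(alu_events[HUMAN])
    n_remod = min(cfg.n_remodeled_promoters, len(gene_ids), len(human_alu_list))
    remod_alus = list(rng.choice(len(human_alu_list), size=n_remod, replace=False)) if n_remod else []
    for j, gi in enumerate(gene_ids):
        chrom, bpos, _ = by_kind["gene"][gi]
        name = f"gene{gi:04d}"
        expr_y = float(rng.lognormal(1.0, 0.8))
        expr_x = expr_y * float(rng.lognormal(0.0, 0.1))
        if j < n_remod:
            ev = human_alu_list[int(remod_alus[j])]
            ev_chrom = next(c for c in chroms if ev in events[c])
            # nearest backbone CpG within 1.5 kb of the insertion point
            pos = cpg_pos[ev_chrom]
            d = np.abs(pos - ev.bpos)
            k = int(np.argmin(d))
            if d[k] <= 1500:
                site_b = int(pos[k])
                brain_p[(ev_chrom, site_b)] = 0.15
                brain_h[(ev_chrom, site_b)] = 0.82
                chrom = ev_chrom
                bpos = site_b + int(rng.integers(-1500, 1500))
                bpos = max(10, min(cfg.chrom_length - 10, bpos))
                expr_x = expr_y * 0.3  # lower in the insertion lineage
                remodeled_genes.append(name)
                remodeled_sites.append(f"{ev_chrom}:{site_b}")
        tss_h = int(coords_h[chrom].to_genome(bpos))
        gene_rows.append(
            {"gene": name, "chrom": chrom, "tss": tss_h, "strand": "+",
             "expr_x": round(expr_x, 4), "expr_y": round(expr_y, 4)}
        )
    genes_df = pd.DataFrame(gene_rows).sort_values(["chrom", "tss"], kind="mergesort")
    genes_df.to_csv(out / "expression.tsv", sep="\t", index=False)
    io.write_bed(
        pd.DataFrame(
            {
                "chrom": genes_df["chrom"],
                "start": genes_df["tss"],
                "end": genes_df["tss"] + 1,
                "name": genes_df["gene"],
                "score": 0,
                "strand": genes_df["strand"],
            }
        ),
        out / "tss.bed",
    )

    # --- coverage files ----------------------------------------------------
    def _emit_coverage(path: Path, site_level_pairs: list[tuple[str, int, float]]):
        n = len(site_level_pairs)
        levels = np.array([lv for _, _, lv in site_level_pairs])
        depths = sample_depths(rng, n, cfg.depth_mean, cfg.depth_dispersion)
        meth = sample_meth_counts(rng, levels, depths, cfg.meth_dispersion)
        d_plus = rng.binomial(depths, 0.5)
        rows = []
        for (chrom, pos, _), dep, m, dp in zip(site_level_pairs, depths, meth, d_plus):
            dep, m, dp = int(dep), int(m), int(dp)
            if dep == 0:
                continue
            m_plus = int(rng.hypergeometric(m, dep - m, dp)) if 0 < dp else 0
            if dp > 0:
                rows.append((chrom, pos, "+", m_plus, dp - m_plus))
            if dep - dp > 0:
                rows.append((chrom, pos + 1, "-", m - m_plus, (dep - dp) - (m - m_plus)))
        df = pd.DataFrame(rows, columns=io.COVERAGE_COLUMNS)
        df = df.sort_values(["chrom", "pos", "strand"], kind="mergesort")
        io.write_coverage(df, path)

    # human coordinates of backbone sites
    backbone_sites_h: list[tuple[str, int, tuple[str, int]]] = []
    for chrom in chroms:
        hpos = coords_h[chrom].to_genome(cpg_pos[chrom])
        for p, hp in zip(cpg_pos[chrom], hpos):
            backbone_sites_h.append((chrom, int(hp), (chrom, int(p))))

    base_sites = [
        (chrom, hp, site_levels[bk]) for chrom, hp, bk in backbone_sites_h
    ] + [
        (chrom, pos, lv) for (chrom, pos), (lv, _) in sorted(derived_site_levels.items())
    ]
    diff_sites = [
        (chrom, hp, float(np.clip(site_levels[bk] + site_x2[bk], 0, 1)))
        for chrom, hp, bk in backbone_sites_h
    ] + [
        (chrom, pos, float(np.clip(lv + x2, 0, 1)))
        for (chrom, pos), (lv, x2) in sorted(derived_site_levels.items())
    ]
    _emit_coverage(out / "coverage_base.tsv", base_sites)
    _emit_coverage(out / "coverage_diff.tsv", diff_sites)

    brain_human_sites = [(c, hp, brain_h[bk]) for c, hp, bk in backbone_sites_h]
    _emit_coverage(out / "coverage_human_brain.tsv", brain_human_sites)
    brain_og_sites = []
    for chrom in chroms:
        ppos = coords_p[chrom].to_genome(cpg_pos[chrom])
        for p, pp in zip(cpg_pos[chrom], ppos):
            brain_og_sites.append((f"og1_{chrom}", int(pp), brain_p[(chrom, int(p))]))
    _emit_coverage(out / "coverage_outgroup_brain.tsv", brain_og_sites)

    # --- SNPs and per-site flags -------------------------------------------
    nonplanted = [r for r in pair_records if not r["planted"]]
    rng.shuffle(nonplanted)
    snp_ids, alt_ids, noev_ids = [], [], []
    snp_rows, flag_rows = [], []
    cursor = 0
    for _ in range(min(cfg.n_snp_masked, len(nonplanted) - cursor)):
        r = nonplanted[cursor]
        cursor += 1
        snp_rows.append((r["chrom_src"], r["pos_src"], r["pos_src"] + 1, "snp", 0, "+"))
        snp_ids.append(r["pair_id"])
    for _ in range(min(cfg.n_alt_allele, len(nonplanted) - cursor)):
        r = nonplanted[cursor]
        cursor += 1
        flag_rows.append((r["chrom_der"], r["pos_der"], True, True))
        alt_ids.append(r["pair_id"])
    for _ in range(min(cfg.n_no_evidence, len(nonplanted) - cursor)):
        r = nonplanted[cursor]
        cursor += 1
        flag_rows.append((r["chrom_src"], r["pos_src"], False, False))
        noev_ids.append(r["pair_id"])
    io.write_bed(
        pd.DataFrame(snp_rows, columns=io.BED_COLUMNS)
        if snp_rows
        else pd.DataFrame(columns=io.BED_COLUMNS),
        out / "snps.bed",
    )
    io.write_site_flags(flag_rows, out / "site_flags.tsv")

    # --- mappability --------------------------------------------------------
    io.write_bed(
        pd.DataFrame(
            [(c, 0, human_len[c], "unique", 0, "+") for c in chroms],
            columns=io.BED_COLUMNS,
        ),
        out / "mappability.bed",
    )

    # --- islands and per-site classes ---------------------------------------
    island_rows = []
    for i in sorted(by_kind.get("island", {})):
        chrom, start, width = by_kind["island"][i]
        hs = int(coords_h[chrom].to_genome(start))
        island_rows.append((chrom, hs, hs + width, f"island{i}", 0, "+"))
    # CpG islands are sequence-defined, so a duplicated island appears at
    # both copies: annotate one mid-duplicon island in the first few duplicons
    for i in range(min(3, cfg.n_duplicons)):
        info = dup_info[i]
        w = cfg.island_width
        off = info["L"] // 2
        island_rows.append(
            (info["chrom_s"], info["hs"] + off, info["hs"] + off + w, f"dupisland{i}a", 0, "+")
        )
        if info["inverted"]:
            b_start = info["ts"] + info["L"] - off - w
        else:
            b_start = info["ts"] + off
        island_rows.append(
            (info["chrom_t"], b_start, b_start + w, f"dupisland{i}b", 0, "+")
        )
    island_rows.sort()
    islands_df = pd.DataFrame(island_rows, columns=io.BED_COLUMNS)
    io.write_bed(islands_df, out / "cpg_islands.bed")

    def _site_class(chrom: str, pos: int) -> str:
        best = np.inf
        for c, s, e, *_ in island_rows:
            if c != chrom:
                continue
            if s <= pos < e:
                return "island"
            d = s - pos if pos < s else pos - e + 1
            best = min(best, d)
        if best < 2000:
            return "shore"
        return "open_sea"

    pair_site_classes = {}
    for r in pair_records:
        chrom_a, pos_a = r["pair_id"].split("|")[0].split(":")
        pair_site_classes[r["pair_id"]] = _site_class(chrom_a, int(pos_a))

    # --- repeats --------------------------------------------------------------
    repeat_rows = []
    for chrom in chroms:
        for e in events[chrom]:
            if e.kind == "alu" and HUMAN in e.present:
                hs = coords_h[chrom].event_start(e)
                repeat_rows.append((chrom, hs, hs + e.length, e.family, 0, "+"))
    for i in sorted(by_kind.get("alu_shared", {})):
        chrom, start, width = by_kind["alu_shared"][i]
        hs = int(coords_h[chrom].to_genome(start))
        fam = str(rng.choice(SHARED_ALU_FAMILIES))
        repeat_rows.append((chrom, hs, hs + width, fam, 0, "+"))
    # Alu elements preferentially near the hypermethylated copy of planted pairs
    for r in planted_recs:
        chrom, pos = r["hyper_site"]
        offset = int(rng.integers(80, 160))
        start = pos + offset
        repeat_rows.append((chrom, start, start + cfg.alu_length, "AluSx", 0, "+"))
    # unrelated repeat classes, placed anywhere (annotation only)
    for _ in range(cfg.n_other_repeats):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        start = int(rng.integers(0, human_len[chrom] - 600))
        fam = str(rng.choice(["LINE/L1", "LTR/ERVL", "Simple_repeat"]))
        repeat_rows.append((chrom, start, start + 500, fam, 0, "+"))
    repeats_df = pd.DataFrame(repeat_rows, columns=io.BED_COLUMNS).sort_values(
        ["chrom", "start"], kind="mergesort"
    )
    io.write_bed(repeats_df, out / "repeats.bed")

    # --- chromatin read tracks --------------------------------------------
    planted_windows: list[dict] = []
    window_size = 500
    read_rows_windows = []
    all_windows = []
    for i, info in enumerate(dup_info):
        aln = alignments[i]
        ca, cb = aln.copy_a, aln.copy_b
        n_win = (info["L"]) // window_size
        for w in range(n_win):
            a_start = ca.start + w * window_size
            if cb.strand == "+":
                b_start = cb.start + w * window_size
            else:
                b_start = cb.end - (w + 1) * window_size
            all_windows.append((i, ca.chrom, a_start, cb.chrom, b_start))
    idx_sel = rng.choice(
        len(all_windows),
        size=min(cfg.n_planted_discordant_windows, len(all_windows)),
        replace=False,
    )
    planted_idx = {int(k) for k in idx_sel}
    for j, (i, chrom_a, a_start, chrom_b, b_start) in enumerate(all_windows):
        if j in planted_idx:
            zero_side = "a" if rng.random() < 0.5 else "b"
            rate_a = 0.0 if zero_side == "a" else cfg.planted_window_rate
            rate_b = 0.0 if zero_side == "b" else cfg.planted_window_rate
            planted_windows.append(
                {
                    "mark": "H3K4me3", "chrom_a": chrom_a, "a_start": int(a_start),
                    "a_end": int(a_start + window_size), "zero_copy": zero_side,
                }
            )
        else:
            rate_a = rate_b = cfg.window_read_rate
        for chrom, start, rate in ((chrom_a, a_start, rate_a), (chrom_b, b_start, rate_b)):
            k = int(rng.poisson(rate))
            for pos in rng.integers(start, start + window_size - 36, size=k):
                read_rows_windows.append((chrom, int(pos), int(pos) + 36, "H3K4me3", 0, "+"))
    io.write_bed(
        pd.DataFrame(read_rows_windows, columns=io.BED_COLUMNS).sort_values(
            ["chrom", "start"], kind="mergesort"
        ),
        out / "reads_H3K4me3.bed",
    )

    read_rows_sp1 = []
    for r in pair_records:
        if not r["planted"]:
            continue
        for site, rate in ((r["hypo_site"], cfg.flank_enrichment_reads),
                           (r["hyper_site"], cfg.flank_base_reads)):
            chrom, pos = site
            k = int(rng.poisson(rate))
            for rp in rng.integers(max(0, pos - 400), pos + 400, size=k):
                read_rows_sp1.append((chrom, int(rp), int(rp) + 36, "SP1", 0, "+"))
    io.write_bed(
        pd.DataFrame(read_rows_sp1, columns=io.BED_COLUMNS).sort_values(
            ["chrom", "start"], kind="mergesort"
        )
        if read_rows_sp1
        else pd.DataFrame(columns=io.BED_COLUMNS),
        out / "reads_SP1.bed",
    )

    # --- chains -------------------------------------------------------------
    og1_len = {c: cfg.chrom_length + coords_p[c].added for c in chroms}
    og2_len = {c: cfg.chrom_length for c in chroms}
    chains1, chains2, polarity = [], [], []
    cid = 1
    for chrom in chroms:
        chains1.append(
            _build_chain(chrom, cfg.chrom_length, events[chrom], f"og1_{chrom}",
                         HUMAN, OG1, human_len[chrom], og1_len[chrom], cid)
        )
        cid += 1
        chains2.append(
            _build_chain(chrom, cfg.chrom_length, events[chrom], f"og2_{chrom}",
                         HUMAN, OG2, human_len[chrom], og2_len[chrom], cid)
        )
        cid += 1
    polarity = [
        dataclasses.replace(ch, chain_id=1000 + k) for k, ch in enumerate(chains1)
    ]
    for i, info in enumerate(dup_info):
        # redirect chain: derived copy lifts onto the ancestral locus
        q_start = int(coords_p[info["chrom_s"]].to_genome(info["s"]))
        polarity.append(
            io.Chain(
                score=2000.0,
                t_name=info["chrom_t"], t_size=human_len[info["chrom_t"]],
                t_start=info["ts"], t_end=info["te"],
                q_name=f"og1_{info['chrom_s']}", q_size=og1_len[info["chrom_s"]],
                q_strand="+", q_start=q_start, q_end=q_start + info["L"],
                chain_id=2000 + i, blocks=[(info["L"], 0, 0)],
            )
        )
    io.write_chain_file(chains1, out / "outgroup1.chain")
    io.write_chain_file(chains2, out / "outgroup2.chain")
    io.write_chain_file(polarity, out / "polarity.chain")
    with open(out / "synteny.tsv", "w") as fh:
        fh.write("chrom\toutgroup_chrom\n")
        for chrom in chroms:
            fh.write(f"{chrom}\tog1_{chrom}\n")

    # --- genome and config ---------------------------------------------------
    io.write_fasta(genome, out / "genome.fasta")
    cfg.to_yaml(out / "config.yaml")

    truth = SyntheticTruth(
        seed=cfg.seed,
        n_pairs_emitted=len(pair_records),
        discordant_pair_ids=sorted(discordant_ids),
        n_discordant_loci_after_1kb=n_loci,
        ancestral_copy_per_pair=dict(sorted(ancestral_truth.items())),
        insertion_events=insertion_truth,
        true_model_coefficients=list(cfg.model_coefficients),
        planted_windows=planted_windows,
        snp_masked_pair_ids=sorted(snp_ids),
        alt_allele_pair_ids=sorted(alt_ids),
        no_evidence_pair_ids=sorted(noev_ids),
        pair_site_classes=dict(sorted(pair_site_classes.items())),
        remodeled_genes=sorted(remodeled_genes),
        remodeled_sites=sorted(remodeled_sites),
        pair_true_levels=dict(sorted(pair_true_levels.items())),
    )
    write_truth(truth, out / "truth.json")
    manifest = {
        "genome": "genome.fasta",
        "alignments": "alignments.txt",
        "coverage_base": "coverage_base.tsv",
        "coverage_diff": "coverage_diff.tsv",
        "coverage_human_brain": "coverage_human_brain.tsv",
        "coverage_outgroup_brain": "coverage_outgroup_brain.tsv",
        "site_flags": "site_flags.tsv",
        "snps": "snps.bed",
        "mappability": "mappability.bed",
        "cpg_islands": "cpg_islands.bed",
        "tss": "tss.bed",
        "repeats": "repeats.bed",
        "reads": {"H3K4me3": "reads_H3K4me3.bed", "SP1": "reads_SP1.bed"},
        "outgroup1_chain": "outgroup1.chain",
        "outgroup2_chain": "outgroup2.chain",
        "polarity_chain": "polarity.chain",
        "synteny": "synteny.tsv",
        "expression": "expression.tsv",
        "truth": "truth.json",
        "config": "config.yaml",
    }
    io.write_json(manifest, out / "manifest.json")
    return truth


# ---------------------------------------------------------------------------
# Lightweight generators for focused experiments

def simulate_model_input(
    coefficients: tuple[float, float, float, float],
    n: int,
    noise_sd: float,
    seed: int | None = None,
) -> pd.DataFrame:
    """Direct draws from the interaction model (x1 ~ U[0,1], x2 ~ U[-1,1])."""
    rng = np.random.default_rng(seed)
    x1 = rng.uniform(0, 1, n)
    x2 = rng.uniform(-1, 1, n)
    b0, b1, b2, b3 = coefficients
    y = b0 + b1 * x1 + b2 * x2 + b3 * x1 * x2
    if noise_sd > 0:
        y = y + rng.normal(0, noise_sd, n)
    return pd.DataFrame({"x1": x1, "x2": x2, "y": y})


def simulate_pair_set(
    n: int,
    depth_model: tuple[float, float] = (30.0, 0.02),
    correlated: bool = False,
    seed: int | None = None,
    mixture_weights: tuple[float, float] = (0.35, 0.65),
    mixture_means: tuple[float, float] = (0.08, 0.88),
    concentration: float = 20.0,
    meth_dispersion: float = 0.0,
    correlation_noise: float = 0.03,
):
    """Pairs of CpG count observations with or without paralog correlation.

    ``correlated=False`` draws the two true levels independently (a true
    null for the permutation machinery); ``correlated=True`` gives the
    second site the first site's level plus a small Gaussian wobble.
    Returns a list of ParalogousCpGPair with counts attached.
    """
    from .dupmap import CpGSite as _Site
    from .methdiv import ParalogousCpGPair

    rng = np.random.default_rng(seed)
    comp = rng.choice(2, size=n, p=list(mixture_weights))
    means = np.array(mixture_means)[comp]
    la = rng.beta(means * concentration, (1 - means) * concentration)
    if correlated:
        lb = np.clip(la + rng.normal(0, correlation_noise, n), 0, 1)
    else:
        comp_b = rng.choice(2, size=n, p=list(mixture_weights))
        means_b = np.array(mixture_means)[comp_b]
        lb = rng.beta(means_b * concentration, (1 - means_b) * concentration)
    da = sample_depths(rng, n, depth_model[0], depth_model[1])
    db = sample_depths(rng, n, depth_model[0], depth_model[1])
    ma = sample_meth_counts(rng, la, da, meth_dispersion)
    mb = sample_meth_counts(rng, lb, db, meth_dispersion)
    pairs = []
    for i in range(n):
        pairs.append(
            ParalogousCpGPair(
                site_a=_Site("simA", 10 * i),
                site_b=_Site("simB", 10 * i),
                counts_a=MethylCounts(int(ma[i]), int(da[i] - ma[i])),
                counts_b=MethylCounts(int(mb[i]), int(db[i] - mb[i])),
            )
        )
    return pairs


def simulate_ortho_sites(
    n_events: int = 10,
    sites_per_event: int = 60,
    max_elevation: float = 0.2,
    decay: float = 300.0,
    shift: float = 0.0,
    base_range: tuple[float, float] = (0.15, 0.35),
    depth: int = 200,
    max_dist: int = 2000,
    seed: int | None = None,
):
    """Orthologous CpG sites around synthetic insertion events.

    Events are spaced far apart; each contributes sites at uniform signed
    distances within ``max_dist``.  The reference level is the outgroup
    level plus an exponential-decay elevation (and an optional constant
    ``shift`` applied within the events' flanks).  Returns (events,
    sites, expected_x_levels) where the last is the noiseless reference
    level per site.
    """
    from .lineage import InsertionEvent, OrthologousCpG

    rng = np.random.default_rng(seed)
    spacing = 10 * max_dist
    events = [
        InsertionEvent(
            lineage="human", family="AluY", chrom="chr1",
            start=spacing * (i + 1), end=spacing * (i + 1) + 300,
        )
        for i in range(n_events)
    ]
    sites = []
    expected = []
    for ev in events:
        d_signed = rng.integers(-max_dist, max_dist + 1, size=sites_per_event)
        for d in d_signed:
            pos = ev.start + int(d) if d < 0 else ev.end - 1 + int(d)
            base = float(rng.uniform(*base_range))
            lx = float(np.clip(base + max_elevation * np.exp(-abs(d) / decay) + shift, 0, 1))
            mx = int(rng.binomial(depth, lx))
            my = int(rng.binomial(depth, base))
            sites.append(
                OrthologousCpG(
                    chrom_x="chr1", pos_x=pos, pos_y=pos,
                    counts_x=MethylCounts(mx, depth - mx),
                    counts_y=MethylCounts(my, depth - my),
                )
            )
            expected.append(lx)
    return events, sites, np.array(expected)
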