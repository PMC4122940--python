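# Methods

This note documents the models, conventions and numerical choices behind
`paradiverge`, the assumptions of the synthetic-data generator, and what
the passing tests do and do not demonstrate about real data.

## Coordinates and pairing

All intervals are 0-based, half-open; formats with other conventions are
converted at the I/O boundary and nowhere else. A CpG site is keyed by
the position of its C on the plus strand; because the dinucleotide is
strand-symmetric, bisulfite reads reported on the minus strand (the G
at `pos`) are folded onto the plus-strand C at `pos − 1` and the strands
summed. Whether the underlying study combined strands is not something
the within-sample design depends on; combining is declared here and
applied uniformly.

Duplication alignments are parsed from a pairwise text format (header
plus two gapped sequence lines); records whose aligned span is ≤ 1 kb or
whose identity is ≤ 0.90 are rejected with a logged warning, applying
the standard segmental-duplication inclusion rule to the alignment span
(the rule's unit — copy or span — is not fixed by convention; the span
is used here). The coordinate map built from an alignment is an
involution on non-gap positions, and this is enforced by property tests
over fuzzed gapped and inverted alignments. When one genomic position
participates in several duplicon alignments, each alignment contributes
its own pair; deduplication happens only in the motif-export path
(1-kb rule below).

## Exact tests

Both the Fisher test on a pair's 2×2 read-count table and the binomial
test on a window's read split use the minimum-likelihood two-sided
definition: the p-value sums the probabilities of all outcomes no more
likely than the observed one. Both are computed on exact integers
(binomial coefficients), with a single float division at the end.
Rationale: the discordance cutoff (5×10⁻⁷) sits deep in the tail, where
the tie-comparison epsilon of floating-point implementations is the
dominant source of irreproducibility; read depths are capped at ~100 by
the filters, so exact enumeration costs microseconds. The test suite
checks agreement with an independent hypergeometric/outcome enumeration
oracle to 10⁻¹² exhaustively for all tables with margins ≤ 30, and
cross-checks scipy's implementations at looser tolerance.

## Filters and thresholds

Defaults follow the within-sample study design throughout: per-site
depth ≥ 6; total depth across the two sites ≤ 100 (sites with enormous
coverage reach significance at biologically marginal differences); SNP
exclusion at the C or either flanking base of either copy; alt-allele
and cytosine-evidence flags consumed as precomputed per-site inputs
(read-level inspection belongs to the mapping stage, which is out of
scope); discordance alpha 5×10⁻⁷ with an option to recompute 0.05/n;
concordance delta 0.20; 100 permutations; 500-bp windows; 100-bp profile
offset; 2-kb shores and promoter windows; 0.4/0.6 remodeling thresholds;
1-kb paired-test radius. Filters are applied in a fixed order (SNP,
alt-allele, evidence, depth, total depth) and a pair is charged to the
first rule it fails, so rejection counts are additive.

## Permutation null

"Shuffling CpG sites between all duplicated regions" is implemented as
random re-pairing: the second member of every pair is replaced by a site
drawn without replacement from the pooled set of all paired sites
(scheme `pool`). An alternative reading — permuting second members among
pairs (`partners`) — is available behind a flag. The empirical p uses
the add-one convention, (#{perm ≥ obs} + 1)/(n_perm + 1), so p = 1/101
is the smallest attainable value at 100 permutations. Self-re-pairing is
possible under `pool` and makes the test very slightly conservative;
calibration tests show the p-value is uniform under a true null at the
resolution 200 replicate datasets provide.

## 1-kb thinning of discordant loci

For motif export, no two retained discordant pairs may have either
corresponding member within 1,000 bp (inclusive). The survivor within a
cluster is an arbitrary but *fixed* choice: greedy selection in genome
order of the first member. A seeded shuffled order is available, but the
canonical order makes the retained count well defined, which the
generator exploits to compute the expected cluster count independently.

## Chromatin windows

Windows tile copy A from its start; the trailing partial window is
dropped. A position enters a window's mask only if uniquely mappable in
both copies and not a gap column, making the mask symmetric by
construction. A read is assigned by its 5′-most mapped position
(unambiguous, conserves counts across nonoverlapping tiles; the
assignment rule is a convention, not given by the design). The binomial
success probability is fixed at 0.5 — both windows are observed in the
same library, so no size normalisation applies. Bonferroni m is the
number of testable windows (count sum > 0) per mark; the discordant
label additionally requires one copy to have zero reads, restricting to
complete loss events.

## Lineage analyses

Ancestral/derived assignment applies only to interchromosomal pairs:
both sites are lifted through the outgroup chain map; if they land on
the same outgroup chromosome, the copy residing on the reference
chromosome syntenic with it is ancestral, and any failed lift yields
"undetermined".

An annotated repeat is a reference-lineage-specific insertion when the
aligning-block coverage of its span is < 0.1 in *both* outgroup maps
while both 200-bp flanks align (coverage ≥ 0.5) — the flank condition
distinguishes a true insertion from an alignment hole. The 0.1 default
tolerates block-edge slop while rejecting genuinely present elements.
Outgroup-specific insertions are read from query-side (dq) gaps present
in one outgroup's chain but absent from the other's, reported as 1-bp
breakpoints on the reference.

Distances to an insertion are measured to the nearest breakpoint (an
element-length-independent choice; midpoints are not). Profile windows
are 500 bp wide advanced by 100 bp along the signed breakpoint distance;
the 95% CI is the normal approximation mean ± 1.96·SE. The paired
t-test covers orthologous sites within 1 kb of any event and reduces to
t = mean(d)/(sd(d)/√n); degenerate inputs (n < 2, zero-variance
differences) return NA or t = 0, p = 1 explicitly.

Promoter windows for the expression linkage default to TSS ± 2 kb
("close proximity" has no fixed value; 2 kb is the common promoter
envelope and is configurable). The sign test on the lower/higher tally
is the exact two-sided binomial at p = ½.

## Interaction model

The divergence model is OLS of Y (absolute methylation difference to the
paralog; a signed variant sits behind a flag) on X₁ (base-cell level),
X₂ (signed differentiation change) and X₁X₂, with four distinct
coefficients β₀..β₃ and an intercept. A constant explanatory column
raises an error naming the column rather than silently dropping rank.
Equal-count binning is rank-then-split with a stable sort, so bin sizes
differ by at most one and ties resolve deterministically.

## The synthetic-data generator

Three genomes share an ancestral *backbone* per chromosome: the
reference, outgroup1 and outgroup2. Lineage-specific segments
(Alu-like insertions specific to the reference or to outgroup1, and the
derived copies of duplications, which are reference-specific) are
spliced in per genome; UCSC-format chains between genomes then follow
mechanically from the segment model, and "redirect" chains map each
derived duplicon copy onto the ancestral locus in outgroup coordinates,
mimicking best-chain liftover. Shared Alu elements are plain backbone
intervals, present everywhere.

Sequences are i.i.d. bases with every accidental CG removed, so the CpG
complement is exactly the planted set (uniformly placed, ≥ 4 bp apart,
at a requested density per kb). Duplicon copies differ by substitutions
at rate 1 − identity at uniformly chosen positions; planted discordant
pairs are protected from substitution so their dinucleotides survive.
Copies are inverted with probability 0.3 (CpG pairing must work under
reverse complement) and the record's copy order is randomised so both
orientations of the analysis are exercised.

True methylation levels come from a two-component beta mixture (weights
0.35/0.65, means 0.08/0.88, concentration 20 — the classic bimodal CpG
landscape). Differentiation changes X₂ mix a narrow component
(70%, N(0, 0.05)) with a broad one (30%, U(−0.6, 0.6)), emulating the
minority of developmentally regulated sites. Non-planted pairs diverge
by the interaction model with default coefficients
(0.05, −0.04, 0.35, −0.20) and Gaussian noise (sd 0.05), clipped to
[0, 1] with a random sign — small divergences that leave the genome-wide
picture strongly concordant; planted discordant pairs differ by a fixed
delta (default 0.9). Read depths are negative-binomial (mean 30,
dispersion 0.02 — modest overdispersion) and methylated counts
beta-binomial (ρ = 0.02), split binomially across strands. Brain
methylation per species adds an exponential-decay elevation
(max 0.2, decay 300 bp) around that lineage's insertions — the simplest
monotone "seed and spread" shape; remodeled promoter sites override this
with a low-outgroup/high-reference pattern coupled to reduced reference
expression.

The focused discordance-recovery experiment zeroes the model
coefficients so non-planted pairs are exact nulls; there, every
discordant call outside the planted set is a false positive by
construction. In the default bundle the model-driven background means a
rare non-planted pair can carry a real divergence of ~0.3–0.4, which is
detectable at very high depth and is then a correct call, not an error.

**What the generator does not emulate:** read-level artefacts
(mapping bias, bisulfite conversion failure, PCR duplicates), correlated
methylation between neighbouring CpGs, indel polymorphism within
duplicons beyond the alignment gaps, chain noise (block-edge slop,
paralog-confused chains), CpG-island-dependent level structure, and
expression variance models. Passing recovery tests therefore shows the
*procedures* are correct under their stated assumptions, not that the
thresholds are optimal for any particular real dataset.

## Problem sizes

The default bundle uses two 600-kb chromosomes, 20 duplicons (2–5 kb),
~550 CpG pairs, 25 insertions per lineage and ~12,000 orthologous CpGs —
enough to exercise every code path with stable statistics while keeping
a full pipeline run in seconds. The recovery experiments scale up where
their question demands it: ~5,200 pairs/50 planted for discordance
sensitivity, 100 + 100 elements for insertion detection, n = 10,000 for
model-parameter recovery, 200 replicate datasets for permutation
calibration.

## Known limitations

* Segmental duplications are consumed, never detected; real inputs must
  provide the alignment file.
* The chain parser supports the single-coverage subset the analyses
  need (blocks non-overlapping on the target side per map); overlapping
  chain stacks must be pre-filtered to best chains, with the exception
  of redirect chains that live inside primary-chain gaps.
* Ancestral assignment requires an interchromosomal pair and a synteny
  table; intrachromosomal polarity is out of reach of the rule.
* The expression linkage consumes a processed per-gene expression
  table; no RNA-seq quantification is performed.
* Motif discovery and region-set enrichment are delegated to external
  tools (MEME/HOMER, GREAT); the package only exports their inputs
  (flank FASTA, foreground/background BED).
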