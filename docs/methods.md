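# Methods

`genoloss` detects gene-loss events (unitary pseudogenes) in query
species from reference-anchored pairwise genome alignments, screens
them for association with convergently evolved phenotypes, and dates
them. This note documents the models, the tunable parameters, the
synthetic data the tests run on, and the choices made where the design
was genuinely open.

## Detecting inactivating mutations

Each reference CDS exon is paired with its aligned query sequence.
The scanner reports:

- **FS_INS / FS_DEL** — insertions or deletions whose length is not a
  multiple of 3 (reading-frame shifts), any size.
- **STOP_IN_INS** — frame-preserving insertions that introduce a
  premature stop codon, read in the insertion's frame together with
  the flanking query bases of the interrupted codon.
- **STOP_SUBST** — substitutions creating an in-frame stop (TAA, TAG,
  TGA; standard nuclear code, no selenocysteine recoding), read on the
  reference codon grid. Codons containing N are never called.
- **SPLICE_DONOR / SPLICE_ACCEPTOR** — query intron flanks deviating
  from the consensus donor (GT/GC) or acceptor (AG). First exons have
  no acceptor check, last exons no donor check, single-exon
  transcripts no splice checks at all.
- **BIG_INDEL** — frame-preserving indels strictly longer than 50 bp
  (51 bp qualifies, 50 bp does not).
- **EXON_DELETED / EXON_UNALIGNED** — exons without aligned query
  sequence, distinguished by the length of the query region between
  the nearest up- and downstream aligning blocks: shorter than the
  exon means the sequence is absent (deleted). Either becomes
  *missing data* when that inter-anchor region overlaps an assembly
  N-run or when no anchors exist (contig edge).

**Compensated frameshifts.** A maximal run of consecutive frameshifts
whose signed lengths sum to 0 mod 3 restores the downstream frame and
is marked non-inactivating — unless the transiently shifted stretch
between them contains a stop codon on the query's translation grid, in
which case the frameshifts are retained and the shifted stop is
reported as an additional event. A useful consequence (exercised by a
property test): for any placement of offsetting gaps, a query whose
ungapped sequence translates cleanly in the reference frame yields no
surviving frameshift/stop events.

All events carry a position on the reference CDS, expressed as a
fraction of the coding length. Any run of N (length ≥ 1) counts as an
assembly gap; internal coordinates are 0-based half-open everywhere,
converted only at parse/write boundaries (GFF is 1-based closed, BED
and MAF 0-based half-open).

## The filter cascade

Artifacts that mimic inactivating mutations are removed in a fixed
order; each step can only remove events, so per-step counts decrease
monotonically (asserted as an invariant):

1. **Exon presence / assembly gaps** — exon-level calls over gapped
   inter-anchor regions become missing data; point mutations whose
   mutated allele (a codon for stops, the indel stretch for indels)
   lies within 1 bp of an N are dropped (`near_gap`).
2. **Conserved gene order (synteny)** — the gene's query locus must
   lie on the same contig as, and strictly between, the query loci of
   its flanking reference neighbors; a jointly inverted neighborhood
   passes (strand flip). Failure excludes the gene for that species
   (guards against processed pseudogenes and paralogs). Unaligned
   neighbors pass: absence of evidence is not failure.
3. **Realignment rescue** — three exon-structure-aware rescues:
   (a) *splice-site shift*: a disrupted site whose consensus
   dinucleotide reappears within ±18 bp at a frame-preserving offset
   that introduces no stop codon; (b) *precise intron deletion*: the
   next exon follows contiguously in frame on the query (one larger
   composite exon), clearing both splice mutations of the vanished
   intron; (c) *local realignment*: a fresh affine-gap pairwise
   realignment of the ungapped exon pair — mutations it does not
   reproduce were gap-placement artifacts. Realigned mutations are
   matched on class and indel length with a 12-bp positional
   tolerance, which makes the rescue invariant to score-equal gap
   placements (rather than canonicalising indel positions). The
   rescue never adds mutation records.
4. **Terminal trim** — mutations in the first or last 20% of the
   protein are dropped (termini are weakly constrained). Boundaries
   are strict: a mutation exactly at 0.2 or 0.8 is kept.
5. **Isoform selection** — per gene, the annotated isoform with the
   fewest surviving mutations represents the gene; ties go to the
   longer CDS, then the lexicographically smallest transcript id.
   The trim is applied before isoform selection.

The ±18 bp shift window is a small multiple of the codon size covering
common shifts. Known limitation: the shift search accepts any
frame-preserving consensus dinucleotide, so a genuinely dead splice
site with a fortuitous nearby GT/GC can be rescued away; loss evidence
in practice rests mainly on stop and frameshift mutations.

## %intact and loss classification

`%intact` is the largest mutation-free fraction of the coding
sequence: 100 × the widest gap between consecutive elements of
{0} ∪ {surviving mutation positions} ∪ {1}. Mutations at 20% and 55%
leave stretches of 20/35/45%, so %intact = 45. Positions are CDS
fractions (identical to protein fractions up to discretisation); exon
deletions and big indels contribute their start position as a point.
With several isoforms the gene-level value is the maximum.

A gene is a **loss candidate** in a species when %intact < 60 *and* at
least 20% of its exons carry surviving mutations; single-exon
transcripts instead require at least two mutations (still with
%intact < 60, reading the two printed conditions as conjoined). A gene
is **missing data** when it failed synteny or when more than half of
its exons are missing data; otherwise **intact**.

**Ancestral presence.** A loss is only countable if the gene existed in
the common ancestor of reference and query. That ancestor is taken as
the MRCA of the reference and every query species with zero surviving
mutations (post-filter); loss candidates outside the descendant clade
are reclassified `not_ancestrally_present` and dropped. Mutations
identical in class, exon and CDS position across two or more species
are grouped as shared events, which both corroborates the calls
(independently assembled genomes) and places the loss on the common
ancestral branch.

## Phylogenetic screen (forward genomics on %intact)

For each gene, %intact is regressed on a 0/1 trait indicator (1 = the
derived phenotype, "trait group 1") by generalized least squares with
error covariance proportional to the Brownian-motion covariance of the
species tree: cov(i,j) = root-to-MRCA(i,j) path length. No Pagel's λ or
OU transform is applied — Brownian motion is the default of the pGLS
framework, and p values are invariant under global rescaling of the
tree. With identity covariance the fit reduces exactly to OLS (tested
to 1e-10). The slope's two-sided p comes from the t distribution with
n−2 df; a constant response gives slope 0, p = 1 by convention.

Gene prefilters, applied before fitting: excluded if more than 50% of
either trait group is missing data; excluded if fewer than 90% of the
background (trait-2) species have %intact ≥ 90 or if ≥ 5% of them have
%intact < 60. Missing species are row-deleted with the covariance
subset accordingly. Selection: p < 1e-6 *and* slope negative (lower
%intact in trait group 1) — the two-sided p alone would also select
the reverse pattern.

## Dating losses

On the loss branch the gene evolved under selection (Ka/Ks = Ks_sel)
until inactivation and neutrally (Ka/Ks = 1) afterwards, so the
whole-branch ratio K is the time-weighted mixture
K = Ks_sel·Ts/T + 1·Tn/T, giving

    Tn = T (K − Ks_sel) / (1 − Ks_sel),

applied to both bounds of the divergence time T (user input, e.g. a
TimeTree confidence interval). Tn is clamped to [0, T] (sampling noise
can push K outside [Ks_sel, 1]); substituting Tn back recovers K
exactly (tested as an algebraic inverse).

Ka/Ks uses Nei–Gojobori (1986) counting: per-codon synonymous-site
fractions averaged over the two sequences, pathway-averaged difference
counts, Jukes–Cantor correction of both proportions. Changes to or
from stop codons count as non-synonymous; codons with a stop in either
sequence are skipped; ratios are flagged undefined at Ks = 0 or
p ≥ 3/4. The implementation is checked against an independently
written brute-force pathway-enumeration oracle to 1e-10. Fewer than 30
codons triggers an instability warning. Ks_sel pools Ka and Ks sums
over intact-species pairs; K uses the lost sequence against its
closest intact relative as a proxy for the branch's ancestral sequence
— a deliberate simplification (no ancestral reconstruction) that
mixes in the proxy's own selected branch and therefore biases Tn/T
slightly low for terminal-branch losses; the dating tests quantify the
recovered Tn/T under a known halfway switch.

## Read validation

The mutated allele with ≥ 50 bp of flanking assembly sequence on each
side (≥ 101 bp context for a substitution; the junction for indels) is
matched exactly — no alignment, no quality use — against unassembled
reads in both orientations (reads are unstranded). At least 10 reads
containing the full context validate the mutation. The full context
must lie inside a single read, which determines the read lengths this
is useful for: the simulator's read defaults are long accurate reads
(10 kb, 1e-4 error, HiFi-grade) at 20× coverage, under which an
interior locus collects ≥ 10 exact matches with probability ≈ 0.99.
The validation experiment evaluates loci further than one read length
from a contig end: with a megabase-scale simulated genome and 10-kb
reads, edge loci are systematically undercovered — an artifact of the
small simulated genome, not of the method.

## The synthetic-evolution generator

The generator emits every input the pipeline consumes — reference
genome + GFF3 annotation, query genomes, per-exon MAF alignments,
Newick tree, trait table, reads, and a truth table — with no heuristic
aligner anywhere: exons are lists of ancestral columns (substitution =
replace, deletion = empty, insertion = attach), and ref-vs-query
alignments are rendered exactly from shared columns, so every detected
mutation is attributable to a recorded event.

Defaults describe the screen-scale study conditions: a 40-leaf tree
(root-to-leaf ≈ 0.12 neutral substitutions/site), 2,000 genes of 1–8
exons (90–210 bp each, CDS length a multiple of 3), 120-bp introns
with GT…AG boundaries, target Ka/Ks 0.2 under selection (achieved by
accepting non-synonymous proposals with probability ω; stop-creating
and splice-disrupting changes are rejected while conserved),
frame-preserving terminal-branch indels at 0.03 of the substitution
rate, assembly base errors at 1e-4 (consensus-grade accuracy), ~6
N-gaps/Mb of ~300 bp with error clusters planted at gap edges, and
optional per-gene×species splice-shift and precise-intron-deletion
artifacts. Loss branches switch to ω = 1 at a configurable fraction of
the branch and receive injected mutations — one stop, one frameshift
deletion, one frameshift insertion — placed in the middle 50% of the
CDS across distinct exons (so the printed loss thresholds are
satisfiable by construction) and pinned against later drift so the
truth table stays exact. Convergent losses name the same genes on
several independent branches.

Simplifications a user should know about: substitution proposals are
unbiased (κ = 1), which keeps the counting estimator's calibration
transparent; natural indels occur only on terminal branches (internal
branches would need per-base identity tracking to align exactly) while
injected loss indels may sit on internal branches; intron interiors
and intergenic spacers do not accumulate substitutions (they are never
scanned; only their splice dinucleotides evolve); no repeats, GC
isochores, or empirical indel spectra; the reference assembly is
uncorrupted; all sequences are forward-strand. Passing tests therefore
demonstrate the detection/filtering/screening logic under exact
alignments and known truth — not robustness to aligner error, repeat
content, or annotation noise in real genomes.

## Problem sizes used by the test suite

The screen-scale experiment runs 2,000 conserved genes × 15 query
species on a 16-leaf tree with 20 genes lost convergently on three
independent internal branches plus the full artifact set; it checks
the monotone filter cascade, a conserved-gene false-call rate ≤ 0.5%
(measured per gene × species call), ≥ 95% recovery of injected losses
in all descendant species, and correct ancestral placement. The pGLS
power/specificity test uses a 40-leaf tree with three derived lineages
and 1,000 phylogeny-correlated null genes. Dating runs 50 replicates
of 3,000-codon genes with a halfway neutrality switch. Read validation
uses ~1,400 genes on a two-leaf tree with reads at 20×. The whole
suite completes in about a minute on one CPU.

## Numerical and degenerate-input choices

- Terminal-trim and loss-threshold boundaries as stated above (strict
  %intact < 60, inclusive ≥ 20% exon fraction, strict > 50 bp indels).
- percent_intact of an empty set is 100; it is non-increasing under
  adding mutations and equals 100 iff no mutation survives.
- GLS covariance condition number > 1e12 raises (degenerate tree);
  a zero-total-length tree is rejected outright.
- Ka/Ks: Ks = 0 or Jukes–Cantor divergence (p ≥ 3/4) → flagged,
  ratio None; dating requires Ks_sel < 1.
- Context extraction truncates (with a warning) within 50 bp of a
  contig end and refuses contexts overlapping an N-run.
- All randomness flows from explicit integer seeds; a fixed seed
  yields byte-identical generator output (hash-compared in tests).
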