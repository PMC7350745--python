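# Methods

This note documents the models, conventions and design choices behind each
stage of the pipeline, what the synthetic data does and does not emulate,
and the numerical details a maintainer would need.

## Coordinates and formats

All internal interval arithmetic is 0-based half-open on the forward
strand; conversion to/from GFF3's 1-based inclusive coordinates happens
only at the I/O boundary and is a bijection (property-tested). Sequences
are upper-cased on read; soft-masking is not tracked. `N` is allowed in
nucleotide records and any codon containing `N` translates to `X`; `X` is
allowed in proteins and is neutral in motif scoring (log-odds 0, never
consensus-identical).

## Motif models

A motif is a conserved amino-acid block of width 7–50 residues. Discovery
operates on a seed alignment rather than unaligned sequences: each column
is scored by information content against the seed-set residue background,
`IC(c) = Σ_r p_r log₂(p_r / q_r)` with a pseudocount of 0.01 per cell, and
maximal runs of columns with IC ≥ 2.0 bits and gap fraction ≤ 20% become
motifs (runs over 50 columns are split into near-equal pieces; runs under 7
are dropped). Motifs are numbered by decreasing total IC, which mirrors the
common practice of numbering motifs by discovery significance rather than
position. Expectation-maximization discovery and E-values are deliberately
out of scope: downstream stages need only scannable models and consensus
strings, and conservation is reported as total IC instead.

The 2.0-bit threshold was chosen against the pseudocounted IC bias of a
random column: with ≥ 12 aligned sequences the expected IC of an
unconserved column is ≈ 0.8–1.5 bits, while a conserved column at ≤ 15%
substitution exceeds 3 bits, so 2.0 separates the two regimes with margin.

Scanning is sliding-window log-odds in bits. Presence requires consensus
identity ≥ 0.6 **and** positive log-odds. The 0.6 default is intentionally
below the ~0.71 consensus identity at which diverged motif variants are
still treated as the same motif in cross-genotype comparisons, and is
configurable everywhere. Overlapping hits within one protein are resolved
by keeping the higher log-odds hit (ties: smaller motif id), giving the
non-overlapping tiled architectures used for presence/absence tables.

Motif-vs-motif identity (`compare_motifs`) is a global affine-gap alignment
of the two consensus strings; identity is identical columns over total
alignment columns, as a percentage.

## Paralog scan

The detection strategy finds family members that annotation missed:

1. Six-frame translation with per-residue coordinate maps back to
   forward-strand codon intervals (verified against a naive per-codon
   oracle, both strands).
2. Anchor search: every presence-called occurrence of the spatially first
   and last motifs of the seed architecture, in any frame. Unlike best-hit
   scanning, all qualifying windows are kept (a chromosome track can hold
   several members); overlapping qualifying windows reduce to local score
   maxima.
3. Window construction: paired anchors within 1.5 × target length delimit
   the window directly. A lone anchor opens a window of the target length
   (default 280 residues — the family's typical full protein length)
   positioned with offsets learned from the seed proteins: the mean
   distance from the N-terminus to the first anchor, and from the last
   anchor to the C-terminus. The positioning rule is a package decision
   (the strategy itself only fixes the 280-residue extension); learning the
   offsets from the seed family centers the window the way the family is
   built, and both are configurable.
4. Stop handling: windows are clipped to the stop-free translated segment
   containing the anchor rather than rejected — truncated members are
   biologically real. Candidates shorter than 90 residues are discarded;
   the shortest credible real members are ≈ 106 residues, so 90 keeps all
   of them while suppressing fragments.
5. Membership: ≥ 3 of the family motifs present (the canonical inclusion
   rule for this kind of clade). Overlapping same-strand candidates
   collapse to one (max motif count, then longer protein, then smaller
   start). Proteins with duplicated motif sets would be reported once with
   repeated hits, not split.
6. Reconciliation: ≥ 50% reciprocal overlap with an annotated gene on the
   same strand ⇒ `confirms-annotated`; otherwise `novel`.

Known limitation: the scan is single-exon. Multi-exon members are found
only insofar as one exon carries enough motifs; this matches the biology of
predominantly mono-exonic tandem arrays but will under-call spliced
paralogs. Both raw chromosome sequence and translated proteome input work:
scanning a proteome is just running `architecture` + the ≥ 3-motif filter on
each protein, while the genomic scan handles the unannotated space.

## Conservation

Pairwise alignment is global Gotoh with BLOSUM62 and gap open 10 / extend 1
for protein (match +2 / mismatch −1, open 10 / extend 0.5 for DNA); a gap
run of length L costs open + (L−1)·extend. Biopython's `PairwiseAligner`
provides the C implementation; tests verify score equality against an
independent pure-Python three-state DP on random instances.

Percent identity defaults to identical columns divided by columns where at
least one member of the pair is non-gap (double-gap columns skipped). The
alternative "shorter-sequence denominator" convention is implemented
because published identity figures frequently do not state theirs; the two
can differ by a few points on gappy alignments, which is why any comparison
against published means should carry a ±2–3 point tolerance.

Progressive MSA: UPGMA guide tree on 1 − identity/100 distances (ties in
joining broken lexicographically by cluster label), then profile–profile
Gotoh along the tree with expected-pair column scores `f_Aᵀ S f_B`
(frequencies exclude gaps, so gappy columns score proportionally less) and
the same gap model. With exactly two sequences the entry point delegates to
the pairwise aligner so the two agree by construction. No iterative
refinement is attempted. A note on testing: a progressive alignment can
only be bounded by, never required to match, the exhaustive multi-sequence
optimum, so the oracle test checks `SP(progressive) ≤ SP(exhaustive 3-way
DP)` with equality on unambiguous triples.

Trees are neighbor-joining (scikit-bio) on alignment identity distances.
Maximum-likelihood search is out of proportion to the claim the tree
supports — that the family is monophyletic against outgroup proteins — so
NJ with a column-resampling bootstrap (support = fraction of replicates
containing each internal bipartition, exact by construction) is used as the
in-repo proxy, and monophyly-with-support is the tested property.

## Promoter census

Promoters are the 3000 bases upstream of the annotated gene start (the TSS
proxy; no 5′ evidence is used), reverse-complemented for minus-strand genes
so position −1 is always adjacent to the TSS. Regions clipped at a
chromosome edge are flagged and warned about.

IUPAC patterns are matched with overlap counting (a lookahead regex,
verified against an exhaustive per-position matcher), on both strands by
default — the convention of classic plant cis-element catalogues — with a
forward-only mode provided because published occurrence totals do not
always state their strand convention; convention sweeps should report both.
A palindromic pattern is counted once per position in both-strand mode.
`elements_in_all` and `unique_elements` are exact set operations on the
count table.

## Co-expression consensus

Per series: genes are log₂(x+1)-transformed, then filtered (nonzero
variance and mean ≥ 0.1 on the log scale — correlation is undefined on
constant genes, and near-silent genes contribute only noise). Adjacency is
unsigned, `a_ij = |cor|^β` with β = 6, the customary unsigned default when
no scale-free fit is specified; signed mode is available. TOM follows the
standard unsigned formula and is tested to 1e−10 against a triple-loop
oracle. Clade connectivity of a gene is its **mean** TOM to the clade
members — invariant to clade size, unlike sum, and less outlier-prone than
max. Clade members themselves are eligible candidates by default
(configurable), and an alternative union-of-member-lists mode is available
by running single-gene neighborhoods per member and uniting them. Rankings
break ties lexicographically so top-k is deterministic. The consensus
reports genes present in ≥ m of the per-series top-k neighborhoods,
excluding the clade itself; by construction the ≥ m set is nested in the
≥ m−1 set.

## Expression statistics

Z-scores use sample sd (denominator n−1); constant rows are emitted as
zeros and flagged rather than erroring. Fold-dominance is computed on the
raw (untransformed) scale: per series, the focal member's mean over samples
divided by the mean over samples and genes of the rest of the clade; the
aggregate is the arithmetic mean of per-series ratios (a pooled variant is
also reported, since the aggregation order is a genuine ambiguity in how
such ratios get summarized). The statistic is scale-invariant per series.
DEG frequency counts contrast membership only; no differential-expression
testing is performed here — DEG tables are inputs.

## Synthetic data

The generator emulates: one chromosome carrying a tandem array of
single-exon ~280-residue paralogs sharing an ordered set of 9 motif
templates (default widths 50 down to 7); per-member substitution at a
configurable rate; N-terminal truncations for designated members (defaults
mirror a family of 18 with two members missing their first four motifs);
about a third of members on the minus strand; only a subset of members
annotated (default 12 of 18, leaving 6 to discover); 3000-bp promoters
containing **exactly** the planted per-element counts on the
transcription-oriented strand (iterative repair re-draws background
positions that spuriously match, with exact final verification); and
expression series in which module genes share a latent per-sample profile
(`√ρ·z + √(1−ρ)·ε` on the log₂ scale, exponentiated to TPM-like positives)
against an independent background.

Divergence model: motif residues mutate at the stated rate; inter-motif
linker residues are fully re-drawn whenever the rate is positive. This
mirrors the empirical structure of such clades — motifs conserved, linkers
highly variable — and is what makes motif discovery a meaningful test (at a
uniform low rate the whole protein would be one conserved block). At rate 0
every member is identical, preserving the degenerate contract.

What the generator does **not** emulate: codon usage bias, introns,
indel evolution within motifs, promoter composition beyond uniform
background plus planted elements, and realistic expression distributions
(library-size effects, zero inflation, batch structure). Passing tests
therefore demonstrate the algorithms' correctness on data with the stated
structure, not performance on real genomes, where annotation noise,
repeats and splicing add failure modes the scan documents as limitations.

The generator is a pure function of (spec, seed); identical inputs give
byte-identical outputs.

## Problem sizes

The test suite and acceptance script run at sizes chosen to exercise every
code path while staying desk-scale: 20 generated genomes of 5–20 members
for recovery; 2000 genes × 12 samples × 5 series for the consensus;
100-gene TOM and 50-pair alignment oracles; 200 random 3-kb sequences for
the census oracle; promoter-identity MSAs on the 400 bp adjacent to the TSS
(the DNA profile aligner is quadratic in length, and identity summaries
stabilize well below full promoter length; the census always uses the full
3 kb).
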