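# Methods

This note documents the models, parameter choices and numerical
conventions behind each stage, what the synthetic generator does and
does not emulate, and the design decisions taken where the workflow was
genuinely open.

## Coordinates and formats

All genomic and protein coordinates crossing the API are 1-based
inclusive (the GFF3 convention); no half-open intervals are exposed.
FASTA parsing goes through Biopython; gene loci are derived from
protein/transcript ids by a configurable rule (default: strip common
isoform suffixes `_P01`, `_T01`, `-T01`, `.1`), because splice-variant
collapsing depends entirely on correct locus grouping. HMMER per-domain
tables are read in a tolerant whitespace-delimited dialect: only the
target name, full-sequence E-value and alignment coordinates are
consumed; extra columns are ignored so minor HMMER versions parse
identically. Newick output writes branch lengths with 6 decimals and
integer bootstrap supports as internal node labels; characters with
structural meaning in leaf names are replaced by `_` rather than quoted,
for maximal downstream-tool compatibility.

## Census

Members are proteins with ≥ 1 domain hit at full-sequence E-value ≤ the
cutoff (default 1e-5). The comparison is inclusive (≤): search tools
conventionally report pass-at-threshold as passing, and the cutoff's
provenance does not state strictness. Isoforms collapse per locus; the
representative is the longest protein (ties: lexicographically smallest
id) — the standard convention for family censuses. Census rows are
ordered by locus id and named `<prefix>1..N`, which makes naming
deterministic and mirrors how published family numbering follows locus
order.

Molecular weight is the sum of average (isotope-abundance-weighted)
residue masses plus one water (18.01524 Da). The isoelectric point is
the root of the Henderson–Hasselbalch net-charge function, found by
bisection on pH ∈ [0, 14] to |charge| < 1e-4 or 100 iterations; the pKa
set defaults to the EMBOSS values (N-term 8.6, C-term 3.6, K 10.8,
R 12.5, H 6.5, D 3.9, E 4.1, C 8.5, Y 10.1) and is configurable.
Published pI values depend on the tool's pKa set, so exact third-party
pI values are not an accuracy surface for this operation; the packaged
published table carries its own printed values. Sequences containing X
stay in the census but get no MW/pI (with a warning) since X has no
defined mass or pKa.

The packaged 86-row census table stores molecular weight in Daltons as
printed even though the source header says kDa (the values, e.g.
55337.9, are plainly Daltons); the unit is documented rather than
guessed at. Its internal consistency checks: 86 rows, checksum, and the
summary statistics the table itself implies (chromosome counts 17/13/3
on chr4/chr1/chr8, lengths 111–809 aa, pI 4.4973–10.717). Where the
narrative text disagrees with the table (text maximum length 734 aa vs
table 809; text pI maximum 7.7965 vs table 10.717; text MW maximum
72083.7 vs table 89139.9), the census computes from the table's data;
the mean pI over all 86 rows computes to 6.4529.

## Phylogeny

Distances are protein p-distances: mismatches over columns where both
sequences carry residues, gapped columns excluded pairwise. The
uncorrected p-distance is the default; the Kimura protein correction
d = −ln(1 − p − 0.2p²) is opt-in (p ≥ 0.854 maps to a configurable
ceiling, default 10). Unaligned inputs can use `pairwise_global` mode,
which aligns each pair with the duplication-stage aligner first.

Neighbor joining is the canonical algorithm: join the pair minimising
Q(i,j) = (r−2)d(i,j) − R_i − R_j; branch lengths
v_i = d(i,j)/2 + (R_i − R_j)/(2(r−2)); reduced distances
d(u,m) = (d(i,m)+d(j,m)−d(i,j))/2; the result is an unrooted tree with
a trifurcating root. Negative branch lengths are clamped to zero with
the deficit moved to the sibling edge (PHYLIP-compatible); at the final
trifurcation the closed-form lengths are clamped at zero without
redistribution. Q-ties are broken towards the lexicographically
smallest pair of subtree labels (a subtree is labelled by its smallest
leaf), making the topology deterministic and independent of input
order. On additive matrices NJ provably recovers the generating tree;
the tests verify this against an exhaustive least-squares topology
enumeration for 4–8 taxa and against scikit-bio's independent NJ.

Bootstrap replicate r resamples alignment columns with a fresh RNG
seeded `seed + r` — reproducible and trivially parallelisable. Support
on an internal edge is the percentage of replicates containing the same
(canonicalised) bipartition, rounded to the nearest integer.

Subfamily assignment midpoint-roots the tree (the workflow's reference
figure is rooted without a stated rule; midpoint is the standard
assumption-free choice), then gives each query leaf the majority anchor
label of its smallest proper ancestor clade containing ≥ 1 anchor.
Majority ties, or anchors reachable only at the root, yield
`UNASSIGNED`; a label never propagates unless it is in the anchor set.

## Duplication criteria

Global alignment is Needleman–Wunsch with affine gaps through
Biopython's `PairwiseAligner` (BLOSUM62, gap open 10, gap extend 0.5; a
gap of length k costs open + k·extend, end gaps included). The source
workflow does not state its aligner, so these conventional defaults are
configurable; correctness is pinned to an independent textbook
three-matrix DP oracle in the tests. Identity = identical columns /
both-residue columns; coverage = both-residue columns / length of the
longer input, interpreting "covered most of the longest gene" at the
protein level.

A pair is an event iff identity > 0.80 AND coverage > 0.80 — strictly
greater, per the criteria's "> 80%" wording. Since coverage can never
exceed shorter/longer length, pairs whose length ratio is ≤ the
coverage threshold are skipped before aligning; a property test checks
the shortcut never changes results. "Tightly linked" genes (same
chromosome with gap ≤ 200 kb or ≤ 5 intervening census genes — both
configurable; the phrase is used without a published definition)
contribute one event per linked cluster, retaining the
highest-identity pair. Classification: tandem if same chromosome and
(gap ≤ 200 kb or ≤ 5 intervening genes), else segmental.

## Structure and motifs

Intron statistics use each gene's representative transcript — the same
longest-protein isoform the census chose, keeping the panels of a
family figure consistent. Motif discovery itself (MEME-style EM) is out
of scope; occurrences are consumed as a table. A motif is
subfamily-specific when present in ≥ 70% of the subfamily and ≤ 20% of
the remaining genes; these two thresholds are invented defaults (the
qualitative claim being formalised gives no numbers) and are
parameters of the call.

## Expression and qPCR

Clustering mirrors the Cluster 3.0 heatmap workflow: per-gene scaling
(z-score with sd = 0 rows mapping to zeros, or unit-max), Pearson
distance d = 1 − r (centred) or Euclidean, and agglomerative
average/complete/single linkage implemented directly so NA cells can be
handled by pairwise-complete observations and ties broken
deterministically (equal-distance merges resolve to the smallest
original cluster-index pair). Genes observed in < 50% of tissues are
excluded with a warning. The implementation is cross-checked against
scipy's linkage on complete data and against a naive exhaustive
agglomeration oracle.

Duplicate pairs are "similar" when Pearson r ≥ 0.8 over
pairwise-complete tissues (< 3 shared observations → undeterminable).

Comparative Ct: replicate Ct values are averaged before ΔCt (the
source protocol reports three biological replicates without an
aggregation rule; mean-first is the common convention), and the
per-replicate 2^−ΔΔCt spread is returned separately for error bars.
ΔΔCt = ΔCt(sample) − ΔCt(calibrator); relative expression = 2^−ΔΔCt,
so sample = calibrator gives exactly 1 and the sample↔calibrator swap
is exactly reciprocal.

## Synthetic generator

The generator plants a family whose magnitudes mirror the maize census:
86 genes in 8 subfamilies (LISCL largest with 28; SCR and LS smallest
with 4), 18 loci carrying a second splice form (104 member transcripts),
11 duplicate pairs (3 SHR, 3 PAT1, 2 LISCL, 1 each DELLA/SCL3/LS; 4
tandem, 7 segmental), 80% intronless genes, 10 chromosomes, 13 tissues,
40 decoy proteins, and 9 of 11 duplicate pairs with concordant
expression.

Each protein is a subfamily-specific N-terminal block (120 aa) plus the
shared ordered C-terminal blocks (LHRI 30, VHIID 40, LHRII 30, PFYRE 40,
SAW 40 aa) mutated at rate 0.15 per subfamily; genes mutate their
subfamily consensus at rate 1 − √(background identity), so two genes of
one subfamily sit near the 0.5 background-identity ceiling and far below
the 0.8 duplication criterion. Duplicates copy a source gene and mutate
exactly round((1 − 0.92)·L) positions to different residues — with no
indels, global-alignment identity is analytically 1 − k/L ≈ 0.92 and
coverage 1. All family proteins have equal length, so the proteome is
its own trivial alignment; p-distance phylogenies need no aligner.
Anchor proteins (2 per subfamily) are extra draws from each consensus.

Placement guarantees the duplication stage's cluster-collapse can never
merge two planted pairs: each tandem pair sits adjacent (gap 2–50 kb)
on its own chromosome, segmental pairs span two distinct chromosomes
with distinct chromosome pairs, and intergenic gaps have a 300 kb floor
so tandem-window defaults classify the planted classes correctly.
Intron counts are drawn to hit the intronless fraction exactly over the
final gene set (duplicates inherit their source's structure, matching
the observation that duplicated genes share gene structure); the
remaining genes draw 1–5 introns with weights mirroring the published
tally. Domain-table E-values are log-uniform in [1e-30, 1e-6] for
members and [1e-4, 1] for decoys — unambiguous separation at the 1e-5
cutoff, with threshold-boundary cases exercised by explicit fixtures
instead. Motifs 1–6, 9, 11 are widespread (95% presence), motifs 15–17
are planted only in the LISCL analog, and the remaining motifs
concentrate in one designated non-LISCL subfamily each (85% in / 5%
out).

Expression profiles come from per-subfamily archetypes (2^N(5, 2) per
tissue) with per-cell lognormal noise (sd 0.2 in log2 units);
archetypes are rejection-sampled to pairwise |log-correlation| ≤ 0.3 so
the planted clusters are separable by construction. The first 9
duplicate pairs share archetypes; the rest have the copy reassigned to
the least-correlated other archetype, making exactly 9/11 = 81.82%
similar calls. Ct values follow Ct = 28 − log2(expression) + N(0, 0.1)
with 3 replicates; the reference gene is constant at Ct ≈ 20
(sd 0.04, CV ≪ 2%). One non-duplicate gene carries an exact 4-fold
expression ratio between two tissues for ΔΔCt parameter recovery; with
replicate noise sd 0.1 the ΔΔCt estimator's sd is ≈ 0.12 log2 units,
and tests use a 3σ bound of 0.35.

What the generator does **not** emulate: indels and alignment ambiguity
(duplicate identities are exact by construction), rate heterogeneity or
realistic evolutionary models, codon structure, unbalanced tissue
coverage/missing cells, amplification-efficiency variation in qPCR, and
genome-scale gene density. Passing the planted-truth tests therefore
shows the algorithms are correct under clean, well-separated signals —
not that real proteomes will separate as cleanly.

## Problem sizes

The default analysis runs at the study's own scale (86 genes + 16
anchors, 102-leaf trees, ~3.7k pairwise alignments for the duplication
scan) and completes in seconds to tens of seconds per stage; bootstrap
analyses in the numbered scripts use 100 replicates, which stabilises
support percentages at this leaf count while keeping the analysis
interactive (the library default is 1000, matching common practice for
publication trees). Oracle-backed checks use 200 random 4–8-taxon
matrices for NJ and 500 random ≤ 60-mer pairs for alignment.

## Known limitations

* The pI bisection assumes a monotone net-charge curve, true for the
  Henderson–Hasselbalch model used; exotic pKa sets violating
  monotonicity are not supported.
* `find_duplicate_pairs` aligns all length-compatible pairs (O(n²)
  alignments); for censuses of a few hundred genes this is seconds, but
  no indexing/pre-screening beyond the length-ratio bound is provided.
* Subfamily assignment depends on midpoint rooting; a long-branch query
  that midpoint rooting isolates can be left `UNASSIGNED`.
* Intervening-gene counts in linkage/tandem rules are computed over the
  census genes only, not a full genome annotation; with sparse censuses
  the bp-gap rule dominates, which is why both criteria are exposed.
* The heatmap itself is not rendered; the clustered order and scaled
  matrix are exported for any standard heatmap viewer.
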