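# Methods

## The objects

A plastome is modeled as a named circular DNA string over {A,C,G,T,N}
with an annotation set (gene name, category ∈ {protein_coding, tRNA,
rRNA, pseudogene}, strand, ordered exon intervals, copy tag) and, once
computed, a region partition. All internal coordinates are 0-based,
half-open, on the forward strand of the normalized circle; GFF3 I/O
(1-based inclusive) converts at the boundary. Introns are derived as the
gaps between consecutive exons, never stored. After normalization the
region order is LSC, IRb, SSC, IRa with LSC starting at 0; features
never wrap the origin (a wrapping input feature is split on load).

## Inverted-repeat detection

Detection is exact-match by design: real plastome IR copies are
effectively identical, and exactness keeps every downstream coordinate
deterministic. The sequence (doubled, to cover the circular wrap) is
k-mer indexed (k = 31) against its doubled reverse complement; seed hits
are grouped by diagonal, merged into maximal runs, and every maximal
disjoint pair of reverse-complement copies ≥ `min_ir_len` (default
1,000 bp — real IRs are ~26 kb, tRNA-scale repeats must not trigger) is
a candidate. The longest pair wins; ties break toward the smallest start
coordinate. Repeats covering > 90% of the circle are rejected as
degenerate. A mismatch-tolerant mode is deliberately out of scope.

Orientation is not intrinsically defined for a circle: both strands
read LSC, IRb, SSC, IRa. `normalize` therefore takes the
lexicographically smaller of the two LSC-first rotations (forward wins
ties), which makes normalization idempotent and invariant under
rotation and reverse-complementation. The pipeline makes one pragmatic
exception: genomes whose detected LSC already starts at 0 (generator
output) keep their coordinates, so truth manifests and variant tables
share one frame.

## Junction analysis

Gene extent for junction purposes is the full genomic span (first exon
start to last exon end, introns included): IR expansion/contraction is
a statement about gene bodies crossing boundaries, not exon structure.
Spanning genes are reported with the bases on each side (these sum to
the span); genes within a window (default 2,000 bp) are reported with
their circular distance to the junction. The IRa/LSC junction coincides
with the origin; origin-split gene halves are re-joined for reporting.
Which repeat copy is called "IRa" versus "IRb" is a convention fixed by
the normalized order, not a biological fact.

## Variant scanning

The internal aligner is global affine-gap (Gotoh): match +2, mismatch
−3, gap open −5, gap extend −2, where a gap of length g costs
open + g·ext. Traceback tie-breaking is deterministic: diagonal
(match/mismatch) over vertical (deletion) over horizontal (insertion).
Scores are small integers kept in float32, so equality tests in the
traceback are exact. At genome scale the full DP is infeasible, so
unique shared 31-mers are chained co-linearly (longest increasing
subsequence) and only inter-anchor segments are solved by DP — adequate
for the high-identity genomes this pipeline targets; an external MSA
can be supplied instead. Sequences whose lengths differ by more than
the band (default 2,000 bp) are rejected.

Calling walks alignment columns: mismatching base columns are SNPs
(N never calls); maximal gap runs in the sample are deletions and in
the reference insertions, anchored at the last reference base before
the event and left-normalized (shifting an indel within a homopolymer
yields one canonical position). Adjacent gap runs separated by a match
column are distinct loci. Runs shorter than `min_indel_len` (default
5 bp) move to a side table but stay counted. Events are classified by
the reference partition region and by context: genic (overlaps an
exon), intronic (inside a gene span but not an exon), else intergenic
with the flanking genes named.

## Codon usage

CDS are spliced in strand order and screened: length ≥ 300 nt, length
divisible by 3, no internal stop, no N (each exclusion is recorded with
its reason). Counting uses translation table 11; the start codon counts
as its literal codon and stop codons form their own family, excluded
from RSCU — the common convention where no explicit rule exists.
Frequencies are reported per-mille. GC3 is the G/C fraction at third
positions over all counted codons. Clustering of genomes uses
average-linkage hierarchical clustering on Euclidean distances between
the 64-dimensional frequency vectors (RSCU vectors by flag); genomes
are pre-sorted by name so leaf order is deterministic.

## Ka/Ks (NG86)

Synonymous site fractions per codon come from the nine single-base
neighbors; a mutation creating a stop codon is nonsynonymous. S is
averaged over the two sequences; N = 3·(codons compared) − S, so
S + N ≡ 3·codons. Multi-difference codon pairs are averaged over all
minimal pathways, excluding pathways through stop codons unless every
pathway is blocked. pS = Sd/S and pN = Nd/N receive the Jukes–Cantor
correction d = −(3/4)·ln(1 − 4p/3), undefined at p ≥ 3/4. Ks = 0 (or an
undefined correction) leaves the ratio undefined and flagged rather
than forced. Classification: > 1 positive, = 1 (tolerance 1e−9)
neutral, < 1 purifying. Codon columns containing gaps, Ns or stop
codons are skipped. Proteins are aligned with BLOSUM62 (open −10,
extend −1, same tie-breaking) and back-translated exactly onto their
source codons; internal stops translate as X for alignment purposes.
NG86 is the single estimator implemented: it is the canonical counting
method and fully specifiable; model-averaged estimators are out of
scope. Genes are paired by name using the copy-tag-0 representative.

## Phylogeny

Shared genes are protein-coding genes with copy number ≥ 1 in every
genome, sorted alphabetically. Per gene, proteins are aligned pairwise
for two taxa or by star alignment onto the first taxon for more —
insertions relative to the anchor merge per anchor position,
left-justified — which is adequate at the ≥ 99% identity of congeneric
plastomes (external alignments are accepted where that assumption
fails). Distances use pairwise deletion of gap columns; the default
model is the Poisson correction d = −ln(1 − p) (p-distance by flag), a
standard choice for protein supermatrices; a saturated pair (p = 1) is
an error. Neighbor joining follows Saitou–Nei with the Q criterion;
ties break toward the lowest taxon-index pair, negative branch lengths
clamp to zero, and the final three-taxon star is resolved exactly — NJ
is exact on additive matrices, which the test suite exploits as an
oracle. Bootstrap resamples supermatrix columns with replacement;
support is the percentage of replicates containing each internal
bipartition. All computation is unrooted; outgroup rooting is display
only.

## The synthetic-data generator

The generator emulates the statistical structure of a congeneric pear
plastome cohort; its defaults are the study conditions, not tuning
knobs.

Geometry and composition: LSC 87,962 / SSC 19,201 / IR 26,386 bp
(total 159,935), GC target 0.3659. Backgrounds are i.i.d. draws at the
target GC; protein-coding genes are ATG + sense codons + TAA with codon
weights solved by bisection so the expected codon GC equals the target
(the fixed AT-rich start/stop codons leave measured genome GC ~0.1
percentage point below target, well inside the generator's ±0.3 point
contract). A flag forces all third positions to A/T (GC3 exactly 0; the
start codon becomes ATA in that mode).

Gene complement: 118 genes — 77 protein-coding, 31 tRNA, 8 rRNA, 2
pseudogenes, with 16 genes duplicated in the IRs (32 IR-resident
features), intron-bearing genes in every region (ndhA's 1,125 bp intron
is the longest; ycf3 carries two), and three junction-spanning genes
planted with fixed extensions: rps19-like 120 bp into the repeat at
LSC/IRb, ndhF-like 12 bp at IRb/SSC, ycf1-like 1,074 bp at SSC/IRa. The
fourth junction coincides with the normalized origin, where a spanning
gene would wrap; a trnH-like gene sits just downstream instead. Because
IRa mirrors IRb, the ycf1 tail's mirror necessarily overlaps the
planted ndhF 3' end (the classic ndhF/ΨYcf1 overlap); four ycf1 codons
are pinned so the mirrored ndhF tail stays stop-free, and the generated
ndhF consequently has no terminal stop codon (it passes every screen
that matters, which reject only internal stops). Repeat-boundary bases
are adjusted so the planted IR pair cannot extend by a chance
complementary base, keeping detection exact.

Divergence: per-genotype SNPs are Bernoulli draws per base with
separate single-copy and IR rates (IR ≤ SC by default — the repeat is
more conserved); IRb edits are mirrored into IRa so repeat identity is
preserved structurally. A SNP landing in a protein-coding exon is
steered to a synonymous change with probability `syn_bias` (default
0.7) when one exists — the generator's stand-in for purifying
selection, and the reason the selection screen reports a purifying
majority. Indels are planted from a plan (region, kind, length,
context) with positions drawn from matching reference context,
non-overlapping, applied right-to-left, with left-normalized manifest
coordinates; SNPs avoid indel footprints. Genotypes can share mutation
components (a rate triple with its own seed): carriers inherit
identical edits, which plants true internal branches — without this,
independent divergence from one reference yields a star tree on which
sisterhood has no support. The default five-genotype cohort plants
((HB1, HB2), ((JBL, BET), ERC)): the close pair differs by ~20 SNPs and
15 indels (11 insertions, 4 deletions, all LSC, net +46 bp, so its
genome is 159,981 bp), the others carry 32/57/31 indel loci with one
mirrored IRb pair in the ERC-like genotype, and annotation-level gene
deletions (atpB, trnI-GAT) exercise gain–loss.

What the generator does *not* emulate: substitution-model structure
(no transition/transversion bias), rate heterogeneity along the genome,
recombination, IR expansion/contraction as a mutational event,
sequencing error or assembly artifacts. Passing tests therefore
demonstrate correctness of the analyses under clean, known divergence —
not robustness to annotation error or alignment ambiguity in real data.

## Numerical and determinism notes

All randomness flows from explicit integer seeds through NumPy
generators; derived seeds stay below 2^31. Identical configuration and
seed give byte-identical FASTA/GFF3/TSV/Newick outputs (asserted by the
test suite). Degenerate inputs are errors, not silent results: no
qualifying repeat, repeats covering > 90% of the circle, saturated
distances, empty codon overlap, translation mismatches in
back-translation. Problem sizes in the tests — full-size 159.9 kb
cohorts for the end-to-end checks, 4–17 kb cohorts for the 50-config
round-trip sweep, 100 random additive matrices of 5–12 taxa, all
2,155 low-difference sense-codon pairs — were chosen so the whole suite
exercises every contract at full fidelity while staying quick to run.
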