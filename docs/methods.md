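# Methods

This note records the models, parameter choices and numerical conventions
behind each stage, what the synthetic data does and does not emulate, and
the design decisions taken where more than one reading was defensible.

## Assembly intake and curation

Contig splitting removes every maximal run of at least `cutn` consecutive
`N`/`n` characters (default 5) and splits the entry there; shorter runs are
kept verbatim, empty fragments dropped, and contigs numbered in input order.
Only the letter N triggers splitting — other IUPAC ambiguity codes are data,
not joins. Characters outside the IUPAC nucleotide alphabet are an input
error naming the character. All coordinates in the package are 1-based
inclusive (GFF3 convention).

L90 is the smallest m such that the m largest contigs reach 90% of the
assembly length. The quality filter discards assemblies with L90 *higher
than* 100 or *more than* 999 contigs — thresholds are strict, so a genome
sitting exactly on a bound passes. Quality ordering is (L90 ascending,
contig count ascending, genome id ascending); the third key is ours, added
to make the order total and deterministic.

The greedy distance filter sweeps that ordered list once: each survivor
discards every later survivor at distance < `min_dist` (10⁻⁴; one change
per 10 kb, near draft sequencing accuracy — such genomes are redundant) or
> `max_dist` (0.06; beyond the usual ≥ 94% ANI species boundary). The
best-quality genome is therefore always kept, every discard records the
kept partner that triggered it, and re-running the filter on the kept set
is the identity. The result is order-dependent by construction: a genome is
only ever compared against earlier (better) survivors.

## MinHash sketching

A sketch is the `s` smallest distinct 64-bit hashes of a genome's canonical
k-mers (k = 21, s = 10 000 by default; canonical = lexicographic min of the
k-mer and its reverse complement; windows containing anything outside
A/C/G/T are skipped). K-mers are packed 2 bits per base, which also makes
the canonical choice a plain integer `min`. The hash is a fixed
splitmix64-style finaliser over the packed k-mer, keyed by an explicit
`hash_seed` (default 42): fully deterministic across runs and platforms, no
external hashing dependency.

Two sketches estimate Jaccard similarity with the *merged* bottom-s
estimator: among the s smallest hashes of the union, the fraction present
in both sketches. This differs from the intersection-of-sketches estimator
at small scale, which is why the choice is pinned here. The distance is
D = −(1/k)·ln(2j/(1+j)), with j = 0 capped at D = 1 to keep matrices
finite (any value above `max_dist` filters identically). For a pair
diverged by i.i.d. substitutions at rate p the estimator concentrates
around −ln(1−p) (≈ 0.0619 at p = 0.06), the usual D ≈ 1 − ANI regime.

## Annotation and nomenclature

Field widths are fixed at 4 (species code) + 4 (MMYY) + 5 (genome index) +
4 (contig), dot-separated — exactly 20 characters for the contig header;
the gene identifier appends a border flag and a 5-digit gene number for 27.
We read the stated 20-character width as applying to the contig-level
header, since these widths force the full gene identifier beyond 20. A gene
is a border gene iff it is the first or last gene called on its contig.
Genome indices follow the quality order (best genome = 00001).

The ORF caller is deliberately naive and documented as a stand-in for a
real prokaryotic gene finder: maximal complete ORFs (ATG/GTG/TTG start to
the first in-frame TAA/TAG/TGA, stop included, ≥ 90 nt) on both strands;
overlapping calls resolved by keeping the longer (ties: leftmost, then
forward strand); genes numbered 1..n in (contig, start) order. Translation
uses the bacterial code (table 11), with alternative start codons rendered
as M. External GFF3 + FASTA annotations can be loaded to bypass the caller
entirely.

## Pangenome construction

Similarity edges come from global pairwise protein alignment with BLOSUM62,
gap open −11, gap extend −1 — the standard scoring fixed once so results
are deterministic; in the regimes that matter here (≥ 95% within-family
identity vs < 50% between) the edge set is insensitive to reasonable
alternatives. Identity is identical columns over *all* alignment columns
(internal gaps included); coverage is the aligned span over each sequence's
length, and an edge requires identity ≥ 0.8 and coverage ≥ 0.8 of *both*
sequences. An exact prefilter skips pairs sharing no protein 5-mer; two
sequences of these lengths at ≥ 80% identity always share one, so the
prefilter cannot change results (and tests check that).

Families are connected components of the edge graph by default; set-cover
and greedy-incremental modes exist with documented lexicographic
tie-breaks, and both refine the connected components. Family ids are
1..F in order of each family's lexicographically smallest member, making
all three output files (membership list, presence TSV, counts TSV)
byte-deterministic.

## Persistence classification

Thresholds compare counts with ≥ against tol·G directly (no rounding), so
a family sitting exactly on the boundary is included ("at least"). Strict
mode excludes a family if *any* genome carries several copies — the reading
under which core ⊆ strict ⊆ mixed ⊆ multi holds at equal tol, which the
definitions' nesting implies; the alternative (tolerating multi-copy
genomes outside the counted fraction) would break that chain.

## Alignment and back-translation

Families are aligned at the protein level by a built-in star aligner:
centre = longest sequence (ties by id), every other sequence globally
aligned to the centre with the same BLOSUM62 scoring, pairwise gap patterns
merged under once-a-gap-always-a-gap. It is a stand-in for a progressive
aligner and can be bypassed with externally computed protein alignments per
family. Terminal stop codons are trimmed before back-translation so each
nucleotide row is exactly 3× its protein row; each residue is replaced by
its source codon and each gap by `---`, so ungapping any row reproduces the
original coding sequence exactly — the invariant the tests assert verbatim.
Genomes where a family is absent *or multi-copy* get all-gap rows (no
arbitrary copy choice); families are concatenated in ascending family id.

## Tree inference

p-distances use pairwise gap deletion — appropriate for padding-heavy
mixed-persistent concatenates, where complete deletion could erase most
columns; a pair with no comparable columns is an error naming the pair.
Neighbor joining is the standard Q-criterion algorithm with two pinned
conventions: ties broken by smallest Q then lexicographically smallest node
pair (a node's key is its smallest descendant leaf), and negative branch
lengths clamped to zero with the deficit moved to the sister branch,
preserving path lengths through the join. The output is unrooted, written
as Newick with a trifurcation at the final join. On additive matrices NJ
recovers the generating tree exactly; tests verify this against exhaustive
topology enumeration up to 6 taxa and against an independent NJ
implementation.

## Synthetic data

The generator draws everything from NumPy's PCG64 generator, explicitly
seeded; a dataset regenerated with its recorded seed is byte-identical.
Genome simulation is i.i.d. per-base with a GC dial; divergence is i.i.d.
substitution to a different base at rate p (so observed Hamming divergence
concentrates at p and expected sketch distance at −ln(1−p)); fragmentation
inserts N-runs at random cut points so contig splitting inverts it exactly.

Planted family datasets are built for unambiguous recovery: genes sit
non-overlapping on the forward strand, separated by 60 bp spacers of the
self-reverse-complementary 12-mer `TTAATTAATTAA`, which places a stop codon
in every reading frame of both strands within any 12 bp window and contains
no start codon — so no ORF can cross a spacer. Each gene is ATG + random
non-stop codons + TAA, 110–150 codons; each planted copy (ancestor or
variant) is accepted only if the ORF caller, shown the gene between two
spacers, reports it as the unique ORF at exact coordinates, and is redrawn
otherwise. Family variants diverge from their ancestor at 1% per site
(pairwise ~2%, keeping within-family identity ≥ 95%, comfortably above the
80% edge threshold) with starts/stops preserved and no in-frame stops;
unrelated families are independent draws (< 50% identity, far below it).
No indels, recombination, rearrangement or gene-tree discordance are
simulated — truth identities stay computable in closed form. Passing the
recovery tests therefore shows the machinery is correct on cleanly
separated families, not that the thresholds are well-chosen for real data,
where identity distributions are continuous and fragmented genes blur
coverage.

## Problem sizes

The reference recovery scenario is 10 genomes × (50 core + 20 accessory +
5 multi-copy) families; sketch calibration uses 1-Mb genome pairs (10
replicates at p = 0.06, 25 at p = 10⁻⁴) and parameter-recovery checks use
100–200 kb genomes with sketch size 5000; the oracle suites use 1000 random
contig lists, 200-node random graphs, random 15×8 count matrices, and all
105 six-taxon topologies. These sizes were chosen so the whole suite
exercises every contract while staying a desk-scale package; the all-vs-all
pangenome stage is O(n²) in gene count by design and is meant for tens of
genomes, not thousands.

## Known limitations

The ORF caller has no ribosome-binding or coding-potential model and will
mispredict on real genomes; the star aligner is weaker than progressive
aligners on divergent families (both are bypassable with external inputs).
Sketch distances saturate for very distant genomes (D capped at 1).
Clustering ignores synteny. NJ is provided as the only tree method;
likelihood-based inference is out of scope.
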