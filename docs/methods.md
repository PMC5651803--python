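# Methods

## Scope and data model

`mitocomp` analyses annotated mitochondrial genomes that need not be a
single closed circle: a `MitoGenome` is a list of contigs (each with a
circularity flag) plus strand-aware gene features (CDS / rRNA / tRNA).
Coordinates are 0-based half-open internally and 1-based inclusive in GFF3
on disk. GFF3 has no native representation for a feature crossing the
origin of a circular contig, so the package uses a documented dialect:
`start > end` together with a `circular_wrap=true` attribute; such a
feature is the contig tail followed by its head. Gene sequences are always
reported in sense (transcribed) orientation; minus-strand features are
reverse complemented on extraction.

Translation uses NCBI genetic codes via Biopython's tables, defaulting to
table 5 (invertebrate mitochondrial: AGA/AGG = Ser, TGA = Trp). A terminal
stop codon is excluded from the chain and trailing 1–2 nt are ignored; an
internal stop raises an error naming the codon index, or — with
`internal_stop="mask"` — is emitted as `?` so that downstream complete
deletion removes the column (useful for simulated diverged CDS, where
random substitutions create in-frame stops).

## Composition and strand asymmetry

AT skew = (A−T)/(A+T) and GC skew = (G−C)/(G+C), counting only the
respective bases; when the denominator is zero the skew is *undefined*
and encoded as NaN, never 0 (0 is a meaningful skew). N bases are excluded
from every compositional count. Sliding windows (default 300 bp wide)
start at position 0 and advance by `step`; on circular contigs they cross
the origin, giving ⌈L/step⌉ windows, on linear contigs
⌊(L−width)/step⌋+1. Window centers are reported. The anchoring phase is a
convention (documented, configurable); computing the statistic with
width = L reproduces the whole-sequence summary.

"Heavy" strand is defined operationally as the strand with the greater
G+T content (ties resolve to the forward/record strand). The strand
molecular-weight difference is |W₁−W₂|/mean(W₁,W₂)×100 with per-residue
average masses dAMP 313.21, dCMP 289.18, dGMP 329.21, dTMP 304.20 g/mol —
the constants are fixed in code and configurable, since average vs
monoisotopic conventions differ between tools.

## Codon accounting

Stop-codon completeness is judged from the sequence: length ≡ 0 (mod 3)
ending TAA/TAG → complete; ≡ 2 ending TA → partial_TA; ≡ 1 ending T →
partial_T; otherwise the reportable status `no_stop`. Incomplete stops are
the classical polyadenylation-completed terminators of animal mtDNA.
Chain lengths follow: complete → bp/3 − 1, partial → ⌊bp/3⌋. When an
annotation and the sequence disagree, the sequence wins and the conflict
is logged (`W002`).

Four-fold degeneracy is a property of the codon family alone: a third
position is neutral iff the four completions of its first two bases
encode one amino acid with no stop among them. The families are derived
programmatically from the genetic code (for table 5: TCN, CTN, CCN, CGN,
ACN, GTN, GCN, GGN and AGN — AGN qualifies only because AGA/AGG = Ser).
The neutral-site GC skew of a gene is the GC skew over those third-position
bases *on the sense strand*, so its sign reflects the gene's orientation
relative to the mutational pressure gradient. The exact strand property
(tested) is: for a minus-strand gene the sense-strand skew equals minus
the skew of the same physical sites read on the forward strand. Strict
antisymmetry under re-annotating a CDS on the opposite strand does not
hold in general (the reverse reading frame has different codon families),
which is why the invariant is stated on physical sites.

RSD (relative standard deviation) of ortholog lengths uses the sample
(n−1) standard deviation over the mean, ×100, rounded half-up to two
decimals. The sample convention is the one consistent with the published
per-gene values this package reproduces (population SD would give 0.35
instead of 0.41 for the atp6 row).

## Distances

p-distance = mismatches / kept sites on a gap-free block; complete
deletion first removes every column containing `-` or `?` in any row
(missing data and gaps are treated identically). Standard errors come
from a site bootstrap: columns resampled with replacement, 1000
replicates by default, SE = sample SD of replicate p values,
deterministic given the seed (replicates are generated in fixed chunk
order). The included pairwise aligner is plumbing: optimal
Needleman–Wunsch under a linear gap score via Biopython's
PairwiseAligner, first (deterministic) traceback; affine gaps are out of
scope. Sliding-window distances report window coordinates in alignment
space; windows with zero kept sites are NaN. Gene concatenation is
column-wise in the caller-given (documented) order; p and the bootstrap
distribution are invariant to that order.

## Gene order

A gene order is a signed circular permutation, normalized by rotating —
and, if the anchor is on the minus strand, flipping the whole circle —
so that *cox1* (the most conserved marker, and therefore the least
arbitrary origin) comes first with positive sign. Two annotations that
differ only by rotation or by which strand was sequenced normalize
identically; normalization is idempotent.

Breakpoint distance counts signed circular adjacencies of A absent from B,
where (x, y) matches (x, y) or the reading-direction mirror (−y, −x).
Event inference searches over the three classical event classes
(block transposition, block reversal, reverse transposition). Blocks
exclude the anchor position — on a circle this loses no generality, since
an operation on a block containing the anchor equals one on its
complement. Each event changes at most three adjacencies, so
⌈breakpoints/3⌉ lower-bounds the event count; this bound prunes an
iterative-deepening DFS with lexicographic tie-breaking. Every returned
solution is replay-checked (hard postcondition). `bfs_min_events` is an
exact bidirectional BFS oracle, guarded to ≤ 10 genes and cap ≤ 4 (the
event graph has hundreds of neighbors per state); the test suite certifies
the heuristic against it on hundreds of planted instances. The four-taxon
parsimony scenario grows event-balls around each cherry's leaves from
radius 0 up to k (default 2), intersects them to obtain candidate internal
orders, and minimizes the five-edge total with breakpoint-bound pruning;
candidate pairs are capped, so the result is a certified upper bound
rather than a proof of global optimality. This is deliberately simpler
than full common-interval machinery; where the exact oracle applies, the
two agree.

Multi-contig genomes are concatenated in declared contig order with
fragmentation marker tokens; comparisons go through `restrict_to_shared`,
which drops markers and private genes and reports what was dropped.

## Repeats

Tandem arrays: for each unit length u ≤ 6, maximal runs of
seq[i] == seq[i+u] (a run of r matches spans r+u bases, i.e. (r+u)/u
copies). Units are reported in canonical (lexicographically smallest)
rotation, and non-primitive units are skipped, so each locus is reported
once; a trailing partial copy counts when ≥ half a unit. Every report
passes a literal re-scan of its slice (tested invariant).

Terminal palindromes: within each terminal window (default 500 bp), exact
seed matches of length ≥ min_len between the window and its reverse
complement are extended maximally (inward extension preserves arm
disjointness), with an optional bounded mismatch tolerance during
extension (default 0 = exact).

Dotplot: exact word matches (default word 11) in forward and
reverse-complement orientation, merged into maximal diagonals; coordinates
are 0-based in each input, and the output is transpose-symmetric.

## Read-level profiling

K-mer counting is canonical (min of k-mer and reverse complement; k odd so
no k-mer is self-complementary), exact and in-memory — adequate for the
desk-scale read sets the generator produces; disk-backed counting is out
of scope. Genome size: the histogram is smoothed with a 3-bin moving
average (raw histograms are noisy at desk scale), candidate peaks are
interior local maxima at multiplicity ≥ 4 (excluding the low-copy slope);
if none exists the status is `no_nontrivial_maximum` — the expected
outcome for genomes too large or repeat-rich for the available coverage —
otherwise size = total k-mers / peak multiplicity. The pg→bp constant is
0.978 × 10⁹ bp/pg.

## Synthetic data generator

The generator emulates the features this toolkit targets: a circular
~20 kb molecule with 13 CDS (published *C. glacialis* lengths; cytb/nd1/nd5
carry incomplete stops by default), 2 rRNAs (1125/656 bp), 22 tRNAs
(66 bp), long internal NCRs (defaults 800/1500/2500 bp) that are *not*
AT-rich, each holding a TATA tandem array ("TATA"×8 by default) flanked by
G/C guard bases so planted coordinates are exactly recoverable, and
300 bp terminal NCRs holding planted inverted repeats (15 bp arms). The
ancestral gene order is the pancrustacean-like ground pattern anchored on
cox1; planted events rearrange it, and the truth object records the event
list such that replaying it reproduces the emitted order exactly. Overall
AT content is controlled at 58.3% by default (the non-AT-rich regime of
the target genomes; realized within 2 points at ≥ 20 kb — CDS stop-codon
rejection and the slightly AT-enriched rRNAs shift it marginally).

Divergence is Jukes–Cantor-like: each site independently substituted with
probability p, uniform over the three alternatives — sufficient because
p-distances are model-free. Reads are error-free, uniform over the
(circularized) sequence, half reverse-complemented, at an expected depth
equal to the requested coverage.

What the generator does *not* emulate: indels, sequencing errors,
heterozygosity, selection/codon-usage bias, transposable-element families,
and real NCR sequence structure beyond the planted repeats. Passing tests
therefore demonstrate correctness of the accounting, statistics and search
machinery on known ground truth — not robustness to alignment ambiguity or
assembly artifacts in real data.

## Problem sizes and determinism

Test and acceptance runs use desk-scale sizes chosen to keep the suite
fast while leaving the estimators in their asymptotic regime: 8–10 gene
orders for oracle-certified search (500 planted instances), 2 kb sequence
pairs × 100 seeded runs × 1000 bootstrap replicates for parameter
recovery, and 50× error-free 150 bp reads from the ~20 kb default genome
for k-mer size estimation (expected peak ≈ 50·(150−21+1)/150 ≈ 43).
Every stochastic step takes an explicit seed; a single NumPy generator is
seeded once per call and consumed in a fixed, documented order, so reruns
are byte-identical (tested).

## CLI

Subcommands `simulate`, `report`, `compare`, `kmer-hist`, `genome-size`,
`gene-order`, `skew-profile`; all parameters are explicit options with the
seeds surfaced in outputs (no hidden config state). Warnings are
machine-parsable (`Wxxx` prefixes) on stderr. Exit codes: 0 success, 2
input error, 3 bounded search exhausted.
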