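# Methods

## Scope and model

The package reconstructs chromatin contacts from tiled Micro-Capture-C
libraries. The physical model of a library molecule is: two MNase
fragments (mono-nucleosome scale) joined by proximity ligation in a random
relative orientation, sheared to a ~200 bp sonication fragment, and
sequenced 2×150 bp, so most molecules are read end-to-end and the ligation
junction lies inside the sequenced sequence. The unit of evidence is the
**ligation junction**: the oriented base-pair boundary between the two
fragments, together with the sonication (outer) ends of the molecule,
which fingerprint PCR duplicates.

All internal coordinates are 0-based half-open; BED files pass through
unchanged and the pairs-style junction TSV is converted to 1-based at the
I/O boundary only.

## Capture panel design

Target regions are tiled with fixed-length oligos (default 70 nt) stepped
`oligo_len − overlap` apart (default overlap 35 nt, i.e. 2× coverage of
every interior base). If the final regular tile does not reach the region
end, one extra tile is right-anchored at the end so no tail is uncovered.
Repeat annotation comes from FASTA soft-masking; an oligo is rejected if
its lowercase fraction exceeds `repeat_threshold` (default 0.3), if it
contains any N, or if it carries a homopolymer run longer than 10. These
thresholds are standard panel-design heuristics, exposed in the API and
CLI; no genome-wide uniqueness screen is performed (it would require a
whole-genome index, out of scope for a desk-scale tool).

## Synthetic library

The simulator is the package's source of ground truth and encodes the
study conditions as its defaults: a 50 kb random genome (5% soft-masked in
200–800 bp stretches) with two capture regions at [0.1 L, 0.4 L) and
[0.6 L, 0.9 L); 20,000 ligation events; fragment lengths ~Normal(180, 25)
truncated to [50, 400] bp; sonication windows ~Normal(200, 30) placed
uniformly on the molecule (so the junction is retained with probability
proportional to overlap); 150 bp paired-end reads with adapter
read-through when the insert is shorter than the read; a contact-distance
law P(d) ∝ d^−1 on [30 bp, L/2]; 20% of events seeded outside the capture
regions (chosen so that the on-target read fraction lands near the ~80%
a well-designed tiled panel achieves); 10% PCR duplication; and one
loop-like anchor pair at (8250, 16250) with 50× enrichment over the
same-distance background (computed from the decay law in a 200 bp window;
anchor coordinates sit at 500 bp bin centres so the designed signal is not
split across bin pairs at the evaluation resolution). Sequencing errors
are i.i.d. substitutions (default 10⁻³; evaluations of exact-coordinate
recovery use 0). PCR duplicates re-sequence the same sonicated window with
a ±2 bp jitter on the window ends, which is precisely the noise the
wobble deduplication exists to absorb.

Each sequenced molecule yields a truth record with both junction
coordinates and orientations, the sonication ends, a duplicate flag and,
for duplicates, the template read. The truth table, FASTQ, FASTA and BED
are all deterministic functions of the seed.

**Canonical junction coordinates.** When the two fragments' flanking
sequences agree for a few bases around the splice (chance micro-homology,
~1/4 per base and side), every split point inside the agreement run yields
the identical read, so the junction position is not identifiable beyond
that run. Both the simulator truth and the junction caller therefore
report junctions at the *read-leftmost* edge of the micro-homology zone —
the analogue of left-aligning an indel. Without this convention,
exact-coordinate agreement between truth and calls would be capped near
~56% for fundamental reasons rather than algorithmic ones.

What the simulator does **not** model: multi-fragment concatemers (the
junction reconstruction is pairwise, which motivates a two-fragment
default), indels, optical duplicates, capture-hybridization
thermodynamics, chromatin-driven fragment placement (fragments are
uniform), or genuine repeat families (soft-masked stretches are still
random sequence). Passing tests therefore demonstrate correctness of the
reconstruction machinery, not robustness to repeat-rich real genomes.

## Read processing

*Trimming*: 3′ adapter read-through is removed by an exact search for the
adapter's first 12 bases plus a mismatch-tolerant scan (10% mismatches,
minimum 3 bp) for shorter terminal prefixes; pairs trimmed below 20 bp are
dropped.

*Merging*: the 3′ end of R1 is compared with the reverse complement of R2
over candidate overlaps (exhaustive up to 30 bp, probe-located beyond);
the overlap with the lowest mismatch density ≤ 0.25 (ties to longer) is
merged, higher-quality base winning at mismatches. Non-overlapping mates
are processed as two independent reads; junctions are never called across
mates.

*Chimeric splitting*: a k-mer index (k = 15) over both strands of every
region sequence proposes candidate windows; each window is scored with
Smith–Waterman local alignment (match +1, mismatch −1). Gap penalties are
deliberately stiff (open −5, extend −3): with the conventional cheap gaps
an alignment can bridge a 30 bp genomic jump for a cost of ~32, absorbing
exactly the short-range junctions the method exists to resolve, and can
over-extend past a junction through locally similar sequence. Stiff gaps
still admit 1–2 bp indels inside long segments. Alignments containing an
internal target- or query-side gap ≥ 5 bp are split at the gap — a ≥5 bp
genomic jump the read does not carry *is* a junction candidate, and a
≥5 bp query gap breaks the read-adjacency rule regardless. Accepted
segments require length ≥ 20 bp, score ≥ 20 and identity ≥ 0.9 (all
configurable); selection is greedy by score, requiring each segment to
contribute ≥ 10 bp of read not claimed by a better one and capping query
overlaps at 35 bp; uncovered read flanks are re-aligned recursively.

*Second pass*: each segment's read substring is aligned end-to-end
(infix) against the full reference with edlib on both strands. Segments
whose best placement is > 1 kb from the first-pass locus, or which have
equally good placements elsewhere, are flagged ambiguous and excluded.
The edit-distance budget is permissive (25%) because a segment may carry a
short over-extension past its true ligation point; over-extension inflates
edit distance without moving the *outer* alignment ends, which are the
coordinates junction calling relies on.

## Junction calling and deduplication

Within a read, consecutive segments whose read-space ends are less than
5 bp apart evidence one junction (three segments yield two junctions,
single segments none). Coordinates are anchored on each segment's stable
end — the first fragment from its read-left end, the second from its
read-right end — so over-extension of either alignment cannot shift them.
When genome and read sequences are available the splice point is refined:
starting from the first segment's read end (guaranteed to lie in the
second fragment's territory) the caller walks left while the read matches
the second fragment's reference, skipping a mismatch only when the next
8 bases keep matching (an isolated sequencing error, essentially never a
junction edge), and places the junction at the stop — the canonical
left edge of the micro-homology zone defined above. A short verification
of the read against the first fragment's reference guards against
spurious splits; query overlaps > 35 bp yield no junction.

Sonication ends are the outer genomic ends of the read's first and last
segments. Junction partners are stored in canonical (chrom, pos) order,
swapping sonication ends alongside.

Two junctions are PCR duplicates iff they share both chromosomes and all
four coordinates (two junction positions, two sonication ends) agree
within ±2 bp, applied per coordinate. Duplicates are clustered by single
linkage — the most permissive reading of a ±2 bp wobble — implemented as a
sorted sweep over (chrom1, pos1) with union–find; a brute-force O(n²)
oracle backs the implementation in the test suite. The representative
with the lexicographically smallest read id is kept, making the output
independent of input order.

Distance filters are applied separately per consumer: density-plot export
removes intra-chromosomal junctions closer than 10 bp (self-ligation
artefacts crowd the diagonal); matrices use an independent threshold,
default 0.

## Matrices

Each junction increments counts[b1, b2] and counts[b2, b1] (the diagonal
once), so total matrix mass equals 2×(off-diagonal junctions) +
(diagonal junctions). ICE masks zero-marginal bins, then iteratively
divides by the outer product of mean-normalized row sums until the
largest deviation from 1 is below 10⁻⁵ (≤ 200 iterations), accumulating
the per-bin bias; the balanced matrix is rescaled to the raw unmasked
mass. Re-balancing a balanced matrix is a no-op to within tolerance. Only
zero-marginal masking is applied by default; no percentile coverage
filter is used.

Display convention: linear colour scale at 500 bp, log10(x + pseudocount)
at 20–50 bp with the pseudocount equal to the smallest positive entry,
which keeps zeros at the bottom of the colour range without producing −∞.

Condition comparisons downsample every junction table uniformly without
replacement to the smallest table (seeded, deterministic), build and
balance matrices per condition, and subtract balanced values; bins masked
in either input are masked in the output. Subtracting *balanced* rather
than raw matrices is a design choice (the alternative is not excluded by
the data model) and no smoothing is applied. Replicates are pooled at the
junction level before matrix construction, which keeps the downsampling
unit (junctions per condition or replicate) well defined.

Density plots report each junction's exact (pos1, pos2) with a local
density from a 20 bp 2-D histogram smoothed by a Gaussian kernel
(σ = 3 cells), sorted ascending so dense points draw last.

## Evaluation semantics

Recovery is measured over the junctions the design can in principle see:
non-duplicate truth records whose junction point lies within a sequenced
read with ≥ 20 bp of flank on both sides (the minimum alignable segment)
and whose junction-proximal fragment ends both fall inside capture
regions — the chimeric splitter, like the hybridization panel it models,
only recognizes capture-region sequence. On the default error-free
conditions ~99% of such junctions are recovered with both coordinates
exactly equal to the canonical truth, and the 50× anchor is the largest
off-diagonal entry of its distance band in the balanced 500 bp matrix.

## Problem sizes and numerics

The shipped study conditions (50 kb genome, 20,000 events) process in
about a minute on one CPU; unit fixtures use a 12 kb genome with a few
hundred events. ICE tolerance 10⁻⁵, alignment thresholds as above, ±2 bp
wobble, and the 5 bp/10 bp distance rules are all module parameters with
the defaults stated here. Degenerate inputs raise: empty region sets,
all-masked matrices, inverted intervals, unknown chromosomes, negative
distance thresholds, malformed FASTQ records (with the record number).

## Known limitations

Multi-way concatemers are not simulated and only pairwise consecutive
junctions are called; repeat families and copy-number structure are not
modelled, so ambiguity handling is exercised only by a synthetic
duplicated-locus fixture; micro-homology canonicalization means reported
junction coordinates can differ by a few bases from the physical ligation
point whenever flanking sequences coincide; and the CLI operates on one
sample at a time (replicate pooling is a library-level operation).
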