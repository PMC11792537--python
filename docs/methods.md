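# Methods

This note documents the models and procedures implemented in `dgrscan`,
the defaults and why they were chosen, the numerical conventions, what the
synthetic-data generators do and do not emulate, and the known
limitations.

## Coordinates and windowing

All public coordinates are 1-based inclusive; BED output (0-based
half-open) is converted in one place (`dgrscan.io.interval_to_bed`).
Sliding windows follow the convention (window W, step S, terminal
extension E): windows start at 1, 1+S, 1+2S, … while they fit entirely,
and the last fitting window is extended to the sequence end when the
uncovered 3′ tail is at most E. The bacterial convention is
(3001, 500, 1500) and the phage convention (101, 20, 50); for both, the
tail is always shorter than the step, so the windows tile the sequence
exactly. Sequences shorter than W yield a single full-length window.

## Prophage evidence and region calling

Per-window signals: the four nucleotide fractions among non-N bases
(all-N windows are missing); median ORF length, median intergenic gap and
strand-switch count over ORFs whose midpoint falls in the window (missing
with fewer than two member ORFs) plus coding density; mean read depth and
breadth (breadth = fraction of positions with depth strictly above zero).
A virome sample is discarded as potentially host-contaminated when its
reads cover strictly more than 25% of the strain's cumulative contig
length.

The region caller converts each signal to a robust z-score
(median-centred, scaled by 1.4826·MAD) and sums *signed, orientation-
adjusted* scores: depth, breadth and coding density count positively, ORF
length, intergenic gap and strand switches negatively (prophages depress
them), and GC content contributes its absolute z because the direction of
the compositional shift is genome-dependent. Summing oriented scores
rather than magnitudes keeps the null distribution centred at zero, which
is what makes the caller quiet on shuffled tracks. Two numerical guards
matter for discrete or saturated signals: when the MAD is zero the scale
falls back to the mean absolute deviation (a constant signal scores
zero), and z-scores are clipped at ±20 so no single signal can dominate
or produce infinities. Windows with summed score above 3.0 are merged
across gaps of at most one window; merged regions shorter than 15 kb are
dropped (documented prophages in this setting are ~32–60 kb, so 15 kb is
conservative). External predictor intervals, when supplied, add a fixed
bonus (default 2.0) to the windows they cover. These caller constants are
package choices; the underlying study combined the evidence tracks
visually, so the caller is an explicit automated stand-in, not a
reconstruction.

The induction coverage ratio divides the mean depth inside the prophage
interval by the mean depth over the remainder of the contig; a zero
denominator is reported as an infinite ratio with a flag rather than an
error. Transposable-phage termini are the two split-read junction
positions with the highest support (exact-position aggregation; ties
break toward the smaller coordinate; a single observed position yields
one terminus and a missing second).

## DGR detection

The genome is compared to itself and to its reverse complement. Exact
12-nt seed words (words occurring more than 50 times are treated as
low-complexity and skipped) are clustered along diagonals (band ±20 nt,
join distance 200 nt) and each cluster is extended by gapped local
alignment (Biopython `PairwiseAligner`, local mode) with match +2,
mismatch −3, gap open −5 and gap extend −2, where a gap of length L costs
5 + 2(L−1). For same-orientation candidates the two extraction windows
are kept disjoint so the extension cannot collapse onto the trivial
self-identity. The identity alignment and mirror duplicates are removed,
alignments shorter than 90 columns or under 50% identity are discarded,
and overlapping alignments are reduced to the highest-scoring
representative per locus pair (ties break toward the leftmost). An
E-value gate is not used: the explicit length/identity/mismatch criteria
dominate, and the in-repo aligner keeps the stage deterministic and
testable. Precomputed 12-column self-hit tables are accepted instead; the
segments they name are re-aligned under the same scoring to recover the
per-column detail the tabular format lacks.

A repeat pair is accepted as a DGR TR/VR pair when the alignment is ≥90
columns with ≥50% identity (computed over alignment columns), has ≥5
mismatch columns (gap columns are neither mismatches nor part of any
denominator), and at least 75% (inclusive) of mismatch columns carry the
template adenine on one side. Because a self-comparison reads each repeat
on an arbitrary strand, the bias is evaluated in both readings of both
sides — adenine as aligned, or thymine when the cassette lies on the
complementary strand — which makes detection invariant under
reverse-complementing the genome; the reported `tr_strand` records the
cassette strand. Ties in the bias fraction deterministically assign the
template to side 1 in the forward reading.

Domain-table post-processing merges overlapping or adjacent envelope
intervals per (protein, profile) pair; a profile is assignable only with
≥100 covered residues, the maximal-coverage profile wins, ties break by
smaller e-value then lexicographic profile id, and the RVT_1 profile
flags RT genes. Locus assembly groups pairs whose TRs reciprocally
overlap by ≥50% (a template serving several VRs produces near-identical
TR intervals), attaches the nearest RT ORF with its distance (circular
distance on request; no cutoff is imposed, but distances over 10 kb set a
review flag), and maps each VR onto the protein coordinates of the ORF it
overlaps most (codons overlapped, strand-aware; VRs crossing an ORF
boundary are flagged partial, VRs outside all ORFs intergenic).

## DGR activity

MSA column statistics are indexed by the positions of a designated
ungapped reference; columns where the reference holds a gap are dropped.
Gap symbols of non-reference rows count as a fifth symbol in the column
tallies ("symbols", not just nucleotides); characters outside {A,C,G,T,−}
count toward the column size but can never be the consensus. Variation is
1 − (most frequent symbol count)/n; ties for the most frequent symbol
break in the fixed order A < C < G < T < gap (the tie-break cannot affect
variation). A column is conserved when the top symbol reaches 90%
(inclusive), conserved-A when that symbol is adenine. The windowed tracks
are the arithmetic mean of per-position variation and
100·(conserved-A)/(conserved) per window (missing when a window has no
conserved column — the ratio is undefined, not 0 or 100).

Pileup variation is 1 − max(A,C,G,T)/depth per position (missing at zero
depth; insertions and deletions are not counted). A sample enters the
analysis only when depth ≥10 holds over ≥95% of the genome, both
boundaries inclusive. The activity call compares the mean windowed
variation of windows intersecting a VR against the genome: active when it
exceeds the median by more than k·MAD (k = 5, raw MAD), with
(mean − median)/MAD reported as the effect size. The k·MAD rule is a
package choice — the underlying observation is a visually obvious spike —
and k = 5 keeps the false-positive rate of the call at the per-mille
level on flat backgrounds while the planted 30% minor-allele signal
exceeds the threshold by orders of magnitude.

Inclusive fraction boundaries computed from integer counts (e.g. 9/10 ≥
0.9) are compared with a 1e-9 slack so binary rounding cannot flip a
printed-precision boundary.

## Host linking and clustering

Merged-hit coverage is the union of query intervals divided by the query
length. Detection thresholds are inclusive: 0.75 (read breadth in a
metagenome), 0.95 (hit coverage on an isolate contig, computed per
subject contig), 0.30 (database-genome match over a prophage region),
0.95 (cognate-genome identification). Spacer matching is an exhaustive
gap-free Hamming scan of both strands allowing floor(0.05·L) mismatches —
at typical spacer lengths (25–45 nt) the 95%-identity budget is ≤2
mismatches, so the scan is both faithful to the criterion and complete,
with no heuristic seeding. Species-level clustering is greedy: genomes
sorted by length descending (ties by id) join the first representative
they match at ANI ≥95 and coverage of the shorter genome ≥85, else found
a new cluster; ANI/coverage values come from a table and are symmetrized
by the maximum.

## Synthetic data

The generators reproduce the statistical contrasts each stage consumes,
with complete ground truth and byte-identical output for identical seeds.

* **Host + prophage** — i.i.d. nucleotides at two GC levels (defaults
  0.56 host / 0.48 prophage, a moderate compositional contrast); ORFs
  drawn from two regimes: gene length ~ Normal(900, 300) truncated at 150
  nt with Exp(120) intergenic gaps and strand-switch probability 0.35 in
  the host, versus Normal(450, 150), Exp(40) and 0.08 in the prophage.
  Defaults: 120-kb contig, 40-kb prophage.
* **Planted DGR** — a 120-nt genome segment becomes the TR; each VR site
  receives a copy substituted only at TR adenine positions (to C/G/T
  uniformly), with a placeholder RT ORF near the TR. Three guarantees
  make the planted truth exactly recoverable by construction rather than
  with high probability: substitutions are interior (≥3 nt from the
  repeat ends) and *anchored* (every alignment prefix and suffix scores
  strictly positive under the +2/−3 scoring, so no optimal local aligner
  can trim or shift the extent); the VR flanks are written as 8-nt
  homopolymer barriers distinct from the TR flank barriers, which
  mismatch under every gap phasing; and at least one unmutated run of
  seed length (12 nt) is preserved so a word-seeded self-comparison can
  discover the pair at any substitution count.
* **Cognate genomes** — n substitution-only copies (default 30) with
  i.i.d. background substitutions (default 2×10⁻³) plus independent
  substitution at VR adenine targets (default rate 0.3). Because the
  cognates are substitution-only, the identity alignment is the true MSA
  and no aligner enters the tests.
* **Depth / pileup** — Poisson depth (base 5) elevated ratio-fold over
  the prophage; pileups place the reference base at each position with a
  0.2% per-base error spread over the other three bases and one fixed
  alternative base at the minor fraction at VR targets.
* **Spacers / junctions** — spacers excised at recorded positions and
  strands with exactly the requested mismatches; junction positions drawn
  at the two prophage borders with probability 1 − noise (default 10%
  noise, uniform).

What the generators do **not** emulate: real genomes are not i.i.d.
(repeat families, skews, mobile elements), real ORF callers make errors,
read depth is not independent Poisson (GC bias, mappability), cognate
genomes recombine and carry indels, and pileup errors are not uniform.
Passing tests therefore demonstrate correctness of the implemented
criteria and recoverability under the stated statistical structure — not
performance on real assemblies, where the thresholds (not the code paths)
carry the uncertainty.

## Verification

Windowed statistics are checked exactly (tolerance 1e-9) against
brute-force recomputation over literal window positions on 100 random
instances up to 20 kb. The repeat detector is checked against an
exhaustive affine-gap Smith–Waterman oracle (full genome-vs-genome
matrix, self-identity diagonal forbidden, identical scoring) on 50 random
genomes of 1.5–2.5 kb, half with planted repeats at 0–12 substitutions.
Threshold boundaries are asserted on both sides. Stochastic recovery uses
100 seeded runs (detection, cognate variation, pileup activity), 20 runs
per planted ratio, and 50 runs for termini and prophage regions — sizes
chosen so the full suite completes in well under a minute per criterion
on one CPU. `scripts/acceptance.py` re-runs all of these from a single
seed and writes the measured quantities as JSON.

## Known limitations

* The candidate-region caller is a calibrated stand-in for a visual
  overlay; its cutoffs (score 3.0, 15 kb, one-window gap merge) are not
  fitted to data.
* Same-orientation tandem repeats closer than ~150 nt can collapse onto
  the self-identity during extension and be missed; DGR TR/VR pairs are
  typically far apart.
* The exhaustive oracle (and hence the equivalence guarantee) reports the
  single best off-diagonal alignment per orientation; multi-repeat
  equivalence is exercised through planted multi-VR cases instead.
* Whether breadth in the coverage tracks should use a minimum-depth
  cutoff above zero is an open convention; depth > 0 is used.
* The pileup variation counts substitutions only; a peak shifted 3′ of a
  VR (as reverse-transcription intermediates can produce) is not
  modelled, and the activity call only tests VR-overlapping windows.
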