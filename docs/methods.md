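# Methods notes

This note records the conventions, defaults and design choices behind each
stage, in the spirit of a methods appendix. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Coordinates and formats

Internally every interval is 0-based half-open; minus-strand matches are
carried in an explicit strand field, never as swapped coordinates or
reverse-complemented stored sequences. On disk each dialect keeps its
native convention: the 12-column alignment table and ACE layouts are
1-based inclusive, with `sstart > send` encoding minus strand in the
table. FASTQ qualities are fixed at Phred+33 with no offset
auto-detection — an ambiguous offset is an error, not a guess. The minimal
ACE reader parses only CO and AF records (orientation U→`+`, C→`-`,
offsets shifted to 0-based); BQ/QA/DS fidelity is out of scope.

## Read cleaning

Cleaning mirrors seqclean-style category semantics: per read, (1) trim
terminal homopolymer runs ≥ 10 nt and flanking Ns (a read that is one
homopolymer end to end is left untrimmed so the low-complexity test can
classify it as contamination rather than as an empty trim); (2) reject
*short* if the trimmed length is under 70 nt; (3) reject *dust* if the
low-complexity score reaches the threshold; (4) reject *low quality* if
mean Phred < 20 (skipped for FASTA input without qualities). Each read
lands in exactly one category, so the counts always partition the input.

The dust score is the classical windowed triplet statistic: per 64-nt
window, `100 · Σ_t c_t(c_t−1)/2 / ((w−2)(w−3)/2)` over triplet counts
`c_t`, maximized over windows stepped by half a window; sequences under
5 nt score 0. A uniform-random sequence scores ≈ 1.6, a pure homopolymer
or dimer repeat scores ≈ 100, and the default threshold of 7 separates
them by a wide margin. The threshold, window, minimum length and quality
cutoff are all configurable; only the 70-nt length limit is treated as the
canonical default, the others are declared approximations of common EST
practice.

## The aligner

Seed-and-extend with exact k-mer seeds (k = 11) on both strands. Seed
diagonals are clustered (gap ≤ 32) and each cluster is resolved by a
banded affine-gap Smith–Waterman (band = cluster span + 16 per side) with
full traceback, so the reported score is the exact local optimum within
the band — on planted-homology pairs whose optimal alignment stays near
the seed diagonal this equals the unrestricted Smith–Waterman score, which
is what the oracle-equivalence test asserts. One best HSP is reported per
diagonal cluster; distinct clusters yield the multiple HSPs per pair that
the consistency indices expect.

Scoring is megablast-like: match +1, mismatch −2, gap open −5 (covering
the first gap base), gap extend −2. E-values use Karlin–Altschul
statistics with λ solved numerically from `Σ p_i p_j e^{λ s_ij} = 1` under
uniform base frequencies (λ ≈ 1.333 for +1/−2) and K fixed at 0.35. These
e-values are ranking and thresholding devices, not calibrated p-values;
the two canonical cutoffs are 1e-05 for database-style screens and 1e-10
for strict cross-dataset matching. Per-k-mer subject positions are capped
at 64 to bound seeding cost on simple repeats; the banded DP still covers
the merged diagonal range, so repeat-to-repeat alignments survive. The
inner DP loop is numba-compiled.

External alignment tables are accepted everywhere an internal alignment
would be computed, so any search tool emitting the 12-column dialect can
stand in bit-for-bit. Translated (BLASTX-style) search is not implemented;
protein-level annotation consumes precomputed tables or nucleotide
proxies.

## Consistency indices

The ICI/ECI summation is normalized by the query length and clamped to
[0, 100]: the two anchors (a full-length perfect read mapping and a
perfect self-alignment both score exactly 100) force that normalization.
Because overlapping HSPs would double-count query bases and break the
≤ 100 anchor, HSPs are first reduced to a pairwise-disjoint set on the
query axis, greedily by descending score (ascending start as tie-break) —
greedy rather than optimal weighted interval scheduling, for transparency;
the asserted property is disjointness, not optimality. The clamp can still
trigger when gap columns inflate an alignment length beyond the query
span; each clamping is logged.

ECI is directional — ECI(a,b) and ECI(b,a) are separate scores — and the
reported average is over directed pairs with at least one HSP (pairs that
never align are excluded from the average, a declared choice since either
averaging set is defensible; the flagging step is unaffected). Flagged
pairs (ECI > 75 by default) are deduplicated to unordered pairs carrying
the larger directional score. Assembled reads with no HSP to their own
contig contribute ICI 0 to the average and are listed separately, since
they count against assembly quality.

## Antisense detection

Strand calls come from the assembly layout only; no re-alignment. Ties
(equal plus and minus counts) are excluded from both the antisense read
total and the "contigs with ≥ 1 antisense read" count but tracked in
their own counter; the percentage denominator is all contigs, ties
included. The rule is orientation-free: relabeling every strand leaves
all counts unchanged. The `min(n_plus, n_minus)` count is also unchanged
when noise flips which strand holds the majority, but excluding tied
contigs biases the recovered antisense fraction slightly downward at high
antisense probability and low coverage — at 20× coverage and p = 0.30 the
expected bias is ≈ −0.009, inside the 3σ binomial band the recovery test
uses; at lower coverage it would not be.

## Comparative statistics

Cross-dataset matching counts distinct query ids with ≥ 1 HSP at the
cutoff ("query genes") and distinct subject ids hit by such HSPs
("subject genes"), per direction. No-match unigenes (NMUs) use union
semantics across all supplied reference tables: a unigene is an NMU only
if it has no qualifying hit anywhere. KOG assignment gates on both
subject coverage (≥ 0.5 of the reference protein) and e-value (≤ 1e-10);
the published description of the annotation procedure is qualitative
("stricter, more significant"), so these two defaults are declared,
prominent and configurable — the e-value matching the strict cross-dataset
cutoff, the coverage a conventional half-length rule. A unigene may carry
several KOGs (multifunctional genes). KOG-ratio counts are distinct
unigenes per group and raw (not library-size normalized); a zero
denominator yields an explicit infinity flag rather than a pseudocount,
and infinite ratios qualify as expansions only when the numerator itself
reaches the threshold.

## ORFs and motifs

ORFs follow the stop-to-stop convention (maximal stop-free codon runs in
all six frames, sequence ends acting as boundaries), matching getorf-style
screening; an ATG-initiated mode is available since ORF counts are
convention-sensitive. Minimum lengths are in nucleotides; the two standard
screening cutoffs are 100 nt and 300 nt (a 100-aa protein).

The motif scanner applies the four orbicularian classes in priority order
polyA → (GA)n → GPGX(X) → GGX; within a class matches are maximal and
non-overlapping, and a later class may not claim residues already covered.
The GPGX(X) scan prefers the 5-mer unit unless that would consume the G
opening an immediately following unit. GGX's X is unrestricted (the
literature names only "a small subset" of residues), and its observed
composition is reported. The candidate flag — motif coverage ≥ 0.30 over a
peptide of ≥ 60 aa, scanned over all ORFs ≥ 180 nt of a transcript — is an
explicit, labeled approximation of manual spidroin curation, not a
validated classifier; serine/alanine/threonine fractions are reported
alongside for mygalomorph-style (S/A-rich) silks, which the coverage flag
does not capture.

## Synthetic data

The generator's defaults are the study conditions the tests assume:

- **Transcriptome**: 40 gene families, paralog count geometric with mean
  2 (shared between datasets A and B unless an expansion spec overrides a
  family, so neutral families have copy ratio exactly 1 and planted
  expansions are unambiguous), 2% per-duplication substitution rate,
  transcript lengths log-normal (median 800 nt, σ = 0.35, floor 150 nt),
  5% spidroin families. Spidroin transcripts are ATG + reverse-translated
  motif-grammar repeats (150–300 aa) + a 100-aa random C-terminal block +
  stop.
- **Reads**: length normal(250, 50) truncated at 40 nt (GS-FLX-era
  figures), Poisson read counts at 10× mean coverage, 1% substitutions,
  1% homopolymer-indel per run ≥ 3 (the characteristic 454 error, reduced
  to single-base run-length changes; no flowgram simulation), uniform
  start positions (no 3′/5′ bias — irrelevant to every implemented
  statistic), flat Phred qualities, configurable antisense, contaminant
  (pure homopolymer/dimer reads) and forced-short fractions.
- **Truth assembly**: one contig per transcript with ≥ 2 reads, consensus
  equal to the transcript, truth strands and offsets in the layout;
  single-read transcripts become singlets; contaminants join neither.

Antisense reads here are "biologically real" (truth strand −) rather than
library artifacts, which turns the majority rule into a parameter-recovery
problem. What passing tests on this generator shows is that the statistics
recover planted structure under a faithful error model; what it cannot
show is robustness to real assembler behavior (consensus errors, chimeras,
mis-clustering), cDNA normalization effects, or quality-score structure —
assemblies are consumed as input precisely because the assembler is out of
scope.

## Problem sizes and numerical choices

The heavier checks run at deliberately moderate scale chosen for a laptop
CPU: the ICI monotonicity suite uses ~2,000 reads per rate over five
substitution rates, antisense recovery uses ~10,000 reads per probability,
and the aligner oracle uses 64 planted pairs ≤ 200 nt against a
full-matrix DP reference. All randomness flows through explicit integer
seeds (numpy `default_rng`); reruns are byte-identical. Ties are broken
deterministically everywhere (score then start for HSP selection; e-value,
then coverage, then protein id for KOG hits). Degenerate inputs are
defined rather than special-cased: empty files parse to empty lists,
sequences shorter than the seed word align to nothing, reads without
qualities cannot fail the quality gate, and a zero cross-match table
yields (0, 0).
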