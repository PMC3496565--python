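# Methods

This note documents the models and procedures baculokit implements, the
parameters that matter, what the synthetic-data generator does and does
not emulate, and the numerical choices made where the design was open.

## Coordinates and topology

All coordinates are 1-based inclusive (GenBank convention). A feature on
a circular genome may wrap the origin; it is stored as `start > end` and
split into two GFF3/BED parts sharing one ID on output, reassembled on
input. BED emission converts to 0-based half-open. The map origin
convention is the granulin anchor: position 1 is the A of the anchor
gene's start codon and "clockwise" is its coding strand; genomes without
an anchor annotation keep their native origin. `N` bases are excluded
from composition statistics and count as mismatches in every comparison.

## ORF model

Candidates are ATG-initiated, internal-stop-free reading frames ending
at the first in-frame stop, enumerated in all six frames; on circular
genomes the scan runs on a doubled sequence and calls are deduplicated
modulo the genome length, with a guard that only stop-delimited segments
are reported (the leading edge of a circular scan would otherwise
truncate a segment that begins before the origin). Each stop-to-stop
segment contributes its 5′-most ATG as the canonical candidate; shorter
in-frame starts are kept as `alt_starts`.

The length threshold is a protein of ≥ 50 aa, i.e. a CDS of ≥ 153 nt
including the stop codon. The widely quoted "150 nt (50 aa)" shorthand
is off by one codon; `count_stop_in_min=True` restores the literal
150-nt reading.

"Minimal overlap" selection is a greedy policy: candidates are retained
longest-first provided their overlap with every retained ORF is at most
`max_overlap_nt` (default 75 nt, either strand). Ties break by smaller
start, then + strand, so output is deterministic. Published annotations
typically involve manual curation (homology, promoter evidence); exact
reproduction of a curated gene set from this rule alone is not promised,
which is why the pipeline has a first-class annotation-ingest mode.

## Promoter model

A flat 150-nt window immediately 5′ of the start codon, on the coding
strand, circular wrap allowed, truncated only near the ends of linear
genomes. Motifs are IUPAC degenerate strings matched exhaustively
(overlaps included) on the coding strand only, matching baculovirus
promoter convention. The early call requires at least one (TATA, CAKT)
pair whose spacer — counted from the TATA end to the CAKT start,
both endpoints included in the 20–40 range — is valid; anchoring the
spacer at the TATA start instead is a config option, since the prose
convention ("20–40 nucleotides downstream") is ambiguous. Whether the
published early count includes dual-promoter ORFs is equally ambiguous,
so summaries report all three conventions (`n_early_any`,
`n_early_only`, `n_both`).

## Palindromes, hrs, and ori-like regions

An imperfect palindrome with arm *a* and loop *g* satisfies: arm
vs reverse-complemented arm with at most ⌊a·rate⌋ mismatches (default
rate 0.2), g ≤ max_loop (default 40), a ≥ min_arm (default 15, matching
the 15-bp conserved ends of tortricid-GV hrs). For every loop placement
the scan finds the largest valid arm (maximality: any extension breaks
the budget); overlapping calls reduce greedily to the best by (longest
arm, fewest mismatches, smallest start). The scan is vectorised over
genome positions per (loop, depth) pair — O(max_loop · max_arm) numpy
passes — and is tested for exact agreement with a quadratic
per-position oracle. Defaults are exposed in config: the source
literature describes the structures (58-bp cores, 15-bp ends, ~70% AT)
but prescribes no thresholds.

Hr clustering is single linkage with `max_gap` 1,000 nt between
palindrome spans, honouring adjacency across the circular origin; the hr
interval is the envelope of its members. Conserved ends come from a
progressive multiple alignment of all palindrome sequences: the
consensus is read off densely occupied columns only (≥ 50% occupancy),
because a minority of divergent cores can insert sparse columns inside
the conserved flanks; the first and last `block_len` consensus columns
are reported along with whether the left flank is approximately the
reverse complement of the right.

Hairpin ΔG is a deliberately transparent approximation, not a
secondary-structure predictor: unified nearest-neighbour stacking terms
summed over consecutive matched stem pairs, a hairpin-loop initiation
penalty from a size table (Jacobson–Stockmayer-style log extrapolation
above 10 nt, loops clamped to the physical minimum of 3), and a flat
+1.0 kcal/mol per mismatched pair. It preserves orderings (GC stems
stabler than AT; mismatches destabilise) and is reproducible by hand
summation; published minimum-free-energy values from full folding
servers are comparison output, never asserted.

Direct repeats are found by exact k-mer seeding (k = 6), chaining on
each diagonal, and merging chains across small diagonal drift (≤ 2k) so
gapped copies with different unit lengths form one pair; only runs of
≥ k+4 anchor a pair, isolated k-mers in AT-rich sequence being mostly
noise. Identity is recomputed by global alignment over aligned columns,
which penalises length-mismatched junk merges. Among overlapping
candidates the longest above-threshold pair wins, so truncated sub-pairs
never mask full ones. An ori-like (non-hr) candidate needs the evidence
triple: ≥ 2 direct-repeat pairs (≥ 72% identity, unit ≥ 25 nt) within
600 bp of an hr, and AT fraction ≥ 0.62 over the union of the hr
envelope and the repeat units themselves (intervening background does
not dilute the evidence). Repeat-dense AT-rich regions without hr
context are reported at tier 2.

## Alignment

Pairwise global alignment is Needleman–Wunsch with affine gaps (a gap of
length L costs open + L·extend); the dynamic programme is Biopython's
`PairwiseAligner` with a fixed deterministic traceback, and scores are
cross-checked in tests against an independent DP written from the
recurrence. Defaults: DNA match +1 / mismatch −1 / open 2 / extend 1;
protein BLOSUM62 with open 10 / extend 0.1 (a BLOSUM45 preset covers
low-identity use). The progressive multiple aligner builds a UPGMA guide
tree from pairwise identity distances and merges profiles with an
affine-gap profile-profile DP; multiple alignment uses stiffer DNA gaps
(match 2 / mismatch −1 / open 10 / extend 0.5) because averaged profile
scores are small and cheap gaps shred related sequences. Output row
order equals input order. Percent identity offers both denominators
(`aligned_columns`, the default, and `shorter_seq`) because published
identity tables rarely state theirs.

## Orthologs, classes, fusions

Reciprocal best hits use global alignment score with a shared-k-mer
prescreen (top 10 candidates aligned) replacing database BLAST searches,
which are out of scope; ties break deterministically by identity then id
order, and the pairing is symmetric by construction. Gene classes derive
from presence patterns over user-supplied genus panels: core = present
in every genome of every panel; unique = present only in the focal
genome; GV-specific = confined to the betabaculovirus panel;
lepidopteran = present in both lepidopteran-infecting panels. The
packaged reference tables (31 core gene names, the 19-member
GV-exclusive ORF set, the 17-member unique ORF set, and the
alkaline-exonuclease/helicase-2 fusion layout: 383 + 47 + 456 = 886 aa)
ship as editable data, not hard-coded logic. Composite (fusion) proteins
are annotated by locally aligning each reference domain to the protein;
a domain below the score floor is reported absent, not an error.

## Synteny

The gene parity plot is ortholog-order-based: one point per shared
family at its positional index in each genome's clockwise order, plus
strand agreement. Blocks are greedy monotone chains allowing index gaps
up to `max_index_gap` (default 2, tolerating isolated unshared genes),
labelled forward or inverted; bp spans come from feature intervals so a
"~20 kb inversion" claim is checkable in bp, not just gene counts. No
rearrangement-distance machinery is attempted.

## Phylogeny

Complete deletion removes every column with a gap or missing symbol in
any taxon before distances are computed. The default distance is the
gamma-corrected proportion of differing sites,
d = a[(1−p)^(−1/a) − 1] with shape a = 2.25; as a → ∞ it reduces to the
Poisson correction −ln(1−p) (tested to relative error < 10⁻³ at
a = 10⁶). A `dayhoff_equal_input` variant applies the same correction
with the equal-input (stationary-frequency) bound using Dayhoff
amino-acid frequencies, as a documented approximation to matrix-based
ML distances whose exact published computation is not recoverable.
UPGMA (average linkage, merge height d/2) is retained deliberately
despite its molecular-clock assumption, because it is the method the
workflow standardises on; ties break on the lexicographically smallest
member-taxon pair so taxon relabelling cannot change the result. The
bootstrap resamples supermatrix columns with replacement (site
bootstrap on the concatemer), rebuilds the tree per replicate, and
scores each full-data clade by the percentage of replicates containing
it; saturated replicates (p = 1 pairs) are skipped and count against
support. Newick output carries branch lengths and supports as internal
labels and round-trips through the bundled parser.

## Synthetic data: what it emulates, and what passing means

The generator emulates the *architecture* of a granulovirus-style
genome, with the study conditions as defaults: AT target 0.585; ORF
cassettes (a 150-nt engineered promoter window + ATG + stop-free codons
+ TAA) on both strands with an early/late/both/none class mix; 16 hr
cassettes holding 26 palindromes (1–3 each, arm 21 / loop 16, shared
15-bp conserved ends, ~0.75 AT cores) separated by > 1 kb so clusters
are unambiguous; and one ori cassette (31-bp tandem pair plus an
imperfect 79/72-bp pair at 85% aligned identity, AT 0.75) adjacent to an
hr. The default genome length for end-to-end runs is 40 kb with 30 ORFs:
the repeat complement is kept at the full published scale while the ORF
count is scaled down to keep test and acceptance runtimes in seconds.

Two constructions make exact truth possible. First, planted palindromes
carry exactly the detector's mismatch budget (⌊arm·rate⌋), with
mismatches at pair depths 2–5 and the first 13 extension pairs forced to
mismatch, so no loop-shifted or arm-extended variant of a planted
palindrome can tie or beat it under the maximal-arm rule. Second, after
assembly the background is *scrubbed*: the package's own detectors run
iteratively and every chance feature (a spurious ORF that would survive
minimal-overlap selection, a spurious palindrome) is disrupted by a
point mutation validated not to damage any planted feature — stop
codons avoid planted CDS and palindrome margins, mutations inside
promoter windows must leave the window's classification unchanged, and
mutations inside planted ORF bodies must not create in-frame stops.
Packing, window repair and scrubbing are all driven by one seeded
generator, so a recipe + seed is byte-reproducible; a bounded number of
independent build attempts absorbs rare unscrubbable layouts before a
`PackingError` is raised.

What the generator does **not** emulate: codon usage and amino-acid
composition bias, transcription-level evidence, gene density approaching
real genomes (~90% coding), overlapping gene arrangements, hr sequence
heterogeneity between loci, or indel evolution in protein families
(families are substitution-only, hence aligned by construction, with
gamma-distributed site rates — shape 2.25 by default — and an
empirical-matrix-biased replacement kernel). Passing the planted-truth
suites therefore demonstrates correctness of the detectors and pipeline
plumbing under the stated conditions, not annotation accuracy on real
genomes, where curation judgement and biological noise dominate.

## Problem sizes

Default test/acceptance scales: 40-kb genomes (detection in ~1 s);
oracle cross-checks on 2–5-kb sequences over 20 seeds; protein families
of 60–120 residues over 6–8 taxa; bootstrap 100 replicates; RBH panels
of 30 families. These are the package's chosen verification scales; all
are parameters.

## Known limitations

- The minimal-overlap ORF policy is one defensible reading of an
  under-specified rule; curated gene sets will differ.
- The ΔG model ranks hairpins; it does not predict folding-server
  minimum free energies.
- The equal-input Dayhoff distance is an approximation; for publication
  phylogenies an external ML tool should corroborate the topology.
- UPGMA assumes a molecular clock; rate heterogeneity between lineages
  will distort the rooting (an NJ alternative is a natural extension,
  deliberately not bundled).
- Identity percentages depend on the denominator convention; both are
  reported, neither is asserted against published tables.
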