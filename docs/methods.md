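# Methods

This note records the models, conventions, parameter defaults and numerical
choices behind `mitocomp`, and what its synthetic-data tests do and do not
establish about real data.

## Coordinate and annotation conventions

All coordinates are 1-based inclusive on the given strand; conversion to
0-based half-open happens only at I/O boundaries (GenBank parsing, BED-like
export). Features may not span the origin of the circular genome in the
table dialect; the circle is closed instead by the wrap spacer computed
from the last feature to the first.

The signed spacer between a feature and its successor is
`gap = next.start − end − 1`; negative values are overlaps. Each gap is
attributed to the pair (feature, next feature). Published organisation
tables for these genomes are sometimes footnoted the other way ("distance
from the previous gene") while their printed numbers follow gap-to-next;
this package follows the printed-number convention throughout.

Coding lengths subtract the stop codon: 3 bp for `TAA`/`TAG`, 2 for the
partial `TA-`, 1 for `T-` (incomplete stops are completed by
polyadenylation of the transcript and are not part of the reading frame as
annotated). A coding length not divisible by 3 raises a warning, not an
error — such rows occur in deposited tables and should be visible, not
fatal.

The bundled *A. cinerea* counts table totals 3720 codons, which equals the
summed coding lengths (11160 bp) divided by 3; a prose figure of 3721
circulates for the same genome and is inconsistent with the per-gene
lengths, so 3720 is treated as authoritative here. Similarly, the
recomputed phenylalanine frequency is 353/3720 = 9.49%, one rounding step
below the commonly quoted 9.50%.

## Codon usage

Counting is done on coding sequences after trimming annotated partial
stops and any trailing complete stop; every remaining codon is counted as
written, including nonstandard initiation codons (an annotated `AAA` start
counts as Lys, `GCU` as Ala). This choice makes the total equal the full
coding length over three with nothing excluded but stops — which is the
only reading consistent with the bundled totals. It is reversible by
preprocessing the input sequences. Codons containing ambiguous bases are
dropped with a warning; an internal stop is an error naming the gene and
offset, because it indicates a frame or annotation problem upstream.

RSCU families pool by encoded amino acid under translation table 5, giving
the 6-codon leucine and 8-codon serine families; the bundled values
(UUA 4.25 with 503 leucines, UCU 2.38 with 367 serines) arise only under
this pooling. A family with zero total gets RSCU 0.00 for all members.
Display rounding is 2 decimals, half-up; internal values are unrounded.

## Comparative structure validation (CCS)

The compensatory-substitution criterion is operationalised without a tree:
a pair-position is *covarying-supported* when ≥ 2 distinct canonical pair
states (Watson–Crick A–U/U–A/G–C/C–G or wobble G·U/U·G) occur across taxa.
Two substitutions that preserve pairing must have happened in some order on
any genealogy relating the taxa, so the observed state set is the
tree-free content of the criterion. *Conserved* requires exactly one
canonical state present in at least a configurable fraction of non-gapped
rows (default 1.0 — conservation "across all sampled taxa"); everything
else is *unsupported*. Rows gapped at either paired column are excluded
from that position; a position with no usable rows is flagged "no data"
and excluded from helix summaries.

Mutual information between paired columns uses plug-in joint and marginal
frequencies with no pseudocounts — the statistic is descriptive (structure
logos), not inferential — and is therefore biased upward for small taxon
samples; values are in bits, bounded by 2 on the 4-letter alphabet.

## tRNA cloverleaf search

The cloverleaf schema is a set of testable predicates: acceptor stem 7 bp,
DHU stem 3–4 bp (or absent, the metazoan mitochondrial trnS(agn) case),
anticodon stem 5 bp with 7-nt loop, TΨC stem 3–6 bp, 2-nt "UR" connector
between acceptor and DHU arms, single nucleotide between DHU and anticodon
stems, conserved U immediately 5′ of the anticodon, and a 0–4 nt 3′ tail
(discriminator). The search enumerates every segmentation the schema
allows for sequences of 55–95 nt and scores canonical+wobble pairs in
stems. An assignment is admissible when the acceptor stem has at least 5
canonical couplets (noncanonical pairs at the 5th/6th couplet are a known
feature of these tRNAs); if none is admissible the result is "no
cloverleaf", not an exception.

Ties break deterministically: more canonical pairs, then fewer mismatched
stem couplets, then a longer TΨC stem, then the leftmost acceptor
placement, then smaller segment parameters. The "fewer mismatches" key
precedes stem-length preferences because a mismatched couplet absorbed
from a loop is not additional pairing evidence; without it the search
occasionally lengthens the TΨC stem spuriously. Soft constraints (UR
connector, anticodon-loop U, per-stem mismatch budget of 1, DHU absence)
are reported as violations on the best assignment rather than pruning the
search.

## Control-region detectors

**Tandem repeats.** For each candidate period *p*, positions where the
sequence matches itself *p* bp downstream are computed; a run of *p*-wide
windows at ≥ `min_identity` (default 80%) seeds a candidate. Because
chance matches in the flanks can shift the seeded phase by up to one
period, boundaries are refined by anchoring on a middle tile and, over all
phase offsets, extending tiles outward while consecutive tiles agree at
`min_identity` under *ungapped* identity (tiles are equal length; gapped
alignment is too permissive for boundary decisions). The phase with the
most copies, then the most matches, wins. A trailing copy of at least half
a unit is counted and flagged partial when it matches at a relaxed
threshold (`min_identity` − 10, floor 50%). Overlapping candidates are
merged preferring more copies, then longer span, then smaller unit: the
copy-count key outranks span because a harmonic of the true period (unit
2*p*, half the copies) can absorb chance-matching flanks and win on raw
span. Defaults `min_unit` 10, `min_copies` 2, `min_identity` 80% admit the
unit lengths (≈120–780 bp) and within-array identities seen in orthopteran
control regions. Per-copy identities are reported against the first copy
using the global aligner below. Ungapped tile extension means arrays whose
copies differ by indels are found only if the indel displacement stays
within the identity budget; copy-length variation beyond that is a known
limitation.

**Repeat-unit identity.** Needleman–Wunsch global alignment with match +1,
mismatch −1, gap −2 (linear), identity = matched columns / all alignment
columns (gaps included), reported to 2 decimals. Published identity
percentages for such units rarely state their alignment parameters; these
are documented defaults, not a claim of equivalence to any specific tool.
Argument order is canonicalised before aligning so the measure is exactly
symmetric despite alignment tie-breaking.

**Stem-loops.** For every loop placement the stem grows outward,
tolerating `max_mismatch` internal mismatches (default 0) with wobble G·T
allowed by default; terminal couplets must pair, so stems are maximal.
Mismatch tolerance is exposed because proposed control-region stem-loops
in some taxa pair imperfectly. Note that wobble pairing is not
strand-symmetric (the reverse complement of G·T is A·C), so exact
mirror-image invariance under reverse complement holds only for
Watson–Crick-only scanning.

**T-stretches.** Maximal runs of T allowing ≤ `max_interruptions` non-T
positions, with `min_len` counting T positions only; the ">17 bp"
convention is the default `min_len` 18. With purine bounding required, the
bases immediately flanking the run must exist and be A or G (a stretch at
the sequence edge does not qualify — the flank is unobserved).

**Motifs.** IUPAC degenerate scanning with one hit per start position per
strand and a `(X)n` quantifier meaning one or more copies of the symbol,
matched longest-first with backtracking. Minus-strand hits are mapped back
to input coordinates.

**Dyad symmetry.** A sequence is dyad-symmetric when it equals its reverse
complement, ignoring the central base for odd lengths.

All hit lists are ordered by start, then length, then label, and all
detectors are deterministic.

## Synthetic data: what it emulates and what it does not

Generators are seeded explicitly (the seed is a required field) and
byte-reproducible. Background composition defaults to 75% A+T, the
control-region regime of these genomes. Planted elements are placed
non-overlapping with guard bands; stem-loop flanks are forced non-pairing
and loop ends unpaired so the planted stem length is the unique maximal
one; repeat divergence is substitution-only, applied per copy relative to
the first.

Consequences for interpretation: recovery tests establish correctness of
the detectors' logic and coordinates under substitution noise on
homogeneous backgrounds. They do not establish performance on real control
regions, where copies differ by indels, elements overlap (stem-loops
inside repeat units are common — one such case is tested explicitly),
background is locally repetitive, and flanking context can extend true
stems. The CCS generator cycles each position's pair-state menu across
rows, so planted verdicts are realised exactly; it does not simulate
substitution processes along a phylogeny, and conservation statistics on
its output have no evolutionary interpretation.

Measured under these conditions (100 seeds, 700-bp regions; also run as an
acceptance battery): planted repeat/stem-loop/T-stretch/motif recovery is
100/100 at zero divergence, and repeat recovery remains 100/100 at 5%
per-copy divergence with units of 40 bp × 3 copies.

## Problem sizes in the test suite

The oracle batteries use deliberately small instances — two-row exhaustive
pair-state enumeration (16² combinations), 1000 random annotations of ≤ 15
features for the occupancy oracle, 100-seed recovery on 700-bp control
regions, brute-force alignment on strings of ≤ 12 nt — chosen so each
oracle is exact and the full suite runs in seconds while still covering
every code path the larger inputs would.

## Known limitations

- Gene-order comparison reports adjacency differences and named block
  swaps; it is not a rearrangement-distance or breakpoint-median method.
- The repeat detector assumes substitution-dominated divergence between
  copies (see above); it reports what is present at the configured
  identity floor, so genuinely periodic chance matches in flanks are
  reported as part of an array when they exceed the threshold.
- Cloverleaf validation checks the schema; it does not predict structures
  thermodynamically and will mis-segment sequences whose true structure
  departs from the schema in ways the violation list cannot express.
- Helix models are inputs to be validated, never inferred; alignments are
  consumed, not built.
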