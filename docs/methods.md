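# Methods

This note documents the models and procedures implemented in karyoscan,
the parameters that matter, what the synthetic-data generator does and
does not emulate, and the design choices made where conventions were
genuinely open.

## Coordinate and format conventions

FASTA and AGP coordinates are 1-based inclusive internally (AGP's native
convention); every exported interval (BED, truth files, detector calls)
is 0-based half-open. Lowercase (soft-masked) bases are preserved on
write and folded to uppercase for analysis. When no AGP is available, a
layout is inferred from sequence: every maximal run of ≥ 10 N becomes a
spanned gap (the NCBI assembly-stats convention; configurable), and
sequences whose names match `^(?:chr)?(\d+|X|Y|MT?)$` are treated as
chromosome-assigned.

## Contiguity statistics

Contigs break at **every** AGP gap line, spanned or unspanned, regardless
of declared gap length — this, not the N-run heuristic, is what public
assembly reports use when an AGP exists. Scaffolds are objects split at
unspanned (linkage "no") gaps; a scaffold's length includes its spanned
gaps. Unspanned gap counts come from AGP linkage, never from sequence,
because some dialects omit them from FASTA. The mitochondrial sequence
counts toward the chromosome number but is excluded from N50/L50 by
default (`include_mt` includes it). Unlocalized scaffolds (assigned to a
chromosome without being the chromosome object) are counted separately
from unplaced scaffolds; with name-pattern assignment this count is zero
unless assignments are supplied explicitly.

Nx/Lx use the standard definition: sort lengths descending, accumulate,
and report the element at which the running sum first reaches x% of the
total. Ties and degenerate inputs (single element, all equal) need no
special casing under this definition; the empty set is an error.

## Window quality classification

Windows default to 1,000 bp, non-overlapping, with the last window of
each sequence possibly short. From coordinate-sorted alignments, a
window's depth is aligned-bases-overlapping / window width, while
pairing and insert statistics count the reads whose leftmost aligned
base falls in the window. Improper insert sizes are |template length|
outside [0.5×, 2×] the modal insert, estimated from a 10 bp histogram of
the data unless explicit bounds are given.

GC normalization divides each window's depth by the **median** depth of
its GC bin (width 0.02); the median resists collapsed repeats, which
would drag a mean upward and mask true high-coverage windows. Bins with
fewer than 50 windows fall back to the global median — extreme-GC bins
are exactly where depth estimates are least stable.

Default thresholds: LC below 0.25× normalized depth, HC above 2.0×,
properly-paired minimum 0.80, improper-insert maxima 0.10, minimum 4
reads per window (below which a window is classified LC — its
fractional statistics are too noisy to interpret). These cut-offs are
conventional coverage-anomaly heuristics, are exposed in configuration,
and are deliberately not claimed to reproduce any published full-scale
quality table, whose exact thresholds live in prior QC work. A window
intersecting a mask interval by ≥ 1 bp counts as masked.

Relaxing any single threshold can never increase flagged bases
(classification is monotone), which the suite checks directly.

## Telomere scan

The scan finds exact occurrences of TTAGGG and CCCTAA and chains
successive occurrences whose starts are ≤ 48 bp (8 unit lengths) apart
into maximal arrays; an array is reported only if it contains ≥ 5
identical consecutive same-strand units. Retention requires ≥ 200 exact
units, span > 2 kb, and density > 0.5 (strict for span and density,
inclusive for the unit count, as the criteria are stated). This replaces
an external tandem-repeat finder deliberately: the retention decision
depends only on exact-unit counts, span and density, which the chaining
scan computes directly. TTAGGG has no non-trivial period and shares no
characters with CCCTAA at any alignment, so occurrences cannot overlap
and greedy counting is exact. The density denominator is the chained
span; raw counts and spans are reported so the alternative
(repeat-region-span) convention can be recomputed downstream.

One consequence worth knowing: a 334-unit array spans 2,004 bp, only
4 bp above the strict 2 kb span criterion. Pure arrays of that size are
retained with exact boundaries, but under per-base mutation the terminal
units are often destroyed and the chained span falls below 2 kb, so
mutation-tolerance experiments use 400-unit (2,400 bp) planted arrays,
which leave the intended margin; the zero-margin 334-unit case is kept
for the exact-boundary checks.

## Centromere calling

RepeatMasker `.out` rows are parsed with the C-strand column swap
(complement hits report repeat coordinates as (left), end, begin);
consensus length is repeat end + remaining left bases on either strand.
The divergence/length filter removes rows with divergence > 40% or
aligned consensus fraction < 70%, keeping both boundaries exactly; it is
applied before centromeric-class selection and merging, and can be
disabled. Centromeric rows are selected by repeat class
(`Satellite/centr`) or an optional user-supplied name pattern, since
library naming varies.

The monomer search is k-mer seeded (k = 13), ungapped, both strands:
each exact seed proposes a full-length monomer placement whose identity
(matches / aligned length) must reach 0.70; overlapping placements of
one monomer on one strand merge with length-weighted identity. Ungapped
extension suffices because satellite arrays are tandem and largely
indel-free at the identity levels of interest; k = 13 balances seed
specificity (4^13 ≈ 6.7×10^7) against tolerance of ~10% divergence.

Evidence streams (default library, novel library, monomer hits) merge
per sequence in one coordinate space: intervals whose gap is ≤ 500 bp
collapse into super-regions (the output is therefore pairwise separated
by strictly more than 500 bp — the merge is stated as "closer than
500 bp" in some conventions, which differs only at a gap of exactly
500 bp; the ≤ rule keeps the output-separation invariant clean), and
super-regions > 5 kb (strict) become centromere calls with source
provenance and merge counts. The pre-retention merged-region length
median/mean are reported as a summary.

## Marker concordance

Karyotype order is numeric chromosomes ascending, then X, Y, MT, then
non-chromosome scaffolds in natural sort order. Placing unplaced
scaffolds **after** all chromosomes gives their markers the highest
ranks, which renders them as a distinct band at the top of a rank
dotplot rather than scattering them; excluding them instead is possible
by filtering placements first. Manifest chromosome dialects (e.g.
`SSC1`) are normalized via a small pattern plus an optional per-chip
alias table.

All unmapped markers carry the literal assembly rank −1 before the rank
transform, forming one tie block resolved by average ranks — the
standard Spearman tie convention (the implementation delegates to
scipy's `spearmanr`, which is exactly rank-transform + Pearson; an
independent hand-rolled oracle checks it in the tests). Pooling all
chips into one ranking is the implemented convention; a per-chip
breakdown is reported alongside.

Marker spacing uses consecutive mapped markers within each chromosome,
never across boundaries; the SD is the sample (n−1) form, with a single
spacing defined to have SD 0. The largest spacing is reported as the
marker desert with its interval.

The exact-occurrence probe placer (unique exact match counting both
strands; zero or multiple occurrences → unmapped) exists for
simulation-backed tests; mapping real probes against a real genome with
mismatches is an external aligner's job. The reported coordinate is the
occurrence start by default, with a strand-aware 3′-anchor option, since
manifest conventions differ.

## Synthetic-data generator

The generator emulates the feature structure the pipeline must detect:

- per-chromosome background sequence at configured GC (defaults 0.40 /
  0.46 / 0.52 across three chromosomes of 600/450/300 kb — a size chosen
  to exercise every stage in seconds while leaving thousands of windows
  per genome);
- telomeric arrays of 334 units per end (the ~2 kb scale of a real
  vertebrate telomere in an assembly), optionally mutated per base;
- one centromeric satellite array of a seed-derived 340 bp monomer
  (the length scale of known pig centromeric monomers), default 50 kb,
  planted as a whole number of monomer copies so the truth extent is
  exact;
- spanned gaps (N runs with AGP linkage "yes") and unspanned gaps
  (100 N, AGP type U linkage "no"), written over interior background so
  planted-feature coordinates stay fixed;
- a window track whose read counts are negative binomial around a
  GC-bias-scaled mean (a smooth unimodal curve peaking at GC 0.45).
  Dispersion 100 gives a count CV of ~0.1 at 30× nominal depth in 1 kb
  windows, typical of GC-corrected Illumina coverage. Planted anomalies:
  LC at 0.15×, HC (collapsed duplication) at 2.5×, misassembly windows
  with properly-paired fraction ~0.5 and inflated improper-insert
  fractions;
- probe sets of unique 70-mers with configurable dropout (probe sites
  overwritten in the derived assembly) and whole- or part-chromosome
  inversions applied through the structural-edit machinery with a
  coordinate lift table.

Because chance motif occurrences adjacent to a planted telomere would
legitimately extend the chained array, the generator scrubs
telomere-motif occurrences from a 2 kb band inside the background next
to each planted array; planted truth is therefore recoverable with exact
boundaries at zero noise, which the suite verifies.

Everything is byte-deterministic under a fixed seed; the window track
and probe set draw from streams derived from the same seed.

What the generator does **not** emulate — and what passing tests
therefore do not show about real data: read-level artefacts (duplicates,
chimeras, mapping quality), indel divergence in satellites, higher-order
repeat structure, interspersed repeat families beyond the planted
satellites, haplotypic variation, and the genuine thresholds behind any
published full-scale quality table. Detector performance on real
assemblies depends on those factors; the synthetic results establish
correctness of the computations and calibration under the stated noise
model, not field performance.

## Numerical and degenerate-input choices

- `nx` of an empty set, GC normalization of an all-zero-depth track, and
  spacing with fewer than two mapped markers anywhere are errors, not
  silent defaults.
- Spearman ρ with zero variance in either rank vector is reported as
  undefined (NaN) rather than raised, since all-unmapped placements are
  a legitimate (if useless) outcome.
- Interval merging sorts by (start, end) and is idempotent by
  construction; ties in marker sorting break by marker id to keep ranks
  deterministic.
- Derived seeds in the acceptance script stay below 2^31.

## Problem sizes

The test suite and acceptance script run on three-chromosome 1.35 Mb
genomes (or single 200 kb chromosomes for replicate loops), 20 seeded
replicates per recovery property, and 1,000 random instances per oracle
equivalence check — sizes chosen so the full synthetic suite completes
in about a minute and a half on one CPU while every property retains
statistical force.
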