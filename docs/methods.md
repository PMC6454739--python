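# Methods

This note records the models, conventions and design choices behind
each analysis, what the synthetic-data generator does and does not
emulate, and the numerical details a user would need to reproduce or
modify the behaviour.

## Coordinates and sequence handling

All coordinates are 0-based half-open (BED semantics); 1-based closed
coordinates appear only in RepeatMasker-format IO and human-readable
messages.  FASTA input is uppercased and IUPAC ambiguity codes other
than N are converted to N (counted and logged): downstream statistics
only distinguish A/C/G/T/N.  GC content is (G+C)/(A+C+G+T) with N
excluded from numerator and denominator; an all-N segment yields NaN
rather than a value.  The final partial window of a sequence is
retained and densities are normalized by actual window length, because
chromosome termini — exactly where telomere signal lives — would
otherwise be discarded.

## Mappability

Every k-mer (default k = 50, the read-length scale at which uniqueness
is usually assessed) scores 1/(number of exact occurrences of the k-mer
or its reverse complement in the whole assembly); a base's score is the
mean over the k-mers overlapping it, and k-mers containing N score 0.
Strand-combined counting matches read-mapping semantics, where a read
from either strand aligns to both. Occurrence counting uses 64-bit
polynomial rolling hashes (collision probability ~1e-5 at tens of
megabases); exact-position searches (motifs, primers) additionally
verify candidates by string comparison, so collisions cannot produce
false hits there.  The tests check hash-based counting against an exact
dictionary oracle at the ≤ 100 kbp scale.

## Telomere calling

TTAGG and its reverse complement CCTAA are counted in non-overlapping
10 kbp windows; a motif spanning a window boundary belongs to the
window containing its start, which makes window counts exactly
additive.  A distal telomere is called at a sequence end when any of
the outermost 2 windows exceeds 10% motif density (fraction of window
covered by motif copies); the call interval is the maximal contiguous
run of above-threshold windows, and both ends are evaluated
independently so a metacentric chromosome can carry two distal
telomeres.  The threshold+contiguity rule is this package's
formalization — the windows it calls are two orders of magnitude above
a uniform-random background (~1% density), so the call set is
insensitive to the exact threshold.  Fold enrichment is the call's
per-bp density over the mean density of all non-call windows.  Calls
are made only at true sequence termini, not at internal gap edges.

## Tandem repeat annotation

The internal annotator is exact-seed (16-mers of the canonical element,
both strands) plus semi-global unit-cost alignment (edlib) of the
canonical against a padded window around each seed cluster; divergence
is edits / alignment columns.  Defaults max_divergence = 0.30 and
min_length = 50 admit far more divergent copies than the arrays the
package targets (AvaI ≈ 6.6%, AluI ≈ 3.9% divergence in a long-read
assembly).  When co-optimal alignment ends exist the span closest to
the canonical length is taken, and residual ≤ 8 bp overlaps between
adjacent copies are trimmed — tandem context otherwise makes copy
boundaries ambiguous by a base or two.  Overlap resolution is greedy by
score = length × (1 − divergence), ties to the leftmost start.  Greedy
has no uniform optimality guarantee: on dense random overlap structures
it averages ≈ 97% of the exhaustive maximum-weight disjoint set but can
fall to ≈ 50% in adversarial cases (the tests flag such cases and
require them rare).  Arrays are maximal runs of same-family
non-overlapping hits with inter-copy gaps ≤ 50 bp — real AvaI/AluI
arrays are essentially gap-free, but small interruptions occur; every
retained hit counts as an array member regardless of matched length.
The shipped AvaI/AluI "canonical" sequences are synthetic stand-ins of
the correct lengths (the GenBank consensus entries are not
redistributed), generated deterministically and screened to contain no
telomeric 5-mer so repeat arrays cannot confound motif scans; all
machinery accepts any consensus FASTA in their place.

## Centromere delineation and profiles

A candidate centromere is a maximal run of consecutive 100 kbp windows
with GC below a threshold that defaults to the assembly's own
genome-wide GC (recomputed per input rather than hard-coded, so the
rule transfers across assemblies with different base composition).
With cluster seeding on (default) only runs overlapping an AvaI cluster
(≥ 3 copies, arrays merged within 100 kbp) are reported; the unseeded
mode reports all runs, which recovers low-GC blocks lacking a mapped
cluster.  Distance-binned profiles assign each 1 kbp window to the bin
of the distance from its midpoint to the nearest cluster *boundary*
(bins starting at 0–20 kbp imply boundary-relative distance); per-bin
means carry 95% percentile bootstrap CIs (2.5/97.5 quantiles of 2000
seeded resamples of windows).  Empty bins report NaN, never zero.

## Genetic map congruence and recombination

Primer pairs are located by exact search (both strands).  A marker is
placed at the midpoint of the minimal-span convergent pair on one
chromosome; pairs > 1 kbp apart are `ambiguous_distant`, overlapping
primer targets `ambiguous_overlap`, and a marker with a single mapped
primer is placed at that primer (markers with no mapped primer are
unmapped).  Congruence is formalized as a longest non-decreasing
subsequence of cM values along physical order per chromosome (ties in
cM may sit in either order); members are congruent, the remaining
unambiguous placements incongruent, and a marker on the wrong linkage
group is incongruent outright.  This is the package's central
formalization of "collinear with the map" and is checked against an
exhaustive maximal-collinear-subset oracle for small n.  Zero-distance
filtering drops every marker whose cM equals the previous marker's
within a linkage group, keeping the first of each run.

The recombination rate is the ratio of sums Σ ΔcM / Σ Δbp·10⁻⁶ over
adjacent congruent marker pairs in cM order — not the mean of per-pair
ratios, which explodes when physical gaps are tiny (the alternative is
available as `method="mean_of_ratios"`).  Region-scoped estimates keep
only pairs with both markers inside a region.  CIs resample pairs with
replacement (2000 replicates, percentile).

## Subtelomere/telomere alignment profiles

Columns where the backbone row has a gap are removed, so profile
coordinates are backbone positions.  Pairwise divergence per 100 bp
window is mismatches/compared columns over all row pairs, skipping
columns where either row has a gap; a pair contributes only when ≥ 50%
of the window is comparable.  Depth counts rows with ≥ 50% non-gap in
the window (`depth_mode="span"` instead counts rows whose aligned span
covers the window — both readings of a coverage curve are exposed).
Motif densities are computed on gap-stripped per-row text so gaps do
not split motifs, then averaged over rows.  CIs bootstrap rows; a
replicate pair drawn twice from the same original row is excluded from
the divergence statistic (it is not an independent comparison).  The
junction is the start of the first window beginning a run of ≥ 5
windows whose combined canonical+variant density exceeds 0.5 — both
thresholds configurable; the rule is this package's formalization.

## Assembly comparison

Blocks are classified from the two placement maps; target coverage is
merged per category, overlaps between categories resolve to the earlier
category in the fixed order (same_chromosome, new_anchor, switched,
lost_anchor, both_unplaced), and the unaligned target remainder is
split by placement status — so category bp sums exactly to the target
assembly size, invariant to block order and splitting.  Window-level
feature statistics assign each 1 kbp window by majority overlap (ties
to the earlier category) with window-bootstrap CIs.

## The synthetic generator

`simulate_genome` emulates a desk-scale version of the honeybee genome
architecture: by default 3 chromosomes × 5 Mbp plus 10 × 20 kbp
unplaced contigs, background GC 34.6%, one 2.3 Mbp centromeric block
per chromosome at 22.7% GC containing an AvaI tandem array (26/11/5
copies at 6.6% divergence), AluI arrays (80/21 copies at 3.9%) near the
short-arm ends, distal telomeres of ~Poisson(1177) TTAGG copies at the
long-arm termini (both termini on chromosome 1, CCTAA-oriented on the
left, emulating a metacentric fusion chromosome), a shared 3 kbp
subtelomere containing a GC-rich 400 bp conserved element (5.5%
pairwise divergence) and a ~350 bp junction element ending 100 bp
before the junction, ~500 microsatellite markers as exact primer pairs
flanking a planted core (guaranteeing exact placement), and one
unplaced contig with 900 CCTAA copies plus one with an AluI array.
Marker cM positions accumulate at 21.6 cM/Mbp outside and 7.9 cM/Mbp
inside centromeres with multiplicative gamma noise (shape 25) per
interval; because centromeres occupy ~46% of the desk-scale genome, the
realized genome-wide rate is a mixture (≈ 15 cM/Mbp), and the truth
table records the realized per-scope rates so estimator recovery is
assessed against what was actually planted.

The telomere variant gradient is a per-copy variant probability
declining linearly from 0.5 at the junction to 0 at the tip, realized
by error-diffusion thinning (deterministic density, random variant
types) so the decline is monotone at kbp scale; TCAGG/CTGGG events are
planted inside the TCAGGCTGGG higher-order repeat with probability
h = c/(2−c), which realizes a co-occurrence fraction c (default 0.9).
`simulate_end_alignment` derives all rows from one ancestral end with
per-position substitution rates solved from the target pairwise
divergence D via D = 2m − (4/3)m² (independent row mutations to a
uniformly different base), with rare deletions (0.5%) in non-backbone
rows.  `simulate_blocks` realizes category bp proportions exactly by
construction.

What the generator does **not** emulate: base-composition
heterogeneity beyond the centromere/background dichotomy (uniform
random background gives ~1% telomeric-motif density versus ~0.4% in
the real genome, and occasional 10 kbp windows exceed the unplaced
screen's 30-motif constant by chance), indels inside repeat copies
(divergence is substitution-only, so copy boundaries are exact),
assembly gaps, sequencing error, transposable-element families, and
genuine map errors (markers are congruent by construction unless
perturbed).  Passing tests therefore demonstrate correct recovery of
planted signal under clean conditions, not robustness to every real
data pathology.

## Problem sizes and runtimes

Defaults keep everything desk-scale: the 15.2 Mbp synthetic genome runs
the full telomere/centromere/repeat/map pipeline in well under a
minute; the recombination-recovery study uses 20 seeded replicates of
the default genome; bootstrap calibration uses 200 trials of 100
windows with 2000 replicates each.  All bootstraps take an explicit
seed and are bit-reproducible.
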