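# Methods

This note documents the models, parameter defaults, numerical choices,
and known limitations of the `transhic` pipeline. It describes what the
code computes; every empirical number quoted in the README is produced by
the test suite or the acceptance script at run time.

## Coordinate conventions

All coordinates are 0-based half-open (BED-native) throughout the
package; 1-based external dialects are converted at the I/O boundary.
Anchors of a bin pair are kept in canonical order: the chromosome earlier
in the layout order first, and within one chromosome the lower start
coordinate first. Canonical ordering makes reflected bin pairs identical,
so each contact is stored exactly once.

## Read-pair classification

A di-tag is classified into exactly one of eight classes, evaluated in a
fixed precedence order so that per-class counts are deterministic even
when a pair satisfies several artifact definitions:

unmapped → low MAPQ (either mate < `mapq_min`, default 10) → duplicate
(consumed as an upstream flag, not recomputed) → same fragment in the
same orientation → dangling end → self-circle → off-site digestion →
keep.

Geometry definitions (standard Hi-C conventions; fixed here because the
upstream descriptions leave them implicit):

* *inward-facing*: the upstream mate (smaller 5' position) on the +
  strand, the downstream mate on −; *outward-facing* is the reverse.
  Separation is measured between 5' positions. At equal 5' positions the
  + read counts as upstream, which keeps classification invariant under
  mate swap.
* *dangling end*: inward-facing, same chromosome, separation <
  `min_inward`; *self-circle*: outward-facing, separation <
  `min_outward`. In situ Hi-C analyses typically tune these two thresholds
  per library from insert-size distributions; here they are required
  configuration with documented defaults of 1,000 and 25,000 bp — values
  in the range conventional for MboI in situ Hi-C.
* *pair fragment size*: the sum of the two mates' distances to the
  restriction-fragment end each read points away from (+ reads to the
  higher-coordinate end, − reads to the lower). The sum of the two
  per-mate distances is used: it aggregates the per-read definition over
  the pair.
  Pairs above `max_frag` (1,200 bp) are off-site digestion products.

Chimeric reads (split at the ligation signature — the junction sequence is
validated to be a reverse-complement palindrome of even length, e.g.
`GATCGATC`, `AAGCTAGCTT`) contribute an error estimate: an evaluable
chimera is an error unless its 3' segment and the other mate are
inward-facing within `chim_dist` (1,200 bp). The rate is errors over
evaluable chimeras; with no evaluable records the rate is NaN.

## Binning

Nominal boundaries at multiples of `bin_width` (50 kbp) are snapped to
the nearest candidate boundary — restriction site or blacklist-region
edge — with ties resolved to the lower coordinate. Chromosome ends are
always boundaries; degenerate bins (two nominals snapping to one
candidate) are dropped; a chromosome longer than one bin with no
candidates keeps nominal boundaries and warns. Counting conserves reads:
every record increments exactly one canonical bin pair or the
skipped-record tally (off-whitelist chromosomes, e.g. chrM).

## The enrichment statistic

For a target bin pair t in the interaction plane of its chromosome pair,
four neighborhoods are formed with half-width x (default 5 bins, i.e.
250 kbp at 50 kbp bins): a quadrant of sides x+1 between the target and
the diagonal with the target in its corner; horizontal and vertical
stripes of length 2x+1 centred on the target; and a (2x+1)-sided centred
square. With y the cross-library mean count (unstored pairs = 0) and a
prior count p (default 0.5):

    lfc_N(t) = log2( (y_t + p) / (mean over N\{t} of y + p) )
    enrichment(t) = min over defined N of lfc_N(t)

Documented choices where the statistic's informal description leaves room:

* **Target exclusion.** The target is excluded from every neighborhood
  mean; including it would let strong pairs inflate their own background.
* **Borders and the diagonal.** Neighborhoods are truncated at plane
  borders; cis neighborhoods additionally exclude the diagonal and the
  lower triangle (each cis contact lives once in the upper triangle). A
  neighborhood left empty after truncation is undefined; a target with
  every neighborhood undefined gets NaN enrichment and is never called.
* **Trans quadrant.** "Closest to the diagonal" has no meaning between
  two different chromosomes, so trans targets omit the quadrant and take
  the minimum over the three remaining neighborhoods. This is the
  conservative reading: an extra neighborhood could only lower the
  minimum.
* **Abundance.** Raw cross-library mean counts, no between-library
  normalization (none is described for detection); a normalization hook
  exists but defaults off. The prior is needed for empty backgrounds and
  is exposed in config.
* **Sparse evaluation.** Enrichment is evaluated at stored (non-zero)
  pairs; optionally only at stored pairs above an abundance floor. All
  stored pairs always contribute to neighborhood backgrounds, so with the
  floor set to the calling threshold this is exact with respect to
  calling: a pair at or below the count threshold can never be called.
  The dense brute-force oracle in the test suite checks the unrestricted
  evaluation to 1e-9.

Putative loops: enrichment > `enrichment_min` (0.5) AND mean count >
`mean_count_min` (10) AND, for cis, more than `diag_exclusion` (1) bins
off the diagonal. All three thresholds are strict inequalities.

## Annotation and end-distance profiles

An interaction is flagged when either anchor overlaps a blacklist /
centromere / telomere region by at least 1 bp (overlap, not containment —
the stricter reading for a removal filter, under half-open semantics).
Removal never mutates surviving interactions and is idempotent.

The normalized end distance of an anchor uses its midpoint m (symmetric
and bin-width independent): telomere reference min(m, L−m)/L in
[0, 0.5]; centromere reference |m − c|/L with c the centromere midpoint.
Both anchors of every interaction contribute one value to the profile of
its class (trans or cis), summarised by median, mean, and a fixed
0.02-wide histogram. A two-sample Mann-Whitney statistic comparing trans
vs cis values is reported as a descriptive aid only, never used as a
filter.

## Lineage comparison

Two bin pairs overlap when the anchor1–anchor1 and anchor2–anchor2 gaps
are both ≤ `maxgap` (100 kb, inclusive — "separation less than maxgap" is
ambiguous at equality, so the inclusive convention is fixed and
documented); overlapping or abutting anchors have gap 0 and different
chromosomes are infinitely far apart. Anchors are compared slot-by-slot
in canonical order only; canonical ordering makes cross-pairing redundant
outside exotic same-chromosome-pair geometries excluded by construction.

Interactions pooled over lineages are clustered into connected components
under this overlap relation; each component lands in the partition cell
named by the exact set of lineages it contains. An interaction is
lineage-specific when its component contains no other lineage (non-overlap
with *all* others, matching "unique" semantics). Component counting makes
a loop shared by three lineages count once in the all-three cell.

Expression association: genes overlapping either anchor of a
lineage-specific interaction by ≥ 1 bp are collected; *expressed* means
RPKM strictly above `rpkm_min` (5) in any lineage; *lineage-restricted*
means expressed-or-DE-flagged in the interaction's lineage and in no
other. DE flags are consumed as precomputed input (the differential
expression fit itself is out of scope). Cross-species conservation maps
both anchors through an orthology table (any-overlap on the source side)
and asks whether some interaction of the other species overlaps the
mapped pair; unmapped anchors are never conserved.

## The synthetic generator

Every generator is a pure function of (spec, seed); per-library count
draws use split RNG streams so increasing `n_libraries` never perturbs
earlier libraries.

* **Genome.** Chromosomes of equal length; restriction sites as a Poisson
  process (mean spacing 400 bp — the scale of a 4-cutter like MboI);
  telomeres as the first/last `width` bp of each chromosome; one
  centromere per chromosome at a configurable offset, chromosome start by
  default (acrocentric, as in mouse); blacklist intervals of fixed 50 kb
  length dropped uniformly to cover ≈ `blacklist_fraction` (default 0.05)
  of the genome — merging makes realised coverage marginally below
  nominal, which the generator's own Monte-Carlo test accounts for.
* **Contacts.** Independent Poisson draws per library at bin resolution.
  Cis mean: `cis_rate · sep^(−α)` with α = 1 and 10 expected counts at
  1-bin separation (a generic distance-decay background); the undefined
  separation-0 mean reuses the separation-1 value — self pairs are never
  callable anyway. Trans mean: uniform `trans_background_rate` (default
  1), multiplied by the telomere or centromere fold where both anchors'
  bins fall in the respective end regions of different chromosomes, and
  by the loop fold over bin pairs containing a planted loop. Counts are
  simulated at bin resolution because detection consumes bin counts;
  read-level simulation exists separately for the filter tests.
  Per-library variation is pure Poisson (no overdispersion) because the
  detection statistic uses only the cross-library mean.
* **Read pairs.** Per-class record counts are fixed (rounded from the
  artifact fractions) and each artifact's geometry is constructed to be
  unambiguous under the default thresholds, so planted compositions are
  recovered exactly — these libraries test the classifier's bookkeeping,
  not its behaviour on borderline geometries. Default composition: 30%
  artifacts (8% low-MAPQ, 5% duplicate, 4% same-fragment, 8% dangling,
  2% self-circle, 3% off-site), matching the ~70% assignment rate typical
  of in situ Hi-C; 20% of records carry an evaluable chimeric segment of
  which 5% are planted errors.
* **Expression.** RPKM = mean · exp(σZ − σ²/2) with σ = 0.25, so the
  expectation equals the specified mean; a DE effect multiplies the mean
  in one lineage and sets that lineage's flag; a zero base gives exact
  zeros and no flags.

What the generator does **not** emulate: mappability structure within
bins, genomic distance-dependence of trans contacts, overdispersion
between biological replicates, copy-number and allelic effects,
sequence-level reads. Passing tests therefore demonstrate the pipeline's
arithmetic and its operating characteristics under the stated stochastic
model, not performance on real libraries.

## Study conditions and problem sizes

The packaged studies fix these conditions:

* *Null specificity*: two 10 Mb chromosomes, 50 kb bins, α = 1, trans
  λ = 1, two libraries; 50 seeds; the false trans-call count is recorded
  per seed.
* *Planted-loop power*: the same background with one fold-20 trans bin
  pair planted on an exact grid bin pair; 100 seeds; recall and
  top-enrichment rank are recorded.
* *Telomere-clustering recovery*: two 100 Mb chromosomes, telomere fold
  10 over 2 Mb ends, plus 30 planted cis loops per chromosome (fold 50,
  anchor separations 5–40 bins, uniform positions — the genome-wide cis
  loop structure real maps carry, and the source of a spread-out cis
  profile); 50 seeds; trans and cis end-distance medians are recorded.
* *Lineage partition*: two 40 Mb chromosomes, 5 shared + (3, 8, 4)
  private planted trans loops with anchors ≥ 1.2 Mb apart, so bin-pair
  overlap at maxgap 100 kb recovers the design exactly.

These sizes keep each study in the seconds-to-minutes range on a single
core while leaving the detection problem statistically non-trivial
(planted folds are order-of-magnitude, not arbitrary-precision, effects).

## Known limitations

* The min.inward/min.outward defaults are conventions; real libraries
  should set them from their own insert-size distributions.
* The trans-quadrant omission, target exclusion, border truncation, and
  inclusive maxgap are documented design decisions; alternative readings
  exist and would shift calls near plane edges and overlap boundaries.
* Blacklist-aware bin snapping uses blacklist edges as boundary
  candidates; it does not remove blacklisted bins from the grid — removal
  happens at the interaction level, after calling.
* `conserved_across_species` enumerates candidate pairs directly; it is
  intended for the handfuls of lineage-specific interactions the analysis
  produces, not for genome-wide sets.
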