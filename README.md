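# transhic

Trans-chromosomal interaction calling from Hi-C read pairs: artifact
filtering, restriction-site-aware binning, local-neighborhood enrichment
loop detection, blacklist/centromere/telomere annotation, and
cross-lineage comparison — with a synthetic Hi-C generator so the whole
pipeline can be exercised and validated at desk scale.

## The problem

Genome-wide chromosome conformation capture (in situ Hi-C) detects
contacts both within chromosomes (*cis*) and between chromosomes
(*trans*). Candidate trans contacts are the weakest and most
artifact-prone signal in a Hi-C map: they are dominated by ligation
artifacts at the read-pair level, by anomalous-mappability (blacklisted)
regions at the genomic level, and by the bulk spatial clustering of
centromeres and telomeres in the nucleus. Deciding whether any *specific*,
potentially gene-regulatory trans contact exists in a cell population
therefore requires an explicit chain of filters, each of which this
package implements as a tested, reusable step:

1. **Read-pair filtering** (`transhic.pairs`) — reads spanning the
   ligation signature (e.g. `GATCGATC` for MboI) are split; each mate is
   assigned to its restriction fragment; pairs are classified in a fixed
   precedence order as unmapped / low-MAPQ (< 10) / duplicate /
   same-fragment / dangling end (inward-facing, short separation) /
   self-circle (outward-facing, short separation) / off-site digestion
   (pair fragment size > 1200 bp) / keep. A chimeric-alignment error rate
   is estimated from the 3' segments of split reads.
2. **Binning** (`transhic.bins`) — kept pairs are counted into ~50 kbp bin
   pairs whose boundaries are snapped to the nearest restriction site or
   blacklist edge; mitochondrial and unplaced-scaffold pairs are excluded;
   bin pairs are stored sparsely in canonical order with one count vector
   per library.
3. **Loop calling** (`transhic.enrichment`) — for each bin pair the
   cross-library mean count is compared to four surrounding neighborhoods
   in its interaction plane (quadrant toward the diagonal, horizontal and
   vertical stripes, centred square; half-width x = 5 bins). The
   *enrichment value* is the minimum log2 fold change over the
   neighborhoods, so a call must exceed **all** of its surroundings:

   ```
   enrichment(t) = min_N  log2( (y_t + 0.5) / (mean_{N \ {t}} y + 0.5) )
   ```

   Putative loops: enrichment > 0.5, mean count > 10, more than 1 bin off
   the diagonal (all strict).
4. **Annotation** (`transhic.annotate`) — calls with an anchor overlapping
   ENCODE-style blacklist regions, centromeres, or telomeres are flagged
   and removed; normalized end-distance profiles (anchor midpoint distance
   to the nearest telomere or to the centromere, divided by chromosome
   length) show whether the surviving trans contacts simply track
   chromosome-end clustering.
5. **Comparison** (`transhic.compare`) — interaction sets from several
   cell populations are partitioned into common vs lineage-specific calls
   (bin-pair overlap: both anchor gaps <= 100 kb), lineage-specific calls
   are overlaid on gene expression (expressed = RPKM > 5, strict) and
   differential-expression flags, and mapped through an orthology table to
   test cross-species conservation.

The synthetic generator (`transhic.simulate`) produces genomes,
restriction maps, blacklists, artifact-bearing read-pair libraries with
ground-truth labels, Poisson contact maps with a power-law cis
distance-decay background, uniform trans background, sub-telomeric /
sub-centromeric clustering, planted loops of configurable fold, and
lineage-structured expression tables — every downstream stage is testable
without external data.

## Worked example

Plant a single 20-fold trans contact on a background map (two 10 Mb
chromosomes, 1/d cis decay, Poisson(1) trans background, two libraries)
and call loops with the default thresholds:

```python
from transhic import (PipelineConfig, SimulationSpec, build_bins,
                      call_putative_loops, simulate_binned_contacts,
                      simulate_genome)

cfg = PipelineConfig()                       # standard defaults
spec = SimulationSpec(seed=7)                # two 10 Mb chromosomes
layout, blacklist, cen, tel = simulate_genome(spec)
grid = build_bins(layout, blacklist, cfg.bin_width)

# plant one 20-fold trans contact on an exact bin pair
a = grid.bins[grid.bin_id("chr1", 5_000_000)]
b = grid.bins[grid.bin_id("chr2", 5_000_000)]
spec.planted_loops = [(a, b, 20.0)]

counts = simulate_binned_contacts(
    layout, {"telomere": tel, "centromere": cen}, spec, grid)
calls = call_putative_loops(counts, cfg=cfg)
for c in calls:
    print(f"{c.anchor1.chrom}:{c.anchor1.start}-{c.anchor1.end} x "
          f"{c.anchor2.chrom}:{c.anchor2.start}-{c.anchor2.end}  "
          f"mean={c.mean_count:.1f}  enrichment={c.enrichment:.2f}  "
          f"trans={c.is_trans}")
```

Output:

```
chr1:4999739-5050660 x chr2:4949606-5000070  mean=19.0  enrichment=3.69  trans=True
```

Exactly the planted bin pair is called (bin edges sit on restriction
sites, hence the non-round coordinates): its mean count of ~19 is the
planted 20-fold excess over the Poisson(1) background, and the enrichment
of 3.69 log2 units says the pair exceeds every one of its neighborhoods
by more than 12-fold. Nothing else on the ~40,000-pixel trans plane
passes.

## The analysis

`analysis/` contains numbered drivers that run the full narrative on a
simulated three-lineage immune-cell cohort (B, CD4, CD8):

| script | what it does |
| --- | --- |
| `01_simulate_cohort.py` | genome + annotations + per-lineage contact maps with shared/private planted loops and telomeric clustering |
| `02_filter_read_pairs.py` | read-pair library simulation and artifact filtering |
| `03_detect_interactions.py` | per-lineage loop calling, planted-loop recovery |
| `04_annotate_interactions.py` | blacklist/centromere/telomere removal, end-distance profiles |
| `05_compare_lineages.py` | common/unique partition, expression association, cross-species check |

Run them in order (`python analysis/01_simulate_cohort.py` …); outputs
land under `results/`. On this cohort the detector recovers every planted
loop; the majority of its trans calls track the planted telomeric
clustering and are removed by the annotation step, reproducing the
qualitative behaviour the pipeline is designed to expose.

A thin CLI mirrors the same steps on files:
`transhic simulate | process-pairs | detect | annotate | compare`.

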