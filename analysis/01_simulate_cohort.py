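#!/usr/bin/env python
"""Simulate a three-lineage immune-cell Hi-C cohort.

Generates one synthetic genome (two 40 Mb chromosomes, MboI-like sites,
blacklist/centromere/telomere annotations) and, per lineage (B, CD4, CD8),
a binned two-library contact map containing: the shared cis/trans
background, sub-telomeric trans clustering (fold 8 over 1 Mb ends), five
trans loops shared by all lineages, and a private set of trans loops per
lineage (3 for B, 8 for CD8, 4 for CD4). Writes everything under
results/sim/.
"""

from pathlib import Path

from transhic import PipelineConfig, SimulationSpec, simulate_binned_contacts, simulate_genome
from transhic import io as tio
from transhic.bins import build_bins
from transhic.simulate import ClusterSpec, simulate_lineage_interaction_sets

OUT = Path(__file__).resolve().parent.parent / "results" / "sim"
SEED = 20240901
PRIVATE = {"B": 3, "CD8": 8, "CD4": 4}


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = PipelineConfig()
    spec = SimulationSpec(
        seed=SEED,
        chrom_length=40_000_000,
        telomere_cluster=ClusterSpec(width=1_000_000, fold=8.0),
    )
    layout, blacklist, centromere, telomere = simulate_genome(spec)
    grid = build_bins(layout, blacklist, cfg.bin_width)
    tio.write_chrom_sizes(layout, OUT / "chrom.sizes")
    tio.write_sites(layout, OUT / "sites.tsv")
    tio.write_bed(blacklist, OUT / "blacklist.bed")
    tio.write_bed(centromere, OUT / "centromere.bed")
    tio.write_bed(telomere, OUT / "telomere.bed")
    tio.write_bin_table(grid, OUT / "bins.tsv")

    # planted truth: 5 shared + private trans loops per lineage
    planted = simulate_lineage_interaction_sets(
        layout, n_shared=5, private_counts=PRIVATE, seed=SEED
    )
    for lineage, interactions in planted.items():
        tio.write_interactions_bedpe(interactions, OUT / f"truth_{lineage}.bedpe")
        lin_spec = SimulationSpec(
            seed=SEED + {"B": 1, "CD8": 2, "CD4": 3}[lineage],
            chrom_length=spec.chrom_length,
            telomere_cluster=spec.telomere_cluster,
            planted_loops=[
                (it.anchor1, it.anchor2, 25.0) for it in interactions
            ],
        )
        counts = simulate_binned_contacts(
            layout,
            {"telomere": telomere, "centromere": centromere},
            lin_spec,
            grid,
        )
        tio.write_counts(counts, OUT / f"counts_{lineage}.tsv")
        print(
            f"{lineage}: {len(interactions)} planted loops "
            f"({PRIVATE[lineage]} private), {counts.n_entries} bin pairs, "
            f"{counts.total()} total counts"
        )
    print(f"genome: {len(grid)} bins, blacklist covers "
          f"{blacklist.total_length() / (2 * spec.chrom_length):.3f} of the genome")
    print(f"wrote cohort to {OUT}")


if __name__ == "__main__":
    main()
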