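"""Reusable synthetic studies exercising the whole pipeline.

Each study wires the generator to the detector under a fixed set of study
conditions and measures an operating characteristic of the method: false
trans calls on pure background, recovery of a single planted trans loop,
and recovery of planted sub-telomeric trans clustering in the normalized
end-distance profiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .annotate import end_distance_profile
from .bins import build_bins
from .config import PipelineConfig
from .enrichment import call_putative_loops
from .genome import Region
from .simulate import ClusterSpec, SimulationSpec, simulate_binned_contacts, simulate_genome


def _detect(spec: SimulationSpec, cfg: PipelineConfig):
    layout, blacklist, cen, tel = simulate_genome(spec)
    grid = build_bins(layout, blacklist, cfg.bin_width)
    counts = simulate_binned_contacts(
        layout, {"telomere": tel, "centromere": cen}, spec, grid
    )
    calls = call_putative_loops(counts, cfg=cfg)
    return layout, grid, cen, calls


def null_trans_calls(seed: int, cfg: PipelineConfig | None = None) -> int:
    """Number of trans interactions called on a pure-background genome
    (two 10 Mb chromosomes, 1/d cis decay, Poisson(1) trans, 2 libraries).
    """
    cfg = cfg or PipelineConfig()
    spec = SimulationSpec(seed=seed)
    _, _, _, calls = _detect(spec, cfg)
    return sum(1 for c in calls if c.is_trans)


@dataclass
class PlantedLoopOutcome:
    called: bool
    is_top_trans: bool
    enrichment: float


def planted_loop_recovery(
    seed: int, fold: float = 20.0, cfg: PipelineConfig | None = None
) -> PlantedLoopOutcome:
    """Plant one fold-``fold`` trans loop on a single bin pair over the
    default background and ask whether it is called, and whether it is the
    top-enrichment trans call."""
    cfg = cfg or PipelineConfig()
    spec = SimulationSpec(seed=seed)
    layout, blacklist, cen, tel = simulate_genome(spec)
    grid = build_bins(layout, blacklist, cfg.bin_width)
    target1 = grid.bins[grid.bin_id("chr1", layout.length("chr1") // 2)]
    target2 = grid.bins[grid.bin_id("chr2", layout.length("chr2") // 2)]
    spec.planted_loops = [(target1, target2, fold)]
    counts = simulate_binned_contacts(
        layout, {"telomere": tel, "centromere": cen}, spec, grid
    )
    calls = call_putative_loops(counts, cfg=cfg)
    trans = [c for c in calls if c.is_trans]
    planted = [
        c for c in trans if c.anchor1 == target1 and c.anchor2 == target2
    ]
    if not planted:
        return PlantedLoopOutcome(False, False, float("nan"))
    top = max(trans, key=lambda c: c.enrichment)
    return PlantedLoopOutcome(
        True,
        top.anchor1 == target1 and top.anchor2 == target2,
        planted[0].enrichment,
    )


@dataclass
class TelomereRecoveryOutcome:
    trans_median: float
    cis_median: float
    n_trans_calls: int
    n_cis_calls: int


def _random_cis_loops(
    layout, n_per_chrom: int, seed: int, bin_width: int,
    sep_bins: tuple[int, int] = (5, 40), fold: float = 50.0,
) -> list[tuple[Region, Region, float]]:
    """Bin-sized cis loops at uniform positions with loop-scale anchor
    separations, the genome-wide cis structure real maps carry."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 929]))
    loops = []
    for chrom in layout.names:
        n_bins = layout.length(chrom) // bin_width
        for _ in range(n_per_chrom):
            sep = int(rng.integers(sep_bins[0], sep_bins[1] + 1))
            i = int(rng.integers(0, n_bins - sep - 1))
            a = Region(chrom, i * bin_width, (i + 1) * bin_width)
            b = Region(chrom, (i + sep) * bin_width, (i + sep + 1) * bin_width)
            loops.append((a, b, fold))
    return loops


def telomere_clustering_recovery(
    seed: int,
    chrom_length: int = 100_000_000,
    telomere_width: int = 2_000_000,
    telomere_fold: float = 10.0,
    cis_loops_per_chrom: int = 30,
    cfg: PipelineConfig | None = None,
) -> TelomereRecoveryOutcome:
    """Sub-telomeric trans clustering plus genome-wide cis loops: the trans
    end-distance profile should concentrate near 0 while the cis profile
    stays spread along the chromosome."""
    cfg = cfg or PipelineConfig()
    spec = SimulationSpec(
        seed=seed,
        chrom_length=chrom_length,
        telomere_cluster=ClusterSpec(width=telomere_width, fold=telomere_fold),
    )
    layout, blacklist, cen, tel = simulate_genome(spec)
    spec.planted_loops = _random_cis_loops(
        layout, cis_loops_per_chrom, seed, cfg.bin_width
    )
    grid = build_bins(layout, blacklist, cfg.bin_width)
    counts = simulate_binned_contacts(
        layout, {"telomere": tel, "centromere": cen}, spec, grid
    )
    calls = call_putative_loops(counts, cfg=cfg)
    trans_prof, cis_prof, _ = end_distance_profile(
        calls, layout, cen, reference="telomere"
    )
    return TelomereRecoveryOutcome(
        trans_prof.median,
        cis_prof.median,
        trans_prof.values.size // 2,
        cis_prof.values.size // 2,
    )
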