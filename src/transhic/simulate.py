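"""Synthetic Hi-C data with the statistical structure the analysis assumes.

The generators emulate, at desk scale, the features of real Hi-C libraries
that the pipeline is built to exploit or reject: a power-law cis
distance-decay background, a uniform Poisson trans background, optional
sub-telomeric/sub-centromeric trans clustering (multiplicative fold on the
trans background where both anchors fall in the chromosome-end regions of
different chromosomes), planted point-like loops of configurable fold,
artifact-bearing read-pair libraries with unambiguous ground-truth labels,
and lineage-structured expression tables.

Every generator is a pure function of its spec and seed. Per-library count
draws use split RNG streams so changing ``n_libraries`` never perturbs
earlier libraries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bins import BinGrid, BinPairCounts, dense_plane_to_sparse
from .config import PipelineConfig
from .enrichment import Interaction
from .genome import GenomeLayout, Region, RegionSet
from .pairs import Mate, PairClass, ReadPairRecord, assign_fragment


@dataclass
class ClusterSpec:
    """Sub-end trans clustering: chromosome-end width (bp) and the
    multiplicative fold applied to the trans background."""

    width: int = 500_000
    fold: float = 1.0


@dataclass
class ArtifactFractions:
    """Planted artifact composition of a simulated read-pair library.

    Defaults give a kept fraction of 0.70, at the low end of the 70-75%
    assignment rate typical of in situ Hi-C libraries.
    """

    low_mapq: float = 0.08
    duplicate: float = 0.05
    same_fragment: float = 0.04
    dangling_end: float = 0.08
    self_circle: float = 0.02
    offsite_digestion: float = 0.03

    def total(self) -> float:
        return (
            self.low_mapq
            + self.duplicate
            + self.same_fragment
            + self.dangling_end
            + self.self_circle
            + self.offsite_digestion
        )


@dataclass
class SimulationSpec:
    """Study conditions for the synthetic genome and contact maps.

    Defaults describe the baseline desk-scale condition used throughout
    the test battery: two 10 Mb chromosomes, MboI-like restriction-site
    spacing, a 1/distance cis background with 10 expected counts at 1-bin
    separation, a uniform Poisson(1) trans background, no clustering and
    no planted loops, two libraries.
    """

    n_chroms: int = 2
    chrom_length: int = 10_000_000
    site_spacing_mean: int = 400          # bp; MboI (GATC) cuts every ~256-400 bp
    cis_decay_exponent: float = 1.0       # contact probability ~ distance^-alpha
    cis_rate: float = 10.0                # expected counts at 1-bin separation
    trans_background_rate: float = 1.0    # expected counts per trans bin pair
    telomere_cluster: ClusterSpec = field(default_factory=ClusterSpec)
    centromere_cluster: ClusterSpec = field(default_factory=ClusterSpec)
    centromere_offset: int = 0            # bp from chromosome start (acrocentric)
    planted_loops: list[tuple[Region, Region, float]] = field(default_factory=list)
    blacklist_fraction: float = 0.05
    blacklist_interval: int = 50_000      # bp, length of each drawn interval
    n_libraries: int = 2
    lineages: list[str] = field(default_factory=lambda: ["B", "CD4", "CD8"])
    artifact_fractions: ArtifactFractions = field(default_factory=ArtifactFractions)
    n_read_pairs: int = 2_000
    chimera_fraction: float = 0.2         # records carrying an evaluable 3' segment
    chimera_error_rate: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.n_chroms < 1 or self.chrom_length <= 0:
            raise ValueError("need >= 1 chromosome of positive length")
        if self.cis_decay_exponent <= 0:
            raise ValueError("cis decay exponent must be > 0")
        for r in (self.cis_rate, self.trans_background_rate):
            if r < 0:
                raise ValueError("rates must be >= 0")
        for c in (self.telomere_cluster, self.centromere_cluster):
            if c.fold < 1:
                raise ValueError("cluster folds must be >= 1")
        for _, _, fold in self.planted_loops:
            if fold < 1:
                raise ValueError("loop folds must be >= 1")
        if not (0 <= self.blacklist_fraction < 1):
            raise ValueError("blacklist_fraction must be in [0, 1)")
        if self.artifact_fractions.total() > 1:
            raise ValueError("artifact fractions must sum to <= 1")
        if 2 * self.telomere_cluster.width > self.chrom_length:
            raise ValueError("chromosome shorter than its telomere annotations")
        if (
            self.centromere_offset + self.centromere_cluster.width
            > self.chrom_length
        ):
            raise ValueError("centromere annotation exceeds chromosome")


def simulate_genome(
    spec: SimulationSpec,
) -> tuple[GenomeLayout, RegionSet, RegionSet, RegionSet]:
    """Generate a layout plus blacklist/centromere/telomere annotations.

    Restriction sites follow a Poisson process with the given mean spacing;
    telomeres are the first/last ``telomere_cluster.width`` bp of every
    chromosome; one centromere per chromosome sits at ``centromere_offset``
    (chromosome start by default, matching acrocentric mouse karyotypes);
    blacklist intervals of fixed length are dropped uniformly to cover
    about ``blacklist_fraction`` of the genome (merged, so the realised
    coverage is marginally below the nominal target).
    """
    spec.validate()
    ss = np.random.SeedSequence(spec.seed)
    chrom_seeds = ss.spawn(spec.n_chroms)
    chroms = [(f"chr{i + 1}", spec.chrom_length) for i in range(spec.n_chroms)]
    sites: dict[str, np.ndarray] = {}
    blacklist: list[Region] = []
    centromere: list[Region] = []
    telomere: list[Region] = []
    for (name, length), cseed in zip(chroms, chrom_seeds):
        rng = np.random.default_rng(cseed)
        n_exp = int(2 * length / spec.site_spacing_mean) + 10
        gaps = rng.exponential(spec.site_spacing_mean, size=n_exp)
        pos = np.cumsum(gaps)
        pos = np.unique(pos[pos < length].astype(np.int64))
        sites[name] = pos[(pos > 0) & (pos < length)]
        w = spec.telomere_cluster.width
        if w > 0:
            telomere.append(Region(name, 0, w))
            telomere.append(Region(name, length - w, length))
        cw = spec.centromere_cluster.width
        if cw > 0:
            centromere.append(
                Region(name, spec.centromere_offset, spec.centromere_offset + cw)
            )
        if spec.blacklist_fraction > 0:
            n_iv = int(round(spec.blacklist_fraction * length / spec.blacklist_interval))
            starts = rng.integers(0, length - spec.blacklist_interval, size=n_iv)
            for s in np.sort(starts):
                blacklist.append(Region(name, int(s), int(s) + spec.blacklist_interval))
    layout = GenomeLayout(chroms, sites=sites)
    return (
        layout,
        RegionSet("blacklist", blacklist),
        RegionSet("centromere", centromere),
        RegionSet("telomere", telomere),
    )


def _end_mask(grid: BinGrid, chrom: str, regions: RegionSet) -> np.ndarray:
    """Boolean per-bin mask: bin midpoint inside a region of the set."""
    lo, hi = grid.chrom_ranges[chrom]
    mask = np.zeros(hi - lo, dtype=bool)
    for k, b in enumerate(grid.bins[lo:hi]):
        mid = Region(chrom, int(b.midpoint), int(b.midpoint) + 1)
        mask[k] = regions.overlaps(mid)
    return mask


def _loop_cells(
    grid: BinGrid, chrom1: str, chrom2: str, loop: tuple[Region, Region, float]
) -> list[tuple[int, int, float]]:
    """Local (i, j, fold) cells of this plane touched by a planted loop."""
    a, b, fold = loop
    pairs = []
    for first, second in ((a, b), (b, a)):
        if first.chrom == chrom1 and second.chrom == chrom2:
            pairs.append((first, second))
        if chrom1 == chrom2 and first.chrom == chrom1 and second.chrom == chrom1:
            break  # cis: one orientation suffices, cells are canonicalised below
    cells = []
    for first, second in pairs:
        try:
            i0 = grid.local_index(grid.bin_id(chrom1, first.start))
            i1 = grid.local_index(grid.bin_id(chrom1, first.end - 1))
            j0 = grid.local_index(grid.bin_id(chrom2, second.start))
            j1 = grid.local_index(grid.bin_id(chrom2, second.end - 1))
        except (KeyError, ValueError) as exc:
            raise ValueError(f"planted loop anchor not on grid: {exc}") from exc
        for i in range(i0, i1 + 1):
            for j in range(j0, j1 + 1):
                if chrom1 == chrom2 and i > j:
                    i, j = j, i
                cells.append((i, j, fold))
    return cells


def simulate_binned_contacts(
    layout: GenomeLayout,
    annotations: dict[str, RegionSet],
    spec: SimulationSpec,
    grid: BinGrid,
) -> BinPairCounts:
    """Draw per-library Poisson counts over every chromosome-pair plane.

    Cis means follow ``cis_rate * sep^-alpha`` (a self pair, separation 0,
    uses the separation-1 mean; it is never callable anyway). Trans means
    are uniform at ``trans_background_rate``, multiplied by the telomere or
    centromere fold where both anchors' bins fall in the respective
    chromosome-end regions of different chromosomes, and by the loop fold
    over bin pairs containing a planted loop.
    """
    spec.validate()
    libraries = [f"lib{i}" for i in range(spec.n_libraries)]
    lib_seeds = np.random.SeedSequence(spec.seed).spawn(spec.n_libraries)
    lib_rngs = [np.random.default_rng(s) for s in lib_seeds]
    names = layout.names
    tel = annotations.get("telomere")
    cen = annotations.get("centromere")
    tel_masks = {
        c: _end_mask(grid, c, tel) if tel is not None else None for c in names
    }
    cen_masks = {
        c: _end_mask(grid, c, cen) if cen is not None else None for c in names
    }

    all_b1, all_b2, all_counts = [], [], []
    for k1, c1 in enumerate(names):
        for c2 in names[k1:]:
            n1, n2 = grid.n_bins(c1), grid.n_bins(c2)
            if c1 == c2:
                idx = np.arange(n1)
                sep = np.abs(idx[:, None] - idx[None, :]).astype(np.float64)
                sep[sep == 0] = 1.0
                mu = spec.cis_rate * sep ** (-spec.cis_decay_exponent)
            else:
                mu = np.full((n1, n2), spec.trans_background_rate)
                if spec.telomere_cluster.fold > 1 and tel_masks[c1] is not None:
                    block = np.outer(tel_masks[c1], tel_masks[c2])
                    mu[block] *= spec.telomere_cluster.fold
                if spec.centromere_cluster.fold > 1 and cen_masks[c1] is not None:
                    block = np.outer(cen_masks[c1], cen_masks[c2])
                    mu[block] *= spec.centromere_cluster.fold
            for loop in spec.planted_loops:
                for i, j, fold in _loop_cells(grid, c1, c2, loop):
                    mu[i, j] *= fold
            if not np.any(mu > 0):
                continue
            draws = [rng.poisson(mu) for rng in lib_rngs]
            b1, b2, cnt = dense_plane_to_sparse(grid, c1, c2, draws)
            if b1.size:
                all_b1.append(b1)
                all_b2.append(b2)
                all_counts.append(cnt)
    if not all_b1:
        return BinPairCounts(grid, libraries)
    return BinPairCounts(
        grid,
        libraries,
        np.concatenate(all_b1),
        np.concatenate(all_b2),
        np.concatenate(all_counts),
    )


def _clean_mate(
    rng: np.random.Generator, layout: GenomeLayout, cfg: PipelineConfig, chrom: str
) -> Mate:
    """A mate whose 5' position sits near the fragment end it points away
    from, so its frag_end_dist is at most half the off-site threshold."""
    length = layout.length(chrom)
    b = np.concatenate([[0], layout.sites[chrom], [length]])
    for _ in range(200):
        k = int(rng.integers(0, b.size - 1))
        lo, hi = int(b[k]), int(b[k + 1])
        if hi - lo < 2:
            continue
        max_off = min(hi - lo - 1, cfg.max_frag // 2)
        off = int(rng.integers(1, max_off + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        pos = hi - off if strand == "+" else lo + off
        frag, dist = assign_fragment(layout, chrom, pos, strand)
        return Mate(chrom, pos, strand, int(rng.integers(30, 42)), frag, dist)
    raise RuntimeError(f"no fragment of usable length on {chrom}")


def _random_clean_mates(
    rng: np.random.Generator, layout: GenomeLayout, cfg: PipelineConfig
) -> tuple[Mate, Mate]:
    """A valid di-tag (cannot hit any geometry filter)."""
    names = layout.names
    for _ in range(200):
        if len(names) >= 2:
            ca, cb = rng.choice(len(names), size=2, replace=False)
            c1, c2 = names[ca], names[cb]
        else:
            c1 = c2 = names[0]
        m1 = _clean_mate(rng, layout, cfg, c1)
        m2 = _clean_mate(rng, layout, cfg, c2)
        if c1 == c2 and (
            abs(m2.pos5 - m1.pos5) < max(cfg.min_inward, cfg.min_outward)
            or (m1.frag == m2.frag and m1.strand == m2.strand)
        ):
            continue
        return m1, m2
    raise RuntimeError("failed to draw a clean read pair; sites too sparse")


def _fragments(layout: GenomeLayout, chrom: str) -> np.ndarray:
    sites = layout.sites[chrom]
    b = np.concatenate([[0], sites, [layout.length(chrom)]])
    return np.column_stack([b[:-1], b[1:]])


def simulate_read_pairs(
    layout: GenomeLayout,
    spec: SimulationSpec,
    cfg: PipelineConfig | None = None,
) -> tuple[list[ReadPairRecord], list[str]]:
    """A labelled mixture of valid and artifact di-tags.

    Per-class counts are fixed (rounded from the spec fractions) so planted
    compositions are recovered exactly; each artifact's geometry is
    constructed to satisfy its definition unambiguously. Returns the
    records and the parallel ground-truth labels (PairClass values).
    A ``chimera_fraction`` of records carries an evaluable 3' chimeric
    segment, of which ``chimera_error_rate`` are planted mapping errors.
    """
    spec.validate()
    cfg = cfg or PipelineConfig()
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(1)[0])
    n = spec.n_read_pairs
    af = spec.artifact_fractions
    plan: list[tuple[str, int]] = [
        (PairClass.LOW_MAPQ.value, round(n * af.low_mapq)),
        (PairClass.DUPLICATE.value, round(n * af.duplicate)),
        (PairClass.SAME_FRAGMENT.value, round(n * af.same_fragment)),
        (PairClass.DANGLING_END.value, round(n * af.dangling_end)),
        (PairClass.SELF_CIRCLE.value, round(n * af.self_circle)),
        (PairClass.OFFSITE_DIGESTION.value, round(n * af.offsite_digestion)),
    ]
    n_art = sum(c for _, c in plan)
    plan.append((PairClass.KEEP.value, n - n_art))

    records: list[ReadPairRecord] = []
    labels: list[str] = []
    names = layout.names
    long_frags: list[tuple[str, int, int]] = []  # (chrom, lo, hi) sorted by len desc
    for c in names:
        for lo, hi in _fragments(layout, c):
            long_frags.append((c, int(lo), int(hi)))
    long_frags.sort(key=lambda t: t[2] - t[1], reverse=True)

    def make(label: str) -> ReadPairRecord:
        if label == PairClass.KEEP.value:
            m1, m2 = _random_clean_mates(rng, layout, cfg)
            return ReadPairRecord(m1, m2)
        if label == PairClass.LOW_MAPQ.value:
            m1, m2 = _random_clean_mates(rng, layout, cfg)
            bad = Mate(m1.chrom, m1.pos5, m1.strand,
                       int(rng.integers(0, cfg.mapq_min)), m1.frag, m1.frag_end_dist)
            return ReadPairRecord(bad, m2)
        if label == PairClass.DUPLICATE.value:
            m1, m2 = _random_clean_mates(rng, layout, cfg)
            return ReadPairRecord(m1, m2, dup=True)
        if label == PairClass.SAME_FRAGMENT.value:
            for c, lo, hi in long_frags:
                if hi - lo >= 4:
                    p1 = int(rng.integers(lo, hi - 1))
                    p2 = int(rng.integers(lo, hi))
                    s = str(rng.choice(["+", "-"]))
                    f1, d1 = assign_fragment(layout, c, p1, s)
                    f2, d2 = assign_fragment(layout, c, p2, s)
                    m1 = Mate(c, p1, s, int(rng.integers(30, 42)), f1, d1)
                    m2 = Mate(c, p2, s, int(rng.integers(30, 42)), f2, d2)
                    return ReadPairRecord(m1, m2)
            raise RuntimeError("no fragment long enough for a same-fragment pair")
        if label == PairClass.DANGLING_END.value:
            c = str(rng.choice(names))
            sep = int(rng.integers(10, max(11, cfg.min_inward)))
            p1 = int(rng.integers(0, layout.length(c) - sep - 1))
            f1, d1 = assign_fragment(layout, c, p1, "+")
            f2, d2 = assign_fragment(layout, c, p1 + sep, "-")
            m1 = Mate(c, p1, "+", int(rng.integers(30, 42)), f1, d1)
            m2 = Mate(c, p1 + sep, "-", int(rng.integers(30, 42)), f2, d2)
            return ReadPairRecord(m1, m2)
        if label == PairClass.SELF_CIRCLE.value:
            c = str(rng.choice(names))
            sep = int(rng.integers(10, max(11, cfg.min_outward)))
            p1 = int(rng.integers(0, layout.length(c) - sep - 1))
            f1, d1 = assign_fragment(layout, c, p1, "-")
            f2, d2 = assign_fragment(layout, c, p1 + sep, "+")
            m1 = Mate(c, p1, "-", int(rng.integers(30, 42)), f1, d1)
            m2 = Mate(c, p1 + sep, "+", int(rng.integers(30, 42)), f2, d2)
            return ReadPairRecord(m1, m2)
        if label == PairClass.OFFSITE_DIGESTION.value:
            # place each mate at the start (+ strand) of a long fragment so
            # the pair fragment size is the sum of the fragment lengths
            for k in range(len(long_frags) - 1):
                c1, lo1, hi1 = long_frags[k]
                c2, lo2, hi2 = long_frags[k + 1]
                if (hi1 - lo1) + (hi2 - lo2) > cfg.max_frag and (
                    c1 != c2 or len(names) == 1
                ):
                    f1, d1 = assign_fragment(layout, c1, lo1, "+")
                    f2, d2 = assign_fragment(layout, c2, lo2, "+")
                    m1 = Mate(c1, lo1, "+", int(rng.integers(30, 42)), f1, d1)
                    m2 = Mate(c2, lo2, "+", int(rng.integers(30, 42)), f2, d2)
                    if c1 == c2 and f1 == f2:
                        continue
                    return ReadPairRecord(m1, m2)
            raise RuntimeError("no fragment pair long enough for off-site class")
        raise ValueError(f"unknown class {label}")

    for label, count in plan:
        for _ in range(count):
            records.append(make(label))
            labels.append(label)

    # attach evaluable chimeric segments
    n_chim = round(len(records) * spec.chimera_fraction)
    n_err = round(n_chim * spec.chimera_error_rate)
    chim_idx = rng.choice(len(records), size=n_chim, replace=False)
    for k, idx in enumerate(chim_idx):
        rec = records[idx]
        mate = rec.mate2
        if mate.chrom is None:
            continue
        if k < n_err:
            other = next((c for c in names if c != mate.chrom), mate.chrom)
            if other != mate.chrom:
                chim = (other, int(rng.integers(0, layout.length(other))), "+")
            else:  # single chromosome: plant an outward (wrong) orientation
                chim = (mate.chrom, max(0, mate.pos5 - 200), "-")
        else:
            sep = int(rng.integers(50, cfg.chim_dist))
            if mate.strand == "-":
                chim = (mate.chrom, max(0, mate.pos5 - sep), "+")
            else:
                chim = (mate.chrom, mate.pos5 + sep, "-")
        records[idx] = ReadPairRecord(rec.mate1, rec.mate2, rec.dup, chim, rec.lib)
    # shuffle so classes are interleaved, keeping labels aligned
    order = rng.permutation(len(records))
    return [records[i] for i in order], [labels[i] for i in order]


def simulate_genes(
    layout: GenomeLayout,
    n_genes: int,
    gene_length: int = 20_000,
    seed: int = 0,
) -> RegionSet:
    """Uniformly placed fixed-length gene models with stable ids."""
    rng = np.random.default_rng(seed)
    regions, names = [], []
    for k in range(n_genes):
        c = layout.names[int(rng.integers(0, len(layout.names)))]
        start = int(rng.integers(0, layout.length(c) - gene_length))
        regions.append(Region(c, start, start + gene_length))
        names.append(f"gene{k}")
    return RegionSet("gene", regions, names)


def simulate_expression(
    layout: GenomeLayout,
    genes: RegionSet,
    lineages: list[str],
    de_spec: dict[str, tuple[float, tuple[str, float] | None]],
    seed: int = 0,
    sigma: float = 0.25,
) -> pd.DataFrame:
    """Log-normal RPKM values around per-gene means, with DE effects.

    ``de_spec`` maps gene id -> (base RPKM, optional (lineage, fold) DE
    effect). Values are drawn as ``mean * exp(sigma*Z - sigma^2/2)`` so the
    expectation equals the specified mean; a base of exactly 0 yields 0 in
    every lineage and no DE flag. ``de_<lineage>`` is True exactly for
    genes given a DE effect in that lineage.
    """
    if genes.names is None:
        raise ValueError("gene RegionSet must carry names")
    genes.validate_against(layout)
    for gid, (_, effect) in de_spec.items():
        if effect is not None and effect[0] not in lineages:
            raise ValueError(f"unknown lineage {effect[0]!r} in DE spec for {gid}")
    rng = np.random.default_rng(seed)
    rows = []
    for region, gid in zip(genes.regions, genes.names):
        base, effect = de_spec.get(gid, (0.0, None))
        row: dict[str, object] = {
            "gene_id": gid,
            "chrom": region.chrom,
            "start": region.start,
            "end": region.end,
        }
        for lin in lineages:
            mean = base
            if effect is not None and effect[0] == lin:
                mean = base * effect[1]
            if mean <= 0:
                row[f"rpkm_{lin}"] = 0.0
            else:
                z = rng.standard_normal()
                row[f"rpkm_{lin}"] = mean * float(np.exp(sigma * z - sigma**2 / 2))
        for lin in lineages:
            row[f"de_{lin}"] = bool(
                base > 0 and effect is not None and effect[0] == lin
            )
        rows.append(row)
    return pd.DataFrame(rows)


def simulate_lineage_interaction_sets(
    layout: GenomeLayout,
    n_shared: int,
    private_counts: dict[str, int],
    anchor_width: int = 50_000,
    min_separation: int = 1_200_000,
    seed: int = 0,
) -> dict[str, list[Interaction]]:
    """Trans interaction sets with planted shared/private structure.

    ``n_shared`` loops appear identically in every lineage; each lineage
    additionally gets its private loops. All anchors sit on a lattice with
    at least ``min_separation`` between distinct anchor positions, so
    bin-pair overlap at the default maxgap recovers the planted partition
    exactly.
    """
    if len(layout.names) < 2:
        raise ValueError("need >= 2 chromosomes for trans interaction sets")
    rng = np.random.default_rng(seed)
    c1, c2 = layout.names[0], layout.names[1]
    n_total = n_shared + sum(private_counts.values())
    slots1 = np.arange(0, layout.length(c1) - anchor_width, min_separation)
    slots2 = np.arange(0, layout.length(c2) - anchor_width, min_separation)
    if n_total > min(slots1.size, slots2.size):
        raise ValueError("chromosomes too short for the requested loop count")
    pick1 = rng.choice(slots1, size=n_total, replace=False)
    pick2 = rng.choice(slots2, size=n_total, replace=False)

    def loop(k: int) -> Interaction:
        a = Region(c1, int(pick1[k]), int(pick1[k]) + anchor_width)
        b = Region(c2, int(pick2[k]), int(pick2[k]) + anchor_width)
        return Interaction(a, b, mean_count=20.0, enrichment=2.0, is_trans=True)

    shared = [loop(k) for k in range(n_shared)]
    out: dict[str, list[Interaction]] = {}
    k = n_shared
    for lin, cnt in private_counts.items():
        private = [loop(k + j) for j in range(cnt)]
        k += cnt
        out[lin] = [
            Interaction(s.anchor1, s.anchor2, s.mean_count, s.enrichment, s.is_trans)
            for s in shared
        ] + private
    return out
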