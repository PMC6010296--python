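"""Cross-lineage comparison of interaction sets, expression association,
and cross-species conservation through an orthology map.

Two bin pairs overlap when both anchor1-anchor1 and anchor2-anchor2 gaps
are within ``maxgap`` (anchors on different chromosomes are infinitely far
apart; overlapping or abutting anchors have gap 0). An interaction is
unique ("lineage-specific") when it overlaps no interaction called in any
other lineage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .config import PipelineConfig
from .enrichment import Interaction
from .genome import Region, RegionSet


def region_gap(a: Region, b: Region) -> float:
    """Gap in bp between two half-open regions: 0 when they overlap or
    abut, inf when on different chromosomes."""
    if a.chrom != b.chrom:
        return math.inf
    if a.start < b.end and b.start < a.end:
        return 0.0
    return float(max(a.start, b.start) - min(a.end, b.end))


def binpair_overlap(a: Interaction, b: Interaction, maxgap: int = 100_000) -> bool:
    """Equal-type bin-pair overlap: both same-slot anchor gaps <= maxgap.

    Anchors are compared in canonical order only (anchor1 with anchor1,
    anchor2 with anchor2); symmetric and reflexive.
    """
    return (
        region_gap(a.anchor1, b.anchor1) <= maxgap
        and region_gap(a.anchor2, b.anchor2) <= maxgap
    )


@dataclass
class LineagePartition:
    """Interactions grouped by the exact set of lineages they occur in.

    ``cells`` maps a sorted lineage tuple to the overlap groups assigned to
    it: each group is one interaction cluster (connected component under
    bin-pair overlap), so a loop shared by three lineages counts once.
    ``unique`` lists, per lineage, the individual interactions private to
    it.
    """

    lineages: list[str]
    cells: dict[tuple[str, ...], list[list[tuple[str, Interaction]]]] = field(
        default_factory=dict
    )

    @property
    def unique(self) -> dict[str, list[Interaction]]:
        out: dict[str, list[Interaction]] = {lin: [] for lin in self.lineages}
        for key, groups in self.cells.items():
            if len(key) == 1:
                for group in groups:
                    out[key[0]].extend(it for _, it in group)
        return out

    def unique_counts(self) -> dict[str, int]:
        return {lin: len(v) for lin, v in self.unique.items()}

    def cell_counts(self) -> dict[tuple[str, ...], int]:
        return {key: len(groups) for key, groups in self.cells.items()}

    def shared_all_count(self) -> int:
        return len(self.cells.get(tuple(sorted(self.lineages)), []))


def partition_lineages(
    sets: dict[str, list[Interaction]], maxgap: int = 100_000
) -> LineagePartition:
    """Partition interactions into common/unique cells across lineages.

    Duplicate interactions (identical anchors) within one lineage are
    collapsed first. Interactions are clustered into connected components
    under ``binpair_overlap``; each component is assigned to the cell named
    by the set of lineages it contains, so every input interaction lands in
    exactly one cell.
    """
    if len(sets) < 2:
        raise ValueError("need at least 2 lineages to partition")
    nodes: list[tuple[str, Interaction]] = []
    for lin, its in sets.items():
        seen = set()
        for it in its:
            k = it.key()
            if k not in seen:
                seen.add(k)
                nodes.append((lin, it))
    # union-find over pairwise overlaps
    parent = list(range(len(nodes)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            if binpair_overlap(nodes[i][1], nodes[j][1], maxgap):
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[ri] = rj
    groups: dict[int, list[tuple[str, Interaction]]] = {}
    for i, node in enumerate(nodes):
        groups.setdefault(find(i), []).append(node)
    part = LineagePartition(lineages=list(sets))
    for group in groups.values():
        key = tuple(sorted({lin for lin, _ in group}))
        part.cells.setdefault(key, []).append(group)
    return part


@dataclass
class GeneAssociation:
    interaction: Interaction
    lineage: str
    gene_ids: list[str]
    rpkm: dict[str, dict[str, float]]  # gene -> lineage -> RPKM
    expressed: dict[str, bool]  # gene -> expressed anywhere (> rpkm_min)
    lineage_restricted: dict[str, bool]  # gene -> active only in self.lineage


def associate_expression(
    unique: dict[str, list[Interaction]],
    genes: RegionSet,
    expr: pd.DataFrame,
    cfg: PipelineConfig | None = None,
) -> tuple[list[GeneAssociation], int]:
    """Overlay lineage-specific interactions on gene expression.

    For each unique interaction, genes overlapping either anchor (>= 1 bp)
    are collected; a gene is *expressed* when its RPKM exceeds
    ``cfg.rpkm_min`` (strictly) in any lineage, and *lineage-restricted*
    when it is expressed or DE-flagged in the interaction's lineage and in
    no other. Returns the associations and the number of unique
    interactions with at least one expressed, lineage-restricted gene
    (regulatory candidates).

    ``expr`` columns: ``gene_id`` plus ``rpkm_<lineage>`` and
    ``de_<lineage>`` per lineage.
    """
    cfg = cfg or PipelineConfig()
    lineages = sorted(
        c[len("rpkm_"):] for c in expr.columns if c.startswith("rpkm_")
    )
    table = expr.set_index("gene_id")
    if genes.names is None:
        raise ValueError("gene RegionSet must carry gene names")
    out: list[GeneAssociation] = []
    n_candidates = 0
    for lin, its in unique.items():
        for it in its:
            idxs = sorted(
                set(genes.overlapping_indices(it.anchor1))
                | set(genes.overlapping_indices(it.anchor2))
            )
            gene_ids = [genes.names[i] for i in idxs]
            rpkm: dict[str, dict[str, float]] = {}
            expressed: dict[str, bool] = {}
            restricted: dict[str, bool] = {}
            for gid in gene_ids:
                if gid not in table.index:
                    raise KeyError(f"gene {gid} missing from expression table")
                row = table.loc[gid]
                rpkm[gid] = {l: float(row[f"rpkm_{l}"]) for l in lineages}
                expressed[gid] = any(
                    rpkm[gid][l] > cfg.rpkm_min for l in lineages
                )

                def active(l: str) -> bool:
                    return rpkm[gid][l] > cfg.rpkm_min or bool(row[f"de_{l}"])

                restricted[gid] = active(lin) and not any(
                    active(l) for l in lineages if l != lin
                )
            assoc = GeneAssociation(it, lin, gene_ids, rpkm, expressed, restricted)
            out.append(assoc)
            if any(expressed[g] and restricted[g] for g in gene_ids):
                n_candidates += 1
    return out, n_candidates


def map_region(region: Region, ortho: list[tuple[Region, Region]]) -> list[Region]:
    """Orthologous target regions whose source side overlaps ``region``."""
    return [b for a, b in ortho if a.overlaps(region)]


def conserved_across_species(
    set_a: list[Interaction],
    set_b: list[Interaction],
    ortho: list[tuple[Region, Region]],
    maxgap: int = 100_000,
) -> list[tuple[Interaction, Interaction]]:
    """Interactions of genome A whose anchors map through the orthology
    table onto an interaction of genome B (bin-pair overlap semantics in
    genome B). Anchors with no mapping are never conserved."""
    out = []
    for ia in set_a:
        m1s = map_region(ia.anchor1, ortho)
        m2s = map_region(ia.anchor2, ortho)
        hit = None
        for m1 in m1s:
            for m2 in m2s:
                a1, a2 = (m1, m2) if (m1.chrom, m1.start) <= (m2.chrom, m2.start) else (m2, m1)
                mapped = Interaction(a1, a2, 0.0, 0.0, a1.chrom != a2.chrom)
                for ib in set_b:
                    if binpair_overlap(mapped, ib, maxgap):
                        hit = ib
                        break
                if hit:
                    break
            if hit:
                break
        if hit is not None:
            out.append((ia, hit))
    return out
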