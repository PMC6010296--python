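"""Blacklist/centromere/telomere annotation of called interactions and
normalized chromosome-end distance profiles.

An interaction is flagged when either anchor overlaps (>= 1 bp, half-open
semantics) a region of the corresponding set; flagged interactions can then
be removed. End-distance profiles summarise where the anchors of trans
versus cis interactions sit along their chromosomes, with positions
normalised to chromosome length measured from the nearest telomere (range
[0, 0.5]) or from the centromere midpoint (range [0, 1)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as _stats

from .enrichment import Interaction
from .genome import GenomeLayout, Region, RegionSet

HIST_BIN_WIDTH = 0.02


@dataclass
class DistanceProfile:
    values: np.ndarray
    anchor_class: str  # "trans" | "cis"
    reference: str  # "telomere" | "centromere"

    @property
    def median(self) -> float:
        return float(np.median(self.values)) if self.values.size else float("nan")

    @property
    def mean(self) -> float:
        return float(np.mean(self.values)) if self.values.size else float("nan")

    def histogram(self) -> tuple[np.ndarray, np.ndarray]:
        """Counts and edges at fixed bin width over [0, 1]."""
        edges = np.arange(0.0, 1.0 + HIST_BIN_WIDTH, HIST_BIN_WIDTH)
        counts, _ = np.histogram(self.values, bins=edges)
        return counts, edges


def flag_blacklisted(
    interactions: list[Interaction], blacklist: RegionSet
) -> list[Interaction]:
    """Set the 'blacklisted' flag on interactions whose anchors overlap the
    blacklist by >= 1 bp. Order preserved; flags mutated in place."""
    return flag_regions(interactions, blacklist, "blacklisted")


def flag_regions(
    interactions: list[Interaction], regions: RegionSet, flag: str
) -> list[Interaction]:
    for it in interactions:
        if regions.overlaps(it.anchor1) or regions.overlaps(it.anchor2):
            it.flags.add(flag)
    return interactions


def remove_flagged(
    interactions: list[Interaction], which: set[str]
) -> tuple[list[Interaction], dict[str, int]]:
    """Drop interactions carrying any of the given flags.

    Returns the surviving interactions (order preserved, fields untouched)
    and a per-flag removal tally (an interaction with several of the
    requested flags increments each).
    """
    removed = {f: 0 for f in which}
    kept = []
    for it in interactions:
        hit = which & it.flags
        if hit:
            for f in hit:
                removed[f] += 1
        else:
            kept.append(it)
    return kept, removed


def normalized_end_distance(
    anchor: Region,
    layout: GenomeLayout,
    reference: str = "telomere",
    centromeres: RegionSet | None = None,
) -> float:
    """Anchor-midpoint distance to the nearest telomere (min of the two
    chromosome ends) or to the centromere midpoint, normalised to
    chromosome length."""
    length = layout.length(anchor.chrom)
    m = anchor.midpoint
    if reference == "telomere":
        return min(m, length - m) / length
    if reference == "centromere":
        if centromeres is None:
            raise ValueError("centromere reference requires a centromere set")
        cen = centromeres.on(anchor.chrom)
        if not cen:
            raise ValueError(f"no centromere annotated on {anchor.chrom}")
        c = cen[0].midpoint
        return abs(m - c) / length
    raise ValueError(f"unknown reference {reference!r}")


def end_distance_profile(
    interactions: list[Interaction],
    layout: GenomeLayout,
    centromeres: RegionSet | None = None,
    reference: str = "telomere",
) -> tuple[DistanceProfile, DistanceProfile, float]:
    """Normalized end-distance profiles for trans and cis interactions.

    Both anchors of every interaction contribute one value to the profile
    of its class, so each profile holds 2x the interaction count. The third
    return value is a descriptive two-sample Mann-Whitney p-value comparing
    the trans and cis distributions (NaN when either side is empty); it is
    reported, never used as a filter.
    """
    vals: dict[str, list[float]] = {"trans": [], "cis": []}
    for it in interactions:
        cls = "trans" if it.is_trans else "cis"
        for anchor in (it.anchor1, it.anchor2):
            vals[cls].append(
                normalized_end_distance(anchor, layout, reference, centromeres)
            )
    trans = DistanceProfile(np.array(vals["trans"]), "trans", reference)
    cis = DistanceProfile(np.array(vals["cis"]), "cis", reference)
    if trans.values.size and cis.values.size:
        pval = float(
            _stats.mannwhitneyu(trans.values, cis.values, alternative="two-sided").pvalue
        )
    else:
        pval = float("nan")
    return trans, cis, pval
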