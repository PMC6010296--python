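"""Coordinate frame for the pipeline: chromosomes, restriction sites, regions.

All coordinates are 0-based half-open (BED-native) everywhere in the
package; any 1-based external dialect is converted at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Region-set labels whose intervals are merged on construction.
FILTER_LABELS = frozenset({"blacklist", "centromere", "telomere"})


@dataclass(frozen=True, order=True)
class Region:
    """A genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid region {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Region") -> bool:
        """True iff the two half-open intervals share >= 1 bp."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


class GenomeLayout:
    """Chromosome names/lengths plus per-chromosome restriction-cut positions.

    Parameters
    ----------
    chroms
        Ordered ``(name, length)`` pairs; the order defines the canonical
        chromosome order used for anchor sorting.
    sites
        Optional mapping ``name -> sorted array of cut positions`` (bp, each
        in ``[0, length]``, strictly increasing).
    signature
        Ligation-junction sequence, the concatenation of two identical
        half-sites (e.g. ``GATCGATC`` for MboI, ``AAGCTAGCTT`` for HindIII).
    """

    def __init__(
        self,
        chroms: list[tuple[str, int]],
        sites: dict[str, np.ndarray] | None = None,
        signature: str = "GATCGATC",
    ) -> None:
        if not chroms:
            raise ValueError("no chromosomes")
        names = [c[0] for c in chroms]
        if len(set(names)) != len(names):
            dup = next(n for n in names if names.count(n) > 1)
            raise ValueError(f"duplicate chromosome name: {dup}")
        for name, length in chroms:
            if length <= 0:
                raise ValueError(f"non-positive length for {name}: {length}")
        if len(signature) % 2 != 0:
            raise ValueError(f"ligation signature length must be even: {signature!r}")
        comp = str.maketrans("ACGT", "TGCA")
        if signature != signature.translate(comp)[::-1]:
            raise ValueError(
                "ligation signature must be a palindromic junction of two "
                f"half-sites: {signature!r}"
            )
        self.chroms: list[tuple[str, int]] = list(chroms)
        self.signature = signature
        self._index = {name: i for i, (name, _) in enumerate(chroms)}
        self._length = dict(chroms)
        self.sites: dict[str, np.ndarray] = {}
        sites = sites or {}
        for name, pos in sites.items():
            if name not in self._index:
                raise ValueError(f"sites given for unknown chromosome {name}")
            arr = np.asarray(pos, dtype=np.int64)
            if arr.size and (np.any(np.diff(arr) <= 0)):
                raise ValueError(f"restriction sites not strictly increasing on {name}")
            if arr.size and (arr[0] < 0 or arr[-1] > self._length[name]):
                raise ValueError(f"restriction site outside chromosome {name}")
            self.sites[name] = arr
        for name, _ in chroms:
            self.sites.setdefault(name, np.empty(0, dtype=np.int64))

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.chroms]

    def length(self, chrom: str) -> int:
        try:
            return self._length[chrom]
        except KeyError:
            raise KeyError(f"unknown chromosome: {chrom}") from None

    def chrom_index(self, chrom: str) -> int:
        try:
            return self._index[chrom]
        except KeyError:
            raise KeyError(f"unknown chromosome: {chrom}") from None

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._index

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenomeLayout):
            return NotImplemented
        return (
            self.chroms == other.chroms
            and self.signature == other.signature
            and self.sites.keys() == other.sites.keys()
            and all(np.array_equal(self.sites[k], other.sites[k]) for k in self.sites)
        )

    def __repr__(self) -> str:
        return (
            f"GenomeLayout({len(self.chroms)} chroms, "
            f"{sum(s.size for s in self.sites.values())} sites, "
            f"signature={self.signature!r})"
        )


def merge_intervals(regions: list[Region]) -> list[Region]:
    """Merge overlapping/abutting intervals per chromosome, sorted by start."""
    out: list[Region] = []
    by_chrom: dict[str, list[Region]] = {}
    order: list[str] = []
    for r in regions:
        if r.chrom not in by_chrom:
            by_chrom[r.chrom] = []
            order.append(r.chrom)
        by_chrom[r.chrom].append(r)
    for chrom in order:
        rs = sorted(by_chrom[chrom], key=lambda r: (r.start, r.end))
        cur_start, cur_end = rs[0].start, rs[0].end
        for r in rs[1:]:
            if r.start <= cur_end:
                cur_end = max(cur_end, r.end)
            else:
                out.append(Region(chrom, cur_start, cur_end))
                cur_start, cur_end = r.start, r.end
        out.append(Region(chrom, cur_start, cur_end))
    return out


@dataclass
class RegionSet:
    """Labelled genomic intervals (blacklist, centromere, telomere, gene).

    Filter labels (blacklist/centromere/telomere) are merged and therefore
    non-overlapping per chromosome; the ``gene`` label keeps every interval
    (with its name) separate.
    """

    label: str
    regions: list[Region] = field(default_factory=list)
    names: list[str] | None = None

    def __post_init__(self) -> None:
        if self.label in FILTER_LABELS:
            self.regions = merge_intervals(self.regions)
            self.names = None
        else:
            idx = sorted(
                range(len(self.regions)),
                key=lambda i: (self.regions[i].chrom, self.regions[i].start),
            )
            self.regions = [self.regions[i] for i in idx]
            if self.names is not None:
                if len(self.names) != len(idx):
                    raise ValueError("names length does not match regions")
                self.names = [self.names[i] for i in idx]
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        for r in self.regions:
            self._starts.setdefault(r.chrom, None)  # placeholder
        for chrom in list(self._starts):
            rs = [r for r in self.regions if r.chrom == chrom]
            self._starts[chrom] = np.array([r.start for r in rs], dtype=np.int64)
            self._ends[chrom] = np.array([r.end for r in rs], dtype=np.int64)

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self):
        return iter(self.regions)

    def on(self, chrom: str) -> list[Region]:
        return [r for r in self.regions if r.chrom == chrom]

    def overlaps(self, query: Region) -> bool:
        """True iff ``query`` shares >= 1 bp with any region in the set.

        Uses binary search over the per-chromosome sorted interval lists;
        exact for merged (filter-label) sets and for sorted gene sets whose
        intervals may overlap each other (falls back to a scan window).
        """
        starts = self._starts.get(query.chrom)
        if starts is None or starts.size == 0:
            return False
        ends = self._ends[query.chrom]
        if self.label in FILTER_LABELS:
            # merged + disjoint: only the predecessor by start can overlap
            i = int(np.searchsorted(starts, query.end, side="left"))
            return i > 0 and ends[i - 1] > query.start
        return bool(np.any((starts < query.end) & (ends > query.start)))

    def overlapping_indices(self, query: Region) -> list[int]:
        """Indices (into ``self.regions``) of regions overlapping ``query``."""
        starts = self._starts.get(query.chrom)
        if starts is None or starts.size == 0:
            return []
        ends = self._ends[query.chrom]
        mask = (starts < query.end) & (ends > query.start)
        if not np.any(mask):
            return []
        chrom_rows = [i for i, r in enumerate(self.regions) if r.chrom == query.chrom]
        return [chrom_rows[j] for j in np.flatnonzero(mask)]

    def total_length(self) -> int:
        merged = merge_intervals(self.regions) if self.regions else []
        return sum(r.length for r in merged)

    def validate_against(self, layout: GenomeLayout) -> None:
        for r in self.regions:
            if r.chrom not in layout:
                raise ValueError(f"region on unknown chromosome {r.chrom}")
            if r.end > layout.length(r.chrom):
                raise ValueError(
                    f"region {r.chrom}:{r.start}-{r.end} exceeds chromosome length"
                )


def canonical_anchor_order(
    a: Region, b: Region, layout: GenomeLayout | None = None
) -> tuple[Region, Region]:
    """Order two anchors canonically: layout/lexicographic chromosome order
    first, then start coordinate within a chromosome."""
    if a.chrom == b.chrom:
        return (a, b) if a.start <= b.start else (b, a)
    if layout is not None:
        ka, kb = layout.chrom_index(a.chrom), layout.chrom_index(b.chrom)
    else:
        ka, kb = a.chrom, b.chrom  # type: ignore[assignment]
    return (a, b) if ka <= kb else (b, a)
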