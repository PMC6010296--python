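"""Restriction-site-aware genomic bins and sparse bin-pair counts.

Bins nominally tile each chromosome at a fixed width (default 50 kbp), but
every internal boundary is snapped to the nearest restriction-cut position
or blacklisted-region edge, whichever lies closer, so that no restriction
fragment straddles a bin boundary. Counts are stored sparsely in canonical
order (global bin id of anchor1 <= anchor2), one count vector per library.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .genome import GenomeLayout, Region, RegionSet


class BinGrid:
    """An ordered tiling of the genome into bins with global integer ids."""

    def __init__(self, layout: GenomeLayout, boundaries: dict[str, np.ndarray]):
        self.layout = layout
        self.boundaries: dict[str, np.ndarray] = {}
        self.bins: list[Region] = []
        self.chrom_ranges: dict[str, tuple[int, int]] = {}
        for name, length in layout.chroms:
            b = np.asarray(boundaries[name], dtype=np.int64)
            if b[0] != 0 or b[-1] != length or np.any(np.diff(b) <= 0):
                raise ValueError(f"invalid bin boundaries for {name}")
            self.boundaries[name] = b
            start_id = len(self.bins)
            for lo, hi in zip(b[:-1], b[1:]):
                self.bins.append(Region(name, int(lo), int(hi)))
            self.chrom_ranges[name] = (start_id, len(self.bins))

    def __len__(self) -> int:
        return len(self.bins)

    def n_bins(self, chrom: str) -> int:
        lo, hi = self.chrom_ranges[chrom]
        return hi - lo

    def bin_id(self, chrom: str, pos: int) -> int:
        """Global id of the bin containing ``pos`` (0-based)."""
        if chrom not in self.chrom_ranges:
            raise KeyError(f"chromosome {chrom} not on grid")
        if not (0 <= pos < self.layout.length(chrom)):
            raise ValueError(f"position {pos} outside {chrom}")
        b = self.boundaries[chrom]
        local = int(np.searchsorted(b, pos, side="right")) - 1
        return self.chrom_ranges[chrom][0] + local

    def chrom_of(self, bin_id: int) -> str:
        return self.bins[bin_id].chrom

    def local_index(self, bin_id: int) -> int:
        return bin_id - self.chrom_ranges[self.bins[bin_id].chrom][0]


def build_bins(
    layout: GenomeLayout,
    blacklist: RegionSet | None = None,
    width: int = 50_000,
) -> BinGrid:
    """Tile each chromosome at ``width``, snapping internal boundaries.

    Each nominal boundary (multiples of ``width``) moves to the nearest
    candidate boundary — a restriction-cut position or a blacklist edge —
    and the chromosome start/end are always boundaries. Degenerate (empty)
    bins arising from two nominals snapping to one candidate are dropped.
    A chromosome longer than one bin with no candidates at all keeps its
    nominal boundaries and emits a warning.
    """
    if width <= 0:
        raise ValueError("bin width must be > 0")
    boundaries: dict[str, np.ndarray] = {}
    for name, length in layout.chroms:
        nominal = np.arange(width, length, width, dtype=np.int64)
        candidates = [layout.sites[name]]
        if blacklist is not None:
            for r in blacklist.on(name):
                candidates.append(np.array([r.start, r.end], dtype=np.int64))
        cand = np.unique(np.concatenate(candidates)) if candidates else np.empty(0)
        cand = cand[(cand > 0) & (cand < length)]
        if nominal.size and cand.size == 0:
            warnings.warn(
                f"no restriction sites or blacklist edges on {name}; "
                "keeping nominal bin boundaries",
                stacklevel=2,
            )
            snapped = nominal
        elif nominal.size:
            # nearest candidate to each nominal boundary (ties -> lower)
            idx = np.searchsorted(cand, nominal)
            lo = np.clip(idx - 1, 0, cand.size - 1)
            hi = np.clip(idx, 0, cand.size - 1)
            pick = np.where(
                np.abs(cand[lo] - nominal) <= np.abs(cand[hi] - nominal), lo, hi
            )
            snapped = cand[pick]
        else:
            snapped = nominal
        b = np.unique(np.concatenate([[0], snapped, [length]]))
        boundaries[name] = b
    return BinGrid(layout, boundaries)


@dataclass
class BinPairCounts:
    """Sparse per-library counts over canonically ordered bin pairs.

    ``bin1``/``bin2`` are parallel arrays of global bin ids with
    ``bin1 <= bin2``; ``counts`` has shape ``(n_entries, n_libraries)``.
    """

    grid: BinGrid
    libraries: list[str]
    bin1: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    bin2: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    counts: np.ndarray = field(default_factory=lambda: np.empty((0, 0)))

    def __post_init__(self) -> None:
        self.bin1 = np.asarray(self.bin1, dtype=np.int64)
        self.bin2 = np.asarray(self.bin2, dtype=np.int64)
        self.counts = np.atleast_2d(np.asarray(self.counts))
        if self.counts.size == 0:
            self.counts = np.zeros((0, len(self.libraries)), dtype=np.int64)
        if np.any(self.bin1 > self.bin2):
            raise ValueError("bin pairs must be in canonical order (bin1 <= bin2)")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.bin1.size:
            key = self.bin1 * np.int64(len(self.grid.bins) + 1) + self.bin2
            if not np.all(np.diff(key) > 0):  # fast path: already sorted
                key = np.sort(key)
                if np.any(np.diff(key) == 0):
                    raise ValueError("duplicate bin pairs in sparse storage")

    @property
    def n_entries(self) -> int:
        return self.bin1.size

    def mean_counts(self) -> np.ndarray:
        """Cross-library mean count per stored pair."""
        return self.counts.mean(axis=1)

    def total(self) -> int:
        return int(self.counts.sum())

    @classmethod
    def from_dense(
        cls,
        grid: BinGrid,
        chrom1: str,
        chrom2: str,
        matrices: list[np.ndarray],
        libraries: list[str] | None = None,
    ) -> "BinPairCounts":
        """Build sparse counts from per-library dense matrices of one
        chromosome-pair plane. For a cis plane only the upper triangle
        (including the diagonal) is read."""
        if libraries is None:
            libraries = [f"lib{i}" for i in range(len(matrices))]
        b1, b2, counts = dense_plane_to_sparse(grid, chrom1, chrom2, matrices)
        return cls(grid, libraries, bin1=b1, bin2=b2, counts=counts)


def dense_plane_to_sparse(
    grid: BinGrid,
    chrom1: str,
    chrom2: str,
    matrices: list[np.ndarray],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sparse (bin1, bin2, per-library counts) arrays for one plane's
    per-library dense matrices; cis planes read only the upper triangle."""
    off1 = grid.chrom_ranges[chrom1][0]
    off2 = grid.chrom_ranges[chrom2][0]
    n1, n2 = grid.n_bins(chrom1), grid.n_bins(chrom2)
    stack = np.stack([np.asarray(m) for m in matrices])  # (libs, n1, n2)
    if stack.shape[1:] != (n1, n2):
        raise ValueError("matrix shape does not match grid")
    tot = stack.sum(axis=0)
    if chrom1 == chrom2:
        tot = np.triu(tot)
    ii, jj = np.nonzero(tot)
    return off1 + ii, off2 + jj, stack[:, ii, jj].T.astype(np.int64)


def count_pairs(
    records,
    grid: BinGrid,
    chrom_whitelist: set[str] | None = None,
    libraries: list[str] | None = None,
) -> tuple[BinPairCounts, int]:
    """Count kept read pairs into canonical bin pairs.

    Records on chromosomes outside the whitelist (e.g. the mitochondrion or
    unplaced scaffolds) are skipped and tallied. Returns the sparse counts
    and the number of skipped records.
    """
    if chrom_whitelist is None:
        chrom_whitelist = set(grid.chrom_ranges)
    n_libs = 1 + max((rec.lib for rec in records), default=0)
    if libraries is None:
        libraries = [f"lib{i}" for i in range(n_libs)]
    elif len(libraries) < n_libs:
        raise ValueError("fewer library names than library indices in records")
    acc: dict[tuple[int, int], np.ndarray] = {}
    skipped = 0
    for rec in records:
        c1, c2 = rec.mate1.chrom, rec.mate2.chrom
        if c1 not in chrom_whitelist or c2 not in chrom_whitelist:
            skipped += 1
            continue
        b1 = grid.bin_id(c1, rec.mate1.pos5)
        b2 = grid.bin_id(c2, rec.mate2.pos5)
        key = (b1, b2) if b1 <= b2 else (b2, b1)
        if key not in acc:
            acc[key] = np.zeros(len(libraries), dtype=np.int64)
        acc[key][rec.lib] += 1
    if acc:
        keys = sorted(acc)
        bin1 = np.array([k[0] for k in keys], dtype=np.int64)
        bin2 = np.array([k[1] for k in keys], dtype=np.int64)
        counts = np.stack([acc[k] for k in keys])
    else:
        bin1 = bin2 = np.empty(0, dtype=np.int64)
        counts = np.zeros((0, len(libraries)), dtype=np.int64)
    return BinPairCounts(grid, list(libraries), bin1, bin2, counts), skipped
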