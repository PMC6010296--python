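"""Readers and writers for the plain-text formats the pipeline touches.

All on-disk coordinates are 0-based half-open (BED-family). Formats:
chrom.sizes (2-col TSV), restriction-site TSV, BED3/BED4, BEDPE with
annotation columns, sparse bin-pair counts (long TSV) plus a bin table,
read-pair TSV, expression TSV, and a two-sided orthology TSV.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .bins import BinGrid, BinPairCounts
from .enrichment import Interaction
from .genome import GenomeLayout, Region, RegionSet
from .pairs import Mate, ReadPairRecord

_FLAGS = ("blacklisted", "centromeric", "telomeric")


def read_chrom_sizes(path: str | Path, signature: str = "GATCGATC") -> GenomeLayout:
    """Two-column whitespace-delimited (name, length) -> layout, file order
    preserved. Restriction sites can be attached via ``read_sites``."""
    chroms: list[tuple[str, int]] = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 2:
            raise ValueError(f"{path}:{lineno}: expected 'name length'")
        name = parts[0]
        try:
            length = int(parts[1])
        except ValueError:
            raise ValueError(
                f"{path}:{lineno}: non-integer length {parts[1]!r}"
            ) from None
        chroms.append((name, length))
    if not chroms:
        raise ValueError(f"{path}: no chromosomes")
    return GenomeLayout(chroms, signature=signature)


def write_chrom_sizes(layout: GenomeLayout, path: str | Path) -> None:
    Path(path).write_text(
        "".join(f"{n}\t{l}\n" for n, l in layout.chroms)
    )


def read_sites(path: str | Path, layout: GenomeLayout) -> GenomeLayout:
    """Attach restriction-cut positions (TSV: chrom, pos) to a layout."""
    df = pd.read_csv(path, sep="\t", comment="#", names=["chrom", "pos"])
    sites = {
        chrom: np.sort(sub["pos"].to_numpy(dtype=np.int64))
        for chrom, sub in df.groupby("chrom", sort=False)
    }
    return GenomeLayout(layout.chroms, sites=sites, signature=layout.signature)


def write_sites(layout: GenomeLayout, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, _ in layout.chroms:
            for pos in layout.sites[name]:
                fh.write(f"{name}\t{int(pos)}\n")


def read_bed(
    path: str | Path, label: str, layout: GenomeLayout | None = None
) -> RegionSet:
    """BED3+ -> RegionSet. Filter labels are merged; gene intervals are
    kept separate with their names (column 4)."""
    regions: list[Region] = []
    names: list[str] = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{lineno}: expected BED3+")
        chrom, start, end = parts[0], int(parts[1]), int(parts[2])
        if start >= end:
            raise ValueError(
                f"{path}:{lineno}: empty/inverted interval {chrom}:{start}-{end}"
            )
        if layout is not None and chrom not in layout:
            raise ValueError(f"{path}:{lineno}: unknown chromosome {chrom}")
        regions.append(Region(chrom, start, end))
        names.append(parts[3] if len(parts) > 3 else f"region{lineno}")
    rs = RegionSet(label, regions, names if label == "gene" else None)
    if layout is not None:
        rs.validate_against(layout)
    return rs


def write_bed(rs: RegionSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, r in enumerate(rs.regions):
            if rs.names is not None:
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{rs.names[i]}\n")
            else:
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\n")


_BEDPE_COLS = [
    "chrom1", "start1", "end1", "chrom2", "start2", "end2",
    "name", "score", "strand1", "strand2",
    "mean_count", "enrichment", "is_trans", "flags",
]


def write_interactions_bedpe(
    interactions: list[Interaction], path: str | Path
) -> None:
    """Standard BEDPE plus annotation columns (mean_count, enrichment,
    is_trans, comma-joined flags). Round-trips losslessly through
    ``read_interactions_bedpe``."""
    rows = []
    for i, it in enumerate(interactions):
        rows.append(
            (
                it.anchor1.chrom, it.anchor1.start, it.anchor1.end,
                it.anchor2.chrom, it.anchor2.start, it.anchor2.end,
                f"interaction_{i}", f"{it.enrichment:.10g}", ".", ".",
                f"{it.mean_count:.10g}", f"{it.enrichment:.10g}",
                int(it.is_trans), ",".join(sorted(it.flags)) or ".",
            )
        )
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(_BEDPE_COLS) + "\n")
        for row in rows:
            fh.write("\t".join(str(v) for v in row) + "\n")


def read_interactions_bedpe(path: str | Path) -> list[Interaction]:
    out: list[Interaction] = []
    for raw in Path(path).read_text().splitlines():
        if not raw.strip() or raw.startswith("#"):
            continue
        p = raw.split("\t")
        flags = set() if p[13] == "." else set(p[13].split(","))
        out.append(
            Interaction(
                anchor1=Region(p[0], int(p[1]), int(p[2])),
                anchor2=Region(p[3], int(p[4]), int(p[5])),
                mean_count=float(p[10]),
                enrichment=float(p[11]),
                is_trans=bool(int(p[12])),
                flags=flags,
            )
        )
    return out


def write_bin_table(grid: BinGrid, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("bin_id\tchrom\tstart\tend\n")
        for i, b in enumerate(grid.bins):
            fh.write(f"{i}\t{b.chrom}\t{b.start}\t{b.end}\n")


def read_bin_table(path: str | Path, layout: GenomeLayout) -> BinGrid:
    df = pd.read_csv(path, sep="\t")
    boundaries: dict[str, np.ndarray] = {}
    for chrom, sub in df.groupby("chrom", sort=False):
        b = np.concatenate([sub["start"].to_numpy(), [sub["end"].iloc[-1]]])
        boundaries[chrom] = b.astype(np.int64)
    return BinGrid(layout, boundaries)


def write_counts(counts: BinPairCounts, path: str | Path) -> None:
    """Long sparse TSV: bin1_id, bin2_id, lib_id, count (zero cells and
    zero libraries omitted)."""
    with open(path, "w") as fh:
        fh.write("bin1_id\tbin2_id\tlib_id\tcount\n")
        for e in range(counts.n_entries):
            for l in range(len(counts.libraries)):
                c = int(counts.counts[e, l])
                if c:
                    fh.write(
                        f"{int(counts.bin1[e])}\t{int(counts.bin2[e])}\t{l}\t{c}\n"
                    )


def read_counts(
    path: str | Path, grid: BinGrid, libraries: list[str]
) -> BinPairCounts:
    df = pd.read_csv(path, sep="\t")
    if df.empty:
        return BinPairCounts(grid, libraries)
    key = df["bin1_id"].to_numpy(np.int64) * np.int64(len(grid.bins) + 1) + df[
        "bin2_id"
    ].to_numpy(np.int64)
    uniq, inv = np.unique(key, return_inverse=True)
    counts = np.zeros((uniq.size, len(libraries)), dtype=np.int64)
    np.add.at(counts, (inv, df["lib_id"].to_numpy(np.int64)), df["count"].to_numpy(np.int64))
    bin1, bin2 = np.divmod(uniq, np.int64(len(grid.bins) + 1))
    return BinPairCounts(grid, libraries, bin1, bin2, counts)


_PAIR_COLS = [
    "chrom1", "pos1", "strand1", "mapq1", "frag1", "dist1",
    "chrom2", "pos2", "strand2", "mapq2", "frag2", "dist2",
    "dup", "chim_chrom", "chim_pos", "chim_strand", "lib",
]


def write_read_pairs(records: list[ReadPairRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_PAIR_COLS) + "\n")
        for r in records:
            chim = r.chim3 or (".", ".", ".")
            def mf(m: Mate):
                return [
                    m.chrom if m.chrom is not None else ".",
                    m.pos5,
                    m.strand,
                    m.mapq,
                    m.frag if m.frag is not None else ".",
                    m.frag_end_dist if m.frag_end_dist is not None else ".",
                ]
            row = mf(r.mate1) + mf(r.mate2) + [int(r.dup), *chim, r.lib]
            fh.write("\t".join(str(v) for v in row) + "\n")


def read_read_pairs(path: str | Path) -> list[ReadPairRecord]:
    out: list[ReadPairRecord] = []
    lines = Path(path).read_text().splitlines()
    for raw in lines[1:]:
        if not raw.strip():
            continue
        p = raw.split("\t")

        def mate(off: int) -> Mate:
            return Mate(
                chrom=None if p[off] == "." else p[off],
                pos5=int(p[off + 1]),
                strand=p[off + 2],
                mapq=int(p[off + 3]),
                frag=None if p[off + 4] == "." else int(p[off + 4]),
                frag_end_dist=None if p[off + 5] == "." else int(p[off + 5]),
            )

        chim = (
            None
            if p[13] == "."
            else (p[13], int(p[14]), p[15])
        )
        out.append(
            ReadPairRecord(
                mate1=mate(0),
                mate2=mate(6),
                dup=bool(int(p[12])),
                chim3=chim,
                lib=int(p[16]),
            )
        )
    return out


def write_expression(expr: pd.DataFrame, path: str | Path) -> None:
    expr.to_csv(path, sep="\t", index=False)


def read_expression(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in df.columns:
        if col.startswith("de_"):
            df[col] = df[col].astype(bool)
    return df


def write_orthology(
    ortho: list[tuple[Region, Region]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("chromA\tstartA\tendA\tchromB\tstartB\tendB\n")
        for a, b in ortho:
            fh.write(
                f"{a.chrom}\t{a.start}\t{a.end}\t{b.chrom}\t{b.start}\t{b.end}\n"
            )


def read_orthology(path: str | Path) -> list[tuple[Region, Region]]:
    out: list[tuple[Region, Region]] = []
    lines = Path(path).read_text().splitlines()
    for raw in lines[1:]:
        if not raw.strip():
            continue
        p = raw.split("\t")
        if len(p) != 6:
            raise ValueError(f"malformed orthology row: {raw!r}")
        out.append(
            (
                Region(p[0], int(p[1]), int(p[2])),
                Region(p[3], int(p[4]), int(p[5])),
            )
        )
    return out
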