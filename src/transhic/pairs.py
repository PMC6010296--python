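"""Hi-C read-pair classification and filtering.

A di-tag is kept only if it survives, in order: mapping checks (unmapped,
low MAPQ), duplicate marking, same-fragment/same-orientation removal,
dangling-end and self-circle geometry filters, and the off-site-digestion
fragment-size cap. The precedence order is fixed so that per-class counts
are deterministic even when a pair matches several artifact definitions.

Conventions (standard for Hi-C di-tags):

* "inward-facing": the upstream mate (smaller 5' position) is on the +
  strand and the downstream mate on the - strand; "outward-facing" is the
  reverse. Separation is measured between 5' positions.
* The fragment size of a pair is the sum of both mates' distances to the
  restriction-fragment end each read points away from.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .config import PipelineConfig
from .genome import GenomeLayout


class PairClass(str, Enum):
    KEEP = "keep"
    UNMAPPED = "unmapped"
    LOW_MAPQ = "low_mapq"
    DUPLICATE = "duplicate"
    SAME_FRAGMENT = "same_fragment"
    DANGLING_END = "dangling_end"
    SELF_CIRCLE = "self_circle"
    OFFSITE_DIGESTION = "offsite_digestion"


@dataclass(frozen=True)
class Mate:
    """One aligned read of a di-tag. ``chrom is None`` means unmapped."""

    chrom: str | None
    pos5: int
    strand: str
    mapq: int
    frag: int | None = None
    frag_end_dist: int | None = None


@dataclass(frozen=True)
class ReadPairRecord:
    mate1: Mate
    mate2: Mate
    dup: bool = False
    #: (chrom, pos5, strand) of the 5'-mate's 3' chimeric segment, if any.
    chim3: tuple[str, int, str] | None = None
    lib: int = 0


@dataclass
class FilterStats:
    total: int = 0
    counts: dict[str, int] = field(
        default_factory=lambda: {c.value: 0 for c in PairClass}
    )
    assigned_fraction: float = float("nan")
    chimeric_error_rate: float = float("nan")

    def as_dict(self) -> dict[str, float]:
        out: dict[str, float] = {"total": self.total}
        out.update(self.counts)
        out["assigned_fraction"] = self.assigned_fraction
        out["chimeric_error_rate"] = self.chimeric_error_rate
        return out


def split_ligation_read(seq: str, signature: str) -> list[tuple[int, str]]:
    """Split a read at the first ligation-signature occurrence.

    The signature is two copies of a half-site; the read is cut in the
    middle of the signature so each segment keeps one half-site copy.
    Returns ``[(offset, subsequence), ...]``; reads without the signature
    come back as a single segment.
    """
    if not seq:
        raise ValueError("empty sequence")
    if len(signature) % 2 != 0:
        raise ValueError("signature length must be even")
    idx = seq.find(signature)
    if idx < 0:
        return [(0, seq)]
    cut = idx + len(signature) // 2
    return [(0, seq[:cut]), (cut, seq[cut:])]


def assign_fragment(
    layout: GenomeLayout, chrom: str, pos5: int, strand: str
) -> tuple[int, int]:
    """Locate the restriction fragment containing ``pos5``.

    Fragments are the half-open intervals between consecutive cut positions,
    including the chromosome ends. Returns ``(frag_index, frag_end_dist)``
    where the distance runs from the 5' position to the fragment end the
    read points away from: the higher-coordinate end for a + read, the
    lower-coordinate end for a - read.
    """
    length = layout.length(chrom)
    if not (0 <= pos5 < length):
        raise ValueError(f"position {pos5} outside {chrom} (length {length})")
    sites = layout.sites[chrom]
    frag = int(np.searchsorted(sites, pos5, side="right"))
    lo = int(sites[frag - 1]) if frag > 0 else 0
    hi = int(sites[frag]) if frag < sites.size else length
    if strand == "+":
        return frag, hi - pos5
    return frag, pos5 - lo


def _facing(rec: ReadPairRecord) -> tuple[str | None, int]:
    """('inward'|'outward'|None, separation) for same-chromosome pairs."""
    m1, m2 = rec.mate1, rec.mate2
    if m1.chrom is None or m1.chrom != m2.chrom:
        return None, -1
    # tie-break equal 5' positions on strand so the class is mate-order
    # independent: the + read counts as the upstream mate
    up, dn = sorted((m1, m2), key=lambda m: (m.pos5, m.strand != "+"))
    sep = dn.pos5 - up.pos5
    if up.strand == "+" and dn.strand == "-":
        return "inward", sep
    if up.strand == "-" and dn.strand == "+":
        return "outward", sep
    return None, sep


def classify_pair(rec: ReadPairRecord, cfg: PipelineConfig) -> PairClass:
    m1, m2 = rec.mate1, rec.mate2
    if m1.chrom is None or m2.chrom is None:
        return PairClass.UNMAPPED
    if m1.mapq < cfg.mapq_min or m2.mapq < cfg.mapq_min:
        return PairClass.LOW_MAPQ
    if rec.dup:
        return PairClass.DUPLICATE
    if m1.frag is None or m2.frag is None:
        raise ValueError("record lacks fragment assignment")
    if m1.chrom == m2.chrom and m1.frag == m2.frag and m1.strand == m2.strand:
        return PairClass.SAME_FRAGMENT
    facing, sep = _facing(rec)
    if facing == "inward" and sep < cfg.min_inward:
        return PairClass.DANGLING_END
    if facing == "outward" and sep < cfg.min_outward:
        return PairClass.SELF_CIRCLE
    if m1.frag_end_dist is None or m2.frag_end_dist is None:
        raise ValueError("record lacks fragment-end distances")
    if m1.frag_end_dist + m2.frag_end_dist > cfg.max_frag:
        return PairClass.OFFSITE_DIGESTION
    return PairClass.KEEP


def filter_pairs(
    records: list[ReadPairRecord], cfg: PipelineConfig
) -> tuple[list[ReadPairRecord], FilterStats]:
    """Partition records into kept pairs and artifact classes."""
    stats = FilterStats(total=len(records))
    kept: list[ReadPairRecord] = []
    for rec in records:
        cls = classify_pair(rec, cfg)
        stats.counts[cls.value] += 1
        if cls is PairClass.KEEP:
            kept.append(rec)
    if stats.total:
        stats.assigned_fraction = len(kept) / stats.total
    stats.chimeric_error_rate = estimate_chimeric_error(records, cfg)
    return kept, stats


def estimate_chimeric_error(
    records: list[ReadPairRecord], cfg: PipelineConfig
) -> float:
    """Fraction of evaluable chimeric pairs whose 3' segment disagrees with
    its mate.

    A chimera is evaluable when the 5' mate carries a mapped 3' segment.
    The alignment is considered correct only when the 3' segment and the
    other mate are inward-facing and separated by less than ``chim_dist``;
    anything else (wrong orientation, different chromosome, too far apart)
    counts as a mapping error. Returns NaN when nothing is evaluable.
    """
    evaluable = 0
    errors = 0
    for rec in records:
        if rec.chim3 is None:
            continue
        evaluable += 1
        c_chrom, c_pos, c_strand = rec.chim3
        mate = rec.mate2
        if mate.chrom is None or mate.chrom != c_chrom:
            errors += 1
            continue
        if c_pos <= mate.pos5:
            up_strand, dn_strand = c_strand, mate.strand
            sep = mate.pos5 - c_pos
        else:
            up_strand, dn_strand = mate.strand, c_strand
            sep = c_pos - mate.pos5
        inward = up_strand == "+" and dn_strand == "-"
        if not (inward and sep < cfg.chim_dist):
            errors += 1
    if evaluable == 0:
        return float("nan")
    return errors / evaluable
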