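"""Local-neighborhood enrichment statistic and putative-loop calling.

For every stored bin pair, the cross-library mean count is compared against
the average count in four surrounding neighborhoods in the interaction
plane of its chromosome pair:

* a ``(x+1)``-sided square *quadrant* between the target and the diagonal,
  with the target in its corner (cis planes only);
* a *horizontal stripe* of length ``2x+1`` centred on the target;
* a *vertical stripe* of length ``2x+1`` centred on the target;
* a ``(2x+1)``-sided *square* centred on the target.

Each neighborhood yields ``log2((y_t + prior) / (mean(N \\ {t}) + prior))``
over cross-library mean counts ``y`` (unstored pairs count as zero); the
enrichment value of a bin pair is the minimum of these log-fold changes, so
a large value requires the pair to exceed *all* of its surroundings.

Neighborhood conventions (documented design choices): the target itself is
excluded from every neighborhood mean; neighborhoods are truncated at plane
borders and, on cis planes, at the diagonal (diagonal cells never
contribute); for trans planes "closest to the diagonal" is undefined, so
the quadrant is omitted and the minimum runs over the remaining three
neighborhoods.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bins import BinGrid, BinPairCounts
from .config import PipelineConfig
from .genome import Region


@dataclass
class EnrichmentResult:
    """Per-bin-pair log-fold changes and the min-based enrichment value.

    Arrays are parallel over the evaluated bin pairs (a subset of the
    stored pairs when an abundance prefilter is used). ``lfc_quadrant`` is
    NaN for trans pairs; any neighborhood that is empty after truncation is
    NaN, and a pair whose every neighborhood is empty has NaN enrichment
    (undefined — never callable).
    """

    grid: BinGrid
    bin1: np.ndarray
    bin2: np.ndarray
    mean_count: np.ndarray
    lfc_quadrant: np.ndarray
    lfc_horizontal: np.ndarray
    lfc_vertical: np.ndarray
    lfc_square: np.ndarray
    enrichment: np.ndarray
    is_trans: np.ndarray
    x: int = 5
    prior: float = 0.5

    @property
    def n(self) -> int:
        return self.bin1.size


@dataclass
class Interaction:
    """A called bin pair with its statistics and annotation flags."""

    anchor1: Region
    anchor2: Region
    mean_count: float
    enrichment: float
    is_trans: bool
    flags: set[str] = field(default_factory=set)

    def key(self) -> tuple:
        a, b = self.anchor1, self.anchor2
        return (a.chrom, a.start, a.end, b.chrom, b.start, b.end)


def _integral(m: np.ndarray) -> np.ndarray:
    """2-D integral image with a zero first row/column."""
    s = np.zeros((m.shape[0] + 1, m.shape[1] + 1), dtype=np.float64)
    np.cumsum(m, axis=0, out=s[1:, 1:])
    np.cumsum(s[1:, 1:], axis=1, out=s[1:, 1:])
    return s


def _rect(s: np.ndarray, a, b, c, d):
    """Sum over inclusive row range a..b, col range c..d (pre-clipped)."""
    return s[b + 1, d + 1] - s[a, d + 1] - s[b + 1, c] + s[a, c]


def _plane_enrichment(
    ii: np.ndarray,
    jj: np.ndarray,
    ybar: np.ndarray,
    n1: int,
    n2: int,
    is_cis: bool,
    x: int,
    prior: float,
    eval_mask: np.ndarray,
) -> dict[str, np.ndarray]:
    """Neighborhood log-fold changes for one chromosome-pair plane.

    ``ii``/``jj`` are local bin indices of the stored pairs (for cis,
    ``ii <= jj``); ``ybar`` their cross-library mean counts. Only targets
    with ``eval_mask`` get statistics; all stored pairs contribute to the
    neighborhood background.
    """
    m = np.zeros((n1, n2), dtype=np.float64)
    if is_cis:
        off = ii < jj  # diagonal cells are excluded from the plane
        m[ii[off], jj[off]] = ybar[off]
        valid = np.triu(np.ones((n1, n2), dtype=np.float64), k=1)
        sv = _integral(valid)
    else:
        m[ii, jj] = ybar
        sv = None
    sm = _integral(m)

    ti, tj, ty = ii[eval_mask], jj[eval_mask], ybar[eval_mask]
    target_valid = (ti < tj) if is_cis else np.ones(ti.size, dtype=bool)
    tval = np.where(target_valid, ty, 0.0)

    def nbhd(a, b, c, d):
        a = np.clip(a, 0, n1 - 1)
        b = np.clip(b, 0, n1 - 1)
        c = np.clip(c, 0, n2 - 1)
        d = np.clip(d, 0, n2 - 1)
        total = _rect(sm, a, b, c, d)
        if sv is None:
            cnt = (b - a + 1.0) * (d - c + 1.0)
        else:
            cnt = _rect(sv, a, b, c, d)
        # remove the target cell from its own neighborhood
        inside = (a <= ti) & (ti <= b) & (c <= tj) & (tj <= d) & target_valid
        total = total - np.where(inside, tval, 0.0)
        cnt = cnt - inside
        mean = np.full(ti.shape, np.nan)
        ok = cnt > 0
        mean[ok] = total[ok] / cnt[ok]
        return np.log2((ty + prior) / (mean + prior))

    with np.errstate(invalid="ignore"):
        lfc_h = nbhd(ti, ti, tj - x, tj + x)
        lfc_v = nbhd(ti - x, ti + x, tj, tj)
        lfc_s = nbhd(ti - x, ti + x, tj - x, tj + x)
        if is_cis:
            lfc_q = nbhd(ti, ti + x, tj - x, tj)
        else:
            lfc_q = np.full(ti.shape, np.nan)
        stack = np.stack([lfc_q, lfc_h, lfc_v, lfc_s])
        all_nan = np.all(np.isnan(stack), axis=0)
        enr = np.full(ti.shape, np.nan)
        if np.any(~all_nan):
            enr[~all_nan] = np.nanmin(stack[:, ~all_nan], axis=0)
    if is_cis:
        # diagonal targets have no defined statistic
        lfc_q[~target_valid] = np.nan
        lfc_h[~target_valid] = np.nan
        lfc_v[~target_valid] = np.nan
        lfc_s[~target_valid] = np.nan
        enr[~target_valid] = np.nan
    return {
        "quadrant": lfc_q,
        "horizontal": lfc_h,
        "vertical": lfc_v,
        "square": lfc_s,
        "enrichment": enr,
    }


def neighborhood_enrichment(
    counts: BinPairCounts,
    x: int = 5,
    prior: float = 0.5,
    min_mean: float | None = None,
) -> EnrichmentResult:
    """Compute the min-of-neighborhoods enrichment for stored bin pairs.

    ``min_mean``, when given, restricts the evaluated targets to stored
    pairs with cross-library mean count strictly above it; every stored
    pair still contributes to the neighborhood background, so this is
    exact with respect to loop calling at the same abundance threshold
    (pairs at or below it can never be called). Unstored (zero) pairs are
    likewise never evaluated; they cannot pass any positive count
    threshold.
    """
    if x < 1:
        raise ValueError("x must be >= 1")
    grid = counts.grid
    ybar_all = counts.mean_counts()
    if min_mean is None:
        eval_all = np.ones(counts.n_entries, dtype=bool)
    else:
        eval_all = ybar_all > min_mean

    # chromosome index per stored pair
    starts = np.array([grid.chrom_ranges[c][0] for c in grid.chrom_ranges])
    chrom_names = list(grid.chrom_ranges)
    c1 = np.searchsorted(starts, counts.bin1, side="right") - 1
    c2 = np.searchsorted(starts, counts.bin2, side="right") - 1

    out_b1, out_b2, out_y, out_tr = [], [], [], []
    cols: dict[str, list[np.ndarray]] = {
        k: [] for k in ("quadrant", "horizontal", "vertical", "square", "enrichment")
    }
    for pair_key in np.unique(c1 * np.int64(len(chrom_names)) + c2):
        k1, k2 = divmod(int(pair_key), len(chrom_names))
        sel = (c1 == k1) & (c2 == k2)
        if not np.any(eval_all[sel]):
            continue
        name1, name2 = chrom_names[k1], chrom_names[k2]
        ii = counts.bin1[sel] - grid.chrom_ranges[name1][0]
        jj = counts.bin2[sel] - grid.chrom_ranges[name2][0]
        res = _plane_enrichment(
            ii,
            jj,
            ybar_all[sel],
            grid.n_bins(name1),
            grid.n_bins(name2),
            is_cis=(k1 == k2),
            x=x,
            prior=prior,
            eval_mask=eval_all[sel],
        )
        emask = eval_all[sel]
        out_b1.append(counts.bin1[sel][emask])
        out_b2.append(counts.bin2[sel][emask])
        out_y.append(ybar_all[sel][emask])
        out_tr.append(np.full(int(emask.sum()), k1 != k2, dtype=bool))
        for k in cols:
            cols[k].append(res[k])

    def cat(parts, dtype=np.float64):
        return (
            np.concatenate(parts) if parts else np.empty(0, dtype=dtype)
        )

    return EnrichmentResult(
        grid=grid,
        bin1=cat(out_b1, np.int64),
        bin2=cat(out_b2, np.int64),
        mean_count=cat(out_y),
        lfc_quadrant=cat(cols["quadrant"]),
        lfc_horizontal=cat(cols["horizontal"]),
        lfc_vertical=cat(cols["vertical"]),
        lfc_square=cat(cols["square"]),
        enrichment=cat(cols["enrichment"]),
        is_trans=cat(out_tr, bool),
        x=x,
        prior=prior,
    )


def call_putative_loops(
    counts: BinPairCounts,
    enr: EnrichmentResult | None = None,
    cfg: PipelineConfig | None = None,
) -> list[Interaction]:
    """Call putative loops: enrichment strictly above ``enrichment_min``,
    cross-library mean count strictly above ``mean_count_min``, and (for
    cis pairs) more than ``diag_exclusion`` bins off the diagonal."""
    cfg = cfg or PipelineConfig()
    if enr is None:
        enr = neighborhood_enrichment(
            counts,
            x=cfg.x_neighborhood,
            prior=cfg.prior_count,
            min_mean=cfg.mean_count_min,
        )
    grid = counts.grid
    with np.errstate(invalid="ignore"):
        ok = (enr.enrichment > cfg.enrichment_min) & (
            enr.mean_count > cfg.mean_count_min
        )
    off_diag = enr.is_trans | (np.abs(enr.bin1 - enr.bin2) > cfg.diag_exclusion)
    ok &= off_diag
    ok &= ~np.isnan(enr.enrichment)
    out = []
    for idx in np.flatnonzero(ok):
        out.append(
            Interaction(
                anchor1=grid.bins[int(enr.bin1[idx])],
                anchor2=grid.bins[int(enr.bin2[idx])],
                mean_count=float(enr.mean_count[idx]),
                enrichment=float(enr.enrichment[idx]),
                is_trans=bool(enr.is_trans[idx]),
            )
        )
    return out
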