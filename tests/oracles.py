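"""Independent brute-force oracles used to cross-check the implementation.

These deliberately re-derive results by direct enumeration over dense
matrices / per-base arrays, sharing no code with the library paths they
check.
"""

from __future__ import annotations

import math

import numpy as np

NEIGHBORHOODS = ("quadrant", "horizontal", "vertical", "square")


def dense_plane_lfcs(
    ybar: np.ndarray,
    is_cis: bool,
    x: int,
    prior: float,
    targets: list[tuple[int, int]],
) -> dict[tuple[int, int], dict[str, float]]:
    """Neighborhood log-fold changes by explicit submatrix enumeration.

    ``ybar`` is the dense cross-library mean plane. For cis planes only
    strictly upper-triangular cells are valid (diagonal and mirror cells
    never contribute) and diagonal targets are undefined.
    """
    n1, n2 = ybar.shape
    valid = np.ones((n1, n2), dtype=bool)
    if is_cis:
        valid = np.triu(valid, k=1)
    out: dict[tuple[int, int], dict[str, float]] = {}
    for i, j in targets:
        res: dict[str, float] = {}
        if is_cis and i >= j:
            out[(i, j)] = {k: math.nan for k in (*NEIGHBORHOODS, "enrichment")}
            continue
        y_t = ybar[i, j]
        rects = {
            "quadrant": (i, i + x, j - x, j),
            "horizontal": (i, i, j - x, j + x),
            "vertical": (i - x, i + x, j, j),
            "square": (i - x, i + x, j - x, j + x),
        }
        for name, (a, b, c, d) in rects.items():
            if name == "quadrant" and not is_cis:
                res[name] = math.nan
                continue
            a0, b0 = max(a, 0), min(b, n1 - 1)
            c0, d0 = max(c, 0), min(d, n2 - 1)
            vm = valid[a0 : b0 + 1, c0 : d0 + 1].copy()
            if a0 <= i <= b0 and c0 <= j <= d0:
                vm[i - a0, j - c0] = False
            if not vm.any():
                res[name] = math.nan
                continue
            mean = float(ybar[a0 : b0 + 1, c0 : d0 + 1][vm].mean())
            res[name] = math.log2((y_t + prior) / (mean + prior))
        defined = [v for v in res.values() if not math.isnan(v)]
        res["enrichment"] = min(defined) if defined else math.nan
        out[(i, j)] = res
    return out


def linear_scan_fragment(
    sites: np.ndarray, length: int, pos5: int, strand: str
) -> tuple[int, int]:
    """Fragment assignment by scanning every fragment interval."""
    bounds = [0, *[int(s) for s in sites], length]
    for k in range(len(bounds) - 1):
        lo, hi = bounds[k], bounds[k + 1]
        if lo <= pos5 < hi:
            return k, (hi - pos5) if strand == "+" else (pos5 - lo)
    raise AssertionError("position outside chromosome")


def per_base_overlap(region, region_set) -> bool:
    """Any-overlap by testing every base of the query region."""
    for r in region_set.regions:
        if r.chrom != region.chrom:
            continue
        for pos in range(region.start, region.end):
            if r.start <= pos < r.end:
                return True
    return False


def per_base_overlap_fast(region, base_mask: dict[str, np.ndarray]) -> bool:
    """Any-overlap against precomputed per-base boolean chromosome masks."""
    mask = base_mask.get(region.chrom)
    if mask is None:
        return False
    return bool(mask[region.start : region.end].any())
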