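import numpy as np
import pytest

from transhic import GenomeLayout, PipelineConfig, Region
from transhic.bins import BinGrid


@pytest.fixture
def cfg():
    return PipelineConfig()


@pytest.fixture
def toy_layout():
    """Two small chromosomes with a handful of fixed restriction sites."""
    return GenomeLayout(
        [("chr1", 300_000), ("chr2", 200_000)],
        sites={
            "chr1": np.array([40_000, 49_900, 101_000, 150_000, 260_000]),
            "chr2": np.array([30_000, 99_000, 160_000]),
        },
    )


@pytest.fixture
def sparse_layout():
    """Chromosome pair with very sparse sites (long fragments) for
    fragment-size artifact construction."""
    return GenomeLayout(
        [("chrA", 10_000), ("chrB", 10_000)],
        sites={
            "chrA": np.array([3_000, 6_000]),
            "chrB": np.array([4_000, 9_000]),
        },
    )


def uniform_grid(layout: GenomeLayout, width: int) -> BinGrid:
    """Grid with exact nominal boundaries (no snapping), for tests that
    need arithmetically simple bins."""
    boundaries = {}
    for name, length in layout.chroms:
        b = np.arange(0, length, width)
        boundaries[name] = np.append(b, length) if b[-1] != length else b
    return BinGrid(layout, boundaries)


def make_region(chrom: str, start: int, width: int = 50_000) -> Region:
    return Region(chrom, start, start + width)
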