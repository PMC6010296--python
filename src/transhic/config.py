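"""Pipeline configuration and its default thresholds.

Defaults used throughout the analysis:
50 kbp bins, a 5-bin (250 kbp) neighborhood, enrichment > 0.5 (log2),
mean count > 10 across libraries, more than 1 bin off the diagonal,
100 kbp maxgap for bin-pair overlap, MAPQ >= 10, max fragment 1200 bp,
chimera evaluation distance 1200 bp, and an expression threshold of
5 RPKM (strict).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path


@dataclass
class PipelineConfig:
    bin_width: int = 50_000          # bp
    x_neighborhood: int = 5          # bins
    enrichment_min: float = 0.5      # log2 units, strict >
    mean_count_min: float = 10.0     # counts, strict >
    diag_exclusion: int = 1          # bins; called cis pairs need |i-j| > this
    maxgap: int = 100_000            # bp, inclusive <=
    mapq_min: int = 10               # mates below this are discarded
    max_frag: int = 1_200            # bp; pair fragment size above this = off-site
    min_inward: int = 1_000          # bp; inward pairs closer = dangling ends
    min_outward: int = 25_000        # bp; outward pairs closer = self-circles
    chim_dist: int = 1_200           # bp; chimeric 3'-segment evaluation distance
    rpkm_min: float = 5.0            # RPKM, strict >
    prior_count: float = 0.5         # pseudocount for log-fold changes
    seed: int = 0

    _INT_FIELDS = frozenset(
        {
            "bin_width",
            "x_neighborhood",
            "diag_exclusion",
            "maxgap",
            "mapq_min",
            "max_frag",
            "min_inward",
            "min_outward",
            "chim_dist",
            "seed",
        }
    )

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be > 0")
        if self.x_neighborhood < 1:
            raise ValueError("x_neighborhood must be >= 1")
        for name in (
            "enrichment_min",
            "mean_count_min",
            "diag_exclusion",
            "maxgap",
            "mapq_min",
            "max_frag",
            "min_inward",
            "min_outward",
            "chim_dist",
            "rpkm_min",
            "prior_count",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def to_file(self, path: str | Path) -> None:
        """Write as flat ``key = value`` text, one parameter per line."""
        lines = [
            f"{f.name} = {getattr(self, f.name)}"
            for f in dataclasses.fields(self)
        ]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Read flat key-value config; unknown keys are an error (fail-fast
        on typos in threshold names). '#' starts a comment."""
        known = {f.name for f in dataclasses.fields(cls)}
        values: dict[str, object] = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, _, val = line.partition("=")
            key, val = key.strip(), val.strip()
            if key not in known:
                raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
            values[key] = int(val) if key in cls._INT_FIELDS else float(val)
        return cls(**values)  # type: ignore[arg-type]
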