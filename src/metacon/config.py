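"""Run configuration shared by the library pipeline and the CLI."""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Optional

import yaml


@dataclass
class RunConfig:
    """Parameters of a binning run.

    k
        Canonical k-mer size (even, 2-8).  4 balances signature
        resolution against feature-space size and is the default.
    length_threshold_bp
        Fixed long/short split; contigs >= this many bases are clustered
        in phase 1.  2000 bp typically leaves about 20% of assembled
        contigs short.
    short_fraction
        If set, use the quantile split instead: label exactly this
        fraction of contigs (the shortest ones) as short.
    clusters
        Number of bins C.  When None, C is estimated by iterated k-means
        with the cluster-occupancy stopping rule.
    occupancy
        Occupancy threshold of the estimator: stop once fewer than
        occupancy * k clusters are non-empty.
    strict_formulas
        Use the three literal-formula variants at once: strict k-mer
        probability (no reverse-complement pairing), signed column sums
        for H, and an unsmoothed nucleotide model.
    phase2_composition
        ``relative`` (default) scales phase-2 composition rows to
        relative frequencies so short contigs and long-contig centroids
        live on one scale; ``raw`` keeps unscaled pseudo-counts.
    """

    k: int = 4
    length_threshold_bp: int = 2000
    short_fraction: Optional[float] = None
    clusters: Optional[int] = None
    seed: int = 0
    strict_formulas: bool = False
    chunk_len: int = 10_000
    occupancy: float = 0.8
    max_iter: int = 100
    restarts: int = 10
    phase2_composition: str = "relative"
    phase2_distance: str = "l1"
    two_phase: bool = True

    def __post_init__(self) -> None:
        if self.k % 2 != 0 or not (2 <= self.k <= 8):
            raise ValueError("k must be even and in [2, 8]")
        if not (0 < self.occupancy <= 1):
            raise ValueError("occupancy must be in (0, 1]")
        if self.short_fraction is not None and not (0 <= self.short_fraction < 1):
            raise ValueError("short_fraction must be in [0, 1)")
        if self.phase2_composition not in ("relative", "raw"):
            raise ValueError("phase2_composition must be 'relative' or 'raw'")
        if self.phase2_distance not in ("l1", "l2"):
            raise ValueError("phase2_distance must be 'l1' or 'l2'")

    # composition-signature flags implied by strict_formulas
    @property
    def probability_mode(self) -> str:
        return "strict" if self.strict_formulas else "pair"

    @property
    def column_mode(self) -> str:
        return "strict" if self.strict_formulas else "abs"

    @property
    def smooth(self) -> bool:
        return not self.strict_formulas

    @property
    def split_mode(self) -> str:
        return "fixed" if self.short_fraction is None else "quantile"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}
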