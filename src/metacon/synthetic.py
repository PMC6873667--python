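"""Synthetic multi-species communities with known labels.

The generator emulates the situation the binner is built for: G species
with distinct nucleotide composition, each contributing contigs of mixed
lengths, observed across M samples in which each species has its own
abundance so that contigs of one species share a coverage profile.

Sequences are drawn i.i.d. from per-species base-probability models by
default (exactly the background model the composition signature
assumes); an order-1 Markov option introduces model misspecification for
stress tests.  Coverage is species abundance times multiplicative
lognormal noise with mean 1.  Everything is reproducible from a single
seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .io import ContigRecord, ContigSet, CoverageMatrix

_BASES = "ACGT"


def default_models(G: int, gc_range: tuple[float, float] = (0.30, 0.70)) -> np.ndarray:
    """G base-probability vectors spread evenly in GC content.

    Species that differ in GC differ in their whole k-mer spectrum, which
    is the well-separated regime of real communities whose members come
    from distant clades.
    """
    if G < 1:
        raise ValueError("G must be >= 1")
    gcs = np.linspace(gc_range[0], gc_range[1], G) if G > 1 else np.array([0.5])
    return np.array([[(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2] for gc in gcs])


@dataclass
class CommunitySpec:
    """Parameters of a synthetic community.

    The defaults describe a small, clearly separated five-species
    community observed in eight samples: 50 long contigs (2-20 kb) and 15
    short ones (0.5-2 kb) per species, per-sample lognormal species
    abundances (median ~7x coverage, sigma 1 on the log scale) and 10%
    multiplicative coverage noise.
    """

    G: int = 5
    samples: int = 8
    nucleotide_models: Optional[np.ndarray] = None
    contigs_per_species: int = 65
    short_fraction: float = 15 / 65
    long_range: tuple[int, int] = (2000, 20000)
    short_range: tuple[int, int] = (500, 1999)
    abundance_mu: float = 2.0
    abundance_sigma: float = 1.0
    coverage_noise_sd: float = 0.10
    markov_order: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.G < 1:
            raise ValueError("G must be >= 1")
        if not (0 <= self.short_fraction < 1):
            raise ValueError("short_fraction must be in [0, 1)")
        if self.samples < 1:
            raise ValueError("samples must be >= 1")
        if self.markov_order not in (0, 1):
            raise ValueError("markov_order must be 0 or 1")
        if self.nucleotide_models is None:
            self.nucleotide_models = default_models(self.G)
        self.nucleotide_models = np.asarray(self.nucleotide_models, dtype=float)
        if self.nucleotide_models.shape != (self.G, 4):
            raise ValueError("nucleotide_models must be G x 4")
        if np.any(self.nucleotide_models < 0) or not np.allclose(
            self.nucleotide_models.sum(axis=1), 1.0, atol=1e-9
        ):
            raise ValueError("each nucleotide model must be a probability vector")


_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _draw_sequence(rng: np.random.Generator, probs: np.ndarray, length: int,
                   markov_order: int) -> str:
    if markov_order == 0:
        draws = rng.choice(4, size=length, p=probs)
        return _BASE_BYTES[draws].tobytes().decode("ascii")
    else:
        # order-1 chain whose stationary distribution is ``probs``: mix a
        # fresh draw with a copy of the previous base
        stay = 0.5
        draws = np.empty(length, dtype=np.int64)
        draws[0] = rng.choice(4, p=probs)
        fresh = rng.choice(4, size=length, p=probs)
        keep = rng.random(length) < stay
        for i in range(1, length):
            draws[i] = draws[i - 1] if keep[i] else fresh[i]
    return "".join(_BASES[b] for b in draws)


def generate_community(
    spec: CommunitySpec, seed: Optional[int] = None
) -> tuple[ContigSet, CoverageMatrix, dict[str, str]]:
    """Draw a community: contigs, coverage table and true species labels.

    Per species g: ``round(short_fraction * contigs_per_species)`` short
    contigs and the rest long, lengths uniform over the configured
    ranges, sequences from the species' nucleotide model.  Coverage is
    ``Y[c, m] = abundance[g, m] * noise`` with per-(species, sample)
    lognormal abundances and i.i.d. mean-1 lognormal noise per entry.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n_short = int(round(spec.short_fraction * spec.contigs_per_species))
    n_long = spec.contigs_per_species - n_short

    records: list[ContigRecord] = []
    truth: dict[str, str] = {}
    species_of: list[int] = []
    for g in range(spec.G):
        probs = spec.nucleotide_models[g]
        lengths = np.concatenate(
            [
                rng.integers(spec.long_range[0], spec.long_range[1] + 1, size=n_long),
                rng.integers(spec.short_range[0], spec.short_range[1] + 1, size=n_short),
            ]
        )
        for i, L in enumerate(lengths):
            cid = f"s{g}_c{i}"
            records.append(
                ContigRecord(
                    id=cid,
                    sequence=_draw_sequence(rng, probs, int(L), spec.markov_order),
                )
            )
            truth[cid] = f"species_{g}"
            species_of.append(g)

    contigs = ContigSet(records)
    abundance = rng.lognormal(
        mean=spec.abundance_mu, sigma=spec.abundance_sigma,
        size=(spec.G, spec.samples),
    )
    s = spec.coverage_noise_sd
    noise = rng.lognormal(
        mean=-0.5 * s**2, sigma=s, size=(contigs.N, spec.samples)
    ) if s > 0 else np.ones((contigs.N, spec.samples))
    Y = abundance[np.array(species_of)] * noise
    coverage = CoverageMatrix(
        values=Y,
        sample_ids=[f"sample_{m}" for m in range(spec.samples)],
        contig_ids=list(contigs.ids),
    )
    return contigs, coverage, truth


def degrade_separation(spec: CommunitySpec, factor: float) -> CommunitySpec:
    """Pull every species' nucleotide model toward the community mean.

    factor 0 leaves the spec unchanged; factor 1 makes all species
    compositionally identical, destroying the composition signal while
    leaving the coverage signal intact.
    """
    if not (0 <= factor <= 1):
        raise ValueError("factor must be in [0, 1]")
    models = np.asarray(spec.nucleotide_models, dtype=float)
    mean = models.mean(axis=0, keepdims=True)
    new_models = (1 - factor) * models + factor * mean
    return dataclasses.replace(spec, nucleotide_models=new_models)
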