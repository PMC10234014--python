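"""Multi-breed genotype simulator (Balding–Nichols model).

Every downstream module is testable without restricted cattle data by
simulating K diverged breeds.  Per SNP an ancestral allele frequency p is
drawn uniformly (0.05–0.95 by default, mimicking a MAF-filtered marker
set), and breed i's frequency comes from the Balding–Nichols beta
distribution

    p_i ~ Beta( p (1-F_i)/F_i,  (1-p)(1-F_i)/F_i )

whose dispersion parameter F_i is the breed's drift from the ancestral
population and is comparable to the F_ST it generates against the
ancestor.  Genotypes are binomial draws (2 trials at p_i) per SNP with no
linkage between loci.  Crossbreds draw each of their two allele copies
from a parental breed chosen by the ancestry proportions (an F1 takes one
copy from each parent).  Chip panels of lower density are emulated by
uniform random position subsets.

Real cattle breeds sit around pairwise F_ST 0.1–0.3 (closest pairs near
0.13), so simulation settings typically span F from 0.01 (hard, weakly
diverged) to 0.2 (easy, well separated).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .genotype_io import (
    AlleleFrequencyTable,
    BreedLabels,
    GenotypeMatrix,
    SnpMeta,
)

__all__ = [
    "SimulationConfig",
    "simulate_breed_frequencies",
    "simulate_genotypes",
    "simulate_crossbred",
    "make_chip_mask",
]

N_AUTOSOMES = 29  # SNPs are spread over this many chromosomes


@dataclass
class SimulationConfig:
    """Study design for one simulated multi-breed dataset."""

    n_breeds: int = 5
    n_snps: int = 5000
    samples_per_breed: int | dict[str, int] = 30
    drift: float | Sequence[float] = 0.2  # Balding–Nichols F per breed
    ancestral_range: tuple[float, float] = (0.05, 0.95)
    breed_names: list[str] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_breeds < 2:
            raise ValueError("need at least 2 breeds")
        if not self.breed_names:
            self.breed_names = [f"B{i + 1:02d}" for i in range(self.n_breeds)]
        if len(self.breed_names) != self.n_breeds:
            raise ValueError("breed_names length must equal n_breeds")
        lo, hi = self.ancestral_range
        if not 0.0 <= lo < hi <= 1.0:
            raise ValueError("ancestral_range must satisfy 0 <= lo < hi <= 1")
        for f in self.drift_per_breed():
            if not 0.0 < f < 1.0:
                raise ValueError(f"drift F must lie in (0, 1), got {f}")

    def drift_per_breed(self) -> list[float]:
        if np.isscalar(self.drift):
            return [float(self.drift)] * self.n_breeds
        drifts = [float(f) for f in self.drift]  # type: ignore[union-attr]
        if len(drifts) != self.n_breeds:
            raise ValueError("per-breed drift list length must equal n_breeds")
        return drifts

    def counts_per_breed(self) -> dict[str, int]:
        if isinstance(self.samples_per_breed, dict):
            return {b: int(self.samples_per_breed.get(b, 0)) for b in self.breed_names}
        return {b: int(self.samples_per_breed) for b in self.breed_names}


def _make_snp_meta(n_snps: int) -> list[SnpMeta]:
    """Spread SNPs over the autosomes with increasing positions."""
    per_chrom = -(-n_snps // N_AUTOSOMES)  # ceil
    snps = []
    for j in range(n_snps):
        chrom = str(j // per_chrom + 1)
        pos = (j % per_chrom + 1) * 1000
        snps.append(SnpMeta(f"snp{j + 1}", chrom, pos, "A", "C"))
    return snps


def simulate_breed_frequencies(cfg: SimulationConfig) -> AlleleFrequencyTable:
    """True per-breed allele frequencies under the Balding–Nichols model."""
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.ancestral_range
    p = rng.uniform(lo, hi, size=cfg.n_snps)
    freqs = np.empty((cfg.n_breeds, cfg.n_snps))
    for i, f in enumerate(cfg.drift_per_breed()):
        a = p * (1.0 - f) / f
        b = (1.0 - p) * (1.0 - f) / f
        freqs[i] = rng.beta(a, b)
    return AlleleFrequencyTable(list(cfg.breed_names), _make_snp_meta(cfg.n_snps), freqs)


def simulate_genotypes(
    freqs: AlleleFrequencyTable,
    counts: dict[str, int],
    seed: int = 0,
    id_prefix: str = "",
) -> tuple[GenotypeMatrix, BreedLabels]:
    """Binomial(2, p_i) genotypes per breed; sample IDs encode breed + index."""
    unknown = [b for b in counts if b not in freqs.breeds]
    if unknown:
        raise KeyError(f"breeds not in frequency table: {unknown}")
    rng = np.random.default_rng(seed)
    samples: list[str] = []
    mapping: dict[str, str] = {}
    blocks: list[np.ndarray] = []
    for breed, n in counts.items():
        if n < 1:
            raise ValueError(f"breed {breed!r}: need at least 1 sample, got {n}")
        p = freqs.freqs[freqs.breeds.index(breed)]
        blocks.append(rng.binomial(2, p, size=(n, freqs.n_snps)).astype(np.int16))
        for i in range(n):
            sid = f"{id_prefix}{breed}_{i + 1:04d}"
            samples.append(sid)
            mapping[sid] = breed
    codes = np.vstack(blocks)
    breed_order = [b for b in freqs.breeds if b in counts]
    return (
        GenotypeMatrix(samples, list(freqs.snps), codes),
        BreedLabels(mapping, breeds=breed_order),
    )


def simulate_crossbred(
    freqs: AlleleFrequencyTable,
    breed_a: str,
    breed_b: str,
    n: int,
    proportions: tuple[float, float] = (0.5, 0.5),
    seed: int = 0,
    id_prefix: str = "X",
) -> GenotypeMatrix:
    """Crossbred animals between two breeds.

    At the default 0.5/0.5 (an F1) each animal draws one allele copy from
    each parental breed per SNP.  For general proportions each of the two
    copies independently picks its breed of origin with the given
    probabilities, then is Bernoulli at that breed's frequency.
    """
    for b in (breed_a, breed_b):
        if b not in freqs.breeds:
            raise KeyError(f"unknown breed {b!r}")
    w = np.asarray(proportions, dtype=float)
    if w.shape != (2,) or abs(w.sum() - 1.0) > 1e-9 or (w < 0).any():
        raise ValueError("proportions must be two nonnegative numbers summing to 1")
    rng = np.random.default_rng(seed)
    pa = freqs.freqs[freqs.breeds.index(breed_a)]
    pb = freqs.freqs[freqs.breeds.index(breed_b)]

    if np.allclose(w, (0.5, 0.5)):
        codes = (
            rng.binomial(1, pa, size=(n, freqs.n_snps))
            + rng.binomial(1, pb, size=(n, freqs.n_snps))
        ).astype(np.int16)
    else:
        codes = np.zeros((n, freqs.n_snps), dtype=np.int16)
        for copy in range(2):
            from_a = rng.random(size=(n, freqs.n_snps)) < w[0]
            allele_a = rng.binomial(1, pa, size=(n, freqs.n_snps))
            allele_b = rng.binomial(1, pb, size=(n, freqs.n_snps))
            codes += np.where(from_a, allele_a, allele_b).astype(np.int16)
    samples = [f"{id_prefix}_{breed_a}x{breed_b}_{i + 1:04d}" for i in range(n)]
    return GenotypeMatrix(samples, list(freqs.snps), codes)


def make_chip_mask(
    snps: Sequence[SnpMeta],
    fraction: float | None = None,
    count: int | None = None,
    seed: int = 0,
) -> list[tuple[str, int]]:
    """Uniform random subset of SNP positions emulating a lower-density chip."""
    if (fraction is None) == (count is None):
        raise ValueError("give exactly one of fraction or count")
    n = len(snps)
    if fraction is not None:
        if not 0.0 < fraction <= 1.0:
            raise ValueError("fraction must lie in (0, 1]")
        count = max(1, round(fraction * n))
    if not 0 < count <= n:  # type: ignore[operator]
        raise ValueError(f"count must lie in (0, {n}]")
    rng = np.random.default_rng(seed)
    idx = rng.choice(n, size=count, replace=False)
    idx.sort()
    return [(snps[i].chrom, snps[i].pos) for i in idx]
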