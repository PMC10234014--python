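"""Per-SNP breed-informativeness statistics and marker-panel selection.

Three classical statistics score how well one biallelic SNP separates K
breeds, all computed from the breeds x SNPs allele-frequency table:

* ``delta`` — mean absolute allele-frequency difference over all K(K-1)/2
  breed pairs; in [0, 1].
* ``fst`` — mean pairwise Wright's fixation index, per pair
  (H_T - H_S) / H_T with H_T = 2 p̄ (1 - p̄) the heterozygosity expected at
  the mean frequency of the two breeds and H_S = p_i(1-p_i) + p_j(1-p_j);
  defined 0 when H_T = 0.  In [0, 1], reaching 1 at a fixed difference.
* ``in`` — informativeness for assignment, an entropy decomposition over
  both alleles: sum_a [ -p̄_a log2 p̄_a + (1/K) sum_i p_ia log2 p_ia ], with
  p̄_a the unweighted mean over breeds and 0 log2 0 = 0.  In [0, log2 K],
  in bits.

The top-M SNPs by a statistic form a marker panel of "most breed-
informative" (MBI) SNPs.  The integrated DFI panel takes the SNPs common to
the three statistics' expanded top lists: the per-method depth d >= M is
grown until the three top-d lists share at least M SNPs, and the
intersection is ordered by summed per-method rank and truncated to M.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np

from .genotype_io import AlleleFrequencyTable, SnpMeta

__all__ = [
    "METHODS",
    "ScoreTable",
    "MarkerPanel",
    "BreedDistanceMatrix",
    "delta_scores",
    "fst_scores",
    "in_scores",
    "compute_scores",
    "rank_select_top_m",
    "dfi_panel",
    "pairwise_fst_matrix",
    "panel_chip_overlap",
]

METHODS = ("delta", "fst", "in")


def _require_k2(f: AlleleFrequencyTable) -> None:
    if f.k < 2:
        raise ValueError(f"need at least 2 breeds, got {f.k}")


def delta_scores(f: AlleleFrequencyTable) -> np.ndarray:
    """Mean |p_i - p_j| over all unordered breed pairs, per SNP."""
    _require_k2(f)
    p = f.freqs
    pairs = list(combinations(range(f.k), 2))
    acc = np.zeros(f.n_snps)
    for i, j in pairs:
        acc += np.abs(p[i] - p[j])
    return acc / len(pairs)


def _pair_fst(pi: np.ndarray, pj: np.ndarray) -> np.ndarray:
    pbar = 0.5 * (pi + pj)
    h_t = 2.0 * pbar * (1.0 - pbar)
    h_s = pi * (1.0 - pi) + pj * (1.0 - pj)
    # concavity of 2p(1-p) guarantees h_s <= h_t
    assert (h_s <= h_t + 1e-12).all()
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = (h_t - h_s) / h_t
    return np.where(h_t > 0, fst, 0.0)


def fst_scores(f: AlleleFrequencyTable) -> np.ndarray:
    """Mean pairwise (H_T - H_S)/H_T over breed pairs, per SNP."""
    _require_k2(f)
    p = f.freqs
    pairs = list(combinations(range(f.k), 2))
    acc = np.zeros(f.n_snps)
    for i, j in pairs:
        acc += _pair_fst(p[i], p[j])
    return acc / len(pairs)


def _xlog2x(x: np.ndarray) -> np.ndarray:
    """x * log2(x) with the 0 log2 0 = 0 convention."""
    out = np.zeros_like(x, dtype=float)
    nz = x > 0
    out[nz] = x[nz] * np.log2(x[nz])
    return out


def in_scores(f: AlleleFrequencyTable) -> np.ndarray:
    """Informativeness for assignment per SNP, in bits."""
    _require_k2(f)
    total = np.zeros(f.n_snps)
    for allele_freqs in (f.freqs, 1.0 - f.freqs):  # alt then ref allele
        pbar = allele_freqs.mean(axis=0)
        total += -_xlog2x(pbar) + _xlog2x(allele_freqs).mean(axis=0)
    return np.clip(total, 0.0, None)  # clip -0.0 / tiny negatives from rounding


@dataclass
class ScoreTable:
    """Scores and ranks (1 = most informative) per SNP for each statistic."""

    snps: list[SnpMeta]
    scores: dict[str, np.ndarray]
    ranks: dict[str, np.ndarray]

    @classmethod
    def from_scores(cls, snps: Sequence[SnpMeta], scores: dict[str, np.ndarray]) -> "ScoreTable":
        snps = list(snps)
        ranks = {m: _ranks_desc(np.asarray(s, dtype=float), snps) for m, s in scores.items()}
        return cls(snps, {m: np.asarray(s, dtype=float) for m, s in scores.items()}, ranks)

    def to_dataframe(self):
        import pandas as pd

        data = {
            "snp_id": [s.snp_id for s in self.snps],
            "chrom": [s.chrom for s in self.snps],
            "pos": [s.pos for s in self.snps],
        }
        for m in self.scores:
            data[m] = self.scores[m]
        for m in self.ranks:
            data[f"rank_{m}"] = self.ranks[m]
        return pd.DataFrame(data)


def _tie_key(snp: SnpMeta) -> tuple:
    chrom = snp.chrom
    return ((0, int(chrom)) if chrom.isdigit() else (1, chrom), snp.pos)


def _order_desc(scores: np.ndarray, snps: Sequence[SnpMeta]) -> np.ndarray:
    """Indices sorted by descending score; ties by ascending (chrom, pos)."""
    return np.asarray(
        sorted(range(len(scores)), key=lambda j: (-scores[j], _tie_key(snps[j]))),
        dtype=int,
    )

def _ranks_desc(scores: np.ndarray, snps: Sequence[SnpMeta]) -> np.ndarray:
    order = _order_desc(scores, snps)
    ranks = np.empty(len(scores), dtype=int)
    ranks[order] = np.arange(1, len(scores) + 1)
    return ranks


def compute_scores(f: AlleleFrequencyTable) -> ScoreTable:
    """All three statistics plus ranks for every SNP in the table."""
    return ScoreTable.from_scores(
        f.snps,
        {"delta": delta_scores(f), "fst": fst_scores(f), "in": in_scores(f)},
    )


@dataclass
class MarkerPanel:
    """An ordered panel of M selected (most breed-informative) SNPs."""

    method: str  # delta | fst | in | dfi
    m: int
    snps: list[SnpMeta]
    scores: dict[str, np.ndarray]  # per-method scores of the selected SNPs
    ranks: dict[str, np.ndarray]
    depth: int | None = None  # per-method list depth d (dfi only)

    def __post_init__(self) -> None:
        if len(self.snps) != self.m:
            raise ValueError(f"panel holds {len(self.snps)} SNPs, expected M={self.m}")
        ids = [s.snp_id for s in self.snps]
        if len(set(ids)) != len(ids):
            raise ValueError("panel contains duplicate SNPs")

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]

    def positions(self) -> list[tuple[str, int]]:
        return [(s.chrom, s.pos) for s in self.snps]

    def to_dataframe(self):
        import pandas as pd

        data = {
            "snp_id": self.snp_ids,
            "chrom": [s.chrom for s in self.snps],
            "pos": [s.pos for s in self.snps],
        }
        for m in self.scores:
            data[m] = self.scores[m]
        for m in self.ranks:
            data[f"rank_{m}"] = self.ranks[m]
        data["selected_by"] = self.method
        return pd.DataFrame(data)


def rank_select_top_m(table: ScoreTable, method: str, m: int) -> MarkerPanel:
    """Top-M SNPs by one statistic, descending, ties by (chrom, pos)."""
    if method not in table.scores:
        raise KeyError(f"unknown method {method!r}; have {sorted(table.scores)}")
    n = len(table.snps)
    if m > n:
        raise ValueError(f"M={m} exceeds available SNPs ({n})")
    order = _order_desc(table.scores[method], table.snps)[:m]
    return MarkerPanel(
        method=method,
        m=m,
        snps=[table.snps[j] for j in order],
        scores={k: v[order] for k, v in table.scores.items()},
        ranks={k: v[order] for k, v in table.ranks.items()},
    )


def dfi_panel(
    f: AlleleFrequencyTable | ScoreTable,
    m: int,
    growth: float = 1.25,
) -> MarkerPanel:
    """Integrated panel: SNPs common to all three statistics' top-d lists.

    The per-method depth d starts at M and grows multiplicatively (factor
    ``growth``, capped at N) until the intersection of the three top-d lists
    holds at least M SNPs, then d is refined down to the smallest depth that
    still works (intersection size is monotone in d).  Panel members are
    ordered by summed per-method rank, ties by (chrom, pos), truncated to M.
    """
    table = f if isinstance(f, ScoreTable) else compute_scores(f)
    n = len(table.snps)
    if m > n:
        raise ValueError(f"M={m} exceeds available SNPs ({n})")
    if growth <= 1.0:
        raise ValueError("growth factor must exceed 1")

    orders = {meth: _order_desc(table.scores[meth], table.snps) for meth in METHODS}

    def inter_size(d: int) -> int:
        common = set(orders["delta"][:d])
        common &= set(orders["fst"][:d])
        common &= set(orders["in"][:d])
        return len(common)

    # bracket with the multiplicative ladder, then binary-refine to minimal d
    d = m
    while inter_size(d) < m:
        if d >= n:
            raise RuntimeError("intersection never reached M SNPs")  # unreachable at d=N
        d = min(n, math.ceil(d * growth))
    lo = m if d == m else max(m, math.ceil(d / growth))
    hi = d
    while lo < hi:
        mid = (lo + hi) // 2
        if inter_size(mid) >= m:
            hi = mid
        else:
            lo = mid + 1
    d = lo

    common = set(orders["delta"][:d]) & set(orders["fst"][:d]) & set(orders["in"][:d])
    summed_rank = sum(table.ranks[meth] for meth in METHODS)
    chosen = sorted(common, key=lambda j: (summed_rank[j], _tie_key(table.snps[j])))[:m]
    idx = np.asarray(chosen, dtype=int)
    return MarkerPanel(
        method="dfi",
        m=m,
        snps=[table.snps[j] for j in idx],
        scores={k: v[idx] for k, v in table.scores.items()},
        ranks={k: v[idx] for k, v in table.ranks.items()},
        depth=d,
    )


@dataclass
class BreedDistanceMatrix:
    """Symmetric K x K matrix of mean pairwise F_ST between breeds."""

    breeds: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        k = len(self.breeds)
        if self.values.shape != (k, k):
            raise ValueError("distance matrix shape mismatch")

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.breeds, columns=self.breeds)


def pairwise_fst_matrix(f: AlleleFrequencyTable) -> BreedDistanceMatrix:
    """Mean-over-SNPs pairwise F_ST for every breed pair (genetic distance)."""
    _require_k2(f)
    k = f.k
    out = np.zeros((k, k))
    for i, j in combinations(range(k), 2):
        out[i, j] = out[j, i] = _pair_fst(f.freqs[i], f.freqs[j]).mean()
    return BreedDistanceMatrix(list(f.breeds), out)


def panel_chip_overlap(
    panel: MarkerPanel, chip_positions: Iterable[tuple[str, int]]
) -> tuple[int, list[SnpMeta]]:
    """How many panel SNPs sit on a chip given as (chrom, pos) sites."""
    chip = {(str(c), int(p)) for c, p in chip_positions}
    hits = [s for s in panel.snps if (s.chrom, s.pos) in chip]
    return len(hits), hits
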