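"""Genomic breed composition (GBC) by linear regression.

A test animal's genotype vector y (alt-allele counts over a SNP set) is
regressed on the breed allele frequencies of a K-breed reference panel:

    y = 1 mu + X b + e

where X (SNPs x K) holds the reference alt-allele frequency of each SNP in
each breed, mu is an intercept and b the per-breed regression
coefficients.  The composition for breed k is the coefficient ratio
b_k / sum_j b_j, so the K proportions sum to one by construction.  For a
purebred animal of breed k the expected genotype is 2 p_k, which the
regression recovers as b_k = 2, others 0 — composition 1 for breed k.  An
animal is called purebred when its largest composition strictly exceeds a
threshold (0.9 by default).

Ordinary least squares is the default; coefficients may then be negative
and are reported as-is.  An optional nonnegative mode (``mode="nnls"``)
constrains b >= 0 before normalisation.  The residual variance plays no
role in the point estimate and is not reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .genotype_io import AlleleFrequencyTable, BreedLabels, GenotypeMatrix

__all__ = ["GbcEstimate", "estimate_gbc", "call_purebred", "gbc_table"]


@dataclass
class GbcEstimate:
    """Per-animal breed-composition estimate from the regression fit."""

    sample_id: str
    breeds: list[str]
    coefficients: np.ndarray  # b, one per breed
    intercept: float
    gbc: np.ndarray  # b / sum(b), sums to 1

    @property
    def has_negative(self) -> bool:
        return bool((self.coefficients < 0).any())

    @property
    def assigned_breed(self) -> str:
        return self.breeds[int(np.argmax(self.gbc))]

    @property
    def max_gbc(self) -> float:
        return float(self.gbc.max())

    def as_series(self) -> pd.Series:
        return pd.Series(self.gbc, index=self.breeds, name=self.sample_id)


def _collinear_breeds(X: np.ndarray, breeds: Sequence[str]) -> list[tuple[str, str]]:
    pairs = []
    for i in range(X.shape[1]):
        for j in range(i + 1, X.shape[1]):
            if np.allclose(X[:, i], X[:, j]):
                pairs.append((breeds[i], breeds[j]))
    return pairs


def estimate_gbc(
    genotypes: np.ndarray,
    freqs: AlleleFrequencyTable,
    sample_id: str = "sample",
    mode: str = "ols",
) -> GbcEstimate:
    """Fit the composition regression for one animal.

    Parameters
    ----------
    genotypes : 1-D array of alt-allele counts (0/1/2), one per SNP, aligned
        with ``freqs.snps``.
    freqs : reference breed allele frequencies (K x SNPs).
    mode : "ols" (default, unconstrained) or "nnls" (coefficients >= 0).
    """
    y = np.asarray(genotypes, dtype=float).ravel()
    X = freqs.freqs.T  # SNPs x K
    if y.shape[0] != X.shape[0]:
        raise ValueError(f"{y.shape[0]} genotypes vs {X.shape[0]} SNPs in frequency table")
    k = freqs.k
    if y.shape[0] <= k:
        raise ValueError("need more SNPs than breeds to fit the regression")

    design = np.column_stack([np.ones(len(y)), X])
    if np.linalg.matrix_rank(design) < k + 1:
        pairs = _collinear_breeds(X, freqs.breeds)
        detail = f"; identical frequency columns: {pairs}" if pairs else ""
        raise ValueError(f"rank-deficient design (collinear breed frequencies){detail}")

    if mode == "ols":
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        intercept, b = float(beta[0]), beta[1:]
    elif mode == "nnls":
        from scipy.optimize import nnls

        # demean so the intercept is implicit, then constrain b >= 0
        Xc = X - X.mean(axis=0)
        yc = y - y.mean()
        b, _ = nnls(Xc, yc)
        intercept = float(y.mean() - X.mean(axis=0) @ b)
    else:
        raise ValueError(f"unknown mode {mode!r}; choose 'ols' or 'nnls'")

    total = b.sum()
    if abs(total) < 1e-8 * max(np.abs(b).mean(), 1e-300):
        raise ValueError(
            f"sum of regression coefficients ~ 0 ({total:.3e}); composition undefined"
        )
    return GbcEstimate(
        sample_id=sample_id,
        breeds=list(freqs.breeds),
        coefficients=b,
        intercept=intercept,
        gbc=b / total,
    )


def call_purebred(est: GbcEstimate, threshold: float = 0.9) -> tuple[bool, str]:
    """Purebred iff the largest composition strictly exceeds the threshold."""
    return est.max_gbc > threshold, est.assigned_breed


def gbc_table(
    g: GenotypeMatrix,
    labels: BreedLabels,
    freqs: AlleleFrequencyTable,
    mode: str = "ols",
) -> pd.DataFrame:
    """Average composition (percent) of the animals of each labelled breed.

    Rows are the animals' labelled breeds, columns the reference breeds;
    each row averages the per-animal composition vectors and sums to 100%
    (up to rounding).
    """
    lookup = {s.snp_id: j for j, s in enumerate(g.snps)}
    missing = [s.snp_id for s in freqs.snps if s.snp_id not in lookup]
    if missing:
        raise KeyError(f"frequency-table SNPs absent from genotypes: {missing[:5]}")
    idx = [lookup[s.snp_id] for s in freqs.snps]

    rows: dict[str, list[np.ndarray]] = {b: [] for b in labels.breeds}
    for i, sample in enumerate(g.samples):
        breed = labels.mapping.get(sample)
        if breed is None:
            raise KeyError(f"unlabelled test sample {sample!r}")
        est = estimate_gbc(g.codes[i, idx], freqs, sample_id=sample, mode=mode)
        rows.setdefault(breed, []).append(est.gbc)
    table = pd.DataFrame(
        {b: 100.0 * np.mean(v, axis=0) if v else np.full(freqs.k, np.nan)
         for b, v in rows.items()},
        index=freqs.breeds,
    ).T
    table.index.name = "labelled_breed"
    return table
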