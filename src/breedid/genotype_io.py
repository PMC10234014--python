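"""Genotype I/O, quality control, and breed allele frequencies.

The central container is :class:`GenotypeMatrix`: an individuals x SNPs
matrix of alt-allele counts (0/1/2, with ``MISSING`` = -1 allowed only
before QC).  Breed membership lives in :class:`BreedLabels`, and per-breed
alt-allele frequencies in :class:`AlleleFrequencyTable` — the substrate for
every informativeness statistic and for the composition regression.

QC mirrors standard practice for breed-informative marker discovery:
biallelic SNPs only, complete genotyping (the downstream statistics and
classifiers tolerate no missing values), autosomes only, minor-allele
frequency >= 0.05 (pooled over all samples), and PLINK-style windowed LD
pruning at r^2 > 0.2 in a 50-SNP window.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "MISSING",
    "SnpMeta",
    "GenotypeMatrix",
    "BreedLabels",
    "QCConfig",
    "QCReport",
    "AlleleFrequencyTable",
    "read_vcf",
    "write_vcf",
    "read_labels",
    "write_labels",
    "read_tsv",
    "write_tsv",
    "read_positions",
    "write_positions",
    "qc_basic",
    "maf_filter",
    "ld_prune",
    "allele_frequencies",
    "subset_to_positions",
]

MISSING = -1

# default cattle autosomes
CATTLE_AUTOSOMES = frozenset(str(c) for c in range(1, 30))


@dataclass(frozen=True)
class SnpMeta:
    """Identity and genomic position of one SNP (1-based, VCF convention)."""

    snp_id: str
    chrom: str
    pos: int
    ref_allele: str = "A"
    alt_allele: str = "C"

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"SNP {self.snp_id}: pos must be >= 1, got {self.pos}")

    @property
    def is_biallelic_snp(self) -> bool:
        """True for a simple biallelic substitution (one-base ref and alt)."""
        return (
            len(self.ref_allele) == 1
            and len(self.alt_allele) == 1
            and self.ref_allele != self.alt_allele
            and "," not in self.alt_allele
        )


class GenotypeMatrix:
    """Samples x SNPs matrix of alt-allele counts.

    Parameters
    ----------
    samples : sequence of str
        Ordered sample IDs (unique).
    snps : sequence of SnpMeta
        Ordered SNP metadata (unique IDs).
    codes : ndarray of shape (n_samples, n_snps)
        Integer alt-allele counts in {0, 1, 2}, or ``MISSING`` (-1).
    """

    def __init__(
        self,
        samples: Sequence[str],
        snps: Sequence[SnpMeta],
        codes: np.ndarray,
    ) -> None:
        self.samples = list(samples)
        self.snps = list(snps)
        codes = np.asarray(codes, dtype=np.int16)
        if codes.shape != (len(self.samples), len(self.snps)):
            raise ValueError(
                f"codes shape {codes.shape} does not match "
                f"{len(self.samples)} samples x {len(self.snps)} SNPs"
            )
        bad = ~np.isin(codes, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError(f"codes contain {bad.sum()} entries outside {{0,1,2,{MISSING}}}")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample IDs")
        ids = [s.snp_id for s in self.snps]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate SNP IDs")
        self.codes = codes

    # -- basic introspection ------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def has_missing(self) -> bool:
        return bool((self.codes == MISSING).any())

    def positions(self) -> list[tuple[str, int]]:
        return [(s.chrom, s.pos) for s in self.snps]

    # -- subsetting ---------------------------------------------------------

    def take_snps(self, indices: Sequence[int]) -> "GenotypeMatrix":
        idx = np.asarray(indices, dtype=int)
        return GenotypeMatrix(
            self.samples, [self.snps[i] for i in idx], self.codes[:, idx]
        )

    def take_samples(self, sample_ids: Sequence[str]) -> "GenotypeMatrix":
        lookup = {s: i for i, s in enumerate(self.samples)}
        missing = [s for s in sample_ids if s not in lookup]
        if missing:
            raise KeyError(f"samples not in matrix: {missing[:5]}")
        idx = [lookup[s] for s in sample_ids]
        return GenotypeMatrix(list(sample_ids), self.snps, self.codes[idx, :])

    def assert_complete(self, context: str = "") -> None:
        if self.has_missing:
            where = context or "this operation"
            raise ValueError(f"missing genotypes not allowed in {where}; run qc_basic first")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.samples == other.samples
            and self.snps == other.snps
            and np.array_equal(self.codes, other.codes)
        )

    def __repr__(self) -> str:
        return f"GenotypeMatrix({self.n_samples} samples x {self.n_snps} SNPs)"


@dataclass
class BreedLabels:
    """Mapping of sample ID to breed code, with the ordered breed list."""

    mapping: dict[str, str]
    breeds: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: list[str] = []
        for b in self.mapping.values():
            if b not in seen:
                seen.append(b)
        if not self.breeds:
            self.breeds = seen
        if len(self.breeds) < 2:
            raise ValueError(f"need at least 2 breeds, got {len(self.breeds)}")

    @property
    def k(self) -> int:
        return len(self.breeds)

    def samples_of(self, breed: str) -> list[str]:
        return [s for s, b in self.mapping.items() if b == breed]

    def labels_for(self, samples: Sequence[str]) -> np.ndarray:
        missing = [s for s in samples if s not in self.mapping]
        if missing:
            raise KeyError(f"unlabelled samples: {missing[:5]}")
        return np.asarray([self.mapping[s] for s in samples])

    def validate_against(self, g: GenotypeMatrix) -> None:
        absent = [s for s in self.mapping if s not in set(g.samples)]
        if absent:
            raise ValueError(f"labelled samples absent from genotypes: {absent[:5]}")

    def subset(self, samples: Sequence[str]) -> "BreedLabels":
        return BreedLabels({s: self.mapping[s] for s in samples})


@dataclass
class QCConfig:
    """Thresholds for the marker QC and pre-filter pipeline."""

    maf_min: float = 0.05
    ld_r2_max: float = 0.2
    ld_window_snps: int = 50
    ld_step_snps: int = 5
    require_autosomes: bool = True
    autosome_names: frozenset[str] = CATTLE_AUTOSOMES

    def __post_init__(self) -> None:
        if not 0.0 <= self.maf_min <= 0.5:
            raise ValueError(f"maf_min must be in [0, 0.5], got {self.maf_min}")
        if not 0.0 <= self.ld_r2_max <= 1.0:
            raise ValueError(f"ld_r2_max must be in [0, 1], got {self.ld_r2_max}")
        if self.ld_window_snps < 2:
            raise ValueError("ld_window_snps must be >= 2")
        if not 1 <= self.ld_step_snps <= self.ld_window_snps:
            raise ValueError("ld_step_snps must be in [1, ld_window_snps]")


@dataclass
class QCReport:
    """Per-criterion removal tallies; removed + retained = input count."""

    input_snps: int = 0
    removed_non_biallelic: int = 0
    removed_missingness: int = 0
    removed_non_autosomal: int = 0
    removed_maf: int = 0
    removed_ld: int = 0
    retained: int = 0

    @property
    def removed_total(self) -> int:
        return (
            self.removed_non_biallelic
            + self.removed_missingness
            + self.removed_non_autosomal
            + self.removed_maf
            + self.removed_ld
        )

    def check_conservation(self) -> None:
        if self.removed_total + self.retained != self.input_snps:
            raise AssertionError(
                f"QC conservation violated: {self.removed_total} removed + "
                f"{self.retained} retained != {self.input_snps} input"
            )


@dataclass
class AlleleFrequencyTable:
    """Breeds x SNPs alt-allele frequencies (reference population)."""

    breeds: list[str]
    snps: list[SnpMeta]
    freqs: np.ndarray  # shape (K, n_snps)

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.freqs.shape != (len(self.breeds), len(self.snps)):
            raise ValueError(
                f"freqs shape {self.freqs.shape} != ({len(self.breeds)}, {len(self.snps)})"
            )
        if ((self.freqs < 0) | (self.freqs > 1)).any():
            raise ValueError("allele frequencies must lie in [0, 1]")

    @property
    def k(self) -> int:
        return len(self.breeds)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def take_snps(self, indices: Sequence[int]) -> "AlleleFrequencyTable":
        idx = np.asarray(indices, dtype=int)
        return AlleleFrequencyTable(
            self.breeds, [self.snps[i] for i in idx], self.freqs[:, idx]
        )


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def read_vcf(path: str, samples_filter: Sequence[str] | None = None) -> GenotypeMatrix:
    """Read diploid GT calls from a VCF into alt-allele counts.

    Multi-allelic or non-SNP records are retained (alt alleles joined with
    commas) and removed later by :func:`qc_basic`.  Missing calls become the
    ``MISSING`` sentinel.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    all_samples = list(vcf.samples)
    if samples_filter is not None:
        absent = [s for s in samples_filter if s not in all_samples]
        if absent:
            raise KeyError(f"requested samples absent from VCF: {absent[:5]}")
        keep_idx = [all_samples.index(s) for s in samples_filter]
        samples = list(samples_filter)
    else:
        keep_idx = list(range(len(all_samples)))
        samples = all_samples

    snps: list[SnpMeta] = []
    columns: list[np.ndarray] = []
    for i, var in enumerate(vcf):
        alt = ",".join(var.ALT) if var.ALT else "."
        snp_id = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}"
        snps.append(SnpMeta(snp_id, str(var.CHROM), int(var.POS), var.REF, alt))
        col = np.full(len(keep_idx), MISSING, dtype=np.int16)
        gts = var.genotypes  # [[a0, a1, phased], ...]
        for out_j, j in enumerate(keep_idx):
            a0, a1 = gts[j][0], gts[j][1]
            if a0 < 0 or a1 < 0:
                continue
            col[out_j] = int(a0 > 0) + int(a1 > 0)
        columns.append(col)
    vcf.close()
    codes = (
        np.stack(columns, axis=1) if columns else np.empty((len(samples), 0), dtype=np.int16)
    )
    return GenotypeMatrix(samples, snps, codes)


def write_vcf(g: GenotypeMatrix, path: str) -> None:
    """Write a minimal GT-only VCF 4.2 file."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.samples)
            + "\n"
        )
        gt_map = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        for j, snp in enumerate(g.snps):
            gts = "\t".join(gt_map[int(c)] for c in g.codes[:, j])
            fh.write(
                f"{snp.chrom}\t{snp.pos}\t{snp.snp_id}\t{snp.ref_allele}\t"
                f"{snp.alt_allele}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def read_labels(path: str) -> BreedLabels:
    """Read a sample_id<TAB>breed table (header required)."""
    mapping: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if not header.strip():
            raise ValueError(f"empty labels file: {path}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected sample_id<TAB>breed")
            sample, breed = parts[0], parts[1]
            if sample in mapping:
                raise ValueError(f"{path}:{lineno}: duplicate sample ID {sample!r}")
            mapping[sample] = breed
    if not mapping:
        raise ValueError(f"labels file has no data rows: {path}")
    return BreedLabels(mapping)


def write_labels(labels: BreedLabels, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("sample_id\tbreed\n")
        for s, b in labels.mapping.items():
            fh.write(f"{s}\t{b}\n")


def write_tsv(g: GenotypeMatrix, path: str) -> None:
    """Write the TSV genotype dialect: header of snp_ids, rows sample + codes.

    SNP metadata goes to a ``<path>.snps`` sidecar so a round trip through
    :func:`read_tsv` is lossless.
    """
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("sample_id\t" + "\t".join(s.snp_id for s in g.snps) + "\n")
        for i, sample in enumerate(g.samples):
            fh.write(sample + "\t" + "\t".join(str(int(c)) for c in g.codes[i]) + "\n")
    with open(str(path) + ".snps", "w", encoding="utf-8") as fh:
        fh.write("snp_id\tchrom\tpos\tref_allele\talt_allele\n")
        for s in g.snps:
            fh.write(f"{s.snp_id}\t{s.chrom}\t{s.pos}\t{s.ref_allele}\t{s.alt_allele}\n")


def read_tsv(path: str) -> GenotypeMatrix:
    """Read the TSV genotype dialect (with optional ``.snps`` sidecar)."""
    import os

    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if not header or header[0] != "sample_id":
            raise ValueError(f"{path}: first header column must be 'sample_id'")
        snp_ids = header[1:]
        samples: list[str] = []
        rows: list[list[int]] = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(snp_ids) + 1:
                raise ValueError(f"{path}:{lineno}: expected {len(snp_ids) + 1} columns")
            samples.append(parts[0])
            rows.append([int(x) for x in parts[1:]])

    sidecar = str(path) + ".snps"
    if os.path.exists(sidecar):
        meta: dict[str, SnpMeta] = {}
        with open(sidecar, encoding="utf-8") as fh:
            fh.readline()
            for line in fh:
                if not line.strip():
                    continue
                sid, chrom, pos, ref, alt = line.rstrip("\n").split("\t")
                meta[sid] = SnpMeta(sid, chrom, int(pos), ref, alt)
        snps = [meta[sid] for sid in snp_ids]
    else:
        snps = [SnpMeta(sid, "0", j + 1) for j, sid in enumerate(snp_ids)]

    codes = (
        np.asarray(rows, dtype=np.int16)
        if rows
        else np.empty((0, len(snp_ids)), dtype=np.int16)
    )
    return GenotypeMatrix(samples, snps, codes)


def read_positions(path: str) -> list[tuple[str, int]]:
    """Read a chrom<TAB>pos list (header required)."""
    out: list[tuple[str, int]] = []
    with open(path, encoding="utf-8") as fh:
        fh.readline()
        for line in fh:
            if not line.strip():
                continue
            chrom, pos = line.rstrip("\n").split("\t")[:2]
            out.append((chrom, int(pos)))
    return out


def write_positions(positions: Iterable[tuple[str, int]], path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("chrom\tpos\n")
        for chrom, pos in positions:
            fh.write(f"{chrom}\t{pos}\n")


# ---------------------------------------------------------------------------
# QC operations
# ---------------------------------------------------------------------------


def qc_basic(g: GenotypeMatrix, cfg: QCConfig | None = None) -> tuple[GenotypeMatrix, QCReport]:
    """Remove non-biallelic/non-SNP records, SNPs with any missing genotype,
    and (optionally) non-autosomal SNPs.

    Each removed SNP is tallied under the first criterion it fails, in the
    order biallelic -> missingness -> autosome, so tallies sum exactly.
    """
    cfg = cfg or QCConfig()
    report = QCReport(input_snps=g.n_snps)
    keep: list[int] = []
    any_missing = (g.codes == MISSING).any(axis=0)
    for j, snp in enumerate(g.snps):
        if not snp.is_biallelic_snp:
            report.removed_non_biallelic += 1
        elif any_missing[j]:
            report.removed_missingness += 1
        elif cfg.require_autosomes and snp.chrom not in cfg.autosome_names:
            report.removed_non_autosomal += 1
        else:
            keep.append(j)
    report.retained = len(keep)
    report.check_conservation()
    if not keep:
        raise ValueError("qc_basic removed every SNP; nothing to analyse")
    return g.take_snps(keep), report


def maf_filter(g: GenotypeMatrix, maf_min: float = 0.05) -> GenotypeMatrix:
    """Keep SNPs whose pooled minor-allele frequency is >= ``maf_min``.

    The exclusion rule is strict ("MAF less than the threshold is removed"),
    so a SNP sitting exactly at the threshold survives.
    """
    g.assert_complete("maf_filter")
    if g.n_snps == 0:
        return g
    p_alt = g.codes.mean(axis=0) / 2.0
    maf = np.minimum(p_alt, 1.0 - p_alt)
    keep = np.flatnonzero(maf >= maf_min)
    return g.take_snps(keep)


def _window_r2(codes: np.ndarray, idx: Sequence[int]) -> np.ndarray:
    """Pairwise r^2 of the genotype columns ``idx``; zero-variance -> 0."""
    x = codes[:, idx].astype(float)
    x = x - x.mean(axis=0)
    sd = np.sqrt((x**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = np.outer(sd, sd)
        r = (x.T @ x) / denom
    r2 = np.square(np.where(denom > 0, r, 0.0))
    np.fill_diagonal(r2, 0.0)
    return r2


def _assert_sorted(g: GenotypeMatrix) -> None:
    def chrom_key(c: str):
        return (0, int(c)) if c.isdigit() else (1, c)

    pos = [(chrom_key(s.chrom), s.pos) for s in g.snps]
    if any(pos[i] > pos[i + 1] for i in range(len(pos) - 1)):
        raise ValueError("SNPs must be sorted by (chrom, pos) before LD pruning; sort the input")


def ld_prune(g: GenotypeMatrix, cfg: QCConfig | None = None) -> GenotypeMatrix:
    """Windowed greedy LD pruning of genotype columns.

    Within every window of ``ld_window_snps`` consecutive retained SNPs on a
    chromosome, whenever a retained pair has squared Pearson correlation
    above ``ld_r2_max`` the later-positioned SNP is removed.  Windows are
    scanned with stride ``ld_step_snps`` and the whole scan is iterated to a
    fixed point, so on return no within-window retained pair exceeds the
    threshold at any window offset.
    """
    cfg = cfg or QCConfig()
    g.assert_complete("ld_prune")
    _assert_sorted(g)
    w, thr = cfg.ld_window_snps, cfg.ld_r2_max

    retained = np.ones(g.n_snps, dtype=bool)
    chroms = np.asarray([s.chrom for s in g.snps])

    def prune_pass(stride: int) -> bool:
        changed = False
        for chrom in dict.fromkeys(chroms):  # preserve order
            while True:
                idx = np.flatnonzero(retained & (chroms == chrom))
                removed_any = False
                for start in range(0, max(len(idx) - 1, 1), stride):
                    window = idx[start : start + w]
                    live = [j for j in window if retained[j]]
                    if len(live) < 2:
                        continue
                    r2 = _window_r2(g.codes, live)
                    # repeatedly drop the later SNP of the worst offending pair
                    while True:
                        viol = np.argwhere(np.triu(r2, 1) > thr)
                        if viol.size == 0:
                            break
                        a, b = max(viol, key=lambda v: r2[v[0], v[1]])
                        retained[live[b]] = False
                        r2[b, :] = 0.0
                        r2[:, b] = 0.0
                        removed_any = True
                if removed_any:
                    changed = True
                else:
                    break
        return changed

    while prune_pass(cfg.ld_step_snps):
        pass
    # final stride-1 sweep guarantees the invariant at every window offset
    while prune_pass(1):
        pass
    return g.take_snps(np.flatnonzero(retained))


def allele_frequencies(g: GenotypeMatrix, labels: BreedLabels) -> AlleleFrequencyTable:
    """Per-breed alt-allele frequencies: sum(codes) / (2 * n_breed)."""
    g.assert_complete("allele_frequencies")
    labels.labels_for(g.samples)  # raises on unlabelled samples
    freqs = np.empty((labels.k, g.n_snps), dtype=float)
    sample_idx = {s: i for i, s in enumerate(g.samples)}
    for bi, breed in enumerate(labels.breeds):
        rows = [sample_idx[s] for s in labels.samples_of(breed) if s in sample_idx]
        if not rows:
            raise ValueError(f"breed {breed!r} has no samples in the genotype matrix")
        freqs[bi] = g.codes[rows, :].sum(axis=0) / (2.0 * len(rows))
    return AlleleFrequencyTable(list(labels.breeds), list(g.snps), freqs)


def subset_to_positions(
    g: GenotypeMatrix, positions: Iterable[tuple[str, int]]
) -> tuple[GenotypeMatrix, int]:
    """Keep SNPs whose (chrom, pos) is in ``positions``, preserving order.

    Returns the subset and the count of requested positions absent from the
    matrix (silently ignored, e.g. chip sites not segregating here).
    """
    wanted = {(str(c), int(p)) for c, p in positions}
    keep = [j for j, s in enumerate(g.snps) if (s.chrom, s.pos) in wanted]
    present = {(g.snps[j].chrom, g.snps[j].pos) for j in keep}
    n_absent = len(wanted - present)
    return g.take_snps(keep), n_absent
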