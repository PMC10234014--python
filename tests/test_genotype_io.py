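"""Genotype I/O, QC filters, and allele-frequency computation."""

import numpy as np
import pytest

from breedid.genotype_io import (
    MISSING,
    AlleleFrequencyTable,
    BreedLabels,
    GenotypeMatrix,
    QCConfig,
    SnpMeta,
    allele_frequencies,
    ld_prune,
    maf_filter,
    qc_basic,
    read_labels,
    read_tsv,
    read_vcf,
    subset_to_positions,
    write_labels,
    write_tsv,
    write_vcf,
)

from conftest import make_snps


def _matrix(codes, snps=None, samples=None):
    codes = np.asarray(codes)
    snps = snps or make_snps(codes.shape[1])
    samples = samples or [f"ind{i+1}" for i in range(codes.shape[0])]
    return GenotypeMatrix(samples, snps, codes)


# ---------------------------------------------------------------------- VCF


class TestVcf:
    def test_gt_encoding(self, tmp_path):
        """0/0, 0/1, 1/1 map to alt-allele counts 0, 1, 2."""
        vcf = tmp_path / "toy.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ta\tb\n"
            "1\t100\trs1\tA\tC\t.\tPASS\t.\tGT\t0/0\t0/1\n"
            "1\t200\trs2\tG\tT\t.\tPASS\t.\tGT\t1/1\t./.\n"
        )
        g = read_vcf(str(vcf))
        assert g.samples == ["a", "b"]
        assert g.codes[0].tolist() == [0, 2]
        assert g.codes[1].tolist() == [1, MISSING]

    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        codes = rng.integers(0, 3, size=(5, 20))
        codes[2, 4] = MISSING
        g = _matrix(codes)
        path = tmp_path / "rt.vcf"
        write_vcf(g, str(path))
        assert read_vcf(str(path)) == g

    def test_sample_filter_and_missing_sample(self, tmp_path):
        g = _matrix(np.zeros((3, 2), dtype=int))
        write_vcf(g, str(tmp_path / "f.vcf"))
        sub = read_vcf(str(tmp_path / "f.vcf"), samples_filter=["ind3", "ind1"])
        assert sub.samples == ["ind3", "ind1"]
        with pytest.raises(KeyError):
            read_vcf(str(tmp_path / "f.vcf"), samples_filter=["nope"])


class TestTsvDialect:
    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(1)
        g = _matrix(rng.integers(0, 3, size=(4, 7)))
        path = tmp_path / "g.tsv"
        write_tsv(g, str(path))
        assert read_tsv(str(path)) == g

    def test_empty_matrix_header_only(self, tmp_path):
        g = GenotypeMatrix([], make_snps(3), np.empty((0, 3), dtype=int))
        path = tmp_path / "empty.tsv"
        write_tsv(g, str(path))
        lines = path.read_text().splitlines()
        assert lines == ["sample_id\ts1\ts2\ts3"]
        assert read_tsv(str(path)) == g

    def test_single_cell(self, tmp_path):
        g = _matrix([[2]])
        path = tmp_path / "one.tsv"
        write_tsv(g, str(path))
        assert path.read_text().splitlines()[1] == "ind1\t2"


# ------------------------------------------------------------------- labels


class TestLabels:
    def test_k_counts(self, tmp_path):
        p = tmp_path / "l.tsv"
        p.write_text("sample_id\tbreed\ns1\tA\ns2\tA\ns3\tB\n")
        labels = read_labels(str(p))
        assert labels.k == 2 and labels.breeds == ["A", "B"]

    def test_duplicate_and_empty(self, tmp_path):
        p = tmp_path / "dup.tsv"
        p.write_text("sample_id\tbreed\ns1\tA\ns1\tB\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_labels(str(p))
        q = tmp_path / "empty.tsv"
        q.write_text("")
        with pytest.raises(ValueError):
            read_labels(str(q))

    def test_unknown_sample_fails_validation(self, tmp_path):
        labels = BreedLabels({"ghost": "A", "ind1": "B"})
        g = _matrix(np.zeros((1, 2), dtype=int))
        with pytest.raises(ValueError, match="absent"):
            labels.validate_against(g)

    def test_thirteen_breed_reference_shape(self, tmp_path):
        p = tmp_path / "big.tsv"
        rows = [f"b{b}_{i}\tBR{b:02d}" for b in range(13) for i in range(30)]
        p.write_text("sample_id\tbreed\n" + "\n".join(rows) + "\n")
        labels = read_labels(str(p))
        assert labels.k == 13 and len(labels.mapping) == 390

    def test_round_trip(self, tmp_path):
        labels = BreedLabels({"x": "A", "y": "B", "z": "A"})
        write_labels(labels, str(tmp_path / "l.tsv"))
        back = read_labels(str(tmp_path / "l.tsv"))
        assert back.mapping == labels.mapping


# ----------------------------------------------------------------------- QC


class TestQcBasic:
    def test_missingness_and_autosome_removal(self):
        snps = [
            SnpMeta("a", "1", 1),
            SnpMeta("b", "1", 2),
            SnpMeta("c", "X", 3),
            SnpMeta("d", "X", 4),
            SnpMeta("e", "2", 5),
        ]
        codes = np.ones((4, 5), dtype=int)
        codes[0, 1] = MISSING
        g = GenotypeMatrix([f"i{k}" for k in range(4)], snps, codes)
        out, report = qc_basic(g, QCConfig())
        assert [s.snp_id for s in out.snps] == ["a", "e"]
        assert report.removed_missingness == 1
        assert report.removed_non_autosomal == 2
        report.check_conservation()

    def test_non_biallelic_removed(self):
        snps = [SnpMeta("a", "1", 1), SnpMeta("b", "1", 2, "A", "C,T"),
                SnpMeta("c", "1", 3, "AT", "A")]
        g = GenotypeMatrix(["i"], snps, np.zeros((1, 3), dtype=int))
        out, report = qc_basic(g)
        assert [s.snp_id for s in out.snps] == ["a"]
        assert report.removed_non_biallelic == 2

    def test_clean_input_identity(self):
        g = _matrix(np.ones((3, 4), dtype=int))
        out, report = qc_basic(g)
        assert out == g and report.removed_total == 0

    def test_all_removed_raises(self):
        g = GenotypeMatrix(["i"], [SnpMeta("a", "X", 1)], np.zeros((1, 1), dtype=int))
        with pytest.raises(ValueError, match="every SNP"):
            qc_basic(g)


class TestMafFilter:
    @pytest.mark.parametrize(
        "column, kept",
        [
            ([0] * 10, False),       # monomorphic, MAF 0 -> removed
            ([1] + [0] * 9, True),   # alt freq 0.05, exactly at threshold -> kept
            ([2] * 9 + [1], True),   # alt freq 0.95 -> MAF 0.05, at threshold -> kept
            ([1] * 10, True),        # alt freq 0.5 -> kept
        ],
    )
    def test_boundary_rule(self, column, kept):
        codes = np.column_stack([column, [1] * 10])  # companion SNP keeps result nonempty
        out = maf_filter(_matrix(codes), 0.05)
        assert ("s1" in [s.snp_id for s in out.snps]) == kept

    def test_subset_property(self):
        rng = np.random.default_rng(3)
        g = _matrix(rng.integers(0, 3, (50, 30)))
        out = maf_filter(g, 0.1)
        assert set(s.snp_id for s in out.snps) <= set(s.snp_id for s in g.snps)
        assert out.samples == g.samples


def brute_force_window_scan(g, cfg):
    """Max r^2 over every pair within any window of consecutive retained SNPs."""
    worst = 0.0
    chroms = [s.chrom for s in g.snps]
    for chrom in set(chroms):
        idx = [j for j, c in enumerate(chroms) if c == chrom]
        for start in range(len(idx)):
            window = idx[start : start + cfg.ld_window_snps]
            for a in range(len(window)):
                for b in range(a + 1, len(window)):
                    x, y = g.codes[:, window[a]], g.codes[:, window[b]]
                    if x.std() == 0 or y.std() == 0:
                        continue
                    r = np.corrcoef(x, y)[0, 1]
                    worst = max(worst, r * r)
    return worst


class TestLdPrune:
    def test_duplicate_column_pruned(self):
        rng = np.random.default_rng(4)
        base = rng.integers(0, 3, size=50)
        codes = np.column_stack([base, base, rng.integers(0, 3, size=50)])
        g = _matrix(codes)
        out = ld_prune(g, QCConfig())
        ids = [s.snp_id for s in out.snps]
        assert "s1" in ids and "s2" not in ids  # later duplicate dropped

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_no_surviving_window_pair_exceeds_threshold(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(0.1, 0.9, size=60)
        codes = rng.binomial(2, p, size=(200, 60))
        cfg = QCConfig(ld_window_snps=10, ld_step_snps=3)
        out = ld_prune(_matrix(codes), cfg)
        assert brute_force_window_scan(out, cfg) <= cfg.ld_r2_max + 1e-12
        # independent simulated loci: hardly anything should be pruned
        assert out.n_snps >= 50

    def test_single_snp_identity(self):
        g = _matrix([[0], [1], [2]])
        assert ld_prune(g) == g

    def test_unsorted_raises(self):
        snps = [SnpMeta("a", "1", 200), SnpMeta("b", "1", 100)]
        g = GenotypeMatrix(["i", "j"], snps, np.array([[0, 1], [1, 2]]))
        with pytest.raises(ValueError, match="sort"):
            ld_prune(g)


# ------------------------------------------------------- allele frequencies


class TestAlleleFrequencies:
    def test_hand_example(self):
        g = _matrix([[1], [2]])
        labels = BreedLabels({"ind1": "A", "ind2": "A", "extra": "B"})
        # breed A only present; B absent from matrix -> error
        with pytest.raises(ValueError):
            allele_frequencies(g, labels)
        g2 = _matrix([[1, 2], [2, 2], [0, 2]], samples=["a", "b", "c"])
        labels2 = BreedLabels({"a": "X", "b": "X", "c": "Y"})
        table = allele_frequencies(g2, labels2)
        assert table.freqs[0, 0] == pytest.approx(3 / 4)  # codes {1,2} -> 0.75
        assert table.freqs[1, 1] == pytest.approx(1.0)  # alt-fixed breed

    def test_matches_brute_force_tally(self):
        rng = np.random.default_rng(11)
        codes = rng.integers(0, 3, size=(40, 25))
        g = _matrix(codes)
        breeds = [f"B{i}" for i in range(5)]
        labels = BreedLabels({g.samples[i]: breeds[i % 5] for i in range(40)}, breeds=breeds)
        table = allele_frequencies(g, labels)
        for bi, breed in enumerate(breeds):
            rows = [i for i, s in enumerate(g.samples) if labels.mapping[s] == breed]
            for j in range(25):
                tally = sum(int(codes[i, j]) for i in rows)
                assert table.freqs[bi, j] == pytest.approx(tally / (2 * len(rows)))
        assert ((table.freqs >= 0) & (table.freqs <= 1)).all()

    def test_unlabelled_sample_raises(self):
        g = _matrix(np.zeros((2, 2), dtype=int))
        labels = BreedLabels({"ind1": "A", "other": "B"})
        with pytest.raises(KeyError):
            labels.labels_for(g.samples)


class TestSubsetToPositions:
    def test_empty_and_identity(self):
        g = _matrix(np.ones((2, 5), dtype=int))
        empty, absent = subset_to_positions(g, [])
        assert empty.n_snps == 0 and absent == 0
        full, absent = subset_to_positions(g, g.positions())
        assert full == g and absent == 0

    def test_random_half_matches_set_oracle(self):
        rng = np.random.default_rng(5)
        g = _matrix(rng.integers(0, 3, (4, 40)))
        chosen = [g.positions()[i] for i in rng.choice(40, 20, replace=False)]
        chosen += [("99", 1)]  # absent position silently ignored but counted
        sub, absent = subset_to_positions(g, chosen)
        expect = set(chosen) & set(g.positions())
        assert sub.n_snps == len(expect)
        assert absent == 1
        # original SNP order preserved
        assert [s.snp_id for s in sub.snps] == [
            s.snp_id for s in g.snps if (s.chrom, s.pos) in expect
        ]
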