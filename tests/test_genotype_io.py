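import numpy as np
import pytest
from scipy import stats

from riskpred.genotype_io import (
    MISSING,
    GenotypeDataset,
    GenotypeError,
    QCThresholds,
    SNPRecord,
    balance_classes,
    compute_maf,
    encode_additive,
    hwe_test,
    impute_mode,
    qc_filter,
    read_matrix_tsv,
    read_plink_text,
    read_vcf,
    stratified_split,
    write_matrix_tsv,
)


class TestEncodeAdditive:
    @pytest.mark.parametrize(
        "call,expected", [("AA", 0), ("AB", 1), ("BA", 1), ("BB", 2)]
    )
    def test_minor_allele_count(self, call, expected):
        assert encode_additive(call, "A", "B") == expected

    def test_missing_token(self):
        assert encode_additive("00", "A", "B") == MISSING
        assert encode_additive("./.", "A", "B") == MISSING

    def test_unknown_allele_names_snp_and_sample(self):
        with pytest.raises(GenotypeError, match="rs9.*sampleX"):
            encode_additive("AC", "A", "B", snp_id="rs9", sample_id="sampleX")

    def test_allele_swap_complements_to_two(self):
        for a, b in [("A", "G"), ("C", "T")]:
            for call in (a + a, a + b, b + b):
                assert (
                    encode_additive(call, a, b) + encode_additive(call, b, a) == 2
                )


class TestComputeMaf:
    @pytest.mark.parametrize(
        "column,expected",
        [([0, 0, 0, 0], 0.0), ([1, 1, 1, 1], 0.5), ([0, 1, 2, MISSING], 0.5)],
    )
    def test_values(self, column, expected):
        maf, flipped = compute_maf(np.array(column))
        assert maf == pytest.approx(expected)
        assert not flipped

    def test_folding_flags_relabel(self):
        maf, flipped = compute_maf(np.array([2, 2, 2, 1]))
        assert maf == pytest.approx(1 / 8)
        assert flipped

    def test_all_missing_errors(self):
        with pytest.raises(GenotypeError):
            compute_maf(np.array([MISSING, MISSING]))


class TestHweTest:
    def test_exact_proportions_give_p_one(self):
        column = np.repeat([0, 1, 2], [25, 50, 25])
        assert hwe_test(column) == pytest.approx(1.0)

    def test_heterozygote_deficit_rejected(self):
        # 50 AA + 50 BB, no hets: chi-square statistic equals n -> tiny p
        column = np.repeat([0, 2], [50, 50])
        assert hwe_test(column) < 1e-6

    def test_monomorphic_convention(self):
        assert hwe_test(np.zeros(30, dtype=np.int8)) == 1.0

    def test_p_values_uniform_under_null(self, rng):
        """On simulated equilibrium columns the p-value distribution is flat."""
        n, cols = 300, 10_000
        mafs = rng.uniform(0.1, 0.5, size=cols)
        genotypes = rng.binomial(2, mafs[None, :], size=(n, cols))
        pvals = np.array([hwe_test(genotypes[:, j]) for j in range(cols)])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


def _panel(genotypes, labels):
    genotypes = np.asarray(genotypes, dtype=np.int8)
    return GenotypeDataset(
        genotypes,
        np.asarray(labels, np.int8),
        [f"s{i}" for i in range(genotypes.shape[0])],
        [SNPRecord(f"rs{j}") for j in range(genotypes.shape[1])],
    )


class TestQcFilter:
    def test_low_maf_snp_removed(self, rng):
        g = rng.binomial(2, 0.3, size=(200, 5)).astype(np.int8)
        g[:, 2] = 0
        g[0, 2] = 1  # MAF 1/400 = 0.0025 < 0.01
        data = _panel(g, rng.integers(0, 2, 200))
        kept, report = qc_filter(data)
        assert kept.n_snps == 4
        assert report["maf"] == ["rs2"]

    def test_loosest_thresholds_are_identity(self, rng):
        g = rng.binomial(2, 0.3, size=(100, 6)).astype(np.int8)
        data = _panel(g, rng.integers(0, 2, 100))
        kept, _ = qc_filter(data, QCThresholds(0.0, 1.0, 0.0))
        assert kept.n_snps == 6
        assert kept.snp_ids() == data.snp_ids()

    def test_missingness_removal_reason(self, rng):
        g = rng.binomial(2, 0.3, size=(200, 3)).astype(np.int8)
        g[:20, 1] = MISSING  # 10% missing
        data = _panel(g, rng.integers(0, 2, 200))
        kept, report = qc_filter(data)
        assert "rs1" not in kept.snp_ids()
        assert "rs1" in report["missing_rate"]

    def test_monotone_in_thresholds(self, rng):
        g = rng.binomial(2, rng.uniform(0.005, 0.4, 30)[None, :], size=(150, 30))
        g = g.astype(np.int8)
        g[rng.random((150, 30)) < 0.04] = MISSING
        data = _panel(g, rng.integers(0, 2, 150))
        loose, _ = qc_filter(data, QCThresholds(0.01, 0.08, 1e-4))
        tight, _ = qc_filter(data, QCThresholds(0.05, 0.03, 1e-2))
        assert set(tight.snp_ids()) <= set(loose.snp_ids())

    def test_empty_panel_errors(self, rng):
        g = np.zeros((50, 2), dtype=np.int8)  # monomorphic: MAF 0 < any cutoff
        g[0, 0] = 1
        data = _panel(g, rng.integers(0, 2, 50))
        with pytest.raises(GenotypeError, match="every SNP"):
            qc_filter(data, QCThresholds(0.49, 0.0, 0.0))


class TestBalanceAndSplit:
    def test_downsamples_majority(self, rng):
        g = rng.binomial(2, 0.3, size=(250, 4)).astype(np.int8)
        labels = np.r_[np.ones(100), np.zeros(150)].astype(np.int8)
        data = _panel(g, labels)
        balanced = balance_classes(data, seed=3)
        assert int(balanced.labels.sum()) == 100
        assert balanced.n_samples == 200

    def test_already_balanced_keeps_membership(self, toy_dataset):
        balanced = balance_classes(toy_dataset, seed=0)
        assert sorted(balanced.sample_ids) == sorted(toy_dataset.sample_ids)

    def test_seeded_determinism(self, rng):
        g = rng.binomial(2, 0.3, size=(90, 3)).astype(np.int8)
        labels = np.r_[np.ones(30), np.zeros(60)].astype(np.int8)
        data = _panel(g, labels)
        assert balance_classes(data, 7).equals(balance_classes(data, 7))

    def test_split_counts_and_stratification(self, rng):
        g = rng.binomial(2, 0.3, size=(1000, 3)).astype(np.int8)
        labels = np.r_[np.ones(500), np.zeros(500)].astype(np.int8)
        train, test = stratified_split(_panel(g, labels), 0.30, seed=1)
        assert (train.n_samples, test.n_samples) == (700, 300)
        assert int(train.labels.sum()) == 350
        assert int(test.labels.sum()) == 150

    def test_split_is_a_partition(self, rng):
        g = rng.binomial(2, 0.3, size=(101, 3)).astype(np.int8)
        labels = (np.arange(101) % 2).astype(np.int8)
        data = _panel(g, labels)
        train, test = stratified_split(data, 0.30, seed=5)
        assert set(train.sample_ids).isdisjoint(test.sample_ids)
        assert set(train.sample_ids) | set(test.sample_ids) == set(data.sample_ids)

    def test_bad_fraction(self, toy_dataset):
        with pytest.raises(ValueError):
            stratified_split(toy_dataset, 1.5, seed=0)


class TestImputeMode:
    def test_fills_with_most_frequent_code(self):
        g = np.array([[0, 2], [0, 2], [1, 2], [MISSING, MISSING]], dtype=np.int8)
        data = _panel(g, [0, 0, 1, 1])
        filled = impute_mode(data)
        assert filled.genotypes[3, 0] == 0
        assert filled.genotypes[3, 1] == 2
        assert (filled.genotypes != MISSING).all()


class TestFileFormats:
    def test_tsv_round_trip(self, tmp_path, small_cohort):
        path = tmp_path / "m.tsv"
        write_matrix_tsv(small_cohort, path)
        again = read_matrix_tsv(path)
        assert again.equals(small_cohort)

    def test_plink_text_hand_encoding(self, tmp_path):
        (tmp_path / "t.map").write_text("1 rs1 0 100\n1 rs2 0 200\n")
        # rs1: G minor (freq 2/6); rs2: T minor (freq 1/6)
        (tmp_path / "t.ped").write_text(
            "f1 i1 0 0 1 2 A A C T\n"
            "f2 i2 0 0 1 1 A G C C\n"
            "f3 i3 0 0 1 1 G A C C\n"
        )
        data = read_plink_text(tmp_path / "t.ped", tmp_path / "t.map")
        assert data.sample_ids == ["i1", "i2", "i3"]
        assert data.labels.tolist() == [1, 0, 0]
        assert data.genotypes.tolist() == [[0, 1], [1, 0], [1, 0]]
        assert data.snps[0].minor_allele == "G"

    def test_plink_missing_and_errors(self, tmp_path):
        (tmp_path / "t.map").write_text("1 rs1 0 100\n")
        (tmp_path / "t.ped").write_text(
            "f1 i1 0 0 1 2 0 0\nf2 i2 0 0 1 1 A A\nf3 i3 0 0 1 1 A G\n"
        )
        data = read_plink_text(tmp_path / "t.ped", tmp_path / "t.map")
        assert data.genotypes[0, 0] == MISSING
        (tmp_path / "bad.ped").write_text("f1 i1 0 0 1 2 A\n")
        with pytest.raises(GenotypeError, match="bad.ped:1"):
            read_plink_text(tmp_path / "bad.ped", tmp_path / "t.map")

    def test_vcf_alt_minor_coding(self, tmp_path):
        vcf = tmp_path / "t.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "##contig=<ID=1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\ts3\n"
            "1\t100\trs1\tA\tG\t.\tPASS\t.\tGT\t0/1\t0/0\t./.\n"
            "1\t200\trs2\tC\tT\t.\tPASS\t.\tGT\t1/1\t0/1\t0/0\n"
        )
        labels = tmp_path / "labels.tsv"
        labels.write_text("s1 1\ns2 0\ns3 0\n")
        data = read_vcf(vcf, labels)
        assert data.genotypes[0, 0] == 1  # het 0/1 with ALT minor
        assert data.genotypes[2, 0] == MISSING
        assert data.genotypes[:, 1].tolist() == [2, 1, 0]
        assert data.labels.tolist() == [1, 0, 0]

    def test_vcf_major_minor_flip(self, tmp_path):
        # ALT dosage frequency > 0.5, so REF becomes the minor allele
        vcf = tmp_path / "t.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "##contig=<ID=1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\n"
            "1\t100\trs1\tA\tG\t.\tPASS\t.\tGT\t1/1\t0/1\n"
        )
        labels = tmp_path / "labels.tsv"
        labels.write_text("s1 1\ns2 0\n")
        data = read_vcf(vcf, labels)
        assert data.genotypes[:, 0].tolist() == [0, 1]
        assert data.snps[0].minor_allele == "A"
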