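"""Packed genotype storage, PLINK IO, and compressed linear algebra."""

import numpy as np
import pytest

from conftest import dense_standardized, random_genotypes
from ihtglm.genotypes import (
    MISSING,
    CovariateMatrix,
    Design,
    GenotypeMatrix,
    PlinkFormatError,
    read_plink,
    write_plink,
)


class TestBitCodes:
    def test_known_byte_decodes_to_counts(self):
        # counts (0, 1, 2, missing) -> codes (3, 2, 0, 1) -> byte 01 00 10 11
        counts = np.array([[0], [1], [2], [MISSING]], dtype=np.uint8)
        G = GenotypeMatrix.from_counts(counts)
        assert G.packed.shape == (1, 1)
        assert G.packed[0, 0] == 0b01_00_10_11
        assert G.decode()[:, 0].tolist() == [0, 1, 2, MISSING]
        assert G.has_missing

    def test_payload_byte_count(self):
        G = GenotypeMatrix.from_counts(np.zeros((5, 3), dtype=np.uint8))
        assert G.packed.shape == (3, 2)  # ceil(5/4) bytes per SNP

    def test_counts_survive_pack_unpack(self, rng):
        G = random_genotypes(rng, 37, 11, missing_frac=0.1)
        direct = G.decode()
        assert direct.shape == (37, 11)
        assert set(np.unique(direct)) <= {0, 1, 2, MISSING}

    def test_major_allele_counts_are_flipped(self):
        counts = np.array([[2], [2], [2], [1]], dtype=np.uint8)  # freq 7/8
        G = GenotypeMatrix.from_counts(counts)
        assert G.decode()[:, 0].tolist() == [0, 0, 0, 1]
        assert G.maf[0] == pytest.approx(1 / 8)

    def test_invalid_count_rejected(self):
        with pytest.raises(ValueError, match="counts"):
            GenotypeMatrix.from_counts(np.full((2, 2), 5, dtype=np.uint8))


class TestPlinkIO:
    def test_round_trip(self, rng, tmp_path):
        G = random_genotypes(rng, 23, 9, missing_frac=0.05)
        write_plink(tmp_path / "toy", G)
        back = read_plink(tmp_path / "toy")
        assert back.n == 23 and back.p == 9
        assert np.array_equal(back.decode(), G.decode())
        assert np.allclose(back.maf, G.maf)

    def test_bad_magic_rejected(self, rng, tmp_path):
        G = random_genotypes(rng, 8, 3)
        write_plink(tmp_path / "toy", G)
        data = (tmp_path / "toy.bed").read_bytes()
        (tmp_path / "toy.bed").write_bytes(b"\x00\x00" + data[2:])
        with pytest.raises(PlinkFormatError, match="magic"):
            read_plink(tmp_path / "toy")

    def test_truncated_payload_names_expected_bytes(self, rng, tmp_path):
        G = random_genotypes(rng, 10, 4)
        write_plink(tmp_path / "toy", G)
        data = (tmp_path / "toy.bed").read_bytes()
        (tmp_path / "toy.bed").write_bytes(data[:-2])
        with pytest.raises(PlinkFormatError, match="expected 12 bytes"):
            read_plink(tmp_path / "toy")

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_plink(tmp_path / "absent")


class TestImputeMode:
    def test_mode_fills_missing(self):
        col = np.array([[0], [0], [1], [MISSING]], dtype=np.uint8)
        G = GenotypeMatrix.from_counts(col).impute_mode()
        assert G.decode()[:, 0].tolist() == [0, 0, 1, 0]
        assert not G.has_missing

    def test_no_missing_is_identity(self, rng):
        G = random_genotypes(rng, 12, 5)
        assert G.impute_mode() is G

    def test_tie_goes_to_lowest_count(self):
        col = np.array([[0], [0], [1], [1], [MISSING]], dtype=np.uint8)
        G = GenotypeMatrix.from_counts(col).impute_mode()
        assert G.decode()[:, 0].tolist() == [0, 0, 1, 1, 0]

    def test_all_missing_snp_is_an_error(self):
        col = np.full((4, 1), MISSING, dtype=np.uint8)
        with pytest.raises(ValueError, match="all genotypes missing"):
            GenotypeMatrix.from_counts(col).impute_mode()


class TestStandardizedProducts:
    def test_standardized_value_arithmetic(self):
        # maf 0.5, count 2 -> (2 - 1)/sqrt(0.5)
        counts = np.array([[2], [0], [2], [0]], dtype=np.uint8)
        G = GenotypeMatrix.from_counts(counts)
        beta = np.array([1.0])
        out = G.standardized_xv(beta)
        assert out[0] == pytest.approx(1.0 / np.sqrt(0.5))

    def test_zero_vectors(self, rng):
        G = random_genotypes(rng, 10, 6)
        assert np.allclose(G.standardized_xv(np.zeros(6)), 0.0)
        assert np.allclose(G.standardized_xtv(np.zeros(10)), 0.0)

    def test_xv_matches_dense_oracle(self, rng):
        G = random_genotypes(rng, 20, 30)
        Xs = dense_standardized(G)
        beta = np.zeros(30)
        beta[rng.choice(30, 5, replace=False)] = rng.normal(size=5)
        assert np.allclose(G.standardized_xv(beta), Xs @ beta, atol=1e-10)

    def test_xtv_matches_dense_oracle(self, rng):
        G = random_genotypes(rng, 50, 100)
        Xs = dense_standardized(G)
        v = rng.normal(size=50)
        assert np.allclose(G.standardized_xtv(v), Xs.T @ v, atol=1e-10)

    def test_dense_backend_agrees_with_packed(self, rng):
        G = random_genotypes(rng, 40, 25)
        v = rng.normal(size=40)
        beta = rng.normal(size=25)
        assert np.allclose(
            G.standardized_xtv(v, backend="dense"), G.standardized_xtv(v), rtol=1e-5
        )
        assert np.allclose(
            G.standardized_xv(beta, backend="dense"),
            G.standardized_xv(beta),
            rtol=1e-5, atol=1e-5,
        )

    def test_monomorphic_column_is_identically_zero(self):
        counts = np.tile(np.array([[2, 1], [2, 0], [2, 2], [2, 1]], dtype=np.uint8), 1)
        G = GenotypeMatrix.from_counts(counts)
        assert G.monomorphic[0]
        out = G.standardized_xtv(np.ones(4))
        assert out[0] == 0.0

    def test_missing_must_be_imputed_first(self, rng):
        G = random_genotypes(rng, 10, 4, missing_frac=0.2)
        with pytest.raises(ValueError, match="impute"):
            G.standardized_xv(np.ones(4))

    def test_length_checks(self, rng):
        G = random_genotypes(rng, 8, 4)
        with pytest.raises(ValueError):
            G.standardized_xv(np.ones(5))
        with pytest.raises(ValueError):
            G.standardized_xtv(np.ones(9))


class TestDesign:
    def test_block_products_match_dense_oracle(self, rng):
        G = random_genotypes(rng, 30, 12)
        Z = CovariateMatrix.from_array(
            np.column_stack([np.ones(30), rng.normal(size=(30, 2))])
        )
        D = Design(G, Z)
        full = np.column_stack([dense_standardized(G), Z.values])
        b = rng.normal(size=D.width)
        v = rng.normal(size=30)
        assert np.allclose(D.forward(b), full @ b, atol=1e-10)
        assert np.allclose(D.adjoint(v), full.T @ v, atol=1e-10)

    def test_intercept_only_forward_is_constant(self, rng):
        G = random_genotypes(rng, 15, 5)
        Z = CovariateMatrix.intercept_only(15)
        D = Design(G, Z)
        b = np.zeros(6)
        b[5] = 2.5
        assert np.allclose(D.forward(b), 2.5)

    def test_row_subset_matches_dense_oracle(self, rng):
        G = random_genotypes(rng, 25, 10)
        rows = rng.choice(25, 11, replace=False)
        D = Design(G, rows=rows)
        Xs = dense_standardized(G)
        b = rng.normal(size=10)
        v = rng.normal(size=11)
        assert np.allclose(D.forward(b), Xs[rows] @ b, atol=1e-10)
        assert np.allclose(D.adjoint(v), Xs[rows].T @ v, atol=1e-10)

    def test_columns_extracts_standardized_submatrix(self, rng):
        G = random_genotypes(rng, 18, 7)
        Z = CovariateMatrix.intercept_only(18)
        D = Design(G, Z)
        idx = np.array([2, 5, 7])  # two SNPs and the intercept
        full = np.column_stack([dense_standardized(G), Z.values])
        assert np.allclose(D.columns(idx), full[:, idx], atol=1e-12)

    def test_row_count_mismatch_rejected(self, rng):
        G = random_genotypes(rng, 10, 4)
        Z = CovariateMatrix.intercept_only(9)
        with pytest.raises(ValueError):
            Design(G, Z)


class TestCovariateMatrix:
    def test_intercept_column_untouched_others_standardized(self, rng):
        raw = np.column_stack([np.ones(40), rng.normal(5.0, 2.0, size=(40, 2))])
        Z = CovariateMatrix.from_array(raw)
        assert np.allclose(Z.values[:, 0], 1.0)
        assert not Z.standardized[0]
        assert np.allclose(Z.values[:, 1:].mean(axis=0), 0.0, atol=1e-12)
        assert np.allclose(Z.values[:, 1:].std(axis=0), 1.0)


def test_storage_is_two_bits_per_genotype(rng):
    G = random_genotypes(rng, 101, 13)
    assert G.packed.nbytes == ((101 + 3) // 4) * 13
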