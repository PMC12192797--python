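"""SNP and epistasis relationship matrices, partitions, rank diagnostics."""

import numpy as np
import pytest

import epiblup as eb
from epiblup.errors import DegenerateGRMError, DegenerateSNPError

from conftest import panel_from_x, random_panel, with_individuals


def pairwise_features(w, order=2):
    """Explicit ordered-tuple product covariates: n x m^order matrix.

    Row i holds w_ij1 * w_ij2 * ... over all ordered SNP tuples — the
    brute-force design whose cross-product the Hadamard GRM must equal.
    """
    n, m = w.shape
    z = w
    for _ in range(order - 1):
        z = np.einsum("ij,ik->ijk", z, w).reshape(n, -1)
    return z


class TestAdditiveGRM:
    def test_two_by_two_hand_example(self):
        g = panel_from_x([[0, 2], [2, 0]])
        grm = eb.additive_grm(g)
        assert grm.normalization == pytest.approx(1.0)
        assert np.allclose(grm.values, [[2, -2], [-2, 2]])

    def test_single_snp_hand_example(self):
        g = panel_from_x([[0], [1], [2]])
        grm = eb.additive_grm(g)
        # w = (-1, 0, 1), denominator 2pq = 0.5
        assert np.allclose(grm.values,
                           np.array([[2, 0, -2], [0, 0, 0], [-2, 0, 2]]))

    def test_duplicate_individual_gains_no_rank(self, rng):
        """Adding a copy of an existing individual leaves the additive GRM
        rank unchanged (the duplicate row is linearly dependent)."""
        g = random_panel(rng, n=8, m=12)
        base_rank = eb.numerical_rank(eb.additive_grm(g)).rank
        dup = with_individuals(g, [0] + list(range(8)))
        dup_rank = eb.numerical_rank(eb.additive_grm(dup)).rank
        assert dup_rank == base_rank

    def test_monomorphic_rejected(self):
        g = panel_from_x([[0, 1], [0, 1]])
        with pytest.raises(DegenerateSNPError):
            eb.additive_grm(g)


class TestDominanceGRM:
    def test_single_snp_hand_example(self):
        g = panel_from_x([[0], [1], [2]])
        grm = eb.dominance_grm(g)
        # p = 0.5: h = (-0.5, 0.5, -0.5), denominator (2pq)^2 = 0.25
        expect = np.outer([-0.5, 0.5, -0.5], [-0.5, 0.5, -0.5]) / 0.25
        assert np.allclose(grm.values, expect)

    def test_symmetry_and_psd(self, rng):
        g = random_panel(rng, n=15, m=10)
        for grm in (eb.additive_grm(g), eb.dominance_grm(g)):
            assert np.allclose(grm.values, grm.values.T)
            lam = np.linalg.eigvalsh(grm.values)
            assert lam.min() >= -1e-8 * max(lam.max(), 1.0)


class TestEpistasisGRM:
    def test_hand_example_aa(self):
        g = panel_from_x([[0, 2], [2, 0]])
        K_A, K_D = eb.crossproducts(g)
        aa = eb.epistasis_grm("AA", K_A, K_D, g.individual_ids)
        assert aa.normalization == pytest.approx(4.0)
        assert np.allclose(aa.values, [[1, 1], [1, 1]])

    @pytest.mark.parametrize("kind,order", [("AA", 2), ("AD", 2), ("DD", 2)])
    def test_second_order_matches_feature_oracle(self, rng, kind, order):
        """Hadamard product equals the ordered-pair product-covariate cross-product."""
        for _ in range(3):
            g = random_panel(rng, n=20, m=15)
            w = eb.additive_design(g)
            h = eb.dominance_design(g)
            K_A, K_D = w @ w.T, h @ h.T
            grm = eb.epistasis_grm(kind, K_A, K_D, g.individual_ids)
            first, second = (w if kind[0] == "A" else h), (w if kind[1] == "A" else h)
            z = np.einsum("ij,ik->ijk", first, second).reshape(g.n, -1)
            oracle = z @ z.T
            assert np.allclose(grm.values * grm.normalization, oracle,
                               rtol=1e-10, atol=1e-10 * np.abs(oracle).max())

    @pytest.mark.parametrize("kind", ["AAA", "AAD", "ADD", "DDD"])
    def test_third_order_matches_feature_oracle(self, rng, kind):
        g = random_panel(rng, n=12, m=8)
        w = eb.additive_design(g)
        h = eb.dominance_design(g)
        grm = eb.epistasis_grm(kind, w @ w.T, h @ h.T, g.individual_ids)
        z = np.ones((g.n, 1))
        for ch in kind:
            f = w if ch == "A" else h
            z = np.einsum("ij,ik->ijk", z, f).reshape(g.n, -1)
        oracle = z @ z.T
        assert np.allclose(grm.values * grm.normalization, oracle,
                           rtol=1e-10, atol=1e-10 * np.abs(oracle).max())

    def test_mean_diagonal_is_one(self, rng):
        g = random_panel(rng, n=10, m=6)
        for kind, grm in eb.epistasis_grms(g).items():
            assert np.mean(np.diag(grm.values)) == pytest.approx(1.0, abs=1e-12)

    def test_schur_psd(self, rng):
        g = random_panel(rng, n=25, m=10)
        for grm in eb.epistasis_grms(g).values():
            lam = np.linalg.eigvalsh(grm.values)
            assert lam.min() >= -1e-8 * lam.max()


class TestPartitionAA:
    def test_conservation_identity(self, rng):
        """Unnormalized intra + inter equals the global AA Hadamard product."""
        g = random_panel(rng, n=12, m=15, n_chrom=3)
        w = eb.additive_design(g)
        K_A = w @ w.T
        intra, inter = eb.partition_aa(g)
        total = (intra.values * intra.normalization
                 + inter.values * inter.normalization)
        assert np.allclose(total, K_A * K_A, rtol=1e-10,
                           atol=1e-10 * np.abs(K_A * K_A).max())

    def test_two_chromosome_oracle(self, rng):
        """With one SNP per chromosome the inter part is exactly the
        enumerated cross-chromosome pair contribution 2 w_i1 w_i'1 w_i2 w_i'2."""
        g = random_panel(rng, n=10, m=2, n_chrom=2)
        w = eb.additive_design(g)
        intra, inter = eb.partition_aa(g)
        inter_raw = inter.values * inter.normalization
        expect = 2.0 * np.outer(w[:, 0], w[:, 0]) * np.outer(w[:, 1], w[:, 1])
        assert np.allclose(inter_raw, expect, atol=1e-10)
        intra_raw = intra.values * intra.normalization
        expect_intra = (np.outer(w[:, 0], w[:, 0]) ** 2
                        + np.outer(w[:, 1], w[:, 1]) ** 2)
        assert np.allclose(intra_raw, expect_intra, atol=1e-10)

    def test_single_chromosome_inter_degenerate(self, rng):
        g = random_panel(rng, n=8, m=6, n_chrom=1)
        with pytest.raises(DegenerateGRMError):
            eb.partition_aa(g)


class TestNumericalRank:
    def test_identity(self):
        grm = eb.GRM("A", np.eye(5), 1.0,
                     np.array([f"i{k}" for k in range(5)], dtype=object))
        assert eb.numerical_rank(grm).rank == 5

    def test_zero_matrix(self):
        grm = eb.GRM("A", np.zeros((4, 4)), 1.0,
                     np.array(list("abcd"), dtype=object))
        assert eb.numerical_rank(grm).rank == 0

    def test_additive_rank_m_when_n_exceeds_m(self, rng):
        g = random_panel(rng, n=10, m=4)
        assert eb.numerical_rank(eb.additive_grm(g)).rank == 4

    def test_duplicated_individual_reduces_rank(self, rng):
        """n=6 individuals on m=10 SNPs with one duplicate: the duplicate
        costs one dimension and sample-frequency centering another, so the
        additive GRM rank is 4 = (n-1) - 1."""
        g = random_panel(rng, n=5, m=10)
        dup = with_individuals(g, [0, 0, 1, 2, 3, 4])
        assert eb.numerical_rank(eb.additive_grm(dup)).rank == 4

    def test_aa_full_rank_when_products_exceed_n(self, rng):
        """With m(m+1)/2 distinct SNP-pair products >= n, the A-by-A GRM is
        full rank even though the additive GRM is singular."""
        while True:  # duplicate genotype rows would themselves cost rank
            g = random_panel(rng, n=30, m=8)  # 8*9/2 = 36 >= 30
            if len({tuple(r) for r in g.x.tolist()}) == 30:
                break
        assert eb.numerical_rank(eb.additive_grm(g)).rank == 8
        aa = eb.epistasis_grms(g, ("AA",))["AA"]
        assert eb.numerical_rank(aa).rank == 30


class TestLabelInvariance:
    def test_permuting_individuals_permutes_grm(self, rng):
        g = random_panel(rng, n=9, m=7)
        perm = rng.permutation(9)
        gp = g.subset_individuals(perm)
        a = eb.additive_grm(g).values
        ap = eb.additive_grm(gp).values
        assert np.allclose(ap, a[np.ix_(perm, perm)])
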