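"""Genomic relationship construction, tuning/blending, APY and H-inverse."""

import numpy as np
import pandas as pd
import pytest

from stayblup.gmatrix import (
    apy_inverse,
    assemble_H_inverse,
    blend_G,
    build_G,
    build_relationships,
    tune_G,
)
from stayblup.pedigree import build_A22, build_A_inverse
from stayblup.qc import GenotypeMatrix

from .oracles import kinship_A, random_pedigree
from .test_pedigree import ped_from_arrays


def make_g(codes):
    codes = np.asarray(codes, dtype=np.int8)
    n, m = codes.shape
    snp_ids = np.array([f"s{j}" for j in range(m)], dtype=object)
    snp_map = pd.DataFrame({"snp": snp_ids, "chrom": "1", "pos": np.arange(1, m + 1)})
    return GenotypeMatrix(
        np.array([f"a{i}" for i in range(n)], dtype=object), snp_ids, codes, snp_map
    )


def conditional_independence_G(rng, n=50, n_core=20):
    """SPD G whose non-core block is exactly explained by the core plus a
    diagonal: the structure under which the APY recursion is exact."""
    B = rng.normal(size=(n_core, 8))
    Gcc = B @ B.T + 0.3 * np.eye(n_core)
    W = 0.2 * rng.normal(size=(n_core, n - n_core))
    D = rng.uniform(0.3, 0.8, n - n_core)
    Gcn = Gcc @ W
    Gnn = W.T @ Gcc @ W + np.diag(D)
    return np.block([[Gcc, Gcn], [Gcn.T, Gnn]])


class TestBuildG:
    def test_hand_example_two_animals_two_snps(self):
        G = build_G(make_g([[0, 2], [2, 0]]), np.array([0.5, 0.5]))
        np.testing.assert_allclose(G, [[2.0, -2.0], [-2.0, 2.0]])

    def test_fully_average_animal_is_zero(self):
        G = build_G(make_g([[1, 1, 1, 1]]), np.full(4, 0.5))
        np.testing.assert_allclose(G, 0.0, atol=1e-14)

    def test_identical_genotypes_equal_entries(self, rng):
        row = rng.choice([0, 1, 2], size=100)
        g = make_g(np.vstack([row, row]))
        p = np.clip(row / 2.0, 0.05, 0.95)
        G = build_G(g, p)
        assert G[0, 1] == pytest.approx(G[0, 0])
        assert G[0, 1] == pytest.approx(G[1, 1])

    def test_missing_centered_to_zero(self):
        g1 = build_G(make_g([[5, 2], [2, 0]]), np.array([0.5, 0.5]))
        assert g1[0, 0] == pytest.approx(1.0)  # only the second marker contributes

    def test_monomorphic_panel_errors(self):
        with pytest.raises(ValueError, match="monomorphic"):
            build_G(make_g([[2, 2]]), np.array([1.0, 1.0]))

    def test_hw_population_means(self, small_sim):
        from stayblup.qc import allele_frequencies

        _, ds = small_sim
        founders = ds.ped.generation == 0
        g = ds.genotypes.subset(animal_mask=founders)
        G = build_G(g, allele_frequencies(g))
        n = G.shape[0]
        assert np.diag(G).mean() == pytest.approx(1.0, abs=0.05)
        off = (G.sum() - np.trace(G)) / (n * n - n)
        assert off == pytest.approx(0.0, abs=0.05)


class TestTuneBlend:
    def test_fixed_point(self, rng):
        A22 = np.eye(4) + 0.1
        out = tune_G(A22.copy(), A22)
        np.testing.assert_allclose(out, A22, atol=1e-12)

    def test_pure_scaling(self):
        A22 = np.eye(3)  # mean diag 1, mean offdiag 0
        G = 2.0 * A22
        out = tune_G(G, A22)
        np.testing.assert_allclose(out, A22, atol=1e-12)

    def test_postconditions_random(self, rng):
        G = rng.normal(size=(20, 20))
        G = G @ G.T / 20
        A22 = rng.normal(size=(20, 20))
        A22 = A22 @ A22.T / 20 + np.eye(20)
        out = tune_G(G, A22)
        n = 20
        assert np.diag(out).mean() == pytest.approx(np.diag(A22).mean(), abs=1e-10)
        off = lambda M: (M.sum() - np.trace(M)) / (n * n - n)  # noqa: E731
        assert off(out) == pytest.approx(off(A22), abs=1e-10)

    def test_constant_G_is_singular_system(self):
        with pytest.raises(ValueError, match="singular"):
            tune_G(np.ones((3, 3)), np.eye(3))

    def test_blend_endpoints_and_pd_rescue(self, rng):
        A22 = np.eye(5)
        G = np.ones((5, 5))  # singular
        np.testing.assert_allclose(blend_G(A22, A22), A22)
        np.testing.assert_allclose(blend_G(G, A22, tau=1.0), G)
        out = blend_G(G, A22, tau=0.95)
        assert np.linalg.eigvalsh(out).min() >= 0.05 - 1e-12

    def test_tune_blend_preserve_symmetry_pd(self, small_sim):
        from stayblup.qc import allele_frequencies

        _, ds = small_sim
        mask = ds.ped.generation >= 2
        g = ds.genotypes.subset(animal_mask=mask)
        G = build_G(g, allele_frequencies(g))
        A22 = build_A22(ds.ped, g.animal_ids)
        out = blend_G(tune_G(G, A22), A22)
        np.testing.assert_allclose(out, out.T, atol=1e-12)
        assert np.linalg.eigvalsh(out).min() > 0


class TestAPY:
    def test_core_all_equals_dense_inverse_bitwise(self, rng):
        G = conditional_independence_G(rng, n=20, n_core=20)
        from stayblup.gmatrix import _spd_inverse

        apy = apy_inverse(G, np.arange(20))
        np.testing.assert_array_equal(apy.to_dense(), _spd_inverse(G))

    def test_single_noncore_exact(self, rng):
        B = rng.normal(size=(3, 3))
        G = B @ B.T + np.eye(3)
        apy = apy_inverse(G, np.array([0, 1]))
        np.testing.assert_allclose(apy.to_dense(), np.linalg.inv(G), atol=1e-10)

    def test_conditional_independence_structure_exact(self, rng):
        G = conditional_independence_G(rng)
        apy = apy_inverse(G, np.arange(20))
        np.testing.assert_allclose(apy.to_dense(), np.linalg.inv(G), atol=1e-6)

    def test_matvec_matches_dense(self, rng):
        G = conditional_independence_G(rng)
        apy = apy_inverse(G, np.arange(20))
        v = rng.normal(size=50)
        np.testing.assert_allclose(apy.matvec(v), apy.to_dense() @ v, atol=1e-10)

    def test_scattered_core_positions(self, rng):
        G = conditional_independence_G(rng, n=30, n_core=30)
        core = np.sort(rng.choice(30, size=12, replace=False))
        apy = apy_inverse(G, core)
        v = rng.normal(size=30)
        # permutation bookkeeping: dense block assembly matches matvec
        np.testing.assert_allclose(apy.to_dense() @ v, apy.matvec(v), atol=1e-10)

    def test_nonpositive_conditional_variance_errors(self):
        G = np.ones((3, 3))  # rank one: zero conditional variance off-core
        with pytest.raises(ValueError, match="conditional variance"):
            apy_inverse(G, np.array([0]))


class TestHInverse:
    def _fixture(self, rng, n=300, n_geno=100):
        sire, dam = random_pedigree(n, rng)
        ped = ped_from_arrays(sire, dam)
        pick = np.sort(rng.choice(n, size=n_geno, replace=False))
        ids = ped.animal_ids[pick]
        A = kinship_A(sire, dam)
        A22 = A[np.ix_(pick, pick)]
        G = blend_G(A22 + 0.05 * np.diag(rng.random(n_geno)), A22)
        return ped, pick, A, A22, G

    def test_no_genotyped_animals_gives_A_inverse(self, rng):
        sire, dam = random_pedigree(50, rng)
        ped = ped_from_arrays(sire, dam)
        a_inv = build_A_inverse(ped)
        h = assemble_H_inverse(a_inv, None, None, np.array([], dtype=np.int64))
        v = rng.normal(size=50)
        np.testing.assert_allclose(h.matvec(v), a_inv @ v)

    def test_G_equals_A22_cancels(self, rng):
        ped, pick, A, A22, _ = self._fixture(rng, n=120, n_geno=40)
        a_inv = build_A_inverse(ped)
        h = assemble_H_inverse(a_inv, A22, A22.copy(), pick)
        v = rng.normal(size=120)
        np.testing.assert_allclose(h.matvec(v), a_inv @ v, atol=1e-8)

    def test_matches_dense_formula_300_animals(self, rng):
        ped, pick, A, A22, G = self._fixture(rng)
        a_inv = build_A_inverse(ped)
        h = assemble_H_inverse(a_inv, A22, G, pick)
        dense = a_inv.toarray()
        dense[np.ix_(pick, pick)] += np.linalg.inv(G) - np.linalg.inv(A22)
        np.testing.assert_allclose(h.to_sparse().toarray(), dense, atol=1e-8)
        v = rng.normal(size=300)
        np.testing.assert_allclose(h.matvec(v), dense @ v, atol=1e-8)
        np.testing.assert_allclose(h.diagonal(), np.diag(dense), atol=1e-8)

    def test_apy_mode_core_all_matches_direct(self, rng):
        ped, pick, A, A22, G = self._fixture(rng, n=150, n_geno=50)
        a_inv = build_A_inverse(ped)
        h_direct = assemble_H_inverse(a_inv, A22, G, pick, mode="direct")
        h_apy = assemble_H_inverse(a_inv, A22, G, pick, mode="apy")
        v = rng.normal(size=150)
        np.testing.assert_array_equal(h_direct.matvec(v), h_apy.matvec(v))

    def test_genotyped_outside_pedigree_errors(self, rng):
        sire, dam = random_pedigree(10, rng)
        ped = ped_from_arrays(sire, dam)
        a_inv = build_A_inverse(ped)
        with pytest.raises(ValueError, match="outside the pedigree"):
            assemble_H_inverse(a_inv, np.eye(2), np.eye(2), np.array([5, 12]))


def test_build_relationships_end_to_end(small_sim):
    _, ds = small_sim
    mask = ds.ped.generation >= 2
    g = ds.genotypes.subset(animal_mask=mask)
    relset = build_relationships(ds.ped, g, mode="apy", core_size=80, seed=11)
    assert relset.g_blended.shape == (g.n_animals, g.n_animals)
    assert len(relset.core_ids) == 80
    v = np.random.default_rng(0).normal(size=ds.ped.n)
    out = relset.h_inv.matvec(v)
    assert np.isfinite(out).all()
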