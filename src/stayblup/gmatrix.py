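"""Genomic relationship matrices and the single-step H-inverse.

``G`` follows VanRaden's first method: genotypes centered by twice the allele
frequency and the cross-product scaled by ``2 sum_j p_j (1 - p_j)``.  Before
inversion ``G`` is tuned (diagonal/off-diagonal means aligned to ``A22``) and
blended with ``A22`` (default 95/5) to guarantee positive definiteness.  The
inverse is taken directly or with the APY recursion on a core subset, and

    H^-1 = A^-1 + [0 0; 0 G^-1 - A22^-1]

on the genotyped block.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg as la
import scipy.sparse as sp

from .pedigree import Pedigree, build_A22, build_A_inverse
from .qc import MISSING, GenotypeMatrix, allele_frequencies


def _spd_inverse(M: np.ndarray) -> np.ndarray:
    c, low = la.cho_factor(M)
    return la.cho_solve((c, low), np.eye(M.shape[0]))


def build_G(g: GenotypeMatrix, p: np.ndarray) -> np.ndarray:
    """VanRaden method 1: ``G = Z Z'`` with ``Z = (M - 2p) / sqrt(2 sum p(1-p))``.

    Missing codes are replaced by ``2 p_j`` (zero after centering), the
    standard mean imputation.
    """
    p = np.asarray(p, dtype=np.float64)
    denom = float(np.sum(2.0 * p * (1.0 - p)))
    if denom <= 0:
        raise ValueError("all markers monomorphic: sum 2p(1-p) is zero")
    M = g.codes.astype(np.float64)
    M[g.codes == MISSING] = np.nan
    Z = np.nan_to_num(M - 2.0 * p, nan=0.0) / np.sqrt(denom)
    return Z @ Z.T


def tune_G(G: np.ndarray, A22: np.ndarray) -> np.ndarray:
    """Rescale ``G`` to ``a + b G`` so its mean diagonal and mean off-diagonal
    match those of ``A22`` (compatibility of base populations)."""
    n = G.shape[0]
    if A22.shape != G.shape:
        raise ValueError("G and A22 shapes differ")
    dg, da = np.diag(G).mean(), np.diag(A22).mean()
    if n > 1:
        og = (G.sum() - np.trace(G)) / (n * (n - 1))
        oa = (A22.sum() - np.trace(A22)) / (n * (n - 1))
    else:
        og = oa = 0.0
    if abs(dg - og) < 1e-12:
        raise ValueError("G has equal mean diagonal and off-diagonal; tuning system is singular")
    b = (da - oa) / (dg - og)
    a = da - b * dg
    out = a + b * G
    np.fill_diagonal(out, a + b * np.diag(G))
    return out


def blend_G(G: np.ndarray, A22: np.ndarray, tau: float = 0.95) -> np.ndarray:
    """``tau * G + (1 - tau) * A22`` (default keeps 5% pedigree relationships)."""
    if G.shape != A22.shape:
        raise ValueError("G and A22 shapes differ")
    if not 0 < tau <= 1:
        raise ValueError("tau must be in (0, 1]")
    return tau * G + (1.0 - tau) * A22


@dataclass
class APYInverse:
    """APY factorization of ``G``-inverse.

    Stores the core-block inverse, the regression of non-core on core
    ``K = G_cc^-1 G_cn`` and the diagonal conditional variances ``m``; matrix
    products never densify the non-core block.
    """

    core: np.ndarray  # positions of core animals in G's order
    noncore: np.ndarray
    Gcc_inv: np.ndarray
    K: np.ndarray
    minv: np.ndarray
    n: int

    def matvec(self, v: np.ndarray) -> np.ndarray:
        vc, vn = v[self.core], v[self.noncore]
        t = self.K.T @ vc
        out = np.empty_like(v, dtype=np.float64)
        out[self.core] = self.Gcc_inv @ vc + self.K @ (self.minv * t) - self.K @ (self.minv * vn)
        out[self.noncore] = -self.minv * t + self.minv * vn
        return out

    def to_dense(self) -> np.ndarray:
        out = np.zeros((self.n, self.n))
        KM = self.K * self.minv
        out[np.ix_(self.core, self.core)] = self.Gcc_inv + KM @ self.K.T
        out[np.ix_(self.core, self.noncore)] = -KM
        out[np.ix_(self.noncore, self.core)] = -KM.T
        out[np.ix_(self.noncore, self.noncore)] = np.diag(self.minv)
        return out


def apy_inverse(G: np.ndarray, core: np.ndarray) -> APYInverse:
    """APY inverse of ``G`` with the given core positions.

    Non-core animals are treated as conditionally independent given the core;
    each gets a diagonal conditional variance ``m_i = g_ii - g_ic G_cc^-1
    g_ci``.  With core = all animals this is exactly the dense inverse.
    """
    n = G.shape[0]
    core = np.asarray(core, dtype=np.int64)
    mask = np.zeros(n, dtype=bool)
    mask[core] = True
    noncore = np.flatnonzero(~mask)
    Gcc_inv = _spd_inverse(G[np.ix_(core, core)])
    if len(noncore) == 0:
        return APYInverse(core, noncore, Gcc_inv, np.zeros((len(core), 0)),
                          np.zeros(0), n)
    Gcn = G[np.ix_(core, noncore)]
    K = Gcc_inv @ Gcn
    m = np.diag(G)[noncore] - np.einsum("ij,ij->j", Gcn, K)
    if np.any(m <= 0):
        raise ValueError(
            "non-positive conditional variance in APY; core too small or G not positive definite"
        )
    return APYInverse(core, noncore, Gcc_inv, K, 1.0 / m, n)


class HInverse:
    """The single-step ``H``-inverse as an operator.

    ``H^-1 v = A^-1 v + scatter((G^-1 - A22^-1) gather(v))`` over genotyped
    positions; the genotyped-block correction is dense (direct mode) or an
    APY factorization.
    """

    def __init__(self, a_inv: sp.csr_matrix, genotyped_positions: np.ndarray,
                 g_inv, a22_inv: np.ndarray | None):
        self.a_inv = sp.csr_matrix(a_inv)
        self.n = self.a_inv.shape[0]
        self.genotyped = np.asarray(genotyped_positions, dtype=np.int64)
        if self.genotyped.size and (self.genotyped.min() < 0 or self.genotyped.max() >= self.n):
            raise ValueError("genotyped position outside the pedigree")
        self.g_inv = g_inv  # ndarray or APYInverse (None when no genotypes)
        self.a22_inv = a22_inv
        self._sparse = None

    def matvec(self, v: np.ndarray) -> np.ndarray:
        out = self.a_inv @ v
        if self.genotyped.size:
            vg = v[self.genotyped]
            if isinstance(self.g_inv, APYInverse):
                corr = self.g_inv.matvec(vg) - self.a22_inv @ vg
            else:
                corr = self.g_inv @ vg - self.a22_inv @ vg
            out[self.genotyped] += corr
        return out

    def quadratic(self, v: np.ndarray) -> float:
        """``v' H^-1 v`` without materializing the matrix."""
        return float(v @ self.matvec(v))

    def to_sparse(self) -> sp.csr_matrix:
        """Materialize as sparse CSR (desk scale; densifies the APY block)."""
        if self._sparse is None:
            H = self.a_inv.tolil(copy=True)
            if self.genotyped.size:
                gi = self.g_inv.to_dense() if isinstance(self.g_inv, APYInverse) else self.g_inv
                diff = gi - self.a22_inv
                ix = self.genotyped
                H[np.ix_(ix, ix)] = H[np.ix_(ix, ix)].toarray() + diff
            self._sparse = H.tocsr()
        return self._sparse

    def diagonal(self) -> np.ndarray:
        d = self.a_inv.diagonal().copy()
        if self.genotyped.size:
            gi = self.g_inv.to_dense() if isinstance(self.g_inv, APYInverse) else self.g_inv
            d[self.genotyped] += np.diag(gi - self.a22_inv)
        return d


def assemble_H_inverse(
    a_inv: sp.spmatrix,
    a22: np.ndarray | None,
    g_final: np.ndarray | None,
    genotyped_positions,
    mode: str = "direct",
    core: np.ndarray | None = None,
) -> HInverse:
    """Assemble the ``H``-inverse operator.

    With no genotyped animals this degenerates to ``A``-inverse.  ``core``
    gives APY core positions within the genotyped set (required when
    ``mode='apy'`` unless defaulting to all).
    """
    genotyped_positions = np.asarray(genotyped_positions, dtype=np.int64)
    if genotyped_positions.size == 0:
        return HInverse(a_inv, genotyped_positions, None, None)
    if g_final is None or a22 is None:
        raise ValueError("G and A22 required when genotyped animals are present")
    a22_inv = _spd_inverse(a22)
    if mode == "direct":
        g_inv = _spd_inverse(g_final)
    elif mode == "apy":
        core = np.arange(g_final.shape[0]) if core is None else np.asarray(core)
        g_inv = apy_inverse(g_final, core)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return HInverse(a_inv, genotyped_positions, g_inv, a22_inv)


def save_apy(apy: APYInverse, path, core_ids=None) -> None:
    """Persist the APY blocks with an index of core animal IDs (npz)."""
    np.savez_compressed(
        path,
        core=apy.core,
        noncore=apy.noncore,
        Gcc_inv=apy.Gcc_inv,
        K=apy.K,
        minv=apy.minv,
        n=np.array([apy.n]),
        core_ids=np.asarray(core_ids if core_ids is not None else apy.core, dtype=str),
    )


def load_apy(path) -> APYInverse:
    z = np.load(path, allow_pickle=False)
    return APYInverse(
        core=z["core"], noncore=z["noncore"], Gcc_inv=z["Gcc_inv"],
        K=z["K"], minv=z["minv"], n=int(z["n"][0]),
    )


@dataclass
class RelationshipSet:
    """All relationship structures for one analysis."""

    a_inv: sp.csr_matrix
    a22: np.ndarray | None
    g_raw: np.ndarray | None
    g_tuned: np.ndarray | None
    g_blended: np.ndarray | None
    h_inv: HInverse
    genotyped_ids: np.ndarray
    core_ids: np.ndarray | None = None


def build_relationships(
    ped: Pedigree,
    genotypes: GenotypeMatrix | None = None,
    tau: float = 0.95,
    mode: str = "direct",
    core_size: int | None = None,
    seed: int = 0,
) -> RelationshipSet:
    """Pedigree + genomic relationship pipeline: A-inverse, A22, raw/tuned/
    blended G, G-inverse (direct or APY with a seeded random core) and the
    assembled H-inverse."""
    a_inv = build_A_inverse(ped)
    if genotypes is None or genotypes.n_animals == 0:
        h_inv = assemble_H_inverse(a_inv, None, None, np.array([], dtype=np.int64))
        return RelationshipSet(a_inv, None, None, None, None, h_inv, np.array([], dtype=object))
    missing = [a for a in genotypes.animal_ids if a not in ped.index]
    if missing:
        raise ValueError(f"genotyped animals absent from pedigree: {missing[:5]}")
    p = allele_frequencies(genotypes)
    g_raw = build_G(genotypes, p)
    a22 = build_A22(ped, genotypes.animal_ids)
    g_tuned = tune_G(g_raw, a22)
    g_blend = blend_G(g_tuned, a22, tau)
    positions = ped.positions(genotypes.animal_ids)
    core = None
    core_ids = None
    if mode == "apy":
        ng = genotypes.n_animals
        csize = min(ng, core_size if core_size is not None else min(ng, 2000))
        rng = np.random.default_rng(seed)
        core = np.sort(rng.choice(ng, size=csize, replace=False))
        core_ids = genotypes.animal_ids[core]
    h_inv = assemble_H_inverse(a_inv, a22, g_blend, positions, mode=mode, core=core)
    return RelationshipSet(a_inv, a22, g_raw, g_tuned, g_blend, h_inv,
                           np.asarray(genotypes.animal_ids), core_ids)
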