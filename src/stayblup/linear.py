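"""Linear-model single-step GBLUP: mixed-model equations and their solution.

Model: y = X b + Z u + e with u ~ (0, H sigma_u^2), e ~ (0, I sigma_e^2) and a
single fixed factor (contemporary group).  The equations

    [X'X   X'Z ] [b]   [X'y]
    [Z'X   Z'Z + H^-1 lambda] [u] = [Z'y],   lambda = sigma_e^2 / sigma_u^2,

are solved by preconditioned conjugate gradients with a diagonal (Jacobi)
preconditioner.  Phenotypes keep their {1, 2} coding; breeding values are
translation invariant so the coding origin is immaterial.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .gmatrix import HInverse
from .pedigree import Pedigree


@dataclass
class ModelSpec:
    """Trait column, contemporary-group column and the variance ratio."""

    trait: str
    variance_ratio: float  # lambda = sigma_e^2 / sigma_u^2
    cg_col: str = "cg"
    scale: str = "observed"

    def __post_init__(self):
        if self.variance_ratio <= 0:
            raise ValueError("variance_ratio must be positive")


@dataclass
class ModelFit:
    beta: pd.Series
    gebv: np.ndarray  # one entry per pedigree animal
    iterations: int
    residual_norm: float
    converged: bool
    animal_ids: np.ndarray = field(default=None, repr=False)

    def gebv_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"animal": self.animal_ids, "gebv": self.gebv})


def _design(phenos: pd.DataFrame, ped: Pedigree, spec: ModelSpec):
    y = phenos[spec.trait].to_numpy(dtype=np.float64)
    cg_codes, cg_levels = pd.factorize(phenos[spec.cg_col])
    animal_pos = ped.positions(phenos["animal"])
    return y, cg_codes, cg_levels, animal_pos


def build_mme(phenos, ped, h_inv: HInverse, spec: ModelSpec):
    """Assemble the sparse coefficient matrix and right-hand side."""
    y, cg, cg_levels, an = _design(phenos, ped, spec)
    n_cg, n_an = len(cg_levels), ped.n
    m = n_cg + n_an
    nrec = len(y)
    X = sp.coo_matrix((np.ones(nrec), (np.arange(nrec), cg)), shape=(nrec, n_cg)).tocsr()
    Z = sp.coo_matrix((np.ones(nrec), (np.arange(nrec), an)), shape=(nrec, n_an)).tocsr()
    W = sp.hstack([X, Z]).tocsr()
    C = (W.T @ W).tocsr()
    Hfull = sp.bmat(
        [[sp.csr_matrix((n_cg, n_cg)), None], [None, h_inv.to_sparse()]], format="csr"
    )
    C = C + spec.variance_ratio * Hfull
    rhs = W.T @ y
    return C, rhs, cg_levels, n_cg


def solve_mme(
    phenos: pd.DataFrame,
    ped: Pedigree,
    h_inv: HInverse,
    spec: ModelSpec,
    tol: float = 1e-12,
    maxiter: int = 5000,
) -> ModelFit:
    """Solve the mixed-model equations by Jacobi-preconditioned CG.

    GEBV are returned for every pedigree animal, phenotyped or not.  A
    singular system (confounded contemporary group) surfaces as
    non-convergence and is flagged rather than silently accepted.
    """
    C, rhs, cg_levels, n_cg = build_mme(phenos, ped, h_inv, spec)
    d = C.diagonal()
    d[d <= 0] = 1.0
    M = sp.diags(1.0 / d)
    it = 0

    def cb(xk):
        nonlocal it
        it += 1

    sol, info = spla.cg(C, rhs, rtol=tol, atol=0.0, maxiter=maxiter, M=M, callback=cb)
    res = float(np.linalg.norm(C @ sol - rhs) / max(np.linalg.norm(rhs), 1e-300))
    return ModelFit(
        beta=pd.Series(sol[:n_cg], index=cg_levels),
        gebv=sol[n_cg:],
        iterations=it,
        residual_norm=res,
        converged=(info == 0),
        animal_ids=np.asarray(ped.animal_ids),
    )


def reliability_proxy(
    phenos: pd.DataFrame,
    ped: Pedigree,
    h_inv: HInverse,
    spec: ModelSpec,
    sigma_u2: float,
    sigma_e2: float,
    cap: int = 2000,
) -> np.ndarray:
    """Per-animal reliability from the dense inverse of the coefficient matrix.

    ``rel_i = 1 - PEV_i / ((1 + F_i) sigma_u^2)`` with ``PEV_i = (C^-1)_{u_i
    u_i} sigma_e^2``.  Small problems only; refuses systems above ``cap``
    equations because the dense inverse is the point of this diagnostic.
    """
    C, _, _, n_cg = build_mme(phenos, ped, h_inv, spec)
    if C.shape[0] > cap:
        raise ValueError(f"system of order {C.shape[0]} exceeds the cap ({cap})")
    Cinv = np.linalg.inv(C.toarray())
    pev = np.diag(Cinv)[n_cg:] * sigma_e2
    rel = 1.0 - pev / ((1.0 + ped.F) * sigma_u2)
    return np.clip(rel, 0.0, 1.0)
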