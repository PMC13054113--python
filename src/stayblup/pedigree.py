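"""Pedigree storage, inbreeding and pedigree-based relationship matrices.

The additive (numerator) relationship matrix ``A`` is never formed densely in
production paths.  Inbreeding coefficients come from the Meuwissen & Luo
recursion, the sparse ``A``-inverse from Henderson's rules with inbreeding, and
the genotyped-animal block ``A22`` from the tabular method restricted to the
ancestors of the genotyped animals.
"""

from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

#: sentinel index for an unknown parent
UNKNOWN = -1


@dataclass
class Pedigree:
    """A topologically sorted pedigree.

    Parameters
    ----------
    animal_ids
        Animal identifiers, parents stored before their offspring.
    sire, dam
        Per-animal parent positions into ``animal_ids``; :data:`UNKNOWN`
        marks an unknown parent.
    inbreeding
        Per-animal pedigree inbreeding coefficient ``F``; filled lazily by
        :func:`compute_inbreeding`.
    """

    animal_ids: np.ndarray
    sire: np.ndarray
    dam: np.ndarray
    inbreeding: np.ndarray | None = None
    _index: dict = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.animal_ids = np.asarray(self.animal_ids)
        self.sire = np.asarray(self.sire, dtype=np.int64)
        self.dam = np.asarray(self.dam, dtype=np.int64)
        if not (len(self.animal_ids) == len(self.sire) == len(self.dam)):
            raise ValueError("animal_ids, sire and dam must have equal length")
        if np.any(self.sire >= np.arange(self.n)) or np.any(self.dam >= np.arange(self.n)):
            raise ValueError("pedigree is not sorted: a parent is stored at or after its offspring")

    @property
    def n(self) -> int:
        return len(self.animal_ids)

    @property
    def index(self) -> dict:
        if self._index is None:
            self._index = {a: i for i, a in enumerate(self.animal_ids)}
        return self._index

    def positions(self, ids) -> np.ndarray:
        """Positions of ``ids`` in storage order; unknown IDs raise KeyError."""
        idx = self.index
        try:
            return np.array([idx[a] for a in ids], dtype=np.int64)
        except KeyError as exc:
            raise KeyError(f"animal {exc.args[0]!r} not in pedigree") from None

    @property
    def F(self) -> np.ndarray:
        if self.inbreeding is None:
            self.inbreeding = compute_inbreeding(self)
        return self.inbreeding


def build_pedigree(animal_ids, sire_ids, dam_ids, unknown="0") -> Pedigree:
    """Build a sorted :class:`Pedigree` from parallel ID columns.

    Input order is arbitrary; a topological sort places parents before
    offspring.  A parent ID that never appears as an animal is treated as a
    founder side (with a warning).  Cycles are a hard error naming one cycle
    member.
    """
    animal_ids = [str(a) for a in animal_ids]
    sire_ids = [str(a) for a in sire_ids]
    dam_ids = [str(a) for a in dam_ids]
    unknown = str(unknown)
    if len(set(animal_ids)) != len(animal_ids):
        dup = pd.Series(animal_ids).value_counts()
        raise ValueError(f"duplicate animal IDs: {list(dup[dup > 1].index[:5])}")
    known = set(animal_ids)

    def resolve(pid, aid):
        if pid == unknown:
            return None
        if pid == aid:
            raise ValueError(f"animal {aid!r} is its own parent (cycle)")
        if pid not in known:
            warnings.warn(f"parent {pid!r} of {aid!r} not listed as an animal; treated as founder")
            return None
        return pid

    parents = {a: (resolve(s, a), resolve(d, a)) for a, s, d in zip(animal_ids, sire_ids, dam_ids)}

    # Kahn's algorithm on the parent -> offspring DAG
    children: dict[str, list[str]] = {a: [] for a in animal_ids}
    pending = {}
    order = []
    ready = []
    for a in animal_ids:
        deg = sum(p is not None for p in parents[a])
        pending[a] = deg
        if deg == 0:
            ready.append(a)
        for p in parents[a]:
            if p is not None:
                children[p].append(a)
    qi = 0
    while qi < len(ready):
        a = ready[qi]
        qi += 1
        order.append(a)
        for c in children[a]:
            pending[c] -= 1
            if pending[c] == 0:
                ready.append(c)
    if len(order) < len(animal_ids):
        stuck = next(a for a in animal_ids if pending[a] > 0)
        raise ValueError(f"pedigree contains a cycle involving animal {stuck!r}")

    pos = {a: i for i, a in enumerate(order)}
    sire = np.array([UNKNOWN if parents[a][0] is None else pos[parents[a][0]] for a in order])
    dam = np.array([UNKNOWN if parents[a][1] is None else pos[parents[a][1]] for a in order])
    return Pedigree(np.array(order, dtype=object), sire, dam)


def read_pedigree(path) -> Pedigree:
    """Read a 3-column pedigree CSV (``animal,sire,dam``; 0 = unknown)."""
    df = pd.read_csv(path, dtype=str)
    if df.shape[1] < 3:
        raise ValueError("pedigree file needs at least 3 columns: animal, sire, dam")
    a, s, d = (df.iloc[:, k] for k in range(3))
    return build_pedigree(a, s, d)


def write_pedigree(ped: Pedigree, path) -> None:
    sid = np.where(ped.sire == UNKNOWN, "0", ped.animal_ids[np.maximum(ped.sire, 0)])
    did = np.where(ped.dam == UNKNOWN, "0", ped.animal_ids[np.maximum(ped.dam, 0)])
    pd.DataFrame({"animal": ped.animal_ids, "sire": sid, "dam": did}).to_csv(path, index=False)


def _mendelian_variance(sire: int, dam: int, F: np.ndarray) -> float:
    """Within-family (Mendelian sampling) variance ``b`` for one animal."""
    if sire != UNKNOWN and dam != UNKNOWN:
        return 0.5 - 0.25 * (F[sire] + F[dam])
    if sire != UNKNOWN:
        return 0.75 - 0.25 * F[sire]
    if dam != UNKNOWN:
        return 0.75 - 0.25 * F[dam]
    return 1.0


def compute_inbreeding(ped: Pedigree) -> np.ndarray:
    """Pedigree inbreeding coefficients by the Meuwissen & Luo recursion.

    For animal ``i``, ``a_ii = sum_j L_ij^2 b_j`` over its ancestors ``j``,
    where ``L`` is the Cholesky-structure path matrix of ``A`` and ``b_j`` the
    Mendelian-sampling variance; ``F_i = a_ii - 1``.  Ancestors are visited
    with a max-heap so the cost per animal is proportional to its ancestry,
    not to pedigree size.  Full siblings share their coefficient through a
    parent-pair cache.
    """
    n = ped.n
    sire, dam = ped.sire, ped.dam
    F = np.zeros(n)
    b = np.empty(n)
    cache: dict[tuple[int, int], float] = {}
    for i in range(n):
        b[i] = _mendelian_variance(sire[i], dam[i], F)
        s, d = sire[i], dam[i]
        if s == UNKNOWN or d == UNKNOWN:
            F[i] = 0.0
            continue
        key = (s, d) if s < d else (d, s)
        if key in cache:
            F[i] = cache[key]
            continue
        # traverse ancestors of i in decreasing position order
        L: dict[int, float] = {i: 1.0}
        heap = [-i]
        aii = 0.0
        while heap:
            j = -heapq.heappop(heap)
            lj = L.pop(j, 0.0)
            if lj == 0.0:
                continue
            aii += lj * lj * b[j]
            for p in (sire[j], dam[j]):
                if p != UNKNOWN:
                    if p not in L:
                        L[p] = 0.0
                        heapq.heappush(heap, -p)
                    L[p] += 0.5 * lj
        F[i] = aii - 1.0
        cache[key] = F[i]
    ped.inbreeding = F
    return F


def tabular_A(ped: Pedigree, positions=None) -> np.ndarray:
    """Dense numerator relationship matrix by the tabular method.

    When ``positions`` is given, the pedigree is first pruned to the ancestors
    of those animals and the corresponding block is returned (same order as
    ``positions``).  Dense construction; intended for genotyped-block
    extraction and test oracles, not full national pedigrees.
    """
    if positions is not None:
        positions = np.asarray(positions, dtype=np.int64)
        keep = ancestor_closure(ped, positions)
        sub_sire, sub_dam, remap = _restrict(ped, keep)
        A = _tabular_full(sub_sire, sub_dam)
        return A[np.ix_(remap[positions], remap[positions])]
    return _tabular_full(ped.sire, ped.dam)


def ancestor_closure(ped: Pedigree, positions) -> np.ndarray:
    """Sorted positions of ``positions`` plus all their ancestors."""
    keep = np.zeros(ped.n, dtype=bool)
    keep[positions] = True
    for i in range(ped.n - 1, -1, -1):
        if keep[i]:
            for p in (ped.sire[i], ped.dam[i]):
                if p != UNKNOWN:
                    keep[p] = True
    return np.flatnonzero(keep)


def _restrict(ped: Pedigree, keep: np.ndarray):
    remap = np.full(ped.n, UNKNOWN, dtype=np.int64)
    remap[keep] = np.arange(len(keep))
    sub_sire = np.where(ped.sire[keep] == UNKNOWN, UNKNOWN, remap[ped.sire[keep]])
    sub_dam = np.where(ped.dam[keep] == UNKNOWN, UNKNOWN, remap[ped.dam[keep]])
    return sub_sire, sub_dam, remap


def _tabular_full(sire, dam) -> np.ndarray:
    n = len(sire)
    A = np.zeros((n, n))
    for i in range(n):
        s, d = sire[i], dam[i]
        if s != UNKNOWN and d != UNKNOWN:
            A[:i, i] = 0.5 * (A[:i, s] + A[:i, d])
            A[i, i] = 1.0 + 0.5 * A[s, d]
        elif s != UNKNOWN:
            A[:i, i] = 0.5 * A[:i, s]
            A[i, i] = 1.0
        elif d != UNKNOWN:
            A[:i, i] = 0.5 * A[:i, d]
            A[i, i] = 1.0
        else:
            A[i, i] = 1.0
        A[i, :i] = A[:i, i]
    return A


def build_A_inverse(ped: Pedigree) -> sp.csr_matrix:
    """Sparse ``A``-inverse by Henderson's rules with inbreeding.

    For each animal ``i`` with Mendelian-sampling variance ``b_i``, add
    ``1/b_i`` to ``(i,i)``, ``-0.5/b_i`` to each (i, parent) pair and
    ``0.25/b_i`` to each parent-parent pair.
    """
    F = ped.F
    rows, cols, vals = [], [], []
    for i in range(ped.n):
        bi = _mendelian_variance(ped.sire[i], ped.dam[i], F)
        k = 1.0 / bi
        parents = [p for p in (ped.sire[i], ped.dam[i]) if p != UNKNOWN]
        rows.append(i); cols.append(i); vals.append(k)
        for p in parents:
            rows += [i, p]
            cols += [p, i]
            vals += [-0.5 * k, -0.5 * k]
        for p in parents:
            for q in parents:
                rows.append(p); cols.append(q); vals.append(0.25 * k)
    Ainv = sp.coo_matrix((vals, (rows, cols)), shape=(ped.n, ped.n)).tocsr()
    Ainv.sum_duplicates()
    return Ainv


def build_A22(ped: Pedigree, genotyped_ids) -> np.ndarray:
    """Pedigree relationship block among genotyped animals.

    This is the genotyped sub-block of the full tabular ``A`` (not the inverse
    of a sub-block of ``A``-inverse); computed on the ancestor closure of the
    genotyped animals.
    """
    positions = ped.positions(genotyped_ids)
    return tabular_A(ped, positions)


def write_triplets(mat, path) -> None:
    """Write a symmetric matrix as plain ``i j value`` triplets (upper part)."""
    mat = sp.coo_matrix(mat)
    with open(path, "w") as fh:
        for i, j, v in zip(mat.row, mat.col, mat.data):
            if i <= j:
                fh.write(f"{i} {j} {v:.12g}\n")
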