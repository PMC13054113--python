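"""Independent brute-force oracles used by the test suite.

Deliberately naive implementations (recursive kinship, dense solves,
exhaustive searches) kept separate from the package's algorithms.
"""

from __future__ import annotations

import numpy as np

UNK = -1


def kinship_A(sire, dam) -> np.ndarray:
    """Dense numerator relationships by memoized recursive kinship.

    a(i, j) = 2 f(i, j) with f the kinship coefficient; independent of the
    package's forward tabular loop.
    """
    n = len(sire)
    memo = {}

    def f(i, j):
        if i > j:
            i, j = j, i
        key = (i, j)
        if key in memo:
            return memo[key]
        if i == j:
            val = 0.5
            if sire[i] != UNK and dam[i] != UNK:
                val = 0.5 * (1.0 + f(sire[i], dam[i]))
        else:
            # j is the younger (larger index): recurse through j's parents
            val = 0.0
            if sire[j] != UNK:
                val += 0.5 * f(i, sire[j])
            if dam[j] != UNK:
                val += 0.5 * f(i, dam[j])
        memo[key] = val
        return val

    A = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            A[i, j] = A[j, i] = 2.0 * f(i, j)
    return A


def random_pedigree(n, rng, p_founder=0.2):
    """Random sorted pedigree arrays (sire, dam) with unknown parents mixed in."""
    sire = np.full(n, UNK, dtype=np.int64)
    dam = np.full(n, UNK, dtype=np.int64)
    for i in range(1, n):
        if rng.random() > p_founder:
            sire[i] = rng.integers(0, i)
        if rng.random() > p_founder and i > 1:
            d = rng.integers(0, i)
            if d != sire[i]:
                dam[i] = d
    return sire, dam


def dense_mme_solution(y, cg_codes, n_cg, animal_pos, n_animals, H_inv_dense, lam):
    """Direct dense solve of the mixed-model equations."""
    nrec = len(y)
    X = np.zeros((nrec, n_cg))
    X[np.arange(nrec), cg_codes] = 1.0
    Z = np.zeros((nrec, n_animals))
    Z[np.arange(nrec), animal_pos] = 1.0
    W = np.hstack([X, Z])
    C = W.T @ W
    C[n_cg:, n_cg:] += lam * H_inv_dense
    return np.linalg.solve(C, W.T @ y)


def brute_force_hpd(x, prob=0.95):
    """Shortest interval over all contiguous windows of the sorted sample."""
    x = np.sort(np.asarray(x, float))
    n = len(x)
    k = max(1, int(np.ceil(prob * n)))
    if k >= n:
        return x[0], x[-1]
    best = None
    for i in range(n - k):
        w = x[i + k] - x[i]
        if best is None or w < best[0]:
            best = (w, x[i], x[i + k])
    return best[1], best[2]


def halfsib_anova_varcomp(y, family):
    """One-way ANOVA variance components for paternal half-sib families.

    Under an animal model, cov(half sibs) = sigma_u2 / 4, so the
    between-family variance tau2 estimates sigma_u2/4 and the within
    variance estimates 0.75 sigma_u2 + sigma_e2.
    """
    import pandas as pd

    df = pd.DataFrame({"y": y, "fam": family})
    k = df.groupby("fam").size()
    means = df.groupby("fam")["y"].mean()
    grand = df["y"].mean()
    s = len(k)
    n = len(df)
    ssb = float((k * (means - grand) ** 2).sum())
    ssw = float(((df["y"] - df["fam"].map(means)) ** 2).sum())
    msb = ssb / (s - 1)
    msw = ssw / (n - s)
    k0 = (n - float((k**2).sum()) / n) / (s - 1)
    tau2 = (msb - msw) / k0
    sigma_u2 = 4.0 * tau2
    sigma_e2 = msw - 3.0 * tau2
    return sigma_u2, sigma_e2
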