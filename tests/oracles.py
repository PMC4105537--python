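"""Independent brute-force reference implementations used by the tests.

These are deliberately naive (triple loops, dense matrices) and are the
normative definitions the fast implementations must reproduce.
"""
from __future__ import annotations

import numpy as np


def pcit_reference(R: np.ndarray) -> np.ndarray:
    """Naive O(n^3) PCIT: examine every trio with scalar arithmetic."""
    R = np.asarray(R, dtype=float)
    n = R.shape[0]

    def partial(a, b, c):
        den = (1.0 - b * b) * (1.0 - c * c)
        if den <= 0.0:
            return np.nan
        return (a - b * c) / np.sqrt(den)

    eliminated = np.zeros((n, n), dtype=bool)
    for x in range(n):
        for y in range(x + 1, n):
            rxy = R[x, y]
            for z in range(n):
                if z == x or z == y:
                    continue
                rxz, ryz = R[x, z], R[y, z]
                pxy = partial(rxy, rxz, ryz)
                pxz = partial(rxz, rxy, ryz)
                pyz = partial(ryz, rxy, rxz)
                terms = []
                for p, r in ((pxy, rxy), (pxz, rxz), (pyz, ryz)):
                    if np.isfinite(p) and r != 0.0:
                        terms.append(p / r)
                if not terms:
                    continue
                eps = float(np.mean(terms))
                if abs(rxy) < abs(eps * rxz) and abs(rxy) < abs(eps * ryz):
                    eliminated[x, y] = eliminated[y, x] = True
                    break
    significant = ~eliminated & (np.abs(R) > 0)
    np.fill_diagonal(significant, False)
    return significant


def dense_mixed_model_solve(
    Y: np.ndarray, S: np.ndarray, components: tuple[float, float, float, float, float],
    level_counts: tuple[int, int, int],
):
    """GLS/BLUP solve of the full stacked mixed model at fixed components.

    Y is genes x libraries; S the per-gene random design (libraries x q);
    level_counts = (n_tissues, n_animals, n_states).
    Returns (library fixed solutions, per-gene random solutions J x q).
    """
    s2g, s2gt, s2ga, s2gp, s2e = components
    T, K, P = level_counts
    J, L = Y.shape
    q = S.shape[1]
    X = np.tile(np.eye(L), (J, 1))
    Z = np.zeros((J * L, J * q))
    for j in range(J):
        Z[j * L : (j + 1) * L, j * q : (j + 1) * q] = S
    per_gene = np.concatenate(
        [np.full(1, s2g), np.full(T, s2gt), np.full(K, s2ga), np.full(P, s2gp)]
    )
    G = np.diag(np.tile(per_gene, J))
    V = Z @ G @ Z.T + s2e * np.eye(J * L)
    y = Y.ravel()
    Vi = np.linalg.inv(V)
    b = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
    u = G @ Z.T @ Vi @ (y - X @ b)
    return b, u.reshape(J, q)


def best_trio_reference(neighbor_sets: dict[str, set[str]]):
    """Exhaustive trio scoring over explicit neighbor sets."""
    from itertools import combinations

    best = None
    for trio in combinations(sorted(neighbor_sets), 3):
        a, b, c = (neighbor_sets[t] for t in trio)
        coverage = len(a | b | c)
        redundancy = len(a & b) + len(a & c) + len(b & c)
        key = (-coverage, redundancy, trio)
        if best is None or key < best:
            best = key
    return best[2], -best[0], best[1]
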