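"""Independent brute-force oracles used to validate the fast implementations.

These are deliberately naive (explicit loops, full enumeration) and share no
code with the package internals.
"""

import numpy as np


def nodf_brute(mat: np.ndarray) -> float:
    """NODF by explicit iteration over every row pair and column pair."""
    total = 0.0
    n_pairs = 0
    for m in (np.asarray(mat), np.asarray(mat).T):
        n = m.shape[0]
        for i in range(n):
            for j in range(i + 1, n):
                fi, fj = m[i].sum(), m[j].sum()
                if fi == fj:
                    continue
                hi, lo = (i, j) if fi > fj else (j, i)
                shared = int(np.sum((m[hi] == 1) & (m[lo] == 1)))
                total += 100.0 * shared / m[lo].sum()
        n_pairs += n * (n - 1) // 2
    return total / n_pairs


def barber_modularity_brute(mat: np.ndarray, row_g, col_g) -> float:
    """Barber bipartite modularity by double loop over all cells."""
    mat = np.asarray(mat, dtype=float)
    L = mat.sum()
    k = mat.sum(axis=1)
    d = mat.sum(axis=0)
    q = 0.0
    for i in range(mat.shape[0]):
        for j in range(mat.shape[1]):
            if row_g[i] == col_g[j]:
                q += mat[i, j] - k[i] * d[j] / L
    return q / L


def directed_modularity_brute(adj: np.ndarray, g) -> float:
    """Leicht-Newman directed modularity by double loop."""
    adj = np.asarray(adj, dtype=float)
    m = adj.sum()
    kout = adj.sum(axis=1)
    kin = adj.sum(axis=0)
    q = 0.0
    n = adj.shape[0]
    for i in range(n):
        for j in range(n):
            if g[i] == g[j]:
                q += adj[i, j] - kout[i] * kin[j] / m
    return q / m


def set_partitions(n: int):
    """All set partitions of range(n) as assignment arrays (Bell enumeration)."""

    def rec(i, groups):
        if i == n:
            yield groups
            return
        for gi in range(len(groups)):
            yield from rec(i + 1, groups[:gi] + [groups[gi] + [i]] + groups[gi + 1 :])
        yield from rec(i + 1, groups + [[i]])

    for groups in rec(1, [[0]]):
        g = np.empty(n, dtype=int)
        for m, members in enumerate(groups):
            for u in members:
                g[u] = m
        yield g


def exhaustive_bipartite_modularity(mat: np.ndarray) -> float:
    """Global maximum of Barber modularity over every partition of all nodes."""
    r = mat.shape[0]
    best = -np.inf
    for g in set_partitions(r + mat.shape[1]):
        best = max(best, barber_modularity_brute(mat, g[:r], g[r:]))
    return best


def exhaustive_directed_modularity(adj: np.ndarray) -> float:
    best = -np.inf
    for g in set_partitions(adj.shape[0]):
        best = max(best, directed_modularity_brute(adj, g))
    return best


def slope_central_difference(values, row, col, dx_km, dy_km) -> float:
    """4-neighbor gradient magnitude, independent re-derivation."""
    dzdx = (values[row, col + 1] - values[row, col - 1]) / (2 * dx_km)
    dzdy = (values[row - 1, col] - values[row + 1, col]) / (2 * dy_km)
    return float(np.sqrt(dzdx**2 + dzdy**2))
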