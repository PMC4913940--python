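"""Nestedness (NODF) and modularity (M) of binary networks.

NODF averages, over all row pairs and all column pairs, the percentage
paired overlap between the less-filled and the more-filled line, counting
zero whenever the two marginal totals are equal (the decreasing-fill rule).

Modularity uses the bipartite (Barber) null term for plant-animal matrices
and the directed in/out-degree (Leicht-Newman) null term for food webs.
Both reduce to the same module-aggregate form

    Q = sum_m [ e_m / L  -  s_m t_m / L^2 ]

with e_m the links inside module m, and (s_m, t_m) the module sums of
(row-degree, column-degree) respectively (out-degree, in-degree) for the
directed case.  ``maximize_modularity`` searches partitions by simulated
annealing, the approach that mitigates the resolution limit of greedy
agglomeration on small networks.
"""

from __future__ import annotations

import math
import random as _random
from dataclasses import dataclass, field

import numpy as np

from ecoweb.network_io import BipartiteNetwork, DirectedNetwork


@dataclass
class Partition:
    """Module assignment over the nodes of one network.

    For a bipartite network rows (plants) and columns (animals) are assigned
    separately; for a directed network only ``row_modules`` is used.  Module
    indices are contiguous from 0.
    """

    row_modules: np.ndarray
    col_modules: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.row_modules = np.asarray(self.row_modules, dtype=np.int64)
        if self.col_modules is not None:
            self.col_modules = np.asarray(self.col_modules, dtype=np.int64)
        self.normalize()

    def _all(self) -> np.ndarray:
        if self.col_modules is None:
            return self.row_modules
        return np.concatenate([self.row_modules, self.col_modules])

    def normalize(self) -> None:
        """Relabel modules to contiguous indices 0..k-1 in order of first appearance."""
        combined = self._all()
        if combined.size == 0:
            raise ValueError("empty partition")
        _, inverse = np.unique(combined, return_inverse=True)
        # np.unique sorts labels; remap to first-appearance order for stability
        order: dict[int, int] = {}
        out = np.empty_like(inverse)
        for pos, lab in enumerate(inverse):
            if lab not in order:
                order[lab] = len(order)
            out[pos] = order[lab]
        if self.col_modules is None:
            self.row_modules = out
        else:
            r = self.row_modules.size
            self.row_modules = out[:r]
            self.col_modules = out[r:]

    @property
    def n_modules(self) -> int:
        return int(self._all().max()) + 1


@dataclass
class MetricValue:
    """A named structural metric value, optionally with the partition attaining it."""

    name: str
    value: float
    partition: Partition | None = None


@dataclass
class AnnealingSchedule:
    """Simulated-annealing control parameters.

    ``t_initial=None`` picks the starting temperature adaptively so that the
    bulk of early uphill/downhill proposals are accepted.  The chain runs
    ``moves_factor * n^2`` proposals per temperature level with geometric
    cooling, restarted ``restarts`` times from random states; the best
    partition ever visited is returned.
    """

    t_initial: float | None = None
    cooling: float = 0.9
    moves_factor: int = 4
    t_min_ratio: float = 1e-3
    restarts: int = 3

    def __post_init__(self) -> None:
        if self.t_initial is not None and self.t_initial <= 0:
            raise ValueError("initial temperature must be positive")
        if not 0.0 < self.cooling < 1.0:
            raise ValueError("cooling factor must lie in (0, 1)")
        if self.restarts < 1 or self.moves_factor < 1:
            raise ValueError("restarts and moves_factor must be >= 1")


def nodf(net: BipartiteNetwork) -> MetricValue:
    """NODF nestedness of a binary incidence matrix, in [0, 100]."""
    mat = net.incidence.astype(np.int64)
    r, c = mat.shape
    if r < 2 and c < 2:
        raise ValueError("NODF needs at least 2 rows or 2 columns")
    total = 0.0
    n_pairs = 0
    for m in (mat, mat.T):
        n = m.shape[0]
        if n < 2:
            continue
        fills = m.sum(axis=1)
        overlap = m @ m.T
        for i in range(n):
            for j in range(i + 1, n):
                fi, fj = fills[i], fills[j]
                if fi != fj:
                    total += 100.0 * overlap[i, j] / min(fi, fj)
        n_pairs += n * (n - 1) // 2
    return MetricValue("NODF", total / n_pairs)


def _check_partition_sizes(part: Partition, n_rows: int, n_cols: int | None) -> None:
    if part.row_modules.size != n_rows:
        raise ValueError(f"partition covers {part.row_modules.size} rows, network has {n_rows}")
    if n_cols is not None:
        if part.col_modules is None:
            raise ValueError("bipartite partition needs col_modules")
        if part.col_modules.size != n_cols:
            raise ValueError(f"partition covers {part.col_modules.size} columns, network has {n_cols}")


def bipartite_modularity_score(net: BipartiteNetwork, part: Partition) -> float:
    """Barber bipartite modularity of a given plant/animal partition."""
    _check_partition_sizes(part, net.n_plants, net.n_animals)
    b = net.incidence.astype(np.float64)
    k = net.plant_degrees.astype(np.float64)
    d = net.animal_degrees.astype(np.float64)
    L = float(net.n_links)
    same = part.row_modules[:, None] == part.col_modules[None, :]
    return float(((b - np.outer(k, d) / L) * same).sum() / L)


def directed_modularity_score(net: DirectedNetwork, part: Partition) -> float:
    """Leicht-Newman directed modularity of a given node partition."""
    _check_partition_sizes(part, net.n_nodes, None)
    a = net.adjacency.astype(np.float64)
    kout = net.out_degrees.astype(np.float64)
    kin = net.in_degrees.astype(np.float64)
    m = float(net.n_edges)
    if m == 0:
        raise ValueError("network has no edges")
    same = part.row_modules[:, None] == part.row_modules[None, :]
    return float(((a - np.outer(kout, kin) / m) * same).sum() / m)


# ---------------------------------------------------------------------------
# simulated annealing
# ---------------------------------------------------------------------------


def _annealing_problem(net: BipartiteNetwork | DirectedNetwork):
    """Unified node set for the annealer.

    Returns (adjacency lists with weights, s-degrees, t-degrees, L).
    Bipartite: nodes = plants then animals, s = plant degree (0 for animals),
    t = animal degree (0 for plants), each link is one undirected edge.
    Directed: s = out-degree, t = in-degree, a mutual pair weighs 2.
    """
    if isinstance(net, BipartiteNetwork):
        r, c = net.incidence.shape
        n = r + c
        s = np.concatenate([net.plant_degrees, np.zeros(c)]).astype(float)
        t = np.concatenate([np.zeros(r), net.animal_degrees]).astype(float)
        L = float(net.n_links)
        adj: list[list[tuple[int, float]]] = [[] for _ in range(n)]
        rows, cols = np.nonzero(net.incidence)
        for i, j in zip(rows, cols):
            adj[i].append((r + j, 1.0))
            adj[r + j].append((int(i), 1.0))
        return adj, s, t, L, r, c
    a = net.adjacency
    n = a.shape[0]
    s = net.out_degrees.astype(float)
    t = net.in_degrees.astype(float)
    L = float(net.n_edges)
    w = a + a.T  # weight between i and j = number of directed edges either way
    adj = [[] for _ in range(n)]
    for i in range(n):
        for j in np.nonzero(w[i])[0]:
            if j != i:
                adj[i].append((int(j), float(w[i, j])))
    return adj, s, t, L, n, None


class _AnnealState:
    """Partition state with O(degree) incremental modularity updates."""

    __slots__ = ("adj", "s", "t", "L", "n", "g", "E", "S", "T", "members", "q")

    def __init__(self, adj, s, t, L, g):
        self.adj = adj
        self.s = s
        self.t = t
        self.L = L
        self.n = len(adj)
        self.g = list(g)
        nm = max(self.g) + 1
        self.E = [0.0] * nm
        self.S = [0.0] * nm
        self.T = [0.0] * nm
        self.members: list[set[int]] = [set() for _ in range(nm)]
        for u, m in enumerate(self.g):
            self.S[m] += s[u]
            self.T[m] += t[u]
            self.members[m].add(u)
        for u in range(self.n):
            mu = self.g[u]
            for v, w in adj[u]:
                if self.g[v] == mu:
                    self.E[mu] += w
        for m in range(nm):
            self.E[m] /= 2.0  # each internal edge counted from both ends
        self.q = self._full_q()

    def _full_q(self) -> float:
        L = self.L
        return sum(e / L - si * ti / (L * L) for e, si, ti in zip(self.E, self.S, self.T))

    def _new_module(self) -> int:
        for m, mem in enumerate(self.members):
            if not mem:
                return m
        self.E.append(0.0)
        self.S.append(0.0)
        self.T.append(0.0)
        self.members.append(set())
        return len(self.members) - 1

    def links_to(self, u: int) -> dict[int, float]:
        g = self.g
        out: dict[int, float] = {}
        for v, w in self.adj[u]:
            m = g[v]
            out[m] = out.get(m, 0.0) + w
        return out

    def delta_move(self, u: int, b: int, lt: dict[int, float]) -> float:
        a = self.g[u]
        L = self.L
        su, tu = self.s[u], self.t[u]
        la = lt.get(a, 0.0)
        lb = lt.get(b, 0.0)
        d = (lb - la) / L
        # null-term change for source module a: remove u
        d -= ((self.S[a] - su) * (self.T[a] - tu) - self.S[a] * self.T[a]) / (L * L)
        # and for target module b: add u
        d -= ((self.S[b] + su) * (self.T[b] + tu) - self.S[b] * self.T[b]) / (L * L)
        return d

    def apply_move(self, u: int, b: int, lt: dict[int, float]) -> None:
        a = self.g[u]
        self.q += self.delta_move(u, b, lt)
        self.E[a] -= lt.get(a, 0.0)
        self.E[b] += lt.get(b, 0.0)
        self.S[a] -= self.s[u]
        self.T[a] -= self.t[u]
        self.S[b] += self.s[u]
        self.T[b] += self.t[u]
        self.members[a].discard(u)
        self.members[b].add(u)
        self.g[u] = b

    def between(self, ma: int, mb: int) -> float:
        small, other = (ma, mb) if len(self.members[ma]) <= len(self.members[mb]) else (mb, ma)
        tot = 0.0
        g = self.g
        for u in self.members[small]:
            for v, w in self.adj[u]:
                if g[v] == other:
                    tot += w
        return tot

    def delta_merge(self, ma: int, mb: int) -> float:
        L = self.L
        return self.between(ma, mb) / L - (self.S[ma] * self.T[mb] + self.S[mb] * self.T[ma]) / (L * L)

    def apply_merge(self, ma: int, mb: int) -> None:
        self.q += self.delta_merge(ma, mb)
        self.E[ma] += self.E[mb] + self.between(ma, mb)
        self.S[ma] += self.S[mb]
        self.T[ma] += self.T[mb]
        for u in self.members[mb]:
            self.g[u] = ma
        self.members[ma] |= self.members[mb]
        self.members[mb] = set()
        self.E[mb] = self.S[mb] = self.T[mb] = 0.0

    def nonempty(self) -> list[int]:
        return [m for m, mem in enumerate(self.members) if mem]


def _anneal_once(adj, s, t, L, n, seed: int, schedule: AnnealingSchedule):
    rng = _random.Random(seed)
    g0 = [rng.randrange(max(2, min(n, int(math.sqrt(n)) + 1))) for _ in range(n)]
    state = _AnnealState(adj, s, t, L, g0)

    # adaptive starting temperature: accept ~80% of early proposals
    if schedule.t_initial is None:
        deltas = []
        for _ in range(50):
            u = rng.randrange(n)
            lt = state.links_to(u)
            mods = state.nonempty()
            b = rng.choice(mods)
            if b != state.g[u]:
                deltas.append(abs(state.delta_move(u, b, lt)))
        scale = max(deltas) if deltas else 1.0 / max(L, 1.0)
        t0 = max(scale, 1e-9) / math.log(1.0 / 0.8)
    else:
        t0 = schedule.t_initial

    moves_per_level = schedule.moves_factor * n * n
    best_q = state.q
    best_g = list(state.g)
    temp = t0
    t_min = t0 * schedule.t_min_ratio
    while temp > t_min:
        for _ in range(moves_per_level):
            r = rng.random()
            if r < 0.90:
                u = rng.randrange(n)
                lt = state.links_to(u)
                mods = state.nonempty()
                if rng.random() < 0.1 and len(mods) < n:
                    b = state._new_module()
                else:
                    b = rng.choice(mods)
                if b == state.g[u]:
                    continue
                d = state.delta_move(u, b, lt)
                if d >= 0 or rng.random() < math.exp(d / temp):
                    state.apply_move(u, b, lt)
            elif r < 0.95:
                mods = state.nonempty()
                if len(mods) < 2:
                    continue
                ma, mb = rng.sample(mods, 2)
                d = state.delta_merge(ma, mb)
                if d >= 0 or rng.random() < math.exp(d / temp):
                    state.apply_merge(ma, mb)
            else:
                mods = [m for m in state.nonempty() if len(state.members[m]) >= 2]
                if not mods:
                    continue
                ma = rng.choice(mods)
                nodes = list(state.members[ma])
                rng.shuffle(nodes)
                half = nodes[: max(1, len(nodes) // 2)]
                mb = state._new_module()
                # split = sequence of single moves; evaluate via state updates
                q_before = state.q
                g_before = list(state.g)
                for u in half:
                    lt = state.links_to(u)
                    state.apply_move(u, mb, lt)
                d = state.q - q_before
                if not (d >= 0 or rng.random() < math.exp(d / temp)):
                    for u in half:
                        lt = state.links_to(u)
                        state.apply_move(u, g_before[u], lt)
            if state.q > best_q + 1e-15:
                best_q = state.q
                best_g = list(state.g)
        temp *= schedule.cooling
    return best_q, best_g


def maximize_modularity(
    net: BipartiteNetwork | DirectedNetwork,
    seed: int,
    schedule: AnnealingSchedule | None = None,
) -> MetricValue:
    """Maximize modularity by simulated annealing; deterministic given seed.

    The single-module partition (Q = 0) is always a candidate, so the
    returned value is never negative.
    """
    schedule = schedule or AnnealingSchedule()
    adj, s, t, L, r, c = _annealing_problem(net)
    n = len(adj)
    best_q = -math.inf
    best_g: list[int] = []
    for restart in range(schedule.restarts):
        q, g = _anneal_once(adj, s, t, L, n, seed * 10007 + restart, schedule)
        if q > best_q:
            best_q, best_g = q, g
    if best_q < 0.0:
        best_q = 0.0
        best_g = [0] * n
    if c is None:
        part = Partition(np.array(best_g))
    else:
        part = Partition(np.array(best_g[:r]), np.array(best_g[r:]))
    # recompute from scratch to wash out incremental float drift
    if isinstance(net, BipartiteNetwork):
        value = bipartite_modularity_score(net, part)
    else:
        value = directed_modularity_score(net, part)
    return MetricValue("M", max(value, 0.0), part)
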