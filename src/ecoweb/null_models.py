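"""Degree-preserving null models and Z-score standardization.

Food webs are randomized by edge switching: two randomly chosen one-way
edges A->B, C->D are rewired to A->D, C->B (mutual pairs A<->B, C<->D to
A<->D, C<->B) whenever the rewiring creates no self-edge and no multiple
edge.  One-way and mutual edges are swapped in separate pools, so the
per-node triple (one-way in, one-way out, mutual) is preserved exactly.

Bipartite networks are randomized with the probabilistic degree model: cell
(i, j) is filled independently with probability proportional to the product
of the observed plant and animal degrees, p_ij = min(1, k_i d_j / L).  The
averaged-fill variant (p_ij = (k_i/C + d_j/R)/2, the classical null model
II) is available behind ``variant="fill_average"``.

Raw NODF and M are standardized as Z = (X_real - X_null) / SD_null against
an ensemble of (by default) 500 null networks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ecoweb.network_io import BipartiteNetwork, DirectedNetwork, foodweb_to_bipartite
from ecoweb.structure_metrics import AnnealingSchedule, maximize_modularity, nodf


class DegenerateNullError(ValueError):
    """Raised when a null ensemble has zero spread and no Z-score exists."""


@dataclass
class NullEnsemble:
    """Metric values over null-model replicates."""

    metric_name: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size < 2:
            raise ValueError("null ensemble needs at least 2 replicates")

    @property
    def n_replicates(self) -> int:
        return self.values.size

    @property
    def x_null(self) -> float:
        return float(self.values.mean())

    @property
    def sd_null(self) -> float:
        return float(self.values.std(ddof=1))


def z_score(x_real: float, ensemble: NullEnsemble) -> float:
    """Standardized score (X_real - X_null) / SD_null."""
    sd = ensemble.sd_null
    if sd == 0.0:
        raise DegenerateNullError(
            f"null ensemble for {ensemble.metric_name} has zero standard deviation"
        )
    return (x_real - ensemble.x_null) / sd


def _decompose_edges(adjacency: np.ndarray):
    a = adjacency
    mutual_mask = (a & a.T).astype(bool)
    iu, ju = np.nonzero(np.triu(mutual_mask, 1))
    mutual = [(int(i), int(j)) for i, j in zip(iu, ju)]
    oneway_mask = a.astype(bool) & ~mutual_mask
    io, jo = np.nonzero(oneway_mask)
    oneway = [(int(i), int(j)) for i, j in zip(io, jo)]
    return oneway, mutual


def switch_edges_directed(
    net: DirectedNetwork,
    seed: int,
    n_attempts: int | None = None,
    swap_factor: int = 10,
    target_swaps: int | None = None,
) -> DirectedNetwork:
    """Degree-preserving rewiring of a directed network.

    Targets ``swap_factor`` accepted swaps per edge; illegal proposals
    (self-edges, multiple edges, or a one-way edge landing on an existing
    opposite edge, which would create a mutual pair) are rejected and
    retried until the target or the attempt budget (default 100 tries per
    targeted swap) is exhausted.
    """
    rng = np.random.default_rng(seed)
    adj = net.adjacency.copy()
    oneway, mutual = _decompose_edges(adj)
    target = (
        target_swaps
        if target_swaps is not None
        else swap_factor * (len(oneway) + len(mutual))
    )
    if n_attempts is None:
        n_attempts = 100 * max(target, 1)
    accepted = 0
    attempts = 0
    n_one = len(oneway)
    n_mut = len(mutual)
    can_one = n_one >= 2
    can_mut = n_mut >= 2
    if not can_one and not can_mut:
        return DirectedNetwork(net.node_labels, adj)
    p_one = n_one / (n_one + n_mut) if can_one and can_mut else (1.0 if can_one else 0.0)
    while accepted < target and attempts < n_attempts:
        attempts += 1
        if rng.random() < p_one:
            e1, e2 = rng.integers(0, n_one, size=2)
            if e1 == e2:
                continue
            a, b = oneway[e1]
            c, d = oneway[e2]
            # propose a->d, c->b
            if a == d or c == b:
                continue
            if adj[a, d] or adj[d, a] or adj[c, b] or adj[b, c]:
                continue
            adj[a, b] = 0
            adj[c, d] = 0
            adj[a, d] = 1
            adj[c, b] = 1
            oneway[e1] = (a, d)
            oneway[e2] = (c, b)
            accepted += 1
        else:
            e1, e2 = rng.integers(0, n_mut, size=2)
            if e1 == e2:
                continue
            a, b = mutual[e1]
            c, d = mutual[e2]
            # propose a<->d, c<->b
            if a == d or c == b:
                continue
            if adj[a, d] or adj[d, a] or adj[c, b] or adj[b, c]:
                continue
            adj[a, b] = adj[b, a] = 0
            adj[c, d] = adj[d, c] = 0
            adj[a, d] = adj[d, a] = 1
            adj[c, b] = adj[b, c] = 1
            mutual[e1] = (a, d)
            mutual[e2] = (c, b)
            accepted += 1
    return DirectedNetwork(net.node_labels, adj)


def null_bipartite_degreeprob(
    net: BipartiteNetwork,
    seed: int,
    variant: str = "degree_product",
    max_resamples: int = 1000,
    require_filled: bool = True,
) -> BipartiteNetwork:
    """Probabilistic degree-based bipartite null network.

    Cells are drawn independently; by default the matrix is resampled until
    it has no all-zero row or column so NODF and modularity stay defined.
    ``require_filled=False`` skips that rejection step (the draw is then an
    unbiased realization of the cell probabilities, useful for checking the
    model's expectations, but may contain degree-0 species).
    """
    rng = np.random.default_rng(seed)
    k = net.plant_degrees.astype(float)
    d = net.animal_degrees.astype(float)
    r, c = net.incidence.shape
    if variant == "degree_product":
        p = np.minimum(1.0, np.outer(k, d) / net.n_links)
    elif variant == "fill_average":
        p = (k[:, None] / c + d[None, :] / r) / 2.0
    else:
        raise ValueError(f"unknown null variant {variant!r}")
    for _ in range(max_resamples):
        mat = (rng.random((r, c)) < p).astype(np.int8)
        if mat.sum() < 1:
            continue
        if require_filled and (mat.sum(axis=1).min() == 0 or mat.sum(axis=0).min() == 0):
            continue
        return BipartiteNetwork(net.plant_labels, net.animal_labels, mat)
    raise RuntimeError(
        f"could not draw a null matrix without empty rows/columns in {max_resamples} attempts"
    )


def _metric_on(net, metric: str, seed: int, schedule: AnnealingSchedule | None) -> float:
    if metric == "NODF":
        bip = foodweb_to_bipartite(net) if isinstance(net, DirectedNetwork) else net
        return nodf(bip).value
    if metric == "M":
        return maximize_modularity(net, seed=seed, schedule=schedule).value
    raise ValueError(f"unknown metric {metric!r}; expected 'NODF' or 'M'")


def standardize_metric(
    net: BipartiteNetwork | DirectedNetwork,
    metric: str,
    seed: int,
    n_null: int = 500,
    schedule: AnnealingSchedule | None = None,
    variant: str = "degree_product",
) -> tuple[float, NullEnsemble]:
    """Z-score of NODF or M against the null model matching the network kind.

    Directed networks use edge switching; bipartite networks the probabilistic
    degree model.  Each replicate (and each annealing run for M) draws its own
    stream from ``seed`` so results are reproducible.
    """
    if n_null < 2:
        raise ValueError("n_null must be >= 2")
    child_seeds = np.random.SeedSequence(seed).generate_state(2 * n_null + 1) % (2**31)
    x_real = _metric_on(net, metric, seed=int(child_seeds[-1]), schedule=schedule)
    values = np.empty(n_null)
    for i in range(n_null):
        if isinstance(net, DirectedNetwork):
            null_net = switch_edges_directed(net, seed=int(child_seeds[2 * i]))
        else:
            null_net = null_bipartite_degreeprob(net, seed=int(child_seeds[2 * i]), variant=variant)
        values[i] = _metric_on(null_net, metric, seed=int(child_seeds[2 * i + 1]), schedule=schedule)
    ensemble = NullEnsemble(metric, values)
    return z_score(x_real, ensemble), ensemble
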