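"""Weighted graph metrics for structural connectomes.

Implements the three global network descriptors used throughout the
analysis — global efficiency, regional/local efficiency, and multi-level
(Louvain) modularity Q with its community hierarchy — plus partition
similarity between subjects' modular decompositions.

Efficiency follows Latora-Marchiori with edge lengths l_ij = 1/w_ij.
Regional efficiency is the Onnela-style triangle-intensity generalization of
the clustering coefficient,

    E_reg(i) = 2 / (k_i (k_i - 1)) * sum_{j<l} (w~_ij w~_jl w~_li)^(1/3),

with weights renormalized by the global matrix maximum (w~ = w / max w) and
k_i the number of nonzero-weight neighbors; nodes with k_i < 2 score 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import dijkstra

from .connectome import Connectome

__all__ = [
    "GraphMetricsResult",
    "global_efficiency",
    "regional_efficiency",
    "local_efficiency",
    "modularity",
    "louvain_modularity",
    "network_metrics",
    "partition_similarity",
]

_GAIN_TOL = 1e-12


@dataclass
class GraphMetricsResult:
    """Summary of one connectome's network metrics.

    ``partition_levels`` lists node->community assignments from coarse to
    fine; each finer level refines the coarser one.  ``Q`` is the modularity
    of the top (coarsest) level, the scalar reported per subject.
    """

    Q: float
    partition_levels: list[np.ndarray]
    E_glob: float
    E_loc: float
    E_reg: np.ndarray
    n_restarts_used: int = 1

    @property
    def partition(self) -> np.ndarray:
        return self.partition_levels[0]


def _weights(C: Connectome | np.ndarray) -> np.ndarray:
    return C.weights if isinstance(C, Connectome) else np.asarray(C, dtype=float)


# ---------------------------------------------------------------------------
# efficiency


def global_efficiency(C: Connectome | np.ndarray) -> float:
    """Average inverse weighted shortest-path length over all node pairs.

    Edge lengths are 1/w; disconnected pairs contribute 0 (1/inf).
    """
    w = _weights(C)
    n = w.shape[0]
    if n < 2:
        raise ValueError("global efficiency needs at least 2 nodes")
    with np.errstate(divide="ignore"):
        lengths = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), np.inf)
    d = dijkstra(lengths, directed=False)
    np.fill_diagonal(d, np.inf)
    inv = np.where(np.isfinite(d), 1.0 / d, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def regional_efficiency(
    C: Connectome | np.ndarray, i: int | None = None
) -> np.ndarray | float:
    """Per-node triangle-intensity efficiency (vector, or one node's value).

    Weights are renormalized by the matrix maximum before evaluation, making
    the measure invariant to uniform weight scaling.
    """
    w = _weights(C)
    wmax = w.max()
    if wmax <= 0:
        out = np.zeros(w.shape[0])
        return out if i is None else float(out[i])
    w_hat = w / wmax
    cbrt = np.cbrt(w_hat)
    # sum over ordered pairs (j, l): diag of cbrt^3; halve for unordered pairs
    tri = np.einsum("ij,jl,li->i", cbrt, cbrt, cbrt) / 2.0
    k = np.count_nonzero(w, axis=1)
    denom = k * (k - 1) / 2.0
    out = np.where(k >= 2, 2.0 * tri / np.where(denom > 0, 2.0 * denom, 1.0), 0.0)
    return out if i is None else float(out[i])


def local_efficiency(C: Connectome | np.ndarray) -> float:
    """Mean regional efficiency over all nodes."""
    return float(np.mean(regional_efficiency(C)))


# ---------------------------------------------------------------------------
# modularity


def modularity(weights: np.ndarray, partition: np.ndarray) -> float:
    """Weighted Newman-Girvan modularity of a fixed partition.

    ``weights`` is the symmetric zero-diagonal adjacency matrix of the
    original graph; ``partition`` assigns a community id to every node.
    """
    w = np.asarray(weights, dtype=float)
    part = np.asarray(partition)
    two_w = w.sum()
    if two_w <= 0:
        return 0.0
    k = w.sum(axis=1)
    q = 0.0
    for c in np.unique(part):
        sel = part == c
        q += w[np.ix_(sel, sel)].sum() / two_w - (k[sel].sum() / two_w) ** 2
    return float(q)


def _one_level(B: np.ndarray, order: np.ndarray) -> tuple[np.ndarray, bool]:
    """One Louvain local-move phase on the (possibly aggregated) graph B.

    ``B`` may carry diagonal entries storing twice the internal weight of an
    aggregated community.  Returns a contiguous community labelling and
    whether any node moved.
    """
    n = B.shape[0]
    comm = np.arange(n)
    k = B.sum(axis=1)
    two_w = B.sum()
    sigma_tot = k.copy()
    improved = False
    moved = True
    while moved:
        moved = False
        for p in order:
            cp = comm[p]
            sigma_tot[cp] -= k[p]
            row = B[p]
            links: dict[int, float] = {cp: 0.0}
            for q in np.flatnonzero(row):
                if q != p:
                    c = int(comm[q])
                    links[c] = links.get(c, 0.0) + row[q]
            best_c = cp
            best_gain = links[cp] - sigma_tot[cp] * k[p] / two_w
            for c in sorted(links):
                gain = links[c] - sigma_tot[c] * k[p] / two_w
                if gain > best_gain + _GAIN_TOL or (
                    abs(gain - best_gain) <= _GAIN_TOL and c < best_c
                ):
                    best_c, best_gain = c, gain
            comm[p] = best_c
            sigma_tot[best_c] += k[p]
            if best_c != cp:
                moved = improved = True
    # relabel contiguously in order of first appearance
    _, relabel = np.unique(comm, return_inverse=True)
    return relabel, improved


def _aggregate(B: np.ndarray, comm: np.ndarray) -> np.ndarray:
    n_c = comm.max() + 1
    out = np.zeros((n_c, n_c))
    for c in range(n_c):
        sel_c = comm == c
        for d in range(c, n_c):
            sel_d = comm == d
            out[c, d] = out[d, c] = B[np.ix_(sel_c, sel_d)].sum()
    return out


def _louvain_once(w: np.ndarray, rng: np.random.Generator) -> list[np.ndarray]:
    """Full multi-level loop; returns per-level partitions on the original
    nodes, finest first."""
    n = w.shape[0]
    levels: list[np.ndarray] = []
    B = w.copy()
    node_map = np.arange(n)  # original node -> current supernode
    while True:
        order = rng.permutation(B.shape[0])
        comm, improved = _one_level(B, order)
        if not improved and levels:
            break
        mapped = comm[node_map]
        if levels and np.array_equal(mapped, levels[-1]):
            break
        levels.append(mapped)
        if not improved or comm.max() + 1 == B.shape[0]:
            break
        B = _aggregate(B, comm)
        node_map = comm[node_map]
    return levels


def louvain_modularity(
    C: Connectome | np.ndarray,
    n_restarts: int = 20,
    seed: int | np.random.Generator = 0,
) -> tuple[float, list[np.ndarray], int]:
    """Maximize modularity Q with the multi-level (Louvain) algorithm.

    Runs ``n_restarts`` random node orders and keeps the partition hierarchy
    with the best top-level Q (ties keep the earliest restart).  Returns
    ``(Q, partition_levels, n_restarts_used)`` with levels ordered coarse to
    fine on the original nodes.
    """
    w = _weights(C)
    if np.any(w < 0):
        raise ValueError("modularity requires nonnegative weights")
    n = w.shape[0]
    if w.sum() <= 0:
        return 0.0, [np.zeros(n, dtype=int)], 0
    rng = np.random.default_rng(seed)
    best_q = -np.inf
    best_levels: list[np.ndarray] = []
    for _ in range(max(1, n_restarts)):
        levels = _louvain_once(w, rng)
        q = modularity(w, levels[-1])
        if q > best_q + _GAIN_TOL:
            best_q = q
            best_levels = levels
    return float(best_q), best_levels[::-1], max(1, n_restarts)


def network_metrics(
    C: Connectome | np.ndarray,
    n_restarts: int = 20,
    seed: int | np.random.Generator = 0,
) -> GraphMetricsResult:
    """All global metrics of one connectome in a single result object."""
    e_reg = regional_efficiency(C)
    q, levels, used = louvain_modularity(C, n_restarts=n_restarts, seed=seed)
    return GraphMetricsResult(
        Q=q,
        partition_levels=levels,
        E_glob=global_efficiency(C),
        E_loc=float(np.mean(e_reg)),
        E_reg=np.asarray(e_reg),
        n_restarts_used=used,
    )


# ---------------------------------------------------------------------------
# partition similarity


def _contingency(p1: np.ndarray, p2: np.ndarray) -> np.ndarray:
    a = np.unique(p1, return_inverse=True)[1]
    b = np.unique(p2, return_inverse=True)[1]
    table = np.zeros((a.max() + 1, b.max() + 1))
    np.add.at(table, (a, b), 1)
    return table


def partition_similarity(p1, p2, metric: str = "ari") -> float:
    """Similarity of two community partitions of the same node set, in [0, 1].

    ``metric="ari"`` (default): adjusted Rand index clipped below at 0;
    ``metric="nmi"``: normalized mutual information (arithmetic-mean
    normalization).  Both are invariant to community relabelling.
    """
    p1 = np.asarray(p1)
    p2 = np.asarray(p2)
    if p1.shape != p2.shape:
        raise ValueError("partitions must cover the same node set")
    n = p1.size
    table = _contingency(p1, p2)
    if metric == "ari":
        comb = table * (table - 1) / 2.0
        sum_ij = comb.sum()
        a = table.sum(axis=1)
        b = table.sum(axis=0)
        sum_a = (a * (a - 1) / 2.0).sum()
        sum_b = (b * (b - 1) / 2.0).sum()
        total = n * (n - 1) / 2.0
        expected = sum_a * sum_b / total if total else 0.0
        max_index = (sum_a + sum_b) / 2.0
        if max_index == expected:
            return 1.0
        ari = (sum_ij - expected) / (max_index - expected)
        return float(max(0.0, ari))
    if metric == "nmi":
        pxy = table / n
        px = pxy.sum(axis=1)
        py = pxy.sum(axis=0)
        nz = pxy > 0
        mi = np.sum(pxy[nz] * np.log(pxy[nz] / np.outer(px, py)[nz]))
        hx = -np.sum(px[px > 0] * np.log(px[px > 0]))
        hy = -np.sum(py[py > 0] * np.log(py[py > 0]))
        if hx == 0.0 and hy == 0.0:
            return 1.0
        return float(mi / ((hx + hy) / 2.0))
    raise ValueError(f"unknown similarity metric {metric!r}")
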