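"""Significantly mutated subnetworks via insulated heat diffusion.

Each gene sources heat equal to its total mutation frequency.  Heat spreads
along the (unweighted) interaction network by a random walk in which every
node retains a fraction beta of its heat per step; the stationary influence
matrix has the closed form

    F = beta * (I - (1 - beta) * W)^{-1}

with W the column-stochastic walk matrix.  The exchanged-heat matrix
E = F diag(h) records how much heat node i receives from source j.
Thresholding E at delta defines a directed graph whose strongly connected
components (SCCs) of size >= k_min are the candidate subnetworks.  delta is
chosen from heat-permuted data (the smallest threshold keeping the largest
permuted component below l_max, median across permutations), and the count
of components of each size is calibrated against the same permutation null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

logger = logging.getLogger(__name__)


@dataclass
class DiffusionResult:
    """Influence (F) and exchanged-heat (E) matrices for one diffusion run."""

    beta: float
    F: np.ndarray
    E: np.ndarray
    nodes: list


@dataclass
class SubnetworkResult:
    """Subnetworks extracted at one delta plus their permutation calibration."""

    delta: float
    beta: float
    k_min: int
    subnetworks: list[list] = field(default_factory=list)
    significance: pd.DataFrame | None = None

    @property
    def sizes(self) -> list[int]:
        return [len(s) for s in self.subnetworks]


def walk_matrix(graph: nx.Graph) -> tuple[np.ndarray, list]:
    """Column-stochastic walk matrix of an unweighted graph.

    W[i, j] = 1/deg(j) when (i, j) is an edge, else 0.  Isolated nodes are
    removed beforehand with a warning (they cannot exchange heat).

    Returns
    -------
    (W, nodes) : the matrix and the node order of its rows/columns.
    """
    isolated = list(nx.isolates(graph))
    if isolated:
        logger.warning("dropping %d isolated node(s) before diffusion", len(isolated))
        graph = graph.subgraph(n for n in graph if n not in set(isolated))
    nodes = sorted(graph.nodes())
    if not nodes:
        raise ValueError("graph has no non-isolated nodes")
    A = nx.to_numpy_array(graph, nodelist=nodes, weight=None)
    deg = A.sum(axis=0)
    return A / deg, nodes


def diffuse(W: np.ndarray, h: np.ndarray, beta: float, nodes=None) -> DiffusionResult:
    """Insulated heat diffusion: F = beta (I - (1-beta) W)^{-1}, E = F diag(h).

    ``beta`` in (0, 1) is the fraction of heat a node retains per step;
    ``h`` (componentwise >= 0) is aligned to the walk-matrix node order.
    With column-stochastic W every column of F sums to 1, so the heat of
    each source is redistributed, never created: sum_i E[i, j] = h[j].
    """
    if not 0 < beta < 1:
        raise ValueError(f"beta must lie in (0, 1), got {beta}")
    h = np.asarray(h, dtype=float)
    if (h < 0).any():
        raise ValueError("heat scores must be non-negative")
    n = W.shape[0]
    if h.shape != (n,):
        raise ValueError(f"heat vector length {h.shape} does not match W ({n})")
    F = beta * np.linalg.inv(np.eye(n) - (1.0 - beta) * W)
    E = F * h[np.newaxis, :]
    if nodes is None:
        nodes = list(range(n))
    return DiffusionResult(beta=beta, F=F, E=E, nodes=list(nodes))


def _scc_labels(E: np.ndarray, delta: float) -> tuple[int, np.ndarray]:
    """SCC labels of the directed graph with edge j->i iff i != j, E[i,j] >= delta."""
    mask = E >= delta
    np.fill_diagonal(mask, False)
    # csgraph reads A[i, j] as edge i->j; orientation is irrelevant for SCCs
    return connected_components(sp.csr_matrix(mask), directed=True, connection="strong")


def extract_subnetworks(E: np.ndarray, delta: float, k_min: int = 3, nodes=None) -> list[list]:
    """Strongly connected components of the delta-thresholded exchanged-heat graph.

    Returns components with at least ``k_min`` genes, each sorted by gene
    id, ordered by decreasing size (ties by first gene id).
    """
    if delta < 0:
        raise ValueError("delta must be non-negative")
    if k_min < 2:
        raise ValueError("k_min must be at least 2")
    if nodes is None:
        nodes = list(range(E.shape[0]))
    _, labels = _scc_labels(E, delta)
    comps: dict[int, list] = {}
    for node, lab in zip(nodes, labels):
        comps.setdefault(int(lab), []).append(node)
    out = [sorted(c) for c in comps.values() if len(c) >= k_min]
    out.sort(key=lambda c: (-len(c), c))
    return out


def delta_for_heats(F: np.ndarray, h: np.ndarray, l_max: int = 10) -> float:
    """Smallest edge threshold keeping the largest SCC below ``l_max`` genes.

    Candidate thresholds are 0 and the distinct positive off-diagonal
    values of E = F diag(h) (plus a sentinel just above the maximum);
    the answer is found by binary search, valid because raising the
    threshold never merges components.
    """
    if l_max < 2:
        raise ValueError("l_max must be at least 2")
    E = F * np.asarray(h, dtype=float)[np.newaxis, :]
    off = E[~np.eye(E.shape[0], dtype=bool)]
    values = np.unique(off[off > 0])
    if values.size == 0:
        return 0.0
    candidates = np.concatenate([[0.0], values, [np.nextafter(values[-1], np.inf)]])

    def small_enough(delta: float) -> bool:
        _, labels = _scc_labels(E, delta)
        return np.bincount(labels).max() < l_max

    lo, hi = 0, len(candidates) - 1
    if small_enough(candidates[lo]):
        return float(candidates[lo])
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if small_enough(candidates[mid]):
            hi = mid
        else:
            lo = mid
    return float(candidates[hi])


def select_delta(
    W: np.ndarray,
    h: np.ndarray,
    beta: float = 0.4,
    n_perm: int = 100,
    l_max: int = 10,
    seed: int = 0,
    F: np.ndarray | None = None,
) -> float:
    """Median of per-permutation deltas under random heat reassignment.

    For each permutation the heat scores are shuffled uniformly over the
    nodes (network fixed) and :func:`delta_for_heats` is evaluated; the
    median across permutations is returned.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    if F is None:
        F = diffuse(W, np.asarray(h, dtype=float), beta).F
    rng = np.random.default_rng(seed)
    h = np.asarray(h, dtype=float)
    deltas = [delta_for_heats(F, rng.permutation(h), l_max=l_max) for _ in range(n_perm)]
    return float(np.median(deltas))


def subnetwork_significance(
    observed_sizes: list[int],
    F: np.ndarray,
    h: np.ndarray,
    delta: float,
    k_min: int = 3,
    n_perm: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-size empirical p-values and FDR estimates from the heat-permutation null.

    For each size s from k_min to the largest observed component,
    ``count_obs(>= s)`` is compared with the same count on heat-permuted
    data: p(s) = (1 + #{perm: count_perm >= count_obs}) / (n_perm + 1) and
    FDR(s) = mean_perm count_perm / count_obs, capped at 1 (defined as 1
    when nothing of size s was observed).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    h = np.asarray(h, dtype=float)
    rng = np.random.default_rng(seed)
    sizes = np.asarray(sorted(observed_sizes), dtype=int)
    s_max = int(sizes.max()) if sizes.size else k_min
    s_grid = np.arange(k_min, s_max + 1)
    count_obs = np.array([(sizes >= s).sum() for s in s_grid])

    perm_counts = np.zeros((n_perm, len(s_grid)))
    for p in range(n_perm):
        hp = rng.permutation(h)
        comp_sizes = np.array(
            [len(c) for c in extract_subnetworks(F * hp[np.newaxis, :], delta, k_min=k_min)],
            dtype=int,
        )
        perm_counts[p] = [(comp_sizes >= s).sum() for s in s_grid]

    pvals = (1 + (perm_counts >= count_obs[np.newaxis, :]).sum(axis=0)) / (n_perm + 1)
    mean_perm = perm_counts.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr = np.where(count_obs > 0, np.minimum(mean_perm / count_obs, 1.0), 1.0)
    return pd.DataFrame({"size": s_grid, "count": count_obs, "p": pvals, "fdr": fdr})


def find_hot_subnetworks(
    graph: nx.Graph,
    heats: pd.Series | dict,
    beta: float = 0.4,
    n_perm: int = 100,
    l_max: int = 10,
    k_min: int = 3,
    seed: int = 0,
) -> SubnetworkResult:
    """End-to-end diffusion stage: walk matrix, diffusion, delta selection,
    component extraction and permutation calibration.

    ``heats`` maps gene id to heat score (genes absent from the mapping get
    heat 0).  Returns a :class:`SubnetworkResult`.
    """
    W, nodes = walk_matrix(graph)
    h = np.array([float(heats.get(n, 0.0)) for n in nodes])
    res = diffuse(W, h, beta, nodes=nodes)
    delta = select_delta(W, h, beta=beta, n_perm=n_perm, l_max=l_max, seed=seed, F=res.F)
    subnets = extract_subnetworks(res.E, delta, k_min=k_min, nodes=nodes)
    sig = subnetwork_significance(
        [len(s) for s in subnets], res.F, h, delta, k_min=k_min, n_perm=n_perm, seed=seed + 1
    )
    return SubnetworkResult(delta=delta, beta=beta, k_min=k_min, subnetworks=subnets, significance=sig)
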