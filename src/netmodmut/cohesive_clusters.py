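"""Overlapping cohesive clusters on the similarity-weighted network.

A group's *cohesiveness* is its total internal edge weight divided by
internal + boundary weight + a per-gene penalty.  Groups are grown greedily
from high-degree seeds (single-gene additions and removals, largest strict
improvement first), near-duplicates are merged through an overlap graph
(omega = |X ∩ Y|^2 / (|X||Y|)), sparse groups are discarded by a density
threshold, and each surviving cluster is scored by a one-sided
Mann-Whitney U test on its members' in-weights versus out-weights, with
Benjamini-Hochberg adjustment across clusters.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.stats import norm, rankdata
from statsmodels.stats.multitest import multipletests


@dataclass
class CohesiveGroup:
    """A candidate gene cluster with its cohesiveness bookkeeping."""

    genes: frozenset
    w_in: float
    w_bound: float
    cohesiveness: float
    seed: object | None = None
    outlier_seed: bool = False
    density: float | None = None
    p_value: float | None = None
    adjusted_p: float | None = None

    def __len__(self) -> int:
        return len(self.genes)


def _weights(network: nx.Graph, genes) -> tuple[float, float]:
    """Total internal and boundary edge weight of a gene set."""
    genes = set(genes)
    w_in = 0.0
    w_bound = 0.0
    seen = set()
    for g in genes:
        if g not in network:
            raise ValueError(f"gene {g!r} not in the network")
        for u, v, d in network.edges(g, data=True):
            other = v if u == g else u
            if other in genes:
                key = (min(u, v), max(u, v))
                if key not in seen:
                    seen.add(key)
                    w_in += d["weight"]
            else:
                w_bound += d["weight"]
    return w_in, w_bound


def cohesiveness(genes, network: nx.Graph, penalty_rate: float = 2.0) -> float:
    """w_in / (w_in + w_bound + penalty_rate * |genes|).

    ``penalty_rate`` models uncertainty about unobserved interactions; 0
    recovers the penalty-free reading.  Empty or singleton sets with no
    internal weight score 0.
    """
    if penalty_rate < 0:
        raise ValueError("penalty_rate must be non-negative")
    genes = set(genes)
    if not genes:
        return 0.0
    w_in, w_bound = _weights(network, genes)
    denom = w_in + w_bound + penalty_rate * len(genes)
    return w_in / denom if denom > 0 else 0.0


def grow_group(seed, network: nx.Graph, penalty_rate: float = 2.0) -> CohesiveGroup:
    """Greedy cohesiveness hill-climb from a seed gene.

    Each step evaluates every single-gene addition (boundary neighbours)
    and removal (current members, the seed included) and applies the move
    with the largest strict cohesiveness increase; ties break to the
    lexicographically smallest gene id.  The seed itself may be ejected, in
    which case the returned group is flagged ``outlier_seed``.
    """
    if seed not in network:
        raise ValueError(f"seed {seed!r} not in the network")
    strength = {g: sum(d["weight"] for _, _, d in network.edges(g, data=True)) for g in network}

    members = {seed}
    w_in, w_bound = 0.0, strength[seed]
    denom = w_in + w_bound + penalty_rate * 1
    current = w_in / denom if denom > 0 else 0.0

    while True:
        best = None  # (cohesiveness, gene_id, kind, new_w_in, new_w_bound)
        neighbours = {n for g in members for n in network.neighbors(g)} - members
        for cand in neighbours:
            into = sum(
                network[cand][m]["weight"] for m in network.neighbors(cand) if m in members
            )
            nw_in = w_in + into
            nw_bound = w_bound - into + (strength[cand] - into)
            denom = nw_in + nw_bound + penalty_rate * (len(members) + 1)
            c = nw_in / denom if denom > 0 else 0.0
            if best is None or c > best[0] or (c == best[0] and _tie_key(cand) < _tie_key(best[1])):
                best = (c, cand, "add", nw_in, nw_bound)
        for cand in list(members):
            if len(members) == 1:
                continue  # removal would empty the group
            into = sum(
                network[cand][m]["weight"] for m in network.neighbors(cand) if m in members
            )
            nw_in = w_in - into
            nw_bound = w_bound + into - (strength[cand] - into)
            denom = nw_in + nw_bound + penalty_rate * (len(members) - 1)
            c = nw_in / denom if denom > 0 else 0.0
            if best is None or c > best[0] or (c == best[0] and _tie_key(cand) < _tie_key(best[1])):
                best = (c, cand, "remove", nw_in, nw_bound)
        if best is None or best[0] <= current + 1e-12:
            break
        current, gene, kind, w_in, w_bound = best
        if kind == "add":
            members.add(gene)
        else:
            members.remove(gene)

    return CohesiveGroup(
        genes=frozenset(members),
        w_in=w_in,
        w_bound=w_bound,
        cohesiveness=current,
        seed=seed,
        outlier_seed=seed not in members,
    )


def _tie_key(gene) -> str:
    return str(gene)


def find_groups(network: nx.Graph, penalty_rate: float = 2.0) -> list[CohesiveGroup]:
    """Grow one group per seed, seeding in decreasing weighted-degree order.

    Nodes already covered by an accepted group are skipped as seeds; a seed
    ejected from its own group stays eligible as a member of later groups
    but is never used as a seed again.  Duplicate gene sets are reported
    once.
    """
    if network.number_of_nodes() == 0:
        raise ValueError("empty network")
    strength = {g: sum(d["weight"] for _, _, d in network.edges(g, data=True)) for g in network}
    order = sorted(network.nodes(), key=lambda g: (-strength[g], _tie_key(g)))
    covered: set = set()
    used_seeds: set = set()
    seen_sets: set = set()
    groups: list[CohesiveGroup] = []
    for seed in order:
        if seed in covered or seed in used_seeds:
            continue
        used_seeds.add(seed)
        grp = grow_group(seed, network, penalty_rate=penalty_rate)
        covered |= grp.genes
        if grp.genes not in seen_sets:
            seen_sets.add(grp.genes)
            groups.append(grp)
    return groups


def overlap_score(X, Y) -> float:
    """omega(X, Y) = |X ∩ Y|^2 / (|X| |Y|)."""
    X, Y = set(X), set(Y)
    if not X or not Y:
        raise ValueError("overlap score of an empty set is undefined")
    return len(X & Y) ** 2 / (len(X) * len(Y))


def merge_groups(groups, omega_threshold: float = 0.8) -> list[frozenset]:
    """Union-merge groups connected (directly or via paths) in the overlap graph.

    Two groups are adjacent when omega >= ``omega_threshold``; each
    connected component of the overlap graph is replaced by the union of
    its gene sets.  Groups with no such neighbour pass through unchanged.
    Idempotent: merging the merged list changes nothing.
    """
    if not 0 < omega_threshold <= 1:
        raise ValueError("omega_threshold must lie in (0, 1]")
    gene_sets = [g.genes if isinstance(g, CohesiveGroup) else frozenset(g) for g in groups]
    og = nx.Graph()
    og.add_nodes_from(range(len(gene_sets)))
    for i, j in itertools.combinations(range(len(gene_sets)), 2):
        if overlap_score(gene_sets[i], gene_sets[j]) >= omega_threshold:
            og.add_edge(i, j)
    merged = []
    for comp in nx.connected_components(og):
        union: frozenset = frozenset().union(*(gene_sets[i] for i in comp))
        merged.append(union)
    merged.sort(key=lambda s: (-len(s), sorted(map(str, s))))
    # deduplicate identical unions
    out, seen = [], set()
    for s in merged:
        if s not in seen:
            seen.add(s)
            out.append(s)
    return out


def group_density(genes, network: nx.Graph) -> float:
    """Internal weight divided by the number of gene pairs (singletons: 0)."""
    genes = set(genes)
    k = len(genes)
    if k < 2:
        return 0.0
    w_in, _ = _weights(network, genes)
    return w_in / (k * (k - 1) / 2)


def density_filter(groups, network: nx.Graph, min_density: float = 0.3) -> list[frozenset]:
    """Keep groups whose weighted density reaches ``min_density``."""
    if min_density < 0:
        raise ValueError("min_density must be non-negative")
    kept = []
    for g in groups:
        genes = g.genes if isinstance(g, CohesiveGroup) else frozenset(g)
        if group_density(genes, network) >= min_density:
            kept.append(genes)
    return kept


def _member_weights(genes, network: nx.Graph) -> tuple[np.ndarray, np.ndarray]:
    genes = set(genes)
    in_w, out_w = [], []
    for g in sorted(genes, key=_tie_key):
        wi = wo = 0.0
        for u, v, d in network.edges(g, data=True):
            other = v if u == g else u
            if other in genes:
                wi += d["weight"]
            else:
                wo += d["weight"]
        in_w.append(wi)
        out_w.append(wo)
    return np.array(in_w), np.array(out_w)


def _mwu_greater(x: np.ndarray, y: np.ndarray, exact_max: int = 8) -> float:
    """One-sided Mann-Whitney p for 'x stochastically larger than y'.

    Exact enumeration over all rank splits when both samples have at most
    ``exact_max`` values (midranks handle ties); otherwise the normal
    approximation with tie correction and no continuity correction, so
    U = n1 n2 / 2 gives p = 0.5 exactly.
    """
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    if n1 <= exact_max and n2 <= exact_max:
        idx = np.array(list(itertools.combinations(range(n1 + n2), n1)))
        u_all = ranks[idx].sum(axis=1) - n1 * (n1 + 1) / 2
        return float(np.mean(u_all >= u_obs - 1e-12))
    mu = n1 * n2 / 2
    _, counts = np.unique(pooled, return_counts=True)
    n = n1 + n2
    tie_term = ((counts**3 - counts).sum()) / (n * (n - 1))
    sigma2 = n1 * n2 / 12 * (n + 1 - tie_term)
    if sigma2 <= 0:
        return 0.5
    return float(norm.sf((u_obs - mu) / math.sqrt(sigma2)))


def cluster_pvalue(genes, network: nx.Graph) -> float:
    """Mann-Whitney p-value that members' in-weights exceed their out-weights."""
    genes = set(genes)
    if len(genes) < 2:
        raise ValueError("cluster p-value requires at least 2 members")
    in_w, out_w = _member_weights(genes, network)
    return _mwu_greater(in_w, out_w)


def adjust_bh(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals
    return multipletests(pvals, method="fdr_bh")[1]


def find_cohesive_clusters(
    network: nx.Graph,
    penalty_rate: float = 2.0,
    omega_threshold: float = 0.8,
    min_density: float = 0.3,
) -> list[CohesiveGroup]:
    """Full clustering stage: grow, merge, density-filter, test, adjust.

    Returns the surviving clusters (size >= 2) as :class:`CohesiveGroup`
    objects with density, raw and BH-adjusted Mann-Whitney p-values,
    sorted by raw p-value then size.
    """
    raw = find_groups(network, penalty_rate=penalty_rate)
    merged = merge_groups(raw, omega_threshold=omega_threshold)
    dense = [g for g in density_filter(merged, network, min_density=min_density) if len(g) >= 2]
    out = []
    for genes in dense:
        w_in, w_bound = _weights(network, genes)
        out.append(
            CohesiveGroup(
                genes=genes,
                w_in=w_in,
                w_bound=w_bound,
                cohesiveness=cohesiveness(genes, network, penalty_rate=penalty_rate),
                density=group_density(genes, network),
                p_value=cluster_pvalue(genes, network),
            )
        )
    adj = adjust_bh([g.p_value for g in out])
    for g, a in zip(out, adj):
        g.adjusted_p = float(a)
    out.sort(key=lambda g: (g.p_value, -len(g.genes), sorted(map(str, g.genes))))
    return out


def significant_clusters(
    clusters: list[CohesiveGroup], max_adjusted_p: float = 0.1, min_size: int = 3
) -> list[CohesiveGroup]:
    """Clusters with adjusted p below threshold and more than two genes."""
    return [c for c in clusters if c.adjusted_p is not None and c.adjusted_p < max_adjusted_p and len(c.genes) >= min_size]
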