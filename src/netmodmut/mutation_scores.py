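"""Gene mutation frequencies, heat scores and pairwise mutation similarity.

Per-gene gain/loss frequencies are the fractions of samples carrying a +1
or -1 entry; their sum is the gene's *heat* score, the source intensity for
network diffusion.  A gene pair's mutation similarity is the cosine of their
(gain, loss) frequency vectors and is used to weight the edges of an
otherwise unweighted interaction network.
"""

from __future__ import annotations

import logging
from collections import namedtuple
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

BinCounts = namedtuple("BinCounts", ["high", "medium", "low"])

_VARIANTS = ("cosine", "as_printed")


def gene_frequencies(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-gene gain/loss counts, frequencies and heat scores.

    Parameters
    ----------
    matrix : pandas.DataFrame
        Samples x genes matrix with entries in {-1, 0, +1}.

    Returns
    -------
    pandas.DataFrame
        Indexed by gene, with columns ``n_gain``, ``n_loss``, ``f_gain``,
        ``f_loss`` and ``heat`` (= f_gain + f_loss).  The number of samples
        is stored in ``.attrs["n_samples"]``.
    """
    n_samples = matrix.shape[0]
    if n_samples == 0:
        raise ValueError("mutation matrix has zero samples")
    n_gain = (matrix.to_numpy() == 1).sum(axis=0)
    n_loss = (matrix.to_numpy() == -1).sum(axis=0)
    out = pd.DataFrame(
        {
            "n_gain": n_gain,
            "n_loss": n_loss,
            "f_gain": n_gain / n_samples,
            "f_loss": n_loss / n_samples,
        },
        index=matrix.columns.rename("gene"),
    )
    out["heat"] = out["f_gain"] + out["f_loss"]
    out.attrs["n_samples"] = n_samples
    return out


def pair_similarity(fi, fj, variant: str = "cosine") -> float:
    """Mutation similarity of two genes from their (gain, loss) frequencies.

    The default ``cosine`` variant is the standard cosine similarity

        sim = (f_ig f_jg + f_il f_jl) / (sqrt(f_ig^2 + f_il^2) sqrt(f_jg^2 + f_jl^2))

    which lies in [0, 1] for non-negative frequencies.  The ``as_printed``
    variant keeps the unrooted sums in the denominator and can exceed 1;
    it is provided for exact reproduction of the literal formula.

    Either vector being all-zero yields similarity 0 (an unmutated gene
    should not bind a mutated module).
    """
    if variant not in _VARIANTS:
        raise ValueError(f"unknown similarity variant {variant!r}")
    fi = np.asarray(fi, dtype=float)
    fj = np.asarray(fj, dtype=float)
    if (fi < 0).any() or (fj < 0).any():
        raise ValueError("mutation frequencies must be non-negative")
    ni, nj = np.sum(fi * fi), np.sum(fj * fj)
    if ni == 0.0 or nj == 0.0:
        return 0.0
    dot = float(np.dot(fi, fj))
    if variant == "cosine":
        return dot / float(np.sqrt(ni) * np.sqrt(nj))
    return dot / float(ni * nj)


def weight_network(
    edges: Iterable[tuple[str, str]] | nx.Graph,
    freqs: pd.DataFrame,
    variant: str = "cosine",
    strict: bool = False,
) -> nx.Graph:
    """Attach mutation-similarity weights to an interaction edge list.

    Edges with an endpoint absent from ``freqs`` are dropped with a logged
    warning, or raise when ``strict`` is true.  Self-loops and duplicate
    edges are discarded.

    Returns an undirected :class:`networkx.Graph` whose ``weight`` edge
    attribute is the pairwise similarity.
    """
    if isinstance(edges, nx.Graph):
        edges = edges.edges()
    fg = freqs["f_gain"]
    fl = freqs["f_loss"]
    known = set(freqs.index)
    g = nx.Graph()
    n_dropped = 0
    for u, v in edges:
        if u == v:
            continue
        if u not in known or v not in known:
            if strict:
                raise KeyError(
                    f"edge ({u!r}, {v!r}) has an endpoint absent from the "
                    "mutation matrix"
                )
            n_dropped += 1
            continue
        w = pair_similarity((fg[u], fl[u]), (fg[v], fl[v]), variant=variant)
        g.add_edge(u, v, weight=w)
    if n_dropped:
        logger.warning(
            "dropped %d interaction(s) with endpoints absent from the mutation matrix",
            n_dropped,
        )
    return g


def bin_interactions(network: nx.Graph, hi: float = 0.9, lo: float = 0.5) -> BinCounts:
    """Count edges in high (w >= hi), medium (lo <= w < hi) and low (w < lo) bins."""
    if not 0 <= lo <= hi <= 1:
        raise ValueError(f"require 0 <= lo <= hi <= 1, got lo={lo}, hi={hi}")
    w = np.array([d["weight"] for _, _, d in network.edges(data=True)])
    if w.size == 0:
        return BinCounts(0, 0, 0)
    high = int((w >= hi).sum())
    low = int((w < lo).sum())
    return BinCounts(high, int(w.size) - high - low, low)


# ---------------------------------------------------------------------------
# I/O


def read_edge_list(path) -> list[tuple[str, str]]:
    """Read a TSV edge list ``gene_a<TAB>gene_b[<TAB>weight]`` (no header)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    return [(r[0], r[1]) for r in df.itertuples(index=False)]


def write_weighted_edges(network: nx.Graph, path) -> None:
    """Write a weighted TSV edge list ``gene_a  gene_b  weight``."""
    rows = sorted((min(u, v), max(u, v), d["weight"]) for u, v, d in network.edges(data=True))
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)
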