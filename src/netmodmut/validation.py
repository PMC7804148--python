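"""Cross-cohort module matching by overlap rate.

Modules found independently in a discovery and a validation cohort are
matched by the overlap rate |A ∩ B| / min(|A|, |B|); a discovery module is
*validated* when its best validation partner reaches the rate threshold
(50% by convention).  The pairwise rate matrix supports heatmap-style
inspection of within- and between-cohort module overlap.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd


@dataclass(frozen=True)
class MatchedPair:
    """Best validation partner for one discovery module."""

    discovery_index: int
    validation_index: int
    discovery_module: frozenset
    validation_module: frozenset
    n_overlap: int
    overlap_rate: float


def overlap_rate(A, B) -> float:
    """|A ∩ B| / min(|A|, |B|); 1 exactly when one set contains the other."""
    A, B = set(A), set(B)
    if not A or not B:
        raise ValueError("overlap rate of an empty module is undefined")
    return len(A & B) / min(len(A), len(B))


def match_modules(discovery, validation, threshold: float = 0.5) -> list[MatchedPair]:
    """Best validation partner per discovery module, kept at rate >= threshold.

    Ties between validation partners break by the larger number of
    overlapping genes, then by the smaller validation index.  A validation
    module may partner several discovery modules.
    """
    discovery = [set(m) for m in discovery]
    validation = [set(m) for m in validation]
    if not discovery or not validation:
        raise ValueError("module lists must be non-empty")
    pairs = []
    for di, dmod in enumerate(discovery):
        best = None  # (rate, n_overlap, -index)
        for vi, vmod in enumerate(validation):
            rate = overlap_rate(dmod, vmod)
            n = len(dmod & vmod)
            key = (rate, n, -vi)
            if best is None or key > best[0]:
                best = (key, vi, rate, n)
        _, vi, rate, n = best
        if rate >= threshold:
            pairs.append(
                MatchedPair(
                    discovery_index=di,
                    validation_index=vi,
                    discovery_module=frozenset(discovery[di]),
                    validation_module=frozenset(validation[vi]),
                    n_overlap=n,
                    overlap_rate=rate,
                )
            )
    return pairs


def overlap_matrix(list_a, list_b, names_a=None, names_b=None) -> pd.DataFrame:
    """Rectangular matrix of pairwise overlap rates (rows: list_a)."""
    list_a = [set(m) for m in list_a]
    list_b = [set(m) for m in list_b]
    if not list_a or not list_b:
        raise ValueError("module lists must be non-empty")
    if names_a is None:
        names_a = [f"A{i + 1}" for i in range(len(list_a))]
    if names_b is None:
        names_b = [f"B{j + 1}" for j in range(len(list_b))]
    data = [[overlap_rate(a, b) for b in list_b] for a in list_a]
    return pd.DataFrame(data, index=names_a, columns=names_b)
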