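"""Gene-level mutation matrices from segment-level copy-number calls.

Array-based copy-number pipelines report per-sample *segments*, each carrying
one of five discrete somatic states (HOMD, HETD, NEUT, GAIN, AMP).  This
module collapses the five states to three (loss / neutral / gain), applies
the standard segment quality filter (minimum length and probe support), and
intersects the surviving segments with a gene annotation to produce a
samples x genes mutation matrix with entries in {-1, 0, +1}.

Coordinates are 1-based and inclusive on both ends internally; the BED
reader converts from BED's 0-based half-open convention.  Chromosome names
are compared after stripping an optional ``chr`` prefix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

#: Mapping from 5-level array calls to the 3-level gain/neutral/loss code.
STATE_CODES = {"HOMD": -1, "HETD": -1, "NEUT": 0, "GAIN": 1, "AMP": 1}


@dataclass(frozen=True)
class CNASegment:
    """One per-sample copy-number call over a genomic interval.

    ``start``/``end`` are 1-based and inclusive; ``state`` is one of
    HOMD, HETD, NEUT, GAIN, AMP.
    """

    sample_id: str
    chrom: str
    start: int
    end: int
    n_probes: int
    state: str

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(
                f"segment end < start for sample {self.sample_id!r}: "
                f"{self.chrom}:{self.start}-{self.end}"
            )
        if self.n_probes < 0:
            raise ValueError(f"negative probe count: {self.n_probes}")

    @property
    def length(self) -> int:
        """Segment length in base pairs (inclusive coordinates)."""
        return self.end - self.start + 1


@dataclass(frozen=True)
class GeneInterval:
    """A named gene locus, 1-based inclusive coordinates."""

    gene_id: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"gene end < start for {self.gene_id!r}")


def map_state(state: str) -> int:
    """Map a 5-level copy-number state token to -1 (loss), 0 or +1 (gain).

    HOMD and HETD are broadly "loss"; GAIN and AMP are broadly "gain";
    NEUT is neutral.
    """
    try:
        return STATE_CODES[state]
    except KeyError:
        raise ValueError(
            f"unknown CNA state token: {state!r} "
            f"(expected one of {sorted(STATE_CODES)})"
        ) from None


def _norm_chrom(chrom: str) -> str:
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


def filter_segments(
    segments: Iterable[CNASegment],
    min_length_bp: int = 5_000,
    min_probes: int = 10,
) -> list[CNASegment]:
    """Retain well-supported, non-neutral segments.

    A segment survives when its length is at least ``min_length_bp`` AND it
    is supported by at least ``min_probes`` probes AND its state is not
    NEUT (neutral calls carry no mutation).  Input order is preserved.
    """
    return [
        s
        for s in segments
        if s.length >= min_length_bp and s.n_probes >= min_probes and s.state != "NEUT"
    ]


def build_matrix(
    segments: Iterable[CNASegment],
    annotation: Sequence[GeneInterval],
    samples: Sequence[str],
) -> pd.DataFrame:
    """Build the samples x genes mutation matrix from filtered segments.

    Entry (j, i) is the 3-level code of the segment of sample j overlapping
    gene i by at least one base.  When several segments of one sample hit
    the same gene with conflicting signs, the state of the segment with the
    larger overlapping base count wins; an exact tie resolves to loss (-1)
    and a warning is logged.  Genes never overlapped by a segment are 0.

    Parameters
    ----------
    segments : iterable of CNASegment
        Quality-filtered calls (see :func:`filter_segments`).
    annotation : sequence of GeneInterval
        Gene universe; every annotated gene becomes a column.
    samples : sequence of str
        Row order of the matrix.  Every segment's sample must appear here.

    Returns
    -------
    pandas.DataFrame
        Integer matrix indexed by sample id, columns are gene ids,
        entries in {-1, 0, +1}.
    """
    samples = list(samples)
    if len(set(samples)) != len(samples):
        raise ValueError("duplicate sample ids")
    if not annotation:
        raise ValueError("empty gene annotation")
    gene_ids = [g.gene_id for g in annotation]
    if len(set(gene_ids)) != len(gene_ids):
        raise ValueError("duplicate gene ids in annotation")

    trees: dict[str, IntervalTree] = {}
    for g in annotation:
        # intervaltree is half-open; inclusive end -> end + 1
        trees.setdefault(_norm_chrom(g.chrom), IntervalTree()).addi(
            g.start, g.end + 1, g.gene_id
        )

    sample_pos = {s: j for j, s in enumerate(samples)}
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    values = np.zeros((len(samples), len(gene_ids)), dtype=np.int8)
    # per (sample, gene): overlap of the currently winning segment
    best_overlap: dict[tuple[int, int], int] = {}

    segments = list(segments)
    if segments:
        seg_chroms = {_norm_chrom(s.chrom) for s in segments}
        if not seg_chroms & set(trees):
            raise ValueError(
                "no segment chromosome matches the annotation: segments use "
                f"{sorted(seg_chroms)} vs annotation {sorted(trees)} "
                "(after stripping any 'chr' prefix)"
            )

    for seg in segments:
        try:
            j = sample_pos[seg.sample_id]
        except KeyError:
            raise ValueError(
                f"segment sample {seg.sample_id!r} not in the sample list"
            ) from None
        code = map_state(seg.state)
        tree = trees.get(_norm_chrom(seg.chrom))
        if tree is None:
            continue
        for hit in tree.overlap(seg.start, seg.end + 1):
            i = gene_pos[hit.data]
            overlap = min(seg.end + 1, hit.end) - max(seg.start, hit.begin)
            key = (j, i)
            prev = best_overlap.get(key)
            if prev is None or overlap > prev:
                best_overlap[key] = overlap
                values[j, i] = code
            elif overlap == prev and values[j, i] != code:
                # exact overlap tie with conflicting states: resolve to loss
                logger.warning(
                    "tie between conflicting states for sample %s, gene %s; "
                    "resolving to loss",
                    seg.sample_id,
                    hit.data,
                )
                values[j, i] = -1

    return pd.DataFrame(values, index=pd.Index(samples, name="sample"), columns=gene_ids)


# ---------------------------------------------------------------------------
# I/O


def read_segments(path) -> list[CNASegment]:
    """Read a SEG-like TSV: columns sample, chrom, start, end, n_probes, state."""
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "chrom": str})
    required = ["sample", "chrom", "start", "end", "n_probes", "state"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"segment file {path} lacks columns: {missing}")
    return [
        CNASegment(r.sample, r.chrom, int(r.start), int(r.end), int(r.n_probes), r.state)
        for r in df.itertuples(index=False)
    ]


def read_bed(path) -> list[GeneInterval]:
    """Read a 4-column BED (chrom, start, end, gene_id).

    BED is 0-based, half-open; returned intervals are 1-based inclusive.
    """
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "gene_id"],
        dtype={"chrom": str, "gene_id": str}, comment="#",
    )
    return [
        GeneInterval(r.gene_id, r.chrom, int(r.start) + 1, int(r.end))
        for r in df.itertuples(index=False)
    ]


def write_matrix(matrix: pd.DataFrame, path) -> None:
    """Write a mutation matrix as TSV (first column ``sample``)."""
    matrix.to_csv(path, sep="\t", index_label="sample")


def read_matrix(path) -> pd.DataFrame:
    """Read a mutation matrix written by :func:`write_matrix`."""
    return pd.read_csv(path, sep="\t", index_col="sample")
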