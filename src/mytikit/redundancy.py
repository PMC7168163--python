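"""Hobohm algorithm-2 redundancy reduction over a BLOSUM62 distance graph.

Before building a profile model, near-identical sequences are removed so
that heavily sampled subfamilies do not dominate the alignment. Pairwise
distance is ``1 - S(a,b) / min(S(a,a), S(b,b))`` with S the affine-gap
global BLOSUM62 score, clipped to [0, 1]: identical sequences sit at 0 and
unrelated ones near 1. Hobohm-2 then greedily deletes the vertex with the
most sub-threshold neighbours until no such pair remains.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .align import global_align
from .io_formats import Peptide

DEFAULT_THRESHOLD = 0.1


def blosum_distance(a, b) -> float:
    """Normalized BLOSUM62 global-alignment distance in [0, 1]."""
    s_ab = global_align(a, b).score
    s_aa = global_align(a, a).score
    s_bb = global_align(b, b).score
    denom = min(s_aa, s_bb)
    if denom <= 0:
        return 1.0
    return float(np.clip(1.0 - s_ab / denom, 0.0, 1.0))


@dataclass(frozen=True)
class DistanceGraph:
    ids: tuple[str, ...]
    d: np.ndarray  # symmetric, zero diagonal, entries in [0, 1]
    threshold: float = DEFAULT_THRESHOLD

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        if d.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(d, d.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(d) != 0):
            raise ValueError("self-distances must be zero")
        if d.min() < 0 or d.max() > 1:
            raise ValueError("distances must lie in [0, 1]")
        object.__setattr__(self, "d", d)

    @property
    def edges(self) -> list[tuple[str, str]]:
        """Pairs closer than the threshold."""
        out = []
        for i in range(len(self.ids)):
            for j in range(i + 1, len(self.ids)):
                if self.d[i, j] < self.threshold:
                    out.append((self.ids[i], self.ids[j]))
        return out


def build_distance_graph(peptides: Sequence[Peptide], threshold: float = DEFAULT_THRESHOLD) -> DistanceGraph:
    peptides = list(peptides)
    n = len(peptides)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = blosum_distance(peptides[i], peptides[j])
    return DistanceGraph(tuple(p.id for p in peptides), d, threshold)


@dataclass(frozen=True)
class RemovalRecord:
    id: str
    n_neighbors_at_removal: int


def hobohm2_reduce(graph: DistanceGraph) -> tuple[list[str], list[RemovalRecord]]:
    """Greedy Hobohm-2: repeatedly drop the most-connected vertex.

    Ties are broken toward the lexicographically greatest id so runs are
    reproducible. Returns (retained ids in input order, removal log). The
    retained set is guaranteed to contain no pair below the threshold.
    """
    ids = list(graph.ids)
    alive = set(range(len(ids)))
    adj = {
        i: {j for j in alive if j != i and graph.d[i, j] < graph.threshold}
        for i in alive
    }
    removals: list[RemovalRecord] = []
    while True:
        candidates = [i for i in alive if adj[i]]
        if not candidates:
            break
        victim = max(candidates, key=lambda i: (len(adj[i]), ids[i]))
        removals.append(RemovalRecord(ids[victim], len(adj[victim])))
        alive.discard(victim)
        for j in adj[victim]:
            adj[j].discard(victim)
        del adj[victim]
    retained = [ids[i] for i in sorted(alive)]
    for i in alive:
        for j in alive:
            if i < j and graph.d[i, j] < graph.threshold:
                raise AssertionError("retained pair below threshold — greedy invariant broken")
    return retained, removals


def reduce_peptides(peptides: Sequence[Peptide], threshold: float = DEFAULT_THRESHOLD):
    """Convenience wrapper: build the graph, run Hobohm-2, return retained peptides."""
    graph = build_distance_graph(peptides, threshold)
    retained_ids, removals = hobohm2_reduce(graph)
    keep = set(retained_ids)
    return [p for p in peptides if p.id in keep], removals


def reduction_frame(peptides: Sequence[Peptide], retained_ids, removals):
    import pandas as pd

    removed = {r.id: r.n_neighbors_at_removal for r in removals}
    rows = [
        {
            "id": p.id,
            "retained": p.id not in removed,
            "n_neighbors_at_removal": removed.get(p.id, 0),
        }
        for p in peptides
    ]
    return pd.DataFrame(rows)
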