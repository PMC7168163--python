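"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's dynamic-programming code paths:
alignment scores come from exhaustive enumeration of alignments, HMM
probabilities from exhaustive enumeration of state paths, and additive trees
from explicit random tree construction.
"""

from __future__ import annotations

import math
import random
from functools import lru_cache

import dendropy
import numpy as np

from mytikit.align import BLOSUM62, GAP_EXTEND, GAP_OPEN
from mytikit.profile_hmm import _AA_INDEX, AMINO_ACIDS


def brute_global_score(a: str, b: str) -> float:
    """Best affine-gap global score by exhaustive enumeration of alignments."""
    best = [-math.inf]

    def rec(i: int, j: int, score: float, prev: str) -> None:
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score)
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, score + float(BLOSUM62[a[i], b[j]]), "M")
        if i < len(a):
            cost = GAP_EXTEND if prev == "X" else GAP_OPEN + GAP_EXTEND
            rec(i + 1, j, score - cost, "X")
        if j < len(b):
            cost = GAP_EXTEND if prev == "Y" else GAP_OPEN + GAP_EXTEND
            rec(i, j + 1, score - cost, "Y")

    rec(0, 0, 0.0, "M")
    return best[0]


def brute_local_score(a: str, b: str) -> float:
    """Best Smith-Waterman score: max global score over all substring pairs."""

    @lru_cache(maxsize=None)
    def cached(sa: str, sb: str) -> float:
        return brute_global_score(sa, sb)

    best = 0.0
    for i0 in range(len(a)):
        for i1 in range(i0 + 1, len(a) + 1):
            for j0 in range(len(b)):
                for j1 in range(j0 + 1, len(b) + 1):
                    best = max(best, cached(a[i0:i1], b[j0:j1]))
    return best


def enumerate_hmm_paths(hmm, seq: str) -> tuple[float, float]:
    """(total, best) path probability of a sequence under a profile HMM.

    Exhaustive recursion over all begin-to-end state paths in the M/I/D
    architecture; feasible for small models and short sequences only.
    """
    iM, iI, iD = 0, 1, 2
    M = hmm.length
    total = 0.0
    best = 0.0

    def rec(node: int, state: int, i: int, p: float) -> None:
        nonlocal total, best
        if p == 0.0:
            return
        if node == M and i == len(seq):
            pe = p * hmm.transitions[M, state, iM]
            total += pe
            best = max(best, pe)
            return
        tr = hmm.transitions
        if node < M and i < len(seq):
            e = hmm.match_emissions[node, _AA_INDEX[seq[i]]]
            rec(node + 1, iM, i + 1, p * tr[node, state, iM] * e)
        if node < M:
            rec(node + 1, iD, i, p * tr[node, state, iD])
        if i < len(seq):
            e = hmm.insert_emissions[_AA_INDEX[seq[i]]]
            rec(node, iI, i + 1, p * tr[node, state, iI] * e)

    rec(0, 0, 0, 1.0)
    return total, best


def hmm_log_odds(hmm, seq: str, total_prob: float) -> float:
    null = float(np.prod([hmm.background[_AA_INDEX[aa]] for aa in seq]))
    return math.log2(total_prob / null)


def random_additive_tree(rng: random.Random, n_taxa: int):
    """A random binary tree with branch lengths in [0.1, 1] plus its distance matrix."""
    labels = [f"t{i}" for i in range(n_taxa)]
    tns = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=tns)
    for lab in labels[:3]:
        node = dendropy.Node(taxon=tns.get_taxon(lab))
        node.edge.length = rng.uniform(0.1, 1.0)
        tree.seed_node.add_child(node)
    for lab in labels[3:]:
        edges = [e for e in tree.preorder_edge_iter() if e.head_node is not tree.seed_node]
        edge = rng.choice(edges)
        head, parent = edge.head_node, edge.head_node.parent_node
        mid = dendropy.Node()
        total = edge.length
        parent.remove_child(head)
        parent.add_child(mid)
        mid.edge.length = total * rng.uniform(0.3, 0.7)
        mid.add_child(head)
        head.edge.length = max(total - mid.edge.length, 0.05)
        leaf = dendropy.Node(taxon=tns.get_taxon(lab))
        leaf.edge.length = rng.uniform(0.1, 1.0)
        mid.add_child(leaf)
    pdm = tree.phylogenetic_distance_matrix()
    matrix = np.array([
        [pdm.distance(tns.get_taxon(x), tns.get_taxon(y)) for y in labels]
        for x in labels
    ])
    return tree, labels, matrix


def random_peptide(rng: random.Random, length: int, alphabet: str = AMINO_ACIDS) -> str:
    return "".join(rng.choice(alphabet) for _ in range(length))
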