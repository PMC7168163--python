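"""Distance-based phylogeny: p/Poisson distances and neighbor joining.

A deterministic neighbor-joining tree over alignment distances stands in for
a full Bayesian analysis: it is exact on additive distance matrices and
sufficient for clade-level statements (e.g. whether two diverged peptide
families form disjoint clades). Output is Newick via dendropy.
"""

from __future__ import annotations

import math

import dendropy
import numpy as np

from .align import MSA


def msa_distance_matrix(msa: MSA, model: str = "p_distance") -> tuple[tuple[str, ...], np.ndarray]:
    """Pairwise distances over MSA rows.

    p-distance counts mismatches over columns where neither row is gapped;
    the Poisson model corrects it as -ln(1 - p). A pair with no comparable
    column is an error.
    """
    if model not in ("p_distance", "poisson"):
        raise ValueError(f"unknown model {model!r}")
    if len(msa) < 3:
        raise ValueError("need at least 3 rows for a distance matrix")
    n = len(msa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            comparable = mismatch = 0
            for a, b in zip(msa.rows[i], msa.rows[j]):
                if a == "-" or b == "-":
                    continue
                comparable += 1
                if a != b:
                    mismatch += 1
            if comparable == 0:
                raise ValueError(f"rows {msa.ids[i]!r} and {msa.ids[j]!r} share no columns")
            p = mismatch / comparable
            if model == "poisson":
                if p >= 1.0:
                    raise ValueError("saturated pair: Poisson distance undefined")
                p = -math.log(1.0 - p)
            d[i, j] = d[j, i] = p
    return msa.ids, d


def neighbor_joining(ids, matrix) -> dendropy.Tree:
    """Saitou-Nei neighbor joining with deterministic tie-breaks.

    Joins the pair minimizing the Q criterion, breaking ties by the smallest
    (id, id) pair. Negative branch lengths are clamped to zero. Exact on
    additive matrices. Returns an unrooted dendropy tree.
    """
    ids = list(ids)
    d = np.array(matrix, dtype=float)
    if len(ids) < 3:
        raise ValueError("need at least 3 taxa")
    if not np.all(np.isfinite(d)):
        raise ValueError("non-finite distances")

    taxa = dendropy.TaxonNamespace(ids)
    nodes = {}
    for label in ids:
        node = dendropy.Node(taxon=taxa.get_taxon(label))
        nodes[label] = node
    # active: label -> index into d
    active = {label: i for i, label in enumerate(ids)}
    labels = list(ids)
    next_internal = 0

    def clamp(x: float) -> float:
        return max(0.0, x)

    while len(active) > 3:
        names = sorted(active)
        idx = {name: active[name] for name in names}
        r = {name: sum(d[idx[name], idx[o]] for o in names if o != name) for name in names}
        m = len(names)
        best = None
        for a_i, a in enumerate(names):
            for b in names[a_i + 1 :]:
                q = (m - 2) * d[idx[a], idx[b]] - r[a] - r[b]
                key = (q, a, b)
                if best is None or key < best:
                    best = key
        _, a, b = best
        dab = d[idx[a], idx[b]]
        la = 0.5 * dab + (r[a] - r[b]) / (2.0 * (m - 2))
        lb = dab - la
        parent = dendropy.Node()
        parent.add_child(nodes[a])
        nodes[a].edge.length = clamp(la)
        parent.add_child(nodes[b])
        nodes[b].edge.length = clamp(lb)

        new_label = f"__internal_{next_internal}"
        next_internal += 1
        nodes[new_label] = parent
        # grow the matrix with the new node's distances
        new_row = np.zeros(d.shape[0] + 1)
        for o in names:
            if o in (a, b):
                continue
            new_row[idx[o]] = 0.5 * (d[idx[a], idx[o]] + d[idx[b], idx[o]] - dab)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :-1] = new_row[:-1]
        d[:-1, -1] = new_row[:-1]
        del active[a], active[b]
        active[new_label] = d.shape[0] - 1

    # final three-way join: closed-form branch lengths
    (a, b, c) = sorted(active)
    ia, ib, ic = active[a], active[b], active[c]
    la = 0.5 * (d[ia, ib] + d[ia, ic] - d[ib, ic])
    lb = 0.5 * (d[ia, ib] + d[ib, ic] - d[ia, ic])
    lc = 0.5 * (d[ia, ic] + d[ib, ic] - d[ia, ib])
    root = dendropy.Node()
    for label, length in ((a, la), (b, lb), (c, lc)):
        root.add_child(nodes[label])
        nodes[label].edge.length = clamp(length)

    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = root
    tree.is_rooted = False
    return tree


def to_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True).strip()


def leaf_labels(tree: dendropy.Tree) -> set[str]:
    return {leaf.taxon.label for leaf in tree.leaf_node_iter()}


def is_monophyletic(tree: dendropy.Tree, labels) -> bool:
    """True if ``labels`` form a clade on some rooting of the (unrooted) tree.

    Checked via the split/bipartition encoding: a label set is a clade iff
    {labels} vs {rest} is one of the tree's edges.
    """
    labels = frozenset(labels)
    all_labels = frozenset(leaf_labels(tree))
    if not labels or labels == all_labels:
        return True
    tree.encode_bipartitions()
    target = {labels, all_labels - labels}
    for edge in tree.preorder_edge_iter():
        if edge.bipartition is None:
            continue
        side = frozenset(
            t.label for t in edge.bipartition.leafset_taxa(tree.taxon_namespace)
        )
        if side in target:
            return True
    return False
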