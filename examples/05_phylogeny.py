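"""Neighbor-joining tree over two diverged synthetic peptide families.

Two families built on different cysteine-array templates are aligned
together; NJ over p-distances should place each family in its own clade,
the way real mytilin lineages separate by genus.
"""

from mytikit.align import progressive_msa
from mytikit.phylo import is_monophyletic, msa_distance_matrix, neighbor_joining, to_newick
from mytikit.synthetic_data import make_two_family_cohort

families = make_two_family_cohort(seed=17, n_per_family=4)
peptides = families["famA"] + families["famB"]
msa = progressive_msa(peptides)
ids, dist = msa_distance_matrix(msa, model="p_distance")
tree = neighbor_joining(ids, dist)

print(tree.as_ascii_plot(plot_metric="length"))
print(to_newick(tree))
for name, members in families.items():
    mono = is_monophyletic(tree, [p.id for p in members])
    print(f"{name} forms a clade: {mono}")
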