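"""Neighbor-joining tree from extracted markers.

Builds a two-clade cohort, extracts every member's 463 bp marker, computes
pairwise p-distances and a neighbor-joining tree, and cuts the tree into
two groups — which must coincide with the planted clades.
"""

from ardra import (
    FixtureSpec, cut_clusters, distance_matrix, extract_marker, make_cohort,
    nj_tree,
)
from ardra.phylo import _newick
from ardra.seqio import NucleotideSequence, SequenceSet

targets, _, truth = make_cohort(FixtureSpec(seed=3), n_target=10,
                                n_outgroup=4, divergence=3,
                                n_clades=2, clade_divergence=40)
markers = SequenceSet("markers", [
    NucleotideSequence(s.id, extract_marker(s).amplicon.residues)
    for s in targets
])

dm = distance_matrix(markers, model="p_distance")
print(f"mean pairwise p-distance: {dm.condensed_form().mean():.4f}")

tree = nj_tree(dm)
print("\nnewick:", _newick(tree) + ";")

groups = cut_clusters(tree, k=2)
print("\ngroups after cutting the longest internal edge:")
for i, g in enumerate(groups, 1):
    print(f"  group {i}: {sorted(g)}")
planted = {sid: info["clade"] for sid, info in truth["targets"].items()}
print("\nplanted clades:", planted)
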