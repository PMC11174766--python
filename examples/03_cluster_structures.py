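"""UPGMA clustering of a structure set into an ultrametric tree.

Scores all pairs of a 3-family synthetic set, fuses TM-score and RMSD
into a similarity matrix, converts it to distances (1 - S) and builds
the UPGMA tree.  Cutting the tree at k=3 should recover the planted
families exactly at this low noise level (ARI = 1).
"""

import foldclust as fc

spec = fc.SyntheticFamilySpec(n_families=3, members_per_family=4, length=60,
                              sigma=0.3, seed=11)
dataset = fc.generate_dataset(spec)

tree, pairs = fc.structure_tree(dataset.structures)
print("Newick (iTOL-compatible):")
print(fc.to_newick(tree))

partition = fc.cut_tree(tree, k=3)
ari = fc.adjusted_rand_index(partition, dataset.labels)
print(f"\nflat clusters at k=3: {partition}")
print(f"ARI vs planted family labels: {ari:.3f}")
# ARI 1.0 means the structure-derived clusters coincide exactly with the
# generating families; the tree heights are 1 - combined similarity, so a
# merge at height 0.05 joins structures of combined similarity 0.95.
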