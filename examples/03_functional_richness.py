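"""Trait dendrogram and functional richness of a small community.

Builds the Gower-distance / UPGMA dendrogram over body mass, diet guild and
activity stratum, exports Newick, and measures functional richness (total
spanning branch length) for two nested communities.
"""

from pathlib import Path

from retdiv import TraitTable, functional_richness, gower_matrix, to_newick, upgma

traits = TraitTable.from_csv(Path(__file__).parent / "data" / "traits_example.csv")
tree = upgma(gower_matrix(traits))

print("dendrogram:", to_newick(tree))
print(f"total branch length: {tree.total_branch_length:.3f}")
print(f"ultrametric: {tree.check_ultrametric()}")

ground_only = {"PERMAN", "SORTRO", "MICORE"}
with_arboreal = ground_only | {"GLAORE", "TAMHUD"}
fd_small = functional_richness(tree, ground_only)
fd_large = functional_richness(tree, with_arboreal)
print(f"\nFD ground-dwelling community:   {fd_small:.3f}")
print(f"FD with arboreal species added: {fd_large:.3f}")

# Adding the two arboreal squirrels increases FD by the branch length of the
# arboreal clade they span: trait-distinct species contribute more new
# branch length than functionally redundant ones.
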