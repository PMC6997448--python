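"""Cluster motifs by sequence similarity and compare CpG sets by Jaccard.

The motif distance aligns IUPAC words at every ungapped offset, scoring
aligned columns by the Jaccard similarity of their allowed-base sets.
One-position variants land close together; unrelated words sit near 1.
"""

from methmotif import (
    hierarchical_cluster,
    jaccard_distance,
    linkage_to_newick,
    motif_distance_matrix,
)
from methmotif.motif import Motif

words = ["TGACTCA", "TGACTMA", "TGACGTCA", "CCAATCA", "GGCGGR"]
motifs = [Motif.from_consensus(w) for w in words]
dm = motif_distance_matrix(motifs)
print("pairwise distances:")
print(dm.to_frame().round(3).to_string())

assignment, Z = hierarchical_cluster(dm, cut_height=0.3)
for w, c in zip(words, assignment):
    print(f"  {w:9s} -> cluster {c}")
print("dendrogram:", linkage_to_newick(Z, dm.labels))

a = set(range(100))
b = set(range(50, 150))
print(f"Jaccard distance of two half-overlapping 100-CpG sets: "
      f"{jaccard_distance(a, b):.4f}")
# TGACTCA and its M = {A,C} variant merge below the 0.3 cut; the distant
# GC-rich word stays alone.  The Jaccard distance (1 - 50/150 = 0.667) is
# the set-level analogue used to compare per-tumor iDMC collections.
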