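"""LCA taxonomy assignment and aggregation of gene profiles to genera/KOs.

Shows the lowest-common-ancestor rule on annotation hits, then aggregates a
gene-level profile to the genus and KO levels (a gene carrying several KOs
contributes its full abundance to each).
"""

import numpy as np
import pandas as pd

import metagut as mg
from metagut.synthetic_data import genus_lineage

# LCA of two species of the same genus keeps the genus, clears the species
hits = [
    genus_lineage("Bacteroides", "Bacteroides sp001"),
    genus_lineage("Bacteroides", "Bacteroides sp002"),
]
print("LCA within a genus:   ", mg.lca_assign(hits).names)

# hits from different phyla collapse to the kingdom
mixed = [genus_lineage("Clostridium"), genus_lineage("Bacteroides")]
print("LCA across phyla:     ", mg.lca_assign(mixed).names)

# aggregate a random 40-gene profile
rng = np.random.default_rng(3)
genes = [f"g{i:02d}" for i in range(40)]
data = pd.DataFrame(rng.dirichlet(np.ones(40), size=2), index=["m1", "m2"], columns=genes)
profile = mg.AbundanceProfile(data, level="gene")
annotations = mg.generate_annotations(genes, seed=3)

genus = mg.aggregate_profile(profile, annotations, "genus")
ko = mg.aggregate_profile(profile, annotations, "KO")
print(f"genus features:        {len(genus.features)}  (mass {genus.data.sum(axis=1).round(3).tolist()})")
print(f"KO features:           {len(ko.features)}  (mass {ko.data.sum(axis=1).round(3).tolist()})")

# Genus-level mass is below 1 because only annotated genes contribute; KO
# mass can exceed the annotated fraction because multi-KO genes are counted
# once per KO.
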