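# metagut

Gene-catalog metagenomics for mouse gut shotgun sequencing: non-redundant
catalog construction, paired-end abundance quantification, taxonomic and
functional profiling, diversity and group statistics, butyrate-capacity
scoring, gene-flow bookkeeping across strain × diet groups, and genus
co-occurrence networks.

## The problem

Shotgun studies of the mouse gut microbiome — typically two inbred strains
(an obesity-resistant line such as 129S6/Sv and an obesity-prone line such
as C57BL/6) fed low-fat and high-fat diets — need a common computational
backbone: predicted ORFs from per-sample assemblies must be collapsed into a
non-redundant reference gene catalog; reads must be counted against it;
gene-level abundances must be aggregated to genera and KEGG orthologues
(KOs); and group differences must be quantified with rank-based statistics.
`metagut` implements that backbone as a tested Python library, exercised on
a seeded synthetic-data generator that emulates the 2-strain × 3-diet design
(low-fat, high-fat, high-fat + COX inhibitor), so every stage can be
verified against known ground truth without any sequence download.

## The core computations

**Catalog.** Two ORFs are redundant when an *ungapped* alignment at some
relative offset (either strand) exceeds 95% identity and covers more than
90% of the shorter sequence. Redundant pairs are merged by single linkage;
the longest member represents each group; representatives shorter than
100 bp are dropped.

**Abundance.** A read pair adds one copy to one gene when (i) both ends map
within the gene at a moderate insert size, or (ii) one end overlaps a gene
terminus with its mate outside the gene — in both cases at alignment
identity > 90%. With x_i copies on gene i of length L_i, the relative
abundance is

    a_i = (x_i / L_i) / Σ_j (x_j / L_j)

so each sample's gene profile sums to 1. Taxonomy per gene is the lowest
common ancestor of its annotation hits; KO profiles sum gene abundances,
with multi-KO genes counted fully in every KO they carry.

**Statistics.** Shannon diversity (nats), gene count, Chao1 and ICE richness
estimators, rarefaction, Sørensen–Dice similarity; PCoA of Bray–Curtis
distances on square-root-transformed profiles; two-sided Wilcoxon rank-sum
tests with Hommel or Benjamini–Hochberg correction; signed percentage effect
sizes (Abund_i − Abund_j)/Abund_j × 100; one-way PERMANOVA with seeded label
permutations; and a background-corrected reporter z-score for KO modules.

**Function & flow.** Marker proteins (e.g. butyryl-CoA transferase, the
terminal butyrate-formation enzyme) are found by local protein alignment at
≥ 70% identity and ≥ 70% reference coverage; their summed abundance is a
capacity proxy. An editable 11-KO module covering the eight reactions from
acetyl-CoA to butyrate ships as data. Gene-flow tables classify per-gene
enrichment between strains at a baseline diet and track each class across a
diet switch (retained / equalized / flipped / undetectable) with
percentages recomputed bit-exactly from counts against labeled
denominators. Genus co-occurrence networks keep Pearson edges at p < 0.05.

## Worked example

```python
import numpy as np, pandas as pd, metagut as mg

rng = np.random.default_rng(11)
genes = [f"gene{i:02d}" for i in range(50)]
truth = pd.Series(rng.dirichlet(np.ones(50)), index=genes)
lengths = {g: int(rng.integers(300, 2500)) for g in genes}

alignments, pair_truth = mg.simulate_alignments(
    truth, lengths, n_pairs=20_000, f_disqualified=0.10, seed=11)
counts = mg.count_pairs(alignments, lengths,
                        insert_range=mg.default_insert_range(300, 50),
                        sample_id="mouse1")
profile = mg.relative_abundance(counts)
est = profile.data.loc["mouse1"]
print(int(pair_truth.qualifies.sum()), int(counts.counts['mouse1'].sum()),
      round(float(np.corrcoef(est[genes], truth)[0, 1]), 4))
```

prints

```
18012 18012 0.9986
```

— the counter admits exactly the 18,012 pairs that satisfy the counting
criteria (the planted 10% of violating pairs are excluded), and the
length-normalized estimates correlate with the true abundances at r = 0.999.
The scripts in `examples/` walk through each capability the same way:
catalog building, quantification, taxonomy/KO aggregation, diversity and
ordination, group comparison, butyrate scoring, and gene flow + networks.

A thin CLI mirrors the library (`metagut synth | catalog | count |
merge-counts | abundance | aggregate | diversity | ordinate | compare |
permanova | marker-scan | module-abund | gene-flow | census | network`).

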