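# Methods

This note documents the models, conventions and numerical choices behind
`metagut`, in the spirit of the methods documentation of mature analysis
packages: what each procedure assumes, which knobs matter, and what the
synthetic-data tests do and do not demonstrate about real data.

## Catalog construction

Redundancy between two ORFs is decided by an exhaustive ungapped scan: over
every relative offset of the two sequences, on both strands, a pair
qualifies if matches / aligned-columns > 0.95 while aligned-columns /
shorter-length > 0.90 (both strict, matching "greater than" phrasing).
`N` bases never match, not even each other. Qualifying pairs are merged by
**single linkage** — the natural reading of "pairs grouped together" — which
makes the partition independent of input order. The representative is the
longest member, ties broken by lexicographically smallest gene id for
determinism. Representatives shorter than 100 bp are removed *after*
grouping together with their groups' map entries; filtering before grouping
is the plausible alternative reading, and would differ only when a short ORF
bridges two groups.

A k-mer prefilter (k = 12, shared canonical k-mer) prunes candidate pairs.
It is purely an accelerator: sequences shorter than k are paired with
everything, and the test suite asserts equality with the unfiltered run and
with an exhaustive all-pairs oracle. The offset scan is vectorized
(sliding-window containment plus explicit end-overhangs); the oracle in the
tests re-implements it as a per-offset slice comparison so the two routes
share no code.

## Read-pair counting and abundance

A pair contributes one copy to at most one gene:

* criterion (i): both ends map within the gene and the insert size falls in
  a closed "moderate" interval. The interval is deliberately explicit and
  configurable; the synthetic generator's convention is mean ± 3 SD
  (default 300 ± 150 bp for ~90 bp paired-end reads).
* criterion (ii): the mapped end overlaps the first or last base of the
  gene while its mate maps outside the gene region. "Overlaps the
  terminus" is the minimal reading of mapping "onto the end".

Identity must exceed 0.90 strictly. Multi-mapped pairs keep only the
best-identity placement; an identity tie between distinct genes discards
the pair — this preserves "counted as one copy" and determinism at the cost
of a small conservative bias in repetitive regions. From SAM input the
pair's identity is the minimum of its ends' 1 − NM/aligned-length; a mate
that is unmapped or on another reference counts as "outside the gene".

Relative abundance follows the length-normalized form a_i = (x_i/L_i) /
Σ_j (x_j/L_j), normalized over counted genes only (unmapped read mass is
not modeled). Samples with zero counted pairs yield an all-zero row flagged
as empty rather than an error, so downstream code can decide.

## Taxonomy and KO aggregation

Lineages use the fixed seven-rank hierarchy kingdom → species. The LCA of a
gene's hits is the deepest rank at which all hits agree; disagreement at
kingdom yields a fully unassigned lineage (an LCA above kingdom carries no
information). Aggregation sums gene abundances per taxon; at KO level a
gene annotated with k KOs contributes its full abundance to each of them,
so KO row sums may exceed the annotated gene mass — this is intentional and
mirrors standard KO-profile practice. Database searches are out of scope;
annotations arrive as TSV tables.

## Statistics

* **Shannon** is computed in nats on the renormalized row; an all-zero row
  raises an empty-sample error.
* **Gene count** is unrarefied by default (no common-depth subsampling is
  implied by the quantification model); seeded downsampling via
  multivariate hypergeometric draws is available.
* **Chao1** uses S_obs + F1²/(2 F2), switching to the bias-corrected
  F1(F1−1)/(2(F2+1)) form when F2 = 0. **ICE** follows the standard
  Lee–Chao incidence form with the ≤ 10-sample infrequent group and a
  CV correction clipped at zero; when every infrequent feature is a unique
  the coverage estimate degenerates and a Chao2-style fallback is used.
* **PCoA** is classical metric scaling of Bray–Curtis distances on
  square-root-transformed profiles (the transform equalizes common and
  rare features). Euclidean-after-sqrt is available as an option. The
  distance metric is a genuine free choice here; Bray–Curtis is the field
  default for abundance data and is made explicit in the result object.
  Negative eigenvalues are reported but their axes dropped.
* **Wilcoxon comparisons** are two-sided; SciPy's exact null is used for
  small tie-free groups, the mid-rank normal approximation otherwise.
  Correction is a required choice between Hommel and Benjamini–Hochberg —
  both appear in practice and they answer different error-rate questions —
  with Hommel validated against an explicit closed-testing enumeration.
  The significance level is 0.05 throughout. Effect size is
  (Abund_i − Abund_j)/Abund_j × 100 (undefined when the reference mean is
  zero).
* **PERMANOVA** partitions the squared distance matrix into among/within
  components; p = (1 + #{F* ≥ F}) / (1 + n_perm) over seeded label
  permutations (default 999). The permutation loop is vectorized with a
  per-group quadratic form; the implementation is cross-checked against an
  independent reference implementation in the tests.
* **Reporter z-scores** are a reconstruction of the reporter-feature idea:
  per-KO z = Φ⁻¹(1 − p/2) signed by direction of change, module aggregate
  Z = Σz/√k, standardized against seeded same-size random KO sets
  (default 1000). The exact historical variant differs in details that are
  not specified by its usual citation; this implementation is labeled as
  such and validated against exhaustive subset enumeration on small
  universes.

## Marker genes, modules, gene flow

Marker scanning uses local protein alignment with BLOSUM62, gap open −11 /
extend −1 (the conventions of protein BLAST); identity is
identities/aligned columns, coverage is the aligned reference span over the
reference length, thresholds ≥ 0.70 on both. The shipped butyrate module is
**data, not code** (`data/butyrate_module.json`): 11 KOs over the eight
reactions from acetyl-CoA to butyrate, covering both terminal routes
(butyryl-CoA:acetate CoA-transferase; phosphate butyryltransferase +
butyrate kinase). KO identifiers should be adjusted to the KEGG release in
use. The shipped BCT reference protein is a synthetic stand-in (labeled so
in the file) for demonstrations and tests; real scans should supply a
curated reference FASTA.

Gene-flow classification tests each gene between the two strains with the
*unadjusted* two-sided rank-sum p at α = 0.05 — per-gene bookkeeping of
this kind is conventionally reported on raw significance — with direction
from the group means and no fold-change floor. "Became undetectable" means
zero abundance in every follow-up sample of both groups, checked before the
follow-up test. Percentages are recomputed from counts with half-up
rounding to two decimals; because published tables of this kind use both
the parent-class denominator and the baseline shared-class denominator, the
table exposes both, always labeled.

## Co-occurrence networks

All genus pairs are tested with Pearson correlation on relative abundances;
the edge p-value is the two-sided t-transform of r and edges are kept at
p < 0.05 with no correction by default (a BH flag exists). Correlations on
relative abundances are compositional: closure induces spurious negative
correlation, so edges — especially negative ones — describe co-variation of
the analyzed proportions, not of absolute populations. No CLR transform is
applied by default to keep the analysis on the same scale as the profiles.
Exactly constant genera have undefined correlations; they stay in the node
set but carry no edges. Networks are built per strain; merging is left to
the caller.

## Synthetic data generator

The generator emulates the study design the pipeline targets, and its
defaults are the study conditions, not tuning knobs:

* **Design**: 2 strains × 3 diets with 10/10/10 (Sv129) and 7/8/9 (BL6)
  samples for LF/HF/HFI — 54 samples. The third diet (high-fat + COX
  inhibitor) is microbiota-neutral: it receives the same planted shift as
  the high-fat diet, emulating an inhibitor that alters host physiology but
  not the microbiome.
* **Catalog**: parent genes of 150–3000 bp; copies mutated by substitution
  only (no indels), so the expected copy-vs-parent identity is 1 − rate.
  The default 2% rate keeps pairs well above the 95% threshold.
* **Community**: feature baselines are log-normal (σ = 1.5, the heavy skew
  of gene-level profiles); per-sample multiplicative log-normal noise
  (σ = 0.6) makes samples exchangeable under the null. Planted shifts are
  multiplicative: 4-fold on 8% of features for dietary fat, 2-fold on a
  disjoint 4% for strain — the diet effect is required to be at least the
  strain effect, mirroring fat content dominating host genotype.
* **Alignments**: source genes drawn ∝ abundance × length; inserts
  Normal(300, 50) truncated to ±3 SD; qualifying identities uniform in
  [1 − 2·error_rate, 1] (default error 2%); a configurable fraction
  violates the identity or insert rule and is recorded per pair, so
  counting can be asserted exactly.
* All randomness flows from one seed through named substreams (catalog /
  community / alignments / annotations, plus a per-sample stream index),
  making fixtures byte-reproducible.

What passing tests show — and what they do not: the generator produces no
indels, no chimeric assemblies, no base-quality structure, no strain-level
mosaicism and no compositional coupling beyond closure. Recovery results
(abundance r ≥ 0.98, exact partition recovery, ≥ 90% planted-enrichment
detection) therefore demonstrate correctness of the bookkeeping and the
statistics under the stated model, not robustness to real assembly or
mapping artifacts.

## Problem sizes in the standard checks

The packaged verification runs use 200 ORFs for the clustering-vs-oracle
comparison, 10⁵ read pairs over 500 genes for abundance recovery, 1,000
replicates of n = 20 for PERMANOVA type-I calibration, 50 replicates of the
full 54-sample design for the diet-over-strain ordering, and 30
threshold-straddling variants for the marker-scan oracle — sizes chosen to
make the checks sharp while keeping a full run in the order of a minute.
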