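"""Seeded synthetic fixtures with the statistical structure the pipeline assumes.

The generator emulates the study design the analysis is built for: two mouse
strains (an obesity-resistant and an obesity-prone one) each fed three diets
(low-fat, high-fat, and high-fat + COX inhibitor, the last being
microbiota-neutral), with a redundant ORF pool derived from known parent
genes, log-normal community abundances carrying planted diet- and
strain-driven shifts (diet effect >= strain effect), and paired-end
alignments with known insert-size and identity distributions.  Every stage
records its ground truth so recovery can be asserted exactly.

All randomness flows from one explicit seed through named substreams, so the
same seed reproduces every artifact byte-for-byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog import GeneRecord, write_fasta
from .errors import InvalidInputError
from .profiles import RANKS, AnnotationTable, Lineage
from .quantify import PairedAlignment, write_alignment_tsv

_BASES = np.array(list("ACGT"))

# substream tags so each stage draws from an independent, named stream
_STREAMS = {"catalog": 1, "community": 2, "alignments": 3, "annotations": 4}


def _rng(seed: int, stage: str, extra: int = 0) -> np.random.Generator:
    return np.random.default_rng([seed, _STREAMS[stage], extra])


# ------------------------------------------------------------------- design
STRAINS = ("Sv129", "BL6")
DIETS = ("LF", "HF", "HFI")
_GROUP_SIZES = {("Sv129", "LF"): 10, ("Sv129", "HF"): 10, ("Sv129", "HFI"): 10,
                ("BL6", "LF"): 7, ("BL6", "HF"): 8, ("BL6", "HFI"): 9}


def default_design() -> pd.DataFrame:
    """The emulated study design: 54 samples over 2 strains x 3 diets."""
    rows = []
    for (strain, diet), n in _GROUP_SIZES.items():
        for i in range(n):
            rows.append([f"{strain}_{diet}_{i + 1:02d}", strain, diet])
    return pd.DataFrame(rows, columns=["sample_id", "strain", "diet"]).set_index("sample_id")


@dataclass
class PlantedEffects:
    """Multiplicative planted shifts; the diet shift must dominate the strain shift."""

    diet_fold: float = 4.0
    strain_fold: float = 2.0
    n_diet_features: int | None = None  # None -> 8% of the feature universe
    n_strain_features: int | None = None  # None -> 4% of the feature universe

    def __post_init__(self) -> None:
        if self.diet_fold < self.strain_fold:
            raise InvalidInputError("planted diet effect must be >= strain effect")
        if min(self.diet_fold, self.strain_fold) <= 0:
            raise InvalidInputError("fold changes must be positive")

    def resolve(self, n_features: int) -> tuple[int, int]:
        n_diet = self.n_diet_features
        n_strain = self.n_strain_features
        if n_diet is None:
            n_diet = max(1, round(0.08 * n_features))
        if n_strain is None:
            n_strain = max(1, round(0.04 * n_features))
        if n_diet + n_strain > n_features:
            raise InvalidInputError("planted feature sets exceed the feature universe")
        return n_diet, n_strain


@dataclass
class SyntheticTruth:
    """Ground truth accumulated across generator stages."""

    seed: int
    parent_of: dict[str, str] = field(default_factory=dict)  # ORF -> parent gene
    orfs: list[GeneRecord] = field(default_factory=list)
    design: pd.DataFrame | None = None
    abundances: pd.DataFrame | None = None  # samples x genes, rows sum to 1
    diet_features: list[str] = field(default_factory=list)
    strain_features: list[str] = field(default_factory=list)
    effects: PlantedEffects | None = None
    pair_truth: dict[str, pd.DataFrame] = field(default_factory=dict)  # sample -> per-pair truth
    annotations: AnnotationTable | None = None


# ------------------------------------------------------------------ catalog
def generate_catalog(
    n_parents: int = 20,
    copies_per_parent: int = 4,
    substitution_rate: float = 0.02,
    seed: int = 0,
    length_range: tuple[int, int] = (150, 3000),
) -> tuple[list[GeneRecord], SyntheticTruth]:
    """Redundant ORF pool: parents plus substitution-mutated copies.

    Each parent spawns ``copies_per_parent`` copies mutated at the per-base
    substitution rate (always to a different base), so the expected pairwise
    identity between copies of one parent is about (1 - rate)^2 + rate^2/3.
    The true partition (ORF -> parent) is recorded.
    """
    if not 0.0 <= substitution_rate <= 0.3:
        raise InvalidInputError("substitution_rate must lie in [0, 0.3]")
    if length_range[0] < 1 or length_range[0] > length_range[1]:
        raise InvalidInputError("invalid length_range")
    rng = _rng(seed, "catalog")
    truth = SyntheticTruth(seed=seed)
    orfs: list[GeneRecord] = []
    for p in range(n_parents):
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        parent_seq = "".join(rng.choice(_BASES, size=length))
        parent_id = f"parent{p + 1:03d}"
        for c in range(copies_per_parent):
            orf_id = f"{parent_id}_orf{c + 1:02d}"
            if c == 0:
                seq = parent_seq
            else:
                arr = np.array(list(parent_seq))
                hits = rng.random(length) < substitution_rate
                if hits.any():
                    # substitute with one of the three other bases
                    idx = np.flatnonzero(hits)
                    current = np.searchsorted(_BASES, arr[idx])
                    shift = rng.integers(1, 4, size=idx.size)
                    arr[idx] = _BASES[(current + shift) % 4]
                seq = "".join(arr)
            orfs.append(GeneRecord(orf_id, seq))
            truth.parent_of[orf_id] = parent_id
    truth.orfs = orfs
    return orfs, truth


# ---------------------------------------------------------------- community
def generate_community(
    features: Sequence[str],
    design: pd.DataFrame | None = None,
    effects: PlantedEffects | None = None,
    seed: int = 0,
    lognormal_sigma: float = 1.5,
    noise_sigma: float = 0.6,
    truth: SyntheticTruth | None = None,
) -> SyntheticTruth:
    """Log-normal community abundances with planted diet and strain shifts.

    Feature base abundances are log-normal (sigma ~ 1.5, the heavy skew
    typical of gene-level metagenome profiles); each sample adds independent
    multiplicative log-normal noise.  Disjoint feature sets receive the diet
    shift (in every high-fat sample, with or without the COX inhibitor — the
    inhibitor is microbiota-neutral) and the strain shift (in every sample of
    the first strain); rows are renormalized to sum to 1.  With unit fold
    changes the groups are exchangeable.
    """
    if design is None:
        design = default_design()
    if len(design) == 0:
        raise InvalidInputError("design must contain at least one sample")
    effects = effects or PlantedEffects()
    features = list(features)
    n_features = len(features)
    n_diet, n_strain = effects.resolve(n_features)
    rng = _rng(seed, "community")

    base = rng.lognormal(mean=0.0, sigma=lognormal_sigma, size=n_features)
    planted = rng.permutation(n_features)
    diet_idx = planted[:n_diet]
    strain_idx = planted[n_diet : n_diet + n_strain]

    strains = list(dict.fromkeys(design["strain"]))
    values = np.empty((len(design), n_features))
    for row, (sample, meta) in enumerate(design.iterrows()):
        expected = base.copy()
        if meta["diet"] in ("HF", "HFI"):
            expected[diet_idx] *= effects.diet_fold
        if meta["strain"] == strains[0]:
            expected[strain_idx] *= effects.strain_fold
        noise = rng.lognormal(mean=0.0, sigma=noise_sigma, size=n_features)
        values[row] = expected * noise
    values /= values.sum(axis=1, keepdims=True)

    out = truth or SyntheticTruth(seed=seed)
    out.design = design
    out.abundances = pd.DataFrame(values, index=design.index, columns=features)
    out.diet_features = [features[i] for i in diet_idx]
    out.strain_features = [features[i] for i in strain_idx]
    out.effects = effects
    return out


# --------------------------------------------------------------- alignments
def default_insert_range(insert_mean: int = 300, insert_sd: int = 50) -> tuple[int, int]:
    """The generator's 'moderate insert size' interval: mean +/- 3 SD."""
    return insert_mean - 3 * insert_sd, insert_mean + 3 * insert_sd


def simulate_alignments(
    abundances: pd.Series | Mapping[str, float],
    lengths: Mapping[str, int],
    n_pairs: int = 10_000,
    insert_mean: int = 300,
    insert_sd: int = 50,
    error_rate: float = 0.02,
    f_disqualified: float = 0.1,
    read_len: int = 90,
    p_edge: float = 0.05,
    seed: int = 0,
    stream: int = 0,
    sample_tag: str = "S",
) -> tuple[list[PairedAlignment], pd.DataFrame]:
    """Paired alignments for one sample, drawn from the true gene abundances.

    Source genes are drawn with probability proportional to abundance x
    length (read yield scales with both).  Qualifying pairs follow criterion
    (i) geometry (both ends inside the gene, insert ~ Normal(mean, sd)
    truncated to mean +/- 3 SD) or, with probability ``p_edge`` or when the
    gene is too short, criterion (ii) (one end on a gene terminus, mate
    outside).  A fraction ``f_disqualified`` violates either the identity
    threshold or the insert bounds; the per-pair truth (source gene,
    qualifies) is returned alongside.
    """
    if n_pairs < 1:
        raise InvalidInputError("n_pairs must be >= 1")
    if not 0.0 <= f_disqualified <= 1.0 or not 0.0 <= p_edge <= 1.0:
        raise InvalidInputError("fractions must lie in [0, 1]")
    if not 0.0 < error_rate <= 0.045:
        raise InvalidInputError("error_rate must lie in (0, 0.045] to keep qualifying identity > 0.91")
    rng = _rng(seed, "alignments", stream)

    abund = pd.Series(abundances, dtype=float)
    genes = abund.index.to_list()
    lens = np.array([lengths[g] for g in genes], dtype=int)
    weights = abund.to_numpy() * lens
    if weights.sum() <= 0:
        raise InvalidInputError("abundances must carry positive mass")
    weights = weights / weights.sum()

    lo, hi = default_insert_range(insert_mean, insert_sd)
    gene_idx = rng.choice(len(genes), size=n_pairs, p=weights)
    disqualified = rng.random(n_pairs) < f_disqualified
    edge_roll = rng.random(n_pairs) < p_edge

    alignments: list[PairedAlignment] = []
    records = []
    for i in range(n_pairs):
        g = gene_idx[i]
        gene, glen = genes[g], int(lens[g])
        pair_id = f"{sample_tag}_pair{i + 1:06d}"
        qualifies = not disqualified[i]
        identity = float(1.0 - rng.uniform(0.0, 2.0 * error_rate))
        insert = int(np.clip(round(rng.normal(insert_mean, insert_sd)), lo, hi))
        use_edge = edge_roll[i] or glen < max(lo, 2 * read_len)
        bad_identity = False
        if not qualifies:
            # violate identity, or the insert bound when geometry allows it
            bad_identity = use_edge or glen < hi + 1 or rng.random() < 0.5
            if bad_identity:
                identity = float(rng.uniform(0.60, 0.89))
            else:
                insert = hi + int(rng.integers(1, 3 * insert_sd))
                insert = min(insert, glen)
                if insert <= hi:  # gene cannot host an out-of-range insert
                    bad_identity = True
                    identity = float(rng.uniform(0.60, 0.89))
                    insert = int(np.clip(round(rng.normal(insert_mean, insert_sd)), lo, hi))
        if use_edge:
            at_start = rng.random() < 0.5
            span = (0, min(read_len, glen)) if at_start else (max(0, glen - read_len), glen)
            alignments.append(
                PairedAlignment(pair_id, gene, span, None, identity, None, mate_outside_gene=True)
            )
        else:
            insert = min(insert, glen)
            start = int(rng.integers(0, glen - insert + 1))
            span1 = (start, min(start + read_len, glen))
            span2 = (max(start, start + insert - read_len), start + insert)
            alignments.append(PairedAlignment(pair_id, gene, span1, span2, identity, insert))
        records.append([pair_id, gene, qualifies])
    truth = pd.DataFrame(records, columns=["pair_id", "gene_id", "qualifies"])
    return alignments, truth


# -------------------------------------------------------------- annotations
_TAXONOMY: dict[str, tuple[str, str, str, str, str]] = {
    # genus -> (kingdom, phylum, class, order, family)
    "Bacteroides": ("Bacteria", "Bacteroidetes", "Bacteroidia", "Bacteroidales", "Bacteroidaceae"),
    "Prevotella": ("Bacteria", "Bacteroidetes", "Bacteroidia", "Bacteroidales", "Prevotellaceae"),
    "Parabacteroides": ("Bacteria", "Bacteroidetes", "Bacteroidia", "Bacteroidales", "Tannerellaceae"),
    "Tannerella": ("Bacteria", "Bacteroidetes", "Bacteroidia", "Bacteroidales", "Tannerellaceae"),
    "Clostridium": ("Bacteria", "Firmicutes", "Clostridia", "Clostridiales", "Clostridiaceae"),
    "Roseburia": ("Bacteria", "Firmicutes", "Clostridia", "Clostridiales", "Lachnospiraceae"),
    "Blautia": ("Bacteria", "Firmicutes", "Clostridia", "Clostridiales", "Lachnospiraceae"),
    "Dorea": ("Bacteria", "Firmicutes", "Clostridia", "Clostridiales", "Lachnospiraceae"),
    "Ruminococcus": ("Bacteria", "Firmicutes", "Clostridia", "Clostridiales", "Ruminococcaceae"),
    "Faecalibacterium": ("Bacteria", "Firmicutes", "Clostridia", "Clostridiales", "Ruminococcaceae"),
    "Oscillibacter": ("Bacteria", "Firmicutes", "Clostridia", "Clostridiales", "Oscillospiraceae"),
    "Lactobacillus": ("Bacteria", "Firmicutes", "Bacilli", "Lactobacillales", "Lactobacillaceae"),
    "Akkermansia": ("Bacteria", "Verrucomicrobia", "Verrucomicrobiae", "Verrucomicrobiales", "Akkermansiaceae"),
    "Escherichia": ("Bacteria", "Proteobacteria", "Gammaproteobacteria", "Enterobacterales", "Enterobacteriaceae"),
    "Desulfovibrio": ("Bacteria", "Proteobacteria", "Deltaproteobacteria", "Desulfovibrionales", "Desulfovibrionaceae"),
    "Bifidobacterium": ("Bacteria", "Actinobacteria", "Actinomycetia", "Bifidobacteriales", "Bifidobacteriaceae"),
}


def genus_lineage(genus: str, species: str | None = None) -> Lineage:
    if genus not in _TAXONOMY:
        raise InvalidInputError(f"unknown synthetic genus {genus!r}")
    return Lineage((*_TAXONOMY[genus], genus, species))


def generate_annotations(
    gene_ids: Sequence[str],
    seed: int = 0,
    frac_lineage: float = 0.75,
    frac_ko: float = 0.46,
    n_ko_pool: int = 60,
    frac_species: float = 0.5,
    include_module_kos: bool = True,
) -> AnnotationTable:
    """Random but realistic gene annotations of known composition.

    About ``frac_lineage`` of genes get a lineage (genus depth, half of them
    species depth) with a skewed genus distribution; about ``frac_ko`` get
    1-3 KOs from a pool that includes the butyrate-module KOs so module
    scoring has mass to work with.
    """
    rng = _rng(seed, "annotations")
    genera = list(_TAXONOMY)
    genus_weights = rng.dirichlet(np.full(len(genera), 0.6))
    ko_pool = [f"K{10000 + i:05d}" for i in range(n_ko_pool)]
    if include_module_kos:
        from .funcmod import butyrate_module

        ko_pool = sorted(set(ko_pool) | butyrate_module().kos)

    lineages: dict[str, Lineage] = {}
    kos: dict[str, frozenset[str]] = {}
    for gene in gene_ids:
        if rng.random() < frac_lineage:
            genus = genera[rng.choice(len(genera), p=genus_weights)]
            species = f"{genus} sp{rng.integers(1, 4):03d}" if rng.random() < frac_species else None
            lineages[gene] = genus_lineage(genus, species)
        if rng.random() < frac_ko:
            n_ko = int(rng.integers(1, 4))
            picked = rng.choice(len(ko_pool), size=n_ko, replace=False)
            kos[gene] = frozenset(ko_pool[i] for i in picked)
    return AnnotationTable(lineages, kos)


# ------------------------------------------------------------ full fixtures
def write_fixture(
    out_dir: str | Path,
    seed: int = 0,
    n_parents: int = 30,
    copies_per_parent: int = 3,
    substitution_rate: float = 0.02,
    n_pairs_per_sample: int = 2000,
    design: pd.DataFrame | None = None,
    effects: PlantedEffects | None = None,
) -> SyntheticTruth:
    """Emit a complete text fixture directory: FASTA, alignment TSVs,
    annotation TSVs, design TSV and truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    orfs, truth = generate_catalog(
        n_parents, copies_per_parent, substitution_rate, seed, length_range=(300, 1500)
    )
    write_fasta(orfs, out / "orfs.fasta")

    # canonical gene id = the representative each parent group collapses to
    # (copies tie in length, so the lexicographically smallest member wins)
    genes = sorted(f"{pid}_orf01" for pid in set(truth.parent_of.values()))
    design = design if design is not None else default_design()
    truth = generate_community(genes, design, effects, seed=seed, truth=truth)
    design.to_csv(out / "design.tsv", sep="\t")

    lengths = {o.gene_id: o.length_bp for o in orfs if o.gene_id.endswith("_orf01")}
    aln_dir = out / "alignments"
    aln_dir.mkdir(exist_ok=True)
    for i, sample in enumerate(design.index):
        alignments, pair_truth = simulate_alignments(
            truth.abundances.loc[sample],
            lengths,
            n_pairs=n_pairs_per_sample,
            seed=seed,
            stream=i + 1,  # per-sample substream
            sample_tag=sample,
        )
        truth.pair_truth[sample] = pair_truth
        write_alignment_tsv(alignments, aln_dir / f"{sample}.tsv")

    truth.annotations = generate_annotations(genes, seed=seed)
    truth.annotations.write_tsv(out / "lineage.tsv", out / "kos.tsv")

    summary = {
        "seed": seed,
        "n_orfs": len(orfs),
        "genes": genes,
        "parent_of": truth.parent_of,
        "diet_features": truth.diet_features,
        "strain_features": truth.strain_features,
        "effects": None
        if truth.effects is None
        else {
            "diet_fold": truth.effects.diet_fold,
            "strain_fold": truth.effects.strain_fold,
            "n_diet_features": truth.effects.n_diet_features,
            "n_strain_features": truth.effects.n_strain_features,
        },
    }
    (out / "truth.json").write_text(json.dumps(summary, indent=2))
    truth.abundances.to_csv(out / "true_abundances.tsv", sep="\t")
    return truth
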