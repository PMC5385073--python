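"""Marker genes, functional modules, gene-flow bookkeeping and census.

Covers four analyses downstream of the abundance profiles:

* protein-level marker scanning: catalog genes matching a reference marker
  protein (e.g. butyryl-CoA transferase, the terminal enzyme of microbial
  butyrate formation) by local alignment at >= 70% identity and >= 70%
  reference coverage, whose summed abundance serves as a capacity proxy;
* KO-module abundance: summed relative abundance of the KOs of a defined
  module (the shipped butyrate-formation module covers the eight reactions
  from acetyl-CoA to butyrate with 11 KOs) with a per-KO breakdown;
* gene-flow classification: per-gene enrichment classes between two groups at
  a baseline condition, re-examined at a follow-up condition (retained /
  equalized / flipped / undetectable), with percentage bookkeeping against
  explicit, labeled denominators;
* directional census: for a feature universe tested in two strains, how many
  features changed in the same direction, in exactly one strain, or not at
  all.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

from .errors import InvalidInputError, MissingFeatureError
from .quantify import AbundanceProfile
from .stats import ComparisonResult, _rank_sum_test

logger = logging.getLogger(__name__)


# ------------------------------------------------------------- marker genes
@dataclass
class MarkerGeneSet:
    """Reference marker protein(s) plus the catalog genes matching them."""

    name: str
    reference_seqs: list[str]
    identity_threshold: float = 0.70
    coverage_threshold: float = 0.70
    matched_gene_ids: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        for thr in (self.identity_threshold, self.coverage_threshold):
            if not 0.0 < thr <= 1.0:
                raise InvalidInputError("thresholds must lie in (0, 1]")
        if any(not s for s in self.reference_seqs):
            raise InvalidInputError("reference sequences must be non-empty")


def _make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner(mode="local")
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    return aligner


def protein_identity_coverage(reference: str, query: str) -> tuple[float, float]:
    """Best local-alignment identity and reference coverage (BLOSUM62, -11/-1).

    Identity is identities / aligned (gap-free) columns; coverage is the
    aligned reference span divided by the reference length.
    """
    aligner = _make_aligner()
    alignments = aligner.align(reference, query)
    if len(alignments) == 0 or alignments.score <= 0:
        return 0.0, 0.0
    aln = alignments[0]
    counts = aln.counts()
    if counts.aligned == 0:
        return 0.0, 0.0
    identity = counts.identities / counts.aligned
    ref_blocks = aln.aligned[0]
    ref_span = ref_blocks[-1][1] - ref_blocks[0][0]
    return float(identity), float(ref_span / len(reference))


def find_marker_genes(
    catalog_proteins: Mapping[str, str],
    reference: MarkerGeneSet,
) -> MarkerGeneSet:
    """Scan catalog protein translations against the marker reference set.

    A gene matches when its best local alignment to *any* reference sequence
    reaches both thresholds.  An empty catalog yields an empty match set.
    """
    matched: set[str] = set()
    for gene_id, aa_seq in catalog_proteins.items():
        if not aa_seq:
            continue
        for ref in reference.reference_seqs:
            identity, coverage = protein_identity_coverage(ref, aa_seq.rstrip("*"))
            if (
                identity >= reference.identity_threshold
                and coverage >= reference.coverage_threshold
            ):
                matched.add(gene_id)
                break
    return MarkerGeneSet(
        name=reference.name,
        reference_seqs=list(reference.reference_seqs),
        identity_threshold=reference.identity_threshold,
        coverage_threshold=reference.coverage_threshold,
        matched_gene_ids=matched,
    )


def read_marker_fasta(path: str | Path, name: str | None = None, **thresholds) -> MarkerGeneSet:
    seqs = [str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")]
    return MarkerGeneSet(name=name or Path(path).stem, reference_seqs=seqs, **thresholds)


def marker_abundance(
    gene_profile: AbundanceProfile,
    markers: MarkerGeneSet,
) -> pd.Series:
    """Per-sample summed relative abundance of the matched marker genes."""
    if gene_profile.level != "gene":
        raise InvalidInputError("marker_abundance requires a gene-level profile")
    present = [g for g in markers.matched_gene_ids if g in gene_profile.data.columns]
    if not present:
        return pd.Series(0.0, index=gene_profile.data.index, name=markers.name)
    return gene_profile.data[present].sum(axis=1).rename(markers.name)


# --------------------------------------------------------------- KO modules
@dataclass
class FunctionalModule:
    """A named KO set spanning a given number of enzymatic reactions."""

    name: str
    kos: frozenset[str]
    reaction_count: int

    def __post_init__(self) -> None:
        if not self.kos:
            raise InvalidInputError("module KO set must be non-empty")
        if self.reaction_count < 1:
            raise InvalidInputError("reaction_count must be >= 1")

    @classmethod
    def from_json(cls, path: str | Path) -> "FunctionalModule":
        spec = json.loads(Path(path).read_text())
        return cls(spec["name"], frozenset(spec["kos"]), spec["reactions"])


def butyrate_module() -> FunctionalModule:
    """The shipped butyrate-formation module (acetyl-CoA -> butyrate)."""
    text = resources.files("metagut.data").joinpath("butyrate_module.json").read_text()
    spec = json.loads(text)
    return FunctionalModule(spec["name"], frozenset(spec["kos"]), spec["reactions"])


def module_abundance(
    ko_profile: AbundanceProfile,
    module: FunctionalModule,
) -> tuple[pd.Series, pd.DataFrame]:
    """Per-sample module abundance plus the per-KO breakdown.

    Module KOs absent from the profile count as zero and are logged.
    """
    if ko_profile.level != "KO":
        raise InvalidInputError("module_abundance requires a KO-level profile")
    kos = sorted(module.kos)
    missing = [k for k in kos if k not in ko_profile.data.columns]
    if missing:
        logger.warning("module %s: KOs absent from profile treated as 0: %s", module.name, missing)
    breakdown = pd.DataFrame(0.0, index=ko_profile.data.index, columns=kos)
    present = [k for k in kos if k not in missing]
    if present:
        breakdown[present] = ko_profile.data[present]
    return breakdown.sum(axis=1).rename(module.name), breakdown


# ---------------------------------------------------------------- gene flow
def _round_half_up(x: float, decimals: int) -> float:
    # printed tables round half away from zero, not to even
    scale = 10**decimals
    return math.floor(x * scale + 0.5) / scale


def _pct(count: int, denominator: int) -> float:
    if denominator == 0:
        return 0.0
    return _round_half_up(count / denominator * 100.0, 2)


@dataclass
class GeneFlowTable:
    """Cross-condition bookkeeping of per-gene enrichment classes.

    At the baseline condition every gene is classed as equal-abundance,
    enriched in group A, or enriched in group B.  At the follow-up condition
    each baseline class is partitioned further; percentage views support both
    the parent-class denominator and the baseline equal-class denominator
    (both appear in published bookkeeping of this kind, so the denominator is
    always labeled).
    """

    group_a: str
    group_b: str
    baseline: dict[str, int]  # equal / enriched_a / enriched_b
    followup: dict[str, dict[str, int]]  # baseline class -> subclass counts

    def __post_init__(self) -> None:
        for cls, parts in self.followup.items():
            if cls not in self.baseline:
                raise InvalidInputError(f"follow-up partition for unknown class {cls!r}")
            if sum(parts.values()) != self.baseline[cls]:
                raise InvalidInputError(
                    f"follow-up counts for {cls!r} must sum to the baseline count"
                )

    @property
    def total_genes(self) -> int:
        return sum(self.baseline.values())

    def baseline_percentages(self) -> dict[str, float]:
        total = self.total_genes
        return {cls: _pct(n, total) for cls, n in self.baseline.items()}

    def followup_percentages(self, denominator: str = "parent") -> dict[str, dict[str, float]]:
        """Subclass percentages; ``denominator`` is 'parent', 'equal' or 'total'."""
        out: dict[str, dict[str, float]] = {}
        for cls, parts in self.followup.items():
            if denominator == "parent":
                denom = self.baseline[cls]
            elif denominator == "equal":
                denom = self.baseline["equal"]
            elif denominator == "total":
                denom = self.total_genes
            else:
                raise InvalidInputError(f"unknown denominator {denominator!r}")
            out[cls] = {sub: _pct(n, denom) for sub, n in parts.items()}
        return out

    @classmethod
    def from_counts(
        cls,
        baseline: Mapping[str, int],
        followup: Mapping[str, Mapping[str, int]],
        group_a: str = "A",
        group_b: str = "B",
    ) -> "GeneFlowTable":
        return cls(group_a, group_b, dict(baseline), {k: dict(v) for k, v in followup.items()})

    def to_frame(self) -> pd.DataFrame:
        rows = []
        base_pct = self.baseline_percentages()
        for cls, n in self.baseline.items():
            rows.append(["baseline", cls, "", n, base_pct[cls], "total"])
        parent_pct = self.followup_percentages("parent")
        equal_pct = self.followup_percentages("equal")
        for cls, parts in self.followup.items():
            for sub, n in parts.items():
                rows.append(["followup", cls, sub, n, parent_pct[cls][sub], "parent"])
                rows.append(["followup", cls, sub, n, equal_pct[cls][sub], "baseline_equal"])
        return pd.DataFrame(
            rows, columns=["condition", "class", "subclass", "count", "percent", "denominator"]
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _directions(
    frame_a: pd.DataFrame,
    frame_b: pd.DataFrame,
    alpha: float,
) -> pd.Series:
    """Per-gene class: 'a' (higher in A), 'b', or 'equal' at raw p < alpha."""
    genes = frame_a.columns
    a = frame_a.to_numpy(dtype=float)
    b = frame_b.to_numpy(dtype=float)
    out = []
    for k in range(len(genes)):
        p = _rank_sum_test(a[:, k], b[:, k])
        if p < alpha:
            mean_a, mean_b = a[:, k].mean(), b[:, k].mean()
            if mean_a > mean_b:
                out.append("a")
                continue
            if mean_b > mean_a:
                out.append("b")
                continue
        out.append("equal")
    return pd.Series(out, index=genes)


def classify_gene_flow(
    baseline_a: pd.DataFrame | AbundanceProfile,
    baseline_b: pd.DataFrame | AbundanceProfile,
    followup_a: pd.DataFrame | AbundanceProfile,
    followup_b: pd.DataFrame | AbundanceProfile,
    alpha: float = 0.05,
    group_a: str = "A",
    group_b: str = "B",
) -> GeneFlowTable:
    """Classify per-gene enrichment flow from a baseline to a follow-up diet.

    Inputs are samples x genes abundance frames for the two groups under both
    conditions (each group needs >= 2 samples).  Enrichment uses the
    unadjusted two-sided rank-sum p at ``alpha`` (the convention of published
    per-gene bookkeeping); genes with zero abundance in *every* follow-up
    sample of both groups are classed as become-undetectable first.
    """
    frames = []
    for prof in (baseline_a, baseline_b, followup_a, followup_b):
        frames.append(prof.data if isinstance(prof, AbundanceProfile) else prof)
    base_a, base_b, fol_a, fol_b = frames
    genes = base_a.columns
    for frame in frames[1:]:
        if not frame.columns.equals(genes):
            raise InvalidInputError("all four profiles must cover the same genes")
    for frame in frames:
        if len(frame) < 2:
            raise InvalidInputError("each group needs at least 2 samples")

    base_class = _directions(base_a, base_b, alpha)
    undetectable = (fol_a.to_numpy() == 0).all(axis=0) & (fol_b.to_numpy() == 0).all(axis=0)
    fol_class = _directions(fol_a, fol_b, alpha)

    baseline_counts = {"equal": 0, "enriched_a": 0, "enriched_b": 0}
    followup_counts = {
        "equal": {"retained_equal": 0, "gained_a": 0, "gained_b": 0, "undetectable": 0},
        "enriched_a": {"retained": 0, "equalized": 0, "flipped": 0, "undetectable": 0},
        "enriched_b": {"retained": 0, "equalized": 0, "flipped": 0, "undetectable": 0},
    }
    for k, gene in enumerate(genes):
        b_cls = {"a": "enriched_a", "b": "enriched_b", "equal": "equal"}[base_class.iloc[k]]
        baseline_counts[b_cls] += 1
        if undetectable[k]:
            followup_counts[b_cls]["undetectable"] += 1
            continue
        f_dir = fol_class.iloc[k]
        if b_cls == "equal":
            sub = {"equal": "retained_equal", "a": "gained_a", "b": "gained_b"}[f_dir]
        elif b_cls == "enriched_a":
            sub = {"a": "retained", "equal": "equalized", "b": "flipped"}[f_dir]
        else:
            sub = {"b": "retained", "equal": "equalized", "a": "flipped"}[f_dir]
        followup_counts[b_cls][sub] += 1

    return GeneFlowTable(group_a, group_b, baseline_counts, followup_counts)


# ------------------------------------------------------------------- census
def directional_census(
    results_strain1: Sequence[ComparisonResult],
    results_strain2: Sequence[ComparisonResult],
    alpha: float = 0.05,
    use: str = "raw",
) -> tuple[dict[str, int], dict[str, float]]:
    """Cross-strain census of direction of change over a feature universe.

    Features significant (``use`` = 'raw' or 'adjusted' p < alpha) in both
    result sets with the same sign count as same-direction; features
    significant in exactly one set as strain-exclusive; the rest as
    unchanged.  Percentages are over the shared feature universe.
    """
    if use not in ("raw", "adjusted"):
        raise InvalidInputError("use must be 'raw' or 'adjusted'")
    r1 = {r.feature: r for r in results_strain1}
    r2 = {r.feature: r for r in results_strain2}
    if set(r1) != set(r2):
        raise InvalidInputError("feature universes differ between the two result sets")

    def is_sig(r: ComparisonResult) -> bool:
        p = r.p_value if use == "raw" else r.p_adjusted
        return p < alpha and r.mean_a != r.mean_b

    counts = {
        "same_direction": 0,
        "opposite_direction": 0,
        "strain1_only": 0,
        "strain2_only": 0,
        "unchanged": 0,
    }
    for feature in r1:
        a, b = r1[feature], r2[feature]
        sig_a, sig_b = is_sig(a), is_sig(b)
        if sig_a and sig_b:
            same = math.copysign(1, a.mean_a - a.mean_b) == math.copysign(1, b.mean_a - b.mean_b)
            counts["same_direction" if same else "opposite_direction"] += 1
        elif sig_a:
            counts["strain1_only"] += 1
        elif sig_b:
            counts["strain2_only"] += 1
        else:
            counts["unchanged"] += 1
    n = len(r1)
    percentages = {k: census_percentage(v, n) for k, v in counts.items()}
    return counts, percentages


def census_percentage(count: int, universe: int, decimals: int = 1) -> float:
    """Percentage of the feature universe, rounded as printed census tables are."""
    if universe == 0:
        raise InvalidInputError("empty feature universe")
    return _round_half_up(count / universe * 100.0, decimals)
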