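"""Lowest-common-ancestor taxonomy and profile aggregation.

Gene-level taxonomy is decided by the lowest common ancestor of all of a
gene's annotation hits: the deepest rank at which every hit agrees, with all
ranks below it left unassigned.  Gene-level relative abundances are then
aggregated to taxonomic ranks by summation, and to KEGG orthologues (KOs)
with the convention that a gene carrying several KOs contributes its full
abundance to each of them.

Database searches themselves are out of scope: gene -> lineage and
gene -> KO annotations arrive as TSV tables.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .errors import InvalidInputError
from .quantify import AbundanceProfile

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")
_KO_RE = re.compile(r"^K\d{5}$")


@dataclass(frozen=True)
class Lineage:
    """Seven-rank taxonomic lineage; None marks an unassigned rank.

    No assigned rank may sit below an unassigned one.
    """

    names: tuple[str | None, ...]

    def __post_init__(self) -> None:
        if len(self.names) != len(RANKS):
            raise InvalidInputError(f"lineage needs {len(RANKS)} ranks, got {len(self.names)}")
        seen_gap = False
        for name in self.names:
            if name is None:
                seen_gap = True
            elif seen_gap:
                raise InvalidInputError(f"assigned rank below unassigned rank in {self.names}")

    @classmethod
    def from_names(cls, *names: str | None, **by_rank: str | None) -> "Lineage":
        if names and by_rank:
            raise InvalidInputError("pass ranks positionally or by name, not both")
        if by_rank:
            unknown = set(by_rank) - set(RANKS)
            if unknown:
                raise InvalidInputError(f"unknown ranks: {unknown}")
            names = tuple(by_rank.get(r) for r in RANKS)
        filled = tuple(names) + (None,) * (len(RANKS) - len(names))
        return cls(tuple(n if n else None for n in filled))

    def at(self, rank: str) -> str | None:
        return self.names[RANKS.index(rank)]

    @property
    def depth(self) -> int:
        return sum(n is not None for n in self.names)


UNASSIGNED = Lineage((None,) * len(RANKS))


def lca_assign(hits: Iterable[Lineage]) -> Lineage:
    """Deepest rank at which all annotation hits agree; deeper ranks cleared.

    Hits disagreeing already at kingdom yield the fully unassigned lineage.
    """
    hits = list(hits)
    if not hits:
        raise InvalidInputError("lca_assign requires at least one hit")
    consensus: list[str | None] = []
    for level in range(len(RANKS)):
        names = {h.names[level] for h in hits}
        if len(names) == 1 and None not in names:
            consensus.append(names.pop())
        else:
            break
    consensus.extend([None] * (len(RANKS) - len(consensus)))
    return Lineage(tuple(consensus))


@dataclass
class AnnotationTable:
    """gene -> lineage and gene -> KO-set annotation maps."""

    lineages: dict[str, Lineage]
    kos: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        for gene, ko_set in self.kos.items():
            for ko in ko_set:
                if not _KO_RE.match(ko):
                    raise InvalidInputError(f"{gene}: malformed KO identifier {ko!r}")

    def validate_against(self, catalog_genes: Iterable[str]) -> None:
        known = set(catalog_genes)
        stray = (set(self.lineages) | set(self.kos)) - known
        if stray:
            raise InvalidInputError(f"annotated genes missing from catalog: {sorted(stray)[:5]}")

    # ------------------------------------------------------------------ IO
    @classmethod
    def read_tsv(cls, lineage_path: str | Path | None, ko_path: str | Path | None) -> "AnnotationTable":
        lineages: dict[str, Lineage] = {}
        if lineage_path is not None:
            df = pd.read_csv(lineage_path, sep="\t", dtype=str, keep_default_na=False)
            expected = ["gene_id", *RANKS]
            if list(df.columns) != expected:
                raise InvalidInputError(f"lineage TSV columns must be {expected}")
            lineages = {
                rec[0]: Lineage(tuple(n if n else None for n in rec[1:]))
                for rec in df.itertuples(index=False, name=None)
            }
        kos: dict[str, frozenset[str]] = {}
        if ko_path is not None:
            df = pd.read_csv(ko_path, sep="\t", dtype=str, keep_default_na=False)
            if list(df.columns) != ["gene_id", "kos"]:
                raise InvalidInputError("KO TSV columns must be ['gene_id', 'kos']")
            for gene, ko_field in df.itertuples(index=False, name=None):
                kos[gene] = frozenset(k for k in ko_field.split(";") if k)
        return cls(lineages, kos)

    def write_tsv(self, lineage_path: str | Path | None, ko_path: str | Path | None) -> None:
        if lineage_path is not None:
            rows = [
                [gene, *[n or "" for n in lin.names]] for gene, lin in sorted(self.lineages.items())
            ]
            pd.DataFrame(rows, columns=["gene_id", *RANKS]).to_csv(
                lineage_path, sep="\t", index=False
            )
        if ko_path is not None:
            rows = [[gene, ";".join(sorted(ks))] for gene, ks in sorted(self.kos.items())]
            pd.DataFrame(rows, columns=["gene_id", "kos"]).to_csv(ko_path, sep="\t", index=False)


def aggregate_profile(
    gene_profile: AbundanceProfile,
    annotations: AnnotationTable,
    level: str,
) -> AbundanceProfile:
    """Sum gene abundances into taxon or KO features.

    At a taxonomic rank, a gene contributes to the single taxon its lineage
    assigns at that rank (nothing if unassigned there).  At the KO level a
    gene carrying k KOs contributes its full abundance to each of the k KOs.
    Unannotated genes contribute to no feature, so aggregated row sums are
    bounded by the annotated mass.
    """
    if gene_profile.level != "gene":
        raise InvalidInputError("aggregate_profile requires a gene-level profile")
    if level == "KO":
        mapping: dict[str, list[str]] = {}
        for gene, ko_set in annotations.kos.items():
            if gene in gene_profile.data.columns:
                for ko in ko_set:
                    mapping.setdefault(ko, []).append(gene)
        agg = {
            feat: gene_profile.data[genes].sum(axis=1) for feat, genes in sorted(mapping.items())
        }
    elif level in RANKS:
        names = {
            gene: lin.at(level)
            for gene, lin in annotations.lineages.items()
            if gene in gene_profile.data.columns and lin.at(level) is not None
        }
        mapping = {}
        for gene, name in names.items():
            mapping.setdefault(name, []).append(gene)
        agg = {
            feat: gene_profile.data[genes].sum(axis=1) for feat, genes in sorted(mapping.items())
        }
    else:
        raise InvalidInputError(f"unknown aggregation level {level!r}")
    data = pd.DataFrame(agg, index=gene_profile.data.index)
    if data.empty:
        data = pd.DataFrame(index=gene_profile.data.index)
    return AbundanceProfile(data, level=level)
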