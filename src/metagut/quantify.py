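"""Paired-end read counting against a gene catalog and relative abundance.

A read pair contributes exactly one copy to exactly one gene when either

(i)  both ends map within the gene and the insert size lies inside a
     "moderate" closed interval, or
(ii) one end overlaps a gene terminus (first or last base) while its mate
     maps outside the gene region,

and the alignment identity is strictly greater than the threshold (default
0.90).  Multi-mapped pairs keep only their best-identity placement; ties
between distinct genes are discarded.

Per-gene copy counts x_i are turned into relative abundances by length
normalization:

    a_i = (x_i / L_i) / sum_j (x_j / L_j)

so that each sample's gene-level abundances sum to 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog import GeneCatalog
from .errors import InvalidInputError

Span = tuple[int, int]  # 0-based half-open interval on the gene


@dataclass
class PairedAlignment:
    """One candidate placement of a read pair on one catalog gene."""

    pair_id: str
    gene_id: str
    end1_span: Span | None
    end2_span: Span | None
    identity: float
    insert_size: int | None = None
    mate_outside_gene: bool = False

    def __post_init__(self) -> None:
        if self.end1_span is None and self.end2_span is None:
            raise InvalidInputError(f"{self.pair_id}: at least one end span required")
        if not 0.0 <= self.identity <= 1.0:
            raise InvalidInputError(f"{self.pair_id}: identity must be in [0, 1]")
        for span in (self.end1_span, self.end2_span):
            if span is not None and span[0] >= span[1]:
                raise InvalidInputError(f"{self.pair_id}: empty span {span}")


@dataclass
class CountTable:
    """Per-(sample, gene) copy counts together with gene lengths L_i."""

    counts: pd.DataFrame  # genes x samples, non-negative integers
    lengths: pd.Series  # bp per gene, index == counts.index

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.lengths.index):
            self.lengths = self.lengths.reindex(self.counts.index)
        if self.lengths.isna().any():
            missing = self.lengths[self.lengths.isna()].index.tolist()
            raise InvalidInputError(f"genes without length: {missing[:5]}")
        if (self.counts.to_numpy() < 0).any():
            raise InvalidInputError("counts must be non-negative")
        if (self.lengths <= 0).any():
            raise InvalidInputError("gene lengths must be positive")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    def to_tsv(self, path: str | Path) -> None:
        out = self.counts.copy()
        out.insert(0, "length_bp", self.lengths)
        out.to_csv(path, sep="\t", index_label="gene_id")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CountTable":
        df = pd.read_csv(path, sep="\t", index_col="gene_id")
        lengths = df.pop("length_bp")
        return cls(df, lengths)

    @classmethod
    def merge(cls, tables: Sequence["CountTable"]) -> "CountTable":
        genes = tables[0].counts.index
        for t in tables[1:]:
            if not t.counts.index.equals(genes):
                raise InvalidInputError("count tables cover different gene sets")
        return cls(pd.concat([t.counts for t in tables], axis=1), tables[0].lengths)


@dataclass
class AbundanceProfile:
    """Samples x features matrix of relative abundances with a level tag.

    ``level`` is one of gene / KO / a taxonomic rank.  Gene-level rows sum to
    1 for every non-empty sample; aggregated levels carry only the annotated
    fraction of the mass, so their row sums are <= 1.
    """

    data: pd.DataFrame  # samples x features
    level: str = "gene"
    empty_samples: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        values = self.data.to_numpy()
        if (values < 0).any():
            raise InvalidInputError("abundances must be non-negative")
        if self.level == "gene":
            sums = values.sum(axis=1)
            nonempty = ~self.data.index.isin(list(self.empty_samples))
            if not np.allclose(sums[nonempty], 1.0, atol=1e-9):
                raise InvalidInputError("gene-level rows must sum to 1")

    @property
    def samples(self) -> list[str]:
        return list(self.data.index)

    @property
    def features(self) -> list[str]:
        return list(self.data.columns)

    def to_tsv(self, path: str | Path) -> None:
        # features x samples on disk, header row of sample IDs
        self.data.T.to_csv(path, sep="\t", index_label="feature")

    @classmethod
    def from_tsv(cls, path: str | Path, level: str = "gene") -> "AbundanceProfile":
        df = pd.read_csv(path, sep="\t", index_col="feature").T
        empty = frozenset(df.index[df.sum(axis=1) == 0]) if level == "gene" else frozenset()
        return cls(df, level=level, empty_samples=empty)


# ------------------------------------------------------------------ counting
def _qualifies(
    aln: PairedAlignment,
    gene_len: int,
    min_identity: float,
    insert_range: tuple[int, int],
) -> bool:
    if aln.identity <= min_identity:
        return False
    spans = [s for s in (aln.end1_span, aln.end2_span) if s is not None]
    for start, end in spans:
        if start < 0 or end > gene_len:
            return False
    if not aln.mate_outside_gene and len(spans) == 2:
        # criterion (i): both ends within the gene, moderate insert size
        return (
            aln.insert_size is not None
            and insert_range[0] <= aln.insert_size <= insert_range[1]
        )
    if aln.mate_outside_gene and len(spans) == 1:
        # criterion (ii): mapped end must overlap the first or last base
        start, end = spans[0]
        return start == 0 or end == gene_len
    return False


def count_pairs(
    alignments: Iterable[PairedAlignment],
    catalog: GeneCatalog | Mapping[str, int],
    insert_range: tuple[int, int],
    min_identity: float = 0.90,
    sample_id: str = "sample",
) -> CountTable:
    """Count qualifying read pairs per gene for one sample.

    Each pair contributes one copy to at most one gene.  Among a pair's
    placements the best identity wins; an identity tie between distinct genes
    discards the pair.
    """
    if insert_range[0] > insert_range[1]:
        raise InvalidInputError("insert_range.min must be <= insert_range.max")
    lengths = catalog.gene_lengths() if isinstance(catalog, GeneCatalog) else dict(catalog)

    by_pair: dict[str, list[PairedAlignment]] = {}
    for aln in alignments:
        if aln.gene_id not in lengths:
            raise InvalidInputError(f"alignment references unknown gene {aln.gene_id!r}")
        by_pair.setdefault(aln.pair_id, []).append(aln)

    gene_ids = list(lengths)
    counts = dict.fromkeys(gene_ids, 0)
    for placements in by_pair.values():
        best = max(p.identity for p in placements)
        top = [p for p in placements if p.identity == best]
        if len({p.gene_id for p in top}) > 1:
            continue  # ambiguous multi-mapper
        chosen = top[0]
        if _qualifies(chosen, lengths[chosen.gene_id], min_identity, insert_range):
            counts[chosen.gene_id] += 1

    frame = pd.DataFrame({sample_id: pd.Series(counts, dtype=int)})
    return CountTable(frame, pd.Series(lengths, dtype=int))


def relative_abundance(counts: CountTable) -> AbundanceProfile:
    """Length-normalized relative abundances a_i = (x_i/L_i) / sum_j x_j/L_j.

    Samples with zero total counts yield an all-zero row and are flagged in
    ``empty_samples``.
    """
    x = counts.counts.to_numpy(dtype=float)
    length = counts.lengths.to_numpy(dtype=float)
    rate = x / length[:, None]
    totals = rate.sum(axis=0)
    empty = totals == 0
    safe = np.where(empty, 1.0, totals)
    values = (rate / safe).T  # samples x genes
    values[empty, :] = 0.0
    data = pd.DataFrame(values, index=counts.samples, columns=counts.genes)
    return AbundanceProfile(
        data,
        level="gene",
        empty_samples=frozenset(np.asarray(counts.samples)[empty]),
    )


# ----------------------------------------------------------------------- IO
_TSV_COLUMNS = [
    "pair_id",
    "gene_id",
    "end1_span",
    "end2_span",
    "identity",
    "insert_size",
    "mate_outside_gene",
]


def _format_span(span: Span | None) -> str:
    return "" if span is None else f"{span[0]}:{span[1]}"


def _parse_span(text: str) -> Span | None:
    if not text:
        return None
    start, end = text.split(":")
    return (int(start), int(end))


def write_alignment_tsv(alignments: Iterable[PairedAlignment], path: str | Path) -> None:
    """Seven-column tabular dialect mirroring :class:`PairedAlignment`."""
    with open(path, "w") as fh:
        fh.write("\t".join(_TSV_COLUMNS) + "\n")
        for a in alignments:
            fh.write(
                "\t".join(
                    [
                        a.pair_id,
                        a.gene_id,
                        _format_span(a.end1_span),
                        _format_span(a.end2_span),
                        f"{a.identity:.6g}",
                        "" if a.insert_size is None else str(a.insert_size),
                        "1" if a.mate_outside_gene else "0",
                    ]
                )
                + "\n"
            )


def read_alignment_tsv(path: str | Path) -> list[PairedAlignment]:
    out: list[PairedAlignment] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _TSV_COLUMNS:
            raise InvalidInputError(f"unexpected alignment TSV header: {header}")
        for line in fh:
            pair_id, gene_id, s1, s2, ident, insert, outside = line.rstrip("\n").split("\t")
            out.append(
                PairedAlignment(
                    pair_id=pair_id,
                    gene_id=gene_id,
                    end1_span=_parse_span(s1),
                    end2_span=_parse_span(s2),
                    identity=float(ident),
                    insert_size=int(insert) if insert else None,
                    mate_outside_gene=outside == "1",
                )
            )
    return out


def read_sam_alignments(path: str | Path) -> list[PairedAlignment]:
    """Read paired alignments from SAM (references are catalog genes).

    Identity per end is 1 - NM / aligned-length; the pair's identity is the
    minimum over its mapped ends.  Pairs with both ends on the same gene
    become criterion-(i) candidates with insert = |TLEN|; a mapped end whose
    mate is unmapped or on a different reference becomes a criterion-(ii)
    candidate (mate outside the gene region).
    """
    import pysam

    ends: dict[tuple[str, str], list] = {}
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            ends.setdefault((rec.query_name, rec.reference_name), []).append(
                {
                    "read1": rec.is_read1,
                    "span": (rec.reference_start, rec.reference_end),
                    "nm": rec.get_tag("NM") if rec.has_tag("NM") else 0,
                    "alen": rec.query_alignment_length,
                    "tlen": abs(rec.template_length),
                    "mate_unmapped": rec.mate_is_unmapped,
                    "mate_ref": rec.next_reference_name,
                }
            )

    out: list[PairedAlignment] = []
    for (qname, gene), recs in ends.items():
        identities = [1.0 - r["nm"] / r["alen"] for r in recs if r["alen"]]
        identity = min(identities) if identities else 0.0
        if len(recs) == 2:
            r1 = next((r for r in recs if r["read1"]), recs[0])
            r2 = next((r for r in recs if not r["read1"]), recs[1])
            out.append(
                PairedAlignment(
                    pair_id=qname,
                    gene_id=gene,
                    end1_span=r1["span"],
                    end2_span=r2["span"],
                    identity=identity,
                    insert_size=r1["tlen"] or None,
                )
            )
        else:
            r = recs[0]
            mate_outside = r["mate_unmapped"] or r["mate_ref"] != gene
            out.append(
                PairedAlignment(
                    pair_id=qname,
                    gene_id=gene,
                    end1_span=r["span"],
                    end2_span=None,
                    identity=identity,
                    insert_size=None,
                    mate_outside_gene=mate_outside,
                )
            )
    return out
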