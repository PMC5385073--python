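"""Non-redundant gene catalog construction from predicted ORFs.

Shotgun-metagenome assemblies from many samples yield highly redundant sets of
predicted open reading frames.  This module collapses them into a catalog of
representative genes: two ORFs are considered redundant when an *ungapped*
alignment at some relative offset (on either strand) exceeds the identity
threshold (default 95%) while the aligned region covers more than the coverage
threshold (default 90%) of the shorter sequence.  Redundant pairs are merged by
single linkage; each group is represented by its longest member; groups whose
representative is shorter than ``min_length_bp`` (default 100 bp) are dropped
after grouping.

The pairwise criterion is exact (an exhaustive scan over all relative offsets
and both strands); an optional k-mer prefilter only skips sequence pairs that
cannot share a seed and never changes the resulting partition.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import InvalidInputError

_ALPHABET = set("ACGTN")

# distinct sentinel codes so that N never matches anything, not even another N
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_LUT_A = np.full(256, 255, dtype=np.uint8)
_LUT_B = np.full(256, 255, dtype=np.uint8)
for _base, _c in _CODE.items():
    _LUT_A[ord(_base)] = _c
    _LUT_B[ord(_base)] = _c
_LUT_A[ord("N")] = 200
_LUT_B[ord("N")] = 201

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _encode(seq: str, lut: np.ndarray) -> np.ndarray:
    arr = lut[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (arr == 255).any():
        bad = set(seq) - _ALPHABET
        raise InvalidInputError(f"sequence contains characters outside ACGTN: {bad}")
    return arr


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class GeneRecord:
    """A predicted ORF: nucleotide sequence plus optional translation."""

    gene_id: str
    nt_seq: str
    aa_seq: str | None = None

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise InvalidInputError("gene_id must be non-empty")
        if not self.nt_seq:
            raise InvalidInputError(f"{self.gene_id}: empty nucleotide sequence")
        self.nt_seq = self.nt_seq.upper()
        if not set(self.nt_seq) <= _ALPHABET:
            raise InvalidInputError(
                f"{self.gene_id}: alphabet outside ACGTN: {set(self.nt_seq) - _ALPHABET}"
            )

    @property
    def length_bp(self) -> int:
        return len(self.nt_seq)

    def translate(self, table: int = 11) -> str:
        """Translate the ORF with the bacterial genetic code (table 11)."""
        aa = str(Seq(self.nt_seq[: len(self.nt_seq) // 3 * 3]).translate(table=table))
        return aa.rstrip("*")


@dataclass
class GeneCatalog:
    """Representative genes plus the member -> representative redundancy map."""

    representatives: list[GeneRecord]
    redundancy_map: dict[str, str]
    identity_threshold: float = 0.95
    coverage_threshold: float = 0.90
    min_length_bp: int = 100
    _lengths: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        rep_ids = {r.gene_id for r in self.representatives}
        for member, rep in self.redundancy_map.items():
            if rep not in rep_ids:
                raise InvalidInputError(f"{member} maps to unknown representative {rep}")
        for rid in rep_ids:
            if self.redundancy_map.get(rid) != rid:
                raise InvalidInputError(f"representative {rid} must map to itself")
        self._lengths = {r.gene_id: r.length_bp for r in self.representatives}

    def __len__(self) -> int:
        return len(self.representatives)

    @property
    def gene_ids(self) -> list[str]:
        return [r.gene_id for r in self.representatives]

    def gene_lengths(self) -> dict[str, int]:
        return dict(self._lengths)

    # ------------------------------------------------------------------ IO
    def write_fasta(self, path: str | Path) -> None:
        write_fasta(self.representatives, path)

    def write_redundancy_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("member_id\trepresentative_id\n")
            for member, rep in sorted(self.redundancy_map.items()):
                fh.write(f"{member}\t{rep}\n")

    @staticmethod
    def read_redundancy_tsv(path: str | Path) -> dict[str, str]:
        out: dict[str, str] = {}
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("member_id"):
                raise InvalidInputError("redundancy TSV must start with a header row")
            for line in fh:
                member, rep = line.rstrip("\n").split("\t")
                out[member] = rep
        return out


# ---------------------------------------------------------------------- FASTA
def read_fasta(path: str | Path) -> list[GeneRecord]:
    return [GeneRecord(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: Iterable[GeneRecord], path: str | Path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(r.nt_seq), id=r.gene_id, description="") for r in records),
        str(path),
        "fasta",
    )


# ------------------------------------------------------------ pairwise scan
def _offset_matches(long_arr: np.ndarray, short_arr: np.ndarray, min_overlap: int):
    """Matches/overlap for every ungapped offset with overlap >= min_overlap.

    Yields (matches, overlap) pairs; full-containment offsets are computed in
    one vectorized pass, end-overhang offsets individually.
    """
    m, s = long_arr.size, short_arr.size
    windows = sliding_window_view(long_arr, s)
    full = (windows == short_arr).sum(axis=1)
    for n_match in full:
        yield int(n_match), s
    for k in range(min_overlap, s):
        yield int((short_arr[s - k :] == long_arr[:k]).sum()), k  # overhang left
        yield int((short_arr[:k] == long_arr[m - k :]).sum()), k  # overhang right


def ungapped_identity(seq_a: str, seq_b: str) -> tuple[float, float]:
    """Best ungapped identity between two sequences and coverage of the shorter.

    All relative offsets and both strands of ``seq_b`` are scanned; the
    returned offset maximizes the number of matching columns (ties resolved
    toward larger overlap, forward strand first).  Identity is
    matches / aligned columns; coverage is aligned columns / length of the
    shorter sequence.
    """
    if not seq_a or not seq_b:
        raise InvalidInputError("sequences must be non-empty")
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    for s in (seq_a, seq_b):
        if not set(s) <= _ALPHABET:
            raise InvalidInputError(f"alphabet outside ACGTN: {set(s) - _ALPHABET}")
    a = _encode(seq_a, _LUT_A)
    best_matches, best_overlap = -1, 1
    for strand_b in (seq_b, reverse_complement(seq_b)):
        b = _encode(strand_b, _LUT_B)
        long_arr, short_arr = (a, b) if a.size >= b.size else (b, a)
        for matches, overlap in _offset_matches(long_arr, short_arr, 1):
            if matches > best_matches or (matches == best_matches and overlap > best_overlap):
                best_matches, best_overlap = matches, overlap
    shorter = min(len(seq_a), len(seq_b))
    return best_matches / best_overlap, best_overlap / shorter


def is_redundant_pair(
    seq_a: str,
    seq_b: str,
    identity_threshold: float = 0.95,
    coverage_threshold: float = 0.90,
) -> bool:
    """True when some ungapped offset exceeds both thresholds (strict >)."""
    if not seq_a or not seq_b:
        raise InvalidInputError("sequences must be non-empty")
    a = _encode(seq_a.upper(), _LUT_A)
    shorter = min(len(seq_a), len(seq_b))
    # smallest integer overlap with overlap / shorter > coverage_threshold
    min_overlap = int(np.floor(coverage_threshold * shorter)) + 1
    if min_overlap > shorter:
        return False
    for strand_b in (seq_b.upper(), reverse_complement(seq_b.upper())):
        b = _encode(strand_b, _LUT_B)
        long_arr, short_arr = (a, b) if a.size >= b.size else (b, a)
        for matches, overlap in _offset_matches(long_arr, short_arr, min_overlap):
            if matches > identity_threshold * overlap:
                return True
    return False


# --------------------------------------------------------------- clustering
class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def _candidate_pairs(seqs: Sequence[str], k: int) -> Iterable[tuple[int, int]]:
    """Pairs sharing at least one canonical k-mer (plus all pairs touching
    sequences shorter than k, which carry no seed)."""
    buckets: dict[str, list[int]] = {}
    short_idx: list[int] = []
    for i, seq in enumerate(seqs):
        if len(seq) < k:
            short_idx.append(i)
            continue
        kmers = {seq[j : j + k] for j in range(len(seq) - k + 1)}
        for km in kmers:
            rc = reverse_complement(km)
            buckets.setdefault(min(km, rc), []).append(i)
    seen: set[tuple[int, int]] = set()
    for members in buckets.values():
        if len(members) < 2:
            continue
        uniq = sorted(set(members))
        for pair in itertools.combinations(uniq, 2):
            if pair not in seen:
                seen.add(pair)
                yield pair
    for i in short_idx:
        for j in range(len(seqs)):
            if j != i:
                yield (min(i, j), max(i, j))


def cluster_orfs(
    orfs: Sequence[GeneRecord],
    identity_threshold: float = 0.95,
    coverage_threshold: float = 0.90,
    min_length_bp: int = 100,
    prefilter_k: int | None = 12,
) -> GeneCatalog:
    """Group redundant ORFs by single linkage and keep the longest per group.

    A pair is redundant when an ungapped alignment (any offset, either strand)
    exceeds ``identity_threshold`` with the aligned region covering more than
    ``coverage_threshold`` of the shorter sequence.  Groups whose
    representative (the longest member; ties broken by lexicographically
    smallest gene_id) is shorter than ``min_length_bp`` are removed after
    grouping, together with their redundancy-map entries.
    """
    orfs = list(orfs)
    ids = [o.gene_id for o in orfs]
    if len(set(ids)) != len(ids):
        dupes = {g for g in ids if ids.count(g) > 1}
        raise InvalidInputError(f"duplicate gene_ids: {sorted(dupes)[:5]}")
    seqs = [o.nt_seq for o in orfs]

    uf = _UnionFind(len(orfs))
    if prefilter_k is None:
        pairs: Iterable[tuple[int, int]] = itertools.combinations(range(len(orfs)), 2)
    else:
        pairs = _candidate_pairs(seqs, prefilter_k)
    for i, j in pairs:
        if uf.find(i) != uf.find(j) and is_redundant_pair(
            seqs[i], seqs[j], identity_threshold, coverage_threshold
        ):
            uf.union(i, j)

    groups: dict[int, list[int]] = {}
    for i in range(len(orfs)):
        groups.setdefault(uf.find(i), []).append(i)

    representatives: list[GeneRecord] = []
    redundancy_map: dict[str, str] = {}
    # deterministic output order: by first-appearing member of each group
    for root in sorted(groups, key=lambda r: min(groups[r])):
        members = groups[root]
        rep_idx = min(members, key=lambda i: (-orfs[i].length_bp, orfs[i].gene_id))
        rep = orfs[rep_idx]
        if rep.length_bp < min_length_bp:
            continue
        representatives.append(rep)
        for i in members:
            redundancy_map[orfs[i].gene_id] = rep.gene_id

    return GeneCatalog(
        representatives,
        redundancy_map,
        identity_threshold=identity_threshold,
        coverage_threshold=coverage_threshold,
        min_length_bp=min_length_bp,
    )
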