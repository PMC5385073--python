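"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately naive and kept separate from the package:
exhaustive offset scans, closed-testing enumeration, a plain Gotoh DP, and
direct summations.
"""

from __future__ import annotations

import itertools

import numpy as np
from Bio.Align import substitution_matrices

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def naive_offset_scan(seq_a: str, seq_b: str):
    """All (identity, coverage) pairs over every ungapped offset, both strands."""
    out = []
    for b in (seq_b, revcomp(seq_b)):
        la, lb = len(seq_a), len(b)
        shorter = min(la, lb)
        for offset in range(-(lb - 1), la):
            start_a, end_a = max(0, offset), min(la, offset + lb)
            overlap = end_a - start_a
            if overlap < 1:
                continue
            seg_a = seq_a[start_a:end_a]
            seg_b = b[start_a - offset : end_a - offset]
            matches = sum(
                1 for x, y in zip(seg_a, seg_b) if x == y and x != "N"
            )
            out.append((matches / overlap, overlap / shorter))
    return out


def naive_redundant(seq_a: str, seq_b: str, id_thr: float = 0.95, cov_thr: float = 0.90) -> bool:
    """Exhaustive check of the redundancy criterion (strict > on both)."""
    return any(
        ident > id_thr and cov > cov_thr for ident, cov in naive_offset_scan(seq_a, seq_b)
    )


def naive_redundant_fast(
    seq_a: str, seq_b: str, id_thr: float = 0.95, cov_thr: float = 0.90
) -> bool:
    """Offset-by-offset numpy scan of the redundancy criterion.

    Only offsets whose overlap can satisfy the strict coverage bound are
    examined (smaller overlaps cannot qualify); each offset is compared by a
    direct array slice, independent of the implementation's vectorization.
    """
    a = np.frombuffer(seq_a.encode(), dtype=np.uint8)
    shorter = min(len(seq_a), len(seq_b))
    min_overlap = int(np.floor(cov_thr * shorter)) + 1
    for b_str in (seq_b, revcomp(seq_b)):
        b = np.frombuffer(b_str.encode(), dtype=np.uint8)
        for offset in range(-(len(b) - min_overlap), len(a) - min_overlap + 1):
            start_a, end_a = max(0, offset), min(len(a), offset + len(b))
            overlap = end_a - start_a
            if overlap < min_overlap:
                continue
            seg_a = a[start_a:end_a]
            seg_b = b[start_a - offset : end_a - offset]
            matches = int(((seg_a == seg_b) & (seg_a != ord("N"))).sum())
            if matches > id_thr * overlap:
                return True
    return False


def single_linkage_partition_fast(seqs: dict[str, str], id_thr: float = 0.95, cov_thr: float = 0.90):
    """All-pairs single-linkage partition using the numpy offset scan."""
    ids = list(seqs)
    parent = {g: g for g in ids}

    def find(g):
        while parent[g] != g:
            parent[g] = parent[parent[g]]
            g = parent[g]
        return g

    for a, b in itertools.combinations(ids, 2):
        if find(a) != find(b) and naive_redundant_fast(seqs[a], seqs[b], id_thr, cov_thr):
            parent[find(a)] = find(b)
    groups: dict[str, set[str]] = {}
    for g in ids:
        groups.setdefault(find(g), set()).add(g)
    return {frozenset(v) for v in groups.values()}


def single_linkage_partition(seqs: dict[str, str], id_thr: float = 0.95, cov_thr: float = 0.90):
    """All-pairs single-linkage groups as frozensets of gene_ids."""
    ids = list(seqs)
    parent = {g: g for g in ids}

    def find(g):
        while parent[g] != g:
            parent[g] = parent[parent[g]]
            g = parent[g]
        return g

    for a, b in itertools.combinations(ids, 2):
        if find(a) != find(b) and naive_redundant(seqs[a], seqs[b], id_thr, cov_thr):
            parent[find(a)] = find(b)
    groups: dict[str, set[str]] = {}
    for g in ids:
        groups.setdefault(find(g), set()).add(g)
    return {frozenset(v) for v in groups.values()}


def hommel_closed_testing(p_values):
    """Hommel adjusted p-values by explicit closed testing with Simes tests."""
    p = np.asarray(p_values, dtype=float)
    n = len(p)
    adjusted = np.zeros(n)
    for i in range(n):
        worst = 0.0
        for size in range(1, n + 1):
            for subset in itertools.combinations(range(n), size):
                if i not in subset:
                    continue
                sub = np.sort(p[list(subset)])
                simes = min(len(sub) * sub[j] / (j + 1) for j in range(len(sub)))
                worst = max(worst, min(simes, 1.0))
        adjusted[i] = worst
    return adjusted


_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def gotoh_local(ref: str, query: str, open_score: float = -11.0, extend_score: float = -1.0):
    """Plain Gotoh local alignment; returns (identity, ref_coverage).

    Identity is identities / aligned (gap-free) columns of one optimal
    alignment; coverage is the reference span of that alignment divided by
    the reference length.
    """
    m, n = len(ref), len(query)
    NEG = -1e9
    H = np.zeros((m + 1, n + 1))
    P = np.full((m + 1, n + 1), NEG)  # gap in query (consumes ref)
    Q = np.full((m + 1, n + 1), NEG)  # gap in ref (consumes query)
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            P[i, j] = max(H[i - 1, j] + open_score, P[i - 1, j] + extend_score)
            Q[i, j] = max(H[i, j - 1] + open_score, Q[i, j - 1] + extend_score)
            diag = H[i - 1, j - 1] + _BLOSUM62[ref[i - 1], query[j - 1]]
            H[i, j] = max(0.0, diag, P[i, j], Q[i, j])
    score = H.max()
    if score <= 0:
        return 0.0, 0.0
    i, j = np.unravel_index(np.argmax(H), H.shape)
    i_end = int(i)
    identities = aligned = 0
    state = "H"
    while i > 0 and j > 0:
        if state == "H":
            if H[i, j] == 0:
                break
            diag = H[i - 1, j - 1] + _BLOSUM62[ref[i - 1], query[j - 1]]
            if H[i, j] == diag:
                aligned += 1
                identities += ref[i - 1] == query[j - 1]
                i, j = i - 1, j - 1
            elif H[i, j] == P[i, j]:
                state = "P"
            else:
                state = "Q"
        elif state == "P":
            if P[i, j] == H[i - 1, j] + open_score:
                state = "H"
            i -= 1
        else:
            if Q[i, j] == H[i, j - 1] + open_score:
                state = "H"
            j -= 1
    if aligned == 0:
        return 0.0, 0.0
    return identities / aligned, (i_end - int(i)) / m


def permanova_by_hand(dist: np.ndarray, labels):
    """Pseudo-F from the explicit among/within sum-of-squares partition."""
    labels = np.asarray(labels)
    n = len(labels)
    d2 = np.asarray(dist, dtype=float) ** 2
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    g = len(np.unique(labels))
    ss_among = ss_total - ss_within
    return (ss_among / (g - 1)) / (ss_within / (n - g))
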