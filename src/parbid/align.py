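"""Pairwise and progressive multiple alignment, plus query-coverage stats.

Pairwise alignment is affine-gap dynamic programming (optimal, via
Biopython's ``PairwiseAligner``); ``semi_global`` mode leaves terminal gaps
of either sequence unpenalized, which is the model used both for mapping
reads into a bait and for BLAST-like query-coverage computation.

The multiple aligner is a plain progressive scheme: a guide order from
k-mer distances (k=6) followed by sequential profile-profile merges with
the same affine scoring.  It targets closely related marker sequences
(<10% divergence) where any reasonable aligner agrees; an externally
aligned FASTA may be supplied downstream instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from Bio import Align as _bioalign

from .seqcore import SequenceRecord

__all__ = [
    "PairwiseAlignment",
    "Alignment",
    "CoverageStats",
    "pairwise_align",
    "progressive_msa",
    "query_coverage",
    "DEFAULT_SCORING",
]

#: (match, mismatch, gap_open, gap_extend) — conventional nucleotide defaults.
DEFAULT_SCORING = (1.0, -1.0, -4.0, -1.0)


@dataclass
class PairwiseAlignment:
    aligned_a: str
    aligned_b: str
    score: float
    mode: str

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned strings must have equal length")


@dataclass
class Alignment:
    """A multiple alignment: >=2 equal-length gapped rows."""

    records: List[SequenceRecord]

    def __post_init__(self) -> None:
        if len(self.records) < 2:
            raise ValueError("an alignment needs at least 2 rows")
        ncol = len(self.records[0].residues)
        for rec in self.records:
            if len(rec.residues) != ncol:
                raise ValueError(f"row {rec.id!r} length != {ncol}")

    @property
    def ncol(self) -> int:
        return len(self.records[0].residues)

    @property
    def ids(self) -> List[str]:
        return [r.id for r in self.records]

    @classmethod
    def from_equal_length_records(cls, records: Sequence[SequenceRecord]) -> "Alignment":
        """Treat already-homologous equal-length records as aligned rows."""
        rows = [SequenceRecord(r.id, r.residues, r.description, allow_gaps=True)
                for r in records]
        return cls(rows)


@dataclass
class CoverageStats:
    query_id: str
    aligned_query_fraction: float
    identity_fraction: float

    def __post_init__(self) -> None:
        for name in ("aligned_query_fraction", "identity_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} out of [0,1]: {v}")


def _make_aligner(mode: str, match: float, mismatch: float,
                  gap_open: float, gap_extend: float) -> "_bioalign.PairwiseAligner":
    if mode not in ("global", "semi_global"):
        raise ValueError(f"unknown mode {mode!r}")
    a = _bioalign.PairwiseAligner()
    a.mode = "global"
    a.match_score = match
    a.mismatch_score = mismatch
    a.open_gap_score = gap_open
    a.extend_gap_score = gap_extend
    if mode == "semi_global":
        a.end_insertion_score = 0.0
        a.end_deletion_score = 0.0
    return a


def pairwise_align(
    a: str,
    b: str,
    mode: str = "global",
    match: float = DEFAULT_SCORING[0],
    mismatch: float = DEFAULT_SCORING[1],
    gap_open: float = DEFAULT_SCORING[2],
    gap_extend: float = DEFAULT_SCORING[3],
) -> PairwiseAlignment:
    """Optimal affine-gap pairwise alignment.

    ``gap_open`` is the score of the first gapped base, ``gap_extend`` of
    each further base (a length-L gap scores gap_open + (L-1)*gap_extend).
    """
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    aligner = _make_aligner(mode, match, mismatch, gap_open, gap_extend)
    aln = aligner.align(a, b)[0]  # first optimal alignment: deterministic
    return PairwiseAlignment(str(aln[0]), str(aln[1]), float(aln.score), mode)


def query_coverage(
    query: SequenceRecord,
    subject: SequenceRecord,
    match: float = DEFAULT_SCORING[0],
    mismatch: float = DEFAULT_SCORING[1],
    gap_open: float = DEFAULT_SCORING[2],
    gap_extend: float = DEFAULT_SCORING[3],
) -> CoverageStats:
    """Fraction of the query aligned to subject residues (semi-global).

    Mirrors BLAST-style "query coverage": terminal gaps are free, so only
    the portion of the query that actually pairs with subject residues
    counts.  ``identity_fraction`` is computed over those aligned pairs.
    """
    aligner = _make_aligner("semi_global", match, mismatch, gap_open, gap_extend)
    aln = aligner.align(subject.residues, query.residues)[0]
    blocks = aln.aligned  # pairs of (subject, query) coordinate blocks
    aligned = 0
    identical = 0
    for (ts, te), (qs, qe) in zip(blocks[0], blocks[1]):
        aligned += te - ts
        identical += sum(
            1 for x, y in zip(subject.residues[ts:te], query.residues[qs:qe]) if x == y
        )
    qlen = len(query.residues)
    return CoverageStats(
        query_id=query.id,
        aligned_query_fraction=aligned / qlen if qlen else 0.0,
        identity_fraction=(identical / aligned) if aligned else 0.0,
    )


# ---------------------------------------------------------------------------
# progressive MSA
# ---------------------------------------------------------------------------

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def _kmer_set(seq: str, k: int = 6) -> set:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def _kmer_distance_matrix(seqs: List[str], k: int = 6) -> np.ndarray:
    sets = [_kmer_set(s, k) for s in seqs]
    n = len(seqs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            denom = min(len(sets[i]), len(sets[j]))
            shared = len(sets[i] & sets[j]) if denom else 0
            d[i, j] = d[j, i] = 1.0 - (shared / denom if denom else 0.0)
    return d


def _profile_counts(rows: List[str]) -> np.ndarray:
    """Per-column A/C/G/T frequency profile; gaps and ambiguity weigh zero."""
    ncol = len(rows[0])
    counts = np.zeros((ncol, 4))
    for row in rows:
        arr = np.frombuffer(row.encode(), dtype=np.uint8)
        for base, idx in _BASE_INDEX.items():
            counts[arr == ord(base), idx] += 1.0
    return counts / len(rows)


def _profile_align(rows_a: List[str], rows_b: List[str], match: float,
                   mismatch: float, gap_open: float, gap_extend: float
                   ) -> Tuple[List[str], List[str]]:
    """Affine-gap profile-profile alignment, row-vectorized DP."""
    fa = _profile_counts(rows_a)
    fb = _profile_counts(rows_b)
    la, lb = fa.shape[0], fb.shape[0]
    # column-pair score: expected match/mismatch over residue frequencies
    same = fa @ fb.T
    any_a = fa.sum(axis=1)[:, None]
    any_b = fb.sum(axis=1)[None, :]
    S = match * same + mismatch * (any_a * any_b - same)

    NEG = -1e12
    M = np.full((la + 1, lb + 1), NEG)
    Ix = np.full((la + 1, lb + 1), NEG)  # gap columns inserted into A (consume B)
    Iy = np.full((la + 1, lb + 1), NEG)  # gap columns inserted into B (consume A)
    ptr_m = np.zeros((la + 1, lb + 1), dtype=np.uint8)  # 0=M,1=Ix,2=Iy predecessor
    ptr_x = np.zeros((la + 1, lb + 1), dtype=np.uint8)  # 0=open(from M),1=extend
    ptr_y = np.zeros((la + 1, lb + 1), dtype=np.uint8)

    M[0, 0] = 0.0
    if lb:
        Ix[0, 1:] = gap_open + gap_extend * np.arange(lb)
        ptr_x[0, 1:] = 1
        ptr_x[0, 1] = 0
    if la:
        Iy[1:, 0] = gap_open + gap_extend * np.arange(la)
        ptr_y[1:, 0] = 1
        ptr_y[1, 0] = 0

    for i in range(1, la + 1):
        prev_m, prev_x, prev_y = M[i - 1], Ix[i - 1], Iy[i - 1]
        # M: diagonal from best of the three at (i-1, j-1)
        stack = np.vstack([prev_m[:-1], prev_x[:-1], prev_y[:-1]])
        best_prev = stack.max(axis=0)
        ptr_m[i, 1:] = stack.argmax(axis=0)
        M[i, 1:] = S[i - 1] + best_prev
        # Iy: vertical (consume A column) from row i-1
        open_y = prev_m + gap_open
        ext_y = prev_y + gap_extend
        Iy[i] = np.maximum(open_y, ext_y)
        ptr_y[i] = (ext_y > open_y).astype(np.uint8)
        # Ix: horizontal within row i — running-max recurrence
        # Ix[i,j] = max(M[i,j-1]+open, Ix[i,j-1]+extend)
        mrow = M[i]
        xrow = Ix[i]
        prow = ptr_x[i]
        run = NEG
        for j in range(1, lb + 1):
            cand_open = mrow[j - 1] + gap_open
            cand_ext = run + gap_extend
            if cand_ext > cand_open:
                xrow[j] = cand_ext
                prow[j] = 1
            else:
                xrow[j] = cand_open
                prow[j] = 0
            run = xrow[j]

    # traceback
    i, j = la, lb
    finals = (M[i, j], Ix[i, j], Iy[i, j])
    state = int(np.argmax(finals))
    cols_a: List[int] = []  # -1 marks a gap column
    cols_b: List[int] = []
    while i > 0 or j > 0:
        if state == 0:
            cols_a.append(i - 1)
            cols_b.append(j - 1)
            state = int(ptr_m[i, j])
            i -= 1
            j -= 1
        elif state == 1:
            cols_a.append(-1)
            cols_b.append(j - 1)
            state = 0 if ptr_x[i, j] == 0 else 1
            j -= 1
        else:
            cols_a.append(i - 1)
            cols_b.append(-1)
            state = 0 if ptr_y[i, j] == 0 else 2
            i -= 1
    cols_a.reverse()
    cols_b.reverse()
    out_a = ["".join(row[c] if c >= 0 else "-" for c in cols_a) for row in rows_a]
    out_b = ["".join(row[c] if c >= 0 else "-" for c in cols_b) for row in rows_b]
    return out_a, out_b


def progressive_msa(
    records: Sequence[SequenceRecord],
    match: float = DEFAULT_SCORING[0],
    mismatch: float = DEFAULT_SCORING[1],
    gap_open: float = DEFAULT_SCORING[2],
    gap_extend: float = DEFAULT_SCORING[3],
) -> Alignment:
    """Progressive multiple alignment (k-mer guide order, profile merges).

    Deterministic for fixed input order and parameters; ties in the guide
    clustering break toward the lowest index pair.
    """
    if len(records) < 2:
        raise ValueError("progressive_msa needs at least 2 records")
    seqs = [r.residues for r in records]
    d = _kmer_distance_matrix(seqs)
    n = len(seqs)
    # average-linkage agglomeration over the k-mer distance matrix
    clusters = {i: ([i], [seqs[i]]) for i in range(n)}
    next_id = n
    sizes = {i: 1 for i in range(n)}
    dd = {}
    for i in range(n):
        for j in range(i + 1, n):
            dd[(i, j)] = d[i, j]
    active = list(range(n))
    while len(active) > 1:
        best_pair = None
        best_val = None
        for ai in range(len(active)):
            for bi in range(ai + 1, len(active)):
                i, j = active[ai], active[bi]
                val = dd[(min(i, j), max(i, j))]
                if best_val is None or val < best_val:
                    best_val = val
                    best_pair = (i, j)
        i, j = best_pair
        members_i, rows_i = clusters[i]
        members_j, rows_j = clusters[j]
        new_i, new_j = _profile_align(rows_i, rows_j, match, mismatch, gap_open, gap_extend)
        clusters[next_id] = (members_i + members_j, new_i + new_j)
        for k in active:
            if k in (i, j):
                continue
            dik = dd[(min(i, k), max(i, k))]
            djk = dd[(min(j, k), max(j, k))]
            wi, wj = sizes[i], sizes[j]
            dd[(min(next_id, k), max(next_id, k))] = (wi * dik + wj * djk) / (wi + wj)
        sizes[next_id] = sizes[i] + sizes[j]
        active = [k for k in active if k not in (i, j)] + [next_id]
        del clusters[i], clusters[j]
        next_id += 1

    members, rows = clusters[active[0]]
    order = np.argsort(members)
    out = []
    for idx in order:
        src = records[members[idx]]
        out.append(SequenceRecord(src.id, rows[idx], src.description, allow_gaps=True))
    return Alignment(out)
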