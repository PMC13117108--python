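"""Targeted read recruitment against a bait sequence and reference-guided
majority-rule consensus of a marker region, with junction-support checks
for indels.

Each read is aligned semi-globally to the bait in both orientations and
recruited when its best alignment reaches the identity/overlap thresholds.
The consensus is a per-column plurality vote over the recruited pileup:
a gap plurality deletes the bait column, and insertions are emitted when a
plurality of junction-spanning reads support identical inserted bases.
Uncovered bait columns emit ``N``.  Indel calls can be corroborated by
counting reads that contain the exact joint flanking sequence across the
junction.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from Bio import Align as _bioalign

from .seqcore import ReadRecord, SequenceRecord, reverse_complement

__all__ = [
    "ReadAlignment",
    "RecruitmentSet",
    "Pileup",
    "IndelCall",
    "ConsensusResult",
    "recruit_reads",
    "build_consensus",
    "check_junction_support",
]

logger = logging.getLogger(__name__)

_BASES = "ACGT"
_GAP = 4  # row index of the gap vote in the pileup count matrix


@dataclass
class ReadAlignment:
    """A recruited read's placement on the bait (plus-strand coordinates)."""

    read_id: str
    orientation: str  # '+' or '-'
    score: float
    identity: float
    aligned_bases: int
    target_blocks: List[Tuple[int, int]]  # bait coordinate blocks
    query_blocks: List[Tuple[int, int]]   # oriented-read coordinate blocks
    oriented_seq: str

    @property
    def span(self) -> Tuple[int, int]:
        return self.target_blocks[0][0], self.target_blocks[-1][1]


@dataclass
class RecruitmentSet:
    bait: SequenceRecord
    recruited: List[Tuple[ReadRecord, ReadAlignment]]
    rejected: int
    min_identity: float
    min_overlap: int


@dataclass
class Pileup:
    """Per-bait-column base counts plus insertion votes keyed by position."""

    counts: np.ndarray  # (bait_length, 5): A, C, G, T, gap
    insertions: Dict[int, Counter]  # bait pos p -> Counter of inserted strings
    junction_cover: Dict[int, int]  # bait pos p -> reads spanning (p-1, p)

    def depth(self, col: int) -> int:
        return int(self.counts[col].sum())


@dataclass
class IndelCall:
    kind: str  # 'insertion' | 'deletion'
    bait_position: int
    consensus_position: int
    length: int
    sequence: str = ""


@dataclass
class ConsensusResult:
    consensus: SequenceRecord
    depth: List[int]  # per consensus column
    indels: List[IndelCall]
    contested_columns: List[int] = field(default_factory=list)  # bait coords
    uncovered_columns: List[int] = field(default_factory=list)  # bait coords


def _aligner(match: float = 1.0, mismatch: float = -1.0,
             gap_open: float = -4.0, gap_extend: float = -1.0):
    a = _bioalign.PairwiseAligner()
    a.mode = "global"
    a.match_score = match
    a.mismatch_score = mismatch
    a.open_gap_score = gap_open
    a.extend_gap_score = gap_extend
    a.end_insertion_score = 0.0
    a.end_deletion_score = 0.0
    return a


def _kmer_index(seq: str, k: int) -> set:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def recruit_reads(
    reads: Sequence[ReadRecord],
    bait: SequenceRecord,
    min_identity: float = 0.90,
    min_overlap: int = 50,
    use_prefilter: bool = False,
    prefilter_k: int = 16,
) -> RecruitmentSet:
    """Semi-global alignment of each read to the bait in both orientations.

    A read is recruited iff its better orientation reaches ``min_identity``
    over at least ``min_overlap`` aligned bases.  The optional exact-k-mer
    prefilter skips alignment of reads sharing no k-mer with the bait in
    either orientation; it is behavior-neutral whenever matching reads
    retain an exact 16-mer, which holds at low error rates.
    """
    if not reads:
        raise ValueError("no reads supplied")
    aligner = _aligner()
    bait_seq = bait.residues
    bait_kmers = _kmer_index(bait_seq, prefilter_k) if use_prefilter else None
    recruited: List[Tuple[ReadRecord, ReadAlignment]] = []
    rejected = 0
    for read in reads:
        best: Optional[ReadAlignment] = None
        for orientation, seq in (("+", read.residues), ("-", reverse_complement(read.residues))):
            if bait_kmers is not None and not (_kmer_index(seq, prefilter_k) & bait_kmers):
                continue
            aln = aligner.align(bait_seq, seq)[0]
            tb, qb = aln.aligned
            aligned = int(sum(e - s for s, e in tb))
            if aligned == 0:
                continue
            identical = 0
            for (ts, te), (qs, qe) in zip(tb, qb):
                identical += sum(1 for x, y in zip(bait_seq[ts:te], seq[qs:qe]) if x == y)
            cand = ReadAlignment(
                read_id=read.id,
                orientation=orientation,
                score=float(aln.score),
                identity=identical / aligned,
                aligned_bases=aligned,
                target_blocks=[(int(s), int(e)) for s, e in tb],
                query_blocks=[(int(s), int(e)) for s, e in qb],
                oriented_seq=seq,
            )
            if best is None or cand.score > best.score:
                best = cand
        if best is not None and best.identity >= min_identity and best.aligned_bases >= min_overlap:
            recruited.append((read, best))
        else:
            rejected += 1
    return RecruitmentSet(bait, recruited, rejected, min_identity, min_overlap)


def build_pileup(rset: RecruitmentSet) -> Pileup:
    L = len(rset.bait)
    counts = np.zeros((L, 5), dtype=np.int64)
    insertions: Dict[int, Counter] = {}
    junction_cover: Dict[int, int] = {}
    base_row = {b: i for i, b in enumerate(_BASES)}
    spans = []
    ins_by_read: List[Dict[int, str]] = []
    for _, ra in rset.recruited:
        seq = ra.oriented_seq
        read_ins: Dict[int, str] = {}
        prev_t = prev_q = None
        for (ts, te), (qs, qe) in zip(ra.target_blocks, ra.query_blocks):
            if prev_t is not None:
                if ts > prev_t:  # bait bases absent from the read: gap votes
                    counts[prev_t:ts, _GAP] += 1
                if qs > prev_q:  # read bases absent from the bait: insertion
                    read_ins[ts if ts > prev_t else prev_t] = seq[prev_q:qs]
            for t, q in zip(range(ts, te), range(qs, qe)):
                row = base_row.get(seq[q])
                if row is not None:
                    counts[t, row] += 1
            prev_t, prev_q = te, qe
        # normalize insertion keys to the bait position they precede
        norm_ins = {}
        for pos, s in read_ins.items():
            norm_ins[pos] = s
        ins_by_read.append(norm_ins)
        spans.append(ra.span)
    for (start, end), read_ins in zip(spans, ins_by_read):
        for p in range(max(1, start + 1), min(L, end)):
            junction_cover[p] = junction_cover.get(p, 0) + 1
        for pos, s in read_ins.items():
            insertions.setdefault(pos, Counter())[s] += 1
    return Pileup(counts, insertions, junction_cover)


def build_consensus(rset: RecruitmentSet) -> ConsensusResult:
    """Majority-rule reference-guided consensus over the recruited pileup.

    Plurality ties resolve to the bait base (conservative reference bias)
    and are logged as contested.  An insertion is emitted at a junction
    when more junction-spanning reads carry an identical inserted string
    than carry none.
    """
    if not rset.recruited:
        raise ValueError("cannot build a consensus from an empty recruitment set")
    pileup = build_pileup(rset)
    bait_seq = rset.bait.residues
    L = len(bait_seq)
    out: List[str] = []
    depth: List[int] = []
    indels: List[IndelCall] = []
    contested: List[int] = []
    uncovered: List[int] = []

    for col in range(L):
        # insertion junction between col-1 and col
        if col in pileup.insertions:
            votes = pileup.insertions[col]
            ins_seq, ins_count = max(votes.items(), key=lambda kv: (kv[1], kv[0]))
            no_ins = pileup.junction_cover.get(col, 0) - sum(votes.values())
            if ins_count > max(no_ins, 0) and ins_count > sum(
                c for s, c in votes.items() if s != ins_seq
            ):
                indels.append(IndelCall("insertion", col, len(out), len(ins_seq), ins_seq))
                out.append(ins_seq)
                depth.extend([ins_count] * len(ins_seq))
        column = pileup.counts[col]
        cov = int(column.sum())
        if cov == 0:
            out.append("N")
            depth.append(0)
            uncovered.append(col)
            continue
        best = int(column.max())
        winners = [i for i in range(5) if column[i] == best]
        if len(winners) > 1:
            contested.append(col)
            bait_row = _BASES.find(bait_seq[col])
            choice = bait_row if bait_row in winners else winners[0]
            logger.info("contested column %d resolved to %s", col,
                        "-" if choice == _GAP else _BASES[choice])
        else:
            choice = winners[0]
        if choice == _GAP:
            indels.append(IndelCall("deletion", col, len(out), 1))
            continue
        out.append(_BASES[choice])
        depth.append(cov)

    consensus = SequenceRecord(
        f"{rset.bait.id}|consensus",
        "".join(out),
        f"reference-guided consensus of {len(rset.recruited)} reads",
    )
    # merge runs of adjacent single-column deletions into one call
    merged: List[IndelCall] = []
    for call in indels:
        if (merged and call.kind == "deletion" and merged[-1].kind == "deletion"
                and call.bait_position == merged[-1].bait_position + merged[-1].length):
            prev = merged[-1]
            merged[-1] = IndelCall("deletion", prev.bait_position,
                                   prev.consensus_position, prev.length + 1)
        else:
            merged.append(call)
    return ConsensusResult(consensus, depth, merged, contested, uncovered)


def check_junction_support(
    reads: Sequence[ReadRecord],
    consensus: SequenceRecord,
    indel_position: int,
    flank: int = 25,
) -> int:
    """Count reads containing the exact joint flanking sequence spanning
    the indel junction at ``indel_position`` (consensus coordinates),
    in either orientation.  Windows hitting a sequence end are truncated
    (logged)."""
    seq = consensus.residues
    if not 0 <= indel_position <= len(seq):
        raise ValueError(f"indel position {indel_position} outside consensus")
    lo = indel_position - flank
    hi = indel_position + flank
    if lo < 0 or hi > len(seq):
        logger.info("junction window at %d truncated to sequence bounds", indel_position)
        lo = max(lo, 0)
        hi = min(hi, len(seq))
    window = seq[lo:hi]
    if not window:
        return 0
    window_rc = reverse_complement(window)
    return sum(1 for r in reads if window in r.residues or window_rc in r.residues)
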