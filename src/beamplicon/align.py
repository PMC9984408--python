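"""Semi-global read-to-amplicon alignment.

The read is aligned globally while amplicon overhangs are free (no penalty
for unaligned reference flanks), which is the natural geometry for an
amplicon-sequencing read that covers a substring of the PCR reference.  Gaps
are affine: a gap of length L costs ``gap_open + L * gap_extend``.

The dynamic programming itself is delegated to Biopython's PairwiseAligner
(C implementation); this module translates its output into per-amplicon-offset
base calls and explicit indel intervals, which is what the quantification
stage consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

from Bio import Align

from beamplicon.io import Read, TargetSite


@dataclass(frozen=True)
class ScoringScheme:
    """Alignment scores; gap of length L costs gap_open + L*gap_extend."""

    match: int = 2
    mismatch: int = -1
    gap_open: int = -6
    gap_extend: int = -1

    def __post_init__(self) -> None:
        if self.match <= 0:
            raise ValueError("match score must be positive")
        if self.mismatch >= 0 or self.gap_open >= 0 or self.gap_extend >= 0:
            raise ValueError("mismatch and gap penalties must be negative")

    def max_score(self, read_length: int) -> int:
        return self.match * read_length


@dataclass
class Alignment:
    """A read-to-amplicon alignment in amplicon coordinates.

    ``aligned_bases`` maps amplicon offsets to read bases for match/mismatch
    columns only.  ``deletions`` are amplicon intervals (0-based half-open)
    absent from the read; ``insertions`` are (amplicon offset, length) pairs
    for read bases inserted immediately before that offset.
    """

    read_id: str
    score: float
    ref_start: int
    ref_end: int
    aligned_bases: dict[int, str]
    deletions: list[tuple[int, int]] = field(default_factory=list)
    insertions: list[tuple[int, int]] = field(default_factory=list)
    ops: list[tuple[str, int]] = field(default_factory=list)

    def has_indel_in(self, window_start: int, window_end: int) -> bool:
        """True if any indel overlaps the amplicon window [start, end)."""
        for d0, d1 in self.deletions:
            if d0 < window_end and d1 > window_start:
                return True
        for pos, _length in self.insertions:
            if window_start < pos < window_end:
                return True
        return False

    def covers(self, start: int, end: int) -> bool:
        return self.ref_start <= start and self.ref_end >= end


@lru_cache(maxsize=8)
def _make_aligner(scheme: ScoringScheme) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = scheme.match
    aligner.mismatch_score = scheme.mismatch
    # Biopython scores the first gap base with open_gap_score and the rest
    # with extend_gap_score; our convention charges open once plus extend per
    # base, so the first base carries open+extend.
    aligner.open_gap_score = scheme.gap_open + scheme.gap_extend
    aligner.extend_gap_score = scheme.gap_extend
    # free end gaps against amplicon overhangs only: the read stays global.
    # (A "deletion" in Biopython's naming is a gap in the query row, i.e. the
    # read skipping reference bases; at the sequence ends these are the
    # unaligned amplicon flanks.)
    aligner.open_end_deletion_score = 0.0
    aligner.extend_end_deletion_score = 0.0
    return aligner


def align_read(read: Read, site: TargetSite,
               scoring: ScoringScheme = ScoringScheme()) -> Alignment:
    """Optimal semi-global alignment of a read against the site's amplicon.

    Among co-optimal alignments, Biopython's first reported alignment is used;
    this choice is deterministic for fixed inputs.
    """
    aligner = _make_aligner(scoring)
    aln = aligner.align(site.amplicon, read.sequence)[0]
    blocks_t, blocks_q = aln.aligned  # target (amplicon) and query (read) runs

    aligned_bases: dict[int, str] = {}
    deletions: list[tuple[int, int]] = []
    insertions: list[tuple[int, int]] = []
    ops: list[tuple[str, int]] = []

    def _push(op: str, length: int) -> None:
        if length <= 0:
            return
        if ops and ops[-1][0] == op:
            ops[-1] = (op, ops[-1][1] + length)
        else:
            ops.append((op, length))

    prev_t = prev_q = None
    for (t0, t1), (q0, q1) in zip(blocks_t, blocks_q):
        if prev_t is not None:
            if t0 > prev_t:  # amplicon bases skipped: deletion in the read
                deletions.append((prev_t, t0))
                _push("deletion", t0 - prev_t)
            if q0 > prev_q:  # read bases with no amplicon partner: insertion
                insertions.append((t0, q0 - prev_q))
                _push("insertion", q0 - prev_q)
        for k in range(t1 - t0):
            ref_off = t0 + k
            base = read.sequence[q0 + k]
            aligned_bases[ref_off] = base
            _push("match" if site.amplicon[ref_off] == base else "mismatch", 1)
        prev_t, prev_q = t1, q1

    if not blocks_t.size:
        return Alignment(read_id=read.id, score=aln.score, ref_start=0,
                         ref_end=0, aligned_bases={}, ops=[])
    return Alignment(
        read_id=read.id,
        score=aln.score,
        ref_start=int(blocks_t[0][0]),
        ref_end=int(blocks_t[-1][1]),
        aligned_bases=aligned_bases,
        deletions=deletions,
        insertions=insertions,
        ops=ops,
    )
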