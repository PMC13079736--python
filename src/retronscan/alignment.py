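"""Read-vs-reference alignment.

Scoring follows a conventional local-alignment parameterization: match +1,
mismatch -2, gap open -4 (charged on the first gapped base), gap extend -1.
Two modes are exposed:

* :func:`align_local` -- Smith-Waterman local alignment (short reads);
* :func:`align_overlap` -- end-gap-free global alignment (full-length
  amplicon long reads; the read and reference overlap freely at the ends).

Both run a tiered strategy: exact substring match, then a seeded ungapped
placement that is accepted only when a prefix/suffix score guard proves no
end-trimming (and, under this scoring, no gap) can improve on it, and
finally the full dynamic program (Bio.Align.PairwiseAligner's C engine).
The guard makes the fast path exact, not approximate: whenever it fires the
returned alignment has optimal local score.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from Bio import Align

MATCH = 1
MISMATCH = -2
GAP_OPEN = -4
GAP_EXTEND = -1

#: events are (type, ref_pos, read_bases, ref_bases)
Event = Tuple[str, int, str, str]


@dataclass
class AlignmentRecord:
    """A read-vs-reference alignment with explicit mismatch/indel events.

    ``ref_start``/``ref_end`` and ``read_start``/``read_end`` are 0-based
    half-open aligned intervals.  ``events`` are sorted by reference
    position; insertions record the reference position *before which* the
    extra read bases sit.  ``shifted`` marks alignments whose reference
    start deviates from the expected amplicon start by more than the
    configured tolerance.
    """

    read_id: str
    read_seq: str
    ref_start: int
    ref_end: int
    read_start: int
    read_end: int
    score: float
    events: List[Event] = field(default_factory=list)
    shifted: bool = False

    @property
    def aligned_len(self) -> int:
        """Reference span of the alignment in nt."""
        return self.ref_end - self.ref_start

    @property
    def n_mismatch(self) -> int:
        return sum(1 for e in self.events if e[0] == "mismatch")

    @property
    def has_indel(self) -> bool:
        return any(e[0] in ("insertion", "deletion") for e in self.events)

    @property
    def net_indel(self) -> int:
        return sum(
            len(e[2]) if e[0] == "insertion" else -len(e[3])
            for e in self.events
            if e[0] in ("insertion", "deletion")
        )

    # -- reconstructions ---------------------------------------------------

    def window_read_seq(self, ref: str, wstart: int, wend: int) -> Optional[str]:
        """Read bases aligned to reference window [wstart, wend).

        Inserted bases whose anchor lies inside the window are included and
        deleted reference bases contribute nothing, so the result carries the
        read's true indel structure over the window.  Returns None when the
        alignment does not span the window.
        """
        return self._walk(ref, wstart, wend, project=False)

    def projected(self, ref: str, wstart: int, wend: int) -> Optional[str]:
        """Substitution-only projection onto reference window [wstart, wend).

        Insertions are removed and deletions are filled with reference bases,
        so the output length always equals the window length.  Returns None
        when the alignment does not span the window.
        """
        return self._walk(ref, wstart, wend, project=True)

    def _walk(self, ref: str, wstart: int, wend: int, project: bool) -> Optional[str]:
        if self.ref_start > wstart or self.ref_end < wend:
            return None
        if not self.events:
            seg = self.read_seq[
                self.read_start + (wstart - self.ref_start) : self.read_start + (wend - self.ref_start)
            ]
            return seg
        out: List[str] = []
        ref_pos = self.ref_start
        read_pos = self.read_start

        def emit(read_bases: str, start_ref: int) -> None:
            # append read bases for matched columns overlapping the window
            lo = max(wstart, start_ref)
            hi = min(wend, start_ref + len(read_bases))
            if hi > lo:
                out.append(read_bases[lo - start_ref : hi - start_ref])

        for etype, pos, read_bases, ref_bases in self.events:
            span = pos - ref_pos  # matched/mismatched columns before the event
            emit(self.read_seq[read_pos : read_pos + span], ref_pos)
            ref_pos += span
            read_pos += span
            if etype == "mismatch":
                emit(self.read_seq[read_pos : read_pos + len(read_bases)], ref_pos)
                ref_pos += len(read_bases)
                read_pos += len(read_bases)
            elif etype == "insertion":
                if not project and wstart <= pos < wend:
                    out.append(read_bases)
                read_pos += len(read_bases)
            elif etype == "deletion":
                if project:
                    lo, hi = max(wstart, pos), min(wend, pos + len(ref_bases))
                    if hi > lo:
                        out.append(ref[lo:hi])
                ref_pos += len(ref_bases)
        emit(self.read_seq[read_pos : read_pos + (self.ref_end - ref_pos)], ref_pos)
        return "".join(out)


class ReferenceIndex:
    """Exact k-mer index of a reference for seeded read placement."""

    def __init__(self, ref: str, k: int = 16):
        self.ref = ref
        self.k = k
        self.arr = np.frombuffer(ref.encode(), dtype=np.uint8)
        index: Dict[str, List[int]] = {}
        for i in range(len(ref) - k + 1):
            index.setdefault(ref[i : i + k], []).append(i)
        self._index = index

    def candidates(self, read: str, n_seeds: int = 4) -> List[int]:
        """Candidate ungapped offsets of ``read`` on the reference."""
        L = len(read)
        if L < self.k:
            return []
        positions = sorted({0, max(0, (L - self.k) // 2), L - self.k, max(0, (L - self.k) // 3)})[:n_seeds]
        offsets: List[int] = []
        for p in positions:
            for hit in self._index.get(read[p : p + self.k], ()):
                o = hit - p
                if 0 <= o <= len(self.ref) - L and o not in offsets:
                    offsets.append(o)
        return offsets


def _mismatch_events(read_arr: np.ndarray, ref_arr: np.ndarray, offset: int,
                     read: str, ref: str, read_off: int = 0) -> List[Event]:
    diff = np.flatnonzero(read_arr != ref_arr)
    return [
        ("mismatch", offset + int(i), read[read_off + int(i)], ref[offset + int(i)])
        for i in diff
    ]


def _ungapped_guard_ok(mism: np.ndarray) -> bool:
    """True when no end-trimming can raise the ungapped local score.

    Trimming k terminal columns containing t mismatches changes the score by
    3t - k; the placement is locally optimal iff this is <= 0 for every
    prefix and suffix.  Under +1/-2/-4/-1 scoring a mismatch column can never
    be profitably replaced by gap columns, so passing the guard certifies
    Smith-Waterman optimality of the full-width placement.
    """
    L = len(mism)
    k = np.arange(1, L + 1)
    pref = np.cumsum(mism)
    if np.any(3 * pref > k):
        return False
    suff = np.cumsum(mism[::-1])
    return not np.any(3 * suff > k)


_LOCAL_ALIGNER = Align.PairwiseAligner(
    mode="local", match_score=MATCH, mismatch_score=MISMATCH,
    open_gap_score=GAP_OPEN, extend_gap_score=GAP_EXTEND,
)
_OVERLAP_ALIGNER = Align.PairwiseAligner(
    mode="global", match_score=MATCH, mismatch_score=MISMATCH,
    open_gap_score=GAP_OPEN, extend_gap_score=GAP_EXTEND,
)
# free end gaps on both sequences: overlap alignment
for _attr in ("open_end_insertion_score", "extend_end_insertion_score",
              "open_end_deletion_score", "extend_end_deletion_score"):
    setattr(_OVERLAP_ALIGNER, _attr, 0.0)


def _events_from_biopython(aln, ref: str, read: str) -> Tuple[int, int, int, int, List[Event]]:
    coords = aln.coordinates
    events: List[Event] = []
    ref_start, read_start = int(coords[0, 0]), int(coords[1, 0])
    for i in range(coords.shape[1] - 1):
        t0, t1 = int(coords[0, i]), int(coords[0, i + 1])
        q0, q1 = int(coords[1, i]), int(coords[1, i + 1])
        if t1 > t0 and q1 > q0:  # diagonal block
            sub_ref = ref[t0:t1]
            sub_read = read[q0:q1]
            for j, (a, b) in enumerate(zip(sub_read, sub_ref)):
                if a != b:
                    events.append(("mismatch", t0 + j, a, b))
        elif t1 > t0:  # gap in read: deletion from the reference
            events.append(("deletion", t0, "", ref[t0:t1]))
        elif q1 > q0:  # gap in reference: insertion of read bases
            events.append(("insertion", t0, read[q0:q1], ""))
    ref_end, read_end = int(coords[0, -1]), int(coords[1, -1])
    return ref_start, ref_end, read_start, read_end, events


def _dp_align(aligner, read: str, ref: str, read_id: str) -> Optional[AlignmentRecord]:
    alns = aligner.align(ref, read)
    if len(alns) == 0:
        return None
    aln = alns[0]
    ref_start, ref_end, read_start, read_end, events = _events_from_biopython(aln, ref, read)
    if aligner.mode == "global":
        # strip end gaps (they are free) so the record reflects the overlap
        while events and events[0][0] == "deletion" and events[0][1] == ref_start:
            ref_start += len(events[0][3]); events.pop(0)
        while events and events[0][0] == "insertion" and events[0][1] == ref_start and read_start == 0:
            read_start += len(events[0][2]); events.pop(0)
        while events and events[-1][0] == "deletion" and events[-1][1] + len(events[-1][3]) == ref_end:
            ref_end = events[-1][1]; events.pop()
        while events and events[-1][0] == "insertion" and events[-1][1] == ref_end:
            read_end -= len(events[-1][2]); events.pop()
    return AlignmentRecord(
        read_id=read_id, read_seq=read, ref_start=ref_start, ref_end=ref_end,
        read_start=read_start, read_end=read_end, score=float(aln.score),
        events=events,
    )


def _try_fast(read: str, index: ReferenceIndex, read_id: str) -> Optional[AlignmentRecord]:
    ref = index.ref
    pos = ref.find(read)
    if pos >= 0:
        return AlignmentRecord(read_id, read, pos, pos + len(read), 0, len(read), float(len(read)))
    read_arr = np.frombuffer(read.encode(), dtype=np.uint8)
    best: Optional[Tuple[float, int, np.ndarray]] = None
    for o in index.candidates(read):
        mism = (read_arr != index.arr[o : o + len(read)])
        m = int(mism.sum())
        score = len(read) - 3 * m
        if best is None or score > best[0]:
            best = (score, o, mism)
    if best is None:
        return None
    score, o, mism = best
    if not _ungapped_guard_ok(mism):
        return None
    events = _mismatch_events(read_arr, index.arr[o : o + len(read)], o, read, ref)
    return AlignmentRecord(read_id, read, o, o + len(read), 0, len(read), float(score), events)


def align_local(
    read: str,
    reference,
    read_id: str = "",
    expected_start: Optional[int] = None,
    start_tolerance: int = 3,
    min_score: Optional[float] = None,
    fast: bool = True,
) -> Optional[AlignmentRecord]:
    """Best local alignment of ``read`` against the reference.

    ``reference`` may be a sequence string or a prebuilt
    :class:`ReferenceIndex` (recommended when aligning many reads).  Returns
    None when no alignment reaches ``min_score`` (default: half the read
    length).  When ``expected_start`` is given, alignments starting more than
    ``start_tolerance`` nt away are flagged ``shifted``.
    """
    if len(read) < 20:
        raise ValueError("read shorter than 20 nt")
    index = reference if isinstance(reference, ReferenceIndex) else ReferenceIndex(reference)
    if min_score is None:
        min_score = 0.5 * len(read)
    rec = _try_fast(read, index, read_id) if fast else None
    if rec is None:
        rec = _dp_align(_LOCAL_ALIGNER, read, index.ref, read_id)
    if rec is None or rec.score < min_score:
        return None
    if expected_start is not None:
        rec.shifted = abs(rec.ref_start - expected_start) > start_tolerance
    return rec


def align_overlap(
    read: str,
    reference,
    read_id: str = "",
    min_score: Optional[float] = None,
    fast: bool = True,
) -> Optional[AlignmentRecord]:
    """End-gap-free alignment of a full-length amplicon read."""
    index = reference if isinstance(reference, ReferenceIndex) else ReferenceIndex(reference)
    if min_score is None:
        min_score = 0.5 * min(len(read), len(index.ref))
    rec = None
    if fast and len(read) <= len(index.ref):
        rec = _try_fast(read, index, read_id)
    if rec is None:
        rec = _dp_align(_OVERLAP_ALIGNER, read, index.ref, read_id)
    if rec is None or rec.score < min_score:
        return None
    return rec
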