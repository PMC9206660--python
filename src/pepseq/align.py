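"""Global pairwise alignment of target-site reads to the reference amplicon.

Needleman–Wunsch with an affine gap model: match +1, mismatch −1, gap open
−5, gap extension 0 — a gap of any length costs 5. End gaps are scored like
internal gaps. Traceback ties are broken deterministically with priority
diagonal > up (gap in reference) > left (gap in query); the choice only
affects the placement of equivalent gaps, never the score.

The implementation is a three-state Gotoh dynamic program kept in plain
Python because downstream filtering needs per-column events (with reference
coordinates and query offsets, so PHRED qualities can be attached) and a
documented tie-break, neither of which library aligners pin down. Scores
are cross-checked against Bio.Align.PairwiseAligner in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

NEG_INF = float("-inf")

MATCH = 1.0
MISMATCH = -1.0
GAP_OPEN = -5.0
GAP_EXTEND = 0.0


@dataclass(frozen=True)
class AlnEvent:
    """One alignment event in reference coordinates.

    ``match``/``mismatch`` events span a single column. ``insertion`` events
    have an empty reference span (``ref_start == ref_end`` is the insertion
    point); ``deletion`` events have an empty query span. Query coordinates
    index the ungapped query, so qualities can be looked up directly.
    """

    kind: str  # match | mismatch | insertion | deletion
    ref_start: int
    ref_end: int
    q_start: int
    q_end: int

    @property
    def length(self) -> int:
        return max(self.ref_end - self.ref_start, self.q_end - self.q_start)


@dataclass
class Alignment:
    """A global alignment with its score and per-column event list."""

    query_aligned: str
    ref_aligned: str
    score: float
    events: list[AlnEvent]

    @property
    def query(self) -> str:
        return self.query_aligned.replace("-", "")

    @property
    def ref(self) -> str:
        return self.ref_aligned.replace("-", "")

    @classmethod
    def from_aligned(cls, query_aligned: str, ref_aligned: str, score: float) -> "Alignment":
        if len(query_aligned) != len(ref_aligned):
            raise ValueError("aligned strings must have equal length")
        return cls(query_aligned, ref_aligned, score, _extract_events(query_aligned, ref_aligned))


def _extract_events(qa: str, ra: str) -> list[AlnEvent]:
    events: list[AlnEvent] = []
    ref_pos = 0
    q_pos = 0
    i = 0
    n = len(qa)
    while i < n:
        qc, rc = qa[i], ra[i]
        if qc != "-" and rc != "-":
            kind = "match" if qc == rc else "mismatch"
            events.append(AlnEvent(kind, ref_pos, ref_pos + 1, q_pos, q_pos + 1))
            ref_pos += 1
            q_pos += 1
            i += 1
        elif rc == "-":  # gap run in reference: insertion
            j = i
            while j < n and ra[j] == "-":
                j += 1
            events.append(AlnEvent("insertion", ref_pos, ref_pos, q_pos, q_pos + (j - i)))
            q_pos += j - i
            i = j
        else:  # gap run in query: deletion
            j = i
            while j < n and qa[j] == "-":
                j += 1
            events.append(AlnEvent("deletion", ref_pos, ref_pos + (j - i), q_pos, q_pos))
            ref_pos += j - i
            i = j
    return events


def align_target(
    query: str,
    ref: str,
    match: float = MATCH,
    mismatch: float = MISMATCH,
    gap_open: float = GAP_OPEN,
    gap_extend: float = GAP_EXTEND,
) -> Alignment:
    """Optimal global alignment of a read to the reference amplicon.

    Three-state Gotoh DP; a length-L gap costs ``gap_open + (L-1)·gap_extend``.
    Ties are resolved diagonal > up > left at every traceback step.
    """
    if not query or not ref:
        raise ValueError("both sequences must be non-empty")
    n, m = len(query), len(ref)

    # D = diagonal end, U = query-consuming gap (gap in ref), L = ref-consuming gap
    D = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    U = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    L = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    D[0][0] = 0.0
    for i in range(1, n + 1):
        U[i][0] = gap_open + (i - 1) * gap_extend
    for j in range(1, m + 1):
        L[0][j] = gap_open + (j - 1) * gap_extend

    for i in range(1, n + 1):
        qc = query[i - 1]
        Di1, Ui1, Li1 = D[i - 1], U[i - 1], L[i - 1]
        Di, Ui, Li = D[i], U[i], L[i]
        for j in range(1, m + 1):
            s = match if qc == ref[j - 1] else mismatch
            Di[j] = max(Di1[j - 1], Ui1[j - 1], Li1[j - 1]) + s
            Ui[j] = max(Di1[j] + gap_open, Ui1[j] + gap_extend, Li1[j] + gap_open)
            Li[j] = max(Di[j - 1] + gap_open, Ui[j - 1] + gap_open, Li[j - 1] + gap_extend)

    # traceback, priority D > U > L
    i, j = n, m
    state = _argmax3(D[i][j], U[i][j], L[i][j])
    score = (D[i][j], U[i][j], L[i][j])[state]
    qa: list[str] = []
    ra: list[str] = []
    while i > 0 or j > 0:
        if state == 0:  # diagonal
            s = match if query[i - 1] == ref[j - 1] else mismatch
            state = _pick_state(D[i - 1][j - 1], U[i - 1][j - 1], L[i - 1][j - 1], D[i][j] - s)
            qa.append(query[i - 1])
            ra.append(ref[j - 1])
            i -= 1
            j -= 1
        elif state == 1:  # up: consume query, gap in reference
            val = U[i][j]
            if D[i - 1][j] + gap_open == val:
                state = 0
            elif U[i - 1][j] + gap_extend == val:
                state = 1
            else:
                state = 2
            qa.append(query[i - 1])
            ra.append("-")
            i -= 1
        else:  # left: consume ref, gap in query
            val = L[i][j]
            if D[i][j - 1] + gap_open == val:
                state = 0
            elif U[i][j - 1] + gap_open == val:
                state = 1
            else:
                state = 2
            qa.append("-")
            ra.append(ref[j - 1])
            j -= 1
    qa.reverse()
    ra.reverse()
    return Alignment.from_aligned("".join(qa), "".join(ra), score)


def _argmax3(a: float, b: float, c: float) -> int:
    if a >= b and a >= c:
        return 0
    if b >= c:
        return 1
    return 2


def _pick_state(d: float, u: float, l: float, target: float) -> int:
    if d == target:
        return 0
    if u == target:
        return 1
    return 2


def gapless_alignment(query: str, ref: str) -> Alignment:
    """The trivial gap-free alignment of two equal-length sequences.

    With the default scoring, a gap-free alignment of equal-length sequences
    with h mismatches scores L − 2h, while any gapped alternative scores at
    most L − d − 10 for indel length d ≥ 1; the gap-free alignment is
    therefore strictly optimal whenever h ≤ 5. Callers use this as a fast
    path and must enforce that bound.
    """
    if len(query) != len(ref):
        raise ValueError("gapless alignment requires equal lengths")
    h = sum(1 for a, b in zip(query, ref) if a != b)
    return Alignment.from_aligned(query, ref, float(len(query) - 2 * h))
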