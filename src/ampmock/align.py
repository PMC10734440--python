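"""Scored pairwise alignment shared by chimera detection, error profiling
and OTU clustering.

One scoring convention is used everywhere: match +1, mismatch -1, gap open
-4 plus -1 per gapped base, terminal (end) gaps free. Identity is reported
as matched columns over query length, so unaligned query tails count
against identity but not as explicit errors.

`edlib` provides a fast unit-cost edit-distance screen used to shortlist
references before scored alignment; the scored alignment itself is always
Biopython's PairwiseAligner.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import edlib
import numpy as np
from Bio import Align

# per-column operation kinds
MATCH = "match"
SUB = "sub"
INS = "ins"  # query base absent from target; attributed to preceding target position
DEL = "del"  # target base skipped by the query


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    # biopython affine convention: a gap of length k scores open + (k-1)*extend;
    # open=-5/extend=-1 realises "open -4 plus -1 per gapped base".
    aligner.open_gap_score = -5.0
    aligner.extend_gap_score = -1.0
    aligner.end_gap_score = 0.0
    return aligner


_ALIGNER = _make_aligner()


@dataclass(frozen=True)
class PairAlignment:
    """Per-column view of one query-vs-target alignment."""

    query: str
    target: str
    score: float
    matches: int
    mismatches: int
    insertions: int
    deletions: int
    #: bool per query position: aligned to target and identical
    query_match: tuple
    #: (kind, target_pos, query_pos) per column; INS carries the preceding
    #: target position, DEL carries query_pos of -1
    ops: tuple

    @property
    def identity_pct(self) -> float:
        """Percent identity: matched columns / query length x 100."""
        return 100.0 * self.matches / len(self.query) if self.query else 0.0

    @property
    def differences(self) -> int:
        """Mismatches plus internal gapped bases."""
        return self.mismatches + self.insertions + self.deletions

    @property
    def aligned_query_bases(self) -> int:
        """Valid (aligned, non-gap) query bases: matches + mismatches."""
        return self.matches + self.mismatches


@lru_cache(maxsize=300_000)
def align_pair(query: str, target: str) -> PairAlignment:
    """Globally align query to target with free end gaps; cached."""
    if not query or not target:
        raise ValueError("align_pair requires non-empty sequences")
    alignment = _ALIGNER.align(target, query)[0]
    tgt_blocks, qry_blocks = alignment.aligned
    qmatch = np.zeros(len(query), dtype=bool)
    ops: list[tuple[str, int, int]] = []
    matches = mismatches = insertions = deletions = 0
    prev_t_end: int | None = None
    prev_q_end: int | None = None
    for (ts, te), (qs, qe) in zip(tgt_blocks, qry_blocks):
        if prev_t_end is not None:
            # internal gaps between aligned blocks
            for tp in range(prev_t_end, ts):
                ops.append((DEL, tp, -1))
                deletions += 1
            for qp in range(prev_q_end, qs):
                ops.append((INS, prev_t_end - 1, qp))
                insertions += 1
        for off in range(te - ts):
            tp, qp = ts + off, qs + off
            if target[tp] == query[qp]:
                qmatch[qp] = True
                matches += 1
                ops.append((MATCH, tp, qp))
            else:
                mismatches += 1
                ops.append((SUB, tp, qp))
        prev_t_end, prev_q_end = te, qe
    return PairAlignment(
        query=query,
        target=target,
        score=alignment.score,
        matches=matches,
        mismatches=mismatches,
        insertions=insertions,
        deletions=deletions,
        query_match=tuple(qmatch.tolist()),
        ops=tuple(ops),
    )


def identity_pct(query: str, target: str) -> float:
    return align_pair(query, target).identity_pct


def edit_distance(query: str, target: str, mode: str = "NW") -> int:
    """Unit-cost edit distance (edlib); mode NW = global, HW = query-in-target."""
    return edlib.align(query, target, mode=mode)["editDistance"]


def screen_best_reference(query: str, ref_ids: list[str], refs: dict[str, str]) -> str:
    """Reference id with the smallest query-in-target edit distance.

    Ties broken lexicographically. Cheap pre-screen: the scored alignment of
    the shortlisted reference(s) decides the final best hit.
    """
    best_id, best_d = None, None
    for rid in sorted(ref_ids):
        d = edit_distance(query, refs[rid], mode="HW")
        if best_d is None or d < best_d:
            best_id, best_d = rid, d
    return best_id
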