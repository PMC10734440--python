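"""Reference-guided two-parent chimera detection and accounting.

A read is called chimeric when stitching two reference parents at a single
breakpoint explains it markedly better than any single reference: the
best two-parent model identity must clear a floor (id_min) and exceed the
best single-parent identity by a gain (delta). Preset modes:

* ``balanced``  — delta 2.0, id_min 98.0 (conservative);
* ``sensitive`` — delta 1.0, id_min 96.0 (higher recall, more false calls).

Any read the sensitive mode rejects, the balanced mode rejects too.

Accounting follows the dual-reference design: classification against the
*mock* references defines true chimeras; classification against an
external *database* defines detected chimeras; undetected = true minus
detected, i.e. the chimeras that survive database-guided filtering because
the database does not contain the actual parents.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .align import PairAlignment, align_pair, screen_best_reference
from .design import gc_fraction

MODES = {
    "balanced": {"delta": 2.0, "id_min": 98.0},
    "sensitive": {"delta": 1.0, "id_min": 96.0},
}


@dataclass
class ChimeraCall:
    read_id: str
    is_chimera: bool
    parent_a: Optional[str]
    parent_b: Optional[str]
    breakpoint: Optional[int]
    best_single_identity: float
    best_model_identity: float
    mode: str
    reference_set: str = "mock"


@dataclass
class ChimeraAccounting:
    n_reads: int
    n_true: int
    n_detected: int
    n_undetected: int
    rate_true: float
    rate_detected: float
    rate_undetected: float
    gc_chimeric_mean: Optional[float] = None
    gc_non_chimeric_mean: Optional[float] = None


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


def find_parent_candidates(query: str, refs: dict[str, str], k: int = 8,
                           top_n: int = 4) -> list[str]:
    """Top references by shared k-mer count, plus the best-identity reference.

    Shared-k-mer ranking ties break by id. The best-single-identity member
    is guaranteed via an edit-distance screen over all references.
    """
    if not refs:
        raise ValueError("empty reference set")
    qk = _kmers(query, k)
    scored = sorted(((len(qk & _kmers(s, k)), rid) for rid, s in refs.items()),
                    key=lambda x: (-x[0], x[1]))
    if not qk or all(c == 0 for c, _ in scored):
        # degenerate: k exceeds query length or no shared k-mers
        best = screen_best_reference(query, list(refs), refs)
        rest = [rid for rid in sorted(refs) if rid != best]
        return [best] + rest[:top_n - 1]
    out = [rid for _, rid in scored[:top_n]]
    best = screen_best_reference(query, list(refs), refs)
    if best not in out:
        out.append(best)
    return out


def best_two_parent_model(
    query: str,
    parent_a: str,
    parent_b: str,
    aln_a: Optional[PairAlignment] = None,
    aln_b: Optional[PairAlignment] = None,
) -> tuple[int, float]:
    """Best single-breakpoint model: parent A explains [0,c), B explains [c,L).

    Returns (breakpoint, model identity percent); ties take the smallest
    breakpoint. Evaluated in O(L) from per-position match indicators of the
    two pairwise alignments.
    """
    aln_a = aln_a or align_pair(query, parent_a)
    aln_b = aln_b or align_pair(query, parent_b)
    L = len(query)
    ma = np.asarray(aln_a.query_match, dtype=np.int64)
    mb = np.asarray(aln_b.query_match, dtype=np.int64)
    pref_a = np.concatenate([[0], np.cumsum(ma)])   # matches of A on [0, c)
    pref_b = np.concatenate([[0], np.cumsum(mb)])
    scores = pref_a + (pref_b[L] - pref_b)          # + matches of B on [c, L)
    c = int(np.argmax(scores))                       # argmax, smallest index on ties
    return c, 100.0 * float(scores[c]) / L


def classify_chimera(query: str, refs: dict[str, str], mode: str = "balanced",
                     read_id: str = "", reference_set: str = "mock",
                     k: int = 8, top_n: int = 4) -> ChimeraCall:
    """Classify one sequence against a reference set."""
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}")
    delta, id_min = MODES[mode]["delta"], MODES[mode]["id_min"]
    if not refs:
        return ChimeraCall(read_id, False, None, None, None, 0.0, 0.0, mode, reference_set)
    cands = find_parent_candidates(query, refs, k=k, top_n=top_n)
    alns = {rid: align_pair(query, refs[rid]) for rid in cands}
    best_single = max(a.identity_pct for a in alns.values())
    best_single_id = min(rid for rid, a in alns.items()
                         if a.identity_pct >= best_single - 1e-12)
    best_model = -1.0
    best_pair: tuple[Optional[str], Optional[str]] = (None, None)
    best_bp: Optional[int] = None
    for pa in cands:
        for pb in cands:
            if pa == pb:
                continue
            bp, mid = best_two_parent_model(query, refs[pa], refs[pb],
                                            aln_a=alns[pa], aln_b=alns[pb])
            if mid > best_model + 1e-12:
                best_model, best_pair, best_bp = mid, (pa, pb), bp
    if best_model < best_single:
        # a two-parent model can always emulate a single parent (c = 0 or L)
        best_model, best_pair, best_bp = best_single, (best_single_id, best_single_id), 0
    is_chim = (
        best_pair[0] is not None
        and best_pair[0] != best_pair[1]
        and best_model >= id_min
        and (best_model - best_single) >= delta
    )
    return ChimeraCall(
        read_id=read_id,
        is_chimera=bool(is_chim),
        parent_a=best_pair[0] if is_chim else None,
        parent_b=best_pair[1] if is_chim else None,
        breakpoint=best_bp if is_chim else None,
        best_single_identity=best_single,
        best_model_identity=best_model,
        mode=mode,
        reference_set=reference_set,
    )


def classify_reads(
    reads: Sequence[tuple[str, str]],
    refs: dict[str, str],
    mode: str = "balanced",
    reference_set: str = "mock",
) -> dict[str, ChimeraCall]:
    """Classify reads, dereplicating first; per-read calls inherit from uniques."""
    by_seq: dict[str, list[str]] = {}
    for read_id, seq in reads:
        by_seq.setdefault(seq, []).append(read_id)
    calls: dict[str, ChimeraCall] = {}
    for seq, ids in sorted(by_seq.items()):
        call = classify_chimera(seq, refs, mode=mode, read_id=ids[0],
                                reference_set=reference_set)
        for rid in ids:
            c = ChimeraCall(**{**call.__dict__, "read_id": rid})
            calls[rid] = c
    return calls


def chimera_accounting(
    reads: Sequence[tuple[str, str]],
    mock_refs: dict[str, str],
    db_refs: dict[str, str],
    mode: str = "balanced",
) -> tuple[ChimeraAccounting, dict[str, ChimeraCall], dict[str, ChimeraCall]]:
    """Total / detected / undetected chimera accounting over a read set.

    True chimeras come from classification against the mock references;
    detected ones from the external database; undetected = true \\ detected.
    Rates are percent of all reads. Also summarises GC content of chimeric
    vs non-chimeric reads (chimeric reads skew GC-rich when formation is
    GC-favoured).
    """
    if not mock_refs or not db_refs:
        raise ValueError("both reference sets must be non-empty")
    n = len(reads)
    true_calls = classify_reads(reads, mock_refs, mode=mode, reference_set="mock")
    det_calls = classify_reads(reads, db_refs, mode=mode, reference_set="database")
    true_ids = {rid for rid, c in true_calls.items() if c.is_chimera}
    det_ids = {rid for rid, c in det_calls.items() if c.is_chimera}
    undet = true_ids - det_ids
    seq_of = dict(reads)
    gc_chim = [gc_fraction(seq_of[r]) for r in true_ids] if true_ids else []
    gc_non = [gc_fraction(s) for r, s in reads if r not in true_ids]
    acc = ChimeraAccounting(
        n_reads=n,
        n_true=len(true_ids),
        n_detected=len(det_ids),
        n_undetected=len(undet),
        rate_true=100.0 * len(true_ids) / n if n else 0.0,
        rate_detected=100.0 * len(det_ids) / n if n else 0.0,
        rate_undetected=100.0 * len(undet) / n if n else 0.0,
        gc_chimeric_mean=float(np.mean(gc_chim)) if gc_chim else None,
        gc_non_chimeric_mean=float(np.mean(gc_non)) if gc_non else None,
    )
    return acc, true_calls, det_calls


def calls_to_frame(calls: dict[str, ChimeraCall]) -> pd.DataFrame:
    rows = [c.__dict__ for c in calls.values()]
    return pd.DataFrame(rows)
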