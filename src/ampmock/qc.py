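"""Quality trimming, length/N filtering, and overlap pair merging.

Trimming follows a windowed-quality rule over the stringency grid
Q20/Q25/Q30 x W5/W2: a read is cut to the longest contiguous segment in
which every fully-contained window of the given width has mean quality at
or above the threshold. Merging is FLASH-like: the overlap minimizing the
mismatch fraction wins, the higher-quality base resolves conflicts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .io import reverse_complement

TRIM_GRID = ("raw", "Q20-W5", "Q25-W5", "Q30-W5", "Q20-W2", "Q25-W2", "Q30-W2")
#: grid ordered by increasing stringency (threshold first, then window)
TRIM_GRID_ORDERED = ("raw", "Q20-W5", "Q20-W2", "Q25-W5", "Q25-W2", "Q30-W5", "Q30-W2")


@dataclass
class ReadRecord:
    read_id: str
    seq: str
    quals: list[int]
    mate: str = "fwd"  # fwd | rev | merged

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.quals):
            raise ValueError(f"{self.read_id}: |seq| != |quals|")

    def __len__(self) -> int:
        return len(self.seq)


def parse_trim_level(level: str) -> Optional[tuple[int, int]]:
    """'Q25-W5' -> (25, 5); 'raw' -> None."""
    if level == "raw":
        return None
    q, w = level.split("-")
    return int(q[1:]), int(w[1:])


def _slice(read: ReadRecord, start: int, end: int) -> ReadRecord:
    return ReadRecord(read.read_id, read.seq[start:end], read.quals[start:end], read.mate)


def trim_sliding(read: ReadRecord, q_threshold: int, window: int,
                 mode: str = "longest") -> ReadRecord:
    """Trim to the longest segment whose internal windows all pass.

    ``mode='longest'`` (default): longest contiguous segment such that every
    length-``window`` window fully inside it has mean quality >=
    ``q_threshold``; leftmost among equals; a segment shorter than the
    window passes on its own mean. ``mode='prefix'`` instead keeps the
    prefix up to the first failing window (Btrim-style 3' cut), for
    sensitivity analysis.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    n = len(read)
    if n == 0:
        return read
    q = np.asarray(read.quals, dtype=float)
    if n >= window:
        means = np.convolve(q, np.ones(window) / window, mode="valid")  # starts 0..n-w
        ok = means >= q_threshold - 1e-9
        if mode == "prefix":
            fails = np.nonzero(~ok)[0]
            if len(fails) == 0:
                return read
            return _slice(read, 0, int(fails[0]) + window - 1)
        if mode != "longest":
            raise ValueError(f"unknown trim mode {mode!r}")
        # longest run of passing windows; run of k windows covers k+window-1 bases
        best_len, best_start = 0, 0
        run_start = None
        for i, flag in enumerate(np.append(ok, False)):
            if flag and run_start is None:
                run_start = i
            elif not flag and run_start is not None:
                seg_len = (i - run_start) + window - 1
                if seg_len > best_len:
                    best_len, best_start = seg_len, run_start
                run_start = None
        if best_len > 0:
            return _slice(read, best_start, best_start + best_len)
    elif mode == "prefix" and q.mean() >= q_threshold:
        return read
    # no window passes (or read shorter than window): best sub-window segment
    # whose own mean passes
    for seg_len in range(min(n, window - 1), 0, -1):
        seg_means = np.convolve(q, np.ones(seg_len) / seg_len, mode="valid")
        hits = np.nonzero(seg_means >= q_threshold - 1e-9)[0]
        if len(hits):
            return _slice(read, int(hits[0]), int(hits[0]) + seg_len)
    return _slice(read, 0, 0)


def filter_read(read: ReadRecord, min_len: int = 200) -> tuple[bool, Optional[str]]:
    """Keep/drop with reason: 'short' (<min_len) or 'ambiguous' (contains N)."""
    if len(read.seq) < min_len:
        return False, "short"
    if "N" in read.seq:
        return False, "ambiguous"
    return True, None


def merge_pairs(
    fwd: ReadRecord,
    rev: ReadRecord,
    min_overlap: int = 20,
    max_mismatch_frac: float = 0.25,
) -> tuple[Optional[ReadRecord], Optional[str]]:
    """Merge a read pair over their best overlap, or reject with a reason.

    The reverse read is reverse-complemented (qualities reversed) first.
    Candidate overlap lengths >= ``min_overlap`` are scored by mismatch
    fraction (ties -> longest). In the overlap the higher-quality base is
    emitted; merged quality is max(q) on agreement and |q1-q2| (floor 2) on
    conflict.
    """
    r_seq = reverse_complement(rev.seq)
    r_quals = rev.quals[::-1]
    f = np.frombuffer(fwd.seq.encode(), dtype=np.uint8)
    r = np.frombuffer(r_seq.encode(), dtype=np.uint8)
    lf, lr = len(f), len(r)
    max_o = min(lf, lr)
    if max_o < min_overlap:
        return None, "no_overlap"
    best = None  # (mm_frac, -overlap, overlap, n_mm)
    for o in range(min_overlap, max_o + 1):
        n_mm = int(np.count_nonzero(f[lf - o:] != r[:o]))
        key = (n_mm / o, -o)
        if best is None or key < best[:2]:
            best = (key[0], key[1], o, n_mm)
    mm_frac, _, o, _ = best
    if mm_frac > max_mismatch_frac:
        return None, "too_divergent"
    fq = np.asarray(fwd.quals)
    rq = np.asarray(r_quals)
    seq = list(fwd.seq[:lf - o])
    quals = list(fwd.quals[:lf - o])
    for i in range(o):
        fb, rb = fwd.seq[lf - o + i], r_seq[i]
        q1, q2 = int(fq[lf - o + i]), int(rq[i])
        if fb == rb:
            seq.append(fb)
            quals.append(max(q1, q2))
        else:
            seq.append(fb if q1 >= q2 else rb)
            quals.append(max(2, abs(q1 - q2)))
    seq.extend(r_seq[o:])
    quals.extend(r_quals[o:])
    return ReadRecord(fwd.read_id, "".join(seq), quals, mate="merged"), None


def trim_level(read: ReadRecord, level: str, mode: str = "longest") -> ReadRecord:
    """Apply one grid level ('raw' is a no-op)."""
    parsed = parse_trim_level(level)
    if parsed is None:
        return read
    q, w = parsed
    return trim_sliding(read, q, w, mode=mode)


@dataclass
class QcSummary:
    library_id: str
    n_in: int = 0
    n_trimmed: int = 0
    n_dropped_short: int = 0
    n_dropped_ambiguous: int = 0
    n_merged: int = 0
    n_reject_overlap: int = 0
    n_reject_divergent: int = 0


def process_pairs(
    fwd_reads: list[ReadRecord],
    rev_reads: list[ReadRecord],
    level: str = "raw",
    min_len: int = 100,
    min_overlap: int = 20,
    max_mismatch_frac: float = 0.25,
    library_id: str = "lib",
) -> tuple[list[ReadRecord], QcSummary]:
    """Trim both mates at one grid level, filter, and merge survivors."""
    summary = QcSummary(library_id=library_id, n_in=len(fwd_reads))
    merged: list[ReadRecord] = []
    for fr, rr in zip(fwd_reads, rev_reads):
        ft = trim_level(fr, level)
        rt = trim_level(rr, level)
        if len(ft) < len(fr) or len(rt) < len(rr):
            summary.n_trimmed += 1
        ok_f, reason_f = filter_read(ft, min_len)
        ok_r, reason_r = filter_read(rt, min_len)
        if not (ok_f and ok_r):
            reason = reason_f or reason_r
            if reason == "short":
                summary.n_dropped_short += 1
            else:
                summary.n_dropped_ambiguous += 1
            continue
        m, reject = merge_pairs(ft, rt, min_overlap, max_mismatch_frac)
        if m is None:
            if reject == "no_overlap":
                summary.n_reject_overlap += 1
            else:
                summary.n_reject_divergent += 1
            continue
        merged.append(m)
        summary.n_merged += 1
    return merged, summary
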