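"""Best-hit alignment against references and error-rate estimation.

Each read is aligned to its best-matching reference (usearch_global-style:
global with free end gaps, highest identity wins) and per-column operations
are pooled into per-position and total substitution / insertion / deletion
counts. Rates are total errors over total valid (aligned, non-gap) read
bases — pooled over bases, not averaged per read. Substitution-only and
all-error rates are both reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .align import DEL, INS, MATCH, SUB, PairAlignment, align_pair, edit_distance
from .io import reverse_complement
from .qc import ReadRecord, TRIM_GRID, trim_level

MIN_ALIGNABLE = 50


@dataclass
class ErrorProfile:
    """Pooled error counts for one stratum of reads."""

    per_position: dict[int, list[int]] = field(default_factory=dict)  # pos -> [sub, ins, del, valid]
    n_sub: int = 0
    n_ins: int = 0
    n_del: int = 0
    n_valid: int = 0
    n_reads: int = 0
    n_unalignable: int = 0
    stratum: dict = field(default_factory=dict)

    @property
    def rate_sub(self) -> Optional[float]:
        return 100.0 * self.n_sub / self.n_valid if self.n_valid else None

    @property
    def rate_all(self) -> Optional[float]:
        if not self.n_valid:
            return None
        return 100.0 * (self.n_sub + self.n_ins + self.n_del) / self.n_valid

    def add_alignment(self, aln: PairAlignment) -> None:
        self.n_reads += 1
        per = self.per_position
        for kind, tpos, _ in aln.ops:
            row = per.setdefault(tpos, [0, 0, 0, 0])
            if kind == MATCH:
                row[3] += 1
            elif kind == SUB:
                row[0] += 1
                row[3] += 1
            elif kind == INS:
                row[1] += 1
            elif kind == DEL:
                row[2] += 1
        self.n_sub += aln.mismatches
        self.n_ins += aln.insertions
        self.n_del += aln.deletions
        self.n_valid += aln.aligned_query_bases

    def position_frame(self) -> pd.DataFrame:
        rows = [{"position": p, "n_sub": v[0], "n_ins": v[1], "n_del": v[2], "n_valid": v[3]}
                for p, v in sorted(self.per_position.items())]
        return pd.DataFrame(rows)


class BestHitAligner:
    """Best-hit search with an edit-distance screen and per-sequence memoisation.

    The screen ranks references by unit-cost query-in-target edit distance
    (a lower bound on scored differences) and scored-aligns only the
    near-minimal ones; the scored identity then decides, ties by id.
    """

    def __init__(self, refs: dict[str, str], screen_margin: int = 3):
        if not refs:
            raise ValueError("empty reference set")
        self.refs = dict(refs)
        self.margin = screen_margin
        self._cache: dict[str, tuple[str, PairAlignment]] = {}

    def __call__(self, seq: str) -> Optional[tuple[str, PairAlignment]]:
        if len(seq) < MIN_ALIGNABLE:
            return None
        hit = self._cache.get(seq)
        if hit is None:
            dists = {rid: edit_distance(seq, r, mode="HW") for rid, r in self.refs.items()}
            dmin = min(dists.values())
            cands = sorted(rid for rid, d in dists.items() if d <= dmin + self.margin)
            best_id, best_aln = None, None
            for rid in cands:
                aln = align_pair(seq, self.refs[rid])
                if best_aln is None or aln.identity_pct > best_aln.identity_pct + 1e-12:
                    best_id, best_aln = rid, aln
            hit = (best_id, best_aln)
            self._cache[seq] = hit
        return hit


def best_hit(read_seq: str, refs: dict[str, str]) -> Optional[tuple[str, PairAlignment]]:
    """One-shot best-hit alignment; returns None for reads under 50 bases."""
    return BestHitAligner(refs)(read_seq)


def accumulate_errors(alignments: Sequence[PairAlignment],
                      stratum: Optional[dict] = None) -> ErrorProfile:
    """Pool per-column operations of many alignments into one profile."""
    prof = ErrorProfile(stratum=dict(stratum or {}))
    for aln in alignments:
        prof.add_alignment(aln)
    return prof


def profile_reads(reads: Sequence[ReadRecord], aligner: BestHitAligner,
                  stratum: Optional[dict] = None,
                  orient_reverse: bool = False) -> ErrorProfile:
    """Best-hit-align reads and pool their errors; reverse reads are
    reverse-complemented onto the reference strand first."""
    prof = ErrorProfile(stratum=dict(stratum or {}))
    for read in reads:
        seq = reverse_complement(read.seq) if orient_reverse else read.seq
        hit = aligner(seq)
        if hit is None:
            prof.n_unalignable += 1
            continue
        prof.add_alignment(hit[1])
    return prof


def error_grid(
    libraries: dict[str, dict[str, list[ReadRecord]]],
    refs: dict[str, str],
    trim_grid: Sequence[str] = TRIM_GRID,
    chimera_read_ids: Optional[set[str]] = None,
    merge_fn=None,
) -> tuple[pd.DataFrame, list[ErrorProfile]]:
    """Error rates per (library x read type x trim level x chimera removal).

    ``libraries`` maps library_id -> {"fwd": [...], "rev": [...]}.
    ``chimera_read_ids`` is the detected-chimera id set; "after" strata
    exclude those reads. ``merge_fn(fwd, rev) -> merged | None`` builds the
    merged read type (defaults to `qc.merge_pairs`).
    """
    from .qc import merge_pairs

    for level in trim_grid:
        if level not in TRIM_GRID:
            raise ValueError(f"unknown trim level {level!r}")
    if merge_fn is None:
        merge_fn = lambda f, r: merge_pairs(f, r)[0]
    chimera_read_ids = chimera_read_ids or set()
    aligner = BestHitAligner(refs)
    profiles: list[ErrorProfile] = []
    for lib_id, pair in sorted(libraries.items()):
        fwd_reads, rev_reads = pair["fwd"], pair["rev"]
        for level in trim_grid:
            ft = [trim_level(r, level) for r in fwd_reads]
            rt = [trim_level(r, level) for r in rev_reads]
            merged = []
            for f, r in zip(ft, rt):
                if len(f) and len(r):
                    m = merge_fn(f, r)
                    if m is not None:
                        merged.append(m)
            by_type = {"fwd": (ft, False), "rev": (rt, True), "merged": (merged, False)}
            for rtype, (reads, orient_rev) in by_type.items():
                reads = [r for r in reads if len(r)]
                for removal in ("before", "after"):
                    subset = (reads if removal == "before"
                              else [r for r in reads if r.read_id not in chimera_read_ids])
                    stratum = {"library": lib_id, "read_type": rtype,
                               "trim": level, "chimera_removal": removal}
                    profiles.append(profile_reads(subset, aligner, stratum, orient_rev))
    rows = []
    for p in profiles:
        rows.append({**p.stratum, "n_reads": p.n_reads, "n_valid": p.n_valid,
                     "n_sub": p.n_sub, "n_ins": p.n_ins, "n_del": p.n_del,
                     "rate_sub": p.rate_sub, "rate_all": p.rate_all})
    return pd.DataFrame(rows), profiles
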