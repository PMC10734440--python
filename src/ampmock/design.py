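"""Mock-community design: strains, GC clustering, abundance tiers, and V4
amplicon extraction by degenerate-primer matching.

The community models a defined mixture of 33 bacterial 16S rRNA clones
split into three 11-strain clusters by V4 GC content (low / medium / high)
and distributed either evenly (3.03% each) or over abundance tiers
(8.41% / 0.67% / 0.01%, one tier per GC cluster).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from .io import read_fasta, read_tsv, reverse_complement, write_tsv

# Earth Microbiome / Caporaso V4 primer pair
PRIMER_515F = "GTGCCAGCMGCCGCGGTAA"
PRIMER_806R = "GGACTACHVGGGTWTCTAAT"

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

GC_CLUSTERS = ("low", "medium", "high")
TIER_VALUES = (8.41, 0.67, 0.01)
EVEN_PERCENT = 100.0 / 33.0  # rendered as 3.03


@dataclass
class Strain:
    strain_id: str
    phylum: str
    full_seq: str
    v4_seq: Optional[str] = None
    gc_percent: Optional[float] = None
    gc_cluster: Optional[str] = None
    primer_mismatches_fwd: int = 0
    primer_mismatches_rev: int = 0
    #: set when extract_v4 gave up ("primer-mismatch", "orientation", ...)
    extraction_flag: Optional[str] = None

    @property
    def amplifiable(self) -> bool:
        return self.v4_seq is not None


@dataclass
class MockDesign:
    strains: list[Strain]
    expected_abundance: dict[str, float]
    design_name: str  # "even" or "tiered"
    community_id: str = ""
    #: gc_cluster -> tier percent, tiered designs only
    tier_map: Optional[dict[str, float]] = field(default=None)

    def validate(self) -> None:
        total = sum(self.expected_abundance.values())
        if abs(total - 100.0) > 0.05:
            raise ValueError(f"expected abundances sum to {total:.3f}, not 100 +/- 0.05")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.strains:
            rows.append({
                "strain_id": s.strain_id,
                "phylum": s.phylum,
                "gc_cluster": s.gc_cluster,
                "gc_percent": None if s.gc_percent is None else round(s.gc_percent, 2),
                "expected_percent": round(self.expected_abundance.get(s.strain_id, 0.0), 2),
                "primer_mismatches_fwd": s.primer_mismatches_fwd,
                "primer_mismatches_rev": s.primer_mismatches_rev,
            })
        return pd.DataFrame(rows)

    def write_tsv(self, path: str | Path, header_comment: str | None = None) -> None:
        write_tsv(self.to_frame(), path, header_comment=header_comment, index=False)


def gc_fraction(seq: str) -> float:
    """GC percent of ``seq``; N bases excluded from numerator and denominator."""
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper()
    counted = sum(seq.count(b) for b in "ACGT")
    if counted == 0:
        raise ValueError("sequence contains no unambiguous A/C/G/T bases")
    return 100.0 * (seq.count("G") + seq.count("C")) / counted


def _window_mismatches(window: str, primer: str) -> int:
    return sum(1 for b, p in zip(window, primer) if b not in IUPAC[p])


def match_primer(seq: str, primer: str, max_mismatch: int) -> list[tuple[int, int]]:
    """All 0-based windows of |primer| whose IUPAC mismatch count <= max_mismatch."""
    seq, primer = seq.upper(), primer.upper()
    k = len(primer)
    hits = []
    for pos in range(len(seq) - k + 1):
        mm = _window_mismatches(seq[pos:pos + k], primer)
        if mm <= max_mismatch:
            hits.append((pos, mm))
    return hits


def _best_site(hits: list[tuple[int, int]]) -> Optional[tuple[int, int]]:
    """Fewest mismatches, then leftmost."""
    if not hits:
        return None
    return min(hits, key=lambda h: (h[1], h[0]))


def extract_v4(
    strain: Strain,
    fwd_primer: str = PRIMER_515F,
    rev_primer: str = PRIMER_806R,
    max_mismatch: int = 2,
) -> Optional[str]:
    """Extract the amplicon between (and excluding) the two primer sites.

    The reverse primer is matched as its reverse complement on the forward
    strand. The best site per primer is fewest-mismatch then leftmost. On
    failure the strain keeps ``v4_seq=None`` and carries an extraction flag;
    such strains stay in the design as low-recovery members.
    """
    seq = strain.full_seq.upper()
    fwd_hits = match_primer(seq, fwd_primer, max_mismatch)
    rev_hits = match_primer(seq, reverse_complement(rev_primer), max_mismatch)
    fwd = _best_site(fwd_hits)
    rev = _best_site(rev_hits)
    if fwd is None or rev is None:
        strain.v4_seq = None
        strain.extraction_flag = "primer-mismatch"
        strain.primer_mismatches_fwd = fwd[1] if fwd else max_mismatch + 1
        strain.primer_mismatches_rev = rev[1] if rev else max_mismatch + 1
        return None
    fwd_pos, fwd_mm = fwd
    rev_pos, rev_mm = rev
    insert_start = fwd_pos + len(fwd_primer)
    if rev_pos < insert_start:
        strain.v4_seq = None
        strain.extraction_flag = "orientation"
        return None
    strain.primer_mismatches_fwd = fwd_mm
    strain.primer_mismatches_rev = rev_mm
    strain.v4_seq = seq[insert_start:rev_pos]
    strain.gc_percent = gc_fraction(strain.v4_seq) if strain.v4_seq else None
    strain.extraction_flag = None
    return strain.v4_seq


def assign_gc_clusters(
    strains: Sequence[Strain],
    overrides: Optional[Mapping[str, str]] = None,
) -> list[Strain]:
    """Assign low/medium/high GC clusters by rank thirds of V4 GC percent.

    Ties break by strain_id. ``overrides`` (strain_id -> cluster) lets an
    explicit membership table trump the rank rule, mirroring a design whose
    clusters were chosen with a few exceptions to pure GC ordering.
    """
    usable = [s for s in strains if s.v4_seq]
    for s in strains:
        if not s.v4_seq:
            warnings.warn(f"strain {s.strain_id} has no V4 amplicon; excluded from clustering")
    if len(usable) % 3 != 0:
        raise ValueError(f"strain count {len(usable)} not divisible by 3")
    for s in usable:
        if s.gc_percent is None:
            s.gc_percent = gc_fraction(s.v4_seq)
    ranked = sorted(usable, key=lambda s: (s.gc_percent, s.strain_id))
    third = len(ranked) // 3
    for i, s in enumerate(ranked):
        s.gc_cluster = GC_CLUSTERS[min(i // third, 2)]
    if overrides:
        by_id = {s.strain_id: s for s in usable}
        for sid, cluster in overrides.items():
            if cluster not in GC_CLUSTERS:
                raise ValueError(f"unknown cluster {cluster!r}")
            if sid in by_id:
                by_id[sid].gc_cluster = cluster
    return list(strains)


def build_design(
    strains: Sequence[Strain],
    mode: str,
    tier_map: Optional[Mapping[str, float]] = None,
    community_id: str = "",
) -> MockDesign:
    """Build an even (100/33% each) or tiered (8.41/0.67/0.01%) design."""
    strains = list(strains)
    if mode == "even":
        if len(strains) != 33:
            warnings.warn(f"even design over {len(strains)} strains, not 33; using 100/n")
        share = 100.0 / len(strains)
        abundance = {s.strain_id: share for s in strains}
        design = MockDesign(strains, abundance, "even", community_id=community_id)
    elif mode == "tiered":
        if tier_map is None or sorted(tier_map) != sorted(GC_CLUSTERS) or \
                sorted(tier_map.values()) != sorted(TIER_VALUES):
            raise ValueError(
                f"tiered mode needs a bijection of {GC_CLUSTERS} onto tiers {TIER_VALUES}")
        missing = [s.strain_id for s in strains if s.gc_cluster is None]
        if missing:
            raise ValueError(f"strains without gc_cluster: {missing}")
        abundance = {s.strain_id: tier_map[s.gc_cluster] for s in strains}
        design = MockDesign(strains, abundance, "tiered", community_id=community_id,
                            tier_map=dict(tier_map))
    else:
        raise ValueError(f"unknown design mode {mode!r}")
    total = sum(design.expected_abundance.values())
    if abs(total - 100.0) > 0.05:
        warnings.warn(f"design abundances sum to {total:.3f}")
    return design


def strains_from_fasta(path: str | Path, phyla: Optional[Mapping[str, str]] = None) -> list[Strain]:
    seqs = read_fasta(path)
    phyla = phyla or {}
    return [Strain(strain_id=sid, phylum=phyla.get(sid, "unknown"), full_seq=seq)
            for sid, seq in seqs.items()]


def design_from_tsv(path: str | Path, strains: Sequence[Strain], design_name: str = "even",
                    community_id: str = "") -> MockDesign:
    """Load a design table (strain_id, phylum, cluster, expected_percent)."""
    df = read_tsv(path)
    by_id = {s.strain_id: s for s in strains}
    abundance = {}
    for _, row in df.iterrows():
        sid = row["strain_id"]
        abundance[sid] = float(row["expected_percent"])
        if sid in by_id and "gc_cluster" in row and pd.notna(row["gc_cluster"]):
            by_id[sid].gc_cluster = row["gc_cluster"]
    return MockDesign(list(strains), abundance, design_name, community_id=community_id)
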