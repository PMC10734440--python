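"""Dereplication, rarefaction, greedy 97% OTU clustering, unique-OTU
flagging, and artifact classification.

Clustering is greedy first-fit over abundance-sorted uniques: a sequence
joins the first centroid it matches at >= 97% identity AND <= 7
differences (the 7-of-253 rule applied conjunctively); otherwise it founds
a new centroid. Centroids never update.

Artifact classes follow the dual-database rule set: a non-chimeric
representative >= 97% identical to a mock strain is that strain; a
chimeric one is a chimera; otherwise >= 70% identity to the external
database with < 70% to the mock database means contaminant, >= 70% to the
mock database means erroneous.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .align import align_pair, edit_distance
from .chimera import classify_chimera
from .errors import BestHitAligner

FLAG_SINGLETON = "singleton"
FLAG_DOUBLETON = "doubleton"
FLAG_OTHER_UNIQUE = "other_unique"
FLAG_SHARED = "shared"


@dataclass
class OtuTable:
    """OTU x library count table with representatives and classifications."""

    representatives: dict[str, str]                  # otu_id -> sequence
    counts: pd.DataFrame                             # index otu_id, columns library_id
    classification: dict[str, str] = field(default_factory=dict)
    flags: dict[str, str] = field(default_factory=dict)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.index)

    def total_counts(self) -> pd.Series:
        return self.counts.sum(axis=1)


def dereplicate(seqs: Sequence[str]) -> list[tuple[str, int]]:
    """Exact-string dereplication, abundance-descending, ties lexicographic."""
    counts = Counter(seqs)
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))


def rarefy(reads: Sequence, depth: int, seed: int = 0,
           rng: Optional[np.random.Generator] = None,
           library: str = "") -> list:
    """Uniform subsample without replacement to ``depth``; error if too deep."""
    if depth > len(reads):
        raise ValueError(
            f"rarefying depth {depth} exceeds library size {len(reads)}"
            + (f" for {library}" if library else ""))
    rng = rng if rng is not None else np.random.default_rng(seed)
    idx = rng.choice(len(reads), size=depth, replace=False)
    return [reads[i] for i in idx]


def cluster_greedy(
    uniques: Sequence[tuple[str, int]],
    identity_threshold: float = 0.97,
    max_errors: int = 7,
) -> tuple[dict[str, str], dict[str, str]]:
    """Greedy first-fit centroid clustering.

    ``uniques`` must be abundance-sorted (from `dereplicate`). Returns
    (otu_id -> centroid sequence, member sequence -> otu_id). The edit
    distance lower-bounds scored differences, so the screen preserves
    exactness of the ``max_errors`` condition.
    """
    centroids: list[tuple[str, str]] = []  # (otu_id, seq)
    membership: dict[str, str] = {}
    for seq, _count in uniques:
        joined = None
        for otu_id, cseq in centroids:
            if abs(len(seq) - len(cseq)) > max_errors:
                continue
            if edit_distance(seq, cseq) > max_errors:
                continue
            aln = align_pair(seq, cseq)
            if aln.identity_pct >= 100.0 * identity_threshold - 1e-9 \
                    and aln.differences <= max_errors:
                joined = otu_id
                break
        if joined is None:
            joined = f"OTU{len(centroids) + 1:04d}"
            centroids.append((joined, seq))
        membership[seq] = joined
    return dict(centroids), membership


def build_otu_table(
    libraries: Mapping[str, Sequence[str]],
    identity_threshold: float = 0.97,
    max_errors: int = 7,
) -> OtuTable:
    """Dereplicate the pooled libraries, cluster, and tabulate counts."""
    pooled: list[str] = []
    for lib in sorted(libraries):
        pooled.extend(libraries[lib])
    uniques = dereplicate(pooled)
    reps, membership = cluster_greedy(uniques, identity_threshold, max_errors)
    data = {lib: Counter(membership[s] for s in seqs)
            for lib, seqs in libraries.items()}
    counts = pd.DataFrame(data).reindex(list(reps)).fillna(0).astype(int)
    counts = counts[sorted(counts.columns)]
    return OtuTable(representatives=reps, counts=counts)


def flag_unique_otus(table: OtuTable, replicate_map: Mapping[str, str]) -> OtuTable:
    """Flag OTUs confined to a single technical replicate.

    An OTU with nonzero counts in exactly one replicate is a singleton
    (total 1), doubleton (total 2), or other_unique (>2); everything else
    is shared.
    """
    reps_per_lib = {lib: replicate_map[lib] for lib in table.counts.columns}
    for otu_id, row in table.counts.iterrows():
        present = {reps_per_lib[lib] for lib, c in row.items() if c > 0}
        total = int(row.sum())
        if len(present) == 1:
            if total == 1:
                table.flags[otu_id] = FLAG_SINGLETON
            elif total == 2:
                table.flags[otu_id] = FLAG_DOUBLETON
            else:
                table.flags[otu_id] = FLAG_OTHER_UNIQUE
        else:
            table.flags[otu_id] = FLAG_SHARED
    return table


def classify_artifacts(
    table: OtuTable,
    mock_refs: dict[str, str],
    external_refs: dict[str, str],
    mode: str = "balanced",
    true_match_threshold: float = 97.0,
    artifact_identity_threshold: float = 70.0,
) -> OtuTable:
    """Classify each representative as true_strain / chimera / contaminant /
    erroneous, in that decision order."""
    mock_hit = BestHitAligner(mock_refs)
    ext_hit = BestHitAligner(external_refs)
    for otu_id, rep in table.representatives.items():
        hit = mock_hit(rep)
        mock_id, mock_identity = (hit[0], hit[1].identity_pct) if hit else (None, 0.0)
        chim = classify_chimera(rep, mock_refs, mode=mode, read_id=otu_id)
        if mock_identity >= true_match_threshold and not chim.is_chimera:
            table.classification[otu_id] = f"true_strain:{mock_id}"
            continue
        if chim.is_chimera:
            table.classification[otu_id] = "chimera"
            continue
        ehit = ext_hit(rep)
        ext_identity = ehit[1].identity_pct if ehit else 0.0
        if ext_identity >= artifact_identity_threshold and mock_identity < artifact_identity_threshold:
            table.classification[otu_id] = "contaminant"
        elif mock_identity >= artifact_identity_threshold:
            table.classification[otu_id] = "erroneous"
        else:
            table.classification[otu_id] = "contaminant:low_confidence"
    return table


def spurious_summary(table: OtuTable) -> pd.DataFrame:
    """Unique-OTU (spurious) decomposition: flag class x artifact class counts."""
    rows = defaultdict(Counter)
    for otu_id in table.otu_ids:
        flag = table.flags.get(otu_id, FLAG_SHARED)
        cls = table.classification.get(otu_id, "unclassified")
        if cls.startswith("true_strain"):
            cls = "true_strain"
        elif cls.startswith("contaminant"):
            cls = "contaminant"
        rows[flag][cls] += 1
    out = pd.DataFrame(rows).T.fillna(0).astype(int)
    order = [FLAG_SINGLETON, FLAG_DOUBLETON, FLAG_OTHER_UNIQUE, FLAG_SHARED]
    return out.reindex([f for f in order if f in out.index])
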