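"""Dereplication, rarefaction, greedy clustering, unique-OTU flags, and
artifact classification."""

import collections

import numpy as np
import pandas as pd
import pytest

from ampmock.align import align_pair
from ampmock.otu import (OtuTable, build_otu_table, classify_artifacts,
                         cluster_greedy, dereplicate, flag_unique_otus,
                         rarefy, spurious_summary)

from conftest import random_seq


class TestDereplicate:
    def test_basic_counting(self):
        assert dereplicate(["A", "A", "C"]) == [("A", 2), ("C", 1)]

    def test_all_distinct_lexicographic(self):
        assert dereplicate(["T", "C", "G"]) == [("C", 1), ("G", 1), ("T", 1)]

    def test_matches_counting_oracle(self):
        rng = np.random.default_rng(0)
        seqs = [random_seq(rng, 5) for _ in range(30)]
        multiset = [seqs[int(i)] for i in rng.integers(0, 30, size=500)]
        got = dereplicate(multiset)
        counts = collections.Counter(multiset)
        assert dict(got) == dict(counts)
        assert got == sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))


class TestRarefy:
    def test_full_depth_is_identity_permutation(self):
        reads = list("AABBBCC")
        out = rarefy(reads, len(reads), seed=1)
        assert sorted(out) == sorted(reads)

    def test_depth_beyond_library_errors(self):
        with pytest.raises(ValueError, match="libX"):
            rarefy(["a"], 5, library="libX")

    def test_seed_reproducibility(self):
        reads = list(range(100))
        assert rarefy(reads, 30, seed=7) == rarefy(reads, 30, seed=7)

    def test_rare_member_sampled_at_its_frequency(self):
        reads = ["a"] * 999 + ["b"]
        rng = np.random.default_rng(3)
        hits = sum("b" in rarefy(reads, 1, rng=rng) for _ in range(10_000))
        se = np.sqrt(10_000 * 0.001 * 0.999)
        assert abs(hits - 10) <= 3 * se


def oracle_first_fit(uniques, threshold=0.97, max_errors=7):
    """Plain re-implementation of first-fit centroid clustering."""
    centroids = []
    membership = {}
    for seq, _ in uniques:
        target = None
        for cid, cseq in centroids:
            aln = align_pair(seq, cseq)
            if aln.identity_pct >= 100 * threshold - 1e-9 and aln.differences <= max_errors:
                target = cid
                break
        if target is None:
            target = f"OTU{len(centroids) + 1:04d}"
            centroids.append((target, seq))
        membership[seq] = target
    return membership


class TestClusterGreedy:
    def _mutant(self, seq, n, rng):
        pos = rng.choice(len(seq), size=n, replace=False)
        s = list(seq)
        for p in pos:
            s[p] = rng.choice([b for b in "ACGT" if b != s[p]])
        return "".join(s)

    def test_one_difference_joins(self):
        rng = np.random.default_rng(1)
        a = random_seq(rng, 253)
        b = self._mutant(a, 1, rng)
        reps, member = cluster_greedy([(a, 5), (b, 1)])
        assert member[a] == member[b]

    def test_eight_differences_split(self):
        """7 of 253 errors is the boundary: 8 differences founds a new OTU."""
        rng = np.random.default_rng(2)
        a = random_seq(rng, 253)
        b = self._mutant(a, 8, rng)
        reps, member = cluster_greedy([(a, 5), (b, 1)])
        assert member[a] != member[b]

    def test_seven_differences_join_at_boundary(self):
        rng = np.random.default_rng(6)
        a = random_seq(rng, 253)
        b = self._mutant(a, 7, rng)
        reps, member = cluster_greedy([(a, 5), (b, 1)])
        # 246/253 = 97.2% >= 97% and 7 <= 7: same OTU
        assert member[a] == member[b]

    def test_matches_first_fit_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            founders = [random_seq(rng, 120) for _ in range(4)]
            seqs = []
            for f in founders:
                seqs.append(f)
                for _ in range(8):
                    seqs.append(self._mutant(f, int(rng.integers(0, 6)), rng))
            uniques = dereplicate(seqs)
            _, member = cluster_greedy(uniques, 0.97, 3)
            oracle = oracle_first_fit(uniques, 0.97, 3)
            assert member == oracle


class TestFlags:
    def _table(self, counts):
        df = pd.DataFrame(counts).T
        reps = {o: "A" * 50 for o in df.index}
        return OtuTable(representatives=reps, counts=df)

    def test_singleton_doubleton_other(self):
        t = self._table({
            "OTU1": {"r1": 1, "r2": 0},
            "OTU2": {"r1": 2, "r2": 0},
            "OTU3": {"r1": 3, "r2": 0},
            "OTU4": {"r1": 1, "r2": 1},
        })
        flag_unique_otus(t, {"r1": "rep1", "r2": "rep2"})
        assert t.flags == {"OTU1": "singleton", "OTU2": "doubleton",
                           "OTU3": "other_unique", "OTU4": "shared"}

    def test_two_libraries_one_replicate_still_unique(self):
        t = self._table({"OTU1": {"l1": 1, "l2": 1}})
        flag_unique_otus(t, {"l1": "repA", "l2": "repA"})
        assert t.flags["OTU1"] == "doubleton"


class TestClassifyArtifacts:
    def _mutant(self, seq, frac, rng):
        n = int(round(frac * len(seq)))
        pos = rng.choice(len(seq), size=n, replace=False)
        s = list(seq)
        for p in pos:
            s[p] = rng.choice([b for b in "ACGT" if b != s[p]])
        return "".join(s)

    def test_decision_order(self, mock_refs, external_db, contaminants):
        rng = np.random.default_rng(4)
        ids = sorted(mock_refs)
        exact = mock_refs[ids[0]]
        # 4% divergence: below the 97% true-strain radius, above 70% vs mock
        erroneous = self._mutant(mock_refs[ids[1]], 0.04, rng)
        chimera = mock_refs[ids[2]][:130] + mock_refs[ids[25]][130:]
        contaminant = list(contaminants.values())[0]
        reps = {"OTU1": exact, "OTU2": erroneous, "OTU3": chimera, "OTU4": contaminant}
        counts = pd.DataFrame({"lib": {o: 1 for o in reps}})
        table = OtuTable(representatives=reps, counts=counts)
        classify_artifacts(table, mock_refs, external_db)
        assert table.classification["OTU1"] == f"true_strain:{ids[0]}"
        assert table.classification["OTU2"] == "erroneous"
        assert table.classification["OTU3"] == "chimera"
        assert table.classification["OTU4"].startswith("contaminant")

    def test_every_otu_classified_and_flagged_once(self, mock_refs, external_db):
        rng = np.random.default_rng(5)
        seqs = {f"l{i}": [mock_refs[s] for s in sorted(mock_refs)[:10]] for i in range(2)}
        table = build_otu_table(seqs)
        flag_unique_otus(table, {l: l for l in seqs})
        classify_artifacts(table, mock_refs, external_db)
        assert set(table.classification) == set(table.otu_ids)
        assert set(table.flags) == set(table.otu_ids)
        summary = spurious_summary(table)
        assert summary.to_numpy().sum() == len(table.otu_ids)


class TestBuildTable:
    def test_counts_match_input_sizes(self, mock_refs):
        seqs = {"A": [mock_refs[s] for s in sorted(mock_refs)[:6]] * 2,
                "B": [mock_refs[s] for s in sorted(mock_refs)[:3]]}
        table = build_otu_table(seqs)
        assert table.counts["A"].sum() == 12
        assert table.counts["B"].sum() == 3
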