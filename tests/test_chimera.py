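"""Two-parent chimera model, mode presets, and dual-reference accounting."""

import numpy as np
import pytest

from ampmock.align import align_pair
from ampmock.chimera import (best_two_parent_model, chimera_accounting,
                             classify_chimera, classify_reads,
                             find_parent_candidates)

from conftest import random_seq


def mutate(seq, frac, rng):
    s = list(seq)
    n = int(round(frac * len(s)))
    for i in rng.choice(len(s), size=n, replace=False):
        s[i] = rng.choice([b for b in "ACGT" if b != s[i]])
    return "".join(s)


@pytest.fixture(scope="module")
def divergent_refs():
    """Two reference families around 85% mutual identity plus decoys."""
    rng = np.random.default_rng(7)
    base = random_seq(rng, 240)
    refs = {"R1": base, "R2": mutate(base, 0.15, rng)}
    for i in (3, 4, 5):
        refs[f"R{i}"] = mutate(base, 0.25, rng)
    return refs


class TestParentCandidates:
    def test_exact_query_ranks_itself_first(self, divergent_refs):
        cands = find_parent_candidates(divergent_refs["R1"], divergent_refs)
        assert cands[0] == "R1"

    def test_half_half_construct_contains_both_parents(self, divergent_refs):
        q = divergent_refs["R1"][:120] + divergent_refs["R2"][120:]
        cands = find_parent_candidates(q, divergent_refs)
        assert {"R1", "R2"} <= set(cands)

    def test_oversized_k_falls_back_to_identity(self, divergent_refs):
        cands = find_parent_candidates(divergent_refs["R2"][:30], divergent_refs, k=64)
        assert cands[0] == "R2"


def oracle_breakpoint(query, parent_a, parent_b):
    """Exhaustive scan over every breakpoint, straight from the alignments."""
    ma = align_pair(query, parent_a).query_match
    mb = align_pair(query, parent_b).query_match
    L = len(query)
    best = None
    for c in range(L + 1):
        score = sum(ma[:c]) + sum(mb[c:])
        if best is None or score > best[0]:
            best = (score, c)
    return best[1], 100.0 * best[0] / L


class TestTwoParentModel:
    def test_pure_parent_query_scores_100(self, divergent_refs):
        q = divergent_refs["R1"]
        bp, mid = best_two_parent_model(q, divergent_refs["R1"], divergent_refs["R2"])
        assert mid == pytest.approx(100.0)

    def test_clean_construct_recovers_junction(self, divergent_refs):
        m = 100
        a, b = divergent_refs["R1"], divergent_refs["R2"]
        q = a[:m] + b[m:]
        bp, mid = best_two_parent_model(q, a, b)
        assert mid == pytest.approx(100.0)
        # ties resolve to the smallest breakpoint, so bp marks the start of
        # the locally identical run ending at the true junction
        assert bp <= m
        assert q[bp:m] == b[bp:m]

    def test_identical_parents_degenerate(self, divergent_refs):
        q = divergent_refs["R1"]
        bp, mid = best_two_parent_model(q, q, q)
        assert bp == 0 and mid == pytest.approx(100.0)

    def test_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(40):
            n = int(rng.integers(60, 260))
            a = random_seq(rng, n)
            b = mutate(a, rng.uniform(0.05, 0.5), rng)
            q = mutate(a[:n // 2] + b[n // 2:], 0.03, rng)
            got = best_two_parent_model(q, a, b)
            exp = oracle_breakpoint(q, a, b)
            assert got[0] == exp[0]
            assert got[1] == pytest.approx(exp[1])


class TestClassifyChimera:
    def test_reference_copy_is_not_chimeric(self, divergent_refs):
        for mode in ("balanced", "sensitive"):
            call = classify_chimera(divergent_refs["R2"], divergent_refs, mode=mode)
            assert not call.is_chimera

    def test_clean_construct_called_in_both_modes(self, divergent_refs):
        q = divergent_refs["R1"][:120] + divergent_refs["R2"][120:]
        for mode in ("balanced", "sensitive"):
            call = classify_chimera(q, divergent_refs, mode=mode)
            assert call.is_chimera
            assert {call.parent_a, call.parent_b} == {"R1", "R2"}
            assert call.breakpoint <= 120
            assert q[call.breakpoint:120] == divergent_refs["R2"][call.breakpoint:120]
            assert call.best_model_identity >= call.best_single_identity

    def test_sensitive_contains_balanced(self, divergent_refs):
        """Any read balanced mode flags, sensitive mode flags too."""
        rng = np.random.default_rng(13)
        n_checked = 0
        for noise in (0.0, 0.01, 0.02, 0.03, 0.05):
            for _ in range(8):
                m = int(rng.integers(40, 200))
                q = mutate(divergent_refs["R1"][:m] + divergent_refs["R2"][m:], noise, rng)
                bal = classify_chimera(q, divergent_refs, mode="balanced")
                sen = classify_chimera(q, divergent_refs, mode="sensitive")
                if bal.is_chimera:
                    assert sen.is_chimera
                n_checked += sen.is_chimera
        assert n_checked > 0

    def test_self_chimera_never_called(self, divergent_refs):
        """A construct whose two parents are the same reference is a normal read."""
        q = divergent_refs["R1"][:100] + divergent_refs["R1"][100:]
        for mode in ("balanced", "sensitive"):
            assert not classify_chimera(q, divergent_refs, mode=mode).is_chimera

    def test_invariant_to_reference_order(self, divergent_refs):
        q = divergent_refs["R1"][:120] + divergent_refs["R2"][120:]
        call1 = classify_chimera(q, divergent_refs)
        call2 = classify_chimera(q, dict(reversed(list(divergent_refs.items()))))
        assert (call1.is_chimera, call1.parent_a, call1.parent_b, call1.breakpoint) == \
               (call2.is_chimera, call2.parent_a, call2.parent_b, call2.breakpoint)


class TestAccounting:
    def test_no_chimeras_means_zero_true_rate(self, mock_refs):
        reads = [(f"r{i}", seq) for i, seq in enumerate(list(mock_refs.values())[:10])]
        acc, *_ = chimera_accounting(reads, mock_refs, mock_refs)
        assert acc.rate_true == 0.0

    def test_identical_reference_sets_leave_nothing_undetected(self, mock_refs):
        ids = sorted(mock_refs)
        q = mock_refs[ids[0]][:130] + mock_refs[ids[20]][130:]
        reads = [("chim", q)] + [(f"r{i}", mock_refs[ids[i]]) for i in range(5)]
        acc, *_ = chimera_accounting(reads, mock_refs, mock_refs)
        assert acc.n_true >= 1
        assert acc.n_undetected == 0

    def test_degraded_database_detects_subset(self, mock_refs, clean_chimeric_pool):
        """Removing references can only lose detections, never add them."""
        reads = [(f"r{i}", m.seq) for i, m in enumerate(clean_chimeric_pool[:300])]
        full = classify_reads(reads, mock_refs, mode="sensitive", reference_set="database")
        kept = dict(list(sorted(mock_refs.items()))[:20])
        degraded = classify_reads(reads, kept, mode="sensitive", reference_set="database")
        full_ids = {r for r, c in full.items() if c.is_chimera}
        degraded_ids = {r for r, c in degraded.items() if c.is_chimera}
        assert degraded_ids <= full_ids
        assert len(degraded_ids) < len(full_ids)

    def test_truth_mode_recall_on_clean_chimeras(self, mock_refs, clean_chimeric_pool):
        reads = [(f"r{i}", m.seq) for i, m in enumerate(clean_chimeric_pool)]
        truth = {f"r{i}": m for i, m in enumerate(clean_chimeric_pool)}
        calls = classify_reads(reads, mock_refs, mode="sensitive")
        n_chim = sum(1 for m in clean_chimeric_pool if m.origin == "chimera")
        tp = sum(1 for r, c in calls.items() if c.is_chimera and truth[r].origin == "chimera")
        fp = sum(1 for r, c in calls.items() if c.is_chimera and truth[r].origin != "chimera")
        assert n_chim > 50
        assert tp / n_chim >= 0.85
        assert fp <= 0.01 * len(reads)

    def test_chimeric_reads_gc_summary_present(self, mock_refs, external_db,
                                               clean_chimeric_pool):
        reads = [(f"r{i}", m.seq) for i, m in enumerate(clean_chimeric_pool[:400])]
        acc, *_ = chimera_accounting(reads, mock_refs, external_db, mode="sensitive")
        assert acc.gc_chimeric_mean is not None
        assert acc.gc_non_chimeric_mean is not None
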