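"""Simulator behaviour: chimera formation mechanics, protocol effects,
sequencing noise model, contaminants, and determinism."""

import collections

import numpy as np
import pytest

from ampmock.simulate import (CROSSTALK_PARTNER, Molecule, SimParams,
                              inject_contaminants, make_contaminants,
                              method_params, simulate_library, simulate_pcr,
                              simulate_reads)
from ampmock.align import edit_distance


def chimera_fraction(design, params, n, seed):
    pool = simulate_pcr(design, params, n, rng=np.random.default_rng(seed))
    return sum(m.origin == "chimera" for m in pool) / len(pool)


class TestPcr:
    def test_no_incomplete_extension_no_chimeras(self, communities):
        params = SimParams(cycles_step1=12, cycles_step2=0, incomplete_ext_prob=0.0)
        pool = simulate_pcr(communities["Bm1"], params, 400,
                            rng=np.random.default_rng(0))
        assert all(m.origin != "chimera" for m in pool)

    def test_error_free_pcr_reproduces_design_amplicons(self, communities, mock_refs):
        params = SimParams(cycles_step1=12, cycles_step2=0,
                           pol_error_rate=0.0, incomplete_ext_prob=0.0)
        pool = simulate_pcr(communities["Bm1"], params, 400,
                            rng=np.random.default_rng(1))
        amplicons = set(mock_refs.values())
        assert all(m.seq in amplicons for m in pool)

    def test_chimera_fraction_increases_with_cycles(self, communities):
        """More PCR cycles accumulate more chimeric products."""
        fracs = {}
        for cycles in (10, 20, 30):
            vals = [chimera_fraction(communities["Bm1"],
                                     SimParams(cycles_step1=cycles, cycles_step2=0,
                                               incomplete_ext_prob=0.03),
                                     800, seed) for seed in (1, 2, 3)]
            fracs[cycles] = np.mean(vals)
        assert fracs[10] < fracs[20] < fracs[30]

    def test_two_step_forms_fewer_chimeras_than_one_step(self, communities):
        """10+20 cycles with fresh reagents beat a single 30-cycle PCR."""
        one = [chimera_fraction(communities["Bm1"],
                                SimParams(cycles_step1=30, cycles_step2=0,
                                          incomplete_ext_prob=0.03), 800, s)
               for s in (1, 2, 3)]
        two = [chimera_fraction(communities["Bm1"],
                                SimParams(cycles_step1=10, cycles_step2=20,
                                          incomplete_ext_prob=0.03), 800, s)
               for s in (1, 2, 3)]
        assert np.mean(two) < np.mean(one)

    def test_low_gc_dominant_community_forms_fewer_chimeras(self, communities):
        """GC-dependent re-annealing: low-GC-heavy community below high-GC-heavy."""
        params = SimParams(cycles_step1=30, cycles_step2=0, incomplete_ext_prob=0.03)
        low = [chimera_fraction(communities["Bm2"], params, 800, s) for s in (1, 2, 3)]
        high = [chimera_fraction(communities["Bm3"], params, 800, s) for s in (1, 2, 3)]
        assert np.mean(low) < np.mean(high)

    def test_truth_chimeras_are_single_breakpoint_two_parent(self, clean_chimeric_pool,
                                                             mock_refs):
        for m in clean_chimeric_pool:
            if m.origin == "chimera":
                pa, pb = m.parent_ids
                assert pa != pb
                assert 0 < m.breakpoint <= len(mock_refs[pa])
            else:
                assert m.breakpoint is None

    def test_primer_mismatched_strains_suppressed(self, strains, communities):
        flagged = {s.strain_id for s in strains if s.primer_mismatches_fwd > 0}
        assert flagged
        params = SimParams(cycles_step1=20, cycles_step2=0,
                           pol_error_rate=0.0, incomplete_ext_prob=0.0)
        pool = simulate_pcr(communities["Bm1"], params, 2000,
                            rng=np.random.default_rng(3))
        counts = collections.Counter(m.parent_ids[0] for m in pool)
        mean_ok = np.mean([counts[s.strain_id] for s in strains
                           if s.primer_mismatches_fwd == 0])
        for sid in flagged:
            assert counts[sid] < 0.25 * mean_ok

    def test_oversampling_warns(self, communities):
        params = SimParams(cycles_step1=2, cycles_step2=0, n_initial=50,
                           incomplete_ext_prob=0.0)
        with pytest.warns(UserWarning):
            pool = simulate_pcr(communities["Bm1"], params, 500,
                                rng=np.random.default_rng(0))
        assert len(pool) == 500


class TestContaminants:
    def test_rate_zero_is_identity(self, contaminants):
        pool = [Molecule("ACGT" * 60, "strain", ("S1",))] * 10
        assert inject_contaminants(pool, contaminants, 0.0) == pool

    def test_rate_one_replaces_everything(self, contaminants):
        pool = [Molecule("ACGT" * 60, "strain", ("S1",))] * 10
        out = inject_contaminants(pool, contaminants, 1.0, np.random.default_rng(0))
        assert all(m.origin == "contaminant" for m in out)

    def test_rate_binomial(self, contaminants):
        pool = [Molecule("ACGT" * 60, "strain", ("S1",))] * 20000
        out = inject_contaminants(pool, contaminants, 0.01, np.random.default_rng(1))
        n = sum(m.origin == "contaminant" for m in out)
        se = np.sqrt(20000 * 0.01 * 0.99)
        assert abs(n - 200) <= 3 * se

    def test_empty_contaminant_set_rejected(self):
        with pytest.raises(ValueError):
            inject_contaminants([], {}, 0.5)

    def test_contaminants_divergent_from_mocks(self, contaminants, mock_refs):
        for c in contaminants.values():
            assert all(edit_distance(c, m) > 0.30 * len(c) for m in mock_refs.values())


class TestSequencing:
    def _pool(self, seq="ACGT" * 64):
        return [Molecule(seq, "strain", ("S1",))]

    def test_pure_crosstalk_miscalls_stay_in_pair(self):
        params = SimParams(read_length=200, qual_decay_fwd=(10, 10),
                           qual_decay_rev=(10, 10), qual_jitter_sd=0.0,
                           crosstalk_bias=1.0)
        pool = self._pool()
        fwd, rev, truth = simulate_reads(pool * 50, params, rng=np.random.default_rng(2))
        tpl = pool[0].seq
        n_miscalls = 0
        for _, seq, _ in fwd:
            for obs, true in zip(seq, tpl):
                if obs != true:
                    n_miscalls += 1
                    assert obs == CROSSTALK_PARTNER[true]
        assert n_miscalls > 50  # Q10 means 10% per base

    def test_q20_realises_one_percent_error(self):
        params = SimParams(read_length=250, qual_decay_fwd=(20, 20),
                           qual_decay_rev=(20, 20), qual_jitter_sd=0.0)
        pool = self._pool("ACGT" * 64)
        n_reads = 400  # 2 x 400 x 250 = 2e5 bases
        fwd, rev, truth = simulate_reads(pool * n_reads, params,
                                         rng=np.random.default_rng(3))
        total = sum(t.n_seq_substitutions for t in truth)
        bases = 2 * n_reads * 250
        p = 0.01
        se = np.sqrt(bases * p * (1 - p))
        assert abs(total - bases * p) <= 3 * se

    def test_noise_free_reads_match_template(self, mock_refs):
        from ampmock.io import reverse_complement
        params = SimParams(read_length=250, qual_decay_fwd=(40, 40),
                           qual_decay_rev=(40, 40), qual_jitter_sd=0.0)
        tpl = list(mock_refs.values())[0]
        fwd, rev, truth = simulate_reads([Molecule(tpl, "strain", ("S",))], params,
                                         rng=np.random.default_rng(4))
        t = truth[0]
        if t.n_seq_substitutions == 0:
            assert fwd[0][1] == tpl[:250]
            assert rev[0][1] == reverse_complement(tpl)[:250]

    def test_every_read_has_one_truth_record(self, communities, contaminants):
        lib = simulate_library(communities["Bm1"], method_params("non_phasing"),
                               120, "libX", contaminants, seed=5)
        fwd_ids = [r[0] for r in lib.fwd]
        truth_ids = [t.read_id for t in lib.truth]
        assert sorted(fwd_ids) == sorted(set(fwd_ids))
        assert sorted(fwd_ids) == sorted(truth_ids)

    def test_library_is_deterministic(self, communities, contaminants):
        a = simulate_library(communities["Bm1"], method_params("two_step_phasing"),
                             60, "libD", contaminants, seed=9)
        b = simulate_library(communities["Bm1"], method_params("two_step_phasing"),
                             60, "libD", contaminants, seed=9)
        assert a.fwd == b.fwd and a.rev == b.rev
        assert [t.__dict__ for t in a.truth] == [t.__dict__ for t in b.truth]


class TestParams:
    def test_probability_bounds_validated(self):
        with pytest.raises(ValueError):
            SimParams(pol_error_rate=1.5)
        with pytest.raises(ValueError):
            SimParams(cycles_step1=40)

    def test_spacer_sum_must_be_seven(self):
        with pytest.raises(ValueError):
            SimParams(spacer_scheme={"lib1": (3, 3)})
        SimParams(spacer_scheme={"lib1": (3, 4)})  # valid

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            method_params("three_step")
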