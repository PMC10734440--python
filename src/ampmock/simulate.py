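"""Ground-truth-labeled amplicon simulator.

Models the mechanistic picture behind PCR chimera formation and MiSeq-style
sequencing noise:

* per-cycle template duplication with polymerase substitution errors;
* incomplete extension producing a fragment pool, with a per-cycle
  "reagent fatigue" ramp so late cycles abort more often — this is what
  makes a fresh-reagent two-step protocol (10+20 cycles) form fewer
  chimeras than a one-step protocol at the same total cycle count;
* fragment re-annealing to a new template with probability
  logistic(a + b*GC): GC-rich fragments bind more strongly, so high-GC
  communities form more chimeras; a fragment that lands on a template of
  its own strain yields a self-chimera, labeled as a normal product;
* primer-mismatch suppression of flagged strains (x0.1 per forward-primer
  mismatch), reproducing consistently low-recovery strains;
* paired-end reads with linear quality decay (reverse worse than forward),
  miscalls at probability 10^(-Q/10) biased toward the fluorophore partner
  (A<->C, G<->T), and Phred+33 FASTQ output;
* contaminant injection and a truth sidecar labeling every read.

Also houses the synthetic reference generators: 33 mock strains in three
11-member GC clusters (cluster means 51.16 / 55.1 / 59.3% by construction)
and a divergent contaminant set (<70% identity to any mock strain).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .align import edit_distance
from .design import (PRIMER_515F, PRIMER_806R, MockDesign, Strain,
                     assign_gc_clusters, build_design, extract_v4, gc_fraction)
from .io import reverse_complement, write_fastq, write_tsv

BASES = "ACGT"
# fluorophore pairs behind cross-talk miscalls
CROSSTALK_PARTNER = {"A": "C", "C": "A", "G": "T", "T": "G"}

METHODS = ("non_phasing", "one_step_phasing", "two_step_phasing")


@dataclass
class SimParams:
    """Protocol and noise parameters for one simulated library."""

    cycles_step1: int = 35
    cycles_step2: int = 0
    pol_error_rate: float = 5e-5      # substitutions per base per copy event
    incomplete_ext_prob: float = 0.015  # per copy event, before fatigue ramp
    ext_fatigue: float = 0.05          # per-cycle relative increase, reset each step
    chimera_gc_coeffs: tuple[float, float] = (-3.0, 4.0)  # logistic(a + b*GC)
    contaminant_rate: float = 0.0
    read_length: int = 250
    qual_decay_fwd: tuple[float, float] = (36.0, 18.0)  # (start Q, end Q)
    qual_decay_rev: tuple[float, float] = (34.0, 5.0)
    #: Q(t) = end + (start-end) * (1 - t^shape); >1 = flat early, diving tail
    qual_decay_shape: float = 4.0
    qual_jitter_sd: float = 2.0
    crosstalk_bias: float = 0.8
    spacer_scheme: Optional[dict[str, tuple[int, int]]] = None
    p_amp: float = 0.9
    primer_mismatch_penalty: float = 0.1  # amp multiplier per fwd-primer mismatch
    n_initial: int = 4000
    pool_cap: int = 12000
    min_frag_len: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("pol_error_rate", "incomplete_ext_prob", "contaminant_rate",
                     "crosstalk_bias", "p_amp", "primer_mismatch_penalty"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0,1]")
        if self.cycles_step1 > 35 or self.cycles_step2 > 35:
            raise ValueError("cycles per PCR step must be <= 35")
        if self.spacer_scheme:
            for lib, (f, r) in self.spacer_scheme.items():
                if f + r != 7:
                    raise ValueError(f"library {lib}: spacer lengths {f}+{r} != 7")


def method_params(method: str, **overrides) -> SimParams:
    """Preset parameters for the three library-preparation protocols.

    Non-phasing and one-step phasing run a single 35-cycle PCR; two-step
    phasing runs 10 target-primer cycles then 20 phasing-primer cycles with
    fresh reagents. Phasing improves base diversity, hence better quality
    curves, with the reverse read always worse than the forward.
    """
    presets = {
        "non_phasing": dict(cycles_step1=35, cycles_step2=0,
                            qual_decay_fwd=(36.0, 18.0), qual_decay_rev=(34.0, 5.0)),
        "one_step_phasing": dict(cycles_step1=35, cycles_step2=0,
                                 qual_decay_fwd=(37.0, 22.0), qual_decay_rev=(35.0, 10.0)),
        "two_step_phasing": dict(cycles_step1=10, cycles_step2=20,
                                 qual_decay_fwd=(38.0, 26.0), qual_decay_rev=(36.0, 14.0)),
    }
    if method not in presets:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    kwargs = dict(presets[method])
    kwargs.update(overrides)
    return SimParams(**kwargs)


@dataclass
class Molecule:
    """One template in the PCR pool."""

    seq: str
    origin: str                      # strain | chimera | contaminant
    parent_ids: tuple[str, ...]
    breakpoint: Optional[int] = None
    n_pcr_subs: int = 0
    amp_weight: float = 1.0          # multiplier on p_amp (primer suppression)


@dataclass
class TruthRecord:
    read_id: str
    origin: str
    parent_ids: tuple[str, ...]
    breakpoint: Optional[int]
    n_pcr_substitutions: int
    n_seq_substitutions: int
    library_id: str


def logistic(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


# ---------------------------------------------------------------------------
# synthetic references

_GC_TARGETS = {"low": 51.16, "medium": 55.1, "high": 59.3}
_GC_SPREAD = {"low": 2.1, "medium": 1.8, "high": 3.3}
V4_LENGTH = 253


def _seq_with_gc_count(ancestor: str, gc_count: int, divergence: float,
                       rng: np.random.Generator) -> str:
    """Derive a strain V4 from the ancestor with an exact G+C count.

    GC is adjusted by flipping A/T<->G/C at random positions; extra neutral
    within-pair swaps (A<->T, G<->C) add divergence without moving GC.
    """
    seq = list(ancestor)
    at_pos = [i for i, b in enumerate(seq) if b in "AT"]
    gc_pos = [i for i, b in enumerate(seq) if b in "GC"]
    delta = gc_count - len(gc_pos)
    if delta > 0:
        for i in rng.choice(len(at_pos), size=delta, replace=False):
            seq[at_pos[i]] = rng.choice(["G", "C"])
    elif delta < 0:
        for i in rng.choice(len(gc_pos), size=-delta, replace=False):
            seq[gc_pos[i]] = rng.choice(["A", "T"])
    swap = {"A": "T", "T": "A", "G": "C", "C": "G"}
    n_swaps = rng.binomial(len(seq), divergence)
    for i in rng.choice(len(seq), size=n_swaps, replace=False):
        seq[i] = swap[seq[i]]
    return "".join(seq)


def _resolve_iupac(primer: str, rng: np.random.Generator) -> str:
    from .design import IUPAC
    return "".join(b if b in "ACGT" else rng.choice(list(IUPAC[b])) for b in primer)


def make_mock_strains(
    seed: int = 0,
    n_mismatched: int = 3,
    divergence: float = 0.10,
) -> list[Strain]:
    """Build 33 synthetic mock strains in three 11-member GC clusters.

    Per-cluster V4 GC targets are symmetric around the cluster means
    51.16 / 55.1 / 59.3%, so each cluster mean is reproduced by
    construction (up to the 1/253 GC granularity). ``n_mismatched`` strains
    carry 1-2 deliberate forward-primer mismatches and become the design's
    consistently low-recovery members.
    """
    rng = np.random.default_rng(seed)
    ancestor = "".join(rng.choice(list(BASES), p=[0.225, 0.275, 0.275, 0.225])
                       for _ in range(V4_LENGTH))
    strains: list[Strain] = []
    idx = 0
    # 0.8 sigma keeps the clusters disjoint so rank-thirds clustering is exact
    offsets = np.linspace(-0.8, 0.8, 11)
    for cluster in ("low", "medium", "high"):
        targets = _GC_TARGETS[cluster] + offsets * _GC_SPREAD[cluster]
        for t in targets:
            idx += 1
            sid = f"MC{idx:02d}"
            gc_count = int(round(t / 100.0 * V4_LENGTH))
            v4 = _seq_with_gc_count(ancestor, gc_count, divergence, rng)
            pad5 = "".join(rng.choice(list(BASES)) for _ in range(30))
            pad3 = "".join(rng.choice(list(BASES)) for _ in range(30))
            fwd_site = _resolve_iupac(PRIMER_515F, rng)
            rev_site = reverse_complement(_resolve_iupac(PRIMER_806R, rng))
            full = pad5 + fwd_site + v4 + rev_site + pad3
            strains.append(Strain(strain_id=sid, phylum=f"phylum{idx:02d}", full_seq=full))
    # plant forward-primer mismatches in a few strains (low-recovery members)
    mm_targets = rng.choice(len(strains), size=n_mismatched, replace=False)
    for j, si in enumerate(sorted(mm_targets)):
        s = strains[si]
        n_mm = 1 + (j % 2)
        site_start = 30
        # mutate non-degenerate primer positions only
        fixed = [k for k, b in enumerate(PRIMER_515F) if b in "ACGT"]
        pos = rng.choice(fixed, size=n_mm, replace=False)
        seq = list(s.full_seq)
        for p in pos:
            cur = seq[site_start + p]
            seq[site_start + p] = rng.choice([b for b in BASES if b != cur])
        s.full_seq = "".join(seq)
    for s in strains:
        extract_v4(s)
    assign_gc_clusters(strains)
    return strains


def make_contaminants(n: int = 12, seed: int = 1,
                      mock_strains: Optional[Sequence[Strain]] = None) -> dict[str, str]:
    """Random amplicon-length contaminant references, <70% identity to mocks."""
    rng = np.random.default_rng(seed)
    mock_seqs = [s.v4_seq for s in (mock_strains or []) if s.v4_seq]
    out: dict[str, str] = {}
    attempts = 0
    while len(out) < n:
        attempts += 1
        if attempts > 50 * n:
            raise RuntimeError("could not generate sufficiently divergent contaminants")
        seq = "".join(rng.choice(list(BASES)) for _ in range(V4_LENGTH))
        # unit-cost edit distance lower-bounds scored differences, so this
        # guarantees identity < 70% under the package convention
        if all(edit_distance(seq, m) > 0.30 * V4_LENGTH for m in mock_seqs):
            out[f"CONT{len(out) + 1:02d}"] = seq
    return out


def standard_communities(strains: Sequence[Strain]) -> dict[str, MockDesign]:
    """The three study communities: even, low-GC-dominant, high-GC-dominant."""
    bm1 = build_design(strains, "even", community_id="Bm1")
    bm2 = build_design(strains, "tiered",
                       {"low": 8.41, "medium": 0.67, "high": 0.01}, community_id="Bm2")
    bm3 = build_design(strains, "tiered",
                       {"low": 0.01, "medium": 0.67, "high": 8.41}, community_id="Bm3")
    return {"Bm1": bm1, "Bm2": bm2, "Bm3": bm3}


# ---------------------------------------------------------------------------
# PCR

def _mutate(seq: str, n_subs: int, rng: np.random.Generator) -> str:
    pos = rng.choice(len(seq), size=n_subs, replace=False)
    s = list(seq)
    for p in pos:
        s[p] = rng.choice([b for b in BASES if b != s[p]])
    return "".join(s)


def simulate_pcr(design: MockDesign, params: SimParams, n_final: int,
                 rng: Optional[np.random.Generator] = None) -> list[Molecule]:
    """Simulate one- or two-step PCR and return ``n_final`` labeled products.

    Each cycle duplicates templates with probability ``p_amp`` (scaled down
    by 0.1 per forward-primer mismatch for flagged strains), adds
    substitutions at ``pol_error_rate`` per copied base, and aborts copies
    at a rising (fatigued) incomplete-extension probability. Aborted
    fragments may re-anneal next cycle with probability logistic(a + b*GC)
    to a template drawn from the pool, forming a single-breakpoint chimera
    (self-chimera if both parents share a strain). Two-step protocols reset
    the fragment pool and the fatigue ramp between steps.
    """
    if n_final < 1:
        raise ValueError("n_final must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    a, b = params.chimera_gc_coeffs
    amplifiable = [s for s in design.strains if s.v4_seq]
    if not amplifiable:
        raise ValueError("design has no amplifiable strains")
    probs = np.array([design.expected_abundance[s.strain_id] for s in amplifiable], float)
    probs /= probs.sum()
    counts = rng.multinomial(params.n_initial, probs)
    pool: list[Molecule] = []
    for s, c in zip(amplifiable, counts):
        w = params.primer_mismatch_penalty ** s.primer_mismatches_fwd
        pool.extend(Molecule(s.v4_seq, "strain", (s.strain_id,), amp_weight=w)
                    for _ in range(c))

    steps = [c for c in (params.cycles_step1, params.cycles_step2) if c > 0]
    for cycles in steps:
        frag_pool: list[Molecule] = []  # fresh reagents: no carried-over fragments
        for cycle in range(1, cycles + 1):
            q_eff = min(1.0, params.incomplete_ext_prob * (1.0 + params.ext_fatigue * cycle))
            # convert last cycle's fragments into chimeric full-length products
            new_products: list[Molecule] = []
            if frag_pool and pool:
                gcs = np.array([gc_fraction(f.seq) / 100.0 for f in frag_pool])
                anneal = rng.random(len(frag_pool)) < 1.0 / (1.0 + np.exp(-(a + b * gcs)))
                partners = rng.integers(0, len(pool), size=len(frag_pool))
                for frag, ok, pi in zip(frag_pool, anneal, partners):
                    if not ok:
                        continue
                    partner = pool[pi]
                    bp = len(frag.seq)
                    if partner.origin == "chimera" and partner.breakpoint is not None \
                            and partner.breakpoint > bp:
                        # suffix would span the partner's own junction, giving a
                        # three-parent product; out of scope, no product formed
                        continue
                    seq = frag.seq + partner.seq[bp:]
                    p_a = frag.parent_ids[0]
                    # suffix past the partner's junction comes from its 3' parent
                    p_b = partner.parent_ids[-1]
                    if p_a != p_b:
                        new_products.append(Molecule(
                            seq, "chimera", (p_a, p_b), breakpoint=bp,
                            n_pcr_subs=frag.n_pcr_subs + partner.n_pcr_subs,
                            amp_weight=frag.amp_weight))
                    else:  # self-chimera: indistinguishable from a normal product
                        new_products.append(Molecule(
                            seq, "strain", (p_a,), breakpoint=None,
                            n_pcr_subs=frag.n_pcr_subs + partner.n_pcr_subs,
                            amp_weight=frag.amp_weight))
            frag_pool = []
            # duplication with errors and incomplete extension
            n = len(pool)
            amp_p = np.fromiter((params.p_amp * m.amp_weight for m in pool), float, count=n)
            do_copy = rng.random(n) < amp_p
            idx = np.nonzero(do_copy)[0]
            n_subs = rng.binomial([len(pool[i].seq) for i in idx], params.pol_error_rate)
            aborts = rng.random(len(idx)) < q_eff
            copies: list[Molecule] = []
            for i, k, abort in zip(idx, n_subs, aborts):
                m = pool[i]
                seq = _mutate(m.seq, int(k), rng) if k else m.seq
                if abort and len(seq) > params.min_frag_len + 1:
                    end = int(rng.integers(params.min_frag_len, len(seq)))
                    if m.origin == "chimera" and m.breakpoint is not None \
                            and end > m.breakpoint:
                        # fragment spans the parent's junction; re-annealing it
                        # would create a multi-parent product — drop the abort
                        continue
                    frag_pool.append(Molecule(seq[:end], "strain", (m.parent_ids[0],),
                                              n_pcr_subs=m.n_pcr_subs + int(k),
                                              amp_weight=m.amp_weight))
                else:
                    copies.append(replace(m, seq=seq, n_pcr_subs=m.n_pcr_subs + int(k)))
            pool.extend(copies)
            pool.extend(new_products)
            if len(pool) > params.pool_cap:
                keep = rng.choice(len(pool), size=params.pool_cap, replace=False)
                pool = [pool[i] for i in keep]

    if n_final > len(pool):
        warnings.warn(f"n_final={n_final} exceeds pool size {len(pool)}; sampling with replacement")
        take = rng.choice(len(pool), size=n_final, replace=True)
    else:
        take = rng.choice(len(pool), size=n_final, replace=False)
    return [pool[i] for i in take]


def inject_contaminants(pool: list[Molecule], contaminants: dict[str, str],
                        rate: float, rng: Optional[np.random.Generator] = None) -> list[Molecule]:
    """Replace each product by a random contaminant amplicon with prob ``rate``."""
    if rate > 0 and not contaminants:
        raise ValueError("contaminant_rate > 0 but no contaminant sequences given")
    if rate == 0:
        return list(pool)
    rng = rng if rng is not None else np.random.default_rng(0)
    ids = sorted(contaminants)
    out = []
    for m in pool:
        if rng.random() < rate:
            cid = ids[int(rng.integers(0, len(ids)))]
            out.append(Molecule(contaminants[cid], "contaminant", (cid,)))
        else:
            out.append(m)
    return out


# ---------------------------------------------------------------------------
# sequencing

def _quality_curve(n: int, start_q: float, end_q: float, shape: float = 4.0) -> np.ndarray:
    if n == 1:
        return np.array([start_q])
    t = np.arange(n) / (n - 1)
    return end_q + (start_q - end_q) * (1.0 - t ** shape)


def _call_read(template: str, expected_q: np.ndarray, params: SimParams,
               rng: np.random.Generator) -> tuple[str, list[int], int]:
    n = len(template)
    quals = np.clip(np.rint(expected_q[:n] + rng.normal(0, params.qual_jitter_sd, n)),
                    2, 40).astype(int)
    p_err = 10.0 ** (-quals / 10.0)
    miscall = rng.random(n) < p_err
    seq = list(template)
    n_err = 0
    for i in np.nonzero(miscall)[0]:
        true_base = seq[i]
        if rng.random() < params.crosstalk_bias:
            seq[i] = CROSSTALK_PARTNER[true_base]
        else:
            others = [x for x in BASES if x not in (true_base, CROSSTALK_PARTNER[true_base])]
            seq[i] = others[int(rng.integers(0, 2))]
        n_err += 1
    return "".join(seq), quals.tolist(), n_err


def simulate_reads(
    pool: Sequence[Molecule],
    params: SimParams,
    library_id: str = "lib",
    rng: Optional[np.random.Generator] = None,
) -> tuple[list[tuple[str, str, list[int]]], list[tuple[str, str, list[int]]], list[TruthRecord]]:
    """Sequence a product pool into paired reads plus a truth sidecar.

    The forward read covers the 5' end of each product, the reverse read the
    reverse complement of the 3' end. Miscalls occur at 10^(-Q/10) and stay
    within the fluorophore pair (A<->C, G<->T) with probability
    ``crosstalk_bias``.
    """
    rng = rng if rng is not None else np.random.default_rng(params.seed + 1)
    L = params.read_length
    fwd_curve = _quality_curve(L, *params.qual_decay_fwd, shape=params.qual_decay_shape)
    rev_curve = _quality_curve(L, *params.qual_decay_rev, shape=params.qual_decay_shape)
    fwd_reads, rev_reads, truth = [], [], []
    for i, mol in enumerate(pool):
        read_id = f"{library_id}:r{i:06d}"
        f_tpl = mol.seq[:L]
        r_tpl = reverse_complement(mol.seq)[:L]
        f_seq, f_quals, f_err = _call_read(f_tpl, fwd_curve, params, rng)
        r_seq, r_quals, r_err = _call_read(r_tpl, rev_curve, params, rng)
        fwd_reads.append((read_id, f_seq, f_quals))
        rev_reads.append((read_id, r_seq, r_quals))
        truth.append(TruthRecord(read_id, mol.origin, mol.parent_ids, mol.breakpoint,
                                 mol.n_pcr_subs, f_err + r_err, library_id))
    return fwd_reads, rev_reads, truth


# ---------------------------------------------------------------------------
# convenience

@dataclass
class SimulatedLibrary:
    library_id: str
    fwd: list[tuple[str, str, list[int]]]
    rev: list[tuple[str, str, list[int]]]
    truth: list[TruthRecord]

    def truth_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.truth:
            rows.append({
                "read_id": t.read_id, "origin": t.origin,
                "parent_ids": ",".join(t.parent_ids),
                "breakpoint": "" if t.breakpoint is None else t.breakpoint,
                "n_pcr_substitutions": t.n_pcr_substitutions,
                "n_seq_substitutions": t.n_seq_substitutions,
                "library_id": t.library_id,
            })
        return pd.DataFrame(rows)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fastq(self.fwd, outdir / f"{self.library_id}_R1.fastq")
        write_fastq(self.rev, outdir / f"{self.library_id}_R2.fastq")
        write_tsv(self.truth_frame(), outdir / f"{self.library_id}_truth.tsv", index=False)


def simulate_library(
    design: MockDesign,
    params: SimParams,
    n_reads: int,
    library_id: str,
    contaminants: Optional[dict[str, str]] = None,
    seed: Optional[int] = None,
) -> SimulatedLibrary:
    """One library end to end: PCR -> contaminant injection -> sequencing.

    PCR and sequencing use independent RNG streams spawned from one seed, so
    outputs are reproducible bit-for-bit given (seed, params).
    """
    root = np.random.default_rng(params.seed if seed is None else seed)
    pcr_rng, seq_rng, cont_rng = [np.random.default_rng(s) for s in root.integers(0, 2**31, 3)]
    pool = simulate_pcr(design, params, n_reads, rng=pcr_rng)
    if params.contaminant_rate > 0:
        pool = inject_contaminants(pool, contaminants or {}, params.contaminant_rate, cont_rng)
    fwd, rev, truth = simulate_reads(pool, params, library_id, rng=seq_rng)
    return SimulatedLibrary(library_id, fwd, rev, truth)
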