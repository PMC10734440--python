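# Methods

This note documents the models, parameter choices, and numerical
conventions behind `ampmock`, and what the synthetic benchmark does and
does not establish about real sequencing data.

## The mock community

The design models 33 bacterial 16S clones split into three 11-member
clusters by V4 GC content, with cluster means 51.16%, 55.1%, and 59.3%.
The synthetic generator derives every strain's V4 (253 bp) from one
ancestor: A/T↔G/C flips set an exact per-strain G+C count, and neutral
within-pair swaps (A↔T, G↔C) at ~10% of positions add divergence without
moving GC. Per-cluster GC targets are symmetric around the cluster mean
(offsets ±0.8 cluster-SD), so the means above hold by construction and the
clusters are disjoint in GC — rank-thirds clustering recovers the intended
membership exactly. Real designs cluster "mostly" by GC with exceptions;
`assign_gc_clusters` accepts an explicit override table for that case.
Pairwise strain identity lands around 80–90%, comparable to congeneric V4
sequences: close enough that chimera detection and 97% OTU clustering are
non-trivial, far enough that the 33 strains form distinct OTUs.

Three strains carry 1–2 deliberate forward-primer mismatches. They remain
in the design but amplify at 0.1× per mismatch, reproducing the
consistently-low-recovery strains that primer mismatch causes in practice.

Communities: Bm1 assigns 100/33 = 3.03% to every strain; Bm2 and Bm3
assign the tiers 8.41 / 0.67 / 0.01% to whole GC clusters (Bm2 puts the
low-GC cluster on top, Bm3 the high-GC cluster).

## PCR model

Each cycle, every template duplicates with probability `p_amp` (0.9,
scaled by the primer penalty). Copies acquire substitutions at
`pol_error_rate` (5×10⁻⁵ per base per copy event, mid-range for a
non-proofreading polymerase; over 30 cycles this accumulates ~0.1–0.2%
per-base PCR error, the floor that survives quality trimming). A copy
aborts with probability `incomplete_ext_prob × (1 + 0.05·cycle)` — the
linear "reagent fatigue" ramp models depleting reagents, and is what makes
a fresh-reagent two-step protocol (10+20 cycles) form fewer chimeras than
a one-step 30–35-cycle protocol at similar totals. Aborted fragments
(uniform abort position, ≥30 bp) enter a fragment pool; next cycle each
re-anneals to a pool template with probability logistic(−3 + 4·GC), the
free-energy proxy for GC-dependent duplex stability (GC 0.50 → ~0.27,
GC 0.60 → ~0.35), and extends into a full-length product whose breakpoint
is the fragment end. A fragment landing on a template of its own strain
yields a self-chimera, recorded as a normal product — this is why
communities dominated by few strains show lower apparent chimera rates.
Chimeras are strictly two-parent/single-breakpoint: pairings or fragments
that would span an existing junction are dropped rather than creating
multi-parent products, which are out of scope.

`incomplete_ext_prob` defaults to 0.015. Chimera accrual is approximately
linear in this parameter; 0.015 places the one-step 35-cycle truth chimera
fraction at the ~10% order that mock-community experiments report, with
two-step around 6–8%. The pool is capped at 12,000 molecules (uniform
subsampling preserves composition); the initial pool of 4,000 molecules
means the 0.01% tier starts at ~0.4 expected copies per strain — such
strains are frequently absent entirely, which is the intended
under-sequencing regime, not an artifact.

## Sequencing model

Reads are 250 bp, substitution-only. Expected quality follows
Q(t) = Q_end + (Q_start − Q_end)(1 − t⁴): flat early, diving tail, as in
real short-read profiles. Reverse curves sit below forward; phasing
protocols get higher curves (non-phasing rev 34→5, one-step 35→10,
two-step 36→14), reflecting the base-diversity benefit of spacer phasing.
Per-base miscall probability is 10^(−Q/10) with jitter-perturbed integer
qualities (SD 2, clipped to [2,40]); a miscall stays within its
fluorophore pair (A↔C, G↔T) with probability 0.8, else lands uniformly on
the other two bases. Phasing spacers (forward+reverse = 7) are carried as
library metadata; indel errors, flow-cell physics, and barcode errors are
not modeled. PCR, contaminant, and sequencing randomness use independent
streams spawned from one seed, so libraries are bit-reproducible.

## Trimming, merging, filtering

Trimming keeps the longest contiguous segment in which every fully
contained window (width 2 or 5) has mean quality ≥ the threshold (20, 25,
30); leftmost wins ties, and a segment shorter than the window passes on
its own mean. The windowed-trimming sentence this implements is ambiguous
between "longest passing segment" and "cut at first failing window"; the
first is the default, the second is available as `mode="prefix"` for
sensitivity analysis. Reads under 200 bases or containing N are dropped in
the OTU path; the error grid applies trimming but not the length filter,
since at stringent levels the filter would empty entire reverse-read
strata and the grid's purpose is to measure the surviving bases.

Merging scans all overlaps ≥20 bases, takes the one minimizing the
mismatch fraction (ties → longest), rejects above 25% mismatches, emits
the higher-quality base per conflicting column, and assigns max(q) on
agreement or |q1−q2| (floor 2) on conflict — FLASH-like conventions where
the underlying procedure leaves the arithmetic unstated.

## Chimera detection and accounting

Rather than reimplement a UCHIME-class scoring function, the criterion
here is explicit. For a query of length L, candidate parents are the
top-4 references by shared 8-mers plus the best-single-identity reference
(found by an edlib edit-distance screen over all references — unit-cost
edit distance lower-bounds scored differences, so the screen is safe; the
scored alignment of the shortlist decides). For each ordered candidate
pair, the two-parent model identity at breakpoint c is
(matches_A on [0,c) + matches_B on [c,L))/L, maximized in O(L) via prefix
sums; ties take the smallest c, so a reported breakpoint marks the start
of the locally identical run containing the true junction. A read is
chimeric iff model ≥ id_min, model − single ≥ δ, and the parents differ:
(δ, id_min) = (2.0, 98.0) balanced, (1.0, 96.0) sensitive. Sensitive calls
are a superset of balanced calls by construction. All scored alignments
use match +1 / mismatch −1 / gap −4 − 1 per base / free end gaps; identity
is matched columns over query length.

Accounting runs the classifier twice: against the mock references (true
chimeras) and against the external database (detected); undetected = true
minus detected. The packaged synthetic database holds a 98–99.8% relative
of most strains, 7 exact matches, and omits 4 strains — the omissions are
what produce the ~30–40% undetected fraction, mirroring how database
incompleteness, not detector failure, leaves chimeras in real data.

A detection limit worth knowing: a breakpoint within ~17 bases of an
amplicon end gives an identity gain below 1 point — indistinguishable from
a normal read at any threshold. With uniform abort positions this caps
clean-chimera recall near 0.9–0.93 (sensitive mode); every miss in
validation runs had gain < δ, i.e. the detector sits at the criterion's
information limit.

## Error profiling

Reads align to their best-hit reference (edit-distance screen, scored
identity decides, ties by id; reads under 50 bases are flagged
unalignable). Valid bases are aligned non-gap read bases; insertions count
at the preceding reference position, deletions at the skipped position;
rates pool all bases (total errors / total valid), not per-read means.
Substitution-only and all-error rates are both emitted. The grid
stratifies by library × read type (fwd/rev/merged) × trim level ×
before/after chimera removal, where "after" excludes reads the database
reference set flagged. Empty strata are emitted with valid = 0 and an
undefined rate.

## OTU pipeline

Rarefaction (uniform, without replacement, seeded) precedes all
processing; the pipeline rarefies to the smallest merged library unless
configured. Greedy first-fit clustering joins an abundance-ranked unique
to the first centroid with identity ≥ 97% and ≤ 7 differences (both
enforced — the 7-of-253 rule is applied conjunctively with the percentage
radius, since either alone admits edge cases at other lengths); centroids
never update. An edlib prescreen skips centroids whose edit distance
already exceeds 7; this cannot change the result because edit distance
lower-bounds scored differences.

Unique OTUs are those present in exactly one technical replicate:
singleton (1 read), doubleton (2), other_unique (>2). Classification order
per representative: (1) ≥97% identity to a mock strain and not chimeric →
that strain; (2) chimeric → chimera; (3) ≥70% to the external database and
<70% to the mocks → contaminant; (4) ≥70% to the mocks → erroneous;
(5) otherwise contaminant with a low-confidence flag. "Not matching the
mock database" is read as <70% identity; the precedence is fixed here
because the source rules are unordered.

## Statistics

One-sample two-tailed t-tests compare observed per-strain or per-cluster
percents to expected (zero-variance inputs are flagged degenerate).
One-way ANOVA uses scipy's F; Fisher's LSD uses the pooled MSE with
N − k degrees of freedom, protected by default (LSD only when ANOVA
rejects at α = 0.05). Compact letters are assigned greedily by descending
mean; groups share a letter iff all pairs within it are non-significant.
Pearson r is computed per library between observed and expected strain
abundances, then summarized as mean ± SD — defined only for tiered
communities, since an even design has a constant expected vector and the
correlation is undefined (flagged, reported as NaN).

## Problem sizes and determinism

Default evaluation sizes — a few hundred reads per library, a handful of
replicates, rarefaction at the smallest merged library — keep a full
simulate-and-evaluate cycle in minutes while leaving every contrast
(protocols, communities, trim levels) with clear effect sizes. The same
code runs at larger sizes unchanged. Every stochastic step draws from
generators derived from one configured seed; rerunning a config reproduces
FASTQ and reports byte-for-byte, and each output table carries the config
hash in a header comment.

## What the benchmark does and does not show

Passing tests establish that the analysis stack measures what the
simulator injected: error rates within binomial error, chimera recall at
the criterion's information limit, artifact classes recovered, and the
direction of every protocol/GC/abundance contrast. The simulator omits
indels, motif-dependent error hotspots, quality-score miscalibration,
barcode cross-talk, and chimera breakpoint hotspots at conserved regions;
real-data rates will differ in magnitude. Directional conclusions (two-step
< one-step chimera rates; low-GC communities form fewer chimeras; trimming
and merging reduce error; singletons concentrate artifacts; low-abundance
strains are under-sequenced) are the transferable content.
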