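# Methods

## The model

DamID fuses a protein of interest to *E. coli* Dam methyltransferase;
binding deposits adenine methylation at nearby GATC sites, which DpnII
digestion and amplification convert into sequencing reads anchored at GATC
motifs.  Two facts shape everything downstream: the native resolution unit
is the *GATC fragment* (interval between consecutive motifs), and the
Dam-alone control measures accessibility-driven background methylation that
must be divided out.

Per fragment, the fusion channel (count `c_x` of `t_x` reads) is compared
with the control (`c_d` of `t_d`) by a two-sided Fisher exact test on the
2×2 contingency table of (in fragment / elsewhere) × (channel).
Conditional on the margins the fragment cell is hypergeometric with support
of width ≤ `c_x + c_d + 1`, so the two-sided P (sum of outcome
probabilities not exceeding the observed table's, with the conventional
1+1e-7 tie guard) is computed by explicit summation over that support,
vectorised across fragments.  This is exact — the test suite checks it
against scipy's `fisher_exact` and against brute-force enumeration with
integer binomials — and fast enough to sweep whole tracks repeatedly.

The direction of the effect is carried separately as a sign
(+1 enriched / −1 depleted / 0 equal rates), so that a single two-sided
statistic yields both the positive (enriched) and negative (depleted)
peaks of the conventional track display.  The effect size is `log2((c_x/t_x + p/m) / (c_d/t_d + p/m))`
with pseudocount `p = 0.5` converted to the rate scale by the mean channel
depth `m = (t_x + t_d)/2`.  Putting the pseudocount on the rate scale
(rather than adding 0.5 to each count) keeps the ratio order-consistent
with the raw rate comparison even when channel depths differ, so the sign
of the log ratio always agrees with the test's enrichment sign — an
invariant the test suite asserts.

Replicates are summed per channel before testing; replicate-to-replicate
disagreement is deliberately *not* averaged away but used as the noise
yardstick for threshold calibration (below).  −log₁₀ P is capped at 300 to
keep serialised tracks finite.

## Replicate-calibrated FDR and peak criteria

A fragment is peak-eligible iff sign = +1, P ≤ min(t\*, 10⁻³) and
log₂ ratio > 1.  Runs of adjacent eligible fragments merge into one peak —
no gap tolerance, because the fragment is the method's resolution unit —
with the summit at the most significant fragment (leftmost on ties) and
the summit-fragment midpoint used for every distance computation.

t\* comes from an empirical false-discovery estimate: the identical
compound calling procedure is applied to a noise track built by Fisher-
testing fusion replicate 1 against replicate 2 (fusion replicates bound the
worst-case noise; a flag switches to Dam-alone replicates).
`FDR(t) = noise peaks / max(signal peaks, 1)` over a grid of 50 log-spaced
thresholds in [10⁻³, 10⁻¹²]; t\* is the loosest grid point with
FDR ≤ 0.05, falling back to the tightest point (with a warning) when the
curve never dips that low — which is the correct behaviour on null data,
where signal and noise are exchangeable and the ratio hovers near 1.
Counting merged intervals means the per-threshold peak count can tick up
by one when tightening splits a peak; the monotone quantities are the
eligible-fragment count and the nesting of tight peaks inside loose ones,
and those are what the tests assert.

Depleted regions are called symmetrically (sign −1, log₂ ratio < −1).

## Annotation and integration conventions

* Promoter = 400 bp upstream of the TSS, strand-aware, truncated at
  chromosome edges.  Summits are classified by precedence
  promoter > 5′UTR > CDS > intron > 3′UTR (the categories overlap in real
  annotations; precedence makes them disjoint), remainder intergenic.
  Expected probabilities for the binomial enrichment test are base-pair
  coverages under the same precedence, recomputed per run.
* TSS distances are summit-to-TSS, unsigned by default (a signed,
  strand-oriented mode exists); alternative TSSs are separate rows, and a
  transcript is peak-proximal if *any* of its TSSs qualifies.
* Direct target: ≥ 8-fold down-regulation in the cognate mutant — computed
  as (FPKM_wt + 1)/(FPKM_mut + 1) ≥ 8, the pseudocount handling zero
  FPKM — plus a summit within 1 kb of a TSS; the significance flag from
  the differential-expression table is required by default (`require_sig`).
  Up-regulated transcripts are never direct targets.
* Co-binding uses the same 1 kb criterion; 2×2 tests are chi-square
  without Yates correction, replaced by Fisher's exact test whenever an
  expected cell is below 5.
* Dynamics presence = summit within ±300 bp of a TSS (boundary inclusive),
  genotype order (*bam*, *aly*, *can*, wt).  Groups I (1,1,1,1) and II
  (1,0,0,0) are fixed by definition; the shipped defaults III = (0,0,0,1),
  IV = (0,0,1,1), V = (1,1,0,0), VI = (1,0,1,1) are conventions satisfying
  the constraints that III/IV acquire binding in spermatocytes and V/VI
  bind already in spermatogonia, and are configurable.  Unmapped patterns
  are "minor", optionally Hamming-merged to the nearest canonical pattern
  (ties stay minor).  Assignment is a pure function of the pattern — no
  iterative clustering — so it is reproducible and parameter-free.
* Tissue specificity: target log-ratio > 0 and every other tissue < 0 or
  null; missing values count as null expression and are encoded as NA,
  never as zero.

## What the generator emulates

`simulate_study` produces a 1 Mb single-chromosome genome (~4000 GATC
fragments at the natural 1/256 motif density), 300 non-overlapping genes on
a jittered grid with promoter/UTR/CDS/intron structure, per-gene binding
truth, count tables, coupled expression and a 10-tissue log-ratio matrix.

Counts follow a Poisson-gamma hierarchy.  The Dam-alone rate of a fragment
is length × lognormal accessibility (σ = 0.5), fixed per genome; each
biological replicate draws a per-fragment Gamma(1/α, α) state (α = 0.05)
shared by the fusion and control libraries collected together, and the
fusion rate multiplies planted fragments by the effect size (default 8);
reads are Poisson at 2×10⁵ per library.  Marginally every library is
negative binomial with dispersion α, the fusion-vs-control comparison is
calibrated (it shares the replicate state), and the replicate-vs-replicate
comparison is overdispersed — exactly the structure that makes an
empirical, replicate-based FDR necessary rather than decorative.  Poisson
replicates would make the noise track degenerate; independent
overdispersion in all four libraries would make the null channel
comparison as noisy as the replicates and the Fisher test meaningless.
The shared-within-replicate state is the one structure consistent with
both calibration and non-trivial noise.

A GATC pair is planted ±150 bp around every TSS, so each promoter owns a
well-covered fragment whose midpoint stays inside the ±300 bp presence
window.  This fixes the generator's resolution at promoters; real genomes
have no such guarantee, and promoters sitting on very long or very short
natural fragments would be measured correspondingly worse.  Passing tests
therefore demonstrate correctness of the statistical machinery under
fragment-level-resolvable binding, not robustness to unfavourable motif
geometry.

Expression coupling: direct targets drop 12–50-fold in the cognate mutant
(so the ≥8-fold rule holds after pseudocounts), factor-repressed genes
(drawn from the spermatogonial dynamics groups) rise ≥4-fold in the shared
factor's mutant, everything else fluctuates by lognormal noise (σ = 0.15)
that never crosses the 4-fold rule.  Testis-specific transcripts are
planted preferentially (weight 5) in the spermatocyte-acquired groups,
ovary-specific in the spermatogonial groups, mirroring the direction of
the biology; the tissue matrix encodes them exactly per the selection
rule, with every non-specific transcript violating it in at least one
neutral tissue.  Coupling probability, fractions, depths and dispersions
are all `SimConfig` fields.

What the generator does **not** emulate: mappability and copy-number
variation, GC bias, PCR duplicates, motif-content effects, partial or
heterogeneous cell populations within a genotype, and real gene-model
complexity (overlapping genes, many isoforms).  Conclusions about those
regimes cannot be drawn from these simulations.

## Numerical and degenerate-input choices

* Two-sided P values within 10⁻¹¹ of 1 are snapped to exactly 1 so that
  identical-proportion tables satisfy P = 1 identically.
* A chromosome without any GATC yields a single fragment and a warning;
  empty sequences are errors.  Minus-strand reads anchor at the right
  fragment boundary (the DpnII fragment end); reads not starting with GATC
  or not anchored at a boundary are discarded and tallied, multi-mapping
  reads are dropped by default (flag to keep).
* Empty peak sets give zero counts and P = 1 in enrichment; empty target
  sets give NA folds; empty dynamics groups give NA rows; a single
  replicate cannot calibrate an FDR and raises.
* The desk-scale preset (1 Mb, 300 genes, depth 2×10⁵, 20-seed batches in
  validation) keeps the full pipeline and its validation suite in the
  low minutes on one CPU; larger genomes only change runtime linearly.

## Known limitations

* The attained level of the two-sided exact test on a null study is ~0.042
  rather than 0.05 — the usual conservativeness of exact conditional tests
  at modest counts (many short fragments carry few reads).  It is in the
  safe direction and disappears as depth grows.
* On studies with few true peaks the FDR curve may never reach 0.05 on the
  default grid (noise and signal extremes are then comparable); the
  tightest-grid-point fallback is deliberate and warned about.
* Colocalization significance uses a binomial model per offset bin around
  permutation-based expectations; bins are not independent of one another,
  so per-bin P values should be read marginally.
* The merged "exon" category of common annotation conventions overlaps
  UTR/CDS; this package reports CDS and UTRs separately under a precedence
  order (a merged category can be added in configuration).
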