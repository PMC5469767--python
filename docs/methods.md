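# Methods

## Problem and scope

`apascope` detects differential alternative cleavage and polyadenylation
(APA) between two groups of RNA-Seq samples from per-base 3′UTR coverage.
It targets the two-isoform case — one proximal and one distal polyA site
per gene — which covers the dominant biological signal in compartment
comparisons (axon vs cell body, injured vs control). Multi-site
segmentation, direct polyA-site calling from 3′-end-seq protocols, read
alignment, and differential-expression model fitting are out of scope;
DE results are consumed as an external table.

## Search space

Each gene is represented by the transcript with the longest annotated
3′UTR (ties broken by transcript id). The APA search space is the
genomically contiguous terminal-exon 3′UTR — from the stop codon's 3′
edge to the annotated transcript end — extended downstream, strand-aware,
by `min(10 kb, distance to the nearest annotated transcript boundary on
either strand)`. Blocking on both strands is conservative: it avoids
absorbing antisense coverage into the extension. Spliced long 3′UTRs
(a distal exon separated by an intron) are not modeled explicitly; they
surface as distal read clusters inside the extension and are detected the
same way. Transcript-relative offset 0 is the first base after the stop
codon; minus-strand coverage is reversed on read so arrays always run
5′→3′.

## Distal polyA site

The distal end *D* is found on coverage merged across all compared
samples (element-wise sum): the scan walks 3′-ward through runs where
coverage ≥ `max(min_abs, frac × anchor mean)` with `anchor_len = 100` nt,
`frac = 0.05`, `min_abs = 1.0`, bridging low-coverage gaps up to
`gap_tol = 50` nt. The gap tolerance bridges alignment dropouts without
absorbing separate downstream genes. A gene whose anchor region has no
coverage is untestable.

## Breakpoint regression and PDUI

Coverage truncated to *D* is fitted with a step-plus-baseline model: one
breakpoint *P* shared by all samples, per-sample weights
`w_long = mean over (P, D)` and `w_short = max(0, mean over [0, P] −
w_long)`. The total squared residual over all samples is minimized by
exhaustive enumeration of every `P ∈ [min_flank, D − min_flank)`
(`min_flank = 50` nt), computed in O(D) per sample with prefix sums and
verified in tests against a literal per-candidate re-computation. Ties in
residual break toward the smallest P (the most proximal site). A uniform
track has `w_short = 0` everywhere; the fit then reports PDUI = 1 with a
degeneracy flag rather than failing. A shared breakpoint is what makes
PDUIs comparable across samples; per-sample weights absorb depth and
expression differences, making *P* and PDUI invariant to rescaling all
tracks by a constant.

## Significance and classification

With replicates, per-sample fitted densities are converted to
read-equivalents — `long = w_long × D / frag_len`,
`short = w_short × (P + 1) / frag_len`, rounded — with `frag_len = 350`
nt, the targeted library insert size. Counts pool within each group into
a 2×2 long/short table tested with a two-sided Fisher exact test (an
all-zero margin yields p = 1); Benjamini–Hochberg adjustment runs across
all tested genes. A gene is *lengthened* when q < `alpha` and
ΔPDUI ≥ `min_dpdui`, *shortened* for ΔPDUI ≤ −`min_dpdui`; defaults
`alpha = 0.05`, `min_dpdui = 0.2` (a common effect floor in APA practice —
the test construction with replicates is a package design choice, since
only significance levels, not machinery, are standard in this setting).
A coverage gate (anchor mean ≥ 20 in every compared sample, raw counts)
keeps meaningless fits out of the multiple-testing pool.

## Bias correction

Coverage non-uniformity along the gene body is handled by an opt-in
`linear_detrend` mode (default off): a least-squares line is fitted to
log1p(coverage) over the distal half of the region — long-isoform-only
under a proximal breakpoint, so the step does not contaminate the slope —
evaluated over the full region, floored at 0.25× its mean to avoid
blow-ups, divided out, and rescaled to preserve the mean. Tracks shorter
than 100 nt are returned unchanged with a warning. Paired simulations at
decay slope 0.5 show the corrected PDUI estimate is less biased than the
raw one.

## Isoform quantification

FPKM is `fragments × 10⁹ / (length × total_fragments)`. The long-isoform
share is the ratio of per-base mean densities, `f_long = min(1,
distal_density / common_density)`, with the common domain defaulting to
the first 400 nt after the stop codon (the region shared by the short and
long isoforms) and the distal segment `(P, D)`. Per-base means rather
than summed reads make the ratio independent of segment lengths; the
clip at 1 absorbs ratio-estimator noise at low coverage instead of
erroring. `fpkm_long + fpkm_short = fpkm_total` holds identically.
Comparative-CT support is the standard `2^−ΔΔCT` fold change.

## Motif scanning

Sequences are scanned as transcribed (sense strand only, 5′→3′); U is
read as T. PolyA-signal search reports every exact, possibly overlapping
hexamer occurrence; the canonical set is AAUAAA, with AUUAAA available by
configuration. PWM scanning scores each window as
`Σ_j log2(p_regularized[base_j, j] / background_j)` with pseudocount
0.01 and uniform 0.25 background; N contributes 0 (background). Hits
require a relative score — position within the span between the minimal
and maximal attainable window scores — of at least 0.8 by default. A PWM
whose extremes coincide (e.g. uniform) has no defined relative score and
is rejected as degenerate. Implementation is vectorized numpy, tested
against both a window-by-window oracle and Biopython PSSM scores.

## Synthetic data

The generator emulates a compartmentalized 2 × 2 × 3 design: groups
ipsi/contra × axon/body, 3 replicates each. Per gene: true distal end *L*
uniform in 500–2000 nt, breakpoint at 0.4 × L, per-base coverage
`Poisson(depth × (1 − bias_beta × i/L) × (π + (1 − π) · 1[i ≤ P]))` with
`depth = 50`, `bias_beta = 0` by default. Gene classes set the distal
usage π per group — lengthened (axon 0.8 vs body 0.3, 25% of genes),
shortened (0.2 vs 0.6, 15%), stable (0.5, 60%) — strong, clearly
separated effects appropriate for validating recovery. 30% of genes have
their annotated transcript end at 0.6 × L so the long isoform appears as
a distal read cluster inside the extension, the signature of an
unannotated 3′UTR. AATAAA hexamers are planted starting at offsets P and
L − 6 in the emitted FASTA. Output (BED12, per-sample bedGraph, FASTA,
sample sheet, truth table) is byte-deterministic given the seed.

What the simulation does **not** emulate: overdispersion beyond Poisson,
fragment-level effects (coverage is generated directly, not from reads),
splicing, GC bias, mappability gaps, and multi-gene overlap beyond the
nearest-neighbor spacing. Passing recovery tests therefore demonstrates
correctness of the inference given the model, not robustness to every
artifact of real libraries; the bias mode and the gap tolerance are the
two knobs addressing real-data deviations.

## Numerical choices and degenerate inputs

Exhaustive enumeration (no heuristic search) makes the fit exactly
reproducible; prefix-sum arithmetic agrees with naive summation to ~1e-9
relative. Read-equivalents round to integers for the exact test. All-zero
tracks give undefined PDUI; a gene missing PDUI in an entire group, or
with D < 2 × min_flank, is untestable and excluded from testing (and from
the BH pool). Fisher p-values come from `scipy.stats.fisher_exact`, BH
from `statsmodels`; both are cross-checked in tests against direct
enumeration and hand-computed step-up values.

## Validation problem sizes

The acceptance checks run at sizes chosen to give tight Monte-Carlo error
while staying desk-scale: 50 instances for oracle equivalence (D ≤ 400,
1–6 samples), 200 genes for recovery (D = 500, 50×), 300 genes for null
calibration, 200 for power, 30 PWM/sequence pairs, and a 40-gene
end-to-end determinism run. Typical results (seed 1): PDUI RMSE ≈ 0.009,
100% of breakpoints within 10 nt, 0% null calls, 100% power at
π = 0.9 vs 0.3 — all recomputed, never stored, by
`scripts/acceptance.py`.

## Known limitations

- One breakpoint per gene: genes with ≥3 used polyA sites are summarized
  by the best two-isoform approximation.
- The Fisher test on pooled read-equivalents treats per-base densities as
  independent fragment counts; with long fragments and few replicates the
  effective sample size is approximate, which is why the ΔPDUI effect
  floor, not the p-value alone, gates classification.
- Annotation choice (which transcript set defines gene ends) materially
  affects results and is deliberately left to the user.
- The extension rule cannot separate a genuine long 3′UTR from an
  unannotated downstream gene closer than 10 kb with continuous coverage;
  the gap tolerance (50 nt) is the only guard.
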