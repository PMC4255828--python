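# Methods

## Scope and model

The package re-implements, as a tested pipeline over synthetic and
packaged worked-example data, a screening analysis for early sexed embryo
transcriptomes: quality trimming, RPKM quantification, per-comparison
quantile normalisation, a weighted proportions differential-expression
test with FDR control, marker-calibrated expression ceilings, and a
multi-contrast set-intersection screen over the eight-library BJ1–BJ8
design (2 sexes × 2 collection windows × 2 replicate pools).

## Read quality control

Trimming is the modified Mott algorithm: base score `limit − p_err`,
`p_err = 10^(−Q/10)`, and the retained region is the contiguous segment
maximising the score sum, found with Kadane's algorithm in O(L). Ties are
broken leftmost-then-longest so output is deterministic; the test suite
checks exact agreement with an O(L²) enumeration oracle on 1,000 random
reads. Trimming precedes filtering (ambiguity, then length); whether the
original workbench applied the ambiguity filter before trimming is
unknowable from its documentation, so the order here is fixed and stated.
Defaults: error limit 0.05, ≤2 ambiguous bases, minimum length 50 nt,
Phred+33 (Phred+64 selectable). `bases_removed` counts trimmed bases from
every input read whether or not the read survives filtering.

## Quantification and normalisation

RPKM uses the library size supplied with the matrix (total mapped reads),
never a column sum inferred silently; "exon model" length is the full
contig length, as no exon structure exists for de novo contigs. Quantile
normalisation follows the standard order-statistic averaging; tied values
within a column receive the mean of the row-means over the tied rank
range. The normalisation scope is per comparison: only the samples
entering a contrast are normalised together, and the scope is recorded on
the matrix. This matters — normalised values are comparable only within
their scope.

## Sample QC ordination

PCoA is classical metric scaling (double-centred squared distances,
`eigh`), axes ordered by eigenvalue, negative eigenvalues reported but
their axes dropped. The default metric is plain Euclidean distance on the
expression values handed in, and QC should run it on **raw** RPKM: that
configuration is the metric-scaling equivalent of a PCA on expression
values and robustly exposes a developmentally lagging library. Two
alternatives are selectable but were measured to be unsuitable for this
purpose: a log2(x+1) Euclidean metric compresses a linear early/late
mixture toward the high-expression profile (a 0.8-lagged library moves
only ~37 % of the way toward the early profile in log space and keeps
ordinating with its replicate), and quantile-normalised input forces
identical column multisets, erasing the magnitude signal entirely.

## The weighted proportions test

For one transcript and a group of libraries with counts `x_i` and totals
`n_i`, proportions `p_i = x_i/n_i` are modelled as binomial sampling
around a group proportion with between-library variance σ². The two-stage
weighted estimate: start with weights ∝ `n_i`; pool `p̂ = Σw_i p_i`; solve
σ² ≥ 0 by bisection of the moment identity `Σ(p_i−p̂)²/v_i = k−1` with
`v_i = p̂(1−p̂)/n_i + σ²`; reweight `w_i ∝ 1/v_i`; iterate to `|Δp̂| <
1e−12` (≤100 rounds). `V = 1/Σ(1/v_i)`; a single library gives the
binomial fallback `V = p̂(1−p̂)/n`. Groups are compared with
`t = (p̂_A−p̂_B)/√(V_A+V_B)`.

**Reference distribution.** Replicated contrasts use Student's t with
`k_A+k_B−2` df. When either group is unreplicated, the statistic is
referenced against the standard normal: the variance on that side is the
*known* binomial one, not an estimate, and a t reference with df = 1 is a
Cauchy whose tails make any small significance level unreachable
regardless of effect size (p = 2/(π|t|) ≈ 0.002 even at |t| = 280) — an
unreplicated contrast would otherwise be silently dead. The df is
reported as `inf` in that case.

**Calibration.** Under a 2v2 negative-binomial null the test is calibrated
(p < 0.05 rate within 3 Monte-Carlo SE of 0.05 at 5,000 transcripts) in
the regime where between-library variation dominates counting noise (mean
counts ≳ 2,000 at dispersion 0.01). At low counts the variance floor —
the binomial term plus σ² clipped at zero — makes the test strictly
conservative, never anti-conservative. Conversely, unreplicated contrasts
ignore between-library variation by construction and are therefore
anti-conservative on overdispersed data; the screen treats their output
accordingly (they are auxiliary evidence, intersected with replicated
contrasts, and a warning is logged when one runs).

**Input bridge.** The test is applied to quantile-normalised expression
through pseudo-counts `x = round(value·L·N/10⁹)` — the exact inverse of
the RPKM formula with each library's true size as the binomial total.
This keeps the proportions interpretable while testing on the normalised
scale. Fold changes are signed ratios of group means (negative when the
case mean is lower, magnitude ≥ 1; double-zero means give a degenerate
+1, single zeros a flagged infinite magnitude — no pseudocounts are
added). FDR control is Benjamini–Hochberg step-up (via statsmodels),
cross-checked against the step-up definition.

## The screen

Fourteen contrasts A–N over BJ1–BJ8 mirror the standard screen layout:
sex contrasts (A–G, case = male) and time contrasts (H–N, case = late),
each with its exclusions — the lagging BJ1 (and its early counterpart
BJ5) are dropped from the workhorse rows. Per contrast: significance at
FDR < 0.001, direction selection by fold-change sign, then the expression
ceiling (female mean < 5 RPKM for sex rows; early mean < 50 RPKM for time
rows). The 50 comes from marker calibration: the early mean of the *sisA*
homologue (44.72) × 1.2 = 53.66, rounded down to the nearest 10 (floored
at 10); both raw and operational values are reported. Intersections are
written in a small set-expression language (`&`, `|`, `-`, parentheses);
the default final set is `(I & L) − (I & L & N)`. Provenance records, per
transcript, every selection, filter removal and intersection drop.

**A structural property worth knowing.** A transcript expressed in males
only (zero in every female library) is found easily by the unreplicated
sex rows (B, D) and the male-only time row (L), but it cannot reach
significance in the replicated mixed-sex time contrast I: its case group
looks like (high, ~0, ~0), for which the weighted statistic is scale-free
(|t| ≈ 1 whatever the magnitude). The final intersection therefore holds
shared zygotic transcripts with male-biased evidence, not strictly
male-limited ones. The recovery driver and the acceptance suite measure
this honestly: ~0.98 sensitivity for the male-limited class in row B,
0 in the final set. Sporadic single-library contaminants show the mirror
behaviour — admitted by the unreplicated sex rows, excluded by the
intersection path.

## Profile classification

`classify_profile` labels a transcript from its early/late means and the
early-vs-late significance call: `undetected` below the detection floor
(default 0.25 normalised RPKM, the lowest credible non-zero signal in the
packaged panel); `zygotic` when the early mean is below the maternal
threshold and the rise is significant; `maternal` when the early mean is
at/above the threshold without a significant rise; `maternal_plus_zygotic`
when both hold; `ambiguous` otherwise. The maternal threshold is a
biological judgement, not the screen's 50-RPKM ceiling: a threshold of
~10 normalised RPKM separates recognised maternal transcripts (*tra-2*-like,
early ≈ 45) from zygotic ones that leak early (*slam*-like, early ≈ 4);
with the 50-RPKM ceiling as threshold, moderately expressed maternal
transcripts would fall to `ambiguous`. The threshold is therefore an
explicit argument.

## Synthetic cohort

Five transcript classes with committed default conditions: maternal_stable
(50 RPKM, flat), maternal_degrading (30 RPKM, ×0.1 early→late, smaug-like),
zygotic_shared (300 RPKM late, ×75, slam-like), zygotic_male_only (40 RPKM
late in males, ×20, exactly 0 in all female libraries), and
contaminant_sporadic (150 RPKM in exactly one random library). Counts are
NB with mean `rpkm·L·N/10⁹` and variance `m + φm²`; φ defaults to 0.01
(BCV 10 %, appropriate for pooled, genetically homogeneous embryo
collections; φ = 0 gives Poisson). Library sizes are N(2e6, 2e5) — a
desk-scale depth; the configured depth sets the scale of the means, so
column totals match the model-implied total (the sum of per-cell means)
rather than the configured depth itself. Lengths are uniform on
200–5,000 bp. One late male replicate (BJ1 by default) is lagged: its
expected profile is `(1−f)·late + f·early` with f = 0.8, reproducing the
observed clustering anomaly. Contaminant expression is a sample-specific
event and is not lagged. All randomness flows from one seed;
identical seeds give bit-identical matrices.

What the simulator does **not** model: genuine sequences or homology, GC
and positional bias, mapping ambiguity, library-preparation batch
effects, and transcript-length–expression correlation. Passing tests
therefore demonstrate the statistical behaviour of the pipeline under its
own noise model, not performance on real libraries.

## Problem sizes and numerics

Default simulated cohorts are 250 transcripts × 8 libraries; the null
calibration uses 5,000 transcripts × 4 libraries; oracle suites use 1,000
random instances. These sizes give Monte-Carlo standard errors small
enough for the stated bands while keeping any run under a few seconds.
Numerical choices: bisection for σ² (60 iterations on a bracket whose
upper end is `Σdev²/(k−1)`, which always bounds the root); convergence
tolerance 1e−12 on p̂; eigenvalue cutoff 1e−9 (relative) for retained
PCoA axes; BH q-values capped at 1; fold-change display caps ∞ at the
writer. Degenerate inputs: an all-zero transcript gets V = 0 and p = 1
against an all-zero partner; empty reads trim to the empty interval;
empty matrices round-trip through IO.

## Known limitations

- Exact p-values of the original workbench implementation are not
  reproducible (its internals are unpublished); worked-example targets are
  restricted to means, fold changes and thresholds, which are
  implementation-independent.
- The replicated-contrast t reference caps attainable significance at
  small k (df = 4 two-sided p cannot go far below ~1e−5 at |t| ≈ 30),
  which bounds per-transcript power at strict FDR levels; measured power
  for the ×75 zygotic class in the 3v3 time contrast is ~0.8 at the
  committed noise level.
- Single-replicate contrasts are anti-conservative on overdispersed data
  (no between-library variance is estimable); they are intersected with
  replicated contrasts rather than trusted alone.
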