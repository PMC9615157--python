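# Methods

## Model and procedure

`mirpair` analyses paired log2-scale expression matrices (features × samples,
already normalized and summarized upstream, e.g. by RMA) for one mRNA and one
miRNA modality over the same samples, labelled responder (R) or non-responder
(NR). Responder status follows the ALDA lithium-response scale: the total is
the A subscale minus the B subscale, clamped to the instrument's 0–10 range,
and a patient is a responder when the total is ≥ 7 (inclusive). Clamping
negative totals to 0 is this package's convention; the instrument defines the
score's range but not the behaviour when B exceeds A.

**Differential expression.** The group contrast is always reported R minus
NR. The default test is the classical pooled-variance two-sample t on
n_R + n_NR − 2 degrees of freedom, which squares to the one-way two-group
ANOVA F. The optional moderated test shrinks each feature's sample variance
toward a common prior,

    s̃²_g = (d0·s0² + d_g·s²_g) / (d0 + d_g),

with (d0, s0²) estimated by moment-matching the marginal distribution of
log s²_g via the digamma/trigamma relations (Newton inversion of the
trigamma function), the standard empirical-Bayes fit for microarray linear
models; the statistic is referred to a t distribution on d0 + d_g df. When
the observed variances carry no excess spread the prior df is infinite and
all variances collapse to the common value (logged as a warning). Features
with zero within-group variance in both groups are assigned t = 0, p = 1 and
flagged rather than dropped, keeping downstream pair counts deterministic.
Adjusted p-values use Benjamini–Hochberg throughout.

A feature is differentially expressed when |FC| ≥ 1.2 and p ≤ 0.05, both
inclusive; |FC| ≥ 1.2 is equivalent to |logratio| ≥ log2(1.2) ≈ 0.26303.

**Pair integration.** Pearson correlation is computed between every DE mRNA
and DE miRNA across the pooled samples of both groups — deliberately not
within-group, matching the upstream design this package reproduces. The
primary significance test is one-sided against ρ < 0 (the repression
hypothesis); a two-sided option exists. One-sidedness is also what the
published ρ ≤ −0.38 screen encodes: the one-sided 5% critical correlation at
n = 20 is 0.3783, while the two-sided value is 0.4438. The deregulation
weight S = −2·lr_miRNA·lr_mRNA is positive exactly when the pair moved in
opposite directions and grows with both shifts.

The cascade applies, cumulatively: correlation p ≤ 0.05; restriction to
mature, organism-matched miRNA probes and collapse of gene isoforms (keeping,
per (gene symbol, miRNA), the most negative correlation, ties broken by
smaller p then lexicographic ids — the keep-rule is this package's
convention); ρ ≤ −0.38; ρ ≤ −0.5; S > 0 (strict). Survivors are ranked by ρ
ascending, then p, then S descending, then ids, for full determinism. The BH
adjustment universe for pair p-values is the set of pairs actually tested
after zero-variance exclusion and isoform collapse. Stage cardinalities are
recorded after each step and are monotone non-increasing by construction.

## Synthetic cohorts

The generator emulates the target study design. Defaults: 11 R and 9 NR
samples; feature baselines uniform on [1, 8] log2 units; within-group
Gaussian noise with SD 0.5; a fraction `frac_de = 0.25` of features per
modality differentially expressed with |logratio| uniform on [0.3, 2.4] and
random sign; 300 mRNAs × 60 miRNAs; 10 planted miRNA→mRNA couplings with
target within-group correlation ρ* = −0.8. Sample sizes, the intensity and
log-ratio ranges, and the gates are fixed by the reproduced design; feature
counts and the DE fraction are chosen to give DE yields and pair counts of
the same order as that design at a size the full test suite can exercise in
seconds.

A planted pair's mRNA is regressed on its miRNA's realised noise:

    mRNA = baseline + group_effect − β·(miRNA − E[miRNA | group]) + N(0, σ_e),

with β = |ρ*|·σ_e / (σ_m·√(1 − ρ*²)) so the within-group population
correlation equals ρ*. The residual scale is σ_e = noise_sd·√(1 − ρ*²): the
coupling partitions the planted mRNA's variance rather than inflating it, so
planted features keep the same marginal noise SD — and hence the same
differential-expression power — as every other feature. Planted pairs get
opposite-direction group shifts (miRNA up in R and mRNA down, or the mirror,
chosen at random per pair), so their true S score is positive. One
`numpy.random.default_rng(seed)` generator drives the whole cohort; identical
seeds give bit-identical outputs.

What the generator does *not* emulate: probe-level microarray artifacts,
batch or hybridization effects, heavy-tailed or intensity-dependent noise,
correlated co-expression modules beyond the planted couplings, and shared
miRNA targets (off by default; a shared-target mode exists to exercise the
isoform/dedup logic). Passing tests therefore demonstrate correctness and
calibration of the pipeline's statistics under a clean Gaussian two-group
model, not robustness to real microarray pathology.

## What recovery tests can and cannot show

Because correlations are computed on pooled samples, any two features whose
group shifts point in opposite directions are truly anti-correlated through
the group mixture, with

    ρ_cross ≈ −c·d_x·d_y / √((c·d_x² + σ²)(c·d_y² + σ²)),   c = p(1−p) ≈ 0.2475

at an 11/9 split. For shifts |d| ≥ 1 and σ = 0.5 this lies between −0.5 and
−0.8, inside the final gate. Null features that pass the DE filter by chance
do so precisely when their noise aligns with the group split, so they too
acquire ≈ −0.5 empirical correlations with genuinely shifted features. The
cascade is therefore *sensitive* (planted couplings are essentially always
recovered and rank first, since their pooled correlation combines the
coupling and the shifts) but not *specific* against coupling truth: measured
over 20 seeds with ten planted-only DE pairs (|logratio| ∈ [1, 2.4],
ρ* = −0.8, 300 × 60 features, n = 20), recall is 1.0 while precision is
≈ 0.12. This mirrors the reproduced analysis itself, whose cascade retains
thousands of candidate pairs before prioritization: the output is an
enriched, ranked candidate list, not a validated interaction set. The test
suite asserts recall and ranking; the precision figure is reported as a
property of the method.

## Numerical choices and edge cases

- Correlations are clipped to [−1, 1] after the matrix product;
  zero-variance features yield undefined (NaN) correlations, are excluded
  from pair testing, and logged.
- `correlation_pvalue` at |ρ| = 1 returns the exact limit of the t-CDF
  (one-sided "less": 0 at ρ = −1, 1 at ρ = +1; two-sided: 0).
- `critical_r` inverts the t relation exactly: |ρ| = |t*|/√(n − 2 + t*²);
  the round trip with `correlation_pvalue` is exact to ≲1e-9.
- Signed fold change satisfies FC(0) = +1 exactly and FC(−x) = −FC(x) for
  x ≠ 0; magnitudes are never below 1.
- Pair tables are written with 2-decimal rounding (correlation p-values in
  2-significant-digit scientific notation), matching the published table's
  precision; matrices are written at full precision so write∘read is the
  identity.
- The permutation check of the correlation p-value averages over several
  vector pairs: at n = 8 the exact permutation null of a single fixed pair
  deviates from the t null by up to ~0.03 (conditioning and discreteness),
  so per-vector agreement within Monte-Carlo error alone cannot be expected.

## Known limitations

- The pooled-correlation screen confounds direct coupling with
  opposite-direction group shifts (see above); interpreting the final list
  requires orthogonal evidence (target prediction, perturbation data).
- The moderated-t prior fit assumes a common residual df across features and
  at least two features with positive variance.
- The fold-change/S-score identities of the bundled published table
  reproduce only up to propagation of its 2-decimal print rounding; the
  printed correlation p-values cannot be recomputed from the rounded ρ
  values and are carried as data, not re-derived.
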