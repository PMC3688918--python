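# Methods

`hypoxmet` implements the discriminant-analysis workflow used in untargeted
two-class UPLC-QTOFMS metabolomics: feature-table preprocessing, unsupervised
exploration with outlier statistics, PLS-DA with nested cross-validation, an
exhaustive label-permutation test with permutation-null variable selection,
accurate-mass annotation, and targeted MRM quantitation rules. This note
records the models, conventions and numerical choices; every empirical claim
below is computed by the test suite or by `scripts/acceptance.py`.

## Preprocessing

The input is a MarkerLynx-style aligned table: one row per detected marker
(retention time in minutes, m/z) and one intensity column per injection,
with 0 encoding "not detected". The filter chain is fixed and
order-dependent:

1. **Replicate collapse (X1).** Each biological sample's replicate
   injections (n = 3 by default) are collapsed to per-feature medians.
   Zeros participate: a marker seen in one of three replicates collapses
   to 0, which is the conservative reading of zero-filled aligned tables.
   An alternative "median of detected only" is deliberately not the
   default.
2. **Blank-feature removal (X2).** A feature detected (intensity above a
   configurable floor, default 0) in at least `min_blank_detections`
   (default 1) solvent-blank injections is treated as background and
   removed. The literature gives no threshold; one detection is the
   conservative choice for contaminant exclusion.
3. **Low-frequency filter (X3).** Features detected in fewer than
   `min_samples` (default 3) collapsed samples are removed; such markers
   are unreliable and inflate chance correlations.

Autoscaling (mean-centering, division by the standard deviation) uses the
sample (n−1) convention throughout; at n = 10 rows the distinction is
material. Zero-variance columns raise an error naming the feature in
interactive use and are dropped with a warning in batch mode.

QC metrics: internal-standard area RSD (100·SD/mean, ddof = 1), signed ppm
mass errors of the IS (1e6·(measured − reference)/reference, reference
reserpine m/z 609.2812), Pearson correlations between replicate intensity
vectors per sample, and per-feature replicate RSDs. Metrics without inputs
are reported as unavailable, never as zero.

## PCA, outlier statistics, clustering

PCA is computed by SVD of the pretreated matrix (equivalent to NIPALS-PCA
at convergence, deterministic and rank-safe). Per-component score
variances use ddof = 1. The Q residual of a row is its squared distance to
the model plane, `‖x − x L Lᵀ‖²`; Hotelling's T² is the sum of squared
scores normalized by per-component score variance, so the training mean of
T² is exactly A(n−1)/n.

95% limits: T² uses the F-form `A(n−1)(n+1)/(n(n−A)) · F₀.₉₅(A, n−A)`;
Q uses the Jackson–Mudholkar approximation from the residual eigenvalues,
falling back to the Box g·χ²ₕ form (g = θ₂/θ₁, h = θ₁²/θ₂) when fewer than
three informative residual eigenvalues remain or h₀ ≤ 0. Empirical
coverage of both limits is verified at ≈95% on multivariate-normal
simulations (2000 replicates, n = 50, p = 5, A = 2 — sizes chosen to keep
the check to seconds).

The number of components can be fixed or selected by leave-one-out
cross-validation. The PRESS is element-wise: pretreatment and PCA are
refit without the held-out row, and each variable of that row is predicted
from the remaining variables through the fold's loadings (least-squares
score estimate excluding the variable, computed by a Sherman–Morrison
downdate). A plain projection of the whole held-out row was considered and
rejected: its residual shrinks with every added component, so its
minimizer is always the search ceiling and it cannot identify the
informative rank.

Hierarchical clustering uses Ward's minimum-variance criterion on
Euclidean distances (scipy linkage), run on the scores of the retained
components; merge heights are tested against an independent
Lance–Williams recurrence.

## PLS-DA, dQ² and NMC

Class labels are coded 0 (hypoxia) / 1 (normoxia) and mean-centered within
each training fold; X is autoscaled with the fold's statistics
(leakage-free; a global-scaling variant can be had by scaling once and
passing `scale=False`). PLS1 components come from NIPALS deflation; for a
univariate response the weight update is stationary after one pass, and
the guard loop (tolerance 1e-12 on the weight change, capped at 500
iterations) exits on its confirming sweep. Cumulative regression vectors
for every truncation a are obtained from `B_a = W_a (P_aᵀW_a)⁻¹ q_a`,
where PᵀW is unit upper triangular, so plain back-substitution suffices.
Scores are mutually orthogonal; predictions satisfy ŷ = X·b exactly.

Out-of-fold predictions are mapped back to the 0/1 scale by adding the
training fold's label mean. On that scale:

- **dQ²** (discriminant Q²) is 1 − PRESS_D/TSS, where the residual of a
  prediction past its own class code in the correct direction (ŷ ≥ 1 for
  class 1, ŷ ≤ 0 for class 0) is set to zero, and TSS = Σ(y − ȳ)². With
  fold-wise centering this is algebraically identical to clipping at the
  fold-specific centered codes (−p, 1−p). dQ² ≥ the standard Q² on any
  input, since clipping can only shrink the PRESS.
- **NMC** counts predictions on the wrong side of the code midpoint 0.5;
  an exact tie counts as misclassified (the decision threshold is not
  stated in the source methodology; the midpoint is the natural choice and
  is documented here).

Model dimensionality (1..3 latent variables, ceiling 3) is chosen by
leave-one-out dQ², refitting pretreatment inside every fold; the smallest
dimensionality attaining the maximum wins ties.

## Double cross-validation and the permutation test

Leave-one-out double CV nests the dimensionality selection (inner LOO on
the n−1 training samples) inside an outer LOO whose held-out predictions
yield unbiased dQ²/NMC figures of merit; the mean of the n outer-fold
regression vectors is `b_real`.

The permutation test enumerates **all** class-size-preserving relabelings,
one per complement pair (a relabeling and its complement give mirror-image
models; the representative assigns position 0 to the low class code),
excluding the true labeling: C(10,5)/2 − 1 = 125 for a balanced 5 vs 5
design. Exhaustive enumeration makes every p-value deterministic given the
data. Running double CV under each relabeling gives null distributions of
dQ², NMC and the regression vector. Model p-values are plain fractions of
null statistics at least as extreme as the real ones (dQ²: ≥, NMC: ≤);
an add-one convention is available (`plus_one=True`). Per-feature
p-values take the smaller of the two per-tail fractions of `b_random`
values at least as extreme as `b_real`; features with p < 0.025 (per tail)
are selected. Signed tails are the default; absolute-value tails are
available. Because the feature matrix is fixed while labels permute, all
fold autoscaling statistics are computed once and shared across the 125
relabelings, which keeps the full test under two seconds at 10 × 112.

A structural property of this design worth knowing: 25 of the 125
relabelings share 4 of 5 labels per class with the truth and therefore
inherit ±0.6 of any real effect. These near-duplicates dominate the null
tails, so a feature must separate the classes decisively — not merely
significantly — before its two-tailed empirical p drops below 0.025 with
only 125 permutations. This is inherent to exhaustive permutation testing
at n = 10, not an artifact of the implementation.

Under an exchangeable-label null the whole procedure's dQ² p-value is
approximately uniform; the suite verifies a rejection rate within
binomial error of α = 0.05 over 200 simulated null datasets (generated at
60 features to keep the check around five minutes).

## Annotation and targeted quantitation

Accurate-mass annotation matches observed feature m/z against theoretical
positive-mode ions of a compound list — [M+H]⁺ (+1.00728 Da), [M+Na]⁺
(+22.98922 Da) and configured neutral losses, seeded with the formic-acid
loss CH₂O₂ (46.00548 Da) typical of pyroglutamic-acid in-source
fragmentation — within ±5 mDa by default, reporting signed errors;
shrinking the tolerance never adds matches.

MRM quantitation fits unweighted ordinary least squares of peak area on
concentration (≥3 points, ≥2 distinct concentrations; weighted regression
is knowingly not implemented), inverts the line for unknowns and flags
concentrations outside the standard-series range. Identity confirmation
requires all three criteria: transition co-elution within ±0.05 min
(tabulated transition RT SDs are an order of magnitude smaller),
confirm/quant abundance ratio within ±25% of a comparable standard's, and
SNR strictly above 9 for both transitions (exactly 9 fails). SNR is an
input field — computing it from raw chromatograms is out of scope. A
missing standard ratio leaves criterion (ii) indeterminate and the
identity unconfirmed, with the reason recorded. Extract concentrations in
nmol/mL convert to tissue loads as nmol/mg = conc/33.3 for homogenates
prepared at 33.3 mg tissue per mL.

## The synthetic-data generator

The generator emulates a two-class neonatal-hypoxia retina profiling
design: 5 + 5 biological samples × 3 replicate injections + 7 solvent
blanks (37 injections) over 365 aligned features, partitioned exactly into
136 blank-borne background contaminants (the only features detected in
blanks; present in ~95% of sample injections, as solvent/background ions
are), 117 low-frequency markers (nonzero replicate median in 1–2 samples),
and 112 reliable features, 8 of which carry the planted class effect. The
planted features use the retention-time/m/z identities and directions of
the emulated study's markers (CDP-choline [M+H]⁺ 489.1157 and [M+Na]⁺
511.0977 elevated in hypoxia; pyroglutamic acid and its in-source
fragment, CDP-DG, GSSG and two unidentified ions elevated in normoxia).

Distributional choices, with defaults:

- **Abundance:** per-feature log-normal, ln-mean 8.5, ln-sd 1.0
  (arbitrary intensity units; the analysis is scale-free after
  autoscaling). Low-frequency markers sit 2 ln units lower, near the
  detection limit.
- **Planted effect:** ±2 log₂ fold change, applied multiplicatively to the
  elevated class.
- **Biological variability:** ln-sd 0.15 (~15% CV) between samples within
  class.
- **Collinear response:** every reliable non-planted feature loads (ln-sd
  0.25, random sign) on one latent physiological score that shifts by 1
  between classes (within-class sd 0.25). This reproduces the collinear,
  metabolome-wide covariance of real tissue responses, in which a single
  principal component dominated by the class effect carries ~25–30% of
  the autoscaled variance; without it, 8 isolated markers could never
  dominate PC1.
- **Replicate noise:** multiplicative log-normal with σ = √ln(1+RSD²),
  RSD 14% — the internal-standard channel draws from the same law, so the
  IS area RSD lands near 14%.
- **Missingness:** a limit-of-detection mechanism. Sample-level detection
  is logistic in log abundance (midpoint 2.2 ln units below the abundance
  mean, unit scale), with reliable features floored at 3 detected samples
  and low-frequency features capped at 2, so the 365 → 229 → 112 filter
  trajectory is exact by construction. Replicate-level dropout uses the
  same logistic (capped at 0.5, at most one replicate of a detected cell),
  so abundant features essentially never lose replicates — this is what
  keeps replicate Pearson correlations high (median ≈ 0.95) while overall
  missingness falls from ≈33% (X1) to ≈13% (X3). The LOD midpoint and
  blank-detection probabilities were derived analytically from the target
  missing fractions: with mean detection ≈0.85 for reliable features,
  zeros ≈ (136·10·0.05 + 117·8.5 + 104·1.5)/3650 ≈ 33% at X1 and
  104·1.5/1120 ≈ 14% at X3.
- **Mass accuracy:** the measured IS m/z is jittered uniformly within
  ±10 ppm per injection.

The noise defaults (biological sd, response loadings) were calibrated
jointly so that the fixed ±2 log₂ effect reproduces the emulated study's
printed behavior — clean double-CV separation (NMC 0 in most seeds, never
above 1 in 20), dQ² around 0.7–0.8, a class-dominated PC1 near 27%, and
recovery of the planted features by the permutation selection (median 8 of
8 over many seeds) — and then frozen. Per-seed recovery is intentionally
not degenerate: roughly 55% of seeds recover all 8, the rest 7 or fewer,
reflecting the knife-edge nature of a 125-permutation null at n = 10.

What the generator does **not** emulate: retention-time drift and
alignment errors, correlated contaminant patterns, heteroscedastic
detector saturation, batch effects (the emulated design randomized
acquisition instead), and real metabolite-metabolite pathway correlations
beyond the single response factor. Passing tests therefore demonstrate
correctness and statistical behavior of the *procedure* under a plausible
data-generating process, not performance on any particular real dataset.

## Problem sizes and runtime

All defaults run on one CPU: a full 125-permutation test of the 10 × 112
matrix takes ~1.6 s (fold-scaling cache + one-pass NIPALS); the
acceptance script (201 permutation tests) ~6 min; the type-I-control
property (200 null datasets at 60 features) ~5 min. These sizes are the
package's chosen defaults for desk-scale verification.

## Known limitations

- Only balanced or mildly unbalanced two-class designs; no PLS2,
  orthogonal-PLS variants or VIP scores.
- The permutation machinery assumes the label vector is the only random
  element; covariate permutation schemes are out of scope.
- Empirical p-values have resolution 1/125 at the default design; p = 0
  means "more extreme than every enumerated relabeling", not zero
  probability.
- The Q/T² limit formulas assume approximately multivariate-normal scores;
  at n = 10 they are indicative, not exact.
- Raw-file handling (vendor formats, mzML), peak picking and alignment are
  upstream of this package's inputs.
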