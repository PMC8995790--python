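# Methods

This note documents the models, estimators, defaults and numerical choices
behind `critmf`, and what the synthetic validation does and does not show
about real recordings.

## Multifractal model and estimator

A scale-free signal is summarized by its scaling function ζ(q): the q-th
structure function of the wavelet p-leaders, S(j, q) = mean_k ℓ(j, k)^q,
behaves as 2^(j·ζ(q)) across dyadic scales j. Expanding ζ(q) around q = 0
gives the log-cumulants; the first two carry nearly all the usable
information. c1 locates the apex of the singularity spectrum D(h) (for a
monofractal signal c1 = H, the Hurst exponent) and c2 its width: the
second-order approximation is the parabola D(h) = 1 + (h − c1)²/(2 c2),
defined only for c2 < 0, with support width 2·sqrt(−2 c2). Concavity of
ζ(q) implies c2 ≤ 0 in theory; sample estimates can still come out
positive, and the package reports such values as-is with a
`positive_c2` flag. They mean the multifractal formalism could not model
the segment — neither multifractal nor monofractal — and their per-group
prevalence is exposed by `report_positive_c2`.

### Wavelet pyramid

- **Wavelet**: Daubechies with 3 vanishing moments (`db3`), configurable.
  The leader formalism needs N_ψ strictly larger than the smoothness of
  trends to be cancelled; db3 annihilates constants, lines and quadratics.
- **Normalization**: detail coefficients of the orthonormal pyramid are
  multiplied by 2^(−j/2) (L1 normalization) so that coefficients of an
  h-regular point scale as 2^(jh) and the log-cumulant slopes are on the
  conventional scale.
- **Boundary policy**: every convolution uses valid mode only — a
  coefficient exists only if its filter support lies wholly inside the
  signal. No border extension is ever invented, so no border-induced
  spurious singularities can enter the leaders, at the price of a few
  coefficients per scale. A consequence used by the leader recursion:
  every retained dyadic node has a complete pair of children at the next
  finer scale.
- **Degenerate inputs**: polynomial annihilation leaves O(n·eps) rounding
  residue; coefficients below 1e−12 × max|x| are snapped to exact zero
  (relative threshold, so estimates stay invariant under positive
  rescaling of the input). A fully zero coefficient set raises a
  degenerate-signal error; isolated exact-zero leader aggregates are
  dropped and counted, and estimation aborts if more than 10% of leaders
  at any fit scale were dropped.

### p-leaders

ℓ^(p)(j,k) aggregates |d|^p · 2^(j′−j) over all coefficients at scales
j′ ≤ j whose dyadic interval lies in the 3-neighbourhood of (j, k); p = ∞
takes the supremum instead (classical leaders). Default p = 2 (the main
analysis setting, comparable to detrended fluctuation analysis exponents);
p = 4 is exposed for sensitivity analyses and tends to produce fewer
positive-c2 estimates. The minimum-regularity condition η(p) > 0 is checked
from the coefficient-based structure-function exponent at q = p; on failure
a warning is emitted and estimation proceeds (no automatic fractional
integration — the pipeline analyzes raw arrhythmic signals).

### Regression

Per scale, C1(j) is the sample mean and C2(j) the unbiased sample variance
of ln ℓ(j,·). Each is fit as b_m + s_m·j by weighted least squares over
j ∈ [j1, j2], weights proportional to the per-scale leader counts n_j
(finer scales estimate their cumulant from more leaders); a uniform option
exists. c_m = s_m / ln 2. Preconditions: j1 < j2 within the available
scales and at least 8 leaders per fit scale.

### Scaling-range selection

The fit range must cover the log-linear (scale-free) part of the spectrum.
`select_scaling_range` condenses a Welch periodogram into half-octave bins
(geometric-mean frequency, mean log-power — this de-noises the estimate
and stops the linearly spaced high frequencies from dominating), fits
log-power against log-frequency inside the band of every candidate window
of at least 3 dyadic scales, and returns the window with the highest R²
together with full per-window diagnostics and a warning flag when no
window reaches R² = 0.95. The automatic choice can always be overridden:
pinning (j1, j2) = (7, 10) at 600 Hz reproduces the 0.4–3.5 Hz band via
f = 3·Sf/(4·2^j). On non-scale-free input (e.g. white noise) the flag
fires and the widest-window slope near 0 makes the failure visible.

### Bootstrap

Confidence intervals come from a single-level circular block bootstrap:
time blocks of leader indices are resampled at the coarsest fit scale and
propagated to finer scales through the dyadic index mapping (coarse index
i covers fine indices i·2^(j2−j) … (i+1)·2^(j2−j) − 1), preserving
cross-scale dependence; (c1, c2) is re-fit per replicate and percentile
intervals are returned. The nominal block length 2·2^(j2−j1+1) is capped
at n_coarse/4 so that at least four blocks always exist (at n = 2^16 and
(j1, j2) = (7, 10) the nominal length would exceed the ~60 available
coarse-scale leaders). This is a deliberate simplification of double
bootstrap schemes; it is honest about being approximate, and its coverage
is checked empirically in the test suite (≥ 70% empirical coverage
asserted at desk scale, nominal 95%).

## Synthetic generators

- **fGn / fBm**: exact-covariance fractional Gaussian noise by circulant
  embedding of γ(k) = ½(|k+1|^2H − 2|k|^2H + |k−1|^2H); cumulative sum
  gives fBm. The embedding eigenvalues are checked; tiny negative values
  are clipped (logged), turning the method into approximate spectral
  synthesis in that rare case. The generator was validated against the
  theoretical autocovariance and the k^2H increment-variance law.
- **MRW**: increments ε_i·exp(ω_i), with ε fGn of parameter H and ω a
  stationary Gaussian log-cascade with Cov(ω_i, ω_j) =
  λ²·ln⁺(L/(|i−j|+1)), horizon L = n/8, mean −Var(ω)/2 (so E exp(ω) = 1).
  λ² = 0 reduces bit-exactly to fBm. Theoretical targets c1 = H + λ²/2 and
  c2 = −λ² were confirmed by ensemble estimation (n = 2^16, 10–20 seeds:
  mean ĉ2 = −0.029 for λ² = 0.03, −0.073 for λ² = 0.08) before being
  frozen as test expectations. The horizon and mean conventions vary in
  the literature; they are fixed here so recovery targets are
  well-defined.
- **Cohorts**: nodes live on an abstract 1-D coordinate x ∈ [0, 1]
  standing in for an anterior–posterior axis (no cortical geometry).
  Controls: H rises linearly 0.35 → 0.90 and λ² rises 0.005 → 0.05 along
  x (opposing gradients of c1 and −c2, both increasing toward posterior
  x). Patients: the same gradients attenuated by 0.6 about their midpoint,
  +0.10 added to H on the anterior 30% of nodes and λ² pulled 0.01 toward
  zero on the posterior 30% — the directions reported for fronto-temporal
  self-similarity increases and parieto-occipital multifractality
  reductions in the clinical population this emulates. One scalar H
  offset (SD 0.04) and one λ² offset (SD 0.004) per subject model trait
  variability. Clinical scores (patients only) are linear in the
  subject's regional ground-truth c1 (negative-symptom score) or c2
  (positive-symptom score) plus Gaussian noise sized for a true
  correlation near 0.8; medication dose correlates with the
  negative-symptom score at ρ = 0.55, so the descriptive mediation check
  lands near R² = 0.30. Every random stream derives from
  (seed, subject index, node index), making cohorts bit-exactly
  reproducible.
- **Generator limitation**: fGn requires H ∈ (0, 1), so ground-truth c1
  is confined below ≈ 1; empirical c1 values above 1 reported for real
  recordings (interpretable under generalized-process theory) are outside
  what this generator can emulate. Default desk-scale cohorts (2^14
  samples, 50 nodes) are deliberately far smaller than a real study's
  5-minute × 8,196-node recordings; the pipeline itself is
  size-agnostic.
- **Feature-level cohorts** (`simulate_feature_cohort`): the calibration
  and power suites need hundreds of cohorts, so they draw per-node feature
  matrices directly — baseline 0.7, Gaussian variability SD 0.1 emulating
  the combined subject-trait and estimator noise of a c1 map, optional
  group offsets at designated nodes. This skips signal synthesis
  entirely; the signal-level estimator chain is validated separately
  (recovery suites, end-to-end pipeline tests). Passing calibration on
  these cohorts shows the inference layer is exact under its own null; it
  does not by itself validate the estimator on real, nonstationary,
  artifact-bearing recordings.

## Group statistics

- **Pseudo t**: t = (mean_A − mean_B)/(SE_Welch + s0). The regularizer s0
  defaults to the median across nodes of the per-node standard-error term
  (the variance-smoothing convention of nonparametric neuroimaging
  statistics), computed once on the observed grouping and held fixed
  across permutations.
- **Max statistics**: per permutation of group labels (sizes preserved),
  the maximum of |t| across nodes forms the null; corrected
  p = (1 + b)/(n_perm + 1) (add-one, so p ∈ [1/(n_perm+1), 1]). When the
  number of distinct assignments is ≤ n_perm the null is enumerated
  exhaustively and p-values are exact fractions (the observed assignment
  counts itself). Permutations are otherwise drawn without enforcing
  uniqueness. Default α = 0.001 for t-maps, 0.05 elsewhere, both exposed.
- **FDR**: Benjamini–Hochberg step-up (via statsmodels), verified against
  a from-definition oracle on all short vectors including ties. Pearson
  correlation maps are FDR-corrected across nodes; Spearman maps are
  reported uncorrected and tagged as such. Subjects missing a covariate
  are dropped pairwise (logged); at least 5 complete subjects required.
- **Mediation check**: descriptive only — r(score, dose) and its square,
  the share of score variance explicable by dose.

## Decoding

Per node, logit P(patient) = a + b·x with the feature standardized by
training-fold mean/SD only (leakage-free). The fit is a two-parameter
Newton iteration vectorized across nodes (cap 25 iterations, gradient
tolerance 1e−8, tiny 1e−10 diagonal jitter for solvability only — not
statistical regularization); on separable data the iteration cap bounds
the diverging coefficients while leaving the decision boundary correct.
It matches unpenalized scikit-learn logistic regression to ~1e−6 in the
coefficients and exactly in fold predictions (asserted in tests); the
vectorization is what makes re-running full 10-fold CV at every node for
every permutation affordable. Constant training features fall back to an
intercept-only majority-class fit (logged); probability ties at 0.5
resolve to the first class.

The chance level is the (1 − α) quantile of the max-across-nodes DA under
label shuffling, with fold assignments re-derived from the shuffled labels
each time; a node is significant only strictly above it. One property
worth knowing: with k = 10 folds on 25+25 subjects the per-class test
counts are 2/3, the training majority therefore anti-correlates with the
test composition, and the null DA mean sits ≈ 0.47 rather than 0.50 — the
usual pessimistic cross-validation bias, which vanishes with exactly
class-balanced folds (k = 5 on this cohort). The permutation threshold is
derived from the same biased statistic, so familywise calibration is
unaffected (verified empirically).

## Pipeline

`run_pipeline` chains simulate → analyze → (optional ROI averaging) →
t-maps → decoding → correlations, writing TSV/JSON outputs plus a manifest
holding every configurable value, the package version and all accumulated
warnings (positive-c2 counts, dropped leaders, regularity violations).
When (j1, j2) is not pinned, the range is selected once on the first
signal and reused — the scaling band is a property of the acquisition, not
of individual nodes. Outputs contain no timestamps or absolute paths, so
identical configs and seeds reproduce every file byte-for-byte. ROI
averaging is the arithmetic mean of member nodes per subject against a
user-supplied or synthetic label map.

## Problem sizes used in the validation suite

Recovery suites use 20 seeds of 2^16-sample signals with fit range
(3, 11), chosen from a pre-registered sweep of mid-scale windows (all
candidates met the targets; differences were marginal). Familywise
calibration uses 200 null feature-level cohorts (25+25 × 50 nodes,
n_perm = 500) for the t-map and 100 cohorts (n_perm = 100) for decoding;
power uses 50 cohorts with a 1.5-pooled-SD offset at 5 of 50 nodes.
End-to-end determinism and pipeline tests run on 4–5 subjects per group,
5–8 nodes, 2^11-sample signals. These sizes are the package's desk-scale
defaults for a reproducible validation run; all procedures accept
study-scale inputs unchanged.

## Known limitations

- Only c1 and c2 are estimated (no higher cumulants), and no fractional
  integration is applied when the minimum-regularity check fails — the
  warning is the contract.
- The bootstrap is a single-level approximation; its intervals are
  slightly anticonservative at short signal lengths.
- The synthetic cohort has no oscillatory components (beyond the optional
  sinusoid used to exercise scaling-range rejection), no sensor noise, no
  artifacts and no cortical geometry; conclusions about real recordings
  require the real preprocessing chain upstream of this package.
- Group comparisons assume exchangeability under the null; no covariate
  adjustment (age, sex) is implemented.
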