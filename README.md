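# critmf — criticality analysis of scale-free neural time series

`critmf` estimates how close resting-state brain dynamics sit to a critical
regime by quantifying two properties of an arrhythmic (broadband,
non-oscillatory) signal:

- **Self-similarity** — the first log-cumulant **c1**, tracking the Hurst
  exponent *H*. Values above 0.5 mean persistent, memory-bearing dynamics.
- **Multifractality** — the second log-cumulant **c2**, tracking the width
  of the singularity spectrum. c2 < 0 means the signal carries a genuine
  diversity of local regularity (Hölder) exponents; c2 = 0 is monofractal;
  estimated c2 > 0 is mathematically ill-defined and is reported with a
  flag rather than clipped, because its prevalence is itself informative in
  clinical data.

It is written for researchers analyzing source-reconstructed M/EEG (or any
long scale-free recording): you bring per-subject node × time matrices, the
package returns per-node (c1, c2) maps and the group-level statistics used
to compare clinical populations — permutation t-maps, decoding maps with a
permutation-derived chance level, and clinical-score correlation maps.

## Method

For a signal *X*, discrete wavelet coefficients *d(j, k)* (Daubechies,
N<sub>ψ</sub> = 3 vanishing moments by default, L1 normalization) are
aggregated into **wavelet p-leaders**

ℓ<sup>(p)</sup>(j, k) = ( Σ<sub>λ′ ⊆ 3λ(j,k), j′ ≤ j</sub> |d(λ′)|<sup>p</sup> 2<sup>j′−j</sup> )<sup>1/p</sup>,

the local ℓ<sup>p</sup> norm of all coefficients at scales finer than *j*
inside the interval of (j, k) and its two neighbours (p = ∞ recovers the
classical wavelet-leader supremum; p = 2 is the default, p = 4 the
sensitivity setting). Per scale, C1(j) = mean ln ℓ(j,·) and
C2(j) = Var ln ℓ(j,·); each c<sub>m</sub> is the slope of C<sub>m</sub>(j)
versus *j* over a fit range [j1, j2], divided by ln 2. The fit range is the
log-linear portion of the Welch PSD, found automatically or pinned by hand;
scales map to frequencies via f = 3·S<sub>f</sub> / (4·2<sup>j</sup>), so at
S<sub>f</sub> = 600 Hz the scales j = 7…10 cover 0.4–3.5 Hz. A circular
block bootstrap over leader time-blocks gives confidence intervals, and the
parabolic singularity spectrum D(h) = 1 + (h − c1)² / (2 c2) summarizes a
multifractal estimate.

Group-level layers:

- **Pseudo t-maps** — two-tailed unpaired pseudo t-tests per node,
  familywise-corrected by the permutation maximum-statistics method.
- **Decoding** — per node, an unregularized logistic classifier under
  stratified 10-fold CV; significance against the max-across-nodes
  accuracy under label shuffling (the "chance level", typically ≈ 70% for
  a 25+25 cohort, not 50%).
- **Clinical correlations** — per-node Pearson r with Benjamini–Hochberg
  FDR across nodes (plus uncorrected Spearman), and a descriptive
  medication-mediation check.

Because clinical M/EEG datasets are rarely shareable, `critmf` ships a
first-class synthetic-cohort generator with exact ground truth: fractional
Brownian motion (c1 = H, c2 = 0), multifractal random walks
(c1 = H + λ²/2, c2 = −λ²), and full two-group cohorts with opposing
anterior–posterior gradients, patient-group offsets, and clinical scores
coupled to regional ground truth.

## Worked example

```python
from critmf import analyze_signal, simulate_mrw

x = simulate_mrw(2**16, H=0.7, lambda2=0.05, seed=2)   # ground truth known
est = analyze_signal(x, sampling_rate=600.0, p=2, j1=3, j2=11)
print(est.c1, est.c2)
```

Running `python examples/analyze_single_signal.py` prints:

```
fBm (H=0.7):  c1 = 0.706  c2 = +0.0001
  95% CI c1 = [0.697, 0.711]  (true H inside: True)
MRW (lambda2=0.05):  c1 = 0.739  c2 = -0.0507  (theory: c1=0.725, c2=-0.050)
  singularity spectrum: apex h = 0.739 (D = 1), width M = 0.637
```

The estimator recovers the monofractal case (c1 ≈ H, c2 ≈ 0) and the
multifractal case (c2 ≈ −λ²) to a few thousandths; the spectrum apex sits
at c1 with dimension 1. The other scripts in `examples/` walk through
scaling-range selection, group t-maps, the decoding chance level, and the
full pipeline; `critmf --help` exposes the same stages as shell commands
(`simulate`, `analyze`, `stats`, `decode`, `correlate`, `run`).

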