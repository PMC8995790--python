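"""Estimate self-similarity (c1) and multifractality (c2) of one signal.

Generates two canonical scale-free signals with known ground truth — a
monofractal fractional Brownian motion (c1 = H, c2 = 0) and a multifractal
random walk (c1 = H + lambda2/2, c2 = -lambda2) — and runs the wavelet
p-leader log-cumulant estimator on each, with bootstrap confidence
intervals and, where defined, the parabolic singularity spectrum.
"""

from critmf import (analyze_signal, legendre_spectrum, simulate_fgn_fbm,
                    simulate_mrw)

n, fs = 2**16, 600.0

fbm = simulate_fgn_fbm(n, H=0.7, seed=1)
est = analyze_signal(fbm, fs, p=2, j1=3, j2=11, n_boot=100, seed=1)
print(f"fBm (H=0.7):  c1 = {est.c1:.3f}  c2 = {est.c2:+.4f}")
print(f"  95% CI c1 = [{est.ci['c1'][0]:.3f}, {est.ci['c1'][1]:.3f}]  "
      f"(true H inside: {est.ci['c1'][0] <= 0.7 <= est.ci['c1'][1]})")

mrw = simulate_mrw(n, H=0.7, lambda2=0.05, seed=2)
est = analyze_signal(mrw, fs, p=2, j1=3, j2=11)
print(f"MRW (lambda2=0.05):  c1 = {est.c1:.3f}  c2 = {est.c2:+.4f}  "
      f"(theory: c1=0.725, c2=-0.050)")
if est.c2 < 0:
    spec = legendre_spectrum(est)
    print(f"  singularity spectrum: apex h = {spec.apex:.3f} (D = 1), "
          f"width M = {spec.width:.3f}")
print("c1 near 0.7 marks a persistent, memory-bearing signal; a negative c2 "
      "marks genuine multifractality (diverse local regularity).")
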