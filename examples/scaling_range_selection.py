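"""Pick the dyadic-scale fit window from the log-linear part of the PSD.

The log-cumulant regression is only meaningful over scales where the power
spectrum is log-linear (scale-free).  This example maps dyadic scales to
frequencies at a 600 Hz sampling rate, then shows the automatic window
selection rejecting a 10 Hz oscillation injected on top of a scale-free
signal.
"""

import numpy as np

from critmf import scale_to_frequency, select_scaling_range, simulate_fgn_fbm

fs = 600.0
print("scale j -> frequency (Hz) at 600 Hz sampling:")
for j in (7, 8, 9, 10):
    print(f"  j = {j:2d}  ->  {scale_to_frequency(j, fs):5.2f} Hz")
print("(j = 7 and j = 10 bound the 0.4-3.5 Hz band)\n")

n = 2**14
t = np.arange(n) / fs
x = simulate_fgn_fbm(n, H=0.8, seed=1) + 40.0 * np.sin(2 * np.pi * 10.0 * t)
(j1, j2), diag = select_scaling_range(x, fs)
print(f"signal = fBm + strong 10 Hz rhythm: selected window (j1, j2) = "
      f"({j1}, {j2})")
print(f"  band {scale_to_frequency(j2, fs):.2f}-"
      f"{scale_to_frequency(j1, fs):.2f} Hz, "
      f"R^2 = {diag['best']['r2']:.3f}, slope = {diag['best']['slope']:.2f}")
print("The chosen band avoids the 10 Hz bump: estimation runs on the "
      "arrhythmic, scale-free portion of the spectrum only.")
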