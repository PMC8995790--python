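"""Log-cumulant regression, scaling function, spectrum, scale mapping."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from critmf.cumulants import (SpectrumUndefinedError, analyze_signal,
                              bootstrap_ci, estimate_zeta, legendre_spectrum,
                              log_cumulants, scale_to_frequency,
                              select_scaling_range)
from critmf.simulate import simulate_fgn_fbm, simulate_mrw
from critmf.wavelets import PLeaders, dwt_coefficients, p_leaders


def exact_leaders(slope=0.8, n_scales=6, n_finest=512, p=2.0):
    """Dispersion-free leaders l(j, k) = 2**(j*slope)."""
    leaders = [np.full(max(n_finest >> (j - 1), 8), 2.0 ** (j * slope))
               for j in range(1, n_scales + 1)]
    return PLeaders(p=p, leaders=leaders, wavelet_order=3,
                    dropped_per_scale=np.zeros(n_scales, int))


class TestLogCumulants:
    def test_exact_power_law_leaders(self):
        est = log_cumulants(exact_leaders(0.8), j1=1, j2=6)
        assert est.c1 == pytest.approx(0.8, abs=1e-12)
        assert est.c2 == pytest.approx(0.0, abs=1e-12)
        assert not est.flags["positive_c2"]

    def test_fbm_recovery_small(self):
        c1s, c2s = [], []
        for seed in range(10):
            x = simulate_fgn_fbm(2**14, 0.7, seed=seed)
            est = log_cumulants(p_leaders(dwt_coefficients(x), 2.0), 3, 9)
            c1s.append(est.c1)
            c2s.append(est.c2)
        assert np.mean(c1s) == pytest.approx(0.7, abs=0.05)
        assert np.mean(c2s) == pytest.approx(0.0, abs=0.02)

    def test_positive_c2_flagged_not_clipped(self):
        # leaders whose log-variance grows with scale force c2 > 0
        rng = np.random.default_rng(3)
        leaders = [np.exp(rng.normal(0, 0.1 * j, size=512 >> (j - 1)))
                   for j in range(1, 7)]
        lead = PLeaders(p=2.0, leaders=leaders, wavelet_order=3,
                        dropped_per_scale=np.zeros(6, int))
        est = log_cumulants(lead, 1, 6)
        assert est.c2 > 0
        assert est.flags["positive_c2"]

    def test_amplitude_invariance(self):
        """Scaling the signal shifts intercepts only; c1 and c2 are unchanged."""
        x = simulate_fgn_fbm(2**13, 0.6, seed=5)
        est1 = analyze_signal(x, j1=3, j2=8)
        est2 = analyze_signal(137.0 * x, j1=3, j2=8)
        assert est2.c1 == pytest.approx(est1.c1, abs=1e-10)
        assert est2.c2 == pytest.approx(est1.c2, abs=1e-10)

    def test_fit_range_validation(self):
        lead = exact_leaders()
        with pytest.raises(ValueError):
            log_cumulants(lead, 4, 4)
        with pytest.raises(ValueError):
            log_cumulants(lead, 1, 12)

    def test_insufficient_leaders_per_scale(self):
        lead = exact_leaders(n_scales=4, n_finest=32)
        with pytest.raises(ValueError, match="leaders"):
            log_cumulants(lead, 1, 4, min_leaders=20)


class TestZeta:
    def test_exact_leaders_linear_zeta(self):
        zeta = estimate_zeta(exact_leaders(0.8), np.array([-1, 0.5, 1, 2]), 1, 6)
        for q, z in zeta.items():
            assert z == pytest.approx(0.8 * q, abs=1e-10)

    def test_fbm_zeta2(self):
        vals = []
        for seed in range(20):
            x = simulate_fgn_fbm(2**14, 0.7, seed=seed)
            lead = p_leaders(dwt_coefficients(x), 2.0)
            vals.append(estimate_zeta(lead, np.array([2.0]), 3, 9)[2.0])
        assert np.mean(vals) == pytest.approx(1.4, abs=0.1)

    def test_zeta_concavity_on_mrw(self):
        """zeta(2) + zeta(0) <= 2*zeta(1) up to numerical tolerance."""
        for seed in range(10):
            x = simulate_mrw(2**14, 0.7, 0.05, seed=seed)
            lead = p_leaders(dwt_coefficients(x), 2.0)
            z = estimate_zeta(lead, np.array([0.0, 1.0, 2.0]), 3, 9)
            assert z[2.0] - 2 * z[1.0] + z[0.0] <= 1e-6


class TestLegendreSpectrum:
    def test_monofractal_spectrum_undefined(self):
        est = log_cumulants(exact_leaders(0.8), 1, 6)
        with pytest.raises(SpectrumUndefinedError):
            legendre_spectrum(est)

    def test_parabola_values(self):
        est = log_cumulants(exact_leaders(0.8), 1, 6)
        est.c2 = -0.02
        spec = legendre_spectrum(est)
        assert spec.apex == pytest.approx(0.8)
        assert np.interp(0.8, spec.h, spec.D) == pytest.approx(1.0, abs=1e-6)
        # D(0.6) = 1 + 0.04 / (2 * -0.02) = 0
        assert np.interp(0.6, spec.h, spec.D) == pytest.approx(0.0, abs=1e-6)
        assert spec.width == pytest.approx(2 * np.sqrt(0.04))

    def test_spectrum_bounded_and_symmetric(self):
        est = log_cumulants(exact_leaders(0.5), 1, 6)
        est.c2 = -0.05
        spec = legendre_spectrum(est)
        assert np.all(spec.D <= 1.0 + 1e-12)
        np.testing.assert_allclose(spec.D, spec.D[::-1], atol=1e-10)


class TestScaleToFrequency:
    def test_printed_correspondences(self):
        assert round(scale_to_frequency(7, 600.0), 1) == 3.5
        assert round(scale_to_frequency(10, 600.0), 1) == 0.4

    @given(j=st.integers(1, 20), fs=st.floats(1.0, 5000.0))
    def test_halving_and_linearity(self, j, fs):
        f = scale_to_frequency(j, fs)
        assert scale_to_frequency(j + 1, fs) == pytest.approx(f / 2)
        assert scale_to_frequency(j, 2 * fs) == pytest.approx(2 * f)

    def test_strictly_decreasing_in_j(self):
        f = scale_to_frequency(np.arange(1, 15), 600.0)
        assert np.all(np.diff(f) < 0)

    def test_preconditions(self):
        with pytest.raises(ValueError):
            scale_to_frequency(0, 600.0)
        with pytest.raises(ValueError):
            scale_to_frequency(3, -1.0)


class TestSelectScalingRange:
    @staticmethod
    def _power_law_signal(n, beta, seed):
        rng = np.random.default_rng(seed)
        f = np.fft.rfftfreq(n, d=1.0)
        amp = np.zeros_like(f)
        amp[1:] = f[1:] ** (-beta / 2)
        phases = rng.standard_normal(len(f)) + 1j * rng.standard_normal(len(f))
        return np.fft.irfft(amp * phases, n)

    def test_pure_power_law_slope(self):
        x = self._power_law_signal(2**14, 1.5, seed=0)
        (j1, j2), diag = select_scaling_range(x, sampling_rate=600.0)
        assert not diag["low_r2_warning"]
        assert diag["best"]["slope"] == pytest.approx(-1.5, abs=0.25)

    def test_sinusoid_excluded_from_band(self):
        n, fs = 2**14, 600.0
        t = np.arange(n) / fs
        x = simulate_fgn_fbm(n, 0.8, seed=1) + 40.0 * np.sin(2 * np.pi * 10.0 * t)
        (j1, j2), diag = select_scaling_range(x, fs)
        f_hi = scale_to_frequency(j1, fs)
        f_lo = scale_to_frequency(j2, fs)
        assert not (f_lo <= 10.0 <= f_hi)

    def test_white_noise_flat_and_flagged(self):
        x = np.random.default_rng(2).normal(size=2**13)
        (j1, j2), diag = select_scaling_range(x, 600.0)
        assert diag["low_r2_warning"]
        assert abs(diag["global"]["slope"]) < 0.2


class TestBootstrap:
    def test_degenerate_leaders_zero_width(self):
        ci = bootstrap_ci(exact_leaders(0.8, n_scales=5, n_finest=1024),
                          j1=1, j2=5, n_boot=50, seed=0)
        lo, hi = ci["c1"]
        assert hi - lo == pytest.approx(0.0, abs=1e-12)
        assert lo == pytest.approx(0.8, abs=1e-12)

    def test_fbm_coverage(self):
        """95% CIs should cover the true H in most independent signals."""
        hits = 0
        n_sig = 20
        for seed in range(n_sig):
            x = simulate_fgn_fbm(2**13, 0.7, seed=seed)
            lead = p_leaders(dwt_coefficients(x), 2.0)
            ci = bootstrap_ci(lead, 3, 8, n_boot=100, alpha=0.05, seed=seed)
            lo, hi = ci["c1"]
            hits += lo <= 0.7 <= hi
        assert hits >= int(0.7 * n_sig)

    def test_ci_width_shrinks_with_signal_length(self):
        widths = {}
        for n in (2**12, 2**15):
            w = []
            for seed in range(8):
                x = simulate_fgn_fbm(n, 0.7, seed=seed)
                lead = p_leaders(dwt_coefficients(x), 2.0)
                ci = bootstrap_ci(lead, 3, 8, n_boot=60, seed=seed)
                w.append(ci["c1"][1] - ci["c1"][0])
            widths[n] = np.mean(w)
        assert widths[2**15] < widths[2**12]

    def test_block_length_capped_to_available_leaders(self):
        """The nominal block length is shrunk so >= 4 blocks always exist."""
        lead = exact_leaders(n_scales=6, n_finest=512)
        ci = bootstrap_ci(lead, 1, 6, n_boot=50, seed=0)
        n_coarse = lead.leaders[5].size
        assert ci["block_len"] <= max(n_coarse // 4, 1)

    def test_n_boot_minimum_enforced(self):
        with pytest.raises(ValueError, match="n_boot"):
            bootstrap_ci(exact_leaders(), 1, 6, n_boot=10)
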