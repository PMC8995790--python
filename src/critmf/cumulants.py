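"""Log-cumulant estimation, scaling functions, and the singularity spectrum.

The scaling function zeta(q) of a scale-free signal admits a polynomial
expansion around q = 0 whose coefficients are the log-cumulants c_m.  The
first two are estimated here from wavelet p-leaders: per dyadic scale j,
C1(j) is the mean and C2(j) the variance of log-leaders, and each c_m is the
slope of C_m(j) against j (divided by ln 2) over a fit range [j1, j2].

c1 tracks the Hurst exponent (self-similarity); c2 < 0 quantifies
multifractality, c2 = 0 is monofractal.  Estimated c2 > 0 is mathematically
ill-defined but does occur on real data; it is reported with a flag and
never clipped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .wavelets import PLeaders, WaveletCoefficients, dwt_coefficients, p_leaders

logger = logging.getLogger(__name__)

__all__ = [
    "LogCumulantEstimate",
    "SingularitySpectrum",
    "SpectrumUndefinedError",
    "scale_to_frequency",
    "log_cumulants",
    "estimate_zeta",
    "legendre_spectrum",
    "select_scaling_range",
    "bootstrap_ci",
    "analyze_signal",
]

#: Largest tolerated fraction of exact-zero leaders at any fit scale before
#: estimation aborts (near-constant segments corrupt the log statistics).
MAX_DROPPED_FRACTION = 0.10


class SpectrumUndefinedError(ValueError):
    """Singularity spectrum requested for a non-multifractal estimate (c2 >= 0)."""


def scale_to_frequency(j: int | np.ndarray, sampling_rate: float) -> float | np.ndarray:
    """Map a dyadic scale j to its characteristic frequency in Hz.

    frequency = 3 * Sf / (4 * 2**j), with Sf the sampling frequency; each
    increment of j halves the frequency.
    """
    j = np.asarray(j)
    if np.any(j < 1):
        raise ValueError("dyadic scale j must be >= 1")
    if sampling_rate <= 0:
        raise ValueError("sampling_rate must be positive")
    out = 3.0 * sampling_rate / (4.0 * 2.0**j)
    return float(out) if out.ndim == 0 else out


@dataclass
class LogCumulantEstimate:
    """Estimated (c1, c2) with per-scale cumulants and fit metadata."""

    c1: float
    c2: float
    c1_se: float
    c2_se: float
    C1_j: np.ndarray          # mean of log-leaders, scales j1..j2
    C2_j: np.ndarray          # variance of log-leaders, scales j1..j2
    n_j: np.ndarray           # leader counts, scales j1..j2
    j1: int
    j2: int
    p: float
    weighting: str
    flags: dict = field(default_factory=dict)
    ci: dict | None = None

    @property
    def scales(self) -> np.ndarray:
        return np.arange(self.j1, self.j2 + 1)


@dataclass
class SingularitySpectrum:
    """Parabolic approximation of the multifractal spectrum D(h)."""

    h: np.ndarray
    D: np.ndarray
    apex: float   # Hölder exponent at the apex, = c1; D(apex) = 1
    width: float  # full support width of {h : D(h) >= 0} = 2*sqrt(-2*c2)


def _wls_line(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> tuple[float, float, float]:
    """Weighted least-squares line fit; returns (slope, intercept, slope SE)."""
    w = w / w.sum()
    xm = np.sum(w * x)
    ym = np.sum(w * y)
    sxx = np.sum(w * (x - xm) ** 2)
    slope = np.sum(w * (x - xm) * (y - ym)) / sxx
    intercept = ym - slope * xm
    resid = y - (intercept + slope * x)
    dof = max(len(x) - 2, 1)
    s2 = np.sum(w * resid**2) * len(x) / dof
    se = float(np.sqrt(s2 / (sxx * len(x))))
    return float(slope), float(intercept), se


def _check_fit_range(leaders: PLeaders, j1: int, j2: int, min_leaders: int) -> None:
    if j1 >= j2:
        raise ValueError(f"need j1 < j2, got ({j1}, {j2})")
    if j1 < 1 or j2 > leaders.n_levels:
        raise ValueError(
            f"fit range ({j1}, {j2}) outside available scales 1..{leaders.n_levels}"
        )
    counts = leaders.counts
    for j in range(j1, j2 + 1):
        if counts[j - 1] < min_leaders:
            raise ValueError(
                f"scale {j} has only {counts[j - 1]} leaders (< {min_leaders})"
            )
        dropped = leaders.dropped_per_scale[j - 1]
        total = counts[j - 1] + dropped
        if dropped / total > MAX_DROPPED_FRACTION:
            raise ValueError(
                f"scale {j}: {dropped}/{total} leaders were exact zeros; "
                "signal too degenerate for log-cumulant estimation"
            )


def log_cumulants(
    leaders: PLeaders,
    j1: int,
    j2: int,
    weighting: str = "counts",
    min_leaders: int = 8,
    coeffs: WaveletCoefficients | None = None,
) -> LogCumulantEstimate:
    """Estimate (c1, c2) by linear regression of log-leader cumulants on scale.

    Per scale j in [j1, j2], C1(j) = mean(ln l(j,.)) and C2(j) = var(ln
    l(j,.)); each C_m(j) is fit as b_m + s_m * j by weighted least squares
    and c_m = s_m / ln 2.  ``weighting='counts'`` weights each scale by its
    leader count (finer scales carry more leaders); 'uniform' weights all
    scales equally.

    A positive c2 estimate is returned as-is with ``flags['positive_c2']``
    set.  If ``coeffs`` is given, the minimum-regularity condition
    eta(p) > 0 is checked and a warning flag is set on failure.
    """
    if weighting not in ("counts", "uniform"):
        raise ValueError("weighting must be 'counts' or 'uniform'")
    _check_fit_range(leaders, j1, j2, min_leaders)

    js = np.arange(j1, j2 + 1, dtype=float)
    C1 = np.empty(len(js))
    C2 = np.empty(len(js))
    n = np.empty(len(js), dtype=int)
    for i, j in enumerate(range(j1, j2 + 1)):
        y = np.log(leaders.leaders[j - 1])
        C1[i] = y.mean()
        C2[i] = y.var(ddof=1)
        n[i] = y.size

    w = n.astype(float) if weighting == "counts" else np.ones_like(js)
    s1, _, se1 = _wls_line(js, C1, w)
    s2, _, se2 = _wls_line(js, C2, w)
    ln2 = np.log(2.0)
    c1, c2 = s1 / ln2, s2 / ln2

    flags: dict = {
        "positive_c2": bool(c2 > 0),
        "dropped_zero_leaders": int(leaders.n_dropped_zero),
    }
    if coeffs is not None and np.isfinite(leaders.p):
        eta = coeffs.structure_exponent(leaders.p, j1, min(j2, coeffs.n_levels))
        flags["eta_p"] = eta
        if eta <= 0:
            flags["min_regularity_warning"] = True
            logger.warning(
                "minimum-regularity condition violated: eta(p=%g)=%.3f <= 0; "
                "p-leader estimates may be unreliable", leaders.p, eta,
            )

    return LogCumulantEstimate(
        c1=c1, c2=c2, c1_se=se1 / ln2, c2_se=se2 / ln2,
        C1_j=C1, C2_j=C2, n_j=n, j1=j1, j2=j2, p=leaders.p,
        weighting=weighting, flags=flags,
    )


def estimate_zeta(
    leaders: PLeaders,
    q_list: np.ndarray,
    j1: int,
    j2: int,
    weighting: str = "counts",
    min_leaders: int = 8,
) -> dict[float, float]:
    """Scaling function zeta(q): slope across scales of log2 S(j, q).

    S(j, q) = mean over positions of l(j, k)**q (the q-th order structure
    function of the leaders).
    """
    _check_fit_range(leaders, j1, j2, min_leaders)
    js = np.arange(j1, j2 + 1, dtype=float)
    n = np.array([leaders.leaders[j - 1].size for j in range(j1, j2 + 1)], float)
    w = n if weighting == "counts" else np.ones_like(js)
    out: dict[float, float] = {}
    for q in np.atleast_1d(q_list):
        logS = np.array(
            [np.log2(np.mean(leaders.leaders[j - 1] ** q)) for j in range(j1, j2 + 1)]
        )
        slope, _, _ = _wls_line(js, logS, w)
        out[float(q)] = slope
    return out


def legendre_spectrum(
    estimate: LogCumulantEstimate, n_grid: int = 201
) -> SingularitySpectrum:
    """Parabolic (second-order) singularity spectrum from (c1, c2).

    D(h) = 1 + (h - c1)**2 / (2 * c2), evaluated on the support where
    D >= 0; the apex sits at h = c1 with D = 1 and the full support width is
    2*sqrt(-2*c2).  Only defined for multifractal estimates (c2 < 0).
    """
    if estimate.c2 >= 0:
        raise SpectrumUndefinedError(
            f"singularity spectrum undefined for c2 = {estimate.c2:.4g} >= 0 "
            f"(positive_c2 flag: {estimate.flags.get('positive_c2', False)})"
        )
    half = np.sqrt(-2.0 * estimate.c2)
    h = np.linspace(estimate.c1 - half, estimate.c1 + half, n_grid)
    D = 1.0 + (h - estimate.c1) ** 2 / (2.0 * estimate.c2)
    return SingularitySpectrum(h=h, D=D, apex=estimate.c1, width=2.0 * half)


def select_scaling_range(
    signal: np.ndarray,
    sampling_rate: float,
    candidate_min_width: int = 3,
    j_max: int | None = None,
    r2_floor: float = 0.95,
    nperseg: int | None = None,
) -> tuple[tuple[int, int], dict]:
    """Pick the dyadic scale window where the PSD is most log-linear.

    Computes a Welch periodogram, maps every candidate window [ja, jb] (with
    jb - ja + 1 >= candidate_min_width) to its frequency band via
    ``scale_to_frequency``, fits log-PSD against log-frequency inside the
    band, and returns the window with the highest coefficient of
    determination R².  Diagnostics for every candidate are returned so the
    choice can be overridden by eye, mirroring how scale ranges are selected
    on real recordings.

    Returns ``((j1, j2), diagnostics)`` where diagnostics holds per-window
    slope and R² plus a ``low_r2_warning`` flag when no window reaches
    ``r2_floor``.
    """
    x = np.asarray(signal, float)
    if j_max is None:
        j_max = max(int(np.log2(x.size)) - 4, candidate_min_width + 1)
    if nperseg is None:
        nperseg = min(x.size, 2 ** (j_max + 2))
    freqs, psd = sps.welch(x, fs=sampling_rate, nperseg=nperseg)

    # Condense the linearly spaced periodogram into half-octave bins
    # (geometric-mean frequency, mean log-power): this de-noises the Welch
    # estimate and stops high frequencies from dominating the fit.
    pos = (freqs > 0) & (psd > 0)
    f_pos, p_pos = freqs[pos], psd[pos]
    n_bins = int(np.ceil(2 * np.log2(f_pos.max() / f_pos.min())))
    edges = f_pos.min() * 2.0 ** (np.arange(n_bins + 1) / 2.0)
    bin_f, bin_logp = [], []
    for i in range(n_bins):
        sel = (f_pos >= edges[i]) & (f_pos < edges[i + 1])
        if sel.any():
            bin_f.append(np.exp(np.mean(np.log(f_pos[sel]))))
            bin_logp.append(np.mean(np.log10(p_pos[sel])))
    bin_f = np.asarray(bin_f)
    bin_logp = np.asarray(bin_logp)

    def window_fit(f_lo, f_hi):
        sel = (bin_f >= f_lo) & (bin_f <= f_hi)
        if sel.sum() < 4:
            return None
        lx, ly = np.log10(bin_f[sel]), bin_logp[sel]
        slope, intercept = np.polyfit(lx, ly, 1)
        resid = ly - (intercept + slope * lx)
        ss_tot = np.sum((ly - ly.mean()) ** 2)
        r2 = 1.0 - np.sum(resid**2) / ss_tot if ss_tot > 0 else 0.0
        return slope, r2, int(sel.sum())

    rows = []
    for ja in range(1, j_max - candidate_min_width + 2):
        for jb in range(ja + candidate_min_width - 1, j_max + 1):
            f_hi = scale_to_frequency(ja, sampling_rate)
            f_lo = scale_to_frequency(jb, sampling_rate)
            fit = window_fit(f_lo, f_hi)
            if fit is None:
                continue
            slope, r2, npts = fit
            rows.append({"j1": ja, "j2": jb, "slope": slope, "r2": r2,
                         "f_lo_hz": f_lo, "f_hi_hz": f_hi, "n_bins": npts})
    if not rows:
        raise ValueError("no candidate scale window with enough PSD support")

    best = max(rows, key=lambda r: r["r2"])
    widest = max(rows, key=lambda r: r["j2"] - r["j1"])
    warning = best["r2"] < r2_floor
    if warning:
        logger.warning(
            "select_scaling_range: best window (%d, %d) has R²=%.3f < %.2f",
            best["j1"], best["j2"], best["r2"], r2_floor,
        )
    diagnostics = {"candidates": rows, "best": best, "global": widest,
                   "low_r2_warning": warning}
    return (best["j1"], best["j2"]), diagnostics


def bootstrap_ci(
    leaders: PLeaders,
    j1: int,
    j2: int,
    n_boot: int = 200,
    alpha: float = 0.05,
    seed: int | None = None,
    block_len: int | None = None,
    weighting: str = "counts",
) -> dict:
    """Circular block-bootstrap percentile CIs for (c1, c2).

    Time blocks of leader indices are resampled at the coarsest fit scale j2
    and the same blocks are propagated to finer scales through the dyadic
    index mapping (index i at scale j2 covers indices i*2**(j2-j) ..
    (i+1)*2**(j2-j) - 1 at scale j), preserving the cross-scale dependence
    of the leaders.  (c1, c2) is re-estimated on every replicate.

    Returns a dict with percentile intervals and the replicate arrays.
    """
    if n_boot < 50:
        raise ValueError("n_boot must be >= 50")
    _check_fit_range(leaders, j1, j2, min_leaders=8)
    rng = np.random.default_rng(seed)

    n_coarse = leaders.leaders[j2 - 1].size
    if block_len is None:
        block_len = 2 * 2 ** (j2 - j1 + 1)
    # Keep at least 4 blocks at the coarsest scale.
    block_len = max(1, min(block_len, n_coarse // 4))
    if n_coarse // block_len < 4:
        raise ValueError(
            f"only {n_coarse} leaders at scale {j2}: too few for >= 4 blocks"
        )
    n_blocks = int(np.ceil(n_coarse / block_len))

    js = np.arange(j1, j2 + 1, dtype=float)
    ln2 = np.log(2.0)
    logs = [np.log(leaders.leaders[j - 1]) for j in range(j1, j2 + 1)]
    sizes = [v.size for v in logs]

    c1_rep = np.empty(n_boot)
    c2_rep = np.empty(n_boot)
    for b in range(n_boot):
        starts = rng.integers(0, n_coarse, size=n_blocks)
        coarse_idx = (
            starts[:, None] + np.arange(block_len)[None, :]
        ).ravel()[:n_coarse] % n_coarse
        C1 = np.empty(len(js))
        C2 = np.empty(len(js))
        n = np.empty(len(js))
        for i, j in enumerate(range(j1, j2 + 1)):
            factor = 2 ** (j2 - j)
            idx = (coarse_idx[:, None] * factor + np.arange(factor)[None, :]).ravel()
            idx = idx[idx < sizes[i]]
            y = logs[i][idx]
            C1[i] = y.mean()
            C2[i] = y.var(ddof=1) if y.size > 1 else 0.0
            n[i] = y.size
        w = n if weighting == "counts" else np.ones_like(js)
        s1, _, _ = _wls_line(js, C1, w)
        s2, _, _ = _wls_line(js, C2, w)
        c1_rep[b] = s1 / ln2
        c2_rep[b] = s2 / ln2

    lo, hi = 100 * alpha / 2, 100 * (1 - alpha / 2)
    return {
        "c1": tuple(np.percentile(c1_rep, [lo, hi])),
        "c2": tuple(np.percentile(c2_rep, [lo, hi])),
        "alpha": alpha,
        "n_boot": n_boot,
        "block_len": block_len,
        "replicates": {"c1": c1_rep, "c2": c2_rep},
    }


def analyze_signal(
    signal: np.ndarray,
    sampling_rate: float = 1.0,
    p: float = 2.0,
    j1: int | None = None,
    j2: int | None = None,
    wavelet_order: int = 3,
    weighting: str = "counts",
    n_boot: int = 0,
    alpha: float = 0.05,
    seed: int | None = None,
) -> LogCumulantEstimate:
    """One-call (c1, c2) estimation for a single time series.

    Computes the wavelet pyramid, p-leaders and log-cumulant regression.  If
    the fit range (j1, j2) is not pinned, it is chosen automatically from
    the log-linear portion of the Welch PSD.  With ``n_boot > 0`` a circular
    block bootstrap adds percentile confidence intervals.
    """
    x = np.asarray(signal, float)
    coeffs = dwt_coefficients(x, wavelet_order=wavelet_order)
    leaders = p_leaders(coeffs, p=p)
    if j1 is None or j2 is None:
        usable = [j for j in range(1, leaders.n_levels + 1)
                  if leaders.counts[j - 1] >= 8]
        (a, b), _ = select_scaling_range(x, sampling_rate, j_max=max(usable))
        j1 = a if j1 is None else j1
        j2 = b if j2 is None else j2
    est = log_cumulants(leaders, j1, j2, weighting=weighting, coeffs=coeffs)
    if n_boot:
        est.ci = bootstrap_ci(
            leaders, j1, j2, n_boot=n_boot, alpha=alpha, seed=seed,
            weighting=weighting,
        )
        est.ci.pop("replicates")
    return est
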