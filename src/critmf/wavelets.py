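"""Discrete wavelet pyramid and wavelet p-leaders.

The multifractal machinery works on L1-normalized detail coefficients of an
orthonormal Daubechies pyramid.  Boundary policy: every convolution is
computed in 'valid' mode, so a coefficient exists only if its filter support
lies entirely inside the signal — border-contaminated coefficients are never
created in the first place.  With this policy every retained node of the
dyadic tree has a complete pair of children at the next finer scale, which
keeps the p-leader aggregation exact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pywt

logger = logging.getLogger(__name__)

__all__ = [
    "WaveletCoefficients",
    "PLeaders",
    "DegenerateSignalError",
    "dwt_coefficients",
    "p_leaders",
]


class DegenerateSignalError(ValueError):
    """Raised when a signal carries no usable wavelet energy (e.g. constant)."""


@dataclass
class WaveletCoefficients:
    """L1-normalized detail coefficients of a dyadic wavelet pyramid.

    ``details[i]`` holds the coefficients of scale ``j = i + 1``; they are the
    orthonormal pyramid outputs multiplied by ``2**(-j/2)`` so that for a
    signal with local Hölder regularity ``h`` the coefficients scale as
    ``2**(j*h)`` across scales.
    """

    details: list[np.ndarray]
    wavelet_order: int
    n_samples: int

    @property
    def n_levels(self) -> int:
        return len(self.details)

    @property
    def counts(self) -> np.ndarray:
        """Number of boundary-free coefficients per scale (decreasing in j)."""
        return np.array([len(d) for d in self.details])

    def structure_exponent(self, q: float, j1: int, j2: int) -> float:
        """Coefficient-based scaling exponent: slope of log2 E|d(j,.)|^q vs j.

        Used for the minimum-regularity check of the p-leader formalism
        (eta(p) > 0 is required for p-leaders to be well defined).
        """
        js = np.arange(j1, j2 + 1)
        y = np.array(
            [np.log2(np.mean(np.abs(self.details[j - 1]) ** q)) for j in js]
        )
        return float(np.polyfit(js, y, 1)[0])


@dataclass
class PLeaders:
    """Wavelet p-leaders of one signal.

    ``leaders[i]`` are the p-leaders at scale ``j = i + 1``.  The leader at
    (j, k) aggregates |d|^p over the dyadic interval [k*2^j, (k+1)*2^j) plus
    its two same-scale neighbours, across all scales j' <= j, with the
    p = infinity case reducing to the classical wavelet-leader supremum.
    """

    p: float
    leaders: list[np.ndarray]
    wavelet_order: int
    n_dropped_zero: int = 0
    dropped_per_scale: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def n_levels(self) -> int:
        return len(self.leaders)

    @property
    def counts(self) -> np.ndarray:
        return np.array([len(v) for v in self.leaders])


def dwt_coefficients(
    signal: np.ndarray,
    wavelet_order: int = 3,
    j_max: int | None = None,
) -> WaveletCoefficients:
    """Compute L1-normalized detail coefficients over dyadic scales 1..j_max.

    Parameters
    ----------
    signal
        One-dimensional, finite-valued array of samples.
    wavelet_order
        Number of vanishing moments of the Daubechies analysis wavelet
        (``db{wavelet_order}``); polynomials of degree < wavelet_order are
        annihilated.
    j_max
        Coarsest scale to compute.  Defaults to the deepest scale that still
        retains at least one boundary-free coefficient.

    Raises
    ------
    ValueError
        If the signal is not 1-D, contains non-finite samples, or is too
        short to reach ``j_max``.
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise ValueError(f"expected a 1-D signal, got shape {x.shape}")
    if x.size < 2:
        raise ValueError("signal too short")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite samples")
    if wavelet_order < 1:
        raise ValueError("wavelet_order must be >= 1")

    wav = pywt.Wavelet(f"db{wavelet_order}")
    lo = np.asarray(wav.dec_lo)
    hi = np.asarray(wav.dec_hi)
    flen = len(lo)

    # Polynomial annihilation leaves O(n * eps) rounding residue; snap it to
    # exact zero (relative to the signal amplitude, so estimates remain
    # invariant to positive rescaling) so degenerate inputs are detectable.
    snap_tol = 1e-12 * np.max(np.abs(x)) if np.any(x != 0) else 0.0

    details: list[np.ndarray] = []
    approx = x
    j = 0
    while True:
        if len(approx) < flen:
            break
        j += 1
        d = np.convolve(approx, hi, mode="valid")[::2]
        approx = np.convolve(approx, lo, mode="valid")[::2]
        if len(d) == 0:
            j -= 1
            break
        d[np.abs(d) < snap_tol] = 0.0
        details.append(d * 2.0 ** (-j / 2.0))
        if j_max is not None and j >= j_max:
            break

    if j_max is not None and len(details) < j_max:
        raise ValueError(
            f"signal of length {x.size} supports only {len(details)} scales, "
            f"j_max={j_max} requested"
        )
    return WaveletCoefficients(details=details, wavelet_order=wavelet_order,
                               n_samples=x.size)


def p_leaders(coeffs: WaveletCoefficients, p: float = 2.0) -> PLeaders:
    """Aggregate wavelet coefficients into p-leaders at every scale.

    For finite p,

        l(j, k) = ( sum_{j' <= j} sum_{k' : lam(j',k') in 3lam(j,k)}
                    |d(j',k')|^p * 2^(j'-j) )^(1/p)

    where 3lam(j,k) is the dyadic interval of (j,k) plus its two same-scale
    neighbours.  p = numpy.inf gives the classical wavelet leader (supremum
    of |d| over the same set).  Aggregates that are exactly zero carry no
    regularity information and are dropped (counted per scale).

    Raises
    ------
    DegenerateSignalError
        If every coefficient is zero (constant / polynomial input).
    """
    if not coeffs.details:
        raise DegenerateSignalError("no wavelet scales available")
    if not (p == np.inf or p > 0):
        raise ValueError("p must be positive or numpy.inf")
    if all(np.all(d == 0) for d in coeffs.details):
        raise DegenerateSignalError(
            "all wavelet coefficients are zero; p-leaders are undefined"
        )

    finite = np.isfinite(p)
    # A[j][k]: aggregate of |d|^p (finite p, with 2^(j'-j) weights) or the
    # supremum of |d| (p = inf) over the single dyadic interval lam(j, k).
    aggregates: list[np.ndarray] = []
    prev: np.ndarray | None = None
    for d in coeffs.details:
        a = np.abs(d) if not finite else np.abs(d) ** p
        if prev is not None:
            n = len(d)
            children = prev[: 2 * n].reshape(n, 2)
            if finite:
                a = a + children.sum(axis=1) / 2.0
            else:
                a = np.maximum(a, children.max(axis=1))
        aggregates.append(a)
        prev = a

    leaders: list[np.ndarray] = []
    dropped = []
    for a in aggregates:
        if len(a) < 3:
            stacked = np.empty((0,))
        elif finite:
            stacked = (a[:-2] + a[1:-1] + a[2:]) ** (1.0 / p)
        else:
            stacked = np.maximum(np.maximum(a[:-2], a[1:-1]), a[2:])
        nz = stacked > 0
        dropped.append(int(np.sum(~nz)))
        leaders.append(stacked[nz])

    n_dropped = int(np.sum(dropped))
    if n_dropped:
        logger.info("p_leaders: dropped %d exact-zero leaders", n_dropped)
    return PLeaders(
        p=p,
        leaders=leaders,
        wavelet_order=coeffs.wavelet_order,
        n_dropped_zero=n_dropped,
        dropped_per_scale=np.array(dropped),
    )
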