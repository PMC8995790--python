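"""Shared fixtures: independent brute-force oracles and small test cohorts.

The oracles deliberately re-derive each quantity from its definition with
explicit loops (no shared code with the package) so that implementation and
check stay on separate routes.
"""

from itertools import combinations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def leader_oracle():
    """Brute-force p-leader from the definition.

    Enumerates every coefficient (j', k') with j' <= j whose dyadic interval
    [k'*2^j', (k'+1)*2^j') lies inside the widened interval
    [(k-1)*2^j, (k+2)*2^j), and aggregates |d|^p * 2^(j'-j) (or the sup for
    p = inf).
    """

    def oracle(details, j, k, p):
        lo_t = (k - 1) * 2**j
        hi_t = (k + 2) * 2**j
        vals = []
        for jp in range(1, j + 1):
            d = details[jp - 1]
            for kp in range(len(d)):
                if kp * 2**jp >= lo_t and (kp + 1) * 2**jp <= hi_t:
                    vals.append((jp, abs(d[kp])))
        if p == np.inf:
            return max(v for _, v in vals)
        s = sum(v**p * 2.0 ** (jp - j) for jp, v in vals)
        return s ** (1.0 / p)

    return oracle


@pytest.fixture(scope="session")
def bh_oracle():
    """Step-up Benjamini–Hochberg from the definition.

    Sorts the p-values, finds the largest rank i with p_(i) <= i*alpha/m,
    rejects everything at or below it, and computes adjusted p-values by the
    running-minimum rule.
    """

    def oracle(pvals, alpha):
        p = np.asarray(pvals, float)
        m = len(p)
        order = np.argsort(p, kind="stable")
        ranked = p[order]
        q_sorted = np.empty(m)
        running = 1.0
        for i in range(m - 1, -1, -1):
            running = min(running, ranked[i] * m / (i + 1))
            q_sorted[i] = running
        q = np.empty(m)
        q[order] = q_sorted
        k_max = 0
        for i in range(m):
            if ranked[i] <= (i + 1) * alpha / m:
                k_max = i + 1
        mask = np.zeros(m, bool)
        mask[order[:k_max]] = True
        return q, mask

    return oracle


@pytest.fixture(scope="session")
def maxstat_enum_oracle():
    """Exhaustive max-|t| permutation test from the definition.

    Enumerates every assignment of n_a subjects to group A, computes the
    Welch-type statistic with the given s0 at every node, and derives exact
    corrected p-values as the fraction of assignments whose max |t| reaches
    the observed |t| of each node.
    """

    def welch_t(a, b, s0):
        na, nb = len(a), len(b)
        se = np.sqrt(a.var(axis=0, ddof=1) / na + b.var(axis=0, ddof=1) / nb)
        return (a.mean(axis=0) - b.mean(axis=0)) / (se + s0)

    def oracle(X, n_a, s0, t_obs, alpha):
        n = X.shape[0]
        maxes = []
        for idx in combinations(range(n), n_a):
            sel = np.zeros(n, bool)
            sel[list(idx)] = True
            maxes.append(np.max(np.abs(welch_t(X[sel], X[~sel], s0))))
        maxes = np.array(maxes)
        p = np.array([(maxes >= abs(t)).mean() for t in t_obs])
        return p, np.quantile(maxes, 1 - alpha), maxes

    return oracle


@pytest.fixture()
def rng():
    return np.random.default_rng(20260920)
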