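"""Group-level inference on node-wise feature maps.

Implements the statistical layer applied to per-node c1/c2 maps: ROI
averaging, two-tailed unpaired pseudo t-tests with maximum-statistics
permutation correction (familywise error control across nodes), clinical
covariate correlations with Benjamini–Hochberg FDR, and a descriptive
medication-mediation check.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats as sst
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "GroupComparisonResult",
    "CorrelationResult",
    "roi_average",
    "pseudo_t",
    "maxstat_permutation",
    "bh_fdr",
    "clinical_correlation",
    "mediation_check",
]


@dataclass
class GroupComparisonResult:
    t: np.ndarray                 # observed pseudo-t per node
    p_corrected: np.ndarray       # maxstat-corrected p per node
    threshold: float              # familywise |t| threshold at level alpha
    mask: np.ndarray              # p_corrected <= alpha
    alpha: float
    n_perm: int
    s0: float
    exact: bool = False           # True when all assignments were enumerated
    seed: int | None = None
    null_max: np.ndarray = field(default_factory=lambda: np.array([]))


@dataclass
class CorrelationResult:
    r: np.ndarray
    p: np.ndarray
    q: np.ndarray | None          # BH-adjusted (Pearson only)
    mask: np.ndarray
    method: str
    corrected: bool
    n_used: int
    alpha: float


def roi_average(
    features: np.ndarray | pd.DataFrame, labels: pd.DataFrame
) -> pd.DataFrame:
    """Average node-level features into ROIs, per subject.

    ``labels`` must map every feature column: columns ``node_id`` and
    ``roi_id`` (optionally ``roi_name``).  Returns a subjects × ROIs frame
    whose columns are the distinct ROI ids in sorted order.
    """
    if isinstance(features, pd.DataFrame):
        node_ids = features.columns.to_numpy()
        values = features.to_numpy()
        index = features.index
    else:
        values = np.asarray(features, float)
        node_ids = np.arange(values.shape[1])
        index = pd.RangeIndex(values.shape[0])
    mapping = dict(zip(labels["node_id"], labels["roi_id"]))
    missing = [n for n in node_ids if n not in mapping]
    if missing:
        raise KeyError(f"nodes missing from label map: {missing[:5]}...")
    roi_of = np.array([mapping[n] for n in node_ids])
    rois = np.unique(roi_of)
    out = np.column_stack([values[:, roi_of == r].mean(axis=1) for r in rois])
    return pd.DataFrame(out, index=index, columns=rois)


def _group_arrays(features: np.ndarray, groups: np.ndarray):
    groups = np.asarray(groups)
    levels = pd.unique(groups)
    if len(levels) != 2:
        raise ValueError(f"expected exactly two groups, got {levels}")
    a = np.asarray(features, float)[groups == levels[0]]
    b = np.asarray(features, float)[groups == levels[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 subjects")
    return a, b, levels


def pseudo_t(
    group_a: np.ndarray, group_b: np.ndarray, s0: float = 0.0
) -> np.ndarray | float:
    """Unpaired pseudo t-statistic with variance regularizer s0.

    t = (mean_a - mean_b) / (sqrt(var_a/n_a + var_b/n_b) + s0).  With
    s0 = 0 this is the Welch statistic; s0 > 0 damps nodes whose standard
    error is near zero (the variance-smoothing convention of nonparametric
    neuroimaging statistics).
    """
    a = np.atleast_2d(np.asarray(group_a, float).T).T
    b = np.atleast_2d(np.asarray(group_b, float).T).T
    se = np.sqrt(a.var(axis=0, ddof=1) / a.shape[0]
                 + b.var(axis=0, ddof=1) / b.shape[0])
    denom = se + s0
    if np.any(denom == 0):
        raise ZeroDivisionError(
            "zero pseudo-t denominator (constant data with s0 = 0)"
        )
    t = (a.mean(axis=0) - b.mean(axis=0)) / denom
    return float(t[0]) if np.isscalar(group_a[0]) and t.size == 1 else t


def _perm_t(features, mask_a, s0):
    """Pseudo-t for a batch of group-A membership masks (B, S) -> (B, N)."""
    X = features
    X2 = features**2
    nA = mask_a.sum(axis=1, keepdims=True).astype(float)
    nB = X.shape[0] - nA
    sumA = mask_a @ X
    sumB = X.sum(axis=0)[None, :] - sumA
    sqA = mask_a @ X2
    sqB = X2.sum(axis=0)[None, :] - sqA
    mA, mB = sumA / nA, sumB / nB
    vA = (sqA - nA * mA**2) / (nA - 1)
    vB = (sqB - nB * mB**2) / (nB - 1)
    vA = np.clip(vA, 0, None)
    vB = np.clip(vB, 0, None)
    se = np.sqrt(vA / nA + vB / nB)
    return (mA - mB) / (se + s0)


def maxstat_permutation(
    features: np.ndarray,
    groups: np.ndarray,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
    s0: float | str = "median",
) -> GroupComparisonResult:
    """Two-tailed pseudo t-test per node, familywise-corrected by max statistics.

    For each permutation of the group labels (group sizes preserved) the
    maximum of |t| across nodes is recorded; the familywise threshold is the
    (1 - alpha) quantile of that null max distribution and the corrected
    p-value of a node is (1 + #{perm : max >= |t_obs|}) / (n_perm + 1).

    The regularizer s0 is computed once from the observed grouping (median
    across nodes of the standard-error term) and held fixed across
    permutations.  When the number of distinct group-A assignments is <=
    n_perm the null is enumerated exhaustively and p-values are exact
    (b / m over all m assignments, the observed one included).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    X = np.asarray(features, float)
    a, b, levels = _group_arrays(X, groups)
    nA = len(a)
    n_sub = X.shape[0]

    se_obs = np.sqrt(a.var(axis=0, ddof=1) / nA
                     + b.var(axis=0, ddof=1) / len(b))
    s0_val = float(np.median(se_obs)) if s0 == "median" else float(s0)
    t_obs = pseudo_t(a, b, s0=s0_val)
    t_obs = np.atleast_1d(t_obs)

    n_assign = comb(n_sub, nA)
    exact = n_assign <= n_perm
    if exact:
        masks = np.zeros((n_assign, n_sub), dtype=bool)
        for i, idx in enumerate(combinations(range(n_sub), nA)):
            masks[i, list(idx)] = True
        logger.info("maxstat: exhaustive enumeration of %d assignments", n_assign)
    else:
        rng = np.random.default_rng(seed)
        masks = np.zeros((n_perm, n_sub), dtype=bool)
        for i in range(n_perm):
            masks[i, rng.choice(n_sub, size=nA, replace=False)] = True

    null_t = _perm_t(X, masks, s0_val)
    null_max = np.abs(null_t).max(axis=1)
    m = len(null_max)
    if exact:
        p_corr = (null_max[None, :] >= np.abs(t_obs)[:, None]).sum(axis=1) / m
    else:
        p_corr = (1 + (null_max[None, :] >= np.abs(t_obs)[:, None]).sum(axis=1)) / (m + 1)
    threshold = float(np.quantile(null_max, 1 - alpha))
    return GroupComparisonResult(
        t=t_obs, p_corrected=p_corr, threshold=threshold,
        mask=p_corr <= alpha, alpha=alpha, n_perm=m, s0=s0_val,
        exact=exact, seed=seed, null_max=null_max,
    )


def bh_fdr(pvalues: np.ndarray, alpha: float = 0.05):
    """Benjamini–Hochberg step-up FDR control.

    Returns ``(qvalues, mask)`` where q-values are the monotone-enforced
    adjusted p-values and mask = (q <= alpha).
    """
    p = np.asarray(pvalues, float)
    if p.size == 0:
        return p.copy(), np.zeros(0, bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    mask, q = multipletests(p, alpha=alpha, method="fdr_bh")[:2]
    return q, mask


def clinical_correlation(
    features: np.ndarray,
    covariate: np.ndarray,
    method: str = "pearson",
    alpha: float = 0.05,
) -> CorrelationResult:
    """Per-node correlation between a feature map and a clinical covariate.

    Subjects with a missing covariate are dropped (logged).  The Pearson
    path applies BH-FDR across nodes; the Spearman path reports raw
    (uncorrected) p-values only, tagged as such.
    """
    X = np.atleast_2d(np.asarray(features, float).T).T
    cov = np.asarray(covariate, float)
    keep = np.isfinite(cov)
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("clinical_correlation: dropping %d subjects with missing "
                    "covariate", n_drop)
    X, cov = X[keep], cov[keep]
    if len(cov) < 5:
        raise ValueError("covariate present for fewer than 5 subjects")
    if np.ptp(cov) == 0:
        raise ValueError("constant covariate")

    n_nodes = X.shape[1]
    r = np.empty(n_nodes)
    p = np.empty(n_nodes)
    for v in range(n_nodes):
        if method == "pearson":
            r[v], p[v] = sst.pearsonr(X[:, v], cov)
        elif method == "spearman":
            r[v], p[v] = sst.spearmanr(X[:, v], cov)
        else:
            raise ValueError("method must be 'pearson' or 'spearman'")
    if method == "pearson":
        q, mask = bh_fdr(p, alpha)
        return CorrelationResult(r=r, p=p, q=q, mask=mask, method=method,
                                 corrected=True, n_used=len(cov), alpha=alpha)
    return CorrelationResult(r=r, p=p, q=None, mask=p <= alpha, method=method,
                             corrected=False, n_used=len(cov), alpha=alpha)


def mediation_check(score: np.ndarray, dose: np.ndarray) -> dict:
    """Descriptive check of how much a symptom score is shared with medication.

    Reports the Pearson correlation between score and dose and the R² of
    score regressed on dose (their squared correlation) — the fraction of
    score variance explicable by medication dosage.  Purely descriptive; no
    causal claim.
    """
    s = np.asarray(score, float)
    d = np.asarray(dose, float)
    keep = np.isfinite(s) & np.isfinite(d)
    s, d = s[keep], d[keep]
    if np.ptp(s) == 0 or np.ptp(d) == 0:
        raise ValueError("constant score or dose")
    r, p = sst.pearsonr(s, d)
    return {"r_score_dose": float(r), "p": float(p), "r2": float(r**2),
            "n": int(keep.sum())}
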