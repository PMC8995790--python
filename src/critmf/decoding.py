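"""Node-wise single-feature decoding of group membership.

Each node's feature (c1 or c2) is used alone to classify subjects with an
unregularized logistic model under stratified k-fold cross-validation; the
decoding accuracy (DA) is the mean over folds of the test-set proportion
correct.  Statistical significance is assessed against a permutation null:
labels are shuffled, the full cross-validation is re-run at every node, and
the maximum DA across nodes per shuffle forms the null distribution whose
(1 - alpha) quantile is the familywise "chance level" — a data-dependent
output of the procedure, typically well above 0.5.

The logistic fit is a two-parameter (intercept + slope) Newton iteration
vectorized across nodes, so that thousands of permutation re-runs stay
cheap; it matches an unpenalized scikit-learn fit to high precision (the
test suite checks this agreement).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

logger = logging.getLogger(__name__)

__all__ = [
    "DecodingResult",
    "stratified_folds",
    "decode_single_feature",
    "decoding_null_threshold",
]

_MAX_NEWTON_ITER = 25   # separable data diverges; the cap bounds the fit
_NEWTON_TOL = 1e-8


@dataclass
class DecodingResult:
    da: np.ndarray                # decoding accuracy per node
    null_max: np.ndarray          # max DA across nodes, one per permutation
    threshold: float              # familywise DA threshold at level alpha
    mask: np.ndarray              # da > threshold (strict)
    alpha: float
    k: int
    n_perm: int
    seed: int | None = None
    flags: dict = field(default_factory=dict)


def stratified_folds(groups: np.ndarray, k: int, seed: int | None = None) -> np.ndarray:
    """Assign every subject to one of k class-balanced test folds.

    Each fold's class ratio is within one subject of the global ratio and
    the assignment is an exact partition.  Deterministic in ``seed``.
    Returns an integer array of fold indices, one per subject.
    """
    groups = np.asarray(groups)
    _, counts = np.unique(groups, return_counts=True)
    if counts.min() < k:
        raise ValueError(f"smallest class has {counts.min()} members < k={k}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = np.empty(len(groups), dtype=int)
    for f, (_, test_idx) in enumerate(skf.split(np.zeros(len(groups)), groups)):
        folds[test_idx] = f
    return folds


def _sigmoid(z):
    return 0.5 * (1.0 + np.tanh(0.5 * z))


def _fit_logistic_batch(x: np.ndarray, y: np.ndarray):
    """Newton fit of logit P(y=1) = a + b*x, batched over leading axes.

    ``x`` has shape (..., n), ``y`` shape (n,).  Returns (a, b) with shape
    (...,).  Unconverged (separable) fits simply stop at the iteration cap,
    which leaves the decision boundary in place.
    """
    shape = x.shape[:-1]
    a = np.zeros(shape)
    b = np.zeros(shape)
    for _ in range(_MAX_NEWTON_ITER):
        z = np.clip(a[..., None] + b[..., None] * x, -35.0, 35.0)
        p = _sigmoid(z)
        r = y - p
        g0 = r.sum(axis=-1)
        g1 = (r * x).sum(axis=-1)
        if max(np.abs(g0).max(), np.abs(g1).max()) < _NEWTON_TOL:
            break
        w = p * (1.0 - p)
        h00 = w.sum(axis=-1) + 1e-10
        h01 = (w * x).sum(axis=-1)
        h11 = (w * x * x).sum(axis=-1) + 1e-10
        det = h00 * h11 - h01**2
        a = a + (h11 * g0 - h01 * g1) / det
        b = b + (h00 * g1 - h01 * g0) / det
    return a, b


def _decode_matrix(features: np.ndarray, y: np.ndarray, folds: np.ndarray) -> np.ndarray:
    """Cross-validated decoding accuracy per node.

    ``features`` is subjects × nodes, ``y`` binary labels, ``folds`` the
    test-fold index per subject.  Features are standardized with the
    training fold's mean/SD only (no leakage); a constant training feature
    degenerates to an intercept-only (majority-class) fit.  Ties at the 0.5
    probability threshold go to class 0.
    """
    X = features.T  # (nodes, subjects)
    k = folds.max() + 1
    acc = np.zeros((k, X.shape[0]))
    for f in range(k):
        test = folds == f
        train = ~test
        mu = X[:, train].mean(axis=1, keepdims=True)
        sd = X[:, train].std(axis=1, keepdims=True)
        degenerate = sd[:, 0] < 1e-12
        sd = np.where(sd < 1e-12, 1.0, sd)
        Xtr = (X[:, train] - mu) / sd
        Xte = (X[:, test] - mu) / sd
        if degenerate.any():
            Xtr[degenerate] = 0.0
            Xte[degenerate] = 0.0
            logger.info("decode: %d nodes constant in training fold %d "
                        "(majority-class fallback)", int(degenerate.sum()), f)
        a, b = _fit_logistic_batch(Xtr, y[train].astype(float))
        pred = _sigmoid(a[:, None] + b[:, None] * Xte) > 0.5
        acc[f] = (pred == y[test][None, :].astype(bool)).mean(axis=1)
    return acc.mean(axis=0)


def decode_single_feature(
    feature: np.ndarray, groups: np.ndarray, k: int = 10, seed: int | None = None
) -> float:
    """Cross-validated decoding accuracy of one per-subject feature.

    Fits an intercept + slope logistic classifier per training fold (feature
    standardized by training-fold statistics) and returns the mean test-set
    proportion correct over the k stratified folds.
    """
    groups = np.asarray(groups)
    y = (groups == pd_unique2(groups)[1]).astype(int)
    folds = stratified_folds(groups, k, seed)
    return float(_decode_matrix(np.asarray(feature, float)[:, None], y, folds)[0])


def pd_unique2(groups: np.ndarray) -> np.ndarray:
    """Two group levels in order of first appearance."""
    levels = []
    for g in groups:
        if g not in levels:
            levels.append(g)
    if len(levels) != 2:
        raise ValueError(f"expected exactly two groups, got {levels}")
    return np.asarray(levels)


def decoding_null_threshold(
    features: np.ndarray,
    groups: np.ndarray,
    k: int = 10,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
) -> DecodingResult:
    """Observed per-node DA plus a max-statistics permutation threshold.

    For each of ``n_perm`` permutations the class labels are shuffled once,
    fold assignments are re-derived from the shuffled labels, the full
    k-fold decoding is re-run at every node, and the maximum DA across
    nodes is recorded.  The familywise threshold ("chance level") is the
    (1 - alpha) quantile of these maxima; a node is flagged when its
    observed DA strictly exceeds it.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    X = np.atleast_2d(np.asarray(features, float).T).T
    groups = np.asarray(groups)
    levels = pd_unique2(groups)
    y = (groups == levels[1]).astype(int)

    folds = stratified_folds(groups, k, seed)
    da_obs = _decode_matrix(X, y, folds)

    rng = np.random.default_rng(seed)
    null_max = np.empty(n_perm)
    for b in range(n_perm):
        y_perm = rng.permutation(y)
        fold_seed = int(rng.integers(2**31))
        folds_b = stratified_folds(y_perm, k, fold_seed)
        null_max[b] = _decode_matrix(X, y_perm, folds_b).max()

    threshold = float(np.quantile(null_max, 1 - alpha))
    return DecodingResult(
        da=da_obs, null_max=null_max, threshold=threshold,
        mask=da_obs > threshold, alpha=alpha, k=k, n_perm=n_perm, seed=seed,
    )
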