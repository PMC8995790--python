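"""Synthetic scale-free signals and two-group cohorts with known ground truth.

The study data this pipeline targets (resting-state source-reconstructed
neural recordings) cannot be redistributed, so every pipeline stage is
validated against synthetic cohorts whose ground-truth self-similarity and
multifractality maps are known exactly:

* fractional Brownian motion (fBm) — canonical monofractal, c1 = H, c2 = 0;
* multifractal random walk (MRW) — log-normally modulated walk,
  c1 = H + lambda2/2, c2 = -lambda2.

A cohort assigns every node a coordinate x in [0, 1] (an abstract
rostro-caudal axis): controls carry opposing monotone gradients of H and
lambda2 along x, patients get the same gradients attenuated plus regional
offsets (higher H on anterior "fronto-temporal" nodes, lambda2 pulled
toward 0 on posterior "parieto-occipital" nodes), and clinical scores are
linearly coupled to regional ground-truth c1/c2 with Gaussian noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SyntheticCohortSpec",
    "SyntheticCohort",
    "simulate_fgn_fbm",
    "simulate_mrw",
    "simulate_cohort",
    "simulate_feature_cohort",
    "synthetic_label_map",
    "mrw_theoretical_c1",
    "mrw_theoretical_c2",
]


def mrw_theoretical_c1(H: float, lambda2: float) -> float:
    """Theoretical first log-cumulant of the MRW: H + lambda2/2."""
    return H + lambda2 / 2.0


def mrw_theoretical_c2(lambda2: float) -> float:
    """Theoretical second log-cumulant of the MRW: -lambda2."""
    return -lambda2


def _circulant_sample(acov: np.ndarray, n: int, rng: np.random.Generator,
                      label: str) -> np.ndarray:
    """Draw one stationary Gaussian vector of length n with autocovariance acov.

    Exact circulant embedding (Davies–Harte).  ``acov`` must hold lags
    0..n.  Slightly negative embedding eigenvalues (from covariances that
    are only approximately embeddable) are clipped to zero with a log
    message; a strongly negative spectrum raises.
    """
    row = np.concatenate([acov, acov[-2:0:-1]])
    m = len(row)
    lam = np.fft.fft(row).real
    neg = lam < 0
    if np.any(neg):
        worst = lam.min()
        if worst < -1e-6 * lam.max():
            logger.warning(
                "%s: circulant embedding not nonnegative (min eig %.3g); "
                "clipping to approximate spectral synthesis", label, worst,
            )
        lam = np.clip(lam, 0.0, None)
    xi = rng.standard_normal(m) + 1j * rng.standard_normal(m)
    y = np.fft.ifft(np.sqrt(lam) * xi) * np.sqrt(m)
    return y.real[:n]


def _fgn(n: int, H: float, rng: np.random.Generator) -> np.ndarray:
    """Exact fractional Gaussian noise (unit-variance increments of fBm)."""
    k = np.arange(n + 1, dtype=float)
    acov = 0.5 * (np.abs(k + 1) ** (2 * H) - 2 * k ** (2 * H)
                  + np.abs(k - 1) ** (2 * H))
    return _circulant_sample(acov, n, rng, f"fGn(H={H})")


def simulate_fgn_fbm(n: int, H: float, seed=None) -> np.ndarray:
    """Fractional Brownian motion of length n with Hurst exponent H.

    Generates exact-covariance fractional Gaussian noise by circulant
    embedding of gamma(k) = (|k+1|^2H - 2|k|^2H + |k-1|^2H)/2 and cumulates
    it.  fBm is the canonical monofractal signal: c1 = H, c2 = 0.
    """
    if not 0 < H < 1:
        raise ValueError(f"H must lie in (0, 1), got {H}")
    rng = np.random.default_rng(seed)
    return np.cumsum(_fgn(n, H, rng))


def simulate_mrw(n: int, H: float, lambda2: float, seed=None,
                 horizon: int | None = None) -> np.ndarray:
    """Multifractal random walk with intermittency lambda2.

    Increments are dX_i = eps_i * exp(omega_i) with eps fractional Gaussian
    noise of parameter H and omega a stationary Gaussian log-cascade with
    Cov(omega_i, omega_j) = lambda2 * ln+( L / (|i-j| + 1) ), correlation
    horizon L = n/8 by default, and mean -Var(omega)/2 so E exp(omega) = 1.
    The returned walk has theoretical c1 = H + lambda2/2, c2 = -lambda2;
    lambda2 = 0 reduces exactly to fBm.
    """
    if not 0 < H < 1:
        raise ValueError(f"H must lie in (0, 1), got {H}")
    if not 0 <= lambda2 <= 0.2:
        raise ValueError(f"lambda2 must lie in [0, 0.2], got {lambda2}")
    rng = np.random.default_rng(seed)
    eps = _fgn(n, H, rng)
    if lambda2 == 0:
        return np.cumsum(eps)
    L = n // 8 if horizon is None else horizon
    k = np.arange(n + 1, dtype=float)
    acov = lambda2 * np.clip(np.log(L / (k + 1)), 0.0, None)
    omega = _circulant_sample(acov, n, rng, f"MRW omega(lambda2={lambda2})")
    omega += -acov[0] / 2.0
    return np.cumsum(eps * np.exp(omega))


@dataclass
class SyntheticCohortSpec:
    """Ground-truth description of a two-group synthetic cohort.

    Node coordinate x runs over [0, 1] (anterior -> posterior stand-in).
    Controls: H(x) and lambda2(x) are linear gradients.  Patients: the same
    gradients with slope multiplied by ``patient_attenuation``, plus
    ``patient_dH`` added to H on nodes with x < ``anterior_frac`` and
    ``patient_dlambda2`` added to lambda2 (a negative default, pulling
    multifractality toward 0) on nodes with x > 1 - ``posterior_frac``.
    Per-subject trait variability adds one scalar H offset and one lambda2
    offset per subject across all nodes.

    Clinical model (patients only): each score is score_mean + coupling *
    (regional true c1 or c2, subject-centred) + Gaussian noise; medication
    dose correlates with the negative-symptom score at level ``dose_rho``.
    """

    n_per_group: int = 25
    n_nodes: int = 50
    n_samples: int = 2**14
    sampling_rate: float = 600.0
    # control gradients (value at x=0, value at x=1); H stays inside (0, 1)
    H_range: tuple[float, float] = (0.35, 0.90)
    lambda2_range: tuple[float, float] = (0.005, 0.05)
    patient_attenuation: float = 0.6
    patient_dH: float = 0.10
    patient_dlambda2: float = -0.01
    anterior_frac: float = 0.3
    posterior_frac: float = 0.3
    subject_H_sd: float = 0.04
    subject_lambda2_sd: float = 0.004
    # clinical couplings (patients)
    sans_mean: float = 35.0
    sans_coupling: float = 300.0      # per unit of regional true c1
    sans_noise_sd: float = 9.0        # targets r ~ 0.8 with subject_H_sd=0.04
    saps_mean: float = 30.0
    saps_coupling: float = 2000.0     # per unit of regional true c2
    saps_noise_sd: float = 7.5
    dose_mean: float = 15.0           # olanzapine-equivalent mg
    dose_sd: float = 6.0
    dose_rho: float = 0.55
    seed: int = 0

    def __post_init__(self):
        if not (0 < min(self.H_range) and max(self.H_range) < 1):
            raise ValueError("control H gradient must stay in (0,1)")
        if min(self.lambda2_range) < 0:
            raise ValueError("lambda2 must be >= 0")
        maps = self.truth_maps()
        for key in ("H_control", "H_patient"):
            if maps[key].min() <= 0 or maps[key].max() >= 1:
                raise ValueError(f"{key} map leaves (0,1); adjust gradients/offsets")

    @property
    def node_x(self) -> np.ndarray:
        return np.linspace(0.0, 1.0, self.n_nodes)

    def truth_maps(self) -> dict[str, np.ndarray]:
        """Ground-truth H and lambda2 per node for each group (no jitter)."""
        x = self.node_x
        h0, h1 = self.H_range
        l0, l1 = self.lambda2_range
        H_ctrl = h0 + (h1 - h0) * x
        lam_ctrl = l0 + (l1 - l0) * x
        # attenuate the gradient about its midpoint, then apply regional offsets
        H_pat = H_ctrl.mean() + self.patient_attenuation * (H_ctrl - H_ctrl.mean())
        lam_pat = lam_ctrl.mean() + self.patient_attenuation * (lam_ctrl - lam_ctrl.mean())
        anterior = x < self.anterior_frac
        posterior = x > 1 - self.posterior_frac
        H_pat = H_pat + self.patient_dH * anterior
        lam_pat = np.clip(lam_pat + self.patient_dlambda2 * posterior, 0.0, None)
        return {
            "H_control": H_ctrl, "lambda2_control": lam_ctrl,
            "H_patient": H_pat, "lambda2_patient": lam_pat,
            "anterior_nodes": np.where(anterior)[0],
            "posterior_nodes": np.where(posterior)[0],
            "c1_control": H_ctrl + lam_ctrl / 2, "c2_control": -lam_ctrl,
            "c1_patient": H_pat + lam_pat / 2, "c2_patient": -lam_pat,
        }


@dataclass
class SyntheticCohort:
    """Simulated cohort: signals, subject table, and the ground-truth manifest."""

    signals: np.ndarray            # (n_subjects, n_nodes, n_samples)
    subjects: pd.DataFrame         # id, group, SANS, SAPS, medication_mg
    sampling_rate: float
    truth: dict

    @property
    def groups(self) -> np.ndarray:
        return self.subjects["group"].to_numpy()


def simulate_cohort(spec: SyntheticCohortSpec) -> SyntheticCohort:
    """Generate signals for every subject and node of a two-group cohort.

    Each (subject, node) signal is an MRW with the node's group-level
    (H, lambda2) plus the subject's trait offsets; signal random streams are
    derived deterministically from (seed, subject index, node index), so a
    cohort is bit-exactly reproducible from its spec.
    """
    truth = spec.truth_maps()
    n_sub = 2 * spec.n_per_group
    groups = np.array(["control"] * spec.n_per_group + ["patient"] * spec.n_per_group)

    trait_rng = np.random.default_rng([spec.seed, 12632274])
    dH_sub = trait_rng.normal(0.0, spec.subject_H_sd, size=n_sub)
    dlam_sub = trait_rng.normal(0.0, spec.subject_lambda2_sd, size=n_sub)

    signals = np.empty((n_sub, spec.n_nodes, spec.n_samples))
    for s in range(n_sub):
        grp = "control" if groups[s] == "control" else "patient"
        Hmap = truth[f"H_{grp}"] + dH_sub[s]
        lammap = np.clip(truth[f"lambda2_{grp}"] + dlam_sub[s], 0.0, 0.2)
        Hmap = np.clip(Hmap, 0.02, 0.98)
        for v in range(spec.n_nodes):
            signals[s, v] = simulate_mrw(
                spec.n_samples, Hmap[v], lammap[v], seed=[spec.seed, s, v]
            )

    subjects = _subject_table(spec, groups, dH_sub, dlam_sub, truth)
    manifest = {
        "spec": {k: (list(v) if isinstance(v, tuple) else v)
                 for k, v in vars(spec).items()},
        "subject_H_offsets": dH_sub.tolist(),
        "subject_lambda2_offsets": dlam_sub.tolist(),
        **{k: (v.tolist() if isinstance(v, np.ndarray) else v)
           for k, v in truth.items()},
    }
    return SyntheticCohort(signals=signals, subjects=subjects,
                           sampling_rate=spec.sampling_rate, truth=manifest)


def _subject_table(spec, groups, dH_sub, dlam_sub, truth) -> pd.DataFrame:
    """Clinical scores coupled to regional ground-truth c1/c2 (patients only)."""
    rng = np.random.default_rng([spec.seed, 6094821])
    n_sub = len(groups)
    sans = np.full(n_sub, np.nan)
    saps = np.full(n_sub, np.nan)
    dose = np.full(n_sub, np.nan)
    pat = np.where(groups == "patient")[0]

    ant = truth["anterior_nodes"]
    post = truth["posterior_nodes"]
    # regional true c1/c2 per patient = group map + subject trait offset
    c1_reg = truth["c1_patient"][ant].mean() + dH_sub[pat]
    c2_reg = truth["c2_patient"][post].mean() - dlam_sub[pat]

    sans[pat] = (spec.sans_mean
                 + spec.sans_coupling * (c1_reg - c1_reg.mean())
                 + rng.normal(0, spec.sans_noise_sd, pat.size))
    saps[pat] = (spec.saps_mean
                 + spec.saps_coupling * (c2_reg - c2_reg.mean())
                 + rng.normal(0, spec.saps_noise_sd, pat.size))
    z = (sans[pat] - np.nanmean(sans[pat])) / np.nanstd(sans[pat])
    dose[pat] = (spec.dose_mean
                 + spec.dose_rho * spec.dose_sd * z
                 + np.sqrt(1 - spec.dose_rho**2) * spec.dose_sd
                 * rng.standard_normal(pat.size))
    sans = np.clip(sans, 0, None)
    saps = np.clip(saps, 0, None)
    dose = np.clip(dose, 0, None)
    return pd.DataFrame({
        "id": [f"sub-{i:03d}" for i in range(n_sub)],
        "group": groups,
        "SANS": sans, "SAPS": saps, "medication_mg": dose,
    })


def simulate_feature_cohort(
    n_per_group: int = 25,
    n_nodes: int = 50,
    effect_nodes: np.ndarray | list | None = None,
    effect_size: float = 0.0,
    baseline: float = 0.7,
    noise_sd: float = 0.1,
    seed=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw a cohort feature matrix directly at the c1/c2 level.

    Emulates the per-node feature maps the estimator produces — baseline
    value plus independent Gaussian estimator/subject variability of SD
    ``noise_sd`` — with ``effect_size`` added to the patient group at
    ``effect_nodes``.  With effect_size = 0 this is an exact global null,
    which is what the familywise-calibration suites need; it deliberately
    skips signal synthesis so that hundreds of cohorts stay cheap.

    Returns ``(features, groups)`` with features shaped (2*n_per_group,
    n_nodes) and groups a string array ('control'/'patient').
    """
    rng = np.random.default_rng(seed)
    n_sub = 2 * n_per_group
    features = baseline + rng.normal(0.0, noise_sd, size=(n_sub, n_nodes))
    groups = np.array(["control"] * n_per_group + ["patient"] * n_per_group)
    if effect_nodes is not None and effect_size != 0.0:
        idx = np.asarray(effect_nodes, dtype=int)
        features[np.ix_(groups == "patient", idx)] += effect_size
    return features, groups


def synthetic_label_map(n_nodes: int, n_rois: int, seed=None) -> pd.DataFrame:
    """Synthetic node -> ROI label map (contiguous blocks along the node axis).

    A stand-in for a cortical parcellation: every node is assigned to one of
    ``n_rois`` regions, each region getting at least one node.
    """
    if n_rois > n_nodes:
        raise ValueError("need at least one node per ROI")
    roi_of_node = np.floor(np.arange(n_nodes) * n_rois / n_nodes).astype(int)
    return pd.DataFrame({
        "node_id": np.arange(n_nodes),
        "roi_id": roi_of_node,
        "roi_name": [f"roi_{r:03d}" for r in roi_of_node],
    })
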