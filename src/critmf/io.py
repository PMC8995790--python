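"""Readers and writers for the pipeline's on-disk formats.

Formats are deliberately plain: TSV for tabular data (features, subjects,
label maps, single-channel signals), JSON for manifests and per-node
records, HDF5 for cohort signal containers (one group per subject holding a
``signals`` dataset shaped nodes × samples with a ``sampling_rate_hz``
attribute).
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "read_signal_tsv",
    "write_features_tsv", "read_features_tsv",
    "write_subjects_tsv", "read_subjects_tsv",
    "write_label_map_tsv", "read_label_map_tsv",
    "write_cohort_h5", "read_cohort_h5",
    "write_json",
]


def read_signal_tsv(path) -> np.ndarray:
    """Single-channel series: one value per line."""
    return np.loadtxt(path, dtype=float, ndmin=1)


def write_features_tsv(features, path, node_ids=None, subject_ids=None) -> None:
    """Subjects × nodes feature table."""
    if isinstance(features, pd.DataFrame):
        df = features
    else:
        X = np.asarray(features, float)
        cols = node_ids if node_ids is not None else [f"node_{i}" for i in range(X.shape[1])]
        idx = subject_ids if subject_ids is not None else [f"sub-{i:03d}" for i in range(X.shape[0])]
        df = pd.DataFrame(X, index=idx, columns=cols)
    df.to_csv(path, sep="\t", index_label="subject")


def read_features_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="subject")


def write_subjects_tsv(subjects: pd.DataFrame, path) -> None:
    subjects.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_subjects_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_label_map_tsv(labels: pd.DataFrame, path) -> None:
    labels.to_csv(path, sep="\t", index=False)


def read_label_map_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_cohort_h5(path, signals: np.ndarray, subject_ids, sampling_rate: float,
                    groups=None) -> None:
    """Cohort container: one HDF5 group per subject with a nodes × samples
    ``signals`` dataset and ``sampling_rate_hz`` attribute."""
    with h5py.File(path, "w") as f:
        for i, sid in enumerate(subject_ids):
            g = f.create_group(str(sid))
            g.create_dataset("signals", data=signals[i])
            g.attrs["sampling_rate_hz"] = float(sampling_rate)
            if groups is not None:
                g.attrs["group"] = str(groups[i])


def read_cohort_h5(path):
    """Returns (signals (S, N, T), subject_ids, sampling_rate, groups|None)."""
    with h5py.File(path, "r") as f:
        sids = sorted(f.keys())
        signals = np.stack([f[s]["signals"][()] for s in sids])
        fs = float(f[sids[0]].attrs["sampling_rate_hz"])
        groups = None
        if "group" in f[sids[0]].attrs:
            groups = np.array([f[s].attrs["group"] for s in sids])
    return signals, sids, fs, groups


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(_jsonable(obj), indent=2, sort_keys=True) + "\n")
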