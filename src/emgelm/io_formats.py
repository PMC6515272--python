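"""Readers and writers: CSV recordings, MAT-file layouts, feature tables.

Three on-disk layouts produce the same :class:`~emgelm.synthetic.EmgRecording`
contract, so every downstream stage is layout-agnostic:

``csv``
    The package's own delimited-text format: one row per sample, columns
    ``ch1..chN``, ``stim_label``, optionally ``true_label``, ``repetition``.
``ninapro_mat``
    MATLAB MAT-file with fields ``emg`` (samples x channels),
    ``stimulus``/``restimulus`` (per-sample class ids) and ``repetition``.
``iee_mat``
    MAT-file with a configurable field map (default: NINAPro field names),
    for database exports whose field naming differs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import loadmat

from .features import FeatureTable
from .synthetic import EmgRecording

logger = logging.getLogger("emgelm")

_FLOAT_FMT = "%.17g"  # lossless float round-trip

DEFAULT_IEE_FIELD_MAP = {
    "emg": "emg",
    "stimulus": "stimulus",
    "repetition": "repetition",
}


@dataclass
class DatasetDescriptor:
    """Where and how to read a recording."""

    layout: str  # csv | ninapro_mat | iee_mat
    path: str
    channel_count: int | None = None
    label_field: str = "stimulus"  # or "restimulus" (NINAPro relabeled stream)
    subject: str | None = None
    assay: str | None = None
    trial: str | None = None
    field_map: dict = field(default_factory=lambda: dict(DEFAULT_IEE_FIELD_MAP))

    def __post_init__(self) -> None:
        if self.layout not in ("csv", "ninapro_mat", "iee_mat"):
            raise ValueError(f"unknown layout {self.layout!r}")
        if self.label_field not in ("stimulus", "restimulus"):
            raise ValueError(f"label_field must be stimulus|restimulus, got {self.label_field!r}")
        if self.channel_count is not None and self.channel_count < 1:
            raise ValueError("channel_count must be >= 1")


def write_recording_csv(recording: EmgRecording, path) -> None:
    """Write a recording to the package CSV format (one row = one sample)."""
    cols = {f"ch{c + 1}": recording.signal[c] for c in range(recording.n_channels)}
    cols["stim_label"] = recording.stim_labels
    if recording.true_labels is not None:
        cols["true_label"] = recording.true_labels
    if recording.repetition_ids is not None:
        cols["repetition"] = recording.repetition_ids
    pd.DataFrame(cols).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_recording_csv(path, sample_rate_hz: float = 2000.0) -> EmgRecording:
    df = pd.read_csv(path)
    ch_cols = [c for c in df.columns if c.startswith("ch")]
    if not ch_cols or "stim_label" not in df.columns:
        raise ValueError(f"{path}: not a recording CSV (need ch* and stim_label columns)")
    ch_cols.sort(key=lambda c: int(c[2:]))
    return EmgRecording(
        signal=df[ch_cols].to_numpy().T,
        sample_rate_hz=sample_rate_hz,
        stim_labels=df["stim_label"].to_numpy(),
        true_labels=df["true_label"].to_numpy() if "true_label" in df else None,
        repetition_ids=df["repetition"].to_numpy() if "repetition" in df else None,
    )


def _mat_field(mat: dict, name: str, path) -> np.ndarray:
    if name not in mat:
        raise ValueError(f"{path}: missing MAT field {name!r}")
    return np.asarray(mat[name])


def _load_mat_layout(descriptor: DatasetDescriptor, field_map: dict,
                     sample_rate_hz: float) -> EmgRecording:
    mat = loadmat(descriptor.path)
    emg = _mat_field(mat, field_map["emg"], descriptor.path).astype(float)
    if emg.ndim != 2:
        raise ValueError(f"{descriptor.path}: emg field must be 2-D")
    signal = emg.T  # MAT layouts store samples x channels
    labels = _mat_field(mat, field_map["stimulus"], descriptor.path).ravel()
    rep_name = field_map.get("repetition")
    if rep_name and rep_name in mat:
        reps = np.asarray(mat[rep_name]).ravel()
    else:
        warnings.warn(f"{descriptor.path}: no repetition field; assuming a single repetition")
        reps = np.ones(signal.shape[1], dtype=np.int64)
    if descriptor.channel_count is not None and signal.shape[0] != descriptor.channel_count:
        raise ValueError(
            f"{descriptor.path}: {signal.shape[0]} channels found, descriptor "
            f"declares {descriptor.channel_count}")
    return EmgRecording(signal=signal, sample_rate_hz=sample_rate_hz,
                        stim_labels=labels, repetition_ids=reps)


def load_recording(descriptor: DatasetDescriptor, sample_rate_hz: float = 2000.0) -> EmgRecording:
    """Load a recording in any supported layout."""
    if not Path(descriptor.path).exists():
        raise FileNotFoundError(descriptor.path)
    if descriptor.layout == "csv":
        rec = read_recording_csv(descriptor.path, sample_rate_hz)
        if descriptor.channel_count is not None and rec.n_channels != descriptor.channel_count:
            raise ValueError(
                f"{descriptor.path}: {rec.n_channels} channels found, descriptor "
                f"declares {descriptor.channel_count}")
        return rec
    if descriptor.layout == "ninapro_mat":
        fmap = {"emg": "emg", "stimulus": descriptor.label_field,
                "repetition": "repetition"}
        return _load_mat_layout(descriptor, fmap, sample_rate_hz)
    # iee_mat: user-configurable field names
    return _load_mat_layout(descriptor, descriptor.field_map, sample_rate_hz)


def write_features_csv(table: FeatureTable, path) -> None:
    table.to_frame().to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_features_csv(path) -> FeatureTable:
    df = pd.read_csv(path)
    meta_cols = [c for c in ("label", "window_start", "repetition") if c in df.columns]
    if "label" not in meta_cols or "window_start" not in meta_cols:
        raise ValueError(f"{path}: not a feature-table CSV")
    feat_cols = [c for c in df.columns if c not in meta_cols]
    return FeatureTable(
        X=df[feat_cols].to_numpy(),
        y=df["label"].to_numpy(),
        feature_names=feat_cols,
        window_starts=df["window_start"].to_numpy(),
        repetitions=df["repetition"].to_numpy() if "repetition" in df else None,
    )
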