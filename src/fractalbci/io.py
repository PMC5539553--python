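"""Epoch container, native file format, segmentation and preprocessing.

The native on-disk format is deliberately plain: one delimited numeric
matrix (channels x samples) per trial plus a single JSON metadata sidecar
per session holding the sampling rate, channel names, labels and task.
EDF recordings can be ingested read-only when ``mne`` is available.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence, Tuple, Union

import numpy as np
from scipy import signal as sps

logger = logging.getLogger(__name__)

__all__ = [
    "MONTAGE_30",
    "DEFAULT_EDF_EXCLUDE",
    "EpochSet",
    "RunConfig",
    "segment_resting",
    "bandpass",
    "write_epochset",
    "read_epochset",
    "select_montage_channels",
    "read_edf",
]

#: The 30 analysis channels of a 33-electrode 10-20 cap after excluding the
#: mastoid references (A1, A2) and the forehead ground.
MONTAGE_30: Tuple[str, ...] = (
    "FP1", "FP2", "F7", "F3", "Fz", "F4", "F8",
    "FT7", "FC3", "FCz", "FC4", "FT8",
    "T3", "C3", "Cz", "C4", "T4",
    "TP7", "CP3", "CPz", "CP4", "TP8",
    "T5", "P3", "Pz", "P4", "T6",
    "O1", "Oz", "O2",
)

DEFAULT_EDF_EXCLUDE: Tuple[str, ...] = ("A1", "A2", "GND", "EKG", "HEOG", "VEOG", "EOG")


@dataclass
class EpochSet:
    """Fixed-length multi-channel epochs with labels and channel names."""

    data: np.ndarray  # (n_trials, n_channels, n_samples)
    fs: float
    channel_names: Sequence[str]
    labels: np.ndarray  # (n_trials,)
    task: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.data.ndim != 3:
            raise ValueError("data must be (trials, channels, samples)")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if len(self.channel_names) != self.data.shape[1]:
            raise ValueError("channel_names length does not match data")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        if self.labels.shape != (self.data.shape[0],):
            raise ValueError("labels length does not match trial count")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def pick_channels(self, indices: Sequence[int]) -> "EpochSet":
        idx = list(indices)
        return EpochSet(data=self.data[:, idx, :], fs=self.fs,
                        channel_names=[self.channel_names[i] for i in idx],
                        labels=self.labels.copy(), task=self.task)

    def class_split(self) -> Tuple["EpochSet", "EpochSet"]:
        classes = np.unique(self.labels)
        if classes.size != 2:
            raise ValueError("expected a binary-labelled session")
        parts = []
        for c in classes:
            mask = self.labels == c
            parts.append(EpochSet(self.data[mask], self.fs, list(self.channel_names),
                                  self.labels[mask], self.task))
        return parts[0], parts[1]


@dataclass
class RunConfig:
    """Resolved analysis configuration with the study defaults.

    tau (samples) and epsilon drive the GPFD saturation loop; kmax the
    Higuchi fit; bands are (low, high) Hz pairs for band-power features.
    """

    tau: int = 50
    epsilon: float = 1e-3
    M_max: int = 50
    kmax: int = 100
    bands: Tuple[Tuple[float, float], ...] = (
        (8.0, 12.0), (12.0, 16.0), (16.0, 20.0), (20.0, 24.0), (24.0, 28.0))
    classifier: str = "knn"
    K: int = 1
    channel_policy: str = "all"
    seed: int = 0
    paths: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "bands" in raw:
            raw["bands"] = tuple(tuple(map(float, b)) for b in raw["bands"])
        return cls(**raw)

    def log_resolved(self) -> None:
        logger.info("resolved config: %s", asdict(self))


# ---------------------------------------------------------------------------
# segmentation and filtering
# ---------------------------------------------------------------------------

def segment_resting(x: np.ndarray, fs: float, epoch_seconds: float = 3.0,
                    overlap_seconds: float = 1.0,
                    max_epochs: Optional[int] = 40,
                    channel_names: Optional[Sequence[str]] = None) -> EpochSet:
    """Segment a continuous recording into overlapping fixed-length epochs.

    Windows advance by ``epoch_seconds - overlap_seconds`` so consecutive
    epochs share exactly ``overlap_seconds``; the earliest ``max_epochs``
    windows are kept (all of them when ``max_epochs`` is None).  A 90-s
    recording at the defaults yields 44 candidate windows, capped to 40.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if overlap_seconds >= epoch_seconds:
        raise ValueError("overlap must be shorter than the epoch")
    n_len = int(round(epoch_seconds * fs))
    step = int(round((epoch_seconds - overlap_seconds) * fs))
    if x.shape[1] < n_len:
        raise ValueError("recording shorter than one epoch")
    starts = range(0, x.shape[1] - n_len + 1, step)
    starts = list(starts) if max_epochs is None else list(starts)[:max_epochs]
    data = np.stack([x[:, s:s + n_len] for s in starts])
    names = list(channel_names) if channel_names is not None else [
        f"CH{i}" for i in range(x.shape[0])]
    return EpochSet(data=data, fs=fs, channel_names=names,
                    labels=np.zeros(len(starts), dtype=int), task="resting")


def bandpass(x: np.ndarray, fs: float, low: float = 0.5, high: float = 100.0,
             order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the last axis; removes DC."""
    if not 0 < low < high < fs / 2:
        raise ValueError("require 0 < low < high < fs/2")
    sos = sps.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(x, dtype=float), axis=-1)


# ---------------------------------------------------------------------------
# native format
# ---------------------------------------------------------------------------

def write_epochset(epochs: EpochSet, path: Union[str, Path]) -> None:
    """Write a session as per-trial delimited matrices + a JSON sidecar."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "fs": epochs.fs,
        "channel_names": list(epochs.channel_names),
        "labels": epochs.labels.tolist(),
        "task": epochs.task,
        "n_trials": epochs.n_trials,
        "n_samples": epochs.n_samples,
    }
    (path / "metadata.json").write_text(json.dumps(meta, indent=1))
    width = len(str(max(epochs.n_trials - 1, 1)))
    for i in range(epochs.n_trials):
        np.savetxt(path / f"trial_{i:0{width}d}.txt", epochs.data[i],
                   fmt="%.10e", delimiter="\t")


def read_epochset(path: Union[str, Path]) -> EpochSet:
    """Read a session written by :func:`write_epochset`."""
    path = Path(path)
    meta_path = path / "metadata.json"
    if not meta_path.exists():
        raise FileNotFoundError(f"metadata sidecar missing: {meta_path}")
    meta = json.loads(meta_path.read_text())
    for key in ("fs", "channel_names", "labels", "n_trials"):
        if key not in meta:
            raise KeyError(f"metadata sidecar missing required key: {key!r}")
    trials = sorted(path.glob("trial_*.txt"))
    if len(trials) != meta["n_trials"]:
        raise ValueError(
            f"expected {meta['n_trials']} trial files, found {len(trials)}")
    data = np.stack([np.atleast_2d(np.loadtxt(p, delimiter="\t")) for p in trials])
    if data.shape[1] != len(meta["channel_names"]):
        raise ValueError("trial matrices do not match the channel-name list")
    return EpochSet(data=data, fs=float(meta["fs"]),
                    channel_names=meta["channel_names"],
                    labels=np.asarray(meta["labels"], dtype=int),
                    task=meta.get("task", ""))


# ---------------------------------------------------------------------------
# optional EDF ingestion
# ---------------------------------------------------------------------------

def select_montage_channels(labels: Sequence[str],
                            exclude: Sequence[str] = DEFAULT_EDF_EXCLUDE) -> list:
    """Indices of analysis channels after dropping references/ground/EOG.

    Matching is case-insensitive on the trailing label part (EDF labels are
    often prefixed, e.g. ``EEG FP1-REF``).  Labels not recognized as 10-20
    names are retained verbatim with a warning.
    """
    excl = {e.upper() for e in exclude}
    montage = {m.upper() for m in MONTAGE_30}
    keep = []
    for i, raw in enumerate(labels):
        token = raw.upper().replace("EEG", "").strip().split("-")[0].strip()
        if token in excl:
            continue
        if token not in montage:
            logger.warning("channel label %r not in the 10-20 montage; retained", raw)
        keep.append(i)
    return keep


def read_edf(path: Union[str, Path],
             exclude: Sequence[str] = DEFAULT_EDF_EXCLUDE) -> Tuple[np.ndarray, float, list]:
    """Read a continuous EDF recording (requires ``mne``).

    Returns ``(data, fs, channel_names)`` with the reference/ground/EOG
    channels removed; segment with :func:`segment_resting` afterwards.
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise ImportError("EDF ingestion requires the optional 'mne' package") from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    keep = select_montage_channels(raw.ch_names, exclude=exclude)
    data = raw.get_data()[keep]
    names = [raw.ch_names[i].replace("EEG", "").strip().split("-")[0].strip()
             for i in keep]
    return data, float(raw.info["sfreq"]), names
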