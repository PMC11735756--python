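"""Epoch containers shared by the simulation, preprocessing and decoding stages.

An :class:`EpochSet` holds single-trial EEG epochs time-locked to the onset of
the fifth tone of a series, together with the per-trial global/local condition
labels and minimal channel metadata. A :class:`NormalizedEpochSet` additionally
carries the instantaneous global field power (GFP) used for normalisation and a
validity mask for time-points whose GFP was too small to divide by.

Containers are plain dataclasses over numpy arrays; persistence is HDF5 via
h5py with a JSON-compatible attribute set, as is conventional for epoch-level
EEG derivatives.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np

STANDARD = "standard"
DEVIANT = "deviant"
CONTRASTS = ("global", "local")


@dataclass
class EpochSet:
    """Trials x channels x samples voltage array with labels and geometry.

    Parameters
    ----------
    data
        Voltages in microvolts, shape ``(n_trials, n_channels, n_samples)``.
    times
        Time axis in seconds relative to fifth-tone onset, length
        ``n_samples``; spans ``[-0.1, 0.5)`` for the default epoch window.
    sfreq
        Sampling rate in Hz.
    labels_global, labels_local
        Per-trial condition labels, each entry ``"standard"`` or ``"deviant"``.
    block
        Per-trial block index (1-based), or zeros when unknown.
    chan_pos
        Optional ``(n_channels, 3)`` unit-sphere electrode coordinates.
    log
        Provenance log: one free-text entry per processing step.
    """

    data: np.ndarray
    times: np.ndarray
    sfreq: float
    labels_global: np.ndarray
    labels_local: np.ndarray
    block: np.ndarray | None = None
    chan_pos: np.ndarray | None = None
    log: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (n_trials, n_channels, n_samples)")
        self.times = np.asarray(self.times, dtype=float)
        self.labels_global = np.asarray(self.labels_global, dtype="U16")
        self.labels_local = np.asarray(self.labels_local, dtype="U16")
        if self.block is None:
            self.block = np.zeros(self.n_trials, dtype=int)
        else:
            self.block = np.asarray(self.block, dtype=int)
        n = self.n_trials
        if not (len(self.labels_global) == len(self.labels_local) == len(self.block) == n):
            raise ValueError("label/block lengths do not match n_trials")
        if len(self.times) != self.data.shape[2]:
            raise ValueError("times length does not match n_samples")

    # -- basic geometry -------------------------------------------------
    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def labels(self, contrast: str) -> np.ndarray:
        if contrast == "global":
            return self.labels_global
        if contrast == "local":
            return self.labels_local
        raise ValueError(f"unknown contrast {contrast!r}; expected one of {CONTRASTS}")

    def deviant_mask(self, contrast: str) -> np.ndarray:
        """Boolean per-trial mask, True where the trial is a deviant."""
        return self.labels(contrast) == DEVIANT

    def subset(self, idx: Sequence[int] | np.ndarray) -> "EpochSet":
        idx = np.asarray(idx)
        return EpochSet(
            data=self.data[idx],
            times=self.times.copy(),
            sfreq=self.sfreq,
            labels_global=self.labels_global[idx],
            labels_local=self.labels_local[idx],
            block=self.block[idx],
            chan_pos=None if self.chan_pos is None else self.chan_pos.copy(),
            log=list(self.log),
        )

    def copy(self) -> "EpochSet":
        out = self.subset(np.arange(self.n_trials))
        out.data = out.data.copy()
        return out

    def with_labels(self, contrast: str, labels: np.ndarray) -> "EpochSet":
        out = self.copy()
        labels = np.asarray(labels, dtype="U16")
        if contrast == "global":
            out.labels_global = labels
        elif contrast == "local":
            out.labels_local = labels
        else:
            raise ValueError(f"unknown contrast {contrast!r}")
        return out

    # -- persistence ----------------------------------------------------
    def save_h5(self, path: str | Path, seed: int | None = None) -> None:
        """Write the epoch set to an HDF5 file plus a JSON sidecar."""
        path = Path(path)
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=self.data)
            f.create_dataset("times", data=self.times)
            f.create_dataset("labels_global", data=self.labels_global.astype("S16"))
            f.create_dataset("labels_local", data=self.labels_local.astype("S16"))
            f.create_dataset("block", data=self.block)
            if self.chan_pos is not None:
                f.create_dataset("chan_pos", data=self.chan_pos)
            f.attrs["sfreq"] = float(self.sfreq)
            if seed is not None:
                f.attrs["seed"] = int(seed)
            f.attrs["log"] = json.dumps(self.log)
        sidecar = {"sfreq": float(self.sfreq), "n_trials": int(self.n_trials),
                   "n_channels": int(self.n_channels), "n_samples": int(self.n_samples)}
        if seed is not None:
            sidecar["seed"] = int(seed)
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def load_h5(cls, path: str | Path) -> "EpochSet":
        with h5py.File(path, "r") as f:
            return cls(
                data=f["data"][()],
                times=f["times"][()],
                sfreq=float(f.attrs["sfreq"]),
                labels_global=f["labels_global"][()].astype("U16"),
                labels_local=f["labels_local"][()].astype("U16"),
                block=f["block"][()],
                chan_pos=f["chan_pos"][()] if "chan_pos" in f else None,
                log=json.loads(f.attrs.get("log", "[]")),
            )


@dataclass
class NormalizedEpochSet:
    """GFP-normalised epochs: every unmasked topography has unit GFP.

    ``mask`` is True where the time-point is valid (GFP above threshold);
    masked points hold zeros and must be excluded from model fitting and
    scoring.
    """

    data: np.ndarray           # (n_trials, n_channels, n_samples), unit-GFP maps
    gfp: np.ndarray            # (n_trials, n_samples) original GFP
    mask: np.ndarray           # (n_trials, n_samples) bool, True = usable
    times: np.ndarray
    sfreq: float
    labels_global: np.ndarray
    labels_local: np.ndarray

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def labels(self, contrast: str) -> np.ndarray:
        if contrast == "global":
            return np.asarray(self.labels_global)
        if contrast == "local":
            return np.asarray(self.labels_local)
        raise ValueError(f"unknown contrast {contrast!r}")

    def deviant_mask(self, contrast: str) -> np.ndarray:
        return self.labels(contrast) == DEVIANT

    def subset(self, idx: Sequence[int] | np.ndarray) -> "NormalizedEpochSet":
        idx = np.asarray(idx)
        return NormalizedEpochSet(
            data=self.data[idx], gfp=self.gfp[idx], mask=self.mask[idx],
            times=self.times, sfreq=self.sfreq,
            labels_global=np.asarray(self.labels_global)[idx],
            labels_local=np.asarray(self.labels_local)[idx],
        )
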