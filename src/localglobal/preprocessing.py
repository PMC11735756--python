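"""Filtering, epoching, artifact handling and GFP normalisation.

The analysis band is 0.1-40 Hz, applied to continuous data with a zero-phase
FIR filter (Hamming window, transition bandwidths 0.1 Hz at the low edge and
10 Hz at the high edge), via MNE. Epochs span -100 to 500 ms (half-open)
around the fifth-tone onset. Cleaning is threshold based: persistently bad
channels are interpolated by inverse-distance weighting, remaining epochs with
any supra-threshold excursion are dropped. Independent-component artifact
removal is deliberately outside this module; externally cleaned continuous
data can enter through :func:`extract_epochs` unchanged.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.model_selection import train_test_split

from .epochs import EpochSet, NormalizedEpochSet

DEFAULT_BAND = (0.1, 40.0)
DEFAULT_EPOCH_WINDOW_MS = (-100.0, 500.0)


def bandpass(data: np.ndarray, sfreq: float, low: float = DEFAULT_BAND[0],
             high: float = DEFAULT_BAND[1]) -> np.ndarray:
    """Zero-phase FIR band-pass of continuous data, shape (..., n_samples).

    DC is removed by the high-pass edge; passband gain is ~1. The fixed
    transition bandwidths (0.1 Hz low, 10 Hz high) imply a filter length of
    ~33 s of data at the low edge, so the input must be continuous data, not
    epochs.
    """
    if not (0 < low < high < sfreq / 2):
        raise ValueError(
            f"invalid band ({low}, {high}) Hz for sfreq {sfreq} Hz: need "
            "0 < low < high < Nyquist")
    import mne

    out = mne.filter.filter_data(
        np.asarray(data, dtype=np.float64), sfreq, l_freq=low, h_freq=high,
        l_trans_bandwidth=0.1, h_trans_bandwidth=10.0,
        fir_design="firwin", fir_window="hamming", phase="zero", verbose="error")
    return out


def read_continuous_edf(path, events_tsv=None):
    """Optional reader: continuous EEG from a European Data Format file and,
    if given, a BIDS-style events table (columns incl. onset, global_label,
    local_label). Returns (data, sfreq, events_dataframe_or_None)."""
    import mne
    import pandas as pd

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    events = pd.read_csv(events_tsv, sep="\t") if events_tsv is not None else None
    return raw.get_data() * 1e6, raw.info["sfreq"], events  # volts -> microvolts


def extract_epochs(continuous: np.ndarray, sfreq: float, event_times: np.ndarray,
                   labels_global: np.ndarray, labels_local: np.ndarray,
                   window_ms: tuple[float, float] = DEFAULT_EPOCH_WINDOW_MS,
                   block: np.ndarray | None = None,
                   chan_pos: np.ndarray | None = None) -> tuple[EpochSet, int]:
    """Cut epochs around fifth-tone onsets from a (channels, samples) array.

    The window is half-open: ``round(0.6 * sfreq)`` samples for the default
    [-100, 500) ms window. Events whose window would run past either edge of
    the recording are dropped with a warning; the second return value is the
    number dropped.
    """
    continuous = np.asarray(continuous, dtype=float)
    if continuous.ndim != 2:
        raise ValueError("continuous data must be (n_channels, n_samples)")
    w0, w1 = window_ms
    offset = int(round(w0 / 1000.0 * sfreq))
    n_samp = int(round((w1 - w0) / 1000.0 * sfreq))
    times = w0 / 1000.0 + np.arange(n_samp) / sfreq

    event_times = np.asarray(event_times, dtype=float)
    starts = np.round(event_times * sfreq).astype(int) + offset
    ok = (starts >= 0) & (starts + n_samp <= continuous.shape[1])
    n_dropped = int(np.sum(~ok))
    if n_dropped:
        warnings.warn(f"extract_epochs: dropped {n_dropped} event(s) too close "
                      "to the recording edge")
    kept = np.where(ok)[0]
    data = np.stack([continuous[:, s:s + n_samp] for s in starts[kept]]) \
        if len(kept) else np.empty((0, continuous.shape[0], n_samp))
    epochs = EpochSet(
        data=data, times=times, sfreq=sfreq,
        labels_global=np.asarray(labels_global)[kept],
        labels_local=np.asarray(labels_local)[kept],
        block=None if block is None else np.asarray(block)[kept],
        chan_pos=chan_pos,
        log=[f"extract_epochs(window_ms={window_ms}, dropped={n_dropped})"])
    return epochs, n_dropped


def baseline_correct(epochs: EpochSet, baseline_ms: tuple[float, float] = (-100.0, 0.0)
                     ) -> EpochSet:
    """Subtract the per-epoch, per-channel mean of the baseline interval."""
    t0, t1 = (b / 1000.0 for b in baseline_ms)
    sel = (epochs.times >= t0) & (epochs.times < t1)
    if not np.any(sel):
        raise ValueError("baseline interval contains no samples")
    out = epochs.copy()
    out.data = out.data - out.data[:, :, sel].mean(axis=2, keepdims=True)
    out.log.append(f"baseline_correct({baseline_ms})")
    return out


def reject_and_interpolate(epochs: EpochSet, amp_thresh: float = 100.0,
                           bad_channel_frac: float = 0.2
                           ) -> tuple[EpochSet, dict]:
    """Threshold-based cleaning.

    A channel exceeding ``amp_thresh`` (absolute microvolts) in more than
    ``bad_channel_frac`` of the epochs is replaced by the inverse-distance
    weighted average of the remaining channels (requires channel positions).
    Afterwards any epoch still containing a supra-threshold excursion is
    dropped. Raises if nothing survives.
    """
    if amp_thresh <= 0 or bad_channel_frac <= 0:
        raise ValueError("thresholds must be > 0")
    out = epochs.copy()
    exceed = np.abs(out.data) > amp_thresh              # (trials, ch, samples)
    frac_bad = exceed.any(axis=2).mean(axis=0)          # per channel
    bad_channels = np.where(frac_bad > bad_channel_frac)[0]

    if len(bad_channels):
        if out.chan_pos is None:
            raise ValueError("channel interpolation requires channel positions")
        good = np.setdiff1d(np.arange(out.n_channels), bad_channels)
        if len(good) == 0:
            raise ValueError("all channels flagged bad; review thresholds")
        for ch in bad_channels:
            d = np.linalg.norm(out.chan_pos[good] - out.chan_pos[ch], axis=1)
            w = 1.0 / np.maximum(d, 1e-6)
            w = w / w.sum()
            out.data[:, ch, :] = np.einsum("g,tgs->ts", w, out.data[:, good, :])

    exceed = np.abs(out.data) > amp_thresh
    drop = exceed.any(axis=(1, 2))
    n_dropped = int(drop.sum())
    if n_dropped == out.n_trials:
        raise ValueError(
            "all epochs exceed the rejection threshold; review amp_thresh")
    kept_idx = np.where(~drop)[0]
    cleaned = out.subset(kept_idx)
    cleaned.data = cleaned.data.copy()
    report = {
        "n_input": int(epochs.n_trials),
        "n_retained": int(cleaned.n_trials),
        "n_dropped": n_dropped,
        "dropped_epochs": [int(i) for i in np.where(drop)[0]],
        "interpolated_channels": [int(c) for c in bad_channels],
        "amp_thresh": float(amp_thresh),
        "bad_channel_frac": float(bad_channel_frac),
    }
    cleaned.log.append(f"reject_and_interpolate: {report}")
    return cleaned, report


def gfp_normalize(epochs: EpochSet, eps: float = 1e-8) -> NormalizedEpochSet:
    """Normalise every instantaneous topography by its global field power.

    The GFP of a topography is the standard deviation across channels of the
    average-referenced potentials (Lehmann-Skrandies). Time-points with GFP
    below ``eps`` are masked (set to zero, flagged invalid) rather than
    divided.
    """
    if epochs.n_channels < 2:
        raise ValueError("GFP requires at least 2 channels")
    ref = epochs.data - epochs.data.mean(axis=1, keepdims=True)
    gfp = ref.std(axis=1)                               # (trials, samples), ddof=0
    mask = gfp > eps
    safe = np.where(mask[:, None, :], gfp[:, None, :], 1.0)
    norm = np.where(mask[:, None, :], ref / safe, 0.0)
    return NormalizedEpochSet(
        data=norm, gfp=gfp, mask=mask, times=epochs.times, sfreq=epochs.sfreq,
        labels_global=epochs.labels_global, labels_local=epochs.labels_local)


def split_cv_test(epochs: EpochSet, contrast: str = "global", cv_frac: float = 0.8,
                  seed: int = 0) -> tuple[EpochSet, EpochSet]:
    """Stratified split into cross-validation (default 80%) and test (20%)
    partitions; class proportions preserved within one trial, disjoint,
    deterministic given ``seed``."""
    labels = epochs.labels(contrast)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both classes must be present to split")
    if counts.min() < 5:
        raise ValueError(
            f"class {classes[counts.argmin()]!r} has only {counts.min()} trials; "
            "need at least 5 per class")
    idx = np.arange(epochs.n_trials)
    cv_idx, test_idx = train_test_split(
        idx, train_size=cv_frac, stratify=labels, random_state=seed % (2**32 - 1))
    return epochs.subset(np.sort(cv_idx)), epochs.subset(np.sort(test_idx))
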