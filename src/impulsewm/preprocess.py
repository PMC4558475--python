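"""Epoch-level preprocessing: baseline correction, channel selection,
temporal smoothing, impulse-locked re-epoching, and an optional
amplitude-based artifact flag.

All operations are trial-count- and metadata-preserving and return new
:class:`~impulsewm.epochs.EpochSet` objects.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .epochs import EpochSet, SAMPLE_STEP_MS, round_to_sample_grid

__all__ = [
    "POSTERIOR_17",
    "baseline_correct",
    "smooth_gaussian",
    "reepoch_impulse",
    "select_channels",
    "flag_artifacts",
]

#: The 17 posterior channels used in all analyses.
POSTERIOR_17 = (
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO7", "PO3", "POz", "PO4", "PO8",
    "O1", "Oz", "O2",
)


def baseline_correct(
    epochs: EpochSet, window_ms: tuple[float, float] = (-200.0, 0.0)
) -> EpochSet:
    """Subtract, per trial and channel, the mean over the baseline window.

    The window is half-open ``[start, stop)`` so the default
    ``(-200, 0)`` excludes the stimulus-onset sample.
    """
    start, stop = window_ms
    if stop <= start:
        raise ValueError("baseline window must have stop > start")
    mask = (epochs.time_ms >= start - 1e-9) & (epochs.time_ms < stop - 1e-9)
    if not mask.any():
        raise ValueError(
            f"baseline window [{start}, {stop}) outside epoch "
            f"[{epochs.time_ms[0]}, {epochs.time_ms[-1]}]"
        )
    baseline = epochs.data[:, :, mask].mean(axis=2, keepdims=True)
    return replace(epochs, data=epochs.data - baseline)


def smooth_gaussian(epochs: EpochSet, sd_ms: float = 8.0) -> EpochSet:
    """Convolve every channel trace with a unit-sum Gaussian along time.

    Kernel SD defaults to 8 ms (2 samples at 250 Hz); support is truncated
    at ±4 SD and edges are handled by reflection, so constant traces pass
    through unchanged.
    """
    if sd_ms <= 0:
        raise ValueError("sd_ms must be > 0")
    sd_samples = sd_ms / SAMPLE_STEP_MS
    data = gaussian_filter1d(epochs.data, sigma=sd_samples, axis=2, mode="reflect", truncate=4.0)
    return replace(epochs, data=data)


def reepoch_impulse(
    long_epochs: EpochSet,
    window_ms: tuple[float, float] = (-200.0, 1400.0),
    onset_column: str = "impulse_onset_ms",
) -> EpochSet:
    """Re-zero each long trial's time axis at its own impulse onset.

    Onsets off the 4 ms sample grid are aligned to the nearest sample
    (halves away from zero). The output spans ``window_ms`` relative to
    the per-trial onset; every trial must provide full coverage.
    """
    trials = long_epochs.trials
    if onset_column not in trials.columns:
        raise ValueError(f"trial table lacks {onset_column!r}")
    onsets = trials[onset_column].to_numpy(dtype=float)
    if np.isnan(onsets).any() or (trials["trial_type"] == "short").any():
        raise ValueError("short trials (no impulse onset) present; select long trials first")

    lo, hi = window_ms
    n_out = int(round((hi - lo) / SAMPLE_STEP_MS)) + 1
    new_time = lo + SAMPLE_STEP_MS * np.arange(n_out)
    out = np.empty((long_epochs.n_trials, long_epochs.n_channels, n_out))
    for i, onset in enumerate(onsets):
        onset_snap = round_to_sample_grid(onset)
        start = long_epochs.time_index(round_to_sample_grid(onset_snap + lo))
        if start + n_out > long_epochs.n_times:
            raise ValueError(
                f"trial {trials['trial_id'].iloc[i]}: epoch does not cover "
                f"{onset_snap + hi} ms"
            )
        out[i] = long_epochs.data[i, :, start : start + n_out]
    return replace(long_epochs, data=out, time_ms=new_time)


def select_channels(epochs: EpochSet, names=POSTERIOR_17) -> EpochSet:
    """Channel subset in the requested order (not the input order)."""
    names = list(names)
    if not names:
        raise ValueError("empty channel selection")
    lookup = {c: i for i, c in enumerate(epochs.channel_names)}
    missing = [c for c in names if c not in lookup]
    if missing:
        raise KeyError(f"unknown channels: {missing}")
    idx = [lookup[c] for c in names]
    return replace(epochs, data=epochs.data[:, idx, :], channel_names=names)


def flag_artifacts(epochs: EpochSet, peak_to_peak_uv: float = 150.0) -> EpochSet:
    """Flag (never drop) trials whose peak-to-peak amplitude on any channel
    exceeds ``peak_to_peak_uv``; adds a boolean ``artifact`` column.

    A coarse stand-in for trial screening; off by default in the pipeline.
    """
    ptp = epochs.data.max(axis=2) - epochs.data.min(axis=2)
    flagged = (ptp > peak_to_peak_uv).any(axis=1)
    trials = epochs.trials.copy()
    trials["artifact"] = flagged
    return replace(epochs, trials=trials)
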