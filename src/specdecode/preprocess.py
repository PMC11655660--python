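"""Epoch-level cleaning: peak-to-peak rejection, evoked-potential
subtraction, and analysis-window cropping.

Windows are half-open ``[start, end)`` on the sample grid, with sample ``i``
at time ``t0 + i/fs``, so sample counts are unambiguous: cropping a 200 Hz
epoch to 0.3-1.5 s always yields 240 samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ConfigurationError, EpochSet


@dataclass
class RejectionThresholds:
    """Peak-to-peak rejection thresholds per channel kind.

    Defaults follow common M/EEG practice: 350 uV for EEG, 5000 fT for
    magnetometers and 4000 fT/cm for gradiometers (expressed in SI units:
    V, T and T/m).
    """

    eeg: float = 350e-6
    magnetometer: float = 5000e-15
    gradiometer: float = 4000e-13  # 4000 fT/cm == 4e-10 T/m

    def __post_init__(self) -> None:
        if min(self.eeg, self.magnetometer, self.gradiometer) <= 0:
            raise ValueError("rejection thresholds must be strictly positive")

    def for_kind(self, kind: str) -> float:
        try:
            return getattr(self, kind)
        except AttributeError:
            raise ConfigurationError(f"no rejection threshold for channel kind {kind!r}")


def reject_epochs(
    epochs: EpochSet, thresholds: RejectionThresholds
) -> tuple[EpochSet, pd.DataFrame]:
    """Drop every epoch in which any channel's peak-to-peak amplitude
    exceeds its kind's threshold.

    Returns the surviving epochs and a report table with one row per
    offending (epoch, channel) pair: columns ``epoch, channel, ptp,
    threshold``.  Applying the same thresholds twice drops nothing on the
    second pass.
    """
    kinds = list(epochs.channels["kind"])
    thr = np.array([thresholds.for_kind(k) for k in kinds])
    ptp = epochs.data.max(axis=2) - epochs.data.min(axis=2)  # epochs x channels
    offending = ptp > thr[None, :]
    rows = []
    ep_idx, ch_idx = np.nonzero(offending)
    for e, c in zip(ep_idx, ch_idx):
        rows.append(
            {
                "epoch": int(e),
                "channel": epochs.channels["name"].iloc[c],
                "ptp": float(ptp[e, c]),
                "threshold": float(thr[c]),
            }
        )
    report = pd.DataFrame(rows, columns=["epoch", "channel", "ptp", "threshold"])
    keep = ~offending.any(axis=1)
    return epochs.select(keep), report


def subtract_evoked(epochs: EpochSet) -> EpochSet:
    """Remove phase-locked activity: within each (subject, task, content,
    demand) cell, subtract the cell-mean timeseries from every trial.

    Non-phase-locked (induced) oscillations survive because their random
    phases cancel in the cell mean; evoked transients, identical across
    trials, are removed.  Raises if any cell holds a single epoch, since
    subtraction would zero that trial.
    """
    residual = epochs.data.copy()
    for key, idx in epochs.condition_cells():
        if len(idx) < 2:
            raise ValueError(f"condition cell {key} has a single epoch; cannot subtract its mean")
        residual[idx] -= residual[idx].mean(axis=0, keepdims=True)
    return EpochSet(
        data=residual, fs=epochs.fs, t0=epochs.t0, channels=epochs.channels, labels=epochs.labels
    )


def crop_window(epochs: EpochSet, start: float, end: float) -> EpochSet:
    """Restrict each epoch to the half-open window [start, end) seconds.

    ``start``/``end`` are relative to stimulus onset and must lie within the
    epoch; the output ``t0`` is the time of the first retained sample.
    """
    eps = 1e-9
    t_end = epochs.t0 + epochs.n_samples / epochs.fs
    if start >= end:
        raise ValueError("window start must precede end")
    if start < epochs.t0 - eps or end > t_end + eps:
        raise ValueError(
            f"window [{start}, {end}) outside epoch [{epochs.t0}, {t_end})"
        )
    i0 = int(np.ceil((start - epochs.t0) * epochs.fs - eps))
    i1 = int(np.ceil((end - epochs.t0) * epochs.fs - eps))
    i0, i1 = max(i0, 0), min(i1, epochs.n_samples)
    return EpochSet(
        data=epochs.data[:, :, i0:i1],
        fs=epochs.fs,
        t0=epochs.t0 + i0 / epochs.fs,
        channels=epochs.channels,
        labels=epochs.labels,
    )
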