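"""Core data containers shared by every pipeline stage.

The universal input is an :class:`EpochSet`: a labelled
``epochs x channels x samples`` tensor with its sampling rate, epoch timing
and per-channel metadata.  Downstream stages exchange per-trial feature
matrices (:class:`SignalFeatures`) for one of the six spectral signals
(aperiodic broadband power, slope, intercept; theta, alpha, beta band power).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

TASKS = ("WM", "SWIT", "MSIT")
CONTENTS = ("alphanumeric", "colour")
DEMANDS = ("easy", "hard")
CHANNEL_KINDS = ("eeg", "magnetometer", "gradiometer")
SIGNALS = ("bb_power", "slope", "intercept", "theta", "alpha", "beta")

#: nominal per-kind signal scale and unit; arbitrary constants recorded in
#: metadata so that downstream standardization has real work to do.
KIND_UNITS = {"eeg": "V", "magnetometer": "T", "gradiometer": "T/m"}
KIND_SCALES = {"eeg": 20e-6, "magnetometer": 300e-15, "gradiometer": 1e-11}

LABEL_COLUMNS = ("subject", "task", "content", "demand", "trial")


class ConfigurationError(ValueError):
    """A configuration value is missing or inconsistent."""


def make_channel_table(kinds: list[str], names: list[str] | None = None) -> pd.DataFrame:
    """Build the channel metadata table from a list of channel kinds."""
    for k in kinds:
        if k not in CHANNEL_KINDS:
            raise ConfigurationError(f"unknown channel kind {k!r}")
    if names is None:
        names = [f"{k.upper()[:3]}{i:03d}" for i, k in enumerate(kinds)]
    return pd.DataFrame(
        {"name": names, "kind": kinds, "unit": [KIND_UNITS[k] for k in kinds]}
    )


@dataclass
class EpochSet:
    """Labelled epoched multichannel recording.

    Parameters
    ----------
    data : ndarray, shape (n_epochs, n_channels, n_samples)
        Signal values, in each channel's physical unit.
    fs : float
        Sampling rate in Hz.
    t0 : float
        Time of the first sample in seconds relative to stimulus onset.
    channels : DataFrame with columns ``name, kind, unit``.
    labels : DataFrame with columns ``subject, task, content, demand, trial``,
        one row per epoch; ``task``/``content``/``demand`` are drawn from the
        closed vocabularies in this module.
    """

    data: np.ndarray
    fs: float
    t0: float
    channels: pd.DataFrame
    labels: pd.DataFrame

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be epochs x channels x samples")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if len(self.channels) != self.data.shape[1]:
            raise ValueError("channel table does not match data")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("label table does not match data")
        for col, vocab in (("task", TASKS), ("content", CONTENTS), ("demand", DEMANDS)):
            bad = set(self.labels[col]) - set(vocab)
            if bad:
                raise ValueError(f"unknown {col} labels: {sorted(bad)}")
        self.labels = self.labels.reset_index(drop=True)

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds relative to stimulus onset."""
        return self.t0 + np.arange(self.n_samples) / self.fs

    def select(self, mask: np.ndarray) -> "EpochSet":
        """Return a new EpochSet restricted to the epochs where mask is True."""
        mask = np.asarray(mask)
        return EpochSet(
            data=self.data[mask],
            fs=self.fs,
            t0=self.t0,
            channels=self.channels,
            labels=self.labels.loc[np.asarray(mask)].reset_index(drop=True),
        )

    def condition_cells(self):
        """Iterate over ``(key, row_indices)`` for each labelled
        (subject, task, content, demand) cell."""
        grouped = self.labels.groupby(
            ["subject", "task", "content", "demand"], sort=True, observed=True
        )
        for key, idx in grouped.groups.items():
            yield key, np.asarray(idx)

    # ------------------------------------------------------------------ I/O
    def save(self, directory: str | Path) -> None:
        """Write the container: ``data.npy`` plus a JSON sidecar with fs,
        epoch timing, channel table and label table."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.save(directory / "data.npy", self.data)
        sidecar = {
            "fs": self.fs,
            "t0": self.t0,
            "channels": self.channels.to_dict(orient="list"),
            "labels": self.labels.to_dict(orient="list"),
        }
        (directory / "meta.json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def load(cls, directory: str | Path) -> "EpochSet":
        directory = Path(directory)
        meta = json.loads((directory / "meta.json").read_text())
        return cls(
            data=np.load(directory / "data.npy"),
            fs=meta["fs"],
            t0=meta["t0"],
            channels=pd.DataFrame(meta["channels"]),
            labels=pd.DataFrame(meta["labels"]),
        )

    def to_mne(self):
        """Export to an :class:`mne.EpochsArray` (requires the optional
        ``mne`` dependency)."""
        import mne

        kind_to_mne = {"eeg": "eeg", "magnetometer": "mag", "gradiometer": "grad"}
        info = mne.create_info(
            list(self.channels["name"]),
            sfreq=self.fs,
            ch_types=[kind_to_mne[k] for k in self.channels["kind"]],
        )
        return mne.EpochsArray(self.data, info, tmin=self.t0, verbose="error")


@dataclass
class SignalFeatures:
    """Observations x features matrix for one spectral signal.

    ``matrix`` rows are trials (or pseudo-trials), columns are channels or
    ROIs named by ``feature_ids``; ``labels`` carries one condition record
    per row.
    """

    signal: str
    matrix: np.ndarray
    feature_ids: list[str]
    labels: pd.DataFrame

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.signal not in SIGNALS:
            raise ValueError(f"unknown signal {self.signal!r}")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("feature matrix contains non-finite entries")
        if self.matrix.shape[0] != len(self.labels):
            raise ValueError("labels do not match matrix rows")
        if self.matrix.shape[1] != len(self.feature_ids):
            raise ValueError("feature_ids do not match matrix columns")

    def select(self, mask: np.ndarray) -> "SignalFeatures":
        mask = np.asarray(mask)
        return SignalFeatures(
            signal=self.signal,
            matrix=self.matrix[mask],
            feature_ids=list(self.feature_ids),
            labels=self.labels.loc[mask].reset_index(drop=True),
        )


@dataclass
class FeatureSet:
    """All six per-trial spectral signals extracted from one EpochSet."""

    values: dict[str, np.ndarray]  # signal -> (n_epochs, n_channels)
    labels: pd.DataFrame
    feature_ids: list[str] = field(default_factory=list)

    def signal(self, name: str, mask: np.ndarray | None = None) -> SignalFeatures:
        """Return one signal as a :class:`SignalFeatures`, optionally
        restricted to the epochs selected by ``mask``."""
        sf = SignalFeatures(
            signal=name,
            matrix=self.values[name],
            feature_ids=list(self.feature_ids),
            labels=self.labels,
        )
        return sf if mask is None else sf.select(mask)

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format table: one (epoch, channel, signal) value per row."""
        frames = []
        for sig, mat in self.values.items():
            df = self.labels.copy()
            wide = pd.DataFrame(mat, columns=self.feature_ids)
            long = pd.concat([df, wide], axis=1).melt(
                id_vars=list(df.columns), var_name="channel", value_name="value"
            )
            long.insert(len(df.columns), "signal", sig)
            frames.append(long)
        return pd.concat(frames, ignore_index=True)
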