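"""Irregular-resampling auto-spectral analysis (IRASA).

IRASA separates a mixed power spectrum into an aperiodic (1/f-like) and an
oscillatory component.  For each resampling factor h the signal is
resampled up by h and down by h (Fourier method); a power-law spectrum is
invariant under the geometric mean of the two branch spectra, while
narrow-band peaks are displaced to f*h and f/h and therefore suppressed by
the median (or mean) across the h set.  Subtracting the aperiodic estimate
from the mixed spectrum leaves the oscillatory component, which may be
negative where the mixed spectrum dips below the aperiodic fit.

Six per-trial features are derived from the separated spectra: aperiodic
broadband power (mean over 3-30 Hz), the slope and intercept of a log-log
straight-line fit to the aperiodic spectrum, and mean oscillatory power in
the theta (3-7 Hz), alpha (8-12 Hz) and beta (15-30 Hz) bands.  The gap at
13-14 Hz between alpha and beta is deliberate and preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .containers import ConfigurationError, EpochSet, FeatureSet, SIGNALS


def frequency_bound(fs: float, h_max: float) -> float:
    """Highest frequency at which the aperiodic spectrum is estimable.

    The down-sampled branch for factor ``h`` has an effective Nyquist of
    ``fs / (2 h)``, so the bound for the whole h set is ``fs / (2 h_max)``.
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    if h_max < 1:
        raise ValueError("h_max must be >= 1")
    return fs / (2.0 * h_max)


def _default_h_set() -> np.ndarray:
    # 1.10 to 1.90 in steps of 0.05
    return np.round(np.arange(22, 39) * 0.05, 2)


@dataclass
class IrasaConfig:
    """Configuration of the separation and feature extraction.

    Defaults: h from 1.10 to 1.90 in steps of 0.05, a 1-30 Hz grid with
    1 Hz spacing, straight-line aperiodic fit and broadband average over
    3-30 Hz, Hann-tapered modified periodogram, log base 10, median
    aggregation across h (switchable to mean).
    """

    h_set: np.ndarray = field(default_factory=_default_h_set)
    freq_grid: np.ndarray = field(default_factory=lambda: np.arange(1.0, 31.0))
    fit_range: tuple = (3.0, 30.0)
    bands: dict = field(
        default_factory=lambda: {"theta": (3.0, 7.0), "alpha": (8.0, 12.0), "beta": (15.0, 30.0)}
    )
    broadband_range: tuple = (3.0, 30.0)
    psd_window: str = "hann"
    log_base: float = 10.0
    h_aggregate: str = "median"  # or "mean"

    def __post_init__(self) -> None:
        self.h_set = np.asarray(self.h_set, dtype=float)
        self.freq_grid = np.asarray(self.freq_grid, dtype=float)
        if self.h_set.size == 0 or np.any(self.h_set <= 1):
            raise ConfigurationError("all resampling factors h must be > 1")
        if np.any(np.diff(self.h_set) <= 0):
            raise ConfigurationError("h_set must be strictly increasing")
        if np.any(np.diff(self.freq_grid) <= 0):
            raise ConfigurationError("freq_grid must be strictly increasing")
        span = (self.freq_grid[0], self.freq_grid[-1])
        for name, (lo, hi) in {**self.bands, "broadband": self.broadband_range,
                               "fit_range": self.fit_range}.items():
            if lo >= hi or lo < span[0] or hi > span[1]:
                raise ConfigurationError(f"band {name!r} outside the frequency grid")
        if self.h_aggregate not in ("median", "mean"):
            raise ConfigurationError("h_aggregate must be 'median' or 'mean'")

    def validate_for_fs(self, fs: float) -> None:
        bound = frequency_bound(fs, float(self.h_set.max()))
        if self.freq_grid[-1] > bound:
            raise ConfigurationError(
                f"frequency grid extends to {self.freq_grid[-1]:g} Hz but only "
                f"{bound:g} Hz is estimable at fs={fs:g} with h_max={self.h_set.max():g}"
            )


@dataclass
class SpectralFrame:
    """Mixed, aperiodic and oscillatory power on a fixed frequency grid.

    Arrays have shape ``(..., n_freqs)``; the leading axes index epochs and
    channels.  ``oscillatory == mixed - aperiodic`` elementwise.
    """

    freqs: np.ndarray
    mixed: np.ndarray
    aperiodic: np.ndarray

    @property
    def oscillatory(self) -> np.ndarray:
        return self.mixed - self.aperiodic


@dataclass
class AperiodicFit:
    """Straight-line fit to the aperiodic spectrum in log-log coordinates.

    ``slope`` is d(log P)/d(log f); ``intercept`` the fitted log-power at
    1 Hz (log f = 0).  Fields are arrays matching the input's leading axes.
    """

    slope: np.ndarray
    intercept: np.ndarray
    rss: np.ndarray


def _interp_onto_grid(freqs: np.ndarray, power: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Linear interpolation of ``power`` (..., len(freqs)) onto ``grid``."""
    idx = np.searchsorted(freqs, grid)
    idx = np.clip(idx, 1, len(freqs) - 1)
    f0, f1 = freqs[idx - 1], freqs[idx]
    w = (grid - f0) / (f1 - f0)
    return power[..., idx - 1] * (1 - w) + power[..., idx] * w


def compute_psd(
    x: np.ndarray, fs: float, freq_grid: np.ndarray, window: str = "hann"
) -> np.ndarray:
    """Hann-tapered modified periodogram evaluated on ``freq_grid``.

    ``x`` may have any leading shape; the last axis is time.  Power is a
    density (units^2/Hz), linearly interpolated from the native FFT grid
    onto the requested one.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[-1] == 0:
        raise ValueError("empty series")
    # zero-pad so the native FFT grid contains the requested frequencies
    # whenever they are commensurate with fs (e.g. an integer grid at an
    # integer rate): evaluation is then exact trigonometric interpolation
    # rather than linear interpolation of noisy neighbouring bins
    n = x.shape[-1]
    nfft = n
    if abs(fs - round(fs)) < 1e-9:
        step = int(round(fs))
        nfft = int(np.ceil(n / step)) * step
    freqs, p = sps.periodogram(x, fs=fs, window=window, nfft=nfft, axis=-1)
    return _interp_onto_grid(freqs, p, np.asarray(freq_grid, dtype=float))


def separate(x: np.ndarray, fs: float, config: IrasaConfig) -> SpectralFrame:
    """Separate the spectra of ``x`` (..., n_samples) into aperiodic and
    oscillatory components on ``config.freq_grid``.

    Resampling uses the Fourier method (:func:`scipy.signal.resample`) with
    branch lengths ``round(n*h)`` and ``round(n/h)``; branch spectra are
    geometric-mean combined per h and aggregated across the h set by the
    configured statistic.
    """
    config.validate_for_fs(fs)
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    if n < 2:
        raise ValueError("series too short to resample")
    lead = x.shape[:-1]
    x2 = x.reshape(-1, n)
    grid = config.freq_grid

    mixed = compute_psd(x2, fs, grid, config.psd_window)
    branches = np.empty((len(config.h_set),) + mixed.shape)
    for i, h in enumerate(config.h_set):
        n_up = int(round(n * h))
        n_dn = int(round(n / h))
        # Resampled series are deliberately (re)interpreted at the original
        # rate: upsampling by h then compresses spectral content to f/h and
        # downsampling stretches it to f*h, so a power law is invariant
        # under the geometric mean of the two branch spectra while
        # narrow-band peaks are displaced and later removed by the median.
        xu = sps.resample(x2, n_up, axis=-1)
        xd = sps.resample(x2, n_dn, axis=-1)
        pu = compute_psd(xu, fs, grid, config.psd_window)
        pd_ = compute_psd(xd, fs, grid, config.psd_window)
        # 4/pi debias: each branch is the geometric mean of two single-taper
        # estimates whose bin values are ~chi^2_2; E[sqrt(X)]^2 = pi/4, so
        # the raw geometric mean underestimates the spectrum by that factor
        branches[i] = (4.0 / np.pi) * np.sqrt(pu * pd_)
    if config.h_aggregate == "median":
        aperiodic = np.median(branches, axis=0)
    else:
        aperiodic = branches.mean(axis=0)
    return SpectralFrame(
        freqs=grid,
        mixed=mixed.reshape(lead + grid.shape),
        aperiodic=aperiodic.reshape(lead + grid.shape),
    )


def fit_aperiodic(
    aperiodic: np.ndarray,
    freqs: np.ndarray,
    fit_range: tuple = (3.0, 30.0),
    log_base: float = 10.0,
) -> AperiodicFit:
    """Ordinary least squares of log(power) on log(frequency).

    ``aperiodic`` has shape (..., n_freqs); the fit uses the grid points
    inside ``fit_range`` (inclusive) and requires strictly positive power
    there.
    """
    freqs = np.asarray(freqs, dtype=float)
    sel = (freqs >= fit_range[0]) & (freqs <= fit_range[1])
    if sel.sum() < 3:
        raise ValueError("need at least 3 grid points inside fit_range")
    p = np.asarray(aperiodic, dtype=float)[..., sel]
    f = freqs[sel]
    if np.any(p <= 0):
        bad = np.unique(np.broadcast_to(f, p.shape)[p <= 0])
        raise ValueError(
            f"aperiodic power must be positive in the fit range; offending "
            f"frequencies: {bad.tolist()}"
        )
    lf = np.log(f) / np.log(log_base)
    lp = np.log(p) / np.log(log_base)
    lf_c = lf - lf.mean()
    slope = (lp * lf_c).sum(axis=-1) / (lf_c**2).sum()
    intercept = lp.mean(axis=-1) - slope * lf.mean()
    resid = lp - (intercept[..., None] + slope[..., None] * lf)
    return AperiodicFit(slope=slope, intercept=intercept, rss=(resid**2).sum(axis=-1))


def band_features(
    frame: SpectralFrame, fit: AperiodicFit, config: IrasaConfig
) -> dict[str, np.ndarray]:
    """The six per-trial signals from a separated spectrum.

    ``bb_power`` is the mean aperiodic power over the broadband range;
    ``theta``/``alpha``/``beta`` are mean oscillatory power over each band
    (negative values retained — truncation would bias decoding features);
    ``slope``/``intercept`` come from ``fit``.
    """
    freqs = frame.freqs
    lo, hi = config.broadband_range
    bb_sel = (freqs >= lo) & (freqs <= hi)
    out = {
        "bb_power": frame.aperiodic[..., bb_sel].mean(axis=-1),
        "slope": fit.slope,
        "intercept": fit.intercept,
    }
    osc = frame.oscillatory
    for name, (blo, bhi) in config.bands.items():
        sel = (freqs >= blo) & (freqs <= bhi)
        out[name] = osc[..., sel].mean(axis=-1)
    return out


def extract_features(epochs: EpochSet, config: IrasaConfig | None = None) -> FeatureSet:
    """Run IRASA per epoch and channel and return all six signals.

    Single-trial spectra are required because decoding operates on per-trial
    features; pseudo-trial averaging happens later on features, never on raw
    series (raw averaging would cancel non-phase-locked oscillations).
    """
    config = config or IrasaConfig()
    frame = separate(epochs.data, epochs.fs, config)
    fit = fit_aperiodic(frame.aperiodic, frame.freqs, config.fit_range, config.log_base)
    values = band_features(frame, fit, config)
    return FeatureSet(
        values={s: values[s] for s in SIGNALS},
        labels=epochs.labels.copy(),
        feature_ids=list(epochs.channels["name"]),
    )
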