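"""Multitaper time-frequency decomposition and baseline normalization (ERSP).

Power is estimated per moving window by averaging periodograms over
orthogonal Slepian (DPSS) tapers.  Two stock parameterizations are used
throughout the package:

* high resolution -- 400 ms window, 50 ms step, 6 tapers at time-bandwidth
  4, 1.5--150 Hz; on a [-0.7, 4.0) s epoch at 500 Hz this yields an
  87 (time) x 76 (frequency) grid;
* low resolution -- 500 ms window, 250 ms step at six target frequencies
  (3, 8, 12, 16, 58, 89 Hz), yielding a 6 x 17 grid on the same epoch.

FFT length defaults to the next power of two of the window length (200
samples -> 256), giving ~1.95 Hz bin spacing and exactly 76 bins inside
[1.5, 150] Hz; window time stamps are window centers, and the first window
starts at the epoch start.  Event-related spectral perturbation (ERSP) is
the single-trial ratio to mean pre-stimulus baseline power at the same
frequency, trial-averaged and expressed in dB.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.signal import windows

from .epochs import TrialEpochs

__all__ = ["TFRParams", "SpectralPerturbation", "multitaper_tfr",
           "baseline_normalize", "HIGH_RES", "LOW_RES", "BAND_DECODING_RES"]


@dataclass
class TFRParams:
    """Multitaper moving-window parameters.

    ``freq_list`` (target frequencies, snapped to the nearest FFT bin) takes
    precedence over ``freq_range`` when given.  ``fft_mode`` is
    ``"next_pow2"`` (default) or ``"exact"`` (FFT length = window length).
    """

    window_s: float = 0.4
    step_s: float = 0.05
    n_tapers: int = 6
    time_bandwidth: float = 4.0
    freq_range: tuple[float, float] = (1.5, 150.0)
    freq_list: tuple[float, ...] | None = None
    fft_mode: str = "next_pow2"

    def __post_init__(self) -> None:
        if self.n_tapers > 2 * self.time_bandwidth - 1 + 1e-9:
            raise ValueError(
                f"{self.n_tapers} tapers exceed 2*NW-1 = {2 * self.time_bandwidth - 1}"
            )
        if self.fft_mode not in ("next_pow2", "exact"):
            raise ValueError(f"unknown fft_mode {self.fft_mode!r}")

    def nfft(self, n_win: int) -> int:
        if self.fft_mode == "exact":
            return n_win
        return int(2 ** np.ceil(np.log2(n_win)))


#: High-resolution parameterization (87 x 76 grid on the stock epoch).
HIGH_RES = TFRParams()

#: Low-resolution parameterization at six target frequencies (6 x 17 grid).
LOW_RES = TFRParams(window_s=0.5, step_s=0.25, freq_list=(3, 8, 12, 16, 58, 89))

#: Band-decoding parameterization (13 time points x 76 frequencies).
BAND_DECODING_RES = TFRParams(window_s=0.5, step_s=0.35)


@dataclass
class SpectralPerturbation:
    """Time-frequency power container.

    ``power`` is ``(trials, channels, freqs, times)`` for raw output and
    ``(channels, freqs, times)`` after baseline normalization (trials are
    averaged before the dB transform).
    """

    power: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    params: TFRParams
    fs: float
    normalized: bool = False
    baseline_window: tuple[float, float] | None = None
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.normalized and np.any(self.power < 0):
            raise ValueError("raw power must be nonnegative")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")
        if self.times.size > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def n_freqs(self) -> int:
        return self.freqs.size

    @property
    def n_times(self) -> int:
        return self.times.size


def expected_grid(n_samples: int, fs: float, params: TFRParams) -> tuple[int, int]:
    """Closed-form (n_times, n_freqs) of the output grid."""
    n_win = int(round(params.window_s * fs))
    step = int(round(params.step_s * fs))
    n_times = (n_samples - n_win) // step + 1
    nfft = params.nfft(n_win)
    all_freqs = np.fft.rfftfreq(nfft, 1.0 / fs)
    if params.freq_list is not None:
        n_freqs = len(params.freq_list)
    else:
        lo, hi = params.freq_range
        n_freqs = int(np.sum((all_freqs >= lo) & (all_freqs <= hi)))
    return n_times, n_freqs


def _select_bins(all_freqs: np.ndarray, params: TFRParams) -> np.ndarray:
    if params.freq_list is not None:
        if max(params.freq_list) > all_freqs[-1]:
            raise ValueError(
                f"requested frequency {max(params.freq_list)} Hz above Nyquist"
            )
        return np.array([int(np.argmin(np.abs(all_freqs - f)))
                         for f in params.freq_list])
    lo, hi = params.freq_range
    if lo > all_freqs[-1]:
        raise ValueError(f"frequency range {params.freq_range} above Nyquist")
    return np.flatnonzero((all_freqs >= lo) & (all_freqs <= min(hi, all_freqs[-1])))


def multitaper_tfr(epochs: TrialEpochs, params: TFRParams = HIGH_RES) -> SpectralPerturbation:
    """Raw multitaper time-frequency power of every trial and channel.

    Per window: demean, taper with each DPSS sequence, FFT (zero-padded per
    ``fft_mode``), and average squared magnitudes over tapers.  Time stamps
    are window centers; the first window starts at the epoch start.
    """
    fs = epochs.fs
    n_win = int(round(params.window_s * fs))
    step = int(round(params.step_s * fs))
    if n_win > epochs.n_samples:
        raise ValueError(
            f"window of {n_win} samples exceeds epoch of {epochs.n_samples}"
        )
    if params.freq_list is not None and max(params.freq_list) > fs / 2:
        raise ValueError("requested frequency above fs/2")

    nfft = params.nfft(n_win)
    all_freqs = np.fft.rfftfreq(nfft, 1.0 / fs)
    bins = _select_bins(all_freqs, params)
    n_times = (epochs.n_samples - n_win) // step + 1
    starts = np.arange(n_times) * step
    centers = epochs.times[0] + (starts + (n_win - 1) / 2.0) / fs

    tapers = windows.dpss(n_win, params.time_bandwidth, Kmax=params.n_tapers)

    out = np.empty((epochs.n_trials, epochs.n_channels, bins.size, n_times))
    # windows of one trial at a time keeps the working set modest
    idx = starts[:, None] + np.arange(n_win)[None, :]
    for tr in range(epochs.n_trials):
        seg = epochs.data[tr][:, idx]                          # (ch, T, n_win)
        seg = seg - seg.mean(axis=2, keepdims=True)
        acc = np.zeros((epochs.n_channels, n_times, bins.size))
        for tap in tapers:
            spec = np.fft.rfft(seg * tap[None, None, :], n=nfft, axis=2)
            acc += np.abs(spec[:, :, bins]) ** 2
        out[tr] = np.transpose(acc, (0, 2, 1)) / params.n_tapers

    return SpectralPerturbation(power=out, freqs=all_freqs[bins], times=centers,
                                params=params, fs=fs, labels=epochs.labels.copy())


def baseline_normalize(tfr: SpectralPerturbation,
                       baseline_window: tuple[float, float] = (-0.7, 0.0)
                       ) -> SpectralPerturbation:
    """Single-trial baseline normalization to dB (the ERSP measure).

    Per trial, channel and frequency, divides each time point by the mean
    power over the pre-stimulus baseline windows (window centers within
    ``baseline_window``), averages the ratio across trials, and applies
    ``10*log10``.
    """
    if tfr.normalized:
        raise ValueError("input must be raw power")
    b0, b1 = baseline_window
    mask = (tfr.times >= b0) & (tfr.times <= b1)
    if not mask.any():
        raise ValueError(f"no window centers inside baseline {baseline_window}")
    base = tfr.power[:, :, :, mask].mean(axis=3)           # (trials, ch, freqs)
    bad = base <= 0
    if np.any(bad):
        tr, ch, fr = np.argwhere(bad)[0]
        raise ValueError(
            f"zero baseline power (trial {tr}, channel {ch}, "
            f"frequency {tfr.freqs[fr]:.2f} Hz)"
        )
    ratio = tfr.power / base[:, :, :, None]
    ersp = 10.0 * np.log10(ratio.mean(axis=0))
    return replace(tfr, power=ersp, normalized=True, baseline_window=baseline_window,
                   labels=None)
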