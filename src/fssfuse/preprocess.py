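"""Filtering, epoching and spectral summaries of multichannel EEG.

The extraction stage expects its input narrowband-filtered around the
steady-state driving frequency (10 +/- 0.5 Hz, zero-phase), and the
reference spectral metrics work on broadband (0.5-30 Hz) data; both
filters are 4th-order Butterworth applied forward-backward so the group
delay is zero and phase-locked averaging is unaffected.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal


@dataclass
class Recording:
    """Continuous multichannel EEG.

    data : channels x samples, microvolts
    events : (onset sample, phase_id) pairs
    """

    data: np.ndarray
    fs: float
    channel_labels: list[str]
    events: list[tuple[int, str]]

    def __post_init__(self):
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if np.isnan(self.data).any():
            raise ValueError("recording contains NaN")
        for onset, _ in self.events:
            if not 0 <= onset < self.n_samples:
                raise ValueError(f"event onset {onset} outside recording")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def channel(self, label: str) -> np.ndarray:
        return self.data[self.channel_labels.index(label)]


@dataclass
class EpochSet:
    """Fixed-length trials cut around stimulus onsets.

    data is trials x channels x samples, or trials x samples for a
    single extracted source.  Epochs include both endpoint samples:
    length = (t_max - t_min) * fs + 1, and index ``onset_index`` maps to
    stimulus onset (t = 0).
    """

    data: np.ndarray
    window: tuple[float, float]
    fs: float

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[-1]

    @property
    def onset_index(self) -> int:
        return int(round(-self.window[0] * self.fs))

    @property
    def times(self) -> np.ndarray:
        return self.window[0] + np.arange(self.n_samples) / self.fs

    def mean(self) -> np.ndarray:
        """Trial average (the evoked response)."""
        return self.data.mean(axis=0)

    def window_slice(self, t_lo: float, t_hi: float, half_open: bool = False) -> slice:
        """Sample slice covering [t_lo, t_hi] (or [t_lo, t_hi) if half_open)."""
        i0 = int(round((t_lo - self.window[0]) * self.fs))
        i1 = int(round((t_hi - self.window[0]) * self.fs))
        if not half_open:
            i1 += 1
        if i0 < 0 or i1 > self.n_samples or i0 >= i1:
            raise ValueError(f"window [{t_lo}, {t_hi}] s outside epoch {self.window}")
        return slice(i0, i1)


def _bandpass_sos(lo: float, hi: float, fs: float, order: int = 4):
    if not 0 < lo < hi < fs / 2:
        raise ValueError(f"invalid band edges ({lo}, {hi}) at fs={fs}")
    return signal.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")


def bandpass_narrow(rec: Recording, center: float = 10.0, halfwidth: float = 0.5,
                    order: int = 4) -> Recording:
    """Zero-phase narrow bandpass around the steady-state frequency."""
    sos = _bandpass_sos(center - halfwidth, center + halfwidth, rec.fs, order)
    out = signal.sosfiltfilt(sos, rec.data, axis=-1)
    return replace(rec, data=out)


def bandpass_broad(rec: Recording, lo: float = 0.5, hi: float = 30.0,
                   order: int = 4) -> Recording:
    """Zero-phase broadband filter used for the raw-channel reference metrics."""
    sos = _bandpass_sos(lo, hi, rec.fs, order)
    out = signal.sosfiltfilt(sos, rec.data, axis=-1)
    return replace(rec, data=out)


def _onsets_seconds(schedule) -> np.ndarray:
    """Accept a TrialSchedule or a bare array of onset times in seconds."""
    onsets = getattr(schedule, "onsets", schedule)
    return np.asarray(onsets, dtype=float)


def epoch(rec_or_series, schedule, t_min: float = -1.0, t_max: float = 7.0,
          fs: float | None = None) -> EpochSet:
    """Cut per-trial epochs around each onset.

    Accepts a :class:`Recording` (-> trials x channels x samples) or a
    bare 1-D series with explicit ``fs`` (-> trials x samples).  The
    sample at t = 0 is exactly the onset sample.
    """
    if t_min >= t_max:
        raise ValueError("need t_min < t_max")
    if isinstance(rec_or_series, Recording):
        data, fs_ = rec_or_series.data, rec_or_series.fs
    else:
        data = np.asarray(rec_or_series, dtype=float)
        if fs is None:
            raise ValueError("fs required when epoching a bare array")
        fs_ = fs
    n_samples = data.shape[-1]
    n_win = int(round((t_max - t_min) * fs_)) + 1
    offset = int(round(t_min * fs_))
    trials = []
    for i, onset_s in enumerate(_onsets_seconds(schedule)):
        start = int(round(onset_s * fs_)) + offset
        stop = start + n_win
        if start < 0 or stop > n_samples:
            raise ValueError(
                f"trial {i} window [{t_min}, {t_max}] s around onset "
                f"{onset_s:.2f} s exceeds recording bounds"
            )
        trials.append(data[..., start:stop])
    return EpochSet(data=np.stack(trials), window=(t_min, t_max), fs=fs_)


def amplitude_spectrum(epochs: EpochSet, t_lo: float | None = None,
                       t_hi: float | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Trial-averaged discrete-Fourier amplitude spectrum.

    Per trial, amplitudes are ``2/N * |rfft|`` so a unit sinusoid spanning
    an integer number of cycles reads 1.0 at its bin; spectra are then
    averaged over trials.  An optional half-open time window [t_lo, t_hi)
    restricts the transform (e.g. the stimulus-on period), which keeps
    the frequency grid aligned with integer-cycle windows.

    Returns (freqs, amp) with amp shaped like the epoch data minus the
    trial axis (channels x bins, or bins for a single source).
    """
    if epochs.n_trials < 1:
        raise ValueError("need at least one trial")
    data = epochs.data
    if t_lo is not None or t_hi is not None:
        t_lo = epochs.window[0] if t_lo is None else t_lo
        t_hi = epochs.window[1] if t_hi is None else t_hi
        data = data[..., epochs.window_slice(t_lo, t_hi, half_open=True)]
    n = data.shape[-1]
    amp = (2.0 / n) * np.abs(np.fft.rfft(data, axis=-1))
    freqs = np.fft.rfftfreq(n, d=1.0 / epochs.fs)
    return freqs, amp.mean(axis=0)


def dominant_frequency(freqs: np.ndarray, amp: np.ndarray,
                       band: tuple[float, float] = (0.5, 30.0)) -> float:
    """Frequency of the maximal amplitude bin within ``band`` (1-D spectrum)."""
    amp = np.asarray(amp)
    if amp.ndim != 1:
        raise ValueError("pass a single channel's spectrum")
    sel = (freqs >= band[0]) & (freqs <= band[1])
    if not sel.any():
        raise ValueError("band contains no frequency bins")
    return float(freqs[sel][np.argmax(amp[sel])])
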