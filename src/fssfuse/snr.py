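"""Evaluation metrics for an extracted steady-state source.

Four indices, all computed from epoched data:

* ``snr_evoked`` — mean power of the trial-averaged source during
  stimulation over mean power in the pre-stimulus baseline;
* ``snr_offset_check`` — the same ratio against the late inter-trial
  window (5.6-7 s), a validity check on a segment the extraction
  objective never saw;
* ``snr_raw`` — spectral SNR of a raw channel: power in the 10 Hz bin of
  the trial-averaged power spectrum over the mean power of the other
  bins in 0.5-30 Hz;
* ``ssvep_amp`` — moving-window time-domain average followed by a DFT,
  read out at 10 Hz, in the data's amplitude units.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .preprocess import EpochSet

STIM_WINDOW = (0.0, 5.0)
BASE_WINDOW = (-1.0, 0.0)
OFFSET_WINDOW = (5.6, 7.0)


@dataclass
class SnrReport:
    """One row of the per-subject, per-phase metric table."""

    phase_id: str
    subject_id: str
    snr_ica: float | None
    snr_fss: float | None
    snr_raw: float | None
    ssvep_amp: float | None
    snr_offset_check: float | None = None
    stim_window: tuple[float, float] = STIM_WINDOW
    base_window: tuple[float, float] = BASE_WINDOW
    offset_window: tuple[float, float] = OFFSET_WINDOW
    # the offset window is not part of the extraction objective; it is a
    # post-hoc validity check only
    offset_blind_to_optimization: bool = True

    def as_dict(self) -> dict:
        return asdict(self)


def _mean_power(trace: np.ndarray) -> float:
    return float(np.mean(trace**2))


def _evoked_ratio(epochs: EpochSet, signal_window, noise_window,
                  single_trial: bool = False) -> float:
    if epochs.data.ndim != 2:
        raise ValueError("expected source epochs (trials x samples)")
    sig_sl = epochs.window_slice(*signal_window)
    noi_sl = epochs.window_slice(*noise_window)
    if single_trial:
        sig = np.mean(epochs.data[:, sig_sl] ** 2)
        noi = np.mean(epochs.data[:, noi_sl] ** 2)
    else:
        avg = epochs.mean()
        sig = _mean_power(avg[sig_sl])
        noi = _mean_power(avg[noi_sl])
    if noi == 0:
        raise ValueError("zero power in the reference window (degenerate input)")
    return float(sig / noi)


def snr_evoked(epochs: EpochSet, stim_window=STIM_WINDOW, base_window=BASE_WINDOW,
               single_trial: bool = False) -> float:
    """Stimulus-on over pre-stimulus power of the trial-averaged source.

    Averaging before squaring rewards phase-locked activity (what the
    extraction optimizes); ``single_trial=True`` switches to mean
    single-trial power in both windows.
    """
    return _evoked_ratio(epochs, stim_window, base_window, single_trial)


def snr_offset_check(epochs: EpochSet, stim_window=STIM_WINDOW,
                     offset_window=OFFSET_WINDOW, single_trial: bool = False) -> float:
    """Stimulus-on over late inter-trial power: attenuation after offset."""
    return _evoked_ratio(epochs, stim_window, offset_window, single_trial)


def _channel_epochs(epochs: EpochSet, channel: int | None) -> np.ndarray:
    if epochs.data.ndim == 3:
        if channel is None:
            raise ValueError("multichannel epochs need a channel index")
        return epochs.data[:, channel, :]
    return epochs.data


def snr_raw(epochs: EpochSet, channel: int | None = None, target: float = 10.0,
            band: tuple[float, float] = (0.5, 30.0),
            window: tuple[float, float] = STIM_WINDOW, guard_bins: int = 1) -> float:
    """Spectral SNR of a raw channel.

    Power spectra are computed per trial on the half-open stimulus
    window and averaged; the bin nearest ``target`` is divided by the
    mean power of the in-band bins excluding the target and its
    ``guard_bins`` immediate neighbours (leakage guard).
    """
    if band[1] >= epochs.fs / 2:
        raise ValueError("band exceeds Nyquist")
    data = _channel_epochs(epochs, channel)
    data = data[:, epochs.window_slice(*window, half_open=True)]
    n = data.shape[-1]
    power = np.mean(np.abs(np.fft.rfft(data, axis=-1)) ** 2, axis=0)
    freqs = np.fft.rfftfreq(n, d=1.0 / epochs.fs)
    target_bin = int(np.argmin(np.abs(freqs - target)))
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    neighbors = in_band.copy()
    lo = max(target_bin - guard_bins, 0)
    neighbors[lo:target_bin + guard_bins + 1] = False
    if not neighbors.any():
        raise ValueError("no neighboring bins left in band")
    return float(power[target_bin] / power[neighbors].mean())


def ssvep_amp(epochs: EpochSet, channel: int | None = None, target: float = 10.0,
              window: tuple[float, float] = STIM_WINDOW,
              win_seconds: float = 1.0, step_seconds: float = 0.1) -> float:
    """Moving-window steady-state amplitude at the target frequency.

    Sliding windows (an integer number of target cycles long, default
    1 s = 10 cycles) over the trial-averaged stimulus-on trace are
    averaged in the time domain; the DFT amplitude ``2/N |X(f)|`` of that
    window average at ``target`` is returned.  For a phase-locked trace
    ``A sin(2 pi f t)`` this recovers A exactly.
    """
    data = _channel_epochs(epochs, channel)
    avg = data.mean(axis=0)[epochs.window_slice(*window, half_open=True)]
    n_win = int(round(win_seconds * epochs.fs))
    cycles = win_seconds * target
    if abs(cycles - round(cycles)) > 1e-9:
        raise ValueError("window must span an integer number of target cycles")
    if n_win > avg.size:
        raise ValueError("moving window longer than the stimulus period")
    step = max(1, int(round(step_seconds * epochs.fs)))
    starts = range(0, avg.size - n_win + 1, step)
    stacked = np.mean([avg[s:s + n_win] for s in starts], axis=0)
    spec = (2.0 / n_win) * np.abs(np.fft.rfft(stacked))
    freqs = np.fft.rfftfreq(n_win, d=1.0 / epochs.fs)
    return float(spec[np.argmin(np.abs(freqs - target))])
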