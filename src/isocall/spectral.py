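"""Spectrograms, onset-aligned average spectrograms and Welch spectra.

Two time-frequency parameterizations are used:

* a display/averaging spectrogram: Hamming window, FFT length 1024,
  75 % overlap;
* a tracking representation: 10-ms sliding window with 50 % overlap,
  median-smoothed along frequency with a 5-point filter; the smoothing
  does not move per-frame dominant-frequency positions, which is asserted
  by :func:`argmax_preserved`.

Average spectrograms are built by normalizing each eligible call's
spectrogram to its own maximum, left-aligning all calls at onset, and
averaging frame-by-frame; at each frame index only calls that are still
defined there contribute (the denominator shrinks with frame index), which
avoids zero-padding bias for unequal call lengths.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal as sps
from scipy.ndimage import median_filter

#: STFT parameters for display / average spectrograms
STFT_NFFT = 1024
STFT_OVERLAP = 0.75
#: tracking-representation parameters
TRACK_WIN_S = 0.010
TRACK_OVERLAP = 0.5
MEDFILT_POINTS = 5
#: lower edge of the analysis band (Hz); isolation calls carry no energy below
ANALYSIS_BAND_LO_HZ = 500.0


@dataclass
class Spectrogram:
    """Linear-power time-frequency matrix (time x frequency)."""

    power: np.ndarray
    times_s: np.ndarray
    freqs_hz: np.ndarray
    params: dict = field(default_factory=dict)

    def normalized(self) -> "Spectrogram":
        """Copy with power scaled so the global maximum is 1."""
        peak = float(self.power.max())
        scale = 1.0 / peak if peak > 0 else 1.0
        return Spectrogram(self.power * scale, self.times_s, self.freqs_hz,
                           dict(self.params, normalized=True))


def _frame_matrix(x: np.ndarray, win: int, hop: int) -> np.ndarray:
    n_frames = 1 + (x.size - win) // hop
    idx = hop * np.arange(n_frames)[:, None] + np.arange(win)[None, :]
    return x[idx]


def _stft_power(x: np.ndarray, fs: float, win: int, hop: int,
                nfft: int, window: np.ndarray) -> Spectrogram:
    frames = _frame_matrix(x, win, hop) * window[None, :]
    spec = np.abs(np.fft.rfft(frames, n=nfft, axis=1)) ** 2
    times = (np.arange(frames.shape[0]) * hop + win / 2) / fs
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fs)
    return Spectrogram(power=spec, times_s=times, freqs_hz=freqs,
                       params={"win": win, "hop": hop, "nfft": nfft})


def stft_spectrogram(call: np.ndarray, fs: float,
                     nfft: int = STFT_NFFT,
                     overlap: float = STFT_OVERLAP) -> Spectrogram:
    """Magnitude-squared STFT (Hamming window of ``nfft`` samples).

    Frame count is ``1 + floor((N - win) / hop)`` with
    ``hop = win * (1 - overlap)``; power is the squared magnitude of the
    DFT of each windowed frame (so summing a frame's one-sided power with
    the negative-frequency bins restored equals ``nfft`` times the windowed
    frame's energy).
    """
    call = np.asarray(call, dtype=np.float64)
    if call.size < nfft:
        raise ValueError(f"call shorter ({call.size}) than window ({nfft})")
    hop = int(round(nfft * (1.0 - overlap)))
    return _stft_power(call, fs, nfft, hop, nfft, np.hamming(nfft))


def average_spectrogram(calls: Sequence[np.ndarray], fs: float,
                        nfft: int = STFT_NFFT,
                        overlap: float = STFT_OVERLAP) -> Spectrogram:
    """Onset-aligned average of per-call normalized spectrograms.

    Every call is normalized to its own maximum power, aligned at frame 0
    (call onset) and averaged; frame ``j`` of the result averages only the
    calls whose spectrograms extend to ``j``.
    """
    if len(calls) == 0:
        raise ValueError("average_spectrogram needs at least one call")
    specs = [stft_spectrogram(np.asarray(c), fs, nfft, overlap).normalized()
             for c in calls]
    n_t = max(s.power.shape[0] for s in specs)
    n_f = specs[0].power.shape[1]
    acc = np.zeros((n_t, n_f))
    cnt = np.zeros(n_t)
    for s in specs:
        m = s.power.shape[0]
        acc[:m] += s.power
        cnt[:m] += 1
    avg = acc / cnt[:, None]
    longest = max(specs, key=lambda s: s.power.shape[0])
    return Spectrogram(power=avg, times_s=longest.times_s,
                       freqs_hz=specs[0].freqs_hz,
                       params=dict(specs[0].params, n_calls=len(specs)))


def welch_spectrum(call: np.ndarray, fs: float,
                   nfft: int = STFT_NFFT) -> tuple[np.ndarray, np.ndarray]:
    """Welch power spectrum of one call, normalized to its maximum.

    Returns ``(freqs_hz, power)`` with ``max(power) == 1``.
    """
    call = np.asarray(call, dtype=np.float64)
    if call.size < nfft:
        raise ValueError(f"call shorter ({call.size}) than one FFT segment ({nfft})")
    freqs, p = sps.welch(call, fs=fs, window="hamming", nperseg=nfft)
    peak = p.max()
    if peak > 0:
        p = p / peak
    return freqs, p


def average_welch(spectra: Sequence[np.ndarray]) -> np.ndarray:
    """Group reduction: arithmetic mean of per-call normalized spectra."""
    if len(spectra) == 0:
        raise ValueError("nothing to average")
    return np.mean(np.stack(spectra), axis=0)


def tf_for_tracking(call: np.ndarray, fs: float,
                    win_s: float = TRACK_WIN_S,
                    overlap: float = TRACK_OVERLAP,
                    nfft: int = STFT_NFFT,
                    medfilt_points: int = MEDFILT_POINTS,
                    return_raw: bool = False):
    """Median-smoothed time-frequency representation for contour tracking.

    10-ms Hamming window, 50 % overlap, zero-padded to ``nfft`` bins, then a
    5-point median filter along frequency within each frame. With
    ``return_raw`` the unsmoothed representation is returned as well (its
    dominant-frequency positions coincide with the smoothed ones).
    """
    call = np.asarray(call, dtype=np.float64)
    win = int(round(win_s * fs))
    if call.size < win:
        raise ValueError(f"call shorter ({call.size}) than window ({win})")
    hop = max(1, int(round(win * (1.0 - overlap))))
    raw = _stft_power(call, fs, win, hop, nfft, np.hamming(win))
    smooth_power = median_filter(raw.power, size=(1, medfilt_points),
                                 mode="nearest")
    smooth = Spectrogram(power=smooth_power, times_s=raw.times_s,
                         freqs_hz=raw.freqs_hz,
                         params=dict(raw.params, medfilt=medfilt_points))
    if return_raw:
        return smooth, raw
    return smooth


def band_mask(freqs_hz: np.ndarray, lo_hz: float = ANALYSIS_BAND_LO_HZ,
              hi_hz: float | None = None) -> np.ndarray:
    hi = freqs_hz[-1] if hi_hz is None else hi_hz
    return (freqs_hz >= lo_hz) & (freqs_hz <= hi)


def dominant_frequency_track(spec: Spectrogram,
                             lo_hz: float = ANALYSIS_BAND_LO_HZ) -> np.ndarray:
    """Per-frame frequency of maximum power within the analysis band."""
    mask = band_mask(spec.freqs_hz, lo_hz)
    sel = np.flatnonzero(mask)
    idx = np.argmax(spec.power[:, sel], axis=1)
    return spec.freqs_hz[sel[idx]]


def argmax_preserved(raw: Spectrogram, smooth: Spectrogram,
                     energy_floor_frac: float = 1e-4,
                     lo_hz: float = ANALYSIS_BAND_LO_HZ) -> np.ndarray:
    """Per-frame check that smoothing kept the dominant-frequency position.

    A frame passes when the smoothed power at the raw dominant bin equals
    the smoothed frame maximum (i.e. the raw peak is still a maximizer
    after filtering; exact float ties between neighbouring bins are not
    counted as movement). Frames whose total power falls below
    ``energy_floor_frac`` of the strongest frame are excluded (returned as
    True) — an essentially empty frame has no meaningful dominant bin.
    """
    sel = np.flatnonzero(band_mask(raw.freqs_hz, lo_hz))
    p_raw = raw.power[:, sel]
    p_sm = smooth.power[:, sel]
    frame_energy = p_raw.sum(axis=1)
    active = frame_energy > energy_floor_frac * frame_energy.max()
    k_raw = np.argmax(p_raw, axis=1)
    ok = p_sm[np.arange(p_sm.shape[0]), k_raw] >= p_sm.max(axis=1)
    return ok | ~active
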