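"""Per-call acoustic features.

The quantitative description of a voiced isolation call used here is:

* duration (s) and level (dB SPL, via the session calibration constant);
* a per-frame fundamental-frequency track F0(t) estimated from the
  autocorrelation of 10-ms frames, with the lag search restricted to
  +-30 % of the expected maximum F0 to avoid octave confusion;
* a per-frame first-harmonic track F1(t) located as the dominant spectral
  peak in a band around 2*F0 of a median-smoothed time-frequency
  representation;
* summary statistics of F0 (mean, max, SD, latency of the maximum) and of
  the harmonic ratio F1/F0 (mean, SD, max, latency of the maximum, and its
  value at the frame of maximum F0).

The harmonic ratio equals 2 for a strictly harmonic call; deviations and
their variability index departures from strict harmonicity (subharmonics,
biphonation, frequency jumps).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .audio_io import DEFAULT_CALIBRATION_DB
from . import spectral
from .voicing import FrameAnalysis, FRAME_S, autocorrelation

#: default expected maximum of F0 (Hz); kitten isolation calls sit near 1 kHz
DEFAULT_EXPECTED_F0_HZ = 1000.0
#: half-width of the relative F0 search band around the expected maximum
F0_BAND_FRAC = 0.30
#: relative band around 2*F0 searched for the first harmonic
F1_BAND = (1.5, 2.5)
#: frames whose tracking autocorrelation peak ratio falls below this floor
#: are marked invalid (automatic stand-in for manual contour control)
MIN_TRACK_PEAK_RATIO = 0.3


class FeatureError(Exception):
    """Raised when a call cannot yield a valid feature vector."""


@dataclass
class ContourTrack:
    """Frame-wise F0/F1 trajectories; NaN marks invalid frames."""

    times_s: np.ndarray
    f0_hz: np.ndarray
    f1_hz: np.ndarray = field(default=None)  # type: ignore[assignment]
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=np.float64)
        self.f0_hz = np.asarray(self.f0_hz, dtype=np.float64)
        if self.f1_hz is None:
            self.f1_hz = np.full_like(self.f0_hz, np.nan)
        self.f1_hz = np.asarray(self.f1_hz, dtype=np.float64)
        if self.valid is None:
            self.valid = np.isfinite(self.f0_hz)
        self.valid = np.asarray(self.valid, dtype=bool)
        if np.any(self.f0_hz[self.valid] <= 0):
            raise ValueError("valid F0 values must be positive")


@dataclass
class CallFeatures:
    """Scalar feature vector for one call."""

    duration_s: float
    level_db: float
    call_class: str
    f0_mean_hz: float = float("nan")
    f0_max_hz: float = float("nan")
    f0_sd_hz: float = float("nan")
    t_f0max_s: float = float("nan")
    hr_mean: float = float("nan")
    hr_sd: float = float("nan")
    hr_max: float = float("nan")
    t_hrmax_s: float = float("nan")
    hr_at_f0max: float = float("nan")
    onset_s: float = float("nan")
    offset_s: float = float("nan")


def f0_search_band(expected_f0_max_hz: float,
                   band_frac: float = F0_BAND_FRAC) -> tuple[float, float]:
    """Frequency band searched for F0: ``[1-band_frac, 1+band_frac] * expected``."""
    return ((1.0 - band_frac) * expected_f0_max_hz,
            (1.0 + band_frac) * expected_f0_max_hz)


def _parabolic_refine(y_m1: float, y_0: float, y_p1: float) -> float:
    """Offset of the vertex of the parabola through three equidistant points."""
    denom = y_m1 - 2.0 * y_0 + y_p1
    if denom >= 0 or not np.isfinite(denom):
        return 0.0
    delta = 0.5 * (y_m1 - y_p1) / denom
    return float(np.clip(delta, -0.5, 0.5))


def frame_f0(frame: np.ndarray, fs: float,
             expected_f0_max_hz: float = DEFAULT_EXPECTED_F0_HZ,
             band_frac: float = F0_BAND_FRAC,
             min_peak_ratio: float = MIN_TRACK_PEAK_RATIO) -> tuple[float, float]:
    """Estimate F0 of one frame by constrained autocorrelation.

    Returns ``(f0_hz, peak_ratio)``; ``(nan, ratio)`` when no acceptable
    peak exists. The lag search covers only frequencies within the +-30 %
    band around the expected F0 maximum, and the winning lag is refined by
    parabolic interpolation of the autocorrelation peak.
    """
    frame = np.asarray(frame, dtype=np.float64)
    lo_hz, hi_hz = f0_search_band(expected_f0_max_hz, band_frac)
    lag_min = max(1, int(np.floor(fs / hi_hz)))
    lag_max = min(frame.size - 1, int(np.ceil(fs / lo_hz)))
    if lag_max <= lag_min:
        return float("nan"), 0.0
    r = autocorrelation(frame)
    if r[0] <= 0:
        return float("nan"), 0.0
    seg = r[lag_min:lag_max + 1]
    k = int(np.argmax(seg))
    lag = lag_min + k
    ratio = float(seg[k] / r[0])
    if ratio < min_peak_ratio:
        return float("nan"), ratio
    if 1 <= lag < r.size - 1:
        lag = lag + _parabolic_refine(r[lag - 1], r[lag], r[lag + 1])
    return float(fs / lag), ratio


def estimate_f0_track(call: np.ndarray, frames: Sequence[FrameAnalysis], fs: float,
                      expected_f0_max_hz: float = DEFAULT_EXPECTED_F0_HZ,
                      band_frac: float = F0_BAND_FRAC) -> ContourTrack:
    """F0 per voiced 10-ms frame of a detected call.

    Unvoiced frames and frames whose tracking peak ratio falls below
    :data:`MIN_TRACK_PEAK_RATIO` are marked invalid (NaN).
    """
    call = np.asarray(call, dtype=np.float64)
    if not any(f.voiced for f in frames):
        raise FeatureError("no voiced frames: cannot estimate F0")
    n_frame = int(round(FRAME_S * fs))
    times = np.array([f.t_center_s for f in frames])
    f0 = np.full(len(frames), np.nan)
    for i, fr in enumerate(frames):
        if not fr.voiced:
            continue
        start = i * n_frame
        chunk = call[start:start + n_frame]
        if chunk.size < n_frame:
            continue
        f0[i], _ = frame_f0(chunk, fs, expected_f0_max_hz, band_frac)
    return ContourTrack(times_s=times, f0_hz=f0)


def estimate_f1_track(call: np.ndarray, f0_track: ContourTrack, fs: float,
                      band: tuple[float, float] = F1_BAND,
                      tf: Optional[spectral.Spectrogram] = None,
                      tf_raw: Optional[spectral.Spectrogram] = None) -> ContourTrack:
    """Fill the F1 trajectory of an F0 track from the spectral peak near 2*F0.

    The dominant bin is located on the median-smoothed 10-ms/50 %
    time-frequency representation within ``band * F0``; the frequency is then
    refined by parabolic interpolation of log power on the raw (unsmoothed)
    representation, whose peak position the smoothing preserves.
    """
    call = np.asarray(call, dtype=np.float64)
    if tf is None or tf_raw is None:
        tf, tf_raw = spectral.tf_for_tracking(call, fs, return_raw=True)
    freqs = tf.freqs_hz
    f1 = np.full_like(f0_track.f0_hz, np.nan)
    for i, (t, f0) in enumerate(zip(f0_track.times_s, f0_track.f0_hz)):
        if not np.isfinite(f0):
            continue
        j = int(np.argmin(np.abs(tf.times_s - t)))
        lo, hi = band[0] * f0, band[1] * f0
        if lo >= freqs[-1]:
            continue  # band beyond Nyquist
        sel = np.flatnonzero((freqs >= lo) & (freqs <= hi))
        if sel.size == 0:
            continue
        spec_sm = tf.power[j]
        raw = tf_raw.power[j]
        # the median filter flattens the peak into a plateau of equal values;
        # break the tie toward the bin the raw spectrum favours
        band_max = spec_sm[sel].max()
        cand = sel[spec_sm[sel] == band_max]
        k = int(cand[int(np.argmax(raw[cand]))])
        logp = np.log10(raw + 1e-30)
        delta = 0.0
        if 1 <= k < freqs.size - 1:
            delta = _parabolic_refine(logp[k - 1], logp[k], logp[k + 1])
        df = freqs[1] - freqs[0]
        f1[i] = freqs[k] + delta * df
    f1[np.isfinite(f1) & np.isfinite(f0_track.f0_hz) & (f1 <= f0_track.f0_hz)] = np.nan
    valid = np.isfinite(f0_track.f0_hz) & np.isfinite(f1)
    return ContourTrack(times_s=f0_track.times_s, f0_hz=f0_track.f0_hz,
                        f1_hz=f1, valid=valid)


def compute_features(seg, call: np.ndarray, track: ContourTrack, fs: float,
                     calibration_db: float = DEFAULT_CALIBRATION_DB,
                     min_valid_frames: int = 3) -> CallFeatures:
    """Reduce a voiced call's tracks to the scalar feature vector.

    Latencies are seconds from the detected segment onset; all statistics
    use valid frames only; the level is the broadband RMS over the whole
    segment converted to dB SPL by the session calibration.
    """
    call = np.asarray(call, dtype=np.float64)
    valid = track.valid & np.isfinite(track.f1_hz)
    if int(valid.sum()) < min_valid_frames:
        raise FeatureError(
            f"need >= {min_valid_frames} valid frames, got {int(valid.sum())}")
    f0 = track.f0_hz[valid]
    f1 = track.f1_hz[valid]
    t = track.times_s[valid]
    hr = f1 / f0
    rms = float(np.sqrt(np.mean(call ** 2)))
    level = calibration_db + 20.0 * np.log10(rms) if rms > 0 else -np.inf
    i_f0max = int(np.argmax(f0))
    i_hrmax = int(np.argmax(hr))
    return CallFeatures(
        duration_s=call.size / fs,
        level_db=float(level),
        call_class=getattr(seg, "call_class", "voiced"),
        f0_mean_hz=float(np.mean(f0)),
        f0_max_hz=float(np.max(f0)),
        f0_sd_hz=float(np.std(f0, ddof=1)) if f0.size > 1 else 0.0,
        t_f0max_s=float(t[i_f0max]),
        hr_mean=float(np.mean(hr)),
        hr_sd=float(np.std(hr, ddof=1)) if hr.size > 1 else 0.0,
        hr_max=float(np.max(hr)),
        t_hrmax_s=float(t[i_hrmax]),
        hr_at_f0max=float(hr[i_f0max]),
        onset_s=getattr(seg, "onset_s", float("nan")),
        offset_s=getattr(seg, "offset_s", float("nan")),
    )
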