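"""Voiced/unvoiced frame classification and whole-call classification.

A detected segment is cut into non-overlapping 10-ms frames. A frame is
voiced when the normalized autocorrelation peak — the maximum of the
autocorrelation over lags corresponding to plausible fundamental
frequencies, divided by the lag-0 value — exceeds 0.6. Frame sequences are
then corrected with a simple-inverse-filter-tracking step (linear-prediction
whitening followed by re-scoring of the residual) and a continuity rule that
flips isolated single-frame disagreements. Whole calls are classified as
voiced, unvoiced, or combined (an unvoiced beginning that switches into a
voiced isolation call).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.linalg import solve_toeplitz
from scipy.signal import lfilter

#: voicing analysis frame length, seconds (non-overlapping)
FRAME_S = 0.010
#: voicing decision threshold on the normalized autocorrelation peak
VOICING_THRESHOLD = 0.6
#: lag search range expressed as a fundamental-frequency band (Hz); covers
#: the ~1 kHz kitten F0 with generous slack on both sides
VOICING_F_RANGE_HZ = (400.0, 2000.0)
#: linear-prediction order of the SIFT inverse filter
LPC_ORDER = 12


@dataclass
class FrameAnalysis:
    """Voicing analysis of one 10-ms frame."""

    frame_index: int
    t_center_s: float
    ac_peak_ratio: float
    best_lag_s: float
    voiced: bool


def autocorrelation(frame: np.ndarray) -> np.ndarray:
    """Raw (biased) autocorrelation of a frame for non-negative lags."""
    frame = np.asarray(frame, dtype=np.float64)
    n = frame.size
    r = np.correlate(frame, frame, mode="full")[n - 1:]
    return r


def _lag_bounds(n: int, fs: float, f_range_hz: tuple[float, float]) -> tuple[int, int]:
    lo_hz, hi_hz = f_range_hz
    lag_min = max(1, int(np.floor(fs / hi_hz)))
    lag_max = min(n - 1, int(np.ceil(fs / lo_hz)))
    return lag_min, lag_max


def _peak_ratio(frame: np.ndarray, fs: float,
                f_range_hz: tuple[float, float]) -> tuple[float, int]:
    r = autocorrelation(frame)
    if r[0] <= 0:
        return 0.0, 0
    lag_min, lag_max = _lag_bounds(frame.size, fs, f_range_hz)
    if lag_max <= lag_min:
        return 0.0, 0
    seg = r[lag_min:lag_max + 1]
    k = int(np.argmax(seg))
    return float(seg[k] / r[0]), lag_min + k


def frame_voicing(frame: np.ndarray, fs: float,
                  f_range_hz: tuple[float, float] = VOICING_F_RANGE_HZ,
                  thresh: float = VOICING_THRESHOLD,
                  frame_index: int = 0, t_center_s: float = 0.0) -> FrameAnalysis:
    """Score one 10-ms frame: voiced iff the normalized autocorrelation
    peak in the search band exceeds ``thresh``. A zero-energy frame is
    unvoiced with ratio 0."""
    frame = np.asarray(frame, dtype=np.float64)
    ratio, lag = _peak_ratio(frame, fs, f_range_hz)
    return FrameAnalysis(frame_index=frame_index, t_center_s=t_center_s,
                         ac_peak_ratio=ratio, best_lag_s=lag / fs,
                         voiced=ratio > thresh)


def analyze_frames(signal: np.ndarray, fs: float,
                   t0_s: float = 0.0,
                   f_range_hz: tuple[float, float] = VOICING_F_RANGE_HZ,
                   thresh: float = VOICING_THRESHOLD) -> list[FrameAnalysis]:
    """Cut a segment into non-overlapping 10-ms frames and score each.

    ``t0_s`` offsets reported frame centers (e.g. the segment onset time).
    A trailing partial frame is dropped.
    """
    signal = np.asarray(signal, dtype=np.float64)
    n_frame = int(round(FRAME_S * fs))
    n = signal.size // n_frame
    out = []
    for i in range(n):
        chunk = signal[i * n_frame:(i + 1) * n_frame]
        out.append(frame_voicing(chunk, fs, f_range_hz, thresh,
                                 frame_index=i,
                                 t_center_s=t0_s + (i + 0.5) * FRAME_S))
    return out


def _lpc_coefficients(frame: np.ndarray, order: int) -> np.ndarray | None:
    """Autocorrelation-method LPC coefficients a_1..a_p (prediction form)."""
    r = autocorrelation(frame)[:order + 1]
    if r[0] <= 0:
        return None
    # small diagonal loading keeps the Toeplitz solve well conditioned on
    # nearly deterministic frames
    r = r / r[0]
    r[0] += 1e-9
    try:
        a = solve_toeplitz((r[:-1], r[:-1]), r[1:])
    except np.linalg.LinAlgError:
        return None
    if not np.all(np.isfinite(a)):
        return None
    return a


def sift_correct(frames: Sequence[FrameAnalysis], signal: np.ndarray, fs: float,
                 lpc_order: int = LPC_ORDER,
                 f_range_hz: tuple[float, float] = VOICING_F_RANGE_HZ,
                 thresh: float = VOICING_THRESHOLD) -> list[FrameAnalysis]:
    """Correct a contiguous frame sequence with SIFT re-scoring.

    Per frame, a linear-prediction inverse filter whitens the spectrum and
    the residual's normalized autocorrelation peak is scored against the
    same threshold; a frame is kept voiced when either the raw or the
    residual score clears the threshold (whitening can only *reveal*
    periodicity masked by spectral coloration — on an already-white frame it
    removes nothing, and on a strongly predictable frame the raw score is
    decisive). A continuity rule then flips any isolated single frame that
    disagrees with both neighbours.
    """
    signal = np.asarray(signal, dtype=np.float64)
    n_frame = int(round(FRAME_S * fs))
    if len(frames) * n_frame > signal.size:
        raise ValueError("frame list does not fit the supplied signal")
    out: list[FrameAnalysis] = []
    for i, fr in enumerate(frames):
        chunk = signal[i * n_frame:(i + 1) * n_frame]
        voiced = fr.voiced
        ratio = fr.ac_peak_ratio
        if not voiced and chunk.size == n_frame:
            a = _lpc_coefficients(chunk, lpc_order)
            if a is not None:
                residual = lfilter(np.concatenate(([1.0], -a)), [1.0], chunk)
                res_ratio, _ = _peak_ratio(residual, fs, f_range_hz)
                if res_ratio > thresh:
                    voiced = True
                    ratio = max(ratio, res_ratio)
        out.append(replace(fr, voiced=voiced, ac_peak_ratio=ratio))
    # continuity: flip isolated single-frame disagreements with both neighbours
    flags = [f.voiced for f in out]
    for i in range(1, len(flags) - 1):
        if flags[i - 1] == flags[i + 1] != flags[i]:
            out[i] = replace(out[i], voiced=flags[i - 1])
            flags[i] = flags[i - 1]
    return out


def classify_call(frame_flags: Sequence[bool],
                  voiced_frac: float = 0.5,
                  lead_s: float = 0.100,
                  min_voiced_s: float = 0.100,
                  frame_s: float = FRAME_S) -> str:
    """Classify a call from its per-frame voicing flags.

    * ``combined`` — a leading unvoiced run of at least ``lead_s`` followed
      by a voiced run of at least ``min_voiced_s`` (the unvoiced-start,
      voiced-continuation pattern);
    * ``voiced`` — at least ``voiced_frac`` of frames voiced and no long
      leading unvoiced run;
    * ``unvoiced`` — everything else.
    """
    flags = list(frame_flags)
    if not flags:
        raise ValueError("cannot classify a call with no frames")
    lead_frames = int(round(lead_s / frame_s))
    min_voiced_frames = int(round(min_voiced_s / frame_s))
    n_lead = 0
    for f in flags:
        if f:
            break
        n_lead += 1
    if n_lead >= lead_frames and n_lead < len(flags):
        run = longest_true_run(flags[n_lead:])
        if run >= min_voiced_frames:
            return "combined"
    frac = sum(flags) / len(flags)
    if frac >= voiced_frac and n_lead < lead_frames:
        return "voiced"
    return "unvoiced"


def longest_true_run(flags: Sequence[bool]) -> int:
    best = cur = 0
    for f in flags:
        cur = cur + 1 if f else 0
        best = max(best, cur)
    return best
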