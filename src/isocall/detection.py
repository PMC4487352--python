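"""Call detection and segmentation.

Sessions are high-pass filtered (Butterworth, 10th order, 500 Hz cutoff,
applied zero-phase so segment boundaries carry no group delay), a 90-ms
sliding RMS is computed over the whole session, and 130 % of the session's
minimum RMS serves as the detection threshold. Maximal runs of
above-threshold window positions become call segments; runs separated by
less than a short merge gap are joined (vocalizations otherwise split at
brief dips) and very short runs are discarded.

Each RMS value is attributed to the *center* of its 90-ms window, which
bounds the onset/offset error of a detected segment by half a window
regardless of how far above threshold the call rises.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import signal as sps

HP_CUTOFF_HZ = 500.0
HP_ORDER = 10
RMS_WINDOW_S = 0.090
RMS_HOP_S = 0.010
THRESHOLD_FACTOR = 1.30
MERGE_GAP_S = 0.050
MIN_DUR_S = 0.030
#: eligibility window for average-spectrogram construction (seconds)
ELIGIBLE_DUR_S = (0.100, 1.500)


@dataclass
class RmsTrack:
    """Sliding-RMS amplitude track over one session."""

    values: np.ndarray
    hop_s: float
    window_s: float
    fs: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if np.any(self.values < 0):
            raise ValueError("RMS values must be non-negative")

    @property
    def times_s(self) -> np.ndarray:
        """Window *start* times of each RMS position."""
        return np.arange(self.values.size) * self.hop_s


@dataclass
class CallSegment:
    """One detected vocalization (0-based half-open sample interval)."""

    onset_sample: int
    offset_sample: int
    fs: float
    call_class: str = "unclassified"
    frame_flags: Optional[np.ndarray] = None
    peak_rms: float = float("nan")

    def __post_init__(self) -> None:
        if self.offset_sample <= self.onset_sample:
            raise ValueError("offset_sample must exceed onset_sample")

    @property
    def onset_s(self) -> float:
        return self.onset_sample / self.fs

    @property
    def offset_s(self) -> float:
        return self.offset_sample / self.fs

    @property
    def duration_s(self) -> float:
        return (self.offset_sample - self.onset_sample) / self.fs


def highpass(signal: np.ndarray, fs: float, cutoff_hz: float = HP_CUTOFF_HZ,
             order: int = HP_ORDER) -> np.ndarray:
    """Zero-phase 10th-order Butterworth high-pass (500 Hz default).

    Implemented as a second-order-section cascade for numerical stability
    and applied forward-backward (``sosfiltfilt``), so the effective
    magnitude response is the squared Butterworth response and the output
    is not delayed relative to the input.
    """
    if fs <= 2 * cutoff_hz:
        raise ValueError(f"fs={fs} too low for a {cutoff_hz} Hz high-pass")
    sos = sps.butter(order, cutoff_hz, btype="highpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(signal, dtype=np.float64))


def sliding_rms(signal: np.ndarray, fs: float, window_s: float = RMS_WINDOW_S,
                hop_s: float = RMS_HOP_S) -> RmsTrack:
    """RMS of ``[t, t+window)`` at positions advancing by ``hop``."""
    x = np.asarray(signal, dtype=np.float64)
    win = int(round(window_s * fs))
    hop = max(1, int(round(hop_s * fs)))
    if win < 1:
        raise ValueError("window must cover at least one sample")
    if x.size < win:
        raise ValueError(f"signal ({x.size} samples) shorter than window ({win})")
    csum = np.concatenate(([0.0], np.cumsum(x ** 2)))
    starts = np.arange(0, x.size - win + 1, hop)
    values = np.sqrt((csum[starts + win] - csum[starts]) / win)
    # cumulative sums can go microscopically negative under cancellation
    return RmsTrack(values=np.nan_to_num(values), hop_s=hop / fs,
                    window_s=win / fs, fs=fs)


def session_threshold(track: RmsTrack, factor: float = THRESHOLD_FACTOR) -> float:
    """Detection threshold: ``factor`` times the session minimum RMS.

    A digitally silent stretch (minimum exactly 0) would disable detection
    entirely; in that degenerate case the smallest *positive* RMS value is
    used instead and a warning is issued.
    """
    if track.values.size == 0:
        raise ValueError("empty RMS track")
    m = float(track.values.min())
    if m == 0.0:
        positive = track.values[track.values > 0]
        if positive.size == 0:
            warnings.warn("all-zero RMS track; threshold is 0")
            return 0.0
        warnings.warn("session minimum RMS is 0 (digital silence); "
                      "using smallest positive value for the threshold")
        m = float(positive.min())
    return factor * m


def detect_segments(track: RmsTrack, threshold: float, fs: float,
                    merge_gap_s: float = MERGE_GAP_S,
                    min_dur_s: float = MIN_DUR_S) -> list[CallSegment]:
    """Segments from maximal above-threshold runs of the RMS track.

    A run of window positions ``i0..i1`` maps to the time interval
    ``[t(i0) + w/2, t(i1) + w/2)`` (window-center attribution), which keeps
    boundary errors within half a window at any SNR.
    Runs separated by less than ``merge_gap_s`` are merged; segments
    shorter than ``min_dur_s`` are dropped. Output is sorted and disjoint.
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    above = track.values > threshold
    if not np.any(above):
        return []
    edges = np.diff(above.astype(np.int8))
    run_starts = list(np.flatnonzero(edges == 1) + 1)
    run_ends = list(np.flatnonzero(edges == -1))  # inclusive index
    if above[0]:
        run_starts.insert(0, 0)
    if above[-1]:
        run_ends.append(above.size - 1)
    half_w = track.window_s / 2.0
    hop = track.hop_s
    intervals = [(i0 * hop + half_w, i1 * hop + half_w, i0, i1)
                 for i0, i1 in zip(run_starts, run_ends)]
    merged = [list(intervals[0])]
    for on, off, i0, i1 in intervals[1:]:
        if on - merged[-1][1] < merge_gap_s:
            merged[-1][1] = off
            merged[-1][3] = i1
        else:
            merged.append([on, off, i0, i1])
    out = []
    for on, off, i0, i1 in merged:
        if off - on < min_dur_s:
            continue
        out.append(CallSegment(onset_sample=int(round(on * fs)),
                               offset_sample=int(round(off * fs)), fs=fs,
                               peak_rms=float(track.values[i0:i1 + 1].max())))
    return out


def spectrogram_eligibility(seg: CallSegment,
                            dur_bounds_s: tuple[float, float] = ELIGIBLE_DUR_S) -> bool:
    """Whether a call enters the average spectrogram: voiced and
    100-1500 ms long (unvoiced/combined calls and extreme durations are
    excluded so the onset region stays well represented)."""
    if seg.call_class == "unclassified":
        raise ValueError("segment must be classified first")
    lo, hi = dur_bounds_s
    return seg.call_class == "voiced" and lo <= seg.duration_s <= hi
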