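import numpy as np
import pytest

from isocall import detection, features, voicing
from isocall import synthetic_calls as sc

FS = 44100


@pytest.fixture(scope="session")
def fs():
    return FS


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20251001)


class SegmentStub:
    """Minimal classified-segment stand-in for feature tests."""

    def __init__(self, call_class="voiced", onset_s=0.0, offset_s=0.5):
        self.call_class = call_class
        self.onset_s = onset_s
        self.offset_s = offset_s


@pytest.fixture
def seg_stub():
    return SegmentStub


def analyze_call(wave, fs=FS, expected_f0=features.DEFAULT_EXPECTED_F0_HZ):
    """Shared helper: frame voicing + SIFT + F0/F1 tracks + features."""
    frames = voicing.analyze_frames(wave, fs)
    frames = voicing.sift_correct(frames, wave, fs)
    f0_track = features.estimate_f0_track(wave, frames, fs, expected_f0)
    full = features.estimate_f1_track(wave, f0_track, fs)
    seg = SegmentStub(offset_s=wave.size / fs)
    return features.compute_features(seg, wave, full, fs)


@pytest.fixture(scope="session")
def small_session():
    """One 60-s hearing session with 20 calls and its ground truth."""
    cohort = sc.cohort_preset("hearing", 1.5, 20, seed=424242)
    return sc.assemble_session(cohort, 60.0)


@pytest.fixture(scope="session")
def detected_segments(small_session):
    rec, ann = small_session
    filtered = detection.highpass(rec.samples, rec.fs)
    track = detection.sliding_rms(filtered, rec.fs)
    thr = detection.session_threshold(track)
    segs = detection.detect_segments(track, thr, rec.fs)
    return rec, ann, filtered, segs
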