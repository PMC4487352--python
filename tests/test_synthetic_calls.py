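import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from isocall import synthetic_calls as sc
from isocall import voicing
from isocall.synthetic_calls import CallSpec, CohortSpec


def fft_peaks(wave, fs, n_peaks, lo_hz=200.0):
    """Independent oracle: strongest spectral peaks of a steady waveform."""
    spec = np.abs(np.fft.rfft(wave * np.hanning(wave.size))) ** 2
    freqs = np.fft.rfftfreq(wave.size, 1 / fs)
    spec[freqs < lo_hz] = 0
    peaks = []
    s = spec.copy()
    df = freqs[1] - freqs[0]
    guard = int(200 / df)
    for _ in range(n_peaks):
        k = int(np.argmax(s))
        peaks.append(freqs[k])
        s[max(0, k - guard):k + guard] = 0
    return sorted(peaks)


class TestF0Contour:
    def test_no_sweep_constant(self):
        spec = CallSpec(duration_s=0.5, base_f0=1000, sweep_up=0)
        track = sc.make_f0_contour(spec, 0.010)
        assert np.all(track.f0_hz == 1000.0)

    def test_sweep_peak_value_and_position(self):
        spec = CallSpec(duration_s=0.5, base_f0=900, sweep_up=300,
                        sweep_frac=0.2)
        track = sc.make_f0_contour(spec, 0.001)
        assert track.f0_hz.max() == pytest.approx(1200.0, abs=1.0)
        t_max = track.times_s[np.argmax(track.f0_hz)]
        assert 0 < t_max <= 0.2 * 0.5 + 1e-9
        # returns to base after the sweep and stays there
        after = track.f0_hz[track.times_s > 0.11]
        assert np.allclose(after, 900.0, atol=1e-6)

    def test_zero_crossing_oracle_recovers_contour(self):
        """Integrating the contour as phase and re-measuring instantaneous
        frequency from zero crossings of the pure-F0 sinusoid must give the
        contour back within 2 % at every frame."""
        fs = 44100
        spec = CallSpec(duration_s=0.4, base_f0=1000, sweep_up=200,
                        sweep_frac=0.25)
        t = np.arange(int(0.4 * fs)) / fs
        f0 = sc._sweep_contour(t, spec)
        phase = 2 * np.pi * np.cumsum(f0) / fs
        tone = np.sin(phase)
        zc = np.flatnonzero((tone[:-1] <= 0) & (tone[1:] > 0)) / fs
        periods = np.diff(zc)
        t_mid = zc[:-1] + periods / 2
        f_est = 1.0 / periods
        track = sc.make_f0_contour(spec, 0.010)
        for tc, f_true in zip(track.times_s, track.f0_hz):
            nearby = f_est[np.abs(t_mid - tc) < 0.005]
            assert nearby.size > 0
            assert np.mean(nearby) == pytest.approx(f_true, rel=0.02)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(base=st.floats(700, 1300), sweep=st.floats(0, 300),
           frac=st.floats(0.05, 0.5))
    def test_contour_positive_and_bounded(self, base, sweep, frac):
        spec = CallSpec(duration_s=0.5, base_f0=base, sweep_up=sweep,
                        sweep_frac=frac)
        track = sc.make_f0_contour(spec, 0.005)
        assert np.all(track.f0_hz > 0)
        assert track.f0_hz.max() <= base + sweep + 1e-6
        assert track.f0_hz.min() >= base - 1e-6


class TestVoicedSynthesis:
    def test_pure_tone_single_peak(self, fs):
        spec = CallSpec(duration_s=0.5, base_f0=1000, sweep_up=0,
                        n_harmonics=1, seed=3)
        w = sc.synth_voiced_call(spec, fs)
        steady = w[2205:-2205]
        spec_db = 10 * np.log10(
            np.abs(np.fft.rfft(steady * np.hanning(steady.size))) ** 2 + 1e-30)
        freqs = np.fft.rfftfreq(steady.size, 1 / fs)
        k = np.argmax(spec_db)
        assert abs(freqs[k] - 1000) < 5
        # all bins away from the peak sit at least 40 dB down
        away = np.abs(freqs - 1000) > 100
        assert spec_db[k] - spec_db[away].max() >= 40

    def test_harmonic_stack_peaks(self, fs):
        spec = CallSpec(duration_s=0.5, base_f0=1000, sweep_up=0,
                        n_harmonics=4, seed=3)
        w = sc.synth_voiced_call(spec, fs)
        peaks = fft_peaks(w[2205:-2205], fs, 4)
        assert np.allclose(peaks, [1000, 2000, 3000, 4000], atol=10)

    def test_subharmonic_adds_half_integer_peaks(self, fs):
        spec = CallSpec(duration_s=0.5, base_f0=1000, sweep_up=0,
                        n_harmonics=2, phenomena=("subharmonic",), seed=5)
        w = sc.synth_voiced_call(spec, fs)
        steady = w[2205:-2205]
        p = np.abs(np.fft.rfft(steady * np.hanning(steady.size))) ** 2
        freqs = np.fft.rfftfreq(steady.size, 1 / fs)
        floor = p.max() * 1e-6
        for f_sub in (500, 1500, 2500):
            band = (freqs > f_sub - 30) & (freqs < f_sub + 30)
            assert p[band].max() > floor * 100

    def test_aliasing_guard(self, fs):
        spec = CallSpec(duration_s=0.2, base_f0=6000, sweep_up=0,
                        n_harmonics=4)
        with pytest.raises(ValueError):
            sc.synth_voiced_call(spec, fs)

    def test_rms_matches_level(self, fs):
        spec = CallSpec(duration_s=0.5, base_f0=1000, level_db=70, seed=1)
        w = sc.synth_voiced_call(spec, fs, calibration_db=94.0)
        level = 94.0 + 20 * np.log10(np.sqrt(np.mean(w ** 2)))
        assert level == pytest.approx(70.0, abs=0.1)


class TestUnvoicedSynthesis:
    def test_sample_count(self, fs):
        w = sc.synth_unvoiced_call(0.3, 65, fs, seed=1)
        assert w.size == 13230

    def test_rms_matches_level(self, fs):
        w = sc.synth_unvoiced_call(0.5, 60, fs, seed=2, calibration_db=94.0)
        level = 94.0 + 20 * np.log10(np.sqrt(np.mean(w ** 2)))
        assert level == pytest.approx(60.0, abs=0.1)

    def test_frames_score_unvoiced(self, fs):
        """Purr frames must land far below the 0.6 voicing criterion."""
        n_voiced = 0
        n_frames = 0
        for seed in range(40):
            w = sc.synth_unvoiced_call(0.3, 65, fs, seed=seed)
            frames = voicing.analyze_frames(w, fs)
            n_voiced += sum(f.voiced for f in frames)
            n_frames += len(frames)
        assert n_frames > 1000
        assert n_voiced / n_frames < 0.01


class TestCombinedSynthesis:
    def test_duration_with_crossfade(self, fs):
        u = CallSpec(duration_s=0.2, call_class="unvoiced", seed=1)
        v = CallSpec(duration_s=0.5, base_f0=1000, call_class="voiced", seed=2)
        w, boundary = sc.synth_combined_call([u, v], fs)
        assert 0.69 <= w.size / fs <= 0.70
        assert boundary == pytest.approx(0.195, abs=0.005)

    def test_classifier_flips_near_boundary(self, fs):
        u = CallSpec(duration_s=0.25, call_class="unvoiced", seed=3)
        v = CallSpec(duration_s=0.5, base_f0=1000, sweep_up=0,
                     call_class="voiced", seed=4)
        w, boundary = sc.synth_combined_call([u, v], fs)
        frames = voicing.analyze_frames(w, fs)
        flags = np.array([f.voiced for f in frames])
        # first voiced frame within +-30 ms of the recorded boundary
        t_first_voiced = np.flatnonzero(flags)[0] * 0.010
        assert abs(t_first_voiced - boundary) <= 0.030
        assert voicing.classify_call(flags) == "combined"

    def test_voiced_only_rejected(self, fs):
        v = CallSpec(duration_s=0.5, call_class="voiced")
        with pytest.raises(ValueError):
            sc.synth_combined_call([v, v], fs)


class TestAssembleSession:
    def test_zero_calls_pure_noise(self):
        rec, ann = sc.assemble_session(
            CohortSpec(calls_per_session=0, seed=1), 10.0,
            noise_floor_db=40.0, calibration_db=94.0)
        assert ann == []
        level = 94.0 + 20 * np.log10(np.sqrt(np.mean(rec.samples ** 2)))
        assert level == pytest.approx(40.0, abs=0.5)

    def test_determinism(self):
        cohort = sc.cohort_preset("hearing", 1.5, 10, seed=99)
        rec1, ann1 = sc.assemble_session(cohort, 30.0)
        rec2, ann2 = sc.assemble_session(cohort, 30.0)
        assert np.array_equal(rec1.samples, rec2.samples)
        assert [a.onset_s for a in ann1] == [a.onset_s for a in ann2]

    @pytest.mark.parametrize("seed", range(0, 100, 7))
    def test_min_gap_between_calls(self, seed):
        cohort = sc.cohort_preset("hearing", 1.0, 12, seed=seed)
        _, ann = sc.assemble_session(cohort, 40.0)
        onsets = np.array([a.onset_s for a in ann])
        offsets = np.array([a.offset_s for a in ann])
        assert np.all(np.diff(onsets) > 0)  # sorted
        gaps = onsets[1:] - offsets[:-1]
        assert np.all(gaps >= sc.MIN_GAP_S - 1e-9)

    def test_cannot_pack_raises(self):
        cohort = sc.cohort_preset("hearing", 1.0, 100, seed=1)
        with pytest.raises(ValueError, match="pack"):
            sc.assemble_session(cohort, 10.0)

    def test_harmonic_truth_no_phenomena(self, fs):
        """With no phenomena the generated stack is exactly harmonic:
        the second spectral peak sits at twice the first."""
        spec = CallSpec(duration_s=0.5, base_f0=950, sweep_up=0, seed=11)
        w = sc.synth_voiced_call(spec, fs)
        p1, p2 = fft_peaks(w[2205:-2205], fs, 2)
        assert p2 / p1 == pytest.approx(2.0, abs=0.02)
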