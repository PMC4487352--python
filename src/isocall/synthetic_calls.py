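"""Synthetic kitten-vocalization sessions with known ground truth.

Voiced isolation calls are modelled as harmonic stacks: a fundamental near
1 kHz with harmonics at integer multiples, amplitudes rolling off by 6 dB
per harmonic, short raised-cosine on/off ramps, and an optional
upward/downward FM sweep at call onset (the juvenile call feature that
disappears with age in hearing animals but persists in deaf ones).
Unvoiced calls are purr-like: band-limited noise with a slow (20-30 Hz)
amplitude modulation and no short-lag periodicity. Combined calls start
unvoiced and crossfade into a voiced call. Nonlinear phonation phenomena
are injected on demand: subharmonics (components at half-integer multiples
of F0), frequency jumps (an instantaneous F0 step), and biphonation (a
second, incommensurate harmonic stack).

Cohort presets encode the group/age structure of the study the simulator
emulates: the fundamental declines with age in all groups, deaf animals
call ~10 dB louder, keep the onset FM sweep at 3 months and show more
nonlinear phenomena, and hearing-impaired animals produce more unvoiced
calls. These presets are simulator conventions chosen to reproduce the
qualitative group differences, not measured values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import signal as sps

from .audio_io import (DEFAULT_CALIBRATION_DB, GroundTruthAnnotation,
                       SessionRecording)
from .features import ContourTrack

DEFAULT_FS = 44100
#: dB-per-harmonic amplitude roll-off of the voiced stack
HARMONIC_ROLLOFF_DB = 6.0
#: on/off ramp length of every call (seconds, raised cosine)
RAMP_S = 0.010
#: crossfade between the parts of a combined call (seconds)
CROSSFADE_S = 0.010
#: minimum silent gap between consecutive calls in a session (seconds)
MIN_GAP_S = 0.200
#: purr band and AM rate range
UNVOICED_BAND_HZ = (500.0, 8000.0)
UNVOICED_AM_HZ = (20.0, 30.0)
#: simulator F0 schedule by age (months -> Hz); "near 1 kHz", declining
F0_BY_AGE = {1.0: 1100.0, 1.5: 1000.0, 2.0: 900.0, 3.0: 800.0}
#: representative postnatal day for each age bin
DAY_BY_AGE = {1.0: 32, 1.5: 39, 2.0: 50, 3.0: 80}
PHENOMENA = ("subharmonic", "freq_jump", "biphonation")


@dataclass
class CallSpec:
    """Parameters of one synthetic call."""

    duration_s: float = 0.6
    base_f0: float = 1000.0
    sweep_up: float = 150.0
    sweep_frac: float = 0.2
    n_harmonics: int = 4
    harmonic_amps: Optional[Sequence[float]] = None
    level_db: float = 65.0
    call_class: str = "voiced"
    phenomena: tuple = ()
    #: constant fractional detuning of harmonics >= 2 (F1 sits at
    #: 2*F0*(1+f1_detune)); models a harmonic ratio offset from 2
    f1_detune: float = 0.0
    #: fractional frequency wobble (SD) of harmonics >= 2, a slow random
    #: drift modelling unstable phonation (smeared spectral peaks)
    harmonic_wobble: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.05 <= self.duration_s <= 2.5):
            raise ValueError(f"duration_s out of range: {self.duration_s}")
        if not (0.0 <= self.sweep_frac <= 0.5):
            raise ValueError(f"sweep_frac out of range: {self.sweep_frac}")
        for p in self.phenomena:
            if p not in PHENOMENA:
                raise ValueError(f"unknown phenomenon {p!r}")

    def amps(self) -> np.ndarray:
        if self.harmonic_amps is not None:
            return np.asarray(self.harmonic_amps, dtype=np.float64)
        k = np.arange(self.n_harmonics)
        return 10.0 ** (-HARMONIC_ROLLOFF_DB * k / 20.0)


@dataclass
class CohortSpec:
    """A group x age cohort: the distribution calls are drawn from."""

    group: str = "hearing"
    age_months: float = 1.0
    calls_per_session: int = 40
    f0_by_age: dict = field(default_factory=lambda: dict(F0_BY_AGE))
    level_db: float = 65.0
    level_offset_db: float = 0.0
    level_sd_db: float = 2.0
    f0_sd: float = 40.0
    sweep_up: float = 150.0
    sweep_persistence: bool = False
    #: age (months) at which the onset FM sweep normally disappears
    sweep_gone_age: float = 2.0
    phenomena_prob: float = 0.05
    unvoiced_prob: float = 0.06
    combined_prob: float = 0.05
    harmonic_amp_jitter: float = 0.1
    f1_detune: float = 0.0
    harmonic_wobble: float = 0.004
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.calls_per_session <= 1000):
            raise ValueError("calls_per_session must be in [0, 1000]")
        if self.age_months not in self.f0_by_age:
            raise ValueError(f"age {self.age_months} not in f0_by_age")

    @property
    def base_f0(self) -> float:
        return self.f0_by_age[self.age_months]

    @property
    def sweep_extent(self) -> float:
        """Onset-sweep extent at this age (0 once the sweep has matured away)."""
        if self.sweep_persistence or self.age_months < self.sweep_gone_age:
            return self.sweep_up
        return 0.0


def cohort_preset(group: str, age_months: float, calls_per_session: int = 40,
                  seed: int = 0, **overrides) -> CohortSpec:
    """Group presets encoding the simulated study conditions.

    deaf: +10 dB level, persistent onset sweep, extra nonlinear phenomena;
    impaired: more unvoiced calls, larger harmonic-amplitude jitter, sweep
    matures late (gone only at 3 months); hearing: baseline.
    """
    kw: dict = dict(group=group, age_months=age_months,
                    calls_per_session=calls_per_session, seed=seed)
    if group == "deaf":
        kw.update(level_offset_db=10.0, sweep_persistence=True,
                  phenomena_prob=0.3, harmonic_amp_jitter=0.2,
                  unvoiced_prob=0.08, f1_detune=0.01, harmonic_wobble=0.015)
    elif group == "impaired":
        kw.update(unvoiced_prob=0.2, combined_prob=0.1,
                  harmonic_amp_jitter=0.25, sweep_gone_age=3.0,
                  harmonic_wobble=0.006)
    elif group != "hearing":
        raise ValueError(f"unknown group {group!r}")
    kw.update(overrides)
    return CohortSpec(**kw)


def _sweep_contour(t: np.ndarray, spec: CallSpec) -> np.ndarray:
    """Instantaneous F0 (Hz) at times ``t`` seconds from call onset."""
    f0 = np.full(t.shape, spec.base_f0, dtype=np.float64)
    t_sweep = spec.sweep_frac * spec.duration_s
    if spec.sweep_up > 0 and t_sweep > 0:
        in_sweep = t < t_sweep
        f0[in_sweep] += spec.sweep_up * 0.5 * (
            1.0 - np.cos(2.0 * np.pi * t[in_sweep] / t_sweep))
    return f0


def make_f0_contour(spec: CallSpec, frame_dt: float) -> ContourTrack:
    """Ground-truth F0 contour sampled every ``frame_dt`` seconds.

    The contour rises from ``base_f0`` by ``sweep_up`` and returns within
    the first ``sweep_frac`` of the call (raised-cosine bump, maximum at
    the midpoint of the sweep), then holds ``base_f0``.
    """
    if frame_dt <= 0:
        raise ValueError("frame_dt must be positive")
    times = np.arange(frame_dt / 2, spec.duration_s, frame_dt)
    return ContourTrack(times_s=times, f0_hz=_sweep_contour(times, spec))


def _ramp(wave: np.ndarray, fs: float, ramp_s: float = RAMP_S) -> np.ndarray:
    n = min(int(round(ramp_s * fs)), wave.size // 2)
    if n > 0:
        env = 0.5 * (1.0 - np.cos(np.pi * np.arange(n) / n))
        wave[:n] *= env
        wave[-n:] *= env[::-1]
    return wave


def _scale_to_level(wave: np.ndarray, level_db: float,
                    calibration_db: float) -> np.ndarray:
    rms = np.sqrt(np.mean(wave ** 2))
    if rms == 0:
        return wave
    target = 10.0 ** ((level_db - calibration_db) / 20.0)
    return wave * (target / rms)


def synth_voiced_call(spec: CallSpec, fs: float = DEFAULT_FS,
                      calibration_db: float = DEFAULT_CALIBRATION_DB) -> np.ndarray:
    """Render one voiced call as a harmonic stack with optional phenomena."""
    if spec.call_class != "voiced":
        raise ValueError("synth_voiced_call needs call_class='voiced'")
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration_s * fs))
    t = np.arange(n) / fs
    f0 = _sweep_contour(t, spec)
    if "freq_jump" in spec.phenomena:
        # instantaneous F0 step at a random interior time
        t_jump = rng.uniform(0.3, 0.8) * spec.duration_s
        factor = rng.choice([1.0 / 1.15, 1.15])
        f0 = np.where(t >= t_jump, f0 * factor, f0)
    if spec.n_harmonics * f0.max() * (1 + spec.f1_detune
                                      + 3 * spec.harmonic_wobble) >= fs / 2:
        raise ValueError("harmonic stack would alias: lower n_harmonics or F0")
    phase = 2.0 * np.pi * np.cumsum(f0) / fs
    amps = spec.amps()
    wobble = np.zeros(n)
    if spec.harmonic_wobble > 0 and n > 64:
        # slow (<20 Hz) drift of the upper harmonics' relative frequency:
        # slow against the 10-ms analysis frame, fast enough that every
        # call samples many independent excursions
        sos = sps.butter(2, min(20.0, fs / 8), btype="lowpass", fs=fs,
                         output="sos")
        raw = sps.sosfiltfilt(sos, rng.standard_normal(n))
        sd = raw.std()
        if sd > 0:
            wobble = spec.harmonic_wobble * raw / sd
    wave = amps[0] * np.sin(phase + rng.uniform(0, 2 * np.pi))
    for k in range(2, spec.n_harmonics + 1):
        f_k = k * f0 * (1.0 + spec.f1_detune + wobble)
        phase_k = 2.0 * np.pi * np.cumsum(f_k) / fs
        wave += amps[k - 1] * np.sin(phase_k + rng.uniform(0, 2 * np.pi))
    if "subharmonic" in spec.phenomena:
        # components at half-integer multiples of F0 interleave the stack;
        # their strength varies from call to call and can rival the second
        # harmonic, which is what perturbs the measured harmonic ratio
        sub_amp = rng.uniform(0.2, 0.5)
        for m in (1, 3, 5):
            if m / 2.0 * f0.max() < fs / 2:
                wave += sub_amp * np.sin(m / 2.0 * phase +
                                         rng.uniform(0, 2 * np.pi))
    if "biphonation" in spec.phenomena:
        # second, independent stack at an incommensurate fundamental
        ratio = rng.uniform(1.17, 1.28)
        amp_bi = rng.uniform(0.3, 0.6)
        phase2 = phase * ratio
        for k in range(1, 3):
            if k * ratio * f0.max() < fs / 2:
                wave += amp_bi * 10.0 ** (-HARMONIC_ROLLOFF_DB * (k - 1) / 20.0) \
                    * np.sin(k * phase2 + rng.uniform(0, 2 * np.pi))
    wave = _ramp(wave, fs)
    return _scale_to_level(wave, spec.level_db, calibration_db)


def synth_unvoiced_call(duration_s: float, level_db: float, fs: float = DEFAULT_FS,
                        seed: int = 0,
                        calibration_db: float = DEFAULT_CALIBRATION_DB) -> np.ndarray:
    """Purr-like unvoiced call: 0.5-8 kHz noise with 20-30 Hz AM.

    The noise band is wide enough that the autocorrelation decays well
    before the shortest lag in the voicing search range, so frames of this
    call score far below the 0.6 voicing threshold.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    noise = rng.standard_normal(n)
    sos = sps.butter(4, UNVOICED_BAND_HZ, btype="bandpass", fs=fs, output="sos")
    noise = sps.sosfiltfilt(sos, noise)
    f_am = rng.uniform(*UNVOICED_AM_HZ)
    t = np.arange(n) / fs
    wave = noise * (1.0 + 0.6 * np.sin(2.0 * np.pi * f_am * t +
                                       rng.uniform(0, 2 * np.pi)))
    wave = _ramp(wave, fs)
    return _scale_to_level(wave, level_db, calibration_db)


def synth_combined_call(specs: Sequence[CallSpec], fs: float = DEFAULT_FS,
                        calibration_db: float = DEFAULT_CALIBRATION_DB
                        ) -> tuple[np.ndarray, float]:
    """Unvoiced beginning crossfaded into a voiced call.

    ``specs`` must be exactly one unvoiced spec followed by one voiced
    spec. Returns ``(waveform, boundary_s)`` with the class switch time at
    the middle of the 10-ms crossfade, seconds from call onset.
    """
    if len(specs) != 2 or specs[0].call_class != "unvoiced" \
            or specs[1].call_class != "voiced":
        raise ValueError("need exactly [unvoiced, voiced] call specs")
    u = synth_unvoiced_call(specs[0].duration_s, specs[0].level_db, fs,
                            seed=specs[0].seed, calibration_db=calibration_db)
    v = synth_voiced_call(specs[1], fs, calibration_db)
    n_x = int(round(CROSSFADE_S * fs))
    n_total = u.size + v.size - n_x
    wave = np.zeros(n_total)
    fade = 0.5 * (1.0 - np.cos(np.pi * np.arange(n_x) / n_x))
    wave[:u.size] = u
    wave[u.size - n_x:u.size] = u[-n_x:] * (1.0 - fade) + v[:n_x] * fade
    wave[u.size:] = v[n_x:]
    boundary_s = (u.size - n_x / 2.0) / fs
    return wave, boundary_s


def _draw_call(cohort: CohortSpec, rng: np.random.Generator, seed: int,
               fs: float, calibration_db: float
               ) -> tuple[np.ndarray, str, CallSpec | None, tuple, float]:
    """One call drawn from the cohort distribution.

    Returns (waveform, call_class, voiced_spec_or_None, phenomena, boundary_s).
    """
    u = rng.random()
    level = cohort.level_db + cohort.level_offset_db + \
        rng.normal(0.0, cohort.level_sd_db)
    if u < cohort.unvoiced_prob:
        dur = rng.uniform(0.3, 0.8)
        wave = synth_unvoiced_call(dur, level, fs, seed=seed,
                                   calibration_db=calibration_db)
        return wave, "unvoiced", None, (), float("nan")
    phenomena: tuple = ()
    if rng.random() < cohort.phenomena_prob:
        phenomena = (str(rng.choice(PHENOMENA)),)
    base_f0 = cohort.base_f0 + rng.normal(0.0, cohort.f0_sd)
    amps = np.asarray(CallSpec(base_f0=base_f0).amps())
    jitter = cohort.harmonic_amp_jitter
    if jitter > 0:
        amps = amps * np.exp(rng.normal(0.0, jitter, size=amps.size))
    vspec = CallSpec(duration_s=float(rng.uniform(0.3, 1.2)), base_f0=base_f0,
                     sweep_up=cohort.sweep_extent, sweep_frac=0.2,
                     harmonic_amps=amps, level_db=level,
                     call_class="voiced", phenomena=phenomena,
                     f1_detune=cohort.f1_detune,
                     harmonic_wobble=cohort.harmonic_wobble, seed=seed)
    if u < cohort.unvoiced_prob + cohort.combined_prob:
        uspec = CallSpec(duration_s=float(rng.uniform(0.15, 0.4)),
                         level_db=level, call_class="unvoiced", seed=seed + 1)
        wave, boundary = synth_combined_call([uspec, vspec], fs, calibration_db)
        return wave, "combined", vspec, phenomena, boundary
    wave = synth_voiced_call(vspec, fs, calibration_db)
    return wave, "voiced", vspec, phenomena, float("nan")


def assemble_session(cohort: CohortSpec, session_len_s: float = 120.0,
                     noise_floor_db: float = 40.0, fs: float = DEFAULT_FS,
                     calibration_db: float = DEFAULT_CALIBRATION_DB
                     ) -> tuple[SessionRecording, list[GroundTruthAnnotation]]:
    """Render a full session: calls at random non-overlapping onsets over a
    white noise floor, with sorted ground-truth annotations.

    Deterministic for a fixed ``cohort.seed``: per-call seeds are spawned
    from the master seed with a counter scheme, so each call is also
    reproducible in isolation.
    """
    master = np.random.default_rng(cohort.seed)
    call_seed_base = int(master.integers(0, 2 ** 31 - 10000))
    calls = []
    for i in range(cohort.calls_per_session):
        calls.append(_draw_call(cohort, master, call_seed_base + 2 * i, fs,
                                calibration_db))
    durations = np.array([c[0].size / fs for c in calls])
    n_calls = len(calls)
    slack = session_len_s - durations.sum() - MIN_GAP_S * (n_calls + 1)
    if slack < 0:
        raise ValueError(
            f"cannot pack {n_calls} calls ({durations.sum():.1f} s) plus "
            f"gaps into {session_len_s} s")
    extra = master.random(n_calls + 1)
    extra = extra / extra.sum() * slack
    onsets = []
    t = 0.0
    for i in range(n_calls):
        t += MIN_GAP_S + extra[i]
        onsets.append(t)
        t += durations[i]
    n_total = int(round(session_len_s * fs))
    noise_rms = 10.0 ** ((noise_floor_db - calibration_db) / 20.0)
    samples = master.standard_normal(n_total) * noise_rms
    annotations = []
    for (wave, cls, vspec, phenomena, boundary), onset in zip(calls, onsets):
        i0 = int(round(onset * fs))
        samples[i0:i0 + wave.size] += wave
        annotations.append(GroundTruthAnnotation(
            onset_s=i0 / fs, offset_s=(i0 + wave.size) / fs, call_class=cls,
            base_f0=vspec.base_f0 if vspec is not None else float("nan"),
            sweep_up=vspec.sweep_up if vspec is not None else 0.0,
            sweep_dur_s=(vspec.sweep_frac * vspec.duration_s
                         if vspec is not None else 0.0),
            phenomena=phenomena, boundary_s=boundary))
    peak = np.max(np.abs(samples))
    if peak > 1.0:  # guard full scale; preserves relative levels
        samples /= peak * 1.01
    rec = SessionRecording(
        samples=samples, fs=int(fs), calibration_db=calibration_db,
        animal_id=f"{cohort.group}_sim", group=cohort.group,
        postnatal_day=DAY_BY_AGE.get(cohort.age_months, 32),
        session_id=f"{cohort.group}_{cohort.age_months}m_seed{cohort.seed}")
    return rec, annotations
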