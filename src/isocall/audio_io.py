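"""Session audio and table I/O.

Conventions used throughout the package:

* amplitudes are dimensionless full-scale values in [-1, 1];
* a single per-session calibration constant ``calibration_db`` gives the
  sound pressure level (dB SPL) that corresponds to an RMS of 1.0, so
  ``level_db = calibration_db + 20*log10(rms)``;
* all times are seconds from session start; sample index ``i`` covers the
  half-open interval ``[i/fs, (i+1)/fs)``;
* frequencies are Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.io import wavfile

#: default SPL at full-scale RMS; recordings made with a calibrated
#: measurement chain should override this per session.
DEFAULT_CALIBRATION_DB = 94.0

GROUPS = ("hearing", "impaired", "deaf")
CALL_CLASSES = ("voiced", "unvoiced", "combined")


class AudioError(Exception):
    """Base class for audio-loading problems."""


class UnsupportedAudioError(AudioError):
    """Encoding or channel layout the pipeline does not accept."""


class EmptyAudioError(AudioError):
    """A WAV file with zero samples."""


@dataclass
class SessionRecording:
    """One recording session: waveform plus calibration and metadata."""

    samples: np.ndarray
    fs: int
    calibration_db: float = DEFAULT_CALIBRATION_DB
    animal_id: str = ""
    group: str = "hearing"
    postnatal_day: int = 30
    session_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.samples.ndim != 1:
            raise UnsupportedAudioError("only mono audio is supported")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples contain non-finite values")
        if self.samples.size and np.max(np.abs(self.samples)) > 1.0 + 1e-9:
            raise ValueError("samples exceed full scale (+-1.0)")
        if not (1 <= self.postnatal_day <= 365):
            raise ValueError(f"postnatal_day out of range: {self.postnatal_day}")
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}; expected one of {GROUPS}")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs


@dataclass
class GroundTruthAnnotation:
    """Simulator-emitted truth for one call (consumed by tests only)."""

    onset_s: float
    offset_s: float
    call_class: str
    base_f0: float = float("nan")
    sweep_up: float = 0.0
    sweep_dur_s: float = 0.0
    phenomena: tuple = ()
    #: unvoiced->voiced switch time for combined calls, seconds from onset
    boundary_s: float = float("nan")

    def __post_init__(self) -> None:
        if not (0.0 <= self.onset_s < self.offset_s):
            raise ValueError("need 0 <= onset_s < offset_s")
        if self.call_class not in CALL_CLASSES:
            raise ValueError(f"unknown call class {self.call_class!r}")


def load_session(path, *, calibration_db: float = DEFAULT_CALIBRATION_DB,
                 animal_id: str = "", group: str = "hearing",
                 postnatal_day: int = 30, session_id: str = "") -> SessionRecording:
    """Read a mono PCM16/PCM32/float WAV file into a :class:`SessionRecording`.

    Integer encodings are normalized to full scale +-1.0. Raises
    ``FileNotFoundError`` for a missing file, :class:`UnsupportedAudioError`
    for stereo or exotic encodings and :class:`EmptyAudioError` for a file
    with no samples.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        fs, data = wavfile.read(str(path))
    except FileNotFoundError:
        raise
    except Exception as exc:  # wavfile raises bare ValueError on bad chunks
        raise UnsupportedAudioError(f"cannot decode {path}: {exc}") from exc
    if data.ndim != 1:
        raise UnsupportedAudioError(f"{path}: expected mono, got shape {data.shape}")
    if data.size == 0:
        raise EmptyAudioError(f"{path}: zero-length audio")
    if data.dtype == np.int16:
        samples = data.astype(np.float64) / 32768.0
    elif data.dtype == np.int32:
        samples = data.astype(np.float64) / 2147483648.0
    elif data.dtype == np.uint8:
        samples = (data.astype(np.float64) - 128.0) / 128.0
    elif data.dtype in (np.float32, np.float64):
        samples = data.astype(np.float64)
    else:
        raise UnsupportedAudioError(f"{path}: unsupported sample dtype {data.dtype}")
    return SessionRecording(samples=samples, fs=int(fs),
                            calibration_db=calibration_db, animal_id=animal_id,
                            group=group, postnatal_day=postnatal_day,
                            session_id=session_id or path.stem)


def save_wav(path, samples: np.ndarray, fs: int, encoding: str = "pcm16") -> None:
    """Write mono audio as RIFF WAV (``pcm16`` or ``float32``)."""
    samples = np.asarray(samples, dtype=np.float64)
    if samples.ndim != 1:
        raise UnsupportedAudioError("only mono audio is supported")
    if encoding == "pcm16":
        scaled = np.clip(np.round(samples * 32768.0), -32768, 32767).astype(np.int16)
        wavfile.write(str(path), int(fs), scaled)
    elif encoding == "float32":
        wavfile.write(str(path), int(fs), samples.astype(np.float32))
    else:
        raise UnsupportedAudioError(f"unsupported encoding {encoding!r}")


#: stable column order of the per-call feature table. Units are carried in
#: the column names: _s seconds, _db dB SPL, _hz Hz; hr_* are dimensionless.
FEATURE_COLUMNS = (
    "call_id", "onset_s", "offset_s", "duration_s", "level_db", "call_class",
    "f0_mean_hz", "f0_max_hz", "f0_sd_hz", "t_f0max_s",
    "hr_mean", "hr_sd", "hr_max", "t_hrmax_s", "hr_at_f0max",
)


def write_call_table(features: Sequence, path) -> None:
    """Write per-call features as CSV, one row per call.

    Numeric fields survive a write/read round trip to 6 significant digits.
    """
    if len(features) == 0:
        raise ValueError("refusing to write an empty call table")
    rows = []
    for i, f in enumerate(features):
        d = f if isinstance(f, dict) else asdict(f)
        d.setdefault("call_id", i)
        rows.append(d)
    frame = pd.DataFrame(rows)
    cols = [c for c in FEATURE_COLUMNS if c in frame.columns]
    cols += [c for c in frame.columns if c not in cols]
    frame[cols].to_csv(path, index=False, float_format="%.6g")


def read_call_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


ANNOTATION_COLUMNS = ("onset_s", "offset_s", "call_class", "base_f0",
                      "sweep_up", "sweep_dur_s", "phenomena", "boundary_s")


def write_annotations(annotations: Sequence[GroundTruthAnnotation], path) -> None:
    """Write simulator ground truth as CSV (phenomena joined with ``+``)."""
    rows = [{**asdict(a), "phenomena": "+".join(a.phenomena)} for a in annotations]
    frame = pd.DataFrame(rows, columns=list(ANNOTATION_COLUMNS))
    frame.to_csv(path, index=False, float_format="%.6g")


def read_annotations(path) -> list[GroundTruthAnnotation]:
    frame = pd.read_csv(path, keep_default_na=False, na_values=["nan", ""])
    out = []
    for _, row in frame.iterrows():
        phen = row.get("phenomena", "")
        phen = tuple(p for p in str(phen).split("+") if p) if isinstance(phen, str) else ()
        out.append(GroundTruthAnnotation(
            onset_s=float(row["onset_s"]), offset_s=float(row["offset_s"]),
            call_class=str(row["call_class"]), base_f0=float(row["base_f0"]),
            sweep_up=float(row["sweep_up"]), sweep_dur_s=float(row["sweep_dur_s"]),
            phenomena=phen, boundary_s=float(row["boundary_s"])))
    return out
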