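"""End-to-end orchestration: synth -> detect -> classify -> features -> stats.

All tunables live in a single :class:`PipelineConfig` that round-trips
through YAML; every source of randomness flows from one master seed. The
whole-session analysis path (:func:`analyze_session`) is the production
surface: it returns per-call features for one recording, and
:func:`run_pipeline` maps it over a synthetic cohort grid (or a set of WAV
files), writing the feature tables, session summaries, grand means, the
developmental comparison table and a manifest.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import detection, features, group_stats, spectral, synthetic_calls, voicing
from .audio_io import (DEFAULT_CALIBRATION_DB, SessionRecording, load_session,
                       write_call_table)


@dataclass
class PipelineConfig:
    """Every tunable of the pipeline, with study defaults."""

    # detection
    hp_cutoff_hz: float = detection.HP_CUTOFF_HZ
    hp_order: int = detection.HP_ORDER
    rms_window_s: float = detection.RMS_WINDOW_S
    rms_hop_s: float = detection.RMS_HOP_S
    threshold_factor: float = detection.THRESHOLD_FACTOR
    merge_gap_s: float = detection.MERGE_GAP_S
    min_dur_s: float = detection.MIN_DUR_S
    # voicing
    voicing_threshold: float = voicing.VOICING_THRESHOLD
    voicing_f_lo_hz: float = voicing.VOICING_F_RANGE_HZ[0]
    voicing_f_hi_hz: float = voicing.VOICING_F_RANGE_HZ[1]
    lpc_order: int = voicing.LPC_ORDER
    # tracking / features
    expected_f0_max_hz: float = features.DEFAULT_EXPECTED_F0_HZ
    f0_band_frac: float = features.F0_BAND_FRAC
    stft_nfft: int = spectral.STFT_NFFT
    stft_overlap: float = spectral.STFT_OVERLAP
    # calibration & statistics
    calibration_db: float = DEFAULT_CALIBRATION_DB
    alpha: float = group_stats.ALPHA
    alpha_normality: float = group_stats.ALPHA_NORMALITY
    # synthetic-study layout
    seed: int = 0
    groups: tuple = ("hearing", "impaired", "deaf")
    ages_months: tuple = (1.0, 1.5, 2.0, 3.0)
    sessions_per_cell: int = 8
    calls_per_session: int = 40
    session_len_s: float = 120.0
    noise_floor_db: float = 40.0
    fs: int = synthetic_calls.DEFAULT_FS

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["groups"] = list(d["groups"])
        d["ages_months"] = list(d["ages_months"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("groups", "ages_months"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=list)
            .encode()).hexdigest()[:16]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and offending input."""

    def __init__(self, stage: str, item: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed on {item!r}: {cause}")
        self.stage = stage
        self.item = item


def analyze_session(rec: SessionRecording,
                    config: Optional[PipelineConfig] = None) -> pd.DataFrame:
    """Full single-session analysis: detection, per-frame voicing with SIFT
    correction, call classification, F0/F1 tracking and feature extraction.

    Returns one row per detected call. F0/harmonic-ratio fields are NaN for
    calls that are not voiced or that yield too few valid frames.
    """
    cfg = config or PipelineConfig()
    filtered = detection.highpass(rec.samples, rec.fs, cfg.hp_cutoff_hz,
                                  cfg.hp_order)
    track = detection.sliding_rms(filtered, rec.fs, cfg.rms_window_s,
                                  cfg.rms_hop_s)
    threshold = detection.session_threshold(track, cfg.threshold_factor)
    segments = detection.detect_segments(track, threshold, rec.fs,
                                         cfg.merge_gap_s, cfg.min_dur_s)
    f_range = (cfg.voicing_f_lo_hz, cfg.voicing_f_hi_hz)
    rows = []
    for i, seg in enumerate(segments):
        chunk = filtered[seg.onset_sample:seg.offset_sample]
        frames = voicing.analyze_frames(chunk, rec.fs, t0_s=0.0,
                                        f_range_hz=f_range,
                                        thresh=cfg.voicing_threshold)
        if not frames:
            continue
        frames = voicing.sift_correct(frames, chunk, rec.fs, cfg.lpc_order,
                                      f_range, cfg.voicing_threshold)
        flags = [f.voiced for f in frames]
        seg.frame_flags = np.asarray(flags)
        seg.call_class = voicing.classify_call(flags)
        rms = float(np.sqrt(np.mean(chunk ** 2)))
        level = rec.calibration_db + 20.0 * np.log10(rms) if rms > 0 else float("nan")
        row = {"call_id": i, "onset_s": seg.onset_s, "offset_s": seg.offset_s,
               "duration_s": seg.duration_s, "level_db": level,
               "call_class": seg.call_class, "peak_rms": seg.peak_rms}
        if seg.call_class in ("voiced", "combined") and any(flags):
            try:
                f0_track = features.estimate_f0_track(
                    chunk, frames, rec.fs, cfg.expected_f0_max_hz,
                    cfg.f0_band_frac)
                full = features.estimate_f1_track(chunk, f0_track, rec.fs)
                feats = features.compute_features(
                    seg, chunk, full, rec.fs, rec.calibration_db)
                row.update({k: v for k, v in asdict(feats).items()
                            if k not in ("onset_s", "offset_s", "duration_s",
                                         "level_db", "call_class")})
            except features.FeatureError:
                pass
        rows.append(row)
    cols = ["call_id", "onset_s", "offset_s", "duration_s", "level_db",
            "call_class", "peak_rms", "f0_mean_hz", "f0_max_hz", "f0_sd_hz",
            "t_f0max_s", "hr_mean", "hr_sd", "hr_max", "t_hrmax_s",
            "hr_at_f0max"]
    frame = pd.DataFrame(rows)
    for c in cols:
        if c not in frame.columns:
            frame[c] = np.nan
    return frame[cols] if len(frame) else pd.DataFrame(columns=cols)


def synthetic_study_sessions(config: PipelineConfig):
    """Yield (SessionRecording, annotations) over the configured cohort grid."""
    seed_seq = np.random.SeedSequence(config.seed)
    n_cells = len(config.groups) * len(config.ages_months) * config.sessions_per_cell
    seeds = seed_seq.generate_state(n_cells) % (2 ** 31 - 1)
    i = 0
    for group in config.groups:
        for age in config.ages_months:
            for _ in range(config.sessions_per_cell):
                cohort = synthetic_calls.cohort_preset(
                    group, age, config.calls_per_session, seed=int(seeds[i]))
                i += 1
                yield synthetic_calls.assemble_session(
                    cohort, config.session_len_s, config.noise_floor_db,
                    config.fs, config.calibration_db)


def run_pipeline(config: PipelineConfig, out_dir,
                 wav_paths: Optional[Sequence] = None,
                 metadata: Optional[pd.DataFrame] = None) -> Path:
    """Run the study end to end and write all outputs under ``out_dir``.

    Without ``wav_paths`` a synthetic study is generated from the config's
    cohort grid. With ``wav_paths``, ``metadata`` must carry one row per
    file (columns: path, animal_id, group, postnatal_day). Outputs:
    ``features/<session>.csv``, ``session_summaries.csv``,
    ``grand_means.csv``, ``developmental_table.csv``, ``manifest.json``.
    """
    out = Path(out_dir)
    (out / "features").mkdir(parents=True, exist_ok=True)

    def iter_sessions():
        # sessions are generated/loaded lazily: a full study would not fit
        # in memory all at once
        if wav_paths is None:
            yield from synthetic_study_sessions(config)
            return
        meta = metadata if metadata is not None else pd.DataFrame()
        for p in wav_paths:
            row = {}
            if len(meta):
                match = meta[meta["path"].astype(str) == str(p)]
                if len(match):
                    row = match.iloc[0].to_dict()
            try:
                rec = load_session(p,
                                   calibration_db=config.calibration_db,
                                   animal_id=str(row.get("animal_id", "")),
                                   group=str(row.get("group", "hearing")),
                                   postnatal_day=int(row.get("postnatal_day", 30)))
            except Exception as exc:
                raise StageError("load", str(p), exc) from exc
            yield rec, None

    summaries = []
    n_sessions = 0
    n_calls_total = 0
    n_annotated = 0
    for rec, ann in iter_sessions():
        n_sessions += 1
        try:
            feats = analyze_session(rec, config)
        except Exception as exc:
            raise StageError("analyze", rec.session_id, exc) from exc
        n_calls_total += len(feats)
        n_annotated += len(ann) if ann is not None else 0
        if len(feats) == 0:
            warnings.warn(f"session {rec.session_id}: no calls detected; "
                          "excluded from summaries")
            continue
        write_call_table(feats.to_dict("records"),
                         out / "features" / f"{rec.session_id}.csv")
        summaries.append(group_stats.summarize_session(
            feats, {"session_id": rec.session_id, "animal_id": rec.animal_id,
                    "group": rec.group, "postnatal_day": rec.postnatal_day}))
    summary_df = group_stats.summaries_frame(summaries)
    summary_df.to_csv(out / "session_summaries.csv", index=False,
                      float_format="%.6g")
    group_stats.grand_means(summary_df).to_csv(out / "grand_means.csv",
                                               float_format="%.6g")
    try:
        dev = group_stats.developmental_table(summary_df)
    except ValueError:
        dev = pd.DataFrame()
    dev.to_csv(out / "developmental_table.csv", index=False,
               float_format="%.6g")
    config.to_yaml(out / "config.yaml")
    manifest = {"config_sha256": config.digest(),
                "n_sessions": n_sessions,
                "n_sessions_with_calls": len(summaries),
                "n_detected_calls": int(n_calls_total),
                "n_annotated_calls": int(n_annotated)}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
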