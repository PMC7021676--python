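"""Run-configuration schema and pipeline orchestration.

A single YAML config (validated by pydantic) drives the whole chain:
simulate -> segment -> localize -> dynamics -> respond.  A master seed
deterministically derives one child seed per stage, so one integer
reproduces an entire run byte for byte.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator

from . import io as sio
from .audio import read_wav, synthesize_audio, write_wav
from .dynamics import (
    emission_distance_stats,
    emission_timeline,
    interanimal_distance,
    proximity_profile,
    time_to_fraction_emitted,
)
from .localization import attribute_signal
from .response import analyze_responses
from .segmentation import SegmentationParams, score_detections, segment_audio
from .simulate import ArenaConfig, BehaviorParams, inject_response_kick, simulate_dyad

logger = logging.getLogger(__name__)

STAGES = ("simulate", "segment", "localize", "dynamics", "respond")


class ArenaSection(BaseModel):
    side_length: float = 76.0
    frame_rate: float = 30.0
    duration: float = 30.0
    audio_rate: float = 250_000.0


class BehaviorSection(BaseModel):
    context: Literal["same_sex", "opposite_sex"] = "same_sex"
    attraction_strength: float = 0.05
    attraction_onset: float = 0.0
    mean_speed: float = 8.0
    speed_sd: float = 2.0
    speed_tau: float = 180.0
    heading_noise: float = 0.35
    emission_hazard_near: float = Field(0.005, ge=0.0, le=1.0)
    emission_hazard_far: float = Field(1e-4, ge=0.0, le=1.0)
    near_threshold: float = Field(20.0, gt=0.0)
    kick_magnitude: float = 0.0
    kick_window: int = Field(5, ge=1)


class SegmentationSection(BaseModel):
    band_low_khz: float = 30.0
    band_high_khz: float = 110.0
    n_tapers: int = 5
    time_bandwidth: float = 3.0
    nfft_list: list[int] = [64, 128, 256]
    ftest_alpha: float = 0.05
    box_freq: int = 11
    box_time: int = 15
    min_pixels: int = 1500
    min_channels: int = 5

    def to_params(self) -> SegmentationParams:
        return SegmentationParams(
            band=(self.band_low_khz * 1e3, self.band_high_khz * 1e3),
            n_tapers=self.n_tapers,
            time_bandwidth=self.time_bandwidth,
            nfft_list=tuple(self.nfft_list),
            ftest_alpha=self.ftest_alpha,
            box=(self.box_freq, self.box_time),
            min_pixels=self.min_pixels,
            min_channels=self.min_channels,
        )


class RunConfig(BaseModel):
    """Schema-validated run configuration with the standard defaults
    (20 cm proximity, 0.95 MPI threshold, 1500 px, 30-110 kHz, alpha
    0.05, 1000 subsample reps at 25%)."""

    outdir: str = "run"
    seed: int = 0
    stages: list[str] = list(STAGES)
    snr_db: float = 20.0
    mpi_threshold: float = 0.95
    proximity_cm: float = 20.0
    alpha: float = 0.05
    subsample_reps: int = 1000
    subsample_fraction: float = 0.25
    respond_mode: Literal["isolated", "all", "epochs"] = "isolated"
    use_truth_events: bool = False
    arena: ArenaSection = ArenaSection()
    behavior: BehaviorSection = BehaviorSection()
    segmentation: SegmentationSection = SegmentationSection()

    @field_validator("stages")
    @classmethod
    def _known_stages(cls, v: list[str]) -> list[str]:
        for s in v:
            if s not in STAGES:
                raise ValueError(f"unknown stage {s!r}")
        return v

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.model_validate(yaml.safe_load(fh) or {})


def _child_seeds(master: int, n: int = len(STAGES)) -> list[int]:
    ss = np.random.SeedSequence(master)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(f"stage '{stage}' needs missing input: {path}")
    return path


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages and return the run report (also
    written to <outdir>/report.json)."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = dict(zip(STAGES, _child_seeds(config.seed)))
    report: dict = {"seed": config.seed, "stage_seeds": seeds,
                    "config": json.loads(config.model_dump_json())}

    arena = ArenaConfig(
        side_length=config.arena.side_length,
        frame_rate=config.arena.frame_rate,
        duration=config.arena.duration,
        audio_rate=config.arena.audio_rate,
    )

    if "simulate" in config.stages:
        behavior = BehaviorParams(**config.behavior.model_dump())
        tracks, truth = simulate_dyad(arena, behavior, seeds["simulate"])
        if behavior.kick_magnitude != 0.0:
            tracks = inject_response_kick(
                tracks, truth.events, behavior.kick_magnitude, behavior.kick_window, arena
            )
            truth.tracks = tracks
        sio.write_tracks_csv(out / "tracks.csv", tracks)
        sio.write_truth_events_csv(out / "truth_events.csv", truth.events)
        audio = synthesize_audio(truth.events, arena, config.snr_db, seeds["simulate"] + 1)
        write_wav(out / "audio.wav", audio)
        report["simulate"] = {"n_frames": tracks.n_frames, "n_true_events": len(truth.events)}
        _truth_events = truth.events
    else:
        _truth_events = None

    if "segment" in config.stages:
        audio = read_wav(_require(out / "audio.wav", "segment"))
        params = config.segmentation.to_params()
        signals = segment_audio(audio, params)
        sio.write_signals_csv(out / "signals.csv", out / "contours.csv", signals)
        report["segment"] = {"n_signals": len(signals)}
        if _truth_events is not None:
            report["segment"].update(
                {k: v for k, v in score_detections(signals, _truth_events).items()
                 if k in ("recall", "precision")}
            )

    if "localize" in config.stages:
        audio = read_wav(_require(out / "audio.wav", "localize"))
        signals = sio.read_signals_csv(
            _require(out / "signals.csv", "localize"), _require(out / "contours.csv", "localize")
        )
        tracks = sio.read_tracks_csv(_require(out / "tracks.csv", "localize"), arena.frame_rate)
        rows = []
        for i, sig in enumerate(signals):
            mid = 0.5 * (sig.start_time + sig.stop_time)
            f = min(int(mid * arena.frame_rate), tracks.n_frames - 1)
            noses = tracks.nose[f]
            jack, mpi = attribute_signal(sig, audio, arena, noses)
            rows.append(
                {
                    "signal_id": i,
                    "time_s": sig.start_time,
                    "mpi_mouse1": mpi.MPI[0],
                    "mpi_mouse2": mpi.MPI[1],
                    "assigned_to": mpi.assigned_to if mpi.assigned_to is not None else np.nan,
                    "est_x_cm": jack.mean_estimate[0],
                    "est_y_cm": jack.mean_estimate[1],
                }
            )
        table = pd.DataFrame(
            rows,
            columns=["signal_id", "time_s", "mpi_mouse1", "mpi_mouse2",
                     "assigned_to", "est_x_cm", "est_y_cm"],
        )
        sio.write_attributed_events_csv(out / "events.csv", table)
        n_assigned = int(table["assigned_to"].notna().sum()) if len(table) else 0
        report["localize"] = {"n_signals": len(table), "n_assigned": n_assigned}
        if _truth_events is not None and len(table):
            correct = 0
            for _, row in table.dropna(subset=["assigned_to"]).iterrows():
                near = min(
                    _truth_events,
                    key=lambda e: abs(e.time - row.time_s),
                    default=None,
                )
                if near is not None and abs(near.time - row.time_s) < 0.1:
                    correct += int(near.vocalizer == int(row.assigned_to))
            report["localize"]["attribution_accuracy"] = (
                correct / n_assigned if n_assigned else float("nan")
            )

    events = None
    if {"dynamics", "respond"} & set(config.stages):
        if config.use_truth_events:
            tracks, truth = _load_truth(out, arena, "dynamics")
            events = truth
        else:
            tracks = sio.read_tracks_csv(_require(out / "tracks.csv", "dynamics"), arena.frame_rate)
            events = sio.read_attributed_events(_require(out / "events.csv", "dynamics"))

    if "dynamics" in config.stages:
        dist = interanimal_distance(tracks)
        timeline = emission_timeline(events, dist, arena.frame_rate)
        prox = proximity_profile(dist, arena.frame_rate, config.proximity_cm)
        metrics = {
            "median_distance_cm": float(np.nanmedian(dist)),
            "proximity_fraction": prox["overall"],
            "proximity_per_minute": prox["per_bin"],
            "time_to_half_emission_s": time_to_fraction_emitted(timeline, 0.5),
            "emission_distance": emission_distance_stats(timeline),
        }
        with open(out / "dynamics.json", "w") as fh:
            json.dump(metrics, fh, indent=2, default=str)
        pd.DataFrame({"minute": range(len(prox["per_bin"])), "proximity_fraction": prox["per_bin"]}).to_csv(
            out / "proximity_per_minute.csv", index=False, float_format="%.6f"
        )
        report["dynamics"] = {
            "n_events": len(events),
            "proximity_fraction": prox["overall"],
        }

    if "respond" in config.stages:
        res = analyze_responses(tracks, events, mode=config.respond_mode, seed=seeds["respond"])
        res["table"].to_csv(out / "response_results.csv", index=False, float_format="%.6f")
        report["respond"] = {
            "mode": config.respond_mode,
            "n_strata": int(len(res["table"])),
            "n_pairs_total": int(res["table"]["n_pairs"].sum()) if len(res["table"]) else 0,
        }

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    return report


def _load_truth(out: Path, arena: ArenaConfig, stage: str):
    tracks = sio.read_tracks_csv(_require(out / "tracks.csv", stage), arena.frame_rate)
    df = pd.read_csv(_require(out / "truth_events.csv", stage))
    from .simulate import VocalEvent

    events = [
        VocalEvent(
            time=float(r.time_s),
            vocalizer=int(r.vocalizer_id),
            source_xy=np.array([r.source_x_cm, r.source_y_cm]),
            contour=np.array([[0.0, 60e3], [0.03, 60e3]]),
        )
        for r in df.itertuples()
    ]
    return tracks, events
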