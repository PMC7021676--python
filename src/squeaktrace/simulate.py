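"""Synthetic dyadic recordings with full ground truth.

Two mice move in a square arena following a correlated random walk with
separately modelled speed (a slow Ornstein–Uhlenbeck process) and heading
(diffusion plus a steering term toward the social partner).  Ultrasonic
emissions are per-frame, per-mouse Bernoulli draws whose hazard depends on
the instantaneous inter-mouse distance, emulating the empirical fact that
mice vocalize primarily in close physical proximity.  An optional
"response kick" raises the receiver's speed after each emission so that
the downstream acceleration statistics have a known effect size to
recover.

Everything is reproducible from a single integer seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

SPEED_OF_SOUND_CM_S = 34300.0  # dry air, ~20 C


def default_mic_positions(side_length: float = 76.0, height: float = 25.0) -> np.ndarray:
    """Eight microphones evenly spaced on the arena perimeter at a fixed height.

    Corners plus edge midpoints: a non-degenerate layout surrounding the
    arena, returned as an (8, 3) array of (x, y, z) in cm.
    """
    s = side_length
    xy = np.array(
        [
            [0.0, 0.0], [s / 2, 0.0], [s, 0.0], [s, s / 2],
            [s, s], [s / 2, s], [0.0, s], [0.0, s / 2],
        ]
    )
    return np.column_stack([xy, np.full(8, float(height))])


@dataclass(frozen=True)
class ArenaConfig:
    """Recording-arena geometry and clocks.

    side_length
        Arena side in cm (square floor).
    frame_rate
        Video sampling rate in Hz.
    duration
        Recording length in seconds.
    mic_positions
        (8, 3) microphone coordinates in cm.
    audio_rate
        Audio sampling rate in Hz.
    """

    side_length: float = 76.0
    frame_rate: float = 30.0
    duration: float = 1800.0
    mic_positions: np.ndarray = None  # type: ignore[assignment]
    audio_rate: float = 250_000.0

    def __post_init__(self) -> None:
        if self.side_length <= 0:
            raise ValueError("side_length must be positive")
        if self.duration < 0:
            raise ValueError(f"duration must be non-negative, got {self.duration}")
        if self.mic_positions is None:
            object.__setattr__(self, "mic_positions", default_mic_positions(self.side_length))
        mics = np.asarray(self.mic_positions, dtype=float)
        if mics.shape != (8, 3):
            raise ValueError("exactly 8 microphone (x, y, z) positions are required")
        if (mics[:, :2] < -1e-9).any() or (mics[:, :2] > self.side_length + 1e-9).any():
            raise ValueError("microphone x,y must lie within or on the arena boundary")
        object.__setattr__(self, "mic_positions", mics)

    @property
    def n_frames(self) -> int:
        return int(round(self.duration * self.frame_rate))


@dataclass
class BehaviorParams:
    """Movement and vocal-emission parameters of the dyad.

    Speed is an OU process (mean ``mean_speed`` cm/s, stationary SD
    ``speed_sd``, relaxation time ``speed_tau`` seconds); the long
    relaxation time keeps frame-scale accelerations small (~0.5 cm/s^2 SD
    over a 167 ms window) so that injected response kicks are the dominant
    acceleration signal.  Heading diffuses with SD ``heading_noise``
    rad/frame and, once ``attraction_onset`` has passed, is steered toward
    the partner with gain ``attraction_strength`` (0 = independent walks).

    Emission hazards are per mouse per video frame; ``near`` applies below
    ``near_threshold`` cm of inter-mouse distance. Contexts (same-sex vs
    opposite-sex) differ only through parameter values, never code paths.
    """

    attraction_strength: float = 0.05
    attraction_onset: float = 0.0  # s
    mean_speed: float = 8.0  # cm/s
    speed_sd: float = 2.0  # cm/s
    speed_tau: float = 180.0  # s
    heading_noise: float = 0.35  # rad/frame
    emission_hazard_near: float = 0.005  # probability / frame / mouse
    emission_hazard_far: float = 1e-4
    near_threshold: float = 20.0  # cm
    kick_magnitude: float = 0.0  # cm/s^2
    kick_window: int = 5  # frames
    nose_offset: float = 3.0  # cm, centroid -> nose along heading
    context: str = "same_sex"

    def __post_init__(self) -> None:
        for name in ("emission_hazard_near", "emission_hazard_far"):
            h = getattr(self, name)
            if not 0.0 <= h <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {h}")
        if self.near_threshold <= 0:
            raise ValueError("near_threshold must be positive")
        if self.kick_window < 1:
            raise ValueError("kick_window must be >= 1")
        if self.context not in ("same_sex", "opposite_sex"):
            raise ValueError("context must be 'same_sex' or 'opposite_sex'")

    @classmethod
    def same_sex(cls, **overrides) -> "BehaviorParams":
        """Female-female preset: proximity (and hence vocal onset) develops late."""
        defaults = dict(context="same_sex", attraction_onset=600.0, attraction_strength=0.05)
        defaults.update(overrides)
        return cls(**defaults)

    @classmethod
    def opposite_sex(cls, **overrides) -> "BehaviorParams":
        """Male-female preset: strong attraction from the start."""
        defaults = dict(context="opposite_sex", attraction_onset=0.0, attraction_strength=0.08)
        defaults.update(overrides)
        return cls(**defaults)


@dataclass
class Tracks:
    """Per-frame positions of both mice on the video clock.

    ``centroid`` and ``nose`` are (n_frames, 2, 2) arrays indexed as
    [frame, mouse_index, xy]; mouse ids 1 and 2 map to indices 0 and 1.
    """

    frame_rate: float
    centroid: np.ndarray
    nose: np.ndarray

    @property
    def n_frames(self) -> int:
        return self.centroid.shape[0]

    def copy(self) -> "Tracks":
        return Tracks(self.frame_rate, self.centroid.copy(), self.nose.copy())


@dataclass
class VocalEvent:
    """One ground-truth emission: when, who, from where, and its chirp contour.

    ``contour`` is a (k, 2) array of (time offset s, frequency Hz) anchor
    points relative to the emission time.
    """

    time: float
    vocalizer: int  # 1 or 2
    source_xy: np.ndarray
    contour: np.ndarray

    @property
    def duration(self) -> float:
        return float(self.contour[-1, 0])


@dataclass
class GroundTruth:
    events: list[VocalEvent]
    tracks: Tracks


def _reflect(x: float, lo: float, hi: float) -> float:
    # fold a coordinate back into [lo, hi] by mirror reflection
    span = hi - lo
    while x < lo or x > hi:
        if x < lo:
            x = 2 * lo - x
        else:
            x = 2 * hi - x
    return x


def _wrap_angle(a: float) -> float:
    return (a + math.pi) % (2 * math.pi) - math.pi


def simulate_dyad(
    arena: ArenaConfig, behavior: BehaviorParams, seed: int
) -> tuple[Tracks, GroundTruth]:
    """Simulate two interacting mice and their vocal emissions.

    Returns the tracks and a :class:`GroundTruth` holding the same tracks
    plus the emission list (time, vocalizer identity, source position at
    the vocalizer's nose, and a randomized frequency-modulated contour in
    the 30-110 kHz band).
    """
    rng = np.random.default_rng(seed)
    n = arena.n_frames
    fps = arena.frame_rate
    L = arena.side_length

    centroid = np.empty((n, 2, 2))
    heading = np.empty((n, 2))
    if n == 0:
        tracks = Tracks(fps, centroid, centroid.copy())
        return tracks, GroundTruth([], tracks)

    pos = rng.uniform(0.1 * L, 0.9 * L, size=(2, 2))
    theta = rng.uniform(-math.pi, math.pi, size=2)
    speed = np.abs(rng.normal(behavior.mean_speed, behavior.speed_sd, size=2))
    centroid[0] = pos
    heading[0] = theta

    rho = math.exp(-1.0 / (fps * behavior.speed_tau)) if behavior.speed_tau > 0 else 0.0
    innov_sd = behavior.speed_sd * math.sqrt(1.0 - rho * rho)
    onset_frame = behavior.attraction_onset * fps

    xi = rng.standard_normal((n, 2))  # speed innovations
    zeta = rng.standard_normal((n, 2))  # heading diffusion
    emit_u = rng.random((n, 2))

    p = [list(pos[0]), list(pos[1])]
    th = list(theta)
    sp = list(speed)
    dt = 1.0 / fps
    kappa = behavior.attraction_strength
    hnoise = behavior.heading_noise
    mean_s = behavior.mean_speed

    for t in range(1, n):
        attract = kappa > 0 and t >= onset_frame
        for m in (0, 1):
            o = 1 - m
            s = mean_s + rho * (sp[m] - mean_s) + innov_sd * xi[t, m]
            sp[m] = abs(s)
            a = th[m]
            if attract:
                bearing = math.atan2(p[o][1] - p[m][1], p[o][0] - p[m][0])
                a += kappa * _wrap_angle(bearing - a)
            a += hnoise * zeta[t, m]
            x0, y0 = p[m]
            dx = sp[m] * dt * math.cos(a)
            dy = sp[m] * dt * math.sin(a)
            # bounce off walls before stepping so the step length (and
            # hence the measured speed) is preserved
            if not 0.0 <= x0 + dx <= L:
                dx = -dx
            if not 0.0 <= y0 + dy <= L:
                dy = -dy
            x = _reflect(x0 + dx, 0.0, L)
            y = _reflect(y0 + dy, 0.0, L)
            dx, dy = x - x0, y - y0
            if dx != 0.0 or dy != 0.0:
                a = math.atan2(dy, dx)
            th[m] = _wrap_angle(a)
            p[m][0], p[m][1] = x, y
            centroid[t, m, 0] = x
            centroid[t, m, 1] = y
            heading[t, m] = th[m]

    nose = centroid + behavior.nose_offset * np.stack(
        [np.cos(heading), np.sin(heading)], axis=-1
    )
    np.clip(nose, 0.0, L, out=nose)

    dist = np.linalg.norm(centroid[:, 0] - centroid[:, 1], axis=1)
    hazard = np.where(
        dist < behavior.near_threshold,
        behavior.emission_hazard_near,
        behavior.emission_hazard_far,
    )
    emitted = emit_u < hazard[:, None]

    events: list[VocalEvent] = []
    frames, mice = np.nonzero(emitted)
    for f, m in zip(frames, mice):
        t_ev = (f + 0.5) / fps
        contour = _random_contour(rng)
        events.append(
            VocalEvent(
                time=float(t_ev),
                vocalizer=m + 1,
                source_xy=nose[f, m].copy(),
                contour=contour,
            )
        )

    tracks = Tracks(fps, centroid, nose)
    return tracks, GroundTruth(events, tracks)


def _random_contour(
    rng: np.random.Generator,
    dur_range: tuple[float, float] = (0.03, 0.08),
    f_start_range: tuple[float, float] = (45e3, 90e3),
    sweep_range: tuple[float, float] = (-15e3, 25e3),
    band: tuple[float, float] = (32e3, 108e3),
    n_anchors: int = 5,
) -> np.ndarray:
    """A frequency-modulated chirp contour: (n_anchors, 2) of (t, f)."""
    dur = rng.uniform(*dur_range)
    f0 = rng.uniform(*f_start_range)
    f1 = float(np.clip(f0 + rng.uniform(*sweep_range), *band))
    t = np.linspace(0.0, dur, n_anchors)
    f = np.linspace(f0, f1, n_anchors)
    return np.column_stack([t, f])


def inject_response_kick(
    tracks: Tracks,
    events: Sequence[VocalEvent],
    kick_magnitude: float,
    kick_window: int,
    arena: ArenaConfig | None = None,
) -> Tracks:
    """Add a post-emission speed boost to the receiving (non-vocalizing) mouse.

    After each emission frame ``e`` the receiver's speed is raised by
    ``kick_magnitude / frame_rate`` per frame for ``kick_window`` frames
    (a linear ramp, i.e. a constant acceleration of ``kick_magnitude``
    cm/s^2 over the window) and then relaxes linearly back over the next
    ``kick_window`` frames.  Overlapping kicks superpose additively.
    Positions are re-integrated along the original step directions so the
    returned tracks are kinematically consistent.
    """
    if kick_window < 1:
        raise ValueError("kick_window must be >= 1")
    if kick_magnitude == 0.0:
        return tracks.copy()

    n = tracks.n_frames
    fps = tracks.frame_rate
    L = arena.side_length if arena is not None else None
    boost = np.zeros((n, 2))
    dv = kick_magnitude / fps  # speed increment per frame, cm/s
    w = kick_window
    for ev in events:
        e = int(ev.time * fps)
        receiver = 2 - ev.vocalizer  # mouse index of the non-vocalizer
        if e + 2 * w >= n:
            logger.warning("kick after event at t=%.3f s truncated at recording end", ev.time)
        for j in range(1, 2 * w + 1):
            idx = e + j
            if idx >= n:
                break
            boost[idx, receiver] += dv * (j if j <= w else 2 * w - j)

    steps = np.diff(tracks.centroid, axis=0)  # (n-1, 2, 2)
    norms = np.linalg.norm(steps, axis=-1)  # (n-1, 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        units = np.where(norms[..., None] > 0, steps / np.where(norms[..., None] == 0, 1, norms[..., None]), 0.0)
    speeds = norms * fps  # cm/s at frames 1..n-1

    new_centroid = np.empty_like(tracks.centroid)
    new_centroid[0] = tracks.centroid[0]
    offset = tracks.nose - tracks.centroid
    for m in (0, 1):
        pos = tracks.centroid[0, m].astype(float).copy()
        for i in range(1, n):
            s = speeds[i - 1, m] + boost[i, m]
            step = units[i - 1, m] * (s / fps)
            if L is not None:
                if not 0.0 <= pos[0] + step[0] <= L:
                    step = step * np.array([-1.0, 1.0])
                if not 0.0 <= pos[1] + step[1] <= L:
                    step = step * np.array([1.0, -1.0])
                pos = pos + step
                pos[0] = _reflect(pos[0], 0.0, L)
                pos[1] = _reflect(pos[1], 0.0, L)
            else:
                pos = pos + step
            new_centroid[i, m] = pos

    new_nose = new_centroid + offset
    if L is not None:
        np.clip(new_nose, 0.0, L, out=new_nose)
    return Tracks(fps, new_centroid, new_nose)


def noisy_jackknife(
    source_xy: np.ndarray, sigma: float, rng: np.random.Generator, n_estimates: int = 8
) -> np.ndarray:
    """Emulate array-localization scatter: the leave-one-microphone-out
    estimates for a signal from ``source_xy`` with isotropic Gaussian
    error ``sigma`` cm.  Returns (n_estimates, 2)."""
    return np.asarray(source_xy, float) + sigma * rng.standard_normal((n_estimates, 2))
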