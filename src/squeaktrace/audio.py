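"""Multichannel ultrasonic audio synthesis and WAV I/O.

Each ground-truth emission is rendered as a frequency-modulated tone that
follows its contour; every microphone receives the tone delayed by the
source-microphone distance over the speed of sound and attenuated as 1/r,
on top of independent stationary Gaussian noise per channel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.io import wavfile

from .simulate import ArenaConfig, SPEED_OF_SOUND_CM_S, VocalEvent

logger = logging.getLogger(__name__)

#: tone RMS / noise RMS is referenced to this source-microphone distance (cm);
#: roughly the distance from the arena centre to a perimeter microphone.
REFERENCE_DISTANCE_CM = 40.0
NOISE_RMS = 0.003
_RAMP_S = 0.003  # cosine onset/offset ramp


@dataclass
class MultichannelAudio:
    """8-channel recording: ``data`` is (n_samples, 8) float32."""

    rate: float
    data: np.ndarray

    @property
    def duration(self) -> float:
        return self.data.shape[0] / self.rate


def synthesize_audio(
    ground_truth_events: Sequence[VocalEvent],
    arena: ArenaConfig,
    snr_db: float = 20.0,
    seed: int = 0,
    duration: float | None = None,
    noise_rms: float = NOISE_RMS,
) -> MultichannelAudio:
    """Render events into an 8-channel recording.

    ``snr_db`` is the per-channel tone-RMS over noise-RMS ratio at
    :data:`REFERENCE_DISTANCE_CM`; the received level scales as 1/r around
    that reference.  Events whose tail extends past the end of the
    recording are truncated (logged).
    """
    rng = np.random.default_rng(seed)
    fs = arena.audio_rate
    dur = arena.duration if duration is None else duration
    n = int(round(dur * fs))
    mics = arena.mic_positions  # (8, 3)
    c = SPEED_OF_SOUND_CM_S

    data = rng.standard_normal((n, 8)) * noise_rms
    amp_ref = noise_rms * 10.0 ** (snr_db / 20.0) * np.sqrt(2.0)  # peak amplitude at r_ref

    for ev in ground_truth_events:
        contour = np.asarray(ev.contour, float)
        if contour[:, 1].min() < 30e3 or contour[:, 1].max() > 110e3:
            raise ValueError("contour frequencies must lie within 30-110 kHz")
        ev_dur = float(contour[-1, 0])
        # cumulative phase on a fine grid, interpolated per channel below
        tg = np.linspace(0.0, ev_dur, max(int(ev_dur * fs) + 1, 2))
        fg = np.interp(tg, contour[:, 0], contour[:, 1])
        phase_g = 2.0 * np.pi * np.concatenate(
            [[0.0], np.cumsum(0.5 * (fg[1:] + fg[:-1]) * np.diff(tg))]
        )
        src = np.array([ev.source_xy[0], ev.source_xy[1], 0.0])
        dists = np.linalg.norm(mics - src, axis=1)  # cm
        if ev.time + ev_dur + dists.max() / c > dur:
            logger.warning("event at t=%.3f s extends past recording end; truncated", ev.time)
        i0 = max(int((ev.time + dists.min() / c - _RAMP_S) * fs) - 2, 0)
        i1 = min(int((ev.time + ev_dur + dists.max() / c) * fs) + 2, n)
        if i1 <= i0:
            continue
        t_abs = np.arange(i0, i1) / fs
        for ch in range(8):
            tau = t_abs - ev.time - dists[ch] / c  # time within the call
            inside = (tau >= 0.0) & (tau <= ev_dur)
            if not inside.any():
                continue
            ph = np.interp(tau[inside], tg, phase_g)
            env = np.minimum(
                1.0,
                np.minimum(tau[inside], ev_dur - tau[inside]) / _RAMP_S,
            )
            amp = amp_ref * (REFERENCE_DISTANCE_CM / max(dists[ch], 1.0))
            seg = data[i0:i1, ch]
            seg[inside] += amp * env * np.sin(ph)

    return MultichannelAudio(rate=fs, data=data.astype(np.float32))


def write_wav(path, audio: MultichannelAudio) -> None:
    wavfile.write(path, int(audio.rate), audio.data)


def read_wav(path) -> MultichannelAudio:
    rate, data = wavfile.read(path)
    if data.ndim == 1:
        data = data[:, None]
    if data.dtype == np.int16:
        data = data.astype(np.float32) / 32768.0
    return MultichannelAudio(rate=float(rate), data=np.asarray(data, np.float32))
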