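"""Ultrasonic vocal-signal extraction from 8-channel audio.

Detection follows the multitaper harmonic-analysis route: each channel is
bandpass filtered to 30-110 kHz, short-time Fourier transformed with K=5
discrete prolate spheroidal (Slepian) tapers at NW=3 over several segment
lengths (NFFT 64/128/256), and each time-frequency point is tested for a
sinusoidal line component with Thomson's harmonic F-test against
F(2, 2K-2).  Per-channel binary masks are combined by a cross-channel
vote, OR-combined across NFFT rasters on the finest grid, convolved with
an 11x15 box to fill small gaps, and 8-connected components of at least
1500 pixels become vocal signals with a power-weighted frequency contour.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage, signal, stats

from .audio import MultichannelAudio
from .simulate import VocalEvent

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SegmentationParams:
    """Detector configuration (defaults are the standard operating point).

    ``min_channels`` is the cross-channel vote: a time-frequency pixel
    survives only when the F-test fires on at least that many of the 8
    microphones, which keeps the pixel-wise false-alarm floor low enough
    for the ``min_pixels`` rule to be meaningful.
    """

    band: tuple[float, float] = (30e3, 110e3)  # Hz
    n_tapers: int = 5  # K
    time_bandwidth: float = 3.0  # NW
    nfft_list: tuple[int, ...] = (64, 128, 256)
    ftest_alpha: float = 0.05
    box: tuple[int, int] = (11, 15)  # (frequency, time) pixels
    min_pixels: int = 1500
    min_channels: int = 5

    def __post_init__(self) -> None:
        if not self.n_tapers < 2 * self.time_bandwidth:
            raise ValueError("need K < 2*NW for well-behaved Slepian tapers")
        if not self.nfft_list:
            raise ValueError("nfft_list must be non-empty")
        if self.min_pixels < 1:
            raise ValueError("min_pixels must be >= 1")
        if self.box[0] < 1 or self.box[1] < 1:
            raise ValueError("box dimensions must be positive")


@dataclass
class TFMask:
    """Binary time-frequency detection mask on one (nfft, hop) raster."""

    mask: np.ndarray  # (n_freqs, n_times) bool
    freqs: np.ndarray  # Hz, band-restricted
    times: np.ndarray  # s, window centres
    nfft: int
    hop: int


@dataclass
class CombinedMask:
    """Channel- and NFFT-combined mask on the finest raster.

    ``dilated`` is the box-convolved support used for the pixel-count
    rule; ``raw`` is the pre-convolution support used for timing and
    contours; ``channel_masks`` is (n_channels, F, T): each channel's own
    detections (OR over NFFTs) on the common raster.
    """

    raw: np.ndarray
    dilated: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    channel_masks: np.ndarray | None = None


@dataclass
class VocalSignal:
    """One segmented vocal signal.

    ``contour`` is (k, 2) of (time s, frequency Hz); ``pixel_count`` is
    the size of the connected component on the combined raster.
    """

    start_time: float
    stop_time: float
    pixel_count: int
    contour: np.ndarray
    source_channel_support: np.ndarray | None = None

    @property
    def duration(self) -> float:
        return self.stop_time - self.start_time


def bandpass_filter(
    data: np.ndarray, fs: float, band: tuple[float, float] = (30e3, 110e3), order: int = 5
) -> np.ndarray:
    """Zero-phase Butterworth bandpass (forward-backward, so event times
    are not shifted).  Rejects sampling rates violating Nyquist for the
    upper band edge."""
    if fs <= 2 * band[1]:
        raise ValueError(f"sampling rate {fs} Hz too low for band edge {band[1]} Hz")
    sos = signal.butter(order, band, btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, np.asarray(data, float), axis=0)


def _ftest_threshold(params: SegmentationParams) -> float:
    k = params.n_tapers
    return float(stats.f.isf(params.ftest_alpha, 2, 2 * k - 2))


def multitaper_ftest_mask(
    channel: np.ndarray,
    fs: float,
    params: SegmentationParams,
    nfft: int,
    return_power: bool = False,
) -> TFMask | tuple[TFMask, np.ndarray]:
    """Thomson harmonic F-test mask for one channel at one segment length.

    Windows advance by ``nfft // 2`` samples.  For each window and
    frequency bin the line-component amplitude is regressed from the K
    taper eigencoefficients and tested against F(2, 2K-2) at
    ``ftest_alpha``; the mask is restricted to the analysis band.
    """
    x = np.asarray(channel, float)
    hop = nfft // 2
    k = params.n_tapers
    thresh = _ftest_threshold(params)
    freqs_all = np.fft.rfftfreq(nfft, 1.0 / fs)
    in_band = (freqs_all >= params.band[0]) & (freqs_all <= params.band[1])
    freqs = freqs_all[in_band]

    if x.size < nfft:
        logger.info("signal shorter than nfft=%d; empty mask", nfft)
        empty = np.zeros((freqs.size, 0), bool)
        out = TFMask(empty, freqs, np.empty(0), nfft, hop)
        return (out, np.zeros((freqs.size, 0))) if return_power else out

    tapers = signal.windows.dpss(nfft, params.time_bandwidth, Kmax=k)  # (K, nfft)
    u0 = tapers.sum(axis=1)  # DC gain of each taper
    u0_ss = float(u0 @ u0)

    windows = sliding_window_view(x, nfft)[::hop]  # (W, nfft) view
    n_win = windows.shape[0]
    times = (np.arange(n_win) * hop + nfft / 2) / fs

    mask = np.empty((freqs.size, n_win), bool)
    power = np.empty((freqs.size, n_win)) if return_power else None
    chunk = max(1, 4_000_000 // (k * nfft))
    for lo in range(0, n_win, chunk):
        hi = min(lo + chunk, n_win)
        y = np.fft.rfft(windows[lo:hi, None, :] * tapers[None, :, :], axis=-1)
        y = y[:, :, in_band]  # (w, K, F)
        mu = np.tensordot(y, u0, axes=([1], [0])) / u0_ss  # (w, F)
        resid = y - mu[:, None, :] * u0[None, :, None]
        denom = np.einsum("wkf,wkf->wf", resid, resid.conj()).real
        num = (k - 1) * (mu * mu.conj()).real * u0_ss
        with np.errstate(divide="ignore", invalid="ignore"):
            fstat = np.where(denom > 0, num / np.where(denom == 0, 1, denom), 0.0)
        mask[:, lo:hi] = (fstat > thresh).T
        if power is not None:
            power[:, lo:hi] = np.einsum("wkf,wkf->wf", y, y.conj()).real.T / k

    out = TFMask(mask, freqs, times, nfft, hop)
    return (out, power) if return_power else out


def _nearest_index(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    """Index of the nearest ``src`` value for each ``dst`` value."""
    idx = np.searchsorted(src, dst)
    idx = np.clip(idx, 1, len(src) - 1)
    left = src[idx - 1]
    right = src[idx]
    idx -= dst - left < right - dst
    return np.clip(idx, 0, len(src) - 1)


def _pool_ranges(src: np.ndarray, tgt: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Source index range [lo, hi) pooled into each target bin.

    Each target bin collects every source centre within half a target
    step, and always at least its single nearest source bin — so the
    mapping neither skips source bins when downsampling nor leaves
    target bins empty when upsampling."""
    half = 0.5 * float(np.median(np.diff(tgt))) if tgt.size > 1 else np.inf
    lo = np.searchsorted(src, tgt - half)
    hi = np.searchsorted(src, tgt + half)
    nearest = _nearest_index(src, tgt)
    return np.minimum(lo, nearest), np.maximum(hi, nearest + 1)


def _resample_mask(
    mask: np.ndarray,
    src_f: np.ndarray,
    src_t: np.ndarray,
    tgt_f: np.ndarray,
    tgt_t: np.ndarray,
) -> np.ndarray:
    """OR-pooling resample of a binary mask onto the target raster."""
    flo, fhi = _pool_ranges(src_f, tgt_f)
    tlo, thi = _pool_ranges(src_t, tgt_t)
    c = np.zeros((mask.shape[0] + 1, mask.shape[1] + 1), np.int32)
    np.cumsum(np.cumsum(mask, axis=0), axis=1, out=c[1:, 1:])
    counts = c[fhi[:, None], thi[None, :]] - c[flo[:, None], thi[None, :]] \
        - c[fhi[:, None], tlo[None, :]] + c[flo[:, None], tlo[None, :]]
    return counts > 0


def combine_and_smooth(
    masks_by_nfft: Sequence[Sequence[TFMask]], params: SegmentationParams
) -> CombinedMask:
    """Combine per-channel, per-NFFT masks onto the finest raster.

    Within each NFFT, channels vote: a pixel is kept when at least
    ``min_channels`` (capped at the number of channels supplied) agree.
    The per-NFFT results are resampled nearest-neighbour onto the raster
    of the smallest NFFT (finest time resolution) and OR-combined, then
    dilated with the box so that any pixel with support after the
    convolution is active.
    """
    groups = [list(g) for g in masks_by_nfft if len(g) > 0]
    if not groups:
        raise ValueError("no masks supplied")
    finest = min(groups, key=lambda g: g[0].nfft)[0]
    tgt_f, tgt_t = finest.freqs, finest.times
    n_channels = max(len(g) for g in groups)
    votes_needed = min(params.min_channels, n_channels)

    raw = np.zeros((tgt_f.size, tgt_t.size), bool)
    per_channel = np.zeros((n_channels, tgt_f.size, tgt_t.size), bool)
    for group in groups:
        live = [m for m in group if m.times.size > 0]
        if not live:
            continue
        # vote on the group's native raster, then resample the voted mask:
        # resampling first would inflate the per-channel false-alarm rate
        voted = np.sum([m.mask for m in live], axis=0) >= min(votes_needed, len(live))
        m0 = live[0]
        same_raster = (
            voted.shape == raw.shape
            and np.array_equal(m0.times, tgt_t)
            and np.array_equal(m0.freqs, tgt_f)
        )
        raw |= voted if same_raster else _resample_mask(
            voted, m0.freqs, m0.times, tgt_f, tgt_t
        )
        for ch, m in enumerate(group):
            if m.times.size == 0:
                continue
            per_channel[ch] |= m.mask if same_raster else _resample_mask(
                m.mask, m.freqs, m.times, tgt_f, tgt_t
            )

    structure = np.ones(params.box, bool)
    dilated = ndimage.binary_dilation(raw, structure=structure)
    return CombinedMask(
        raw=raw,
        dilated=dilated,
        freqs=tgt_f,
        times=tgt_t,
        channel_masks=per_channel,
    )


def extract_signals(
    combined: CombinedMask,
    power: np.ndarray | None,
    params: SegmentationParams,
) -> list[VocalSignal]:
    """Label 8-connected components, apply the pixel-count rule, build
    power-weighted frequency contours, and suppress harmonic copies.

    Timing and contours are read from the pre-convolution support of each
    component (the box convolution exists to bridge small gaps, not to
    time-stretch signals).  When two signals overlap in time for at least
    half of the shorter one and one contour sits within +-10% of an
    integer multiple (>= 2x) of the other, the higher is treated as a
    harmonic and only the fundamental is returned.
    """
    labels, n_comp = ndimage.label(combined.dilated, structure=np.ones((3, 3), bool))
    if n_comp == 0:
        return []
    dt = float(np.median(np.diff(combined.times))) if combined.times.size > 1 else 0.0
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n_comp + 1))

    signals_out: list[VocalSignal] = []
    for comp_id in range(1, n_comp + 1):
        pixel_count = int(sizes[comp_id - 1])
        if pixel_count < params.min_pixels:
            continue
        comp = labels == comp_id
        support = comp & combined.raw
        if not support.any():
            support = comp
        cols = np.nonzero(support.any(axis=0))[0]
        w = power if power is not None else np.ones_like(support, float)
        contour_t = combined.times[cols]
        contour_f = np.empty(cols.size)
        for i, c in enumerate(cols):
            rows = np.nonzero(support[:, c])[0]
            wt = np.maximum(w[rows, c], 1e-30)
            contour_f[i] = float(np.average(combined.freqs[rows], weights=wt))
        sup_frac = None
        if combined.channel_masks is not None:
            sup_frac = combined.channel_masks[:, support].mean(axis=1)
        signals_out.append(
            VocalSignal(
                start_time=float(contour_t[0] - dt / 2),
                stop_time=float(contour_t[-1] + dt / 2),
                pixel_count=pixel_count,
                contour=np.column_stack([contour_t, contour_f]),
                source_channel_support=sup_frac,
            )
        )

    signals_out = _suppress_harmonics(signals_out)
    signals_out.sort(key=lambda s: s.start_time)
    return signals_out


def _suppress_harmonics(
    sigs: list[VocalSignal], tol: float = 0.10, min_overlap: float = 0.5
) -> list[VocalSignal]:
    drop: set[int] = set()
    for i in range(len(sigs)):
        for j in range(len(sigs)):
            if i == j or i in drop or j in drop:
                continue
            a, b = sigs[i], sigs[j]
            lo = max(a.start_time, b.start_time)
            hi = min(a.stop_time, b.stop_time)
            shorter = min(a.duration, b.duration)
            if shorter <= 0 or (hi - lo) < min_overlap * shorter:
                continue
            t = np.linspace(lo, hi, 25)
            fa = np.interp(t, a.contour[:, 0], a.contour[:, 1])
            fb = np.interp(t, b.contour[:, 0], b.contour[:, 1])
            if fa.mean() >= fb.mean():
                hi_idx, ratio = i, float(np.mean(fa / fb))
            else:
                hi_idx, ratio = j, float(np.mean(fb / fa))
            mult = round(ratio)
            if mult >= 2 and abs(ratio - mult) <= tol * mult:
                drop.add(hi_idx)
    return [s for k, s in enumerate(sigs) if k not in drop]


def segment_audio(
    audio: MultichannelAudio, params: SegmentationParams = SegmentationParams()
) -> list[VocalSignal]:
    """Full segmentation of an 8-channel recording."""
    filtered = bandpass_filter(audio.data, audio.rate, params.band)
    n_ch = filtered.shape[1]
    finest = min(params.nfft_list)
    masks_by_nfft: list[list[TFMask]] = []
    power_sum: np.ndarray | None = None
    for nfft in params.nfft_list:
        group = []
        for ch in range(n_ch):
            if nfft == finest:
                m, p = multitaper_ftest_mask(
                    filtered[:, ch], audio.rate, params, nfft, return_power=True
                )
                power_sum = p if power_sum is None else power_sum + p
            else:
                m = multitaper_ftest_mask(filtered[:, ch], audio.rate, params, nfft)
            group.append(m)
        masks_by_nfft.append(group)
    combined = combine_and_smooth(masks_by_nfft, params)
    power = power_sum / n_ch if power_sum is not None else None
    return extract_signals(combined, power, params)


def score_detections(
    signals: Sequence[VocalSignal],
    events: Sequence[VocalEvent],
    tol: float = 0.02,
) -> dict:
    """Match detections to ground-truth events by temporal overlap.

    A detection matches an event when their intervals (padded by ``tol``
    seconds) overlap; each event and detection is used at most once.
    Returns recall, precision and the match list.
    """
    used = set()
    matches = []
    for ei, ev in enumerate(events):
        e0, e1 = ev.time - tol, ev.time + ev.duration + tol
        for si, s in enumerate(signals):
            if si in used:
                continue
            if min(e1, s.stop_time) > max(e0, s.start_time):
                used.add(si)
                matches.append((ei, si))
                break
    recall = len(matches) / len(events) if events else float("nan")
    precision = len(matches) / len(signals) if signals else float("nan")
    return {"recall": recall, "precision": precision, "matches": matches}
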