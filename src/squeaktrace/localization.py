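"""Sound-source localization and vocalizer attribution.

For each segmented signal the array yields eight leave-one-microphone-out
source estimates: with one microphone omitted, pairwise time differences
of arrival (TDOA) among the remaining seven are measured by generalized
cross-correlation on the signal's time-frequency support, and the source
is the least-squares minimizer of the delay residuals over the arena.
The eight estimates define a bivariate-Gaussian probability density over
the cage; each mouse reads the density at its nose, and the Mouse
Probability Index

    MPI_n = D_n / sum_i D_i

must reach 0.95 for the signal to be assigned to mouse n.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .audio import MultichannelAudio
from .segmentation import VocalSignal, bandpass_filter
from .simulate import ArenaConfig, SPEED_OF_SOUND_CM_S

logger = logging.getLogger(__name__)

ASSIGNMENT_THRESHOLD = 0.95
DENSITY_FLOOR = 1e-12  # 1/cm^2
COV_REGULARIZER = 0.25  # cm^2 added to the diagonal
GRID_CELL = 0.5  # cm


@dataclass
class JackknifeSet:
    """Eight leave-one-out source estimates and their mean."""

    estimates: np.ndarray  # (8, 2) cm
    mean_estimate: np.ndarray  # (2,) cm
    low_confidence: bool = False

    @classmethod
    def from_estimates(cls, estimates: np.ndarray, low_confidence: bool = False) -> "JackknifeSet":
        est = np.asarray(estimates, float)
        if est.shape != (8, 2):
            raise ValueError("exactly 8 (x, y) estimates are required")
        return cls(est, est.mean(axis=0), low_confidence)


@dataclass
class SourceDensity:
    """Probability density of the source position on an arena raster."""

    values: np.ndarray  # (nx, ny), 1/cm^2
    cell: float  # cm
    floor: float

    def value_at(self, xy: np.ndarray) -> float:
        ix, iy = self.cell_index(xy)
        return float(self.values[ix, iy])

    def cell_index(self, xy) -> tuple[int, int]:
        ix = int(np.clip(np.floor(xy[0] / self.cell), 0, self.values.shape[0] - 1))
        iy = int(np.clip(np.floor(xy[1] / self.cell), 0, self.values.shape[1] - 1))
        return ix, iy


@dataclass
class MPIResult:
    """Per-mouse densities, MPI values, and the resulting assignment."""

    D: np.ndarray  # (M,) density at each nose
    MPI: np.ndarray  # (M,)
    assigned_to: int | None  # mouse id (1-based) or None
    threshold: float = ASSIGNMENT_THRESHOLD


def gcc_delay(
    a: np.ndarray, b: np.ndarray, fs: float, max_lag_s: float, phat: bool = False
) -> tuple[float, float]:
    """Generalized cross-correlation delay of ``b`` relative to ``a``.

    Positive delay means ``b`` lags ``a``.  Returns (delay seconds,
    normalized peak height) with parabolic sub-sample interpolation.
    """
    n = len(a) + len(b)
    nfft = 1 << int(np.ceil(np.log2(n)))
    fa = np.fft.rfft(a, nfft)
    fb = np.fft.rfft(b, nfft)
    spec = fa * np.conj(fb)
    if phat:
        spec /= np.maximum(np.abs(spec), 1e-30)
    cc = np.fft.irfft(spec, nfft)
    cc = np.concatenate([cc[-(nfft // 2):], cc[: nfft // 2]])
    lags = np.arange(-(nfft // 2), nfft // 2)
    max_lag = int(np.ceil(max_lag_s * fs))
    keep = np.abs(lags) <= max_lag
    cc_k, lags_k = cc[keep], lags[keep]
    i = int(np.argmax(cc_k))
    lag = float(lags_k[i])
    if 0 < i < len(cc_k) - 1:
        y0, y1, y2 = cc_k[i - 1], cc_k[i], cc_k[i + 1]
        denom = y0 - 2 * y1 + y2
        if denom != 0:
            lag += 0.5 * (y0 - y2) / denom
    norm = np.sqrt(float(np.dot(a, a)) * float(np.dot(b, b)))
    peak = float(cc_k[i] / norm) if norm > 0 else 0.0
    # sign: b delayed by d -> correlation peak of a(t)b(t+lag) at lag=-d
    return -lag / fs, peak


def _tdoa_cost(xy: np.ndarray, mics: np.ndarray, pairs, delays, c: float) -> float:
    p = np.array([xy[0], xy[1], 0.0])
    d = np.linalg.norm(mics - p, axis=1)
    # measured delay of channel j relative to i is (r_j - r_i) / c
    res = [delays[k] - (d[j] - d[i]) / c for k, (i, j) in enumerate(pairs)]
    return float(np.dot(res, res))


def _least_squares_source(
    mics: np.ndarray,
    pairs: list[tuple[int, int]],
    delays: np.ndarray,
    side_length: float,
    c: float,
    coarse: float = 2.0,
) -> np.ndarray:
    """Grid-initialized least-squares TDOA solve over the arena floor."""
    g = np.arange(coarse / 2, side_length, coarse)
    gx, gy = np.meshgrid(g, g, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), np.zeros(gx.size)])
    dists = np.linalg.norm(pts[:, None, :] - mics[None, :, :], axis=2)  # (P, n_mics)
    cost = np.zeros(pts.shape[0])
    for k, (i, j) in enumerate(pairs):
        cost += (delays[k] - (dists[:, j] - dists[:, i]) / c) ** 2
    x0 = pts[int(np.argmin(cost)), :2]
    res = optimize.minimize(
        _tdoa_cost,
        x0,
        args=(mics, pairs, delays, c),
        method="Nelder-Mead",
        options={"xatol": 1e-3, "fatol": 1e-14, "maxiter": 400},
    )
    return np.clip(res.x, 0.0, side_length)


def jackknife_localize(
    sig: VocalSignal,
    audio: MultichannelAudio,
    arena: ArenaConfig,
    pad: float = 0.005,
    min_peak: float = 0.05,
) -> JackknifeSet:
    """Eight leave-one-microphone-out TDOA estimates for one signal.

    The audio is cut to the signal's time support (padded) and bandpass
    filtered to its contour's frequency range; all 28 pairwise delays are
    measured once and each omission solves a least-squares problem on the
    21 pairs that exclude the omitted microphone.
    """
    mics = arena.mic_positions
    if mics.shape[0] != 8:
        raise ValueError("8 microphones required")
    spans = mics[:, :2] - mics[:, :2].mean(axis=0)
    if np.linalg.matrix_rank(spans, tol=1e-6) < 2:
        raise ValueError("degenerate (collinear) microphone geometry")
    if sig.duration < 0.005:
        raise ValueError("signal support shorter than 5 ms")

    fs = audio.rate
    c = SPEED_OF_SOUND_CM_S
    max_delay = (np.sqrt(2) * arena.side_length + mics[:, 2].max()) / c
    i0 = max(int((sig.start_time - pad) * fs), 0)
    i1 = min(int((sig.stop_time + pad) * fs), audio.data.shape[0])
    seg = audio.data[i0:i1].astype(float)
    f_lo = max(sig.contour[:, 1].min() - 6e3, 25e3)
    f_hi = min(sig.contour[:, 1].max() + 6e3, 0.45 * fs)
    seg = bandpass_filter(seg, fs, (f_lo, f_hi), order=4)

    delays = np.zeros((8, 8))
    peaks = np.ones((8, 8))
    for i, j in itertools.combinations(range(8), 2):
        d, p = gcc_delay(seg[:, i], seg[:, j], fs, max_delay)
        delays[i, j], delays[j, i] = d, -d
        peaks[i, j] = peaks[j, i] = p

    weak = sum(1 for i, j in itertools.combinations(range(8), 2) if peaks[i, j] < min_peak)
    low_conf = weak > 3
    if low_conf:
        logger.warning("cross-correlation peak below %.2f for %d pairs", min_peak, weak)

    estimates = np.empty((8, 2))
    for omit in range(8):
        keep = [m for m in range(8) if m != omit]
        pairs = list(itertools.combinations(keep, 2))
        dvec = np.array([delays[i, j] for i, j in pairs])
        estimates[omit] = _least_squares_source(mics, pairs, dvec, arena.side_length, c)
    return JackknifeSet.from_estimates(estimates, low_confidence=low_conf)


def build_density(
    jack: JackknifeSet,
    arena: ArenaConfig,
    cell: float = GRID_CELL,
    regularizer: float = COV_REGULARIZER,
    floor: float = DENSITY_FLOOR,
) -> SourceDensity:
    """Bivariate Gaussian over the arena fitted to the jackknife scatter.

    Mean = mean estimate; covariance = sample covariance of the eight
    estimates plus ``regularizer`` on the diagonal (so eight identical
    estimates still give a proper density).  The density is normalized
    over the arena and floored at ``floor`` so the MPI denominator never
    vanishes.
    """
    est = jack.estimates
    if est.shape[0] < 2:
        raise ValueError("need at least 2 estimates")
    mean = jack.mean_estimate
    cov = np.cov(est.T) + regularizer * np.eye(2)

    g = np.arange(cell / 2, arena.side_length, cell)
    gx, gy = np.meshgrid(g, g, indexing="ij")
    diff = np.stack([gx - mean[0], gy - mean[1]], axis=-1)
    cov_inv = np.linalg.inv(cov)
    md = np.einsum("...i,ij,...j->...", diff, cov_inv, diff)
    vals = np.exp(-0.5 * md) / (2 * np.pi * np.sqrt(np.linalg.det(cov)))
    total = vals.sum() * cell * cell
    if total <= 0:
        raise ValueError("density vanished on the grid")
    vals /= total
    np.maximum(vals, floor, out=vals)
    return SourceDensity(values=vals, cell=cell, floor=floor)


def mpi_from_densities(densities) -> np.ndarray:
    """The Mouse Probability Index: each animal's share of the total
    source-density value read at the animals' noses."""
    d = np.asarray(densities, float)
    if (d < 0).any():
        raise ValueError("density values must be non-negative")
    total = d.sum()
    if total <= 0:
        raise ValueError("sum of density values must be positive")
    return d / total


def compute_mpi_and_assign(
    density: SourceDensity,
    nose_positions: np.ndarray,
    threshold: float = ASSIGNMENT_THRESHOLD,
) -> MPIResult:
    """Read the density at each nose, compute MPI, and assign the signal
    to the argmax mouse iff its MPI reaches ``threshold``."""
    noses = np.asarray(nose_positions, float)
    d = np.array([density.value_at(xy) for xy in noses])
    mpi = mpi_from_densities(d)
    best = int(np.argmax(mpi))
    assigned = best + 1 if mpi[best] >= threshold else None
    return MPIResult(D=d, MPI=mpi, assigned_to=assigned, threshold=threshold)


def attribute_signal(
    sig: VocalSignal,
    audio: MultichannelAudio,
    arena: ArenaConfig,
    nose_positions: np.ndarray,
) -> tuple[JackknifeSet, MPIResult]:
    """Full attribution of one signal: jackknife -> density -> MPI."""
    jack = jackknife_localize(sig, audio, arena)
    dens = build_density(jack, arena)
    return jack, compute_mpi_and_assign(dens, nose_positions)
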