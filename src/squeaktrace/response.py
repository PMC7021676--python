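"""Receiver-movement responses to vocal emission.

The statistic: around every qualifying emission, take the receiving
(non-vocalizing) mouse's speed over 11 video frames (367 ms at 30 Hz,
five frames either side of the emission frame).  Pair each such vocal
trajectory with a speed-matched non-vocal control — an 11-frame window of
the same mouse's speed containing no emission by either animal, chosen to
minimize the summed absolute speed difference over the first 6 samples
(200 ms, the time up to and including emission) and used at most once.
Post-emission acceleration is the mean of the five consecutive
frame-to-frame speed changes after the emission frame (167 ms).  Vocal
and control accelerations are compared with a paired t-test within each
stratum (context x vocalizer x relative speed [x epoch]), guarded by a
random-subsampling null, with an optional three-epoch analysis using
bin-restricted controls.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import Tracks, VocalEvent

TRAJECTORY_FRAMES = 11  # 5 before + emission + 5 after
PRE_FRAMES = 5
POST_FRAMES = 5
MATCH_SAMPLES = 6  # first 200 ms: frames e-5 .. e
PROXIMITY_CM = 20.0
ISOLATION_S = 0.367
EPOCH_S = 600.0
SUBSAMPLE_REPS = 1000
SUBSAMPLE_FRACTION = 0.25


def trajectory_span_ms(frame_rate: float = 30.0, n_frames: int = TRAJECTORY_FRAMES) -> int:
    """Duration covered by a trajectory, in whole milliseconds."""
    return int(round(1000.0 * n_frames / frame_rate))


def acceleration_window_ms(frame_rate: float = 30.0, n_frames: int = POST_FRAMES) -> int:
    """Duration of the post-emission acceleration window, in ms."""
    return int(round(1000.0 * n_frames / frame_rate))


def compute_speeds(centroid: np.ndarray, frame_rate: float = 30.0) -> np.ndarray:
    """Per-frame speed (cm/s) of one mouse from its centroid track.

    speed[i] = ||centroid[i] - centroid[i-1]|| * frame_rate; undefined
    (NaN) at frame 0 and wherever a position is missing.
    """
    c = np.asarray(centroid, float)
    if c.shape[0] < 2:
        raise ValueError("track needs at least 2 frames")
    out = np.full(c.shape[0], np.nan)
    out[1:] = np.linalg.norm(np.diff(c, axis=0), axis=1) * frame_rate
    return out


@dataclass
class VocalTrajectory:
    """Receiver speed around one emission, with its stratum labels."""

    samples: np.ndarray  # (11,) cm/s, frames e-5 .. e+5
    emission_frame: int
    vocalizer: int  # mouse id
    receiver: int
    relative_speed: str  # "faster" | "slower" (vocalizer vs receiver at e)
    epoch: int  # 1..3
    isolated: bool
    event_time: float


@dataclass
class MatchedPair:
    vocal: VocalTrajectory
    control: np.ndarray  # (11,)
    control_start: int  # first frame of the control window
    match_cost: float  # cm/s summed over the first 6 samples


@dataclass
class StratumResult:
    """Paired vocal-vs-control acceleration comparison in one stratum."""

    n: int
    vocal_mean: float
    vocal_sd: float
    control_mean: float
    control_sd: float
    t: float
    p: float
    testable: bool
    note: str = ""


def post_acceleration(window: np.ndarray, frame_rate: float = 30.0) -> float:
    """Mean of the 5 consecutive speed changes after the emission frame,
    in cm/s^2.  Telescopes to (v[e+5] - v[e]) * frame_rate / 5."""
    w = np.asarray(window, float)
    return float(np.mean(np.diff(w[PRE_FRAMES:])) * frame_rate)


def build_vocal_trajectories(
    events: Sequence[VocalEvent],
    speeds: np.ndarray,
    dist: np.ndarray,
    frame_rate: float = 30.0,
    proximity_cm: float = PROXIMITY_CM,
    isolation_s: float = ISOLATION_S,
) -> tuple[list[VocalTrajectory], dict]:
    """One trajectory per qualifying emission.

    ``speeds`` is (n_frames, 2): per-frame speed of each mouse.  Events
    are kept when the mice are within ``proximity_cm`` at the emission
    frame and the 11-frame window has defined speeds; the isolated flag
    marks signals with no other signal (either mouse) starting within
    +-``isolation_s``.  A QC dict counts every drop reason.
    """
    n = speeds.shape[0]
    times = np.array([ev.time for ev in events])
    qc = {"total": len(events), "edge": 0, "proximity": 0, "undefined_speed": 0, "kept": 0}
    out: list[VocalTrajectory] = []
    for idx, ev in enumerate(sorted(events, key=lambda e: e.time)):
        e = int(ev.time * frame_rate)
        if e - PRE_FRAMES < 1 or e + POST_FRAMES >= n:
            qc["edge"] += 1
            continue
        if not (dist[e] < proximity_cm):
            qc["proximity"] += 1
            continue
        receiver = 3 - ev.vocalizer
        window = speeds[e - PRE_FRAMES : e + POST_FRAMES + 1, receiver - 1]
        if np.isnan(window).any() or np.isnan(speeds[e, ev.vocalizer - 1]):
            qc["undefined_speed"] += 1
            continue
        gaps = np.abs(times - ev.time)
        isolated = bool(np.sum(gaps <= isolation_s) <= 1)  # only itself
        rel = "faster" if speeds[e, ev.vocalizer - 1] > speeds[e, receiver - 1] else "slower"
        epoch = min(int(ev.time // EPOCH_S), 2) + 1
        out.append(
            VocalTrajectory(
                samples=window.copy(),
                emission_frame=e,
                vocalizer=ev.vocalizer,
                receiver=receiver,
                relative_speed=rel,
                epoch=epoch,
                isolated=isolated,
                event_time=ev.time,
            )
        )
        qc["kept"] += 1
    return out, qc


def build_control_pool(
    speeds_one_mouse: np.ndarray,
    all_event_frames: Sequence[int],
    frame_range: tuple[int, int] | None = None,
    dist: np.ndarray | None = None,
    proximity_cm: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Candidate non-vocal windows for one (receiving) mouse.

    Every 11-frame window (stride 1) that contains no emission start by
    either mouse and no undefined speed qualifies.  ``frame_range``
    restricts window starts to [lo, hi) (used by the epoch analysis).
    By default the pool is not proximity-filtered (the 20 cm rule applies
    to signals, not controls); passing ``dist`` with ``proximity_cm``
    additionally requires the mice to be within that distance at the
    window's centre frame.  Returns (starts, windows), windows (n, 11).
    """
    s = np.asarray(speeds_one_mouse, float)
    n = s.size
    if n < TRAJECTORY_FRAMES:
        return np.empty(0, int), np.empty((0, TRAJECTORY_FRAMES))
    event_mark = np.zeros(n, bool)
    for f in all_event_frames:
        if 0 <= f < n:
            event_mark[f] = True
    from numpy.lib.stride_tricks import sliding_window_view

    windows = sliding_window_view(s, TRAJECTORY_FRAMES)
    has_event = sliding_window_view(event_mark, TRAJECTORY_FRAMES).any(axis=1)
    ok = ~has_event & ~np.isnan(windows).any(axis=1)
    starts = np.nonzero(ok)[0]
    if frame_range is not None:
        lo, hi = frame_range
        starts = starts[(starts >= lo) & (starts + TRAJECTORY_FRAMES <= hi)]
    if dist is not None and proximity_cm is not None:
        centre = np.asarray(dist, float)[starts + PRE_FRAMES]
        starts = starts[centre < proximity_cm]
    return starts, windows[starts]


def match_controls(
    trajectories: Sequence[VocalTrajectory],
    pool_starts: np.ndarray,
    pool_windows: np.ndarray,
) -> tuple[list[MatchedPair], list[VocalTrajectory]]:
    """Greedy chronological speed matching, each control used once.

    Trajectories are processed in order of emission frame; each takes the
    remaining pool window minimizing the summed absolute speed difference
    over the first 6 samples, ties broken by earliest window start.
    Returns matched pairs and any trajectories left unmatched.
    """
    order = np.argsort([t.emission_frame for t in trajectories], kind="stable")
    avail = np.ones(len(pool_starts), bool)
    # pool is generated in ascending start order; argmin then favors the earliest
    pairs: list[MatchedPair] = []
    unmatched: list[VocalTrajectory] = []
    pre = slice(0, MATCH_SAMPLES)
    for k in order:
        traj = trajectories[k]
        if not avail.any():
            unmatched.append(traj)
            continue
        idx = np.nonzero(avail)[0]
        costs = np.abs(pool_windows[idx, pre] - traj.samples[pre]).sum(axis=1)
        # costs within 1e-9 count as tied; the earliest window start wins
        j = idx[int(np.nonzero(costs <= costs.min() + 1e-9)[0][0])]
        avail[j] = False
        pairs.append(
            MatchedPair(
                vocal=traj,
                control=pool_windows[j].copy(),
                control_start=int(pool_starts[j]),
                match_cost=float(np.abs(pool_windows[j, pre] - traj.samples[pre]).sum()),
            )
        )
    return pairs, unmatched


def stratum_test(pairs: Sequence[MatchedPair], frame_rate: float = 30.0) -> StratumResult:
    """Paired t-test of post-emission acceleration, vocal vs control."""
    if len(pairs) < 2:
        return StratumResult(len(pairs), math.nan, math.nan, math.nan, math.nan,
                             math.nan, math.nan, testable=False, note="fewer than 2 pairs")
    va = np.array([post_acceleration(p.vocal.samples, frame_rate) for p in pairs])
    ca = np.array([post_acceleration(p.control, frame_rate) for p in pairs])
    diffs = va - ca
    if np.allclose(diffs, diffs[0]):
        if diffs[0] == 0:
            t, p, note = 0.0, 1.0, ""
        else:  # zero-variance nonzero difference: certain at any alpha
            t, p, note = math.inf if diffs[0] > 0 else -math.inf, 0.0, "difference certain"
    else:
        res = stats.ttest_rel(va, ca)
        t, p, note = float(res.statistic), float(res.pvalue), ""
    return StratumResult(
        n=len(pairs),
        vocal_mean=float(va.mean()), vocal_sd=float(va.std(ddof=1)),
        control_mean=float(ca.mean()), control_sd=float(ca.std(ddof=1)),
        t=t, p=p, testable=True, note=note,
    )


@dataclass
class SubsampleNull:
    """Empirical distribution of subsampled vocal-minus-control means."""

    means: np.ndarray
    m: int
    reps: int
    p: float


def subsample_null(
    pairs: Sequence[MatchedPair],
    m: int | None = None,
    reps: int = SUBSAMPLE_REPS,
    seed: int | np.random.Generator = 0,
    frame_rate: float = 30.0,
) -> SubsampleNull:
    """Random-subsampling guard against spurious significance.

    Each rep draws ``m`` pairs without replacement (default 25% of the
    pairs, rounded up) and records the mean vocal-minus-control
    acceleration difference.  p is twice the smaller tail fraction of the
    rep means around zero, clipped to 1 — if zero lies outside the
    distribution the difference is consistent across subsamples.
    """
    n = len(pairs)
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if m is None:
        m = int(math.ceil(SUBSAMPLE_FRACTION * n))
    if m > n or m < 1:
        raise ValueError(f"subsample size {m} outside 1..{n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    diffs = np.array(
        [post_acceleration(p.vocal.samples, frame_rate) - post_acceleration(p.control, frame_rate)
         for p in pairs]
    )
    means = np.empty(reps)
    for r in range(reps):
        means[r] = diffs[rng.choice(n, size=m, replace=False)].mean()
    p = 2.0 * min(np.mean(means <= 0), np.mean(means >= 0))
    return SubsampleNull(means=means, m=m, reps=reps, p=float(min(p, 1.0)))


def epoch_analysis(
    events: Sequence[VocalEvent],
    speeds: np.ndarray,
    dist: np.ndarray,
    frame_rate: float = 30.0,
    by_relative_speed: bool = True,
) -> dict:
    """Three-epoch replication of the stratum tests.

    The recording is cut into three equal epochs (10-minute bins for a
    30-minute recording; shorter recordings get proportionally shorter
    bins).  Only temporally isolated signals are used, and controls are
    drawn from the same epoch as their vocal trajectory.  Returns
    {(vocalizer, relative_speed, epoch): (StratumResult, pairs)}.
    """
    n = speeds.shape[0]
    epoch_frames = int(EPOCH_S * frame_rate)
    if n < 3 * epoch_frames:
        import warnings

        warnings.warn("recording shorter than 30 min; using proportional epoch bins")
        epoch_frames = max(n // 3, 1)
    trajectories, _ = build_vocal_trajectories(events, speeds, dist, frame_rate)
    trajectories = [t for t in trajectories if t.isolated]
    event_frames = [int(ev.time * frame_rate) for ev in events]

    results: dict = {}
    rel_classes = ("faster", "slower") if by_relative_speed else (None,)
    for vocalizer in (1, 2):
        receiver = 3 - vocalizer
        for epoch in (1, 2, 3):
            lo = (epoch - 1) * epoch_frames
            hi = epoch * epoch_frames if epoch < 3 else n
            starts, windows = build_control_pool(
                speeds[:, receiver - 1], event_frames, frame_range=(lo, hi)
            )
            for rel in rel_classes:
                trajs = [
                    t for t in trajectories
                    if t.vocalizer == vocalizer
                    and lo <= t.emission_frame < hi
                    and (rel is None or t.relative_speed == rel)
                ]
                pairs, _ = match_controls(trajs, starts, windows)
                results[(vocalizer, rel, epoch)] = (stratum_test(pairs, frame_rate), pairs)
                # consume pool windows used by this stratum before the next
                used = {p.control_start for p in pairs}
                keep = ~np.isin(starts, list(used))
                starts, windows = starts[keep], windows[keep]
    return results


def response_table(results: dict, context: str = "") -> pd.DataFrame:
    """Flatten stratum results into the published table layout."""
    rows = []
    for key, value in results.items():
        res = value[0] if isinstance(value, tuple) else value
        row = {"context": context}
        if isinstance(key, tuple):
            names = ["vocalizer", "relative_speed", "bin"][: len(key)]
            row.update(dict(zip(names, key)))
        else:
            row["stratum"] = key
        row.update(
            {
                "n_pairs": res.n,
                "vocal_mean_accel": res.vocal_mean,
                "vocal_sd_accel": res.vocal_sd,
                "control_mean_accel": res.control_mean,
                "control_sd_accel": res.control_sd,
                "t": res.t,
                "p": res.p,
            }
        )
        rows.append(row)
    return pd.DataFrame(rows)


def analyze_responses(
    tracks: Tracks,
    events: Sequence[VocalEvent],
    mode: str = "isolated",
    seed: int = 0,
    subsample: bool = True,
) -> dict:
    """End-to-end stratified response analysis of one recording.

    ``mode``: "isolated" keeps only temporally isolated signals,
    "all" keeps every qualifying signal, "epochs" runs the three-epoch
    analysis (isolated signals, bin-restricted controls).  Returns a dict
    with stratum results, matched pairs, a QC log, and (for the two flat
    modes) subsampling confirmations.
    """
    from .dynamics import interanimal_distance

    fps = tracks.frame_rate
    speeds = np.column_stack(
        [compute_speeds(tracks.centroid[:, m], fps) for m in (0, 1)]
    )
    dist = interanimal_distance(tracks)
    if mode == "epochs":
        results = epoch_analysis(events, speeds, dist, fps)
        return {"mode": mode, "results": results, "table": response_table(results)}

    trajectories, qc = build_vocal_trajectories(events, speeds, dist, fps)
    if mode == "isolated":
        trajectories = [t for t in trajectories if t.isolated]
    elif mode != "all":
        raise ValueError(f"unknown mode {mode!r}")
    event_frames = [int(ev.time * fps) for ev in events]
    rng = np.random.default_rng(seed)

    results: dict = {}
    all_pairs: dict = {}
    nulls: dict = {}
    for vocalizer in (1, 2):
        receiver = 3 - vocalizer
        starts, windows = build_control_pool(speeds[:, receiver - 1], event_frames)
        for rel in ("faster", "slower"):
            trajs = [t for t in trajectories if t.vocalizer == vocalizer and t.relative_speed == rel]
            pairs, unmatched = match_controls(trajs, starts, windows)
            key = (vocalizer, rel)
            results[key] = stratum_test(pairs, fps)
            all_pairs[key] = pairs
            if subsample and len(pairs) >= 4:
                nulls[key] = subsample_null(pairs, seed=rng, frame_rate=fps)
            used = {p.control_start for p in pairs}
            keep = ~np.isin(starts, list(used))
            starts, windows = starts[keep], windows[keep]
    return {
        "mode": mode,
        "results": results,
        "pairs": all_pairs,
        "subsample": nulls,
        "qc": qc,
        "table": response_table(results),
    }
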