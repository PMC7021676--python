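"""Proximity and vocal-timing descriptors of a dyadic recording.

Inter-mouse distance on the video clock, close-proximity profiles
(fraction of time within 20 cm, overall and per minute), the time at
which each mouse has emitted a given fraction of its signals, at-emission
distance statistics, and a group-comparison helper implementing the
small-sample nonparametric policy (Mann-Whitney / Kruskal-Wallis with
Dunn's post-hoc below n = 15, t-test / ANOVA otherwise).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import Tracks, VocalEvent

PROXIMITY_THRESHOLD_CM = 20.0
NONPARAMETRIC_N = 15
ALPHA = 0.05


def interanimal_distance(tracks: Tracks, point: str = "centroid") -> np.ndarray:
    """Euclidean distance between the two mice per frame (cm).

    Uses centroids by default (the most stable tracked point); ``point``
    may be "nose".  Frames where either position is missing (NaN) give
    NaN distances.
    """
    pos = getattr(tracks, point)
    return np.linalg.norm(pos[:, 0] - pos[:, 1], axis=1)


def proximity_profile(
    dist: np.ndarray,
    frame_rate: float = 30.0,
    threshold: float = PROXIMITY_THRESHOLD_CM,
    bin_s: float = 60.0,
) -> dict:
    """Fraction of defined frames with distance < threshold, overall and
    per time bin.  Masked (NaN) frames are excluded from numerator and
    denominator alike."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    d = np.asarray(dist, float)
    defined = ~np.isnan(d)
    close = defined & (d < threshold)
    overall = close.sum() / defined.sum() if defined.any() else float("nan")
    per_bin = []
    bin_frames = int(round(bin_s * frame_rate))
    for lo in range(0, len(d), bin_frames):
        sl = slice(lo, lo + bin_frames)
        n_def = defined[sl].sum()
        per_bin.append(close[sl].sum() / n_def if n_def else float("nan"))
    return {"overall": float(overall), "per_bin": per_bin, "threshold": threshold}


def emission_timeline(
    events: Sequence[VocalEvent], dist: np.ndarray, frame_rate: float = 30.0
) -> pd.DataFrame:
    """Per-event table: time, vocalizer, and inter-mouse distance at the
    emission frame."""
    rows = []
    for ev in sorted(events, key=lambda e: e.time):
        f = min(int(ev.time * frame_rate), len(dist) - 1)
        rows.append({"time_s": ev.time, "vocalizer": ev.vocalizer, "distance_cm": dist[f]})
    return pd.DataFrame(rows, columns=["time_s", "vocalizer", "distance_cm"])


def time_to_fraction_emitted(
    timeline: pd.DataFrame, q: float = 0.5
) -> dict[int, float | None]:
    """Time of the ceil(q*N)-th emission per mouse (the cumulative-count
    step function crossing, no interpolation).  Mice with zero emissions
    are reported as None."""
    if not 0 < q <= 1:
        raise ValueError("q must be in (0, 1]")
    out: dict[int, float | None] = {}
    for mouse in (1, 2):
        times = np.sort(timeline.loc[timeline.vocalizer == mouse, "time_s"].to_numpy())
        if times.size == 0:
            out[mouse] = None
        else:
            k = int(np.ceil(q * times.size))
            out[mouse] = float(times[k - 1])
    return out


def emission_distance_stats(timeline: pd.DataFrame) -> dict[int, dict]:
    """Per-mouse median and IQR of inter-mouse distance at emission."""
    out = {}
    for mouse in (1, 2):
        d = timeline.loc[timeline.vocalizer == mouse, "distance_cm"].dropna().to_numpy()
        if d.size == 0:
            out[mouse] = {"median": None, "iqr": (None, None), "n": 0}
        else:
            q1, med, q3 = np.percentile(d, [25, 50, 75])
            out[mouse] = {"median": float(med), "iqr": (float(q1), float(q3)), "n": int(d.size)}
    return out


@dataclass
class GroupComparison:
    test: str
    statistic: float
    df: int | None
    p: float
    posthoc: pd.DataFrame | None


def _dunn_posthoc(groups: Sequence[np.ndarray]) -> pd.DataFrame:
    """Dunn's rank-based pairwise test with tie correction, Bonferroni
    adjusted across pairs."""
    pooled = np.concatenate(groups)
    n_total = pooled.size
    ranks = stats.rankdata(pooled)
    # tie correction term
    _, counts = np.unique(pooled, return_counts=True)
    tie = (counts**3 - counts).sum() / (12.0 * (n_total - 1))
    mean_ranks, sizes = [], []
    start = 0
    for g in groups:
        mean_ranks.append(ranks[start : start + g.size].mean())
        sizes.append(g.size)
        start += g.size
    rows = []
    n_pairs = len(groups) * (len(groups) - 1) // 2
    for i, j in itertools.combinations(range(len(groups)), 2):
        se = np.sqrt((n_total * (n_total + 1) / 12.0 - tie) * (1 / sizes[i] + 1 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        p = 2 * stats.norm.sf(abs(z))
        rows.append(
            {"group_a": i, "group_b": j, "z": z, "p_raw": p, "p_adj": min(p * n_pairs, 1.0)}
        )
    return pd.DataFrame(rows)


def group_compare(groups: Sequence[Sequence[float]], alpha: float = ALPHA) -> GroupComparison:
    """Compare >= 2 groups of scalars under the sample-size policy.

    Two groups with any n < 15: Mann-Whitney (the first group's rank sum
    is reported as the statistic).  Three or more groups with any n < 15:
    Kruskal-Wallis (df = k - 1) with Dunn's post-hoc.  All n >= 15:
    two-sample t-test or one-way ANOVA with pairwise Welch t post-hoc.
    """
    gs = [np.asarray(g, float) for g in groups]
    if len(gs) < 2:
        raise ValueError("need at least two groups")
    if any(g.size == 0 for g in gs):
        raise ValueError("groups must be non-empty")
    small = any(g.size < NONPARAMETRIC_N for g in gs)
    if len(gs) == 2:
        if small:
            res = stats.mannwhitneyu(gs[0], gs[1], alternative="two-sided")
            ranksum = float(res.statistic + gs[0].size * (gs[0].size + 1) / 2)
            return GroupComparison("mann-whitney", ranksum, None, float(res.pvalue), None)
        res = stats.ttest_ind(gs[0], gs[1])
        return GroupComparison("t-test", float(res.statistic), int(gs[0].size + gs[1].size - 2), float(res.pvalue), None)
    if small:
        res = stats.kruskal(*gs)
        return GroupComparison(
            "kruskal-wallis", float(res.statistic), len(gs) - 1, float(res.pvalue), _dunn_posthoc(gs)
        )
    res = stats.f_oneway(*gs)
    rows = []
    n_pairs = len(gs) * (len(gs) - 1) // 2
    for i, j in itertools.combinations(range(len(gs)), 2):
        t = stats.ttest_ind(gs[i], gs[j], equal_var=False)
        rows.append(
            {"group_a": i, "group_b": j, "t": float(t.statistic),
             "p_raw": float(t.pvalue), "p_adj": min(float(t.pvalue) * n_pairs, 1.0)}
        )
    return GroupComparison(
        "anova", float(res.statistic), len(gs) - 1, float(res.pvalue), pd.DataFrame(rows)
    )
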