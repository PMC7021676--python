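"""CSV interchange formats for tracks, events, and segmented signals."""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .segmentation import VocalSignal
from .simulate import Tracks, VocalEvent

_FLOAT_FMT = "%.6f"


def tracks_to_frame(tracks: Tracks) -> pd.DataFrame:
    rows = []
    n = tracks.n_frames
    for m in (0, 1):
        rows.append(
            pd.DataFrame(
                {
                    "frame": np.arange(n),
                    "mouse_id": m + 1,
                    "nose_x_cm": tracks.nose[:, m, 0],
                    "nose_y_cm": tracks.nose[:, m, 1],
                    "centroid_x_cm": tracks.centroid[:, m, 0],
                    "centroid_y_cm": tracks.centroid[:, m, 1],
                }
            )
        )
    return pd.concat(rows).sort_values(["frame", "mouse_id"], kind="stable").reset_index(drop=True)


def write_tracks_csv(path, tracks: Tracks) -> None:
    tracks_to_frame(tracks).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_tracks_csv(path, frame_rate: float = 30.0) -> Tracks:
    df = pd.read_csv(path)
    n = int(df["frame"].max()) + 1 if len(df) else 0
    centroid = np.full((n, 2, 2), np.nan)
    nose = np.full((n, 2, 2), np.nan)
    for m in (1, 2):
        sub = df[df.mouse_id == m]
        idx = sub["frame"].to_numpy(int)
        centroid[idx, m - 1, 0] = sub["centroid_x_cm"]
        centroid[idx, m - 1, 1] = sub["centroid_y_cm"]
        nose[idx, m - 1, 0] = sub["nose_x_cm"]
        nose[idx, m - 1, 1] = sub["nose_y_cm"]
    return Tracks(frame_rate, centroid, nose)


def write_truth_events_csv(path, events: Sequence[VocalEvent]) -> None:
    pd.DataFrame(
        {
            "time_s": [e.time for e in events],
            "vocalizer_id": [e.vocalizer for e in events],
            "source_x_cm": [e.source_xy[0] for e in events],
            "source_y_cm": [e.source_xy[1] for e in events],
        }
    ).to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_signals_csv(sig_path, contour_path, signals: Sequence[VocalSignal]) -> None:
    pd.DataFrame(
        {
            "signal_id": range(len(signals)),
            "start_s": [s.start_time for s in signals],
            "stop_s": [s.stop_time for s in signals],
            "pixel_count": [s.pixel_count for s in signals],
            "n_contour_points": [len(s.contour) for s in signals],
        }
    ).to_csv(sig_path, index=False, float_format=_FLOAT_FMT)
    rows = []
    for i, s in enumerate(signals):
        for t, f in s.contour:
            rows.append({"signal_id": i, "time_s": t, "freq_khz": f / 1e3})
    pd.DataFrame(rows, columns=["signal_id", "time_s", "freq_khz"]).to_csv(
        contour_path, index=False, float_format=_FLOAT_FMT
    )


def read_signals_csv(sig_path, contour_path) -> list[VocalSignal]:
    sig = pd.read_csv(sig_path)
    con = pd.read_csv(contour_path)
    out = []
    for _, row in sig.iterrows():
        c = con[con.signal_id == row.signal_id]
        contour = np.column_stack([c.time_s.to_numpy(), c.freq_khz.to_numpy() * 1e3])
        out.append(
            VocalSignal(
                start_time=float(row.start_s),
                stop_time=float(row.stop_s),
                pixel_count=int(row.pixel_count),
                contour=contour,
            )
        )
    return out


def write_attributed_events_csv(path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_attributed_events(path, signals=None) -> list[VocalEvent]:
    """Load attributed events back as VocalEvent records (assigned only)."""
    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        if pd.isna(row.assigned_to):
            continue
        out.append(
            VocalEvent(
                time=float(row.time_s),
                vocalizer=int(row.assigned_to),
                source_xy=np.array([np.nan, np.nan]),
                contour=np.array([[0.0, 60e3], [0.03, 60e3]]),
            )
        )
    return out
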