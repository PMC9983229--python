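"""Frame-to-frame linking of detections and track speed statistics.

The linker mirrors the published tracker configuration — a motion model
with a 6 µm maximum link distance and gap closing over up to 3 missing
frames — as constant-velocity ("autoregressive") prediction plus optimal
bipartite assignment per frame.  Gap crossings widen the gate
proportionally to the number of skipped frames.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from pathlib import Path
from scipy.optimize import linear_sum_assignment

logger = logging.getLogger(__name__)

__all__ = [
    "Detection",
    "Track",
    "TrackSet",
    "detections_from_labels",
    "link_frames",
    "mean_track_speed",
]

_BIG = 1e9  # cost sentinel for gated-out pairs


@dataclass(frozen=True)
class Detection:
    frame: int
    y_um: float
    x_um: float
    z_um: float | None = None
    label: int | None = None
    area: float | None = None

    @property
    def position(self) -> np.ndarray:
        if self.z_um is None:
            return np.array([self.y_um, self.x_um])
        return np.array([self.z_um, self.y_um, self.x_um])


@dataclass
class Track:
    track_id: int
    detections: list[Detection] = field(default_factory=list)
    gap_flags: list[bool] = field(default_factory=list)  # True = link crossed a gap

    @property
    def frames(self) -> list[int]:
        return [d.frame for d in self.detections]

    def path_length_um(self) -> float:
        pos = np.array([d.position for d in self.detections])
        return float(np.linalg.norm(np.diff(pos, axis=0), axis=1).sum())


@dataclass
class TrackSet:
    tracks: list[Track]
    max_distance_um: float
    max_gap_frames: int
    motion_model: str
    qc: dict = field(default_factory=dict)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for tr in self.tracks:
            for det, gap in zip(tr.detections, tr.gap_flags):
                rows.append(
                    dict(
                        track_id=tr.track_id,
                        frame=det.frame,
                        y_um=det.y_um,
                        x_um=det.x_um,
                        z_um=det.z_um,
                        gap_flag=gap,
                    )
                )
        return pd.DataFrame(
            rows, columns=["track_id", "frame", "y_um", "x_um", "z_um", "gap_flag"]
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(Path(path), index=False)

    def speed_table(self, frame_interval_s: float) -> pd.DataFrame:
        """Per-track mean speeds (µm/min).  Single-detection tracks carry
        no displacement information; they are excluded and counted in
        ``qc['single_detection_tracks']``."""
        rows = []
        singles = 0
        for tr in self.tracks:
            if len(tr.detections) < 2:
                singles += 1
                continue
            rows.append(
                dict(
                    track_id=tr.track_id,
                    n_detections=len(tr.detections),
                    speed_um_min=mean_track_speed(tr, frame_interval_s),
                )
            )
        self.qc["single_detection_tracks"] = singles
        return pd.DataFrame(rows, columns=["track_id", "n_detections", "speed_um_min"])


def detections_from_labels(labels_by_frame) -> list[Detection]:
    """Build detections from a sequence of per-frame :class:`RegionLabels`
    (2D centroids in µm)."""
    dets = []
    for frame, labels in enumerate(labels_by_frame):
        for _, row in labels.table.iterrows():
            dets.append(
                Detection(
                    frame=frame,
                    y_um=float(row["centroid_y_um"]),
                    x_um=float(row["centroid_x_um"]),
                    label=int(row["label"]),
                    area=float(row[labels.measure_column]),
                )
            )
    return dets


@dataclass
class _Active:
    track: Track
    last_pos: np.ndarray
    velocity: np.ndarray  # per-frame, µm
    last_frame: int


def link_frames(
    detections: list[Detection],
    max_distance_um: float = 6.0,
    max_gap_frames: int = 3,
    motion_model: str = "autoregressive",
) -> TrackSet:
    """Link detections into trajectories.

    Per frame, every active track predicts its position — last position
    plus last velocity times the frame step for the ``autoregressive``
    model, last position for ``nearest`` — and tracks are assigned to
    detections by minimising the summed distances (Hungarian algorithm)
    under the gate ``max_distance_um x frame_step``.  A track left
    unmatched persists for up to ``max_gap_frames`` consecutive missing
    frames before termination; a link that crosses a gap is flagged.
    Deterministic for a fixed input order.
    """
    if max_distance_um <= 0:
        raise ValueError("max_distance_um must be positive")
    if max_gap_frames < 0:
        raise ValueError("max_gap_frames must be >= 0")
    if motion_model not in ("autoregressive", "nearest"):
        raise ValueError(f"unknown motion model {motion_model!r}")

    by_frame: dict[int, list[Detection]] = {}
    for det in detections:
        by_frame.setdefault(det.frame, []).append(det)
    if not by_frame:
        return TrackSet([], max_distance_um, max_gap_frames, motion_model)

    tracks: list[Track] = []
    active: list[_Active] = []
    n_links = 0

    def start_track(det: Detection) -> None:
        tr = Track(track_id=len(tracks), detections=[det], gap_flags=[False])
        tracks.append(tr)
        active.append(
            _Active(
                track=tr,
                last_pos=det.position,
                velocity=np.zeros_like(det.position, dtype=float),
                last_frame=det.frame,
            )
        )

    frames = range(min(by_frame), max(by_frame) + 1)
    for f in frames:
        # retire tracks whose gap can no longer be closed
        active = [a for a in active if f - a.last_frame - 1 <= max_gap_frames]
        dets = by_frame.get(f, [])
        if not dets:
            continue
        if active:
            preds = np.array(
                [
                    a.last_pos
                    + (a.velocity * (f - a.last_frame) if motion_model == "autoregressive" else 0.0)
                    for a in active
                ]
            )
            pos = np.array([d.position for d in dets])
            last = np.array([a.last_pos for a in active])
            dist = np.linalg.norm(preds[:, None, :] - pos[None, :, :], axis=2)
            realized = np.linalg.norm(last[:, None, :] - pos[None, :, :], axis=2)
            gates = np.array([max_distance_um * (f - a.last_frame) for a in active])
            # gate both the prediction error and the realized displacement:
            # the link must stay physically plausible even when the
            # constant-velocity prediction overshoots
            ok = (dist <= gates[:, None]) & (realized <= gates[:, None])
            cost = np.where(ok, dist, _BIG)
            rows, cols = linear_sum_assignment(cost)
            matched_dets = set()
            for i, j in zip(rows, cols):
                if cost[i, j] >= _BIG:
                    continue
                a = active[i]
                det = dets[j]
                step = f - a.last_frame
                a.track.detections.append(det)
                a.track.gap_flags.append(step > 1)
                a.velocity = (det.position - a.last_pos) / step
                a.last_pos = det.position
                a.last_frame = f
                matched_dets.add(j)
                n_links += 1
            for j, det in enumerate(dets):
                if j not in matched_dets:
                    start_track(det)
        else:
            for det in dets:
                start_track(det)

    ts = TrackSet(tracks, max_distance_um, max_gap_frames, motion_model)
    ts.qc = {
        "n_detections": len(detections),
        "n_tracks": len(tracks),
        "n_links": n_links,
    }
    # conservation: every detection is either a link target or a track start
    assert n_links + len(tracks) == len(detections)
    return ts


def mean_track_speed(track: Track, frame_interval_s: float) -> float:
    """Mean tracking speed in µm/min: total path length over total elapsed
    time (gap steps contribute their true elapsed time)."""
    if len(track.detections) < 2:
        raise ValueError("speed undefined for a single-detection track")
    elapsed_frames = track.detections[-1].frame - track.detections[0].frame
    elapsed_min = elapsed_frames * frame_interval_s / 60.0
    return track.path_length_um() / elapsed_min
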