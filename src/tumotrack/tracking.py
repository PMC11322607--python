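"""3D T-cell detection and frame-to-frame trajectory linking.

Detection thresholds the T-cell channel volume, labels connected
components, and keeps only components whose physical volume lies strictly
inside the single-cell gate (280 µm³, 10,000 µm³). Linking solves, per
consecutive frame pair, a global one-to-one assignment (Hungarian) over
candidate pairs within a displacement gate; unmatched detections end or
begin tracks and there is no gap closing — a detection missing for one
frame splits its track, and short fragments are removed by the minimum
duration filter.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import linear_sum_assignment

from tumotrack.scenario import ValidationError

VOLUME_GATE_UM3: Tuple[float, float] = (280.0, 10_000.0)
DEFAULT_MAX_DISPLACEMENT_UM = 30.0
DEFAULT_MIN_DURATION_H = 10.0


@dataclass(frozen=True)
class Detection3D:
    """One thresholded object at one timepoint."""

    t: float                      # h
    position: Tuple[float, float, float]  # (x, y, z) µm, intensity-weighted
    volume: float                 # µm³


@dataclass
class Trajectory:
    """Time-ordered 3D positions (µm) of one tracked cell."""

    cell_id: int
    times: np.ndarray        # (n,) h, strictly increasing, uniform spacing
    positions: np.ndarray    # (n, 3) µm

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.shape != (len(self.times), 3):
            raise ValidationError("positions must be (n_times, 3)")
        if len(self.times) >= 2 and np.any(np.diff(self.times) <= 0):
            raise ValidationError("trajectory timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def duration(self) -> float:
        """Observation span in hours."""
        return float(self.times[-1] - self.times[0])


def detect_3d(volume: np.ndarray, threshold: float | str,
              lateral_pixel_size: float, z_step: float,
              t: float = 0.0,
              volume_gate: Tuple[float, float] = VOLUME_GATE_UM3,
              ) -> List[Detection3D]:
    """Detect cell-sized objects in one (Z, Y, X) volume.

    The volume gate is strict on both sides, retaining components with
    ``low < volume < high`` µm³ — the predicted size range of a single
    cell. Centers of mass are intensity-weighted and reported in µm under
    the pixel-center convention.
    """
    if lateral_pixel_size <= 0 or z_step <= 0:
        raise ValidationError("voxel calibration must be > 0")
    low, high = volume_gate
    if not low < high:
        raise ValidationError(f"volume gate must satisfy low < high, got {volume_gate}")
    volume = np.asarray(volume)
    if volume.ndim != 3:
        raise ValidationError("expected a (Z, Y, X) volume")
    if threshold == "otsu":
        from skimage.filters import threshold_otsu
        if volume.max() == volume.min():
            return []
        threshold = float(threshold_otsu(volume))
    mask = volume > threshold
    if not mask.any():
        return []
    labels, n_obj = ndimage.label(mask)
    voxel_volume = lateral_pixel_size ** 2 * z_step
    counts = np.bincount(labels.ravel())[1:]
    volumes = counts * voxel_volume
    keep = np.flatnonzero((volumes > low) & (volumes < high)) + 1
    detections: List[Detection3D] = []
    if len(keep):
        coms = ndimage.center_of_mass(volume, labels, keep)
        for label, com in zip(keep, coms):
            z_idx, y_idx, x_idx = com
            detections.append(Detection3D(
                t=t,
                position=((x_idx + 0.5) * lateral_pixel_size,
                          (y_idx + 0.5) * lateral_pixel_size,
                          (z_idx + 0.5) * z_step),
                volume=float(volumes[label - 1])))
    return detections


def _match_frame_pair(prev: np.ndarray, curr: np.ndarray,
                      max_displacement: float) -> List[Tuple[int, int]]:
    """Globally optimal gated matching between two detection sets.

    Maximizes the number of matched pairs within the gate and, among those
    matchings, minimizes total Euclidean cost (padded-square Hungarian:
    the cost of leaving a detection unmatched equals the gate, so any
    allowed pair — cost ≤ gate < 2·gate — is preferred to dropping both
    endpoints).
    """
    n, m = len(prev), len(curr)
    if n == 0 or m == 0:
        return []
    dist = np.linalg.norm(prev[:, None, :] - curr[None, :, :], axis=2)
    big = max_displacement
    forbidden = 1e6 * (big + 1.0) * (n + m)
    size = n + m
    cost = np.full((size, size), 0.0)
    block = np.where(dist <= max_displacement, dist, forbidden)
    cost[:n, :m] = block
    cost[:n, m:] = forbidden
    cost[np.arange(n), m + np.arange(n)] = big
    cost[n:, :m] = forbidden
    cost[n + np.arange(m), np.arange(m)] = big
    rows, cols = linear_sum_assignment(cost)
    return [(int(r), int(c)) for r, c in zip(rows, cols)
            if r < n and c < m and dist[r, c] <= max_displacement]


def link(detections_by_frame: Sequence[Sequence[Detection3D]],
         max_displacement: float = DEFAULT_MAX_DISPLACEMENT_UM,
         ) -> List[Trajectory]:
    """Link per-frame detections into trajectories.

    Consecutive frames are matched by minimum-total-cost one-to-one
    assignment among pairs closer than ``max_displacement`` µm; unmatched
    detections terminate or start tracks. Only tracks with ≥ 2 points are
    returned, ordered deterministically by (start frame, first detection
    index).
    """
    if len(detections_by_frame) < 2:
        raise ValidationError("linking requires at least two timepoints")
    if max_displacement <= 0:
        raise ValidationError("max_displacement must be > 0")
    tracks: List[Dict[str, list]] = []
    open_tracks: Dict[int, int] = {}  # detection index in current frame -> track index

    def new_track(det: Detection3D) -> int:
        tracks.append({"t": [det.t], "pos": [det.position]})
        return len(tracks) - 1

    prev_dets = list(detections_by_frame[0])
    open_tracks = {i: new_track(d) for i, d in enumerate(prev_dets)}
    for frame in detections_by_frame[1:]:
        curr_dets = list(frame)
        prev_pos = np.asarray([d.position for d in prev_dets], dtype=float).reshape(-1, 3)
        curr_pos = np.asarray([d.position for d in curr_dets], dtype=float).reshape(-1, 3)
        matches = _match_frame_pair(prev_pos, curr_pos, max_displacement)
        matched_curr = {}
        for r, c in matches:
            track_idx = open_tracks[r]
            tracks[track_idx]["t"].append(curr_dets[c].t)
            tracks[track_idx]["pos"].append(curr_dets[c].position)
            matched_curr[c] = track_idx
        next_open = dict(matched_curr)
        for c, det in enumerate(curr_dets):
            if c not in matched_curr:
                next_open[c] = new_track(det)
        open_tracks = next_open
        prev_dets = curr_dets
    out: List[Trajectory] = []
    cell_id = 0
    for tr in tracks:
        if len(tr["t"]) >= 2:
            out.append(Trajectory(cell_id=cell_id,
                                  times=np.asarray(tr["t"]),
                                  positions=np.asarray(tr["pos"])))
            cell_id += 1
    return out


def filter_tracks(trajectories: Sequence[Trajectory],
                  min_duration_h: float = DEFAULT_MIN_DURATION_H,
                  ) -> List[Trajectory]:
    """Keep trajectories observed for at least ``min_duration_h`` hours."""
    return [tr for tr in trajectories if tr.duration >= min_duration_h]


def trajectories_to_frame(trajectories: Sequence[Trajectory]) -> pd.DataFrame:
    """Tidy table `cell_id, t_h, x_um, y_um, z_um` of all trajectories."""
    rows = []
    for tr in trajectories:
        for t, p in zip(tr.times, tr.positions):
            rows.append((tr.cell_id, t, p[0], p[1], p[2]))
    return pd.DataFrame(rows, columns=["cell_id", "t_h", "x_um", "y_um", "z_um"])


def trajectories_from_frame(df: pd.DataFrame) -> List[Trajectory]:
    """Inverse of :func:`trajectories_to_frame`."""
    out = []
    for cell_id, grp in df.groupby("cell_id", sort=True):
        grp = grp.sort_values("t_h")
        out.append(Trajectory(cell_id=int(cell_id),
                              times=grp["t_h"].to_numpy(),
                              positions=grp[["x_um", "y_um", "z_um"]].to_numpy()))
    return out
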