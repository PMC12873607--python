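"""Linking per-frame localizations into trajectories.

Frame-to-frame correspondence is solved as a globally optimal one-to-one
assignment (Hungarian algorithm) on squared displacement, with a hard
gating radius r_max(k) = sqrt(4 * d_max_expected * k * frame_interval) *
safety_factor for a link spanning k frames. Gap closing is greedy over the
span: direct links (k=1) are assigned first, then detections and track ends
left over compete at k=2, then k=3, up to max_gaps+1. Unmatched detections
start new trajectories.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from .config import LinkingConfig

__all__ = ["link_localizations", "trajectory_stats"]

_BIG = 1e30


def _assign(ends_xy: np.ndarray, dets_xy: np.ndarray, r_max: float):
    """Optimal one-to-one matching under a hard radius gate.

    Returns (end_indices, det_indices) of accepted links, minimizing summed
    squared displacement over admissible pairs.
    """
    d2 = cdist(ends_xy, dets_xy, "sqeuclidean")
    cost = np.where(d2 <= r_max * r_max, d2, _BIG)
    rows, cols = linear_sum_assignment(cost)
    ok = cost[rows, cols] < _BIG
    return rows[ok], cols[ok]


def link_localizations(locs: pd.DataFrame, cfg: LinkingConfig) -> pd.DataFrame:
    """Link a localization table (frame, x_um, y_um, ...) into trajectories.

    Input must be sorted by frame. Returns the same rows with a
    ``trajectory_id`` column, ordered by (trajectory_id, frame); ids are
    assigned in order of track creation. Unlinkable rows become singleton
    trajectories.
    """
    required = {"frame", "x_um", "y_um"}
    missing = required - set(locs.columns)
    if missing:
        raise ValueError(f"localization table missing columns: {sorted(missing)}")
    if len(locs) == 0:
        out = locs.copy()
        out["trajectory_id"] = pd.Series(dtype=int)
        return out
    frames = locs["frame"].to_numpy()
    if np.any(np.diff(frames) < 0):
        raise ValueError("localizations must be sorted by frame")

    xy = locs[["x_um", "y_um"]].to_numpy()
    track_of_row = np.full(len(locs), -1, int)
    # active track state: id -> (row index of last point, last frame)
    last_row: list[int] = []     # per track id
    last_frame: list[int] = []
    next_id = 0

    order = np.arange(len(locs))
    for f in np.unique(frames):
        det_rows = order[frames == f]
        unassigned = np.ones(len(det_rows), bool)
        for k in range(1, cfg.max_gaps + 2):
            if not unassigned.any():
                break
            cand_tracks = [tid for tid in range(next_id) if last_frame[tid] == f - k]
            if not cand_tracks:
                continue
            ends_xy = xy[[last_row[t] for t in cand_tracks]]
            det_idx = det_rows[unassigned]
            e_i, d_i = _assign(ends_xy, xy[det_idx], cfg.r_max(k))
            for ei, di in zip(e_i, d_i):
                tid = cand_tracks[ei]
                row = det_idx[di]
                track_of_row[row] = tid
                last_row[tid] = row
                last_frame[tid] = f
            taken = det_idx[d_i]
            unassigned[np.isin(det_rows, taken)] = False
        for row in det_rows[unassigned]:
            track_of_row[row] = next_id
            last_row.append(row)
            last_frame.append(f)
            next_id += 1

    out = locs.copy()
    out["trajectory_id"] = track_of_row
    return out.sort_values(["trajectory_id", "frame"]).reset_index(drop=True)


def trajectory_stats(trajs: pd.DataFrame, n_timepoints: int = 7) -> dict:
    """Summary counts used for the per-cell minimum-data filter.

    Jump counts per time gap use gapless pairs only (a displacement spanning
    a closed gap is not a valid jump for the histograms) and are uncapped.
    """
    if len(trajs) == 0:
        return {
            "n_trajectories": 0, "n_localizations": 0, "median_length": 0.0,
            "jumps_per_gap": {k: 0 for k in range(1, n_timepoints + 1)},
        }
    from .kinetics import collect_jumps

    lengths = trajs.groupby("trajectory_id").size()
    jumps = {k: len(collect_jumps(trajs, k, None))
             for k in range(1, n_timepoints + 1)}
    return {
        "n_trajectories": int(len(lengths)),
        "n_localizations": int(len(trajs)),
        "median_length": float(lengths.median()),
        "jumps_per_gap": jumps,
    }
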