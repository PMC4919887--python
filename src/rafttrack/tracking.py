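"""Spot detection and nearest-position linking.

Trajectories are recovered from per-frame localizations by connecting the
nearest positions in consecutive frames: a greedy mutual-nearest-neighbor
assignment with a distance gate.  An optional Gaussian-spot detection
front end turns synthetic image stacks into localizations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from skimage.feature import peak_local_max

from .trajectory import Trajectory

log = logging.getLogger(__name__)

DETECTION_COLUMNS = ["frame", "x_um", "y_um", "intensity"]


def detect_spots(stack: np.ndarray, pixel_size: float,
                 threshold_sd: float = 5.0, min_distance_px: int = 3,
                 refine_radius_px: int = 3) -> pd.DataFrame:
    """Detect diffraction-limited spots in an image stack.

    Local maxima above ``background mean + threshold_sd * background sd``
    (background statistics from the median/MAD of each frame) are refined
    to sub-pixel positions by an intensity-weighted centroid in a window
    of ``refine_radius_px``.  Returns a detection table with columns
    ``frame, x_um, y_um, intensity`` in µm coordinates.  Empty frames
    contribute no rows.
    """
    if stack.ndim == 2:
        stack = stack[None]
    if threshold_sd <= 0:
        raise ValueError("threshold_sd must be positive")
    rows = []
    for f, frame in enumerate(stack):
        img = frame.astype(float)
        bg = np.median(img)
        mad = np.median(np.abs(img - bg))
        sd = 1.4826 * mad if mad > 0 else img.std()
        thr = bg + threshold_sd * sd
        coords = peak_local_max(img, min_distance=min_distance_px,
                                threshold_abs=thr, exclude_border=False)
        for cy, cx in coords:
            y0 = max(cy - refine_radius_px, 0)
            y1 = min(cy + refine_radius_px + 1, img.shape[0])
            x0 = max(cx - refine_radius_px, 0)
            x1 = min(cx + refine_radius_px + 1, img.shape[1])
            win = img[y0:y1, x0:x1] - bg
            win = np.clip(win, 0, None)
            tot = win.sum()
            if tot <= 0:
                continue
            ys, xs = np.mgrid[y0:y1, x0:x1]
            rows.append((f, (xs * win).sum() / tot * pixel_size,
                         (ys * win).sum() / tot * pixel_size, tot))
    return pd.DataFrame(rows, columns=DETECTION_COLUMNS)


def link_nearest(detections: pd.DataFrame, max_disp: float,
                 max_gap: int = 0, frame_period: float = 0.025,
                 min_length: int = 2) -> List[Trajectory]:
    """Link per-frame detections into trajectories.

    Frame-to-frame assignment is greedy mutual nearest neighbor: a
    detection is linked to an active track only if each is the other's
    nearest candidate and their distance is at most ``max_disp`` (µm).
    Unmatched detections seed new tracks; a track may bridge up to
    ``max_gap`` missing frames before it is terminated.  Ties are broken
    toward the lower track id.  Every detection belongs to at most one
    track.
    """
    if max_disp <= 0:
        raise ValueError("max_disp must be positive")
    if max_gap < 0:
        raise ValueError("max_gap must be non-negative")
    det = detections.sort_values("frame", kind="stable").reset_index(drop=True)
    dup = det.duplicated(subset=["frame", "x_um", "y_um"])
    if dup.any():
        log.warning("%d duplicate (frame, x, y) detections kept", int(dup.sum()))

    # active tracks: lists of (frame, x, y); terminated collected at the end
    tracks: List[List[tuple]] = []
    active: List[int] = []
    for frame, sub in det.groupby("frame", sort=True):
        frame = int(frame)
        pts = sub[["x_um", "y_um"]].to_numpy()
        # retire tracks whose last frame is too old
        still = []
        for ti in active:
            if frame - tracks[ti][-1][0] <= max_gap + 1:
                still.append(ti)
        active = still
        assigned = np.full(len(pts), -1)
        if active and len(pts):
            last = np.array([[tracks[ti][-1][1], tracks[ti][-1][2]] for ti in active])
            tree_det = cKDTree(pts)
            # nearest detection for each track, then require mutuality
            d_td, near_det = tree_det.query(last)
            tree_trk = cKDTree(last)
            d_dt, near_trk = tree_trk.query(pts)
            order = np.argsort([tracks[t][-1][0] * 0 + t for t in active])  # by id
            used_det = np.zeros(len(pts), bool)
            for rank in order:
                j = near_det[rank]
                if used_det[j] or d_td[rank] > max_disp:
                    continue
                if near_trk[j] == rank:  # mutual
                    tracks[active[rank]].append((frame, pts[j, 0], pts[j, 1]))
                    used_det[j] = True
                    assigned[j] = active[rank]
        survivors = set(assigned[assigned >= 0].tolist())
        # tracks that found no match stay active (until gap expires)
        for j in range(len(pts)):
            if assigned[j] < 0:
                tracks.append([(frame, pts[j, 0], pts[j, 1])])
                survivors.add(len(tracks) - 1)
        active = sorted(set(active) | {t for t in survivors})
    out = []
    for tid, rows in enumerate(tracks):
        if len(rows) < min_length:
            continue
        arr = np.array(rows)
        out.append(Trajectory(track_id=tid, frames=arr[:, 0].astype(int),
                              x=arr[:, 1], y=arr[:, 2], frame_period=frame_period))
    return out


def default_max_disp(D_max: float, frame_period: float) -> float:
    """Gating distance 4·sqrt(4·D_max·τ): four frame-scale RMS displacements."""
    return 4.0 * np.sqrt(4.0 * D_max * frame_period)
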