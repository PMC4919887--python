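"""Detection of transient confinement in single-molecule trajectories.

Implements the probability-of-staying confinement index: for a sliding
window of duration t the maximal excursion R from the window's first
position is measured, and the probability ψ that a freely diffusing
molecule with coefficient D would have stayed within R is estimated with
the standard log-linear approximation

    log10 ψ = 0.2048 − 2.5117 · D t / R² ,

valid for ψ ≲ 0.1.  The confinement index is L = max(0, −log10 ψ − 1),
zero wherever the approximation puts ψ near 1.  A molecule is considered
transiently confined where L stays above a threshold for a minimum
duration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np

from .trajectory import Trajectory

DEFAULT_WINDOW = 30
DEFAULT_THRESHOLD = 3.16
DEFAULT_MIN_DURATION = 10
DEFAULT_MIN_GAP = 2

_A = 0.2048
_B = 2.5117


@dataclass
class ConfinementEvent:
    track_id: int
    start_frame: int
    end_frame: int   # inclusive
    L_max: float
    radius: float    # max distance from the segment centroid, µm


def confinement_index(traj: Trajectory, window: int = DEFAULT_WINDOW,
                      D_ref: float = None) -> np.ndarray:
    """Per-frame confinement index L(t), averaged over covering windows.

    ``D_ref`` is the reference free diffusion coefficient (µm²/s),
    typically the mode of the fast population converted by D = R²/4τ.
    Returns an array aligned with ``traj.frames``; frames not covered by
    any full window carry 0.  Tracks shorter than the window yield an
    all-zero series (with a warning to the caller's discretion).
    """
    if window < 4:
        raise ValueError("window must be at least 4 frames")
    if D_ref is None or D_ref <= 0:
        raise ValueError("D_ref must be a positive diffusion coefficient")
    n = len(traj)
    L = np.zeros(n)
    if n < window or not traj.gap_free():
        return L
    pos = traj.positions
    t_win = window * traj.frame_period
    cover = np.zeros(n)
    Lsum = np.zeros(n)
    for s0 in range(0, n - window + 1):
        seg = pos[s0:s0 + window]
        R = np.max(np.hypot(seg[:, 0] - seg[0, 0], seg[:, 1] - seg[0, 1]))
        R = max(R, 1e-9)
        log_psi = _A - _B * D_ref * t_win / (R * R)
        Lw = max(0.0, -log_psi - 1.0)
        Lsum[s0:s0 + window] += Lw
        cover[s0:s0 + window] += 1.0
    has = cover > 0
    L[has] = Lsum[has] / cover[has]
    return L


def extract_confined_events(traj: Trajectory, L: np.ndarray,
                            threshold: float = DEFAULT_THRESHOLD,
                            min_duration: int = DEFAULT_MIN_DURATION,
                            min_gap: int = DEFAULT_MIN_GAP,
                            ) -> List[ConfinementEvent]:
    """Maximal supra-threshold runs of L as confinement events.

    Runs with L ≥ threshold lasting at least ``min_duration`` frames
    become events; neighboring supra-threshold runs separated by fewer
    than ``min_gap`` sub-threshold frames are merged before the duration
    test.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    L = np.asarray(L, dtype=float)
    above = L >= threshold
    if not above.any():
        return []
    # index runs of consecutive True
    idx = np.nonzero(above)[0]
    runs = []
    start = prev = idx[0]
    for i in idx[1:]:
        if i == prev + 1:
            prev = i
        else:
            runs.append((start, prev))
            start = prev = i
    runs.append((start, prev))
    # merge runs separated by < min_gap
    merged = [runs[0]]
    for s, e in runs[1:]:
        ps, pe = merged[-1]
        if s - pe - 1 < min_gap:
            merged[-1] = (ps, e)
        else:
            merged.append((s, e))
    events: List[ConfinementEvent] = []
    pos = traj.positions
    for s, e in merged:
        if e - s + 1 < min_duration:
            continue
        seg = pos[s:e + 1]
        centroid = seg.mean(axis=0)
        radius = float(np.max(np.hypot(seg[:, 0] - centroid[0],
                                       seg[:, 1] - centroid[1])))
        events.append(ConfinementEvent(
            track_id=traj.track_id,
            start_frame=int(traj.frames[s]),
            end_frame=int(traj.frames[e]),
            L_max=float(L[s:e + 1].max()),
            radius=radius,
        ))
    return events


def detect_confinement(traj: Trajectory, D_ref: float,
                       window: int = DEFAULT_WINDOW,
                       threshold: float = DEFAULT_THRESHOLD,
                       min_duration: int = DEFAULT_MIN_DURATION,
                       min_gap: int = DEFAULT_MIN_GAP) -> List[ConfinementEvent]:
    """Convenience: index + event extraction in one call."""
    L = confinement_index(traj, window=window, D_ref=D_ref)
    return extract_confined_events(traj, L, threshold=threshold,
                                   min_duration=min_duration, min_gap=min_gap)
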