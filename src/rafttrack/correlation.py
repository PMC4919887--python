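"""Phasor pair correlation between trajectories.

Positions are written as complex phasors r(t) = x + iy = A(t)·e^{iθ(t)}.
The degree of correlation of two equal-length segments at lag τ is the
normalized real inner product

    C(τ) = Re[ Σ_t r₁*(t) · r₂(t+τ) ] / ( √Σ|r₁|² · √Σ|r₂|² )
         = Σ_t A₁(t) A₂(t+τ) cos[θ₂(t+τ) − θ₁(t)] / ( √ΣA₁² · √ΣA₂² ),

bounded in [−1, 1] by Cauchy–Schwarz.  Identically moving segments give
C = 1, a 90°-rotated copy gives 0 and an anti-phase copy gives −1.

On raw laboratory coordinates the statistic is dominated by the static
offset of the segments from the coordinate origin, so by default each
segment is referred to its own centroid; C then measures co-movement and
is invariant under independent translations of either molecule.
Segments of two molecules with C above a threshold (0.8 by default) are
the "correlated segments" that can be routed back through the MSD / V
analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .trajectory import Trajectory

DEFAULT_THRESHOLD = 0.8
DEFAULT_WINDOW = 40
DEFAULT_STEP = 20


@dataclass
class PairCorrelationSegment:
    track_id_1: int
    track_id_2: int
    start_frame: int
    window: int
    lag: int
    C: float


def phasorize(xy: np.ndarray, origin_policy: str = "segment_centroid") -> np.ndarray:
    """Complex position series x + iy relative to the chosen origin.

    ``origin_policy`` is ``segment_centroid`` (default) or ``first_point``.
    Under the centroid policy the returned series sums to zero.
    """
    xy = np.atleast_2d(np.asarray(xy, dtype=float))
    z = xy[:, 0] + 1j * xy[:, 1]
    if origin_policy == "segment_centroid":
        z = z - z.mean()
    elif origin_policy == "first_point":
        z = z - z[0]
    else:
        raise ValueError(f"unknown origin_policy {origin_policy!r}")
    return z


def degree_of_correlation(seg1: np.ndarray, seg2: np.ndarray, lag: int = 0,
                          origin_policy: str = "segment_centroid",
                          min_overlap: int = 4) -> float:
    """Degree of correlation C of two equal-length position segments.

    ``lag`` shifts the second segment forward: C compares r₁(t) with
    r₂(t + lag) over the overlap, which must be at least ``min_overlap``
    points.  Raises on zero-norm segments (e.g. a stationary molecule
    under the centroid policy).
    """
    seg1 = np.asarray(seg1, dtype=float)
    seg2 = np.asarray(seg2, dtype=float)
    if len(seg1) != len(seg2):
        raise ValueError("segments must have equal length")
    n = len(seg1)
    if lag < 0 or n - lag < min_overlap:
        raise ValueError("overlap after lag shift is too short")
    a = phasorize(seg1[: n - lag], origin_policy)
    b = phasorize(seg2[lag:], origin_policy)
    na = np.sqrt(np.sum(np.abs(a) ** 2))
    nb = np.sqrt(np.sum(np.abs(b) ** 2))
    if na == 0 or nb == 0:
        raise ValueError("degree of correlation undefined for a zero-norm segment")
    return float(np.real(np.sum(np.conj(a) * b)) / (na * nb))


def degree_of_correlation_reference(seg1, seg2, lag: int = 0,
                                    origin_policy: str = "segment_centroid") -> float:
    """Amplitude–phase (A, θ) loop evaluation of C (testing oracle)."""
    seg1 = np.asarray(seg1, dtype=float)
    seg2 = np.asarray(seg2, dtype=float)
    n = len(seg1)
    a = phasorize(seg1[: n - lag], origin_policy)
    b = phasorize(seg2[lag:], origin_policy)
    A1, th1 = np.abs(a), np.angle(a)
    A2, th2 = np.abs(b), np.angle(b)
    num = sum(A1[t] * A2[t] * np.cos(th2[t] - th1[t]) for t in range(len(a)))
    return num / (np.sqrt((A1 ** 2).sum()) * np.sqrt((A2 ** 2).sum()))


def _overlap_frames(t1: Trajectory, t2: Trajectory) -> np.ndarray:
    return np.intersect1d(t1.frames, t2.frames)


def candidate_pairs(tracks: Sequence[Trajectory], max_distance: float = 0.5,
                    min_overlap: int = DEFAULT_WINDOW) -> List[Tuple[int, int]]:
    """Indices of track pairs that coexist and stay near each other.

    A pair qualifies when the tracks share at least ``min_overlap`` frames
    and their median separation over the shared frames is at most
    ``max_distance`` (µm).
    """
    if max_distance <= 0:
        raise ValueError("max_distance must be positive")
    out = []
    for i in range(len(tracks)):
        for j in range(i + 1, len(tracks)):
            t1, t2 = tracks[i], tracks[j]
            common = _overlap_frames(t1, t2)
            if len(common) < min_overlap:
                continue
            i1 = np.searchsorted(t1.frames, common)
            i2 = np.searchsorted(t2.frames, common)
            sep = np.hypot(t1.x[i1] - t2.x[i2], t1.y[i1] - t2.y[i2])
            if np.median(sep) <= max_distance:
                out.append((i, j))
    return out


def extract_correlated_segments(t1: Trajectory, t2: Trajectory,
                                window: int = DEFAULT_WINDOW,
                                step: int = DEFAULT_STEP,
                                threshold: float = DEFAULT_THRESHOLD,
                                lag: int = 0,
                                origin_policy: str = "segment_centroid",
                                ) -> List[PairCorrelationSegment]:
    """Sliding-window C over a track pair, keeping windows with C > threshold.

    Windows slide over the shared gap-free frame range; each retained
    window records the start frame so the member sub-trajectories can be
    routed to the segment statistics.
    """
    common = _overlap_frames(t1, t2)
    if len(common) < window + lag:
        return []
    i1 = np.searchsorted(t1.frames, common)
    i2 = np.searchsorted(t2.frames, common)
    p1 = t1.positions[i1]
    p2 = t2.positions[i2]
    out: List[PairCorrelationSegment] = []
    for s0 in range(0, len(common) - window - lag + 1, step):
        fr = common[s0:s0 + window + lag]
        if fr[-1] - fr[0] != window + lag - 1:
            continue  # gap inside the window
        c = degree_of_correlation(p1[s0:s0 + window + lag],
                                  p2[s0:s0 + window + lag],
                                  lag=lag, origin_policy=origin_policy)
        if c > threshold:
            out.append(PairCorrelationSegment(t1.track_id, t2.track_id,
                                              int(fr[0]), window, lag, c))
    return out


def correlated_subtracks(t1: Trajectory, t2: Trajectory,
                         segments: Sequence[PairCorrelationSegment],
                         ) -> List[Trajectory]:
    """Member sub-trajectories of retained windows, for downstream stats.

    Sub-track ids are negative copies of nothing meaningful; each keeps
    its parent's id so per-molecule statistics remain attributable.
    """
    out: List[Trajectory] = []
    for seg in segments:
        for t in (t1, t2):
            sel = (t.frames >= seg.start_frame) & (t.frames < seg.start_frame + seg.window)
            if sel.sum() >= 3:
                out.append(Trajectory(t.track_id, t.frames[sel], t.x[sel],
                                      t.y[sel], t.frame_period))
    return out
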