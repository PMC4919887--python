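"""Bidirectional MSD, the normalized variance V, and the (MSD, V) map.

The frame-scale mean squared displacement at interior time point *t* is
the two-sided average of the squared forward and backward single-frame
displacements,

    R²(t) = ( |r(t+τ) − r(t)|² + |r(t) − r(t−τ)|² ) / 2 ,

with τ the frame period.  For free 2D diffusion E[R²] = 4Dτ, which gives
the standard conversion D = R² / (4τ).

The normalized variance V of an R² window is the dimensionless dispersion

    V = 4 · Var(R²) / ⟨R²⟩² ,

calibrated so free diffusion has V = 2 in expectation: the two-term
averaged R² of independent Gaussian steps has Var/mean² = 1/2 exactly.
V is a diagnostic of the local environment: soft actin barriers mix
stalled and mobile step sizes and push V above 2, whereas a lipid-domain
"dressed" protein has compressed step-energy dispersion and V below 2.

Finite windows need care.  The R² series is a two-term moving average of
the squared step series, so neighboring values share one squared step
(lag-1 correlation 1/2 under free diffusion), which biases the sample
variance low by the factor (1 − 1/n); and the squared sample mean
overestimates ⟨R²⟩² by Var(mean).  Both corrections are applied in
:func:`normalized_variance` so that the free-diffusion expectation stays
at 2 for any window length (residual bias is O(1/n²)).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .trajectory import Trajectory

DEFAULT_WINDOW = 40
DEFAULT_STEP = 20
MIN_WINDOW = 20

#: log10 width of the default MSD histogram bins (10 bins per decade)
DEFAULT_LOG_BIN_WIDTH = 0.1


@dataclass
class MsdSeries:
    """Per-frame bidirectional R²(t) of one trajectory (µm²).

    ``t`` holds the frame indices of the interior points the series is
    defined on; points adjacent to frame gaps are skipped.
    """

    track_id: int
    t: np.ndarray
    R2: np.ndarray


@dataclass
class SegmentStat:
    """Sliding-window summary: mean R², V and D of one window."""

    track_id: int
    start_frame: int
    window: int
    mean_R2: float
    V: float
    D: float


@dataclass
class ContourMap:
    """Kernel-smoothed density over (log10 mean R², log10 V)."""

    r2_edges: np.ndarray
    v_edges: np.ndarray
    density: np.ndarray  # shape (len(r2_edges)-1, len(v_edges)-1)
    bandwidth: Tuple[float, float]

    @property
    def r2_centers(self) -> np.ndarray:
        return 0.5 * (self.r2_edges[:-1] + self.r2_edges[1:])

    @property
    def v_centers(self) -> np.ndarray:
        return 0.5 * (self.v_edges[:-1] + self.v_edges[1:])


def msd_series(traj: Trajectory) -> MsdSeries:
    """Bidirectional single-frame MSD series of one trajectory.

    R²(t) is defined at interior points whose both neighbors are exactly
    one frame away; a frame gap invalidates only the adjacent points.
    Tracks with fewer than 3 usable consecutive points yield an empty
    series.
    """
    fr = traj.frames
    pos = traj.positions
    if len(fr) < 3:
        return MsdSeries(traj.track_id, np.empty(0, int), np.empty(0))
    d = np.diff(pos, axis=0)
    sq = (d * d).sum(axis=1)
    consec = np.diff(fr) == 1
    ok = consec[:-1] & consec[1:]  # both lag-1 neighbors present
    R2 = 0.5 * (sq[:-1] + sq[1:])
    return MsdSeries(traj.track_id, fr[1:-1][ok], R2[ok])


def msd_series_reference(traj: Trajectory) -> MsdSeries:
    """Naive double-loop reference for :func:`msd_series` (testing oracle)."""
    fr = list(traj.frames)
    t_out, r_out = [], []
    for i in range(1, len(fr) - 1):
        if fr[i] - fr[i - 1] == 1 and fr[i + 1] - fr[i] == 1:
            fwd = (traj.x[i + 1] - traj.x[i]) ** 2 + (traj.y[i + 1] - traj.y[i]) ** 2
            bwd = (traj.x[i] - traj.x[i - 1]) ** 2 + (traj.y[i] - traj.y[i - 1]) ** 2
            t_out.append(fr[i])
            r_out.append((fwd + bwd) / 2.0)
    return MsdSeries(traj.track_id, np.array(t_out, int), np.array(r_out))


def normalized_variance(R2: np.ndarray, min_window: int = MIN_WINDOW) -> float:
    """Dimensionless dispersion V of an R² window, free-diffusion value 2.

    Applies the finite-window corrections described in the module
    docstring: the unbiased sample variance is scaled by n/(n−1) to undo
    the moving-average overlap, and Var(mean) under the same overlap
    structure is subtracted from the squared mean.  The mean-square
    estimate is floored at 10% of the squared sample mean to keep V
    finite for extremely dispersed windows.
    """
    R2 = np.asarray(R2, dtype=float)
    n = len(R2)
    if n < min_window:
        raise ValueError(f"window of {n} values is shorter than min_window={min_window}")
    m = R2.mean()
    if m <= 0:
        raise ValueError("normalized variance undefined for zero-mean R2 window")
    s2 = R2.var(ddof=1)
    sig2 = s2 * n / (n - 1.0)
    mu2 = m * m - sig2 * (2.0 * n - 1.0) / n**2
    mu2 = max(mu2, 0.1 * m * m)
    return 4.0 * sig2 / mu2


def diffusion_coefficient(mean_R2, tau: float):
    """Convert mean R² (µm²) to a diffusion coefficient via D = R²/(4τ)."""
    if tau <= 0:
        raise ValueError("tau must be positive")
    return np.asarray(mean_R2, dtype=float) / (4.0 * tau)


def segment_stats(traj: Trajectory, window: int = DEFAULT_WINDOW,
                  step: int = DEFAULT_STEP,
                  min_window: int = MIN_WINDOW) -> List[SegmentStat]:
    """Sliding-window (mean R², V, D) summaries of one trajectory.

    Windows are ``window`` R² values long and advance by ``step``;
    windows crossing frame gaps are dropped.
    """
    if window < min_window:
        raise ValueError("window must be at least min_window")
    series = msd_series(traj)
    tau = traj.frame_period
    out: List[SegmentStat] = []
    n = len(series.R2)
    for s0 in range(0, n - window + 1, step):
        t_win = series.t[s0:s0 + window]
        # contiguity: R2 points of a clean window sit on consecutive frames
        if t_win[-1] - t_win[0] != window - 1:
            continue
        w = series.R2[s0:s0 + window]
        m = float(w.mean())
        if m <= 0:
            continue
        v = normalized_variance(w, min_window=min_window)
        out.append(SegmentStat(traj.track_id, int(t_win[0]), window, m, v,
                               float(m / (4.0 * tau))))
    return out


def collect_segment_stats(tracks: Sequence[Trajectory],
                          window: int = DEFAULT_WINDOW,
                          step: int = DEFAULT_STEP) -> List[SegmentStat]:
    out: List[SegmentStat] = []
    for t in tracks:
        out.extend(segment_stats(t, window=window, step=step))
    return out


# ----------------------------------------------------------------------
# MSD histogram and population split
# ----------------------------------------------------------------------

@dataclass
class MsdHistogram:
    edges: np.ndarray          # log-spaced bin edges, µm²
    counts: np.ndarray
    peaks: List[float]         # refined peak locations, µm²
    split_threshold: Optional[float]   # µm²; None when degenerate
    fractions: Tuple[float, float]     # (slow, fast) population fractions
    labels: np.ndarray         # per-segment: 0 slow, 1 fast (all 1 if no split)


def _refine_log_peak(log_centers: np.ndarray, counts: np.ndarray, i: int) -> float:
    """Quadratic sub-bin refinement of a histogram mode (log10 axis)."""
    if 0 < i < len(counts) - 1:
        y0, y1, y2 = counts[i - 1], counts[i], counts[i + 1]
        denom = y0 - 2.0 * y1 + y2
        if denom < 0:
            shift = 0.5 * (y0 - y2) / denom
            shift = float(np.clip(shift, -0.5, 0.5))
            dx = log_centers[1] - log_centers[0]
            return 10 ** (log_centers[i] + shift * dx)
    return 10 ** log_centers[i]


def msd_histogram(stats: Sequence[SegmentStat],
                  log_bin_width: float = DEFAULT_LOG_BIN_WIDTH,
                  method: str = "valley",
                  smooth_bins: float = 1.0) -> MsdHistogram:
    """Log-binned histogram of segment mean R² with a fast/slow split.

    The histogram is lightly smoothed (Gaussian, ``smooth_bins`` bins)
    before mode finding.  Two split methods are available: ``valley``
    places the threshold at the count minimum between the two dominant
    modes; ``gmm`` fits a two-component Gaussian mixture on log10 mean R².
    Unimodal data are flagged degenerate (``split_threshold`` None, a
    single population reported).
    """
    if len(stats) < 2:
        raise ValueError("need at least 2 segments for a histogram")
    vals = np.array([s.mean_R2 for s in stats], dtype=float)
    vals = vals[vals > 0]
    lo = np.floor(np.log10(vals.min()) / log_bin_width) * log_bin_width
    hi = np.ceil(np.log10(vals.max()) / log_bin_width) * log_bin_width
    n_bins = max(int(round((hi - lo) / log_bin_width)), 1)
    log_edges = lo + np.arange(n_bins + 1) * log_bin_width
    counts, _ = np.histogram(np.log10(vals), bins=log_edges)
    smooth = ndimage.gaussian_filter1d(counts.astype(float), smooth_bins)
    log_centers = 0.5 * (log_edges[:-1] + log_edges[1:])

    interior = np.arange(1, len(smooth) - 1)
    is_max = [i for i in interior
              if smooth[i] >= smooth[i - 1] and smooth[i] >= smooth[i + 1]
              and smooth[i] > 0]
    # keep the two highest, well-ordered modes
    is_max.sort(key=lambda i: -smooth[i])
    modes = sorted(is_max[:2])
    peaks = [_refine_log_peak(log_centers, smooth, i) for i in modes]

    threshold = None
    labels = np.ones(len(vals), dtype=int)
    fractions = (0.0, 1.0)
    if len(modes) == 2 and modes[1] - modes[0] >= 2:
        if method == "valley":
            between = slice(modes[0], modes[1] + 1)
            i_min = modes[0] + int(np.argmin(smooth[between]))
            threshold = float(10 ** log_centers[i_min])
        elif method == "gmm":
            from sklearn.mixture import GaussianMixture
            gm = GaussianMixture(n_components=2, random_state=0)
            logv = np.log10(vals).reshape(-1, 1)
            gm.fit(logv)
            means = np.sort(gm.means_.ravel())
            # threshold: density crossover approximated by midpoint
            threshold = float(10 ** means.mean())
        else:
            raise ValueError(f"unknown split method {method!r}")
        labels = (vals > threshold).astype(int)
        slow = float((labels == 0).mean())
        fractions = (slow, 1.0 - slow)
        peaks = sorted(peaks)
    return MsdHistogram(10 ** log_edges, counts, peaks, threshold, fractions, labels)


# ----------------------------------------------------------------------
# (mean R², V) contour map
# ----------------------------------------------------------------------

def contour_map(stats: Sequence[SegmentStat],
                r2_range: Optional[Tuple[float, float]] = None,
                v_range: Optional[Tuple[float, float]] = None,
                n_bins: int = 60,
                bandwidth: Optional[Tuple[float, float]] = None) -> ContourMap:
    """2D kernel-smoothed density of (log10 mean R², log10 V).

    The density is normalized to integrate to 1 over the (log-log) grid.
    The bandwidth defaults to Scott's rule on each log axis.  Repeated
    visits of molecules to one membrane environment concentrate density
    there and form a peak at the environment's characteristic
    coordinates.
    """
    if len(stats) < 10:
        raise ValueError("need at least 10 segments for a contour map")
    r2 = np.array([s.mean_R2 for s in stats])
    v = np.array([s.V for s in stats])
    keep = (r2 > 0) & (v > 0)
    lr, lv = np.log10(r2[keep]), np.log10(v[keep])
    if r2_range is None:
        pad = 0.2
        r2_range = (lr.min() - pad, lr.max() + pad)
    else:
        r2_range = (np.log10(r2_range[0]), np.log10(r2_range[1]))
    if v_range is None:
        pad = 0.2
        v_range = (lv.min() - pad, lv.max() + pad)
    else:
        v_range = (np.log10(v_range[0]), np.log10(v_range[1]))
    r_edges = np.linspace(r2_range[0], r2_range[1], n_bins + 1)
    v_edges = np.linspace(v_range[0], v_range[1], n_bins + 1)
    H, _, _ = np.histogram2d(lr, lv, bins=[r_edges, v_edges])
    n = len(lr)
    dr = r_edges[1] - r_edges[0]
    dv = v_edges[1] - v_edges[0]
    if bandwidth is None:
        # Scott's rule, capped at two bins: the global std overstates the
        # within-mode scale on multimodal data and would smear the peaks
        scott = n ** (-1.0 / 6.0)
        bandwidth = (float(np.clip(scott * lr.std(), 1e-6, 2 * dr)),
                     float(np.clip(scott * lv.std(), 1e-6, 2 * dv)))
    H = ndimage.gaussian_filter(H, (bandwidth[0] / dr, bandwidth[1] / dv),
                                mode="constant")
    total = H.sum() * dr * dv
    if total > 0:
        H /= total
    return ContourMap(10 ** r_edges, 10 ** v_edges, H, bandwidth)


@dataclass
class DensityPeak:
    mean_R2: float
    V: float
    height: float


def find_peaks(cmap: ContourMap, min_separation: int = 3,
               min_prominence: float = 0.05) -> List[DensityPeak]:
    """Local maxima of a contour map, highest first.

    ``min_prominence`` is relative to the global maximum; peak
    coordinates are refined by quadratic interpolation around the bin.
    """
    H = cmap.density
    if H.max() <= 0:
        return []
    size = 2 * min_separation + 1
    local_max = (H == ndimage.maximum_filter(H, size=size, mode="nearest"))
    thr = min_prominence * H.max()
    peaks: List[DensityPeak] = []
    lr_centers = np.log10(cmap.r2_centers)
    lv_centers = np.log10(cmap.v_centers)
    for i, j in zip(*np.nonzero(local_max & (H > thr))):
        x = lr_centers[i]
        y = lv_centers[j]
        if 0 < i < H.shape[0] - 1:
            d = H[i - 1, j] - 2 * H[i, j] + H[i + 1, j]
            if d < 0:
                x += np.clip(0.5 * (H[i - 1, j] - H[i + 1, j]) / d, -0.5, 0.5) \
                     * (lr_centers[1] - lr_centers[0])
        if 0 < j < H.shape[1] - 1:
            d = H[i, j - 1] - 2 * H[i, j] + H[i, j + 1]
            if d < 0:
                y += np.clip(0.5 * (H[i, j - 1] - H[i, j + 1]) / d, -0.5, 0.5) \
                     * (lv_centers[1] - lv_centers[0])
        peaks.append(DensityPeak(10 ** x, 10 ** y, float(H[i, j])))
    peaks.sort(key=lambda p: -p.height)
    return peaks
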