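"""Langevin simulation of membrane receptor diffusion in four regimes.

The simulator produces coarse-grained single-molecule trajectories sampled
at the camera frame period.  Four dynamical regimes are supported:

``free``
    Unobstructed 2D Brownian motion with diffusion coefficient ``D_free``.

``corral``
    Brownian motion in a periodic meshwork of actin compartments.  The
    cytoskeleton is modeled as soft Gaussian potential ridges of height
    ``barrier_height`` (kT) and width ``barrier_width`` on a square lattice
    of period ``2 * corral_radius``, integrated with Euler–Maruyama
    substeps.  Barriers stall the molecule and rarely let it hop to the
    neighboring compartment, which mixes stalled and mobile step sizes and
    raises the normalized variance V above the free-diffusion level 2.

``domain``
    A "dressed protein": the molecule and its shell of ordered lipids move
    as one effective unit.  The shell does two things.  (i) It anchors the
    protein elastically to a slowly diffusing domain center (an
    Ornstein–Uhlenbeck pull with stationary RMS radius ``domain_radius``).
    (ii) It smooths the thermal kick energy at frame scale: the faster the
    protein moves, the stronger the ordered shell it drags, which feeds
    back negatively on the step size.  That feedback is modeled by
    blending the squared kick magnitude between its deterministic mean and
    the thermal (exponential) fluctuation:

        |kick|² = 2·s²·[ d + (1 − d)·E ],   E ~ Exp(1),

    where ``d`` is the screened (dressed) energy fraction
    ``cholesterol · τ / (τ + t_rel)``.  With ``d = 0`` the kick is exactly
    a 2D Gaussian (free diffusion); with ``d > 0`` the dispersion of the
    step energy is compressed, which is what drives the normalized
    variance V below 2.  Mean step energy is preserved for every ``d``.

``pair``
    Two receptors forming a transient dimer.  While bound they share a
    dressed centroid (two stacked shells: screened fraction
    ``1 − (1 − d)²``) and are held together by a stiff harmonic bond of
    stiffness ``pair_spring_k * cholesterol``; unbound they diffuse
    independently.  The bond lifetime scales as
    ``cholesterol² · pair_spring_k`` (cooperative stabilization of the
    bond by the shared cholesterol shell), so depleting cholesterol turns
    a stable dimer into an intermittent one.

All generators are deterministic given (params, seed) and return
noise-free ("true") positions; apply :func:`add_localization_noise` to
emulate the measurement.
"""

from __future__ import annotations

from typing import List, Optional, Sequence, Tuple

import numpy as np

from .params import (
    MembraneModelParams,
    PAIR_SPRING_REF,
    PAIR_T_ON_REF,
    PAIR_T_OFF,
)
from .trajectory import Trajectory


def _make_tracks(pos: np.ndarray, params: MembraneModelParams,
                 first_id: int = 0) -> List[Trajectory]:
    """Wrap an (n_tracks, n_frames, 2) position array into Trajectory records."""
    n_tracks, n_frames, _ = pos.shape
    frames = np.arange(n_frames, dtype=np.int64)
    return [
        Trajectory(
            track_id=first_id + i,
            frames=frames.copy(),
            x=pos[i, :, 0].copy(),
            y=pos[i, :, 1].copy(),
            frame_period=params.frame_period,
        )
        for i in range(n_tracks)
    ]


def _origins(origins, n_tracks: int) -> np.ndarray:
    if origins is None:
        return np.zeros((n_tracks, 2))
    origins = np.asarray(origins, dtype=float)
    if origins.shape != (n_tracks, 2):
        raise ValueError("origins must have shape (n_tracks, 2)")
    return origins


# ----------------------------------------------------------------------
# free diffusion
# ----------------------------------------------------------------------

def simulate_free(params: MembraneModelParams, n_tracks: int,
                  origins=None) -> List[Trajectory]:
    """Simulate unobstructed 2D Brownian motion.

    Each frame-to-frame displacement per axis is Gaussian with variance
    ``2 * D_free * frame_period``; this discretization is exact, so no
    substeps are needed.
    """
    if n_tracks < 1:
        raise ValueError("n_tracks must be >= 1")
    rng = np.random.default_rng(params.seed)
    tau = params.frame_period
    steps = rng.normal(0.0, np.sqrt(2.0 * params.D_free * tau),
                       (n_tracks, params.n_frames - 1, 2))
    pos = np.concatenate(
        [np.zeros((n_tracks, 1, 2)), np.cumsum(steps, axis=1)], axis=1
    )
    pos += _origins(origins, n_tracks)[:, None, :]
    return _make_tracks(pos, params)


# ----------------------------------------------------------------------
# actin corral meshwork
# ----------------------------------------------------------------------

def _lattice_force(xy: np.ndarray, half_width: float, height: float,
                   ridge_w: float) -> np.ndarray:
    """Force (per kT, µm⁻¹) of periodic Gaussian ridges along both axes.

    Ridges sit on the lines x = (2k+1)·half_width and likewise in y, so
    the compartment containing the origin is (−half_width, half_width)².
    The potential is separable; only the two nearest ridges per axis
    contribute materially for ridge_w << half_width.
    """
    u = (xy + half_width) % (2.0 * half_width) - half_width
    f = np.zeros_like(xy)
    for c in (half_width, -half_width):
        s = u - c
        f += height * s / ridge_w**2 * np.exp(-(s * s) / (2.0 * ridge_w**2))
    return f


def simulate_corral(params: MembraneModelParams, n_tracks: int) -> List[Trajectory]:
    """Simulate hop diffusion in a soft-walled actin compartment lattice.

    Overdamped Langevin dynamics ``dx = −D ∇U/kT dt + sqrt(2 D dt) dW``
    integrated with ``params.substeps`` Euler–Maruyama substeps per frame
    and sampled at the frame period.  Tracks start at the center of the
    compartment containing the origin.  Escape beyond the starting
    compartment is suppressed monotonically in ``barrier_height``.
    """
    if n_tracks < 1:
        raise ValueError("n_tracks must be >= 1")
    p = params
    if p.corral_radius <= 0:
        raise ValueError("corral_radius must be positive")
    rng = np.random.default_rng(p.seed)
    dt = p.frame_period / p.substeps
    kick_sd = np.sqrt(2.0 * p.D_free * dt)
    x = np.zeros((n_tracks, 2))
    pos = np.empty((n_tracks, p.n_frames, 2))
    pos[:, 0] = x
    for f in range(1, p.n_frames):
        for _ in range(p.substeps):
            drift = p.D_free * _lattice_force(
                x, p.corral_radius, p.barrier_height, p.barrier_width
            )
            x = x + drift * dt + rng.normal(0.0, kick_sd, (n_tracks, 2))
        pos[:, f] = x
    return _make_tracks(pos, p)


# ----------------------------------------------------------------------
# lipid domain ("dressed protein")
# ----------------------------------------------------------------------

def _blended_kicks(rng: np.random.Generator, per_axis_var: float,
                   dressed_fraction: float, n: int) -> np.ndarray:
    """Isotropic kicks whose squared magnitude is an energy blend.

    ``|kick|² = 2·per_axis_var·[d + (1−d)·E]`` with ``E ~ Exp(1)``; the
    direction is uniform.  For ``d = 0`` this is exactly a 2D Gaussian of
    per-axis variance ``per_axis_var``; the mean energy is the same for
    all ``d``.
    """
    d = dressed_fraction
    energy = 2.0 * per_axis_var * (d + (1.0 - d) * rng.exponential(1.0, n))
    rho = np.sqrt(energy)
    theta = rng.uniform(0.0, 2.0 * np.pi, n)
    return np.column_stack([rho * np.cos(theta), rho * np.sin(theta)])


def simulate_domain(params: MembraneModelParams, n_tracks: int) -> List[Trajectory]:
    """Simulate dressed-protein diffusion in a mobile lipid domain.

    Exact frame-scale discretization of an Ornstein–Uhlenbeck relaxation
    toward a domain center that itself diffuses with ``domain_center_D``,
    with the thermal kick energy screened by the ordered-lipid shell (see
    module docstring).  Both the confinement rate and the kick screening
    scale with the dressing fraction, so ``cholesterol = 0`` or
    ``domain_relaxation_time → ∞`` recover free diffusion exactly.
    """
    if n_tracks < 1:
        raise ValueError("n_tracks must be >= 1")
    p = params
    if p.domain_relaxation_time <= 0:
        raise ValueError("domain_relaxation_time must be positive")
    rng = np.random.default_rng(p.seed)
    tau = p.frame_period
    d = p.dressing  # screened energy fraction in [0, 1)
    # Elastic anchoring: rate chosen so a fully dressed protein has
    # stationary RMS distance domain_radius from the center.
    k_conf = 2.0 * p.D_free / p.domain_radius**2 * d
    lam = np.exp(-k_conf * tau)
    if k_conf > 0:
        kick_var = (p.D_free / k_conf) * (1.0 - lam * lam)
    else:
        kick_var = 2.0 * p.D_free * tau
    center = np.zeros((n_tracks, 2))
    x = np.zeros((n_tracks, 2))
    pos = np.empty((n_tracks, p.n_frames, 2))
    pos[:, 0] = x
    center_sd = np.sqrt(2.0 * p.domain_center_D * tau)
    for f in range(1, p.n_frames):
        center = center + rng.normal(0.0, center_sd, (n_tracks, 2))
        kick = _blended_kicks(rng, kick_var, d, n_tracks)
        x = center + lam * (x - center) + kick
        pos[:, f] = x
    return _make_tracks(pos, p)


# ----------------------------------------------------------------------
# coupled receptor pair
# ----------------------------------------------------------------------

def simulate_pair(params: MembraneModelParams,
                  n_pairs: int) -> List[Tuple[Trajectory, Trajectory]]:
    """Simulate attractively coupled receptor pairs.

    Returns a list of ``(traj_a, traj_b)`` tuples sharing frames, with
    track ids ``2i`` and ``2i + 1``.  Binding is a two-state telegraph
    process: mean bound lifetime
    ``PAIR_T_ON_REF · cholesterol² · (pair_spring_k / PAIR_SPRING_REF)``
    and mean unbound lifetime ``PAIR_T_OFF``.  While bound, the pair
    centroid performs dressed diffusion at ``D_free / 2`` and the
    separation relaxes in the harmonic bond (exact OU update, stable for
    arbitrarily stiff springs); while unbound, both molecules diffuse
    independently at ``D_free``.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    p = params
    if p.pair_spring_k < 0:
        raise ValueError("pair_spring_k must be non-negative")
    rng = np.random.default_rng(p.seed)
    tau = p.frame_period
    d_dim = p.dimer_dressing
    k_bond = p.pair_spring_k * p.cholesterol
    t_on = PAIR_T_ON_REF * p.cholesterol**2 * (p.pair_spring_k / PAIR_SPRING_REF)
    p_unbind = 1.0 - np.exp(-tau / t_on) if t_on > 0 else 1.0
    p_bind = 1.0 - np.exp(-tau / PAIR_T_OFF)
    # separation OU: relative coordinate has diffusivity 2 D and feels the
    # bond with rate 2 D k; exact exponential update
    lam_sep = np.exp(-min(2.0 * p.D_free * k_bond * tau, 700.0)) if k_bond > 0 else 1.0
    sep_eq_var = 2.0 / k_bond if k_bond > 0 else 0.0  # per-axis, kT units
    # each pair lives in a shared lab frame; spread pairs over a field so
    # that pair-candidate search on the emitted table behaves like it
    # would on imaged data
    cen = rng.uniform(0.0, 10.0, (n_pairs, 2))
    sep = (rng.normal(0.0, np.sqrt(sep_eq_var), (n_pairs, 2))
           if k_bond > 0 else np.zeros((n_pairs, 2)))
    bound = np.ones(n_pairs, dtype=bool) if k_bond > 0 else np.zeros(n_pairs, dtype=bool)
    pa = np.empty((n_pairs, p.n_frames, 2))
    pb = np.empty((n_pairs, p.n_frames, 2))
    pa[:, 0] = cen + sep / 2
    pb[:, 0] = cen - sep / 2
    cen_var = p.D_free * tau          # per-axis, centroid at D/2
    sep_free_sd = np.sqrt(4.0 * p.D_free * tau)
    for f in range(1, p.n_frames):
        u = rng.uniform(size=n_pairs)
        bound = np.where(bound, u > p_unbind, u < p_bind)
        kick_dressed = _blended_kicks(rng, cen_var, d_dim, n_pairs)
        kick_gauss = rng.normal(0.0, np.sqrt(cen_var), (n_pairs, 2))
        cen = cen + np.where(bound[:, None], kick_dressed, kick_gauss)
        if k_bond > 0:
            sep_bound = lam_sep * sep + rng.normal(
                0.0, np.sqrt(sep_eq_var * (1.0 - lam_sep**2)), (n_pairs, 2)
            )
        else:
            sep_bound = sep
        sep_free = sep + rng.normal(0.0, sep_free_sd, (n_pairs, 2))
        sep = np.where(bound[:, None], sep_bound, sep_free)
        pa[:, f] = cen + sep / 2
        pb[:, f] = cen - sep / 2
    tracks_a = _make_tracks(pa, p)
    tracks_b = _make_tracks(pb, p)
    out = []
    for i in range(n_pairs):
        tracks_a[i].track_id = 2 * i
        tracks_b[i].track_id = 2 * i + 1
        out.append((tracks_a[i], tracks_b[i]))
    return out


# ----------------------------------------------------------------------
# localization noise and dispatch
# ----------------------------------------------------------------------

def add_localization_noise(tracks: Sequence[Trajectory], sigma_loc: float,
                           seed: int = 0) -> List[Trajectory]:
    """Add independent Gaussian localization error to every position.

    ``sigma_loc`` is the radial RMS error; the per-axis standard deviation
    is ``sigma_loc / sqrt(2)``.  The input tracks are left unmodified.
    """
    if sigma_loc < 0:
        raise ValueError("sigma_loc must be non-negative")
    if sigma_loc == 0:
        return [
            Trajectory(t.track_id, t.frames.copy(), t.x.copy(), t.y.copy(),
                       t.frame_period)
            for t in tracks
        ]
    rng = np.random.default_rng(seed)
    sd = sigma_loc / np.sqrt(2.0)
    out = []
    for t in tracks:
        err = rng.normal(0.0, sd, (len(t), 2))
        out.append(
            Trajectory(t.track_id, t.frames.copy(),
                       t.x + err[:, 0], t.y + err[:, 1], t.frame_period)
        )
    return out


_GENERATORS = {
    "free": simulate_free,
    "corral": simulate_corral,
    "domain": simulate_domain,
}


def simulate(params: MembraneModelParams, n_tracks: int) -> List[Trajectory]:
    """Simulate ``n_tracks`` trajectories in ``params.regime``, including
    localization noise at ``params.sigma_loc``.

    For the pair regime ``n_tracks`` counts pairs and the two members of
    each pair are returned consecutively.
    """
    if params.regime == "pair":
        pairs = simulate_pair(params, n_tracks)
        raw = [t for ab in pairs for t in ab]
    else:
        raw = _GENERATORS[params.regime](params, n_tracks)
    if params.sigma_loc > 0:
        # decorrelate the noise stream from the dynamics stream
        return add_localization_noise(raw, params.sigma_loc,
                                      seed=params.seed + 987_654_321 & 0x7FFFFFFF)
    return raw
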