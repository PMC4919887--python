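"""Parameter containers for the membrane diffusion simulator.

All lengths are in micrometres, times in seconds, diffusion coefficients in
µm²/s and energies in units of the thermal energy kT.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Optional

import yaml

REGIMES = ("free", "corral", "domain", "pair")

#: internal reference stiffness for the dimer bond (kT/µm²); the bound-state
#: lifetime is expressed relative to a bond of this stiffness.
PAIR_SPRING_REF = 20_000.0

#: bound-state lifetime of a reference dimer (cholesterol=1,
#: pair_spring_k = PAIR_SPRING_REF), seconds.
PAIR_T_ON_REF = 10.0

#: mean duration of an unbound excursion of a transient dimer, seconds.
PAIR_T_OFF = 0.3


@dataclass(frozen=True)
class MembraneModelParams:
    """Full parameterization of the four-regime membrane diffusion model.

    Parameters
    ----------
    regime:
        One of ``free``, ``corral``, ``domain``, ``pair``.
    D_free:
        Microscopic free diffusion coefficient, µm²/s.
    corral_radius:
        Half-width of one actin compartment, µm.  Compartments tile the
        plane with period ``2 * corral_radius``.
    barrier_height:
        Height of the soft actin barrier in kT.
    barrier_width:
        Gaussian width of the barrier ridge, µm.
    domain_radius:
        Stationary RMS distance of a fully dressed protein from its lipid
        domain center, µm.
    domain_relaxation_time:
        Relaxation time of the ordered-lipid shell, s.  Shorter shells
        screen thermal kicks more effectively; the infinite limit decouples
        the protein from the domain entirely.
    domain_center_D:
        Diffusion coefficient of the (slow) domain center, µm²/s.
    pair_spring_k:
        Stiffness of the receptor-receptor harmonic bond, kT/µm².  The
        effective bond felt by a pair is ``pair_spring_k * cholesterol``.
    cholesterol:
        Dimensionless stability scale in [0, 1] multiplying the dressing
        strength and the pair coupling.
    sigma_loc:
        Radial RMS localization error, µm (per-axis error is
        ``sigma_loc / sqrt(2)``).
    frame_period:
        Camera frame period τ, s.
    n_frames:
        Number of frames per trajectory.
    substeps:
        Euler–Maruyama substeps per frame (corral integration).
    seed:
        Seed of the simulation random generator.
    """

    regime: str = "free"
    D_free: float = 0.03
    corral_radius: float = 0.1
    barrier_height: float = 6.0
    barrier_width: float = 0.02
    domain_radius: float = 0.15
    domain_relaxation_time: float = 0.025
    domain_center_D: float = 0.002
    pair_spring_k: float = PAIR_SPRING_REF
    cholesterol: float = 1.0
    sigma_loc: float = 0.04
    frame_period: float = 0.025
    n_frames: int = 400
    substeps: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.regime not in REGIMES:
            raise ValueError(f"unknown regime {self.regime!r}; expected one of {REGIMES}")
        if self.D_free <= 0:
            raise ValueError("D_free must be positive")
        if self.frame_period <= 0:
            raise ValueError("frame_period must be positive")
        if self.n_frames < 2:
            raise ValueError("n_frames must be at least 2")
        if self.substeps < 1:
            raise ValueError("substeps must be >= 1")
        if self.sigma_loc < 0:
            raise ValueError("sigma_loc must be non-negative")
        if not (0.0 <= self.cholesterol <= 1.0):
            raise ValueError("cholesterol must lie in [0, 1]")
        if self.barrier_height < 0:
            raise ValueError("barrier_height must be non-negative")
        if self.regime == "corral":
            if self.corral_radius <= 0:
                raise ValueError("corral_radius must be positive")
            if self.barrier_width <= 0:
                raise ValueError("barrier_width must be positive")
        if self.regime == "domain" and self.domain_relaxation_time <= 0:
            raise ValueError("domain_relaxation_time must be positive")
        if self.regime == "pair" and self.pair_spring_k < 0:
            raise ValueError("pair_spring_k must be non-negative")

    # -- dressing ------------------------------------------------------

    @property
    def dressing(self) -> float:
        """Fraction of frame-scale kick energy screened by the lipid shell.

        A shell relaxing faster than the frame period screens the thermal
        fluctuations it can follow; the screened fraction at frame scale is
        ``cholesterol * tau / (tau + t_rel)``.  It vanishes both without
        cholesterol and in the slow-shell (decoupling) limit.
        """
        tau = self.frame_period
        return self.cholesterol * tau / (tau + self.domain_relaxation_time)

    @property
    def dimer_dressing(self) -> float:
        """Screened fraction for a bound receptor pair (two stacked shells)."""
        return 1.0 - (1.0 - self.dressing) ** 2

    def replace(self, **kwargs) -> "MembraneModelParams":
        return replace(self, **kwargs)

    # -- (de)serialization ---------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "MembraneModelParams":
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "MembraneModelParams":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass(frozen=True)
class ImageParams:
    """Rendering geometry for synthetic image stacks.

    ``pixel_size`` is in µm/px, ``shape`` is (height, width) in pixels,
    ``psf_sigma`` is the Gaussian point-spread sigma in µm, ``photons`` the
    expected photon count per molecule per frame, and ``background`` the
    expected background count per pixel.
    """

    pixel_size: float = 0.16
    shape: tuple = (64, 64)
    psf_sigma: float = 0.12
    photons: float = 800.0
    background: float = 20.0

    def __post_init__(self) -> None:
        if self.pixel_size <= 0 or self.psf_sigma <= 0:
            raise ValueError("pixel_size and psf_sigma must be positive")
        if self.photons < 0 or self.background < 0:
            raise ValueError("photons and background must be non-negative")


# Presets for the drug-treatment scenarios: cholesterol redistribution
# (nystatin-like) and depletion (MβCD-like).  These are illustrative
# analogies for qualitative contrasts, not values fitted to any dataset.
CHOLESTEROL_PRESETS = {
    "native": 1.0,
    "redistributed": 0.5,
    "depleted": 0.1,
}
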