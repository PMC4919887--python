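"""Illustrative scenario presets.

The presets map the qualitative experimental contrasts onto simulator
regimes: a fast non-confined population (free), a slow corral-confined
population, lipid-domain diffusion of liganded receptors (domain) and
correlated receptor pairs (pair).  Cholesterol presets represent drug
treatments that redistribute (``redistributed``) or deplete
(``depleted``) membrane cholesterol.  All values are illustrative
analogies chosen for the synthetic study conditions, not parameters
fitted to any measured cell.
"""

from .params import MembraneModelParams, CHOLESTEROL_PRESETS

#: frame-scale MSD peaks of the two diffusing populations (µm²) used by
#: the mixture scenario, converted to D by D = R² / (4τ).
FAST_PEAK_UM2 = 0.8
SLOW_PEAK_UM2 = 0.012


def fast_free(tau: float = 0.025, **kw) -> MembraneModelParams:
    """Non-confined fast population: D = FAST_PEAK_UM2 / 4τ."""
    return MembraneModelParams(regime="free", D_free=FAST_PEAK_UM2 / (4 * tau),
                               frame_period=tau, **kw)


def slow_confined(tau: float = 0.025, **kw) -> MembraneModelParams:
    """Confined slow population in a lipid domain: D = SLOW_PEAK_UM2 / 4τ."""
    return MembraneModelParams(regime="domain", D_free=SLOW_PEAK_UM2 / (4 * tau),
                               frame_period=tau, **kw)


def two_population_mixture(n_tracks: int, fast_fraction: float = 0.5,
                           seed: int = 0, **kw):
    """A figure-style fast/slow mixture; returns (params_fast, params_slow,
    n_fast, n_slow)."""
    n_fast = int(round(n_tracks * fast_fraction))
    n_slow = n_tracks - n_fast
    return (fast_free(seed=seed, **kw), slow_confined(seed=seed + 1, **kw),
            n_fast, n_slow)


def cholesterol_level(treatment: str) -> float:
    try:
        return CHOLESTEROL_PRESETS[treatment]
    except KeyError:
        raise ValueError(
            f"unknown treatment {treatment!r}; expected one of "
            f"{sorted(CHOLESTEROL_PRESETS)}"
        ) from None
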