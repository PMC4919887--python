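# Methods

`rafttrack` analyzes single-particle-tracking (SPT) trajectories of
membrane receptors sampled at a fixed camera frame period τ (default
25 ms), and ships a Langevin simulator whose output carries the
statistical structure the analysis is designed to detect.  This note
records the model, the estimator calibrations, the defaults and their
rationale, and the limits of what the synthetic tests demonstrate.

## The frame-scale MSD and its two-sided form

For a trajectory r(t) sampled every τ, the per-frame mean squared
displacement at an interior time point is the average of the squared
forward and backward single-frame displacements,

    R²(t) = ( |r(t+τ) − r(t)|² + |r(t) − r(t−τ)|² ) / 2 .

For free 2D diffusion E[R²] = 4Dτ, so window means convert to local
diffusion coefficients by D = R²/(4τ).  Frames adjacent to a linking gap
are excluded from the series; a gap therefore invalidates only the time
points that touch it.

## The normalized variance V

The dispersion of R² over a window is the environment diagnostic.  We
use the dimensionless form

    V = 4 · Var(R²) / ⟨R²⟩² ,

where the constant 4 is fixed analytically by free diffusion: each
squared single-frame displacement of a 2D Gaussian walk is exponential
(Var/mean² = 1), the two-term average halves the variance
(Var/mean² = 1/2), hence V = 2 exactly for free diffusion, for every D.
The three regimes then separate as

    corral  V > 2   (stalls at soft barriers widen the step-energy mix)
    free    V = 2
    domain  V < 2   (dressing compresses the step-energy dispersion).

**Finite-window calibration.**  The R² series is a two-term moving
average of the squared-step series, so neighboring values share one
squared step: under free diffusion the series is MA(1) with lag-1
correlation 1/2.  Two finite-sample effects bias the plug-in ratio
`4·s²/m²` low (≈ 1.91 instead of 2 at 40-frame windows): the sample
variance loses a factor (1 − 1/n) to the overlap covariance, and m²
overestimates ⟨R²⟩² by Var(m).  `normalized_variance` therefore uses

    σ̂² = s² · n/(n−1)                       (overlap-corrected variance)
    μ̂² = m² − σ̂²·(2n−1)/n²                  (unbiased mean-square)
    V  = 4 σ̂²/μ̂² ,   μ̂² floored at 0.1·m²  (keeps V finite)

both corrections exact for any i.i.d.-increment process.  The residual
ratio bias is O(1/n²) (measured +0.007 at n = 40).  The μ̂² floor only
engages for extremely dispersed windows (plug-in V ≳ 70).  Windows
default to 40 frames (1 s) advancing by 20; both are exposed because
nothing in the data fixes them uniquely.

## Simulator

All regimes are parameterized by `MembraneModelParams` (lengths µm,
times s, energies kT) and are deterministic given (params, seed).

**Free.**  Exact Gaussian increments, per-axis variance 2Dτ.

**Corral meshwork.**  The cortical cytoskeleton is a periodic square
lattice of soft Gaussian potential ridges of height H (`barrier_height`,
kT) and width w (`barrier_width`) with compartment half-width
`corral_radius`; dynamics are overdamped Langevin, dx = −D∇U/kT·dt +
√(2D dt)·dW, integrated with `substeps` Euler–Maruyama substeps per
frame (default 50; halving it leaves the ensemble moments inside
Monte-Carlo error — asserted by test).  A lattice rather than a single
isolated ridge is essential: a lone Gaussian ridge in an otherwise flat
plane cannot hold a molecule at realistic barrier heights (the exact
mean first-passage time over a 10 kT ridge of 20–30 nm width at
D = 0.1 µm²/s is of order one minute, computed by quadrature), whereas
in a meshwork every escape lands in the neighboring compartment, so
long-range excursions remain bounded while the stall-and-hop step
mixture survives.  Escape is suppressed exponentially in H.

**Lipid domain ("dressed protein").**  The molecule and its shell of
ordered lipids move as one unit.  Two effects, both scaled by the
dressing fraction

    d = cholesterol · τ / (τ + t_rel) ,       t_rel = `domain_relaxation_time`,

which vanishes without cholesterol and in the slow-shell limit
t_rel → ∞ (decoupling):

1. *Anchoring*: an exact discrete Ornstein–Uhlenbeck pull toward a
   domain center that itself diffuses slowly (`domain_center_D`), with
   rate set so the fully dressed stationary RMS radius equals
   `domain_radius`.
2. *Kick-energy smoothing*: the faster the protein moves, the larger
   the ordered shell it drags, a negative feedback on step size.  At
   frame scale this is modeled by drawing isotropic kicks whose squared
   magnitude is the blend `2σ²·[d + (1−d)·E]`, E ~ Exp(1).  With d = 0
   this is exactly a 2D Gaussian kick; d > 0 preserves the mean step
   energy but compresses its dispersion, giving V = 2(1−d)² before
   anchoring corrections.  The smoothing term is the essential one: a
   purely elastic (conditionally Gaussian) confinement provably cannot
   push V below 2, because any isotropic Gaussian step has
   Var(|step|²)/E[|step|²]² ≥ 1.

The domain and pair regimes use exact frame-scale discretizations (OU
updates), so they need no substeps.

**Receptor pair.**  A transient dimer.  Binding is a two-state
telegraph: mean bound lifetime `10 s · cholesterol² · (k/20000)` with k
the bond stiffness `pair_spring_k` (kT/µm²), mean unbound bout 0.3 s.
The quadratic cholesterol dependence encodes cooperative stabilization
of the bond by the shared ordered-lipid shell: a stiff bond without
cholesterol still yields only an intermittent dimer.  While bound, the
centroid performs dressed diffusion at D/2 with the *dimer* dressing
`1 − (1−d)²` (two stacked shells), and the separation relaxes in the
bond by an exact OU update (stable for arbitrarily stiff springs; the
rigid limit k → ∞ reproduces identical motion and C = 1).  Unbound,
both molecules diffuse independently at D.  The default stiffness
20 000 kT/µm² corresponds to ≈ 14 nm RMS bond wobble — a molecular-scale
dimer.  Intermittent binding at depleted cholesterol mixes bound
(centroid-dominated) and unbound (independent) step energies and drives
V of the correlated segments above 2, the "deterministic dimerization"
signature; at native cholesterol the long-lived dressed dimer keeps
those segments well below the lone-dressed-receptor level.

**Localization noise.**  `sigma_loc` is the *radial* RMS error (40 nm
default, the apparatus scale); per-axis σ is `sigma_loc/√2`, added
independently per frame.  A stationary emitter then has mean
R² = 2·sigma_loc² ≈ 0.003 µm², consistent with an MSD determination
accuracy of a few 10⁻³ µm².  Noise is applied after simulation so
true and measured tracks are both available.

## Defaults and why

| parameter | default | rationale |
|---|---|---|
| `D_free` | 0.03 µm²/s | microscopic mobility of a raft/corral-resident receptor; consistent with hop-diffusion compartments holding a molecule for minutes at 10 kT walls |
| `frame_period` | 0.025 s | video-rate SPT sampling |
| `n_frames` | 400 (10 s) | typical usable quantum-dot track length |
| `corral_radius` | 0.1 µm | actin compartments are tens to hundreds of nm |
| `barrier_height` | 6 kT | moderate wall: frequent stalls, occasional hops |
| `barrier_width` | 0.02 µm | filament plus bound proteins |
| `domain_radius` | 0.15 µm | nanoscale raft domain |
| `domain_relaxation_time` | 0.025 s | shell responds on the sampling timescale → dressing d = cholesterol/2 |
| `domain_center_D` | 0.002 µm²/s | domains drift far slower than the protein |
| `pair_spring_k` | 20 000 kT/µm² | ≈14 nm dimer bond wobble |
| `sigma_loc` | 0.04 µm | stated apparatus localization accuracy |
| `substeps` | 50 | kick ≪ barrier width; convergence asserted by test |

Corral sizes, barrier heights and domain radii are **illustrative**:
no measured per-cell values exist to fit, so they are chosen once at
physically plausible magnitudes and exposed in the config.
Cholesterol presets (`native` = 1.0, `redistributed` = 0.5,
`depleted` = 0.1) are interpretive analogies for drug treatments that
redistribute or deplete membrane cholesterol; they are labels on the
stability scale, not fitted dose-response values.

## Confinement detection

The probability-of-staying index: for each 30-frame sliding window the
maximal excursion R from the window's first point gives, under free
diffusion with reference coefficient D_ref, the staying probability
log₁₀ψ = 0.2048 − 2.5117·D t/R²; the index is L = max(0, −log₁₀ψ − 1),
averaged over all windows covering a frame.  Events are maximal runs
with L ≥ 3.16 lasting ≥ 10 frames, with runs separated by < 2
sub-threshold frames merged.  All constants are config-exposed; the
operating point (sensitivity and specificity > 0.8 on a 50/50
free/strong-corral mixture at default settings) is asserted as a
regression test.  D_ref is taken from the fast population (D = R²/4τ of
its histogram mode) or supplied explicitly.

## Pair correlation

Positions are phasors r = x + iy; the degree of correlation of two
equal-length segments at lag ℓ is

    C = Re[ Σ r₁*(t) r₂(t+ℓ) ] / (√Σ|r₁|² √Σ|r₂|²) ∈ [−1, 1].

On raw lab coordinates C is dominated by the segments' static offset
from the coordinate origin, so each segment is referred to its own
centroid by default (`first_point` mode is retained for sensitivity
analysis); C then measures co-movement and is invariant under
independent translations and common rotations.  Default lag 0 and
window 40 match the V analysis; windows with C > 0.8 are the
"correlated segments" forwarded to the V pipeline.  For independent
free 40-frame segments the null probability P(C > 0.8) is below 1%
(Monte-Carlo), so the selection is specific.

## Tracking front end

Spot detection: per-frame median/MAD background, local maxima above
background + 5σ, sub-pixel refinement by intensity-weighted centroid.
Linking: greedy mutual-nearest-neighbor assignment between consecutive
frames with a distance gate (`max_disp`, suggested 4·√(4·D_max·τ)),
optional gap bridging up to `max_gap` frames, ties broken toward the
lower track id (deterministic).  No merging/splitting, no
intensity-based identity maintenance — the linker implements plain
nearest-position connection, which is exact when inter-molecule spacing
is large compared with per-frame displacements (asserted by test).

## What the synthetic tests do and do not show

The simulator reproduces the *statistical signatures* the analysis
keys on (V calibration and ordering, two-population MSD structure,
confinement events, cholesterol-dependent pair correlation), with
mechanisms chosen as the simplest that provably generate each
signature.  Passing tests therefore validate the estimators and the
pipeline, not any particular cell biology: real membranes have
heterogeneous compartment sizes, anomalous transport, blinking
fluorophores and drift, none of which are modeled.  Quantitative
defaults (barrier heights, domain radii, bond lifetimes) are
illustrative throughout.  Problem sizes in the test and acceptance
suites (typically 500 tracks × 400 frames per condition) are chosen so
Monte-Carlo confidence intervals are a few percent of the quantities
asserted.

## Numerical notes

- All randomness flows through `numpy.random.default_rng(seed)`; equal
  (params, seed) gives bit-identical output, and the pipeline writes
  byte-identical CSVs for equal config + seed.
- Euler–Maruyama substeps must keep the substep kick RMS below about a
  third of the barrier width, otherwise particles numerically tunnel
  through ridges; the defaults satisfy this with a factor-2 margin and
  the convergence test guards it.
- `msd_histogram` smooths the log-binned counts (σ = 1 bin) before mode
  finding and refines peaks by quadratic interpolation; the two-mode
  split uses the count minimum between modes (`valley`, default) or a
  1D two-component Gaussian mixture on log R² (`gmm`).
- The contour map caps Scott's-rule bandwidth at two grid bins: the
  global standard deviation overstates the within-mode scale on
  multimodal data, and boundary smoothing uses zero padding so edge
  modes do not reflect.
- Degenerate inputs: stationary windows (⟨R²⟩ = 0) and zero-norm phasor
  segments raise errors rather than returning NaN; empty inputs
  propagate as empty outputs with warnings where the distinction
  matters.
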