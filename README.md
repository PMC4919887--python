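# rafttrack

Single-particle-tracking (SPT) analysis of membrane receptor diffusion,
with a Langevin simulator of the membrane environments that shape it.

Receptor proteins in the plasma membrane do not diffuse freely: cortical
actin forms compartments whose soft barriers stall them, and
cholesterol-rich lipid domains "dress" them in a shell of ordered lipids
that damps their step-size fluctuations.  `rafttrack` implements the
trajectory statistics that tell these environments apart, for
quantum-dot-style trajectories sampled at a frame period τ (25 ms by
default):

- the **bidirectional frame-scale MSD**
  R²(t) = (|r(t+τ)−r(t)|² + |r(t)−r(t−τ)|²)/2, with D = R²/(4τ);
- the **normalized variance** V = 4·Var(R²)/⟨R²⟩², calibrated so free
  diffusion gives V = 2 for every D.  Actin corrals push V above 2,
  lipid domains below 2 — V reads out whether the receptor's
  interaction with its environment is stochastic or deterministic;
- **(MSD, V) contour maps** with peak detection, and log-binned MSD
  histograms with fast/slow population splitting;
- **transient-confinement detection** (probability-of-staying index);
- the **phasor pair correlation** C between two trajectories, with
  selection of highly correlated segments (C > 0.8) for dimerization
  analysis;
- a four-regime **membrane simulator** (free / actin-corral meshwork /
  lipid-domain dressed diffusion / transient receptor dimers with a
  cholesterol-dependent bond), plus localization noise, synthetic TIFF
  rendering, spot detection and nearest-position linking.

Who it is for: anyone who has trajectory tables (`track_id, frame,
x_um, y_um`) or diffraction-limited movies of single membrane proteins
and wants environment fingerprints rather than just a global D — and
anyone who needs a generator of trajectories with known ground truth to
validate such an analysis.

## Worked example

Simulate the three environments at matched mobility and compare their V
fingerprints (`examples/02_regime_signatures.py`):

```python
import numpy as np, rafttrack as rt

D = 0.1
for regime, gen in [("corral", rt.simulate_corral),
                    ("free",   rt.simulate_free),
                    ("domain", rt.simulate_domain)]:
    params = rt.MembraneModelParams(regime=regime, D_free=D, sigma_loc=0.0,
                                    n_frames=400, seed=2)
    v = [s.V for t in gen(params, 300) for s in rt.segment_stats(t)]
    print(regime, round(np.mean(v), 3))
```

prints

```
corral:  V = 2.264  (> 2: barrier stalls)
  free:  V = 2.004  (= 2: reference)
domain:  V = 0.640  (< 2: dressed diffusion)
```

i.e. the corral ensemble sits significantly above the free-diffusion
value 2 and the dressed-domain ensemble well below it.  The
two-population MSD histogram (`examples/03_two_population_histogram.py`)
recovers a slow confined peak at 0.0112 µm² (D ≈ 0.11 µm²/s) and a fast
peak at 0.798 µm² (D ≈ 8 µm²/s) from a simulated mixture, and
`examples/05_correlated_pairs.py` shows the fraction of C > 0.8 windows
rising from 0.02 to 0.95 as the cholesterol scale goes from 0.1 to 1.0,
with the correlated segments' V falling to 0.41.

The other examples cover free-diffusion calibration,
confinement-event extraction and the render → detect → link imaging
round trip.  A thin CLI mirrors the library:

```sh
spt sim --regime domain --n-tracks 100 --out tracks.csv
spt stats --tracks tracks.csv --window 40 --step 20 --out stats.csv
spt confine --tracks tracks.csv --d-ref 0.03
spt corr --tracks pairs.csv --threshold 0.8
spt run --config run.yaml --seed 1 --out results/
```

`spt run` executes simulate → confine → stats → correlate from one YAML
config and writes CSV artifacts, a contour-map figure with its CSV twin,
and a JSON report with a provenance block (config hash, seed, version);
identical config + seed gives byte-identical outputs.

See `docs/methods.md` for the model, the estimator calibrations (the
finite-window correction that keeps free-diffusion V at exactly 2, the
energy-smoothing mechanism behind V < 2) and the meaning and limits of
every default.

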