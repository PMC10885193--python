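# iscatrack

Label-free single-molecule analysis for interferometric scattering
(iSCAT) microscopy of biomolecules on 2D-material surfaces — and a
ground-truthed synthetic movie generator that makes every stage of the
analysis testable.

## The problem

iSCAT images unlabeled molecules through the interference between the
light they scatter and the light reflected at the liquid–solid
interface. On a hexagonal boron nitride (hBN) flake, a long dsDNA coil
binding transiently to the surface appears as a faint, extended blob
with *bright and dark* lobes: the coil spans hundreds of nanometres
laterally (radius of gyration `Rg = sqrt(L·b/6)` ≈ 337 nm for 20 kbp)
and axially, so its image is a superposition of interferometric point
spread functions whose signs flip with nanometre axial displacement.
Extracting binding kinetics and binding-site maps from such movies
requires a pipeline of:

1. **Ratiometric background removal** — per-pixel running median over
   the preceding frames, contrast `c = (I − B)/B`;
2. **Detection** — threshold on |c| (both interference polarities
   count), connected components with morphological consolidation of a
   blob's lobes, absolute-contrast-weighted centre of mass;
3. **Linking** — globally optimal frame-to-frame assignment into
   trajectories; one-frame detections are counted separately as
   single-frame events;
4. **Kinetics** — dwell time = trajectory span × frame period
   (~11 ms at 90.5 Hz); arithmetic means with percentile-bootstrap 95%
   CIs, left-truncated exponential fits, and a discretisation-corrected
   maximum-likelihood mean-dwell estimator; two-surface comparisons by
   Mann–Whitney rank sum;
5. **Spatial statistics** — cross-lane binding histograms with peak
   offsets from etched lane edges, a contrast-bias control, and
   anisotropy diagnostics (decomposed MSD, axial Rayleigh test).

Because raw experimental movies are not required here, the
`simulate` module generates movies with known ground truth — Poisson
arrivals, exponential dwells, 2-D surface diffusion, affinity-patterned
surfaces (uniform / defect square / lane-edge enhanced), interferometric
blob rendering and shot-noise-like pixel noise — so recovery of every
quantity can be verified.

## Worked example

```bash
# 1. simulate a ground-truthed movie (uniform surface, 50 ms mean dwell)
iscatrack simulate --seed 7 --n-frames 1500 --arrival-rate 0.05 --out demo/sim
# -> wrote 1500 frames, 73 events -> demo/sim

# 2. background-correct, detect and link
iscatrack track demo/sim/movie.tif --out demo/track
# -> 325 localizations, 52 trajectories, 11 single-frame events -> demo/track

# 3. dwell-time kinetics
iscatrack analyze demo/track/trajectories.csv --out demo/analysis
# -> N=52 mean=66.7 ms [54.6, 80.1] -> demo/analysis
```

`demo/analysis/kinetics.json` then holds the trajectory count, the
arithmetic mean dwell with its bootstrap 95% CI, the split counts at
the 110 ms threshold, and `corrected_mean_dwell_ms` — the
maximum-likelihood estimate of the underlying continuous mean dwell
once the whole-frame discretisation and the two-frame trajectory
minimum are accounted for (the arithmetic mean of discretised,
truncated dwells is biased upward by roughly half a frame period plus a
truncation offset, so the two numbers differ by design).

In Python the same pipeline is three calls:

```python
import iscatrack as it

cfg = it.SimulationConfig(n_frames=1500, arrival_rate=0.05, seed=7)
surface = it.uniform_surface((cfg.n_px, cfg.n_px))
movie, truth = it.simulate_movie(cfg, surface)
result = it.track_movie(movie)
analysis = it.dwell_analysis(result)
print(analysis.to_dict())
```

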