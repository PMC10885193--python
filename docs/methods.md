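# Methods

This note records the models behind `iscatrack`, the parameters that
matter, and the design decisions taken where more than one reasonable
choice existed. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Polymer and time base

A long dsDNA molecule in solution is treated as an ideal chain: radius
of gyration `Rg = sqrt(L·b/6)` with contour length `L = n_bp × rise`
(rise 0.34 nm/bp, B-form) and Kuhn length `b = 100 nm` (twice the ~50 nm
persistence length). This closed form gives 238 / 337 / 522 nm for
10 / 20 / 48 kbp. The 48 kbp value sits within a nanometre of either
rounding convention, so downstream checks allow ±1 nm. Acquisition runs
at 90.5 Hz over a 3.4 × 3.4 µm field of view; the frame period
(1000/90.5 ≈ 11.05 ms) is the dwell-time quantum.

## The synthetic movie generator

The generator's purpose is statistical: it reproduces the structure the
analysis assumes, with every stochastic element seeded, so that the
pipeline's estimates can be compared with known inputs.

**Kinetics.** Arrivals per frame are Poisson with mean `arrival_rate`;
landing pixels are drawn with probability proportional to the surface
affinity map and jittered uniformly within the pixel. Dwells are
exponential with mean `mean_dwell_ms`, discretised to whole frames by
ceiling (minimum one frame — the single-frame-event class). While
bound, a molecule diffuses with per-axis step variance `2·D·Δt`
(default `D = 0.02 µm²/s`, a plausible scale for a surface-adsorbed
coil; it is a free parameter, not a measured value). The field of view
is absorbing by default (first step outside truncates the observed
dwell — the censoring mechanism that biases dwell estimates downward);
a reflecting mode provides the censoring-free control. Both modes
post-process the *same* random path, so with a shared seed the
absorbing truth is a pointwise truncation of the reflecting truth —
this is what makes the censoring-direction check deterministic at the
truth level.

**Rendering.** A coil is drawn as `K = 12` sub-scatterers placed once
per molecule in a disk of radius `Rg` (337 nm default). Sub-scatterer
`j` contributes a unit-peak Gaussian of width `σ_PSF = 130 nm` with
signed amplitude `A0·cos(φ0 + 4π·n·z_j/λ)` (λ = 635 nm, n = 1.33,
`A0 = 0.05`), so nanometre axial motion inverts contrast and a blob can
carry bright and dark lobes simultaneously. Two constraints are imposed
on the otherwise random placement:

* *Centro-symmetric pairs.* Offsets come in (r, −r) pairs sharing one
  axial offset, with any odd scatterer exactly at the centre. The
  rendered intensity is then point-symmetric about the molecule's
  position, so the blob's optical centroid coincides with the ground
  truth position by construction. Without this, the brightness centre
  of an internally interfering 700 nm blob wanders ~70 nm (median) from
  the geometric centre — not an artefact but a genuine ambiguity in
  what "position" means for an extended molecule; pinning the optical
  centroid makes sub-pixel localization a well-posed target.
* *Stratified axial offsets.* One axial offset per equal slab of the
  300 nm axial spread. The pair phases then always tile more than a
  full interference period, so some pair is always near an amplitude
  extremum and the blob never goes globally dark as its height drifts.
  (With fully random offsets, phases occasionally cluster near the
  null, producing multi-frame detection holes that artificially break
  trajectories.)

The axial coordinate performs a reflected random walk (20 nm steps)
inside the ±150 nm axial span. Pixel noise is zero-mean Gaussian with
std `noise_sigma·sqrt(background)` — the Gaussian limit of shot noise —
with `noise_sigma = 0.158` on a 1000-count background, i.e. a contrast
noise floor of 0.005 and an amplitude-to-noise ratio of 10. Movies are
rendered in float32 (camera-like dynamic range; halves the cost of all
whole-stack operations).

**What the generator does not emulate:** vectorial iPSF physics,
defocus, polarization, worm-like-chain internal dynamics, photon-level
Poisson statistics, background drift, or flake inhomogeneity. Passing
tests therefore demonstrate correctness of the *analysis* under the
stated statistical model, not instrument-level realism.

## Background removal

The background of frame `t` is the per-pixel median (or mean) of the
`window` frames strictly *preceding* `t`; contrast is `(I − B)/B`.
Excluding the current frame keeps even single-frame events out of their
own background. The default window is 150 frames (~1.7 s): a molecule
occupying more than half the window would capture the median, making
it fade while present and leave an inverted ghost after departure, so
the window must comfortably exceed the longest expected dwell. Because
the scattering background is static up to slow drift, the median is
recomputed only every `stride` frames (default 10) and reused in
between; `stride=1` recovers the exact per-frame definition. Warm-up
frames are dropped, not padded.

## Detection

Detection operates on |c| so constructive and destructive lobes both
count. Two standard morphological steps keep one molecule one
detection despite the nodal lines where |c| crosses zero:

* Gaussian pre-smoothing of |c| with σ = 1.5 px before thresholding
  (bridges narrow nodal lines; a matched-filter-scale choice);
* binary closing of the threshold mask with radius 4 px (merges lobes
  separated by wider gaps).

The threshold is calibrated per movie: median + 4 × 1.4826 × MAD of
the smoothed |c| stack (subsampled in time; the noise floor is
stationary). Regions under 50 px are discarded — genuine blobs at this
SNR occupy hundreds of pixels, while smoothed-noise clusters stay well
below 50. A localization whose centroid falls within 2 px of the
border is dropped (the *centroid* rule, not the region-touching rule:
a 20-px-wide blob brushes the border long before its centre does, and
discarding whole regions on contact silently blinds a ~500 nm deep
band of the small field of view).

Regions whose *coarse* envelope (|c| smoothed with σ = 7 px) carries
two local maxima at least 22 px apart are split by nearest-peak
assignment. The 22 px gate sits just above the geometric bound on a
single blob's own lobe separation (2·Rg ≈ 20 px at 33 nm pixels), so a
lone molecule is never split while most transient two-molecule
overlaps are resolved. Overlaps closer than ~22 px remain one
localization — an irreducible ambiguity at this blob size.

Localization is the absolute-contrast-weighted centre of mass of the
region (raw, unsmoothed weights), with pixel centres at
`(i + 0.5)·pixel_nm`, x = column, y = row.

## Linking and dwell times

Between consecutive frames, links minimise total squared displacement
over all one-to-one assignments with every link below `max_disp_nm`
(equivalently: minimise `Σd² + max_disp²·n_unmatched`), solved exactly
by the Hungarian algorithm — deterministic and order-independent.
`LinkConfig` defaults to no gap closing (a vanishing particle ends its
trajectory), matching the separate bookkeeping of single-frame events.

The *pipeline* default is calibrated on synthetic movies and differs:
`max_disp = 700 nm`, `max_gap = 2`, with re-acquisition across a gap
restricted to 250 nm. The generous per-frame radius lets a track ride
through the centroid excursions that occur while two blobs transiently
overlap; the tight gap radius prevents a re-acquired track from
capturing an unrelated nearby arrival. Dwell time is the trajectory's
frame *span* times the frame period (span = count when no gaps);
trajectories need ≥ 2 frames, single-frame detections are reported
separately.

## Dwell statistics

`summarize_dwells` reports the descriptive statistics used for
experimental summaries: arithmetic mean, seeded percentile-bootstrap
95% CI (10,000 resamples; an exhaustive mode enumerates all `n^n`
resamples for tiny samples), and counts at a 110 ms split.
`fit_exponential` is the left-truncated continuous-exponential MLE,
`rate = 1/(mean − min_dwell)`.

For *parameter recovery* neither is adequate: observed dwells are
`Δ·ceil(X/Δ)` conditioned on ≥ 2 frames, and the arithmetic mean of
that quantity overshoots the continuous mean τ by roughly `Δ/2` plus a
truncation term (≈ +30% at τ = 50 ms, Δ = 11 ms). `fit_discrete_dwells`
therefore models the frame count as a left-truncated geometric
variable: with `p = exp(−Δ/τ)`, the MLE is
`p̂ = (N̄ − k)/(N̄ − k + 1)` and `τ̂ = −Δ/ln p̂`, with a seeded
bootstrap CI. This estimator is consistent for τ and is what the
recovery tests and the acceptance script report.

Two-sample comparisons use the two-sided Mann–Whitney rank-sum test:
exact enumeration for small untied samples, normal approximation with
tie correction otherwise.

## Spatial statistics

Positions are projected onto the lane frame (along = lane direction,
cross = signed normal coordinate). Cross-lane histograms use 100 nm
bins anchored at the data minimum (translation-invariant counts);
peaks are local maxima of a 3-bin moving average above the median bin
count, reported with their heights so dominant accumulation peaks can
be ranked above floor fluctuations, and as signed offsets from the
nearest lane edge (positive = inside the trench). The contrast-bias
control groups localization contrast by cross-lane bin and applies the
Kruskal–Wallis rank test (flag at p < 0.01): a flat profile rules out
the "bright edges detect better" artefact. MSD is decomposed into
along/perpendicular components (their sum equals the total identically)
and step-direction isotropy is tested with the Rayleigh test on
*doubled* angles, the standard treatment for axial (bidirectional)
data.

## Validation study designs

* **Dwell recovery** (acceptance): 99 replicates cycling
  τ ∈ {30, 50, 80} ms; each replicate is a 1500-frame movie at
  0.033 arrivals/frame — the surface density scale of the real
  acquisitions (~1100 events over 30,000 frames) — with a reflecting
  boundary (no censoring) and landings kept ≥ 16 px from the border.
  Per condition this pools ≥ 500 events. Asserted: per-replicate
  bootstrap CI covers τ in ≥ 90% of replicates; the pooled
  discretisation-corrected estimate is within 10% of τ and within 10%
  of the same estimator applied to the ground-truth dwells. Density
  matters: at several-fold higher event rates, transiently overlapping
  blobs merge and split trajectories, biasing long-dwell estimates
  downward — a genuine limitation of this blob size on this small
  field of view, not a numerical artefact.
* **Censoring direction**: at the truth level, absorbing dwells are
  pointwise ≤ their reflecting counterparts (shared streams); at the
  pipeline level the pooled estimated mean over matched movie pairs
  must not increase when exits are enabled.
* **Detection quality**: precision and recall ≥ 0.9 against ground
  truth at a 3-pixel match radius, pooled over three 1000-frame movies
  at default SNR. Truth during the background warm-up window is
  excluded (no contrast exists there by construction).
* **Spatial recovery**: affinity ridges injected 300 nm inside each
  trench edge must be recovered within one 100 nm bin; the along-lane
  distribution must pass a χ² uniformity test; the MSD decomposition
  identity must hold to 1e-9 relative.

Problem sizes (frames, replicate counts, event rates) were chosen so
the full suite completes comfortably on a single CPU while keeping
every assertion statistically meaningful.

## Known limitations

* Two molecules closer than ~700 nm are one detection; their
  trajectories are not disentangled (no deflation/re-fitting step).
* Molecules parked longer than about half the background window fade
  into their own background; the window bounds the longest measurable
  dwell (~800 ms at the defaults).
* The discrete-dwell MLE assumes a single exponential population;
  mixtures are out of scope.
* Ground-truth "position" is meaningful at sub-pixel precision only
  because the renderer pins the optical centroid to it; for real data
  the reported positions are optical centroids, which for an extended
  flexible molecule can wander within the coil footprint from frame to
  frame.
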