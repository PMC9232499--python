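# Methods

`oncostream` quantifies collective migration of glioma cells from time-lapse
tracking data and histological sections.  It implements four analysis layers —
trajectory kinematics with likelihood-based pattern classification, pairwise
spatial/directional correlations, nuclear shape and alignment descriptors, and
phase-field border sinuosity — plus ground-truthed synthetic generators for
every input modality.  This note records the models, the defaults and why,
the numerical choices, and the limits of what the synthetic validation shows.

## Trajectory kinematics

Tracks are ordered samples `(t [min], x [µm], y [µm])` per cell, as produced
by a spot tracker (TrackMate-dialect XML or a plain CSV).  For each pair of
consecutive samples the *angle velocity* is `θ = atan2(Δy, Δx) mod 2π` and the
speed is `‖Δr‖/Δt · 60` in µm/h, using the actual time difference of the pair
so gaps in a track never inflate speeds.  A zero-displacement step keeps its
row with `valid = false` (speed 0, heading undefined); by default stationary
steps are excluded from speed summaries (`include_stationary` reverses this).
The default frame interval is 10 min.

Headings are per *step*, not per track: frame-resolved headings maximize the
sample entering the circular statistics, and a config switch
(`per_track_mean`) pools one circular-mean heading per track instead for
sensitivity analysis.  Analysis zones are axis-aligned rectangles evaluated
at the step midpoint with half-open `[min, max)` intervals — deterministic
membership, no double counting where zones tile.

## Pattern classification (swarm / stream / flock)

A zone's heading sample `θ₁…θ_N` is fit with three candidate circular
densities ρ(θ):

| pattern | density | free parameters |
|---|---|---|
| swarm  | uniform `1/2π` | 0 |
| flock  | von Mises `f(θ; μ, κ)` | 2 (μ, κ) |
| stream | `½ f(θ; μ, κ) + ½ f(θ; μ+π, κ)` | 2 (axis μ mod π, κ) |

The antipodal equal-weight mixture is the minimal family expressing "equal
but opposite directions"; its density reduces to
`cosh(κ cos(θ−μ)) / (2π I₀(κ))`.  Both directional families carry two
parameters, so the stream/flock decision is purely likelihood-driven.
Families are compared by `AIC = 2k − 2 logL` and Akaike weights
`AW_i = exp(−Δ_i/2)/Σ_j exp(−Δ_j/2)`; the zone label is the family with the
largest weight, with exact ties broken toward parsimony (swarm, then stream).
AICc is available (`use_aicc`) but off by default: per-zone heading samples
are hundreds of steps, where the small-sample correction is negligible.

Estimation: the von Mises MLE is closed-form in μ (mean-resultant direction)
with κ solving `I₁(κ)/I₀(κ) = R̄` by bracketed root finding; the mixture MLE
initializes its axis from the doubled-angle mean direction
`μ₀ = ½ arg Σ exp(2iθ_n)` and refines (μ, κ) by bounded L-BFGS-B,
multi-started over a concentration ladder with explicit boundary candidates,
to an `ftol` of 1e-14.  Both fits clip κ at 500 so degenerate (delta-like)
samples keep finite likelihoods; clipping is logged.  At κ = 0 both
directional densities reduce exactly to the uniform, a nesting identity the
tests assert to machine precision.  Fitted log-likelihoods are cross-checked
against an independent coarse-to-fine grid search (0.001 rad × 0.01 in κ)
to 1e-3.

Zones with fewer than `min_n = 30` headings get a null label rather than a
fit — below that an Akaike comparison is noise.  A von Mises kernel density
estimate (default kernel concentration 8, a purely visual smoothing) and
rose-plot histograms accompany each classification in reports and figures.

**Expected misclassification of swarms.**  Under truly uniform headings each
directional family gains ~½χ²₂ of log-likelihood by overfitting, so its AIC
beats the swarm's with probability `P(χ²₂ > 4) = e⁻² ≈ 0.135` per family;
the two gains live in different circular harmonics and are nearly
independent, giving a swarm recall of about `(1−e⁻²)² ≈ 0.75` regardless of
sample size.  This is an irreducible property of AIC-weight selection with
this model set — directional patterns are recovered essentially perfectly,
while about a quarter of genuinely disordered zones are assigned a weakly
supported directional label.  Consumers should read AW magnitudes, not only
the argmax label.

## Pairwise spatial and directional correlations

Zone-labeled kinematics are regrouped into per-frame snapshots.  The pair
directional correlation is the mean of `cos(θ_i − θ_j)` over cell pairs
binned by separation (default 0–50 µm in 10-µm bins, the range where the
source analyses report positive correlation).  Pairs are pooled across
frames before averaging (pair-weighted; `frame_weighted` switches to
per-frame means).  Because a perfect stream is antiparallel, the polar
kernel averages toward zero there; a nematic variant `cos 2(θ_i − θ_j)` is
provided and flagged in outputs.  In sector mode each pair contributes twice
(each cell once as focal) classified by the neighbor's bearing in the focal
heading frame: front (−45°, 45°], right (45°, 135°], back (135°, 225°],
left (225°, 315°].

The relative-position map histograms neighbor displacements rotated by
−θ_focal (front = +x), normalized to a probability map.  Nearest-neighbor
distances use a k-d tree; a toroidal option exists solely so the Poisson
closed form `E[NN] = 1/(2√λ)` can be used as an edge-free oracle — real
fields are analyzed unwrapped, and no edge correction is applied inside
zones.

## Nuclear shape and alignment

From an integer-labeled mask with isotropic pixel size: area, Crofton
perimeter, circularity `4πA/P²` (reported as measured; discretization can
push it slightly above 1, never clipped), and the moment-ellipse aspect
ratio `√(λ_max/λ_min)` of the second central moment tensor — the "fit
ellipse" convention, robust to rotation.  Cells are called elongated when
AR ≥ 2.0, the midpoint between the reported group means of spindle-like
(2.63) and round (1.37) glioma nuclei.  Border-touching objects are kept by
default (`exclude_border_objects` to drop them).

The Feret angle is the orientation, in [0°, 180°) from the x-axis, of the
object's longest chord, found over convex-hull antipodal pairs with ties
going to the smallest angle.  Note that for non-elliptical shapes the
longest chord need not follow the figure's long side — a 4:1 rectangle's
longest chord is its diagonal (≈14°), which is also what ImageJ reports; for
the near-elliptical nuclei this descriptor targets, the longest chord and
the elongation axis coincide.  Population alignment is the nematic order
parameter `S = ‖(⟨cos 2θ⟩, ⟨sin 2θ⟩)‖` with mean axis
`½ atan2(⟨sin 2θ⟩, ⟨cos 2θ⟩)`; doubling makes antiparallel axes equivalent,
so S = 1 iff all axes are parallel and S ~ √π/(2√n) for isotropic fields.

## Border sinuosity via Allen–Cahn smoothing

The tumor/brain image is thresholded (fixed value or Otsu) to phases
u = ±1 and relaxed under `∂u/∂t = ε²∇²u + u − u³`, the Allen–Cahn flow of
the double-well `W(u) = (1−u²)²/4` whose minima sit at the two phases.
Explicit Euler with the 5-point Laplacian and zero-flux boundaries; the
stability bound `dt ≤ 0.9·h²/(4ε²)` is enforced before stepping.  In 1-D the
stationary interface is `u(x) = tanh((x−x₀)/(√2 ε))`, fixing ε as the
interface half-width; the default ε = 2 px removes pixel-scale segmentation
noise after the default 200 steps while leaving lobes much wider than ε in
place.  Uniform ±1 fields are exact fixed points and the scheme preserves
the u → −u symmetry exactly.

The smoothed border is the marching-squares zero contour (linear
interpolation); the longest contour terminating on image edges is the
border arc, and `S = L/D` — polyline length over the distance between the
two extreme points — is its sinuosity (≥ 1, invariant to rigid motions and
scaling).  Closed contours (tumor islands) are reported separately with S
undefined.  Smoothing necessarily erodes high-curvature lobes, biasing S
slightly downward; with the defaults the full
binarize → smooth → extract → S pipeline recovers the generated ground
truth within 5% and always preserves the ordering of a flatter versus a
more sinuous border — the comparison that matters for the
collagen-knockdown contrast.

## Synthetic generators and what they do (not) show

All validation inputs are generated, seeded and ground-truthed:

* **Trajectories** — per-step headings from the pattern's law (swarm:
  uniform; flock: von Mises, default κ = 4; stream: von Mises around a
  per-cell antipodal lane, ⌈n/2⌉ cells per direction), step lengths
  `speed·Δt` with mean-one lognormal noise (default CV 0.3; the printed
  speed histograms are broad but carry no distribution form), defaults
  Δt = 10 min, 293 frames (the core movie length; border movies ran 186),
  and per-pattern mean speeds 6.27 / 4.26 / 5.95 µm/h (reported core
  values; the border values 8.01 / 7.95 / 7.55 are provided as constants).
  50 cells in a 400 µm square put nearest neighbors near 30 µm, inside the
  reported 20–40 µm window.  The arena is an imaging window: a cell
  stepping out re-enters opposite **as a new track**, as a tracker would
  close and reopen trajectories at the field edge.  Mirror walls were
  rejected because persistently directional cells pile against them,
  shortening folded steps and reversing headings (measured stream speed
  fell 5.8% below its parameter at 293 frames).  Stream lanes are per-cell
  by default; a `lane_width` option assigns lanes by spatial bands to
  emulate parallel fascicles, and `resample_lane_each_step` provides a
  persistence-free null.
* **Ellipse fields** — non-overlapping ellipses of constant equivalent
  radius (default 12 px), truncated-normal aspect ratios and axial-von
  Mises orientations, rasterized with consecutive labels and per-object
  ground truth.
* **Borders** — binary images of `y = A sin(2πx/λ)` margins with
  salt-and-pepper flips; the ground-truth sinuosity comes from dense
  quadrature of the sine arc length.

These are statistical emulators, not mechanistic models: there is no
cell–cell steric alignment, ECM guidance, confinement, division or death,
no segmentation noise beyond pixel flips, and no heading persistence beyond
the pattern structure.  Passing tests therefore demonstrate that the
estimators recover known statistical structure at realistic sampling — not
that real microscopy meets these assumptions.  Two empirical findings of
the source data are explicitly *not* reproducible from these generators:
the absolute pair-correlation magnitudes (≈0.1–0.4) and the higher
left–right correlation of streams, both of which depend on spatial
organization the statistical trajectory model does not encode (with banded
lanes the emulator's anisotropy is strongest front–back, along the lane).

## Reproducibility

Every generator is deterministic under its seed; identical configs produce
byte-identical CSV/JSON artifacts (fixed float formatting, sorted keys, no
timestamps), and reports embed SHA-256 hashes of config and inputs.
`scripts/acceptance.py` regenerates all headline quantities from scratch at
the sizes stated above (300 classification ensembles at N = 200, 50-seed
recovery at N = 2000, 20-sample oracle comparisons, 256×640 border images)
in well under a minute of compute.
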