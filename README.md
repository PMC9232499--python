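# oncostream

Quantitative analysis of **collective glioma cell migration** from
time-lapse microscopy and histology.  High-grade gliomas contain
*oncostreams* — fascicles of elongated, nematically aligned tumor cells —
and time-lapse imaging of tumor explants shows their cells moving in
organized collective patterns.  This package provides the measurement
machinery for that phenotype:

* **Trajectory kinematics** — read cell tracks (TrackMate-dialect XML or
  CSV), derive per-step headings θ = atan2(Δy, Δx) and speeds (µm/h), and
  partition steps into analysis zones.
* **Motion-pattern classification** — fit a zone's heading sample with three
  circular densities: uniform (*swarm*: no preferred direction), von Mises
  f(θ; μ, κ) (*flock*: one direction), and the antipodal mixture
  ½f(θ; μ, κ) + ½f(θ; μ+π, κ) (*stream*: equal but opposite directions);
  compare them with Akaike weights AW ∝ exp(−ΔAIC/2) and label the zone by
  the largest weight.
* **Pairwise correlations** — pair directional correlation
  C(r) = ⟨cos(θᵢ−θⱼ)⟩ versus cell separation (optionally by front / back /
  left / right sector in the focal heading frame), relative-position maps,
  and nearest-neighbor distance statistics.
* **Shape & alignment** — per-nucleus aspect ratio (moment ellipse),
  circularity 4πA/P², Feret angle, and the nematic order parameter
  S = ‖⟨e^{2iθ}⟩‖ for population alignment.
* **Border sinuosity** — threshold a tumor/brain image to phases ±1, smooth
  the interface with the Allen–Cahn equation ∂u/∂t = ε²∇²u + u − u³, extract
  the zero-level contour, and report its sinuosity S = L/D (curve length
  over endpoint distance).
* **Synthetic generators** — seeded, ground-truthed trajectories, ellipse
  fields and borders emulating the statistical structure of each input, so
  every estimator can be validated end to end.

See `docs/methods.md` for models, defaults and limitations.

## Worked example

Generate a synthetic stream (antipodal lanes, concentration κ = 4, default
mean speed 4.26 µm/h) and classify its pooled headings:

```bash
oncostream generate trajectories --pattern stream --n-cells 40 \
    --n-frames 60 --seed 7 --out stream.csv
oncostream classify stream.csv
```

```json
{
  "label": "stream",
  "n": 2354,
  "akaike_weights": {"flock": 0.0, "stream": 1.0, "swarm": 0.0},
  "mu":    {"flock": 1.6509, "stream": 0.0116, "swarm": null},
  "kappa": {"flock": 0.0145, "stream": 3.9776, "swarm": null}
}
```

Read: from 2354 per-step headings the stream model wins all the Akaike
weight (the printed AW:1 / AW:0 situation), recovering the generating axis
(μ ≈ 0.012 rad vs true 0) and concentration (κ̂ ≈ 3.98 vs true 4).  The
flock fit collapses toward uniform (κ̂ ≈ 0.01) because the two lanes cancel
its mean resultant.

The same works zone-wise from a TOML config (tracks + zone ROIs + options),
producing a deterministic JSON report plus rose plots, model-comparison
panels, speed histograms and correlation curves:

```bash
oncostream run --config analysis.toml --out results/
```

Other subcommands: `kinematics`, `correlate`, `shapes` (labeled-mask
descriptors), `border` (Allen–Cahn sinuosity), and `generate
trajectories|ellipses|border`.  Everything is also available as a library
(`import oncostream`).

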