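# ldquant

Quantitative fluorescence-detected linear dichroism (LD) imaging for
polarization-resolved microscopy.

Fluorophores whose orientation is constrained — dyes in lipid membranes,
labels on cytoskeletal filaments, membrane-anchored fluorescent proteins —
absorb polarized excitation light anisotropically: the fluorescence excited
with horizontal vs vertical polarization differs, and the dichroic ratio
r = F_h/F_v reports molecular orientation. `ldquant` is a Python library
(plus a thin `ldquant` CLI) for scientists who acquire such images on
laser-scanning microscopes and want to go from raw frames to physical
statements about fluorophore orientation:

* **visualize** LD — de-interleave mixed-polarization frames (polarization
  alternated between adjacent pixels), correct background / bleed-through /
  illumination imbalance / bleaching, and render per-pixel r (or r_max) as
  hue with intensity as brightness, including molecular-azimuth overlays;
* **quantitate** LD — segment vesicles and filaments (Hough circles,
  thresholding, external masks), approximate their shape by a spline, and
  extract (θ, log₂ r) curves, where θ is the angle between the excitation
  polarization and the local feature tangent;
* **interpret** LD — fit the one- and two-photon parametric curves

  log₂ r(θ) = A₁ₚ + log₂[(1 + B₁ₚ cos 2(θ−φ₁)) / (1 − B₁ₚ cos 2(θ−φ₂))]

  log₂ r(θ) = A₂ₚ + log₂[(1 + B₂ₚ cos 2(θ−φ₁) + C₂ₚ cos 4(θ−φ₁)) /
  (1 − B₂ₚ cos 2(θ−φ₂) + C₂ₚ cos 4(θ−φ₂))]

  and invert them to a wrapped-Gaussian distribution of transition-dipole
  tilt angles α (mean tilt α₀ from the membrane normal or filament axis,
  width σ, free rotation ρ about the axis). One-photon data constrain a
  single shape parameter and leave a band of consistent (α₀, σ); combining
  1P and 2P data collapses the band. Goodness heat maps (r², RMSD, χ²),
  object-level bootstrap confidence regions, two-Gaussian mixture searches
  and an r_max-only lookup complete the toolkit.

The forward model reduces any tilt distribution to two sufficient
statistics, m₂ = ⟨cos²α⟩ and m₄ = ⟨cos⁴α⟩, from which B₁ₚ, B₂ₚ, C₂ₚ follow
in closed form; a brute-force Monte-Carlo orientation sampler serves as the
independent oracle for every closed form in the test suite. A synthetic
scene generator (vesicle rings and filaments with Poisson noise and
calibration artifacts, plus ground-truth sidecars) makes the whole pipeline
testable without microscope data.

## Worked example

`examples/quantify_vesicle.py` renders 1P and 2P polarization pairs of a
synthetic DiI-like vesicle (transition dipole in the membrane plane,
α₀ = 90°, σ = 10°; 256² pixels, 10⁴ peak photons), runs the full chain —
correction → dichroic-ratio map → circle detection → spline outline →
θ-sample extraction → fits — and prints:

```
1p: 2076 pixel samples along the outline
2p: 1489 pixel samples along the outline
1P fit: B1P=0.888  log2(rmax)=+4.080  r2=0.9982
2P fit: B2P=1.227 C2P=0.247  log2(rmax)=+6.977
combined best (alpha0, sigma) = (89, 10) deg; truth = (90.0, 10.0)
near-optimal cells: 1P-only 37, combined 44
```

Reading: the 1P curve amplitude B₁ₚ = 0.888 corresponds to log₂ r_max ≈ 4.1
— fluorescence excited along the membrane tangent is ~17× brighter than
across it, as expected for an in-plane dye. The combined 1P+2P heat-map scan
recovers the generating distribution to within one 1° grid cell. The other
examples cover the forward model, mixed-frame visualization, pooling with
bootstrap confidence regions, and the mixture/r_max accessory analyses; each
prints what its numbers mean.

The same chains are scriptable from a shell, e.g.

```sh
ldquant simulate --out sim --alpha0 90 --sigma 10 --modality 2p
ldquant process-pair sim/pair.tiff sim/pair.yaml --out proc --min-intensity 100
ldquant segment proc/ldmap.tiff --out seg --radius-min 25 --radius-max 55
ldquant quantify proc/ldmap.tiff seg/outline.csv --out obj1 --modality 2p
ldquant heatmap . --out heat
```

Every subcommand writes its effective configuration next to its outputs;
identical configuration + inputs + seeds give byte-identical outputs.

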