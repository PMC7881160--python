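# Methods

## The photoselection model

A fluorophore's single-photon absorption is described by its transition
dipole moment (TDM) μ̂: the excitation probability is ∝ (μ̂·ê)² for
excitation polarization ê, and ∝ (μ̂·ê)⁴ for two-photon excitation under
the vector approximation (the same vector is assumed to orient 1P and 2P
absorption; no separate 2P tensor is modelled). Molecules attached to a
membrane or filament have a preferred tilt angle α from the local symmetry
axis — the membrane normal, or the filament axis — with free rotation ρ
about that axis.

The tilt density on α ∈ [0°, 90°] is a wrapped, mirror-folded Gaussian with
a spherical area element:

p(α) ∝ sin α · Σₖ Σ± N(α; ±α₀ + 180°k, σ),

folded about 90° because the TDM is an axis (α ≡ 180° − α). The number of
wrap terms grows with σ so the truncated sum always covers ±4σ. One- or
two-component mixtures are supported, with weight-linear moments.

**Why the sin α factor.** The wrapped Gaussian is a density of tilt
*angles*; multiplying by the spherical area element makes σ → ∞ converge to
the uniform axis distribution, for which ⟨cos²α⟩ = 1/3, ⟨cos⁴α⟩ = 1/5 and
all dichroism vanishes. Without it, a "maximally disordered" distribution
would retain spurious LD (b₁ₚ → 1/3), which contradicts the physical
meaning of the isotropic limit. In the σ → 0 limit the factor is irrelevant
(the density collapses onto α₀, and widths below 0.01° use the exact delta
shortcut m₂ = cos²α₀, m₄ = cos⁴α₀), so "pencil" (α₀ ≈ 0°) and "pancake"
(α₀ ≈ 90°) regimes and the 1P magic angle (α₀ = 54.74°, zero 1P dichroism)
are unchanged.

Because absorption probes only even moments of μ̂, two sufficient statistics
determine all observables: m₂ = ⟨cos²α⟩ and m₄ = ⟨cos⁴α⟩ (computed by
trapezoidal quadrature at 0.05°, far below any experimental error). The
ρ-averaged excitation probability at angle β between ê and the symmetry
axis is

- F₁ₚ(β) ∝ m₂ cos²β + ½(1−m₂) sin²β
- F₂ₚ(β) ∝ m₄ cos⁴β + 3(m₂−m₄) cos²β sin²β + ⅜(1−2m₂+m₄) sin⁴β

whose Fourier-normalized coefficients give the dichroic shape parameters:
b₁ₚ = (3m₂−1)/(m₂+1), and b₂ₚ, c₂ₚ as the cos 2β and cos 4β coefficients of
F₂ₚ over its DC term. These reductions are validated in the test suite
against direct Monte-Carlo averaging of (μ̂·ê)² and (μ̂·ê)⁴ over explicitly
sampled orientations (inverse-CDF in α, uniform ρ). Physical ranges:
b₁ₚ ∈ [−1, 1] (−1 for a perfect in-plane axis, +1 for a perfect axial one);
b₂ₚ up to 4/3 and c₂ₚ up to 1/3 at the delta pole, where the 2P intensity
polynomial 1 + b₂ₚcos2β + c₂ₚcos4β touches zero.

The predicted dichroic curve is log₂ r(θ) = log₂[F(β)/F(β+90°)] with
θ → β = 90° − θ for membranes and β = θ for filaments; θ = 0 when the
horizontal polarization is parallel to the local feature tangent (measured
counter-clockwise in the displayed image, mod 180°), which makes in-plane
dyes peak at θ = 0. Ideal curves are exactly antisymmetric about 45°.

## Image processing

* **De-interleaving.** Mixed-polarization frames alternate polarization
  between adjacent pixel columns (or rows); each channel is re-gridded to
  the full pixel grid by linear interpolation along the modulation axis, so
  the pair is co-registered. The modulation scheme and phase (which
  polarization came first) are explicit metadata, defaulting to
  column-alternation with horizontal first.
* **Calibration.** Per-channel background (default: the 1st percentile of
  the channel, for unattended batch runs) is subtracted and clamped at zero;
  bleed-through is removed by linear unmixing with symmetric fraction k,
  f′ₕ = (fₕ − k f_v)/(1−k²); the vertical channel is scaled by an
  illumination gain g.
* **Per-pixel fits.** Multi-polarization stacks (≥4 frames, uniform steps
  spanning ≥165°) are fitted per pixel by F = A + B cos²(θ−C) via harmonic
  regression on the 2θ Fourier component — closed-form, deterministic, and
  exact on noiseless data at uniform angles (nonuniform spacing falls back
  to linear least squares). r_max = (A+B)/A; the azimuth C is the
  polarization of maximal fluorescence, undefined (NaN) where B ≈ 0.
* **Bleaching.** A single-exponential trend is fitted to frame means by
  log-linear regression and divided out. The model is deliberately simple;
  it removes the dominant artifact of sequential acquisition without
  attempting pixelwise photokinetics.
* **Renders.** Hue encodes clipped log₂ r (default range ±2, blue→red) or
  the cyclic azimuth; brightness encodes intensity normalized to its 99th
  percentile; invalid pixels are black. The color-bar and color-wheel
  generators share the exact ramp used by the renderer, and all renders are
  pure functions of their inputs.

## Quantitation and inference

Pixels inside the segmentation are assigned the tangent angle of the
nearest point (Euclidean) on a dense (≤0.5 px) resampling of an
interpolating cubic spline through the outline anchors; pixels farther than
3 px (≈ ring thickness / PSF) are dropped, and outline stretches of
excessive curvature can be excluded automatically (the reproducible stand-in
for manual exclusion of membrane irregularities, alongside external eraser
masks). Each sample carries (θ, log₂ r) and an intensity weight.

Curve fits use weighted nonlinear least squares with multi-starts over
phase (0°, 45°, 90°, 135°) and amplitude (0.1, 0.5, 0.9), the two phases
constrained to |φ₁−φ₂| ≤ 20°, and B₁ₚ ∈ [0, 1). For the free 2P fit both
intensity polynomials must stay positive with a 0.01 margin — this encodes
the "strictly positive" requirement and simultaneously excludes
near-singular curve shapes whose spikes chase noise; C₂ₚ is retained only
when it improves the fit significantly over the nested C = 0 model (F-type
threshold of 4), because the cos 4θ direction is unidentified in weak-LD
data; a 10⁻³ ridge on (B, C) pins the exactly flat degeneracy at zero.
Reported log₂(r_max) is the signed extremum of the fitted curve with the
largest magnitude; near-ties between the positive and negative lobes (the
ideal curves are antisymmetric, so 2% relative) resolve to the lobe nearer
θ = 0, matching the r_max = F_h(θ=0)/F_v(θ=0) convention. χ² uses per-point
variances estimated from local scatter in 18 θ-bins, since photon-level
error propagation is not available for generic input tables.

**Heat maps.** Shape parameters are pre-tabulated on an (α₀, σ) grid
(default 1° spacing, serializable to CSV with a content hash). For every
cell the predicted curve — evaluated at 0.25° θ-bin centers against binned
sufficient statistics (Σw, Σwy, Σwy² per bin), a representation exact up to
sub-bin curvature that makes bootstrap refits a matrix product — is scored
with the curve offset profiled out by weighted least squares (one offset
per modality in combined fits, the distribution shared). Slices report r²
(intensity-weighted), RMSD (unweighted), and χ²; the best cell minimizes
the pooled weighted SSE. Offsets are profiled rather than fixed from the
parametric fit so each cell is judged by the best version of itself.

**Degeneracy and its quantification.** 1P data determine only b₁ₚ, so all
cells on a b₁ₚ level set score identically — the degenerate band. Heat-map
"near-optimal" counts use a Δr² = 0.005 band by default. Two caveats,
verified on synthetic data: (i) near α₀ = 90° the mirror fold makes
adjacent α₀ cells nearly identical, so even noiseless combined maps keep
tens of near-optimal 1°-cells at the pole — the band collapse upon adding
2P data is real but expresses itself at coarser grid resolution (≈5°) for
in-plane truths; (ii) for mid-range truths (e.g. α₀ = σ = 25°) the
contrast between the long 1P band and the compact combined optimum is
visible at any resolution.

**Bootstrap.** The resampling unit is the object (vesicle/cell) — pixels
within an object are strongly correlated, so pixel-level resampling would
be anticonservative. Each replicate resamples objects with replacement and
refits the best cell; the confidence mask is the smallest cell set
containing the requested fraction (default 95%) of replicate best fits,
always including the full-data best cell. Deterministic given the seed.

**Mixture search.** Exhaustive over two components on a coarse grid (α₀
step 5°, σ ∈ {5…45°}, fraction step 0.1 — a full search stays well under a
CPU-minute), scoring closed-form mixture shape parameters against the
targets by squared residual; near-ties (10⁻⁹) are broken toward the higher
differential entropy of the mixture tilt density (trapezoid on the 0.05°
grid, in bits) — the least committed of equally good answers. Non-uniqueness
is inherent and the ranked list, not the top element, is the result.

## The synthetic-scene generator

Scenes emulate the paper-grade acquisition regime: equatorial vesicle
cross-sections (rings) or filament segments with a Gaussian radial profile
(default width 3 px ≈ PSF at 100 nm pixel spacing), per-pixel intensities
driven by the forward model through the analytically known local tangent,
scaled to a peak expected photon count (default 10⁴), then illumination
imbalance, bleed-through mixing, per-frame bleaching (stacks), background,
and Poisson sampling applied in acquisition order. Truth sidecars carry the
distribution, the tangent map and the noise-free channels.

What the generator does **not** emulate — and hence what passing tests do
not certify about real data: optical PSF blur beyond the radial profile,
high-NA polarization mixing, out-of-plane membrane tilt (available only as
a σ-inflation knob), membrane ruffling, detector nonlinearity, sample
motion, and registration errors (inputs are assumed pre-aligned).

## Numerical choices and defaults

| Parameter | Default | Rationale |
|---|---|---|
| quadrature step | 0.05° | error ≪ experimental noise |
| σ clamp / delta shortcut | 0.01° | avoids division by zero; exact below |
| lookup grid | α₀ 0–90°, σ 1–90°, 1° | resolution of published heat maps is unstated; 1° oversamples it |
| θ-bin width (maps) | 0.25° | binning bias ≪ cell-to-cell differences |
| min intensity | 0 (off) | set ≈1% of peak for photon-limited data |
| max pixel–outline distance | 3 px | ring thickness ≈ PSF |
| hue range | log₂ r ∈ [−2, 2] | visually arbitrary; recorded in output metadata |
| bootstrap | 200 replicates, 95% | <50 replicates triggers a warning |
| fit multi-starts | φ×B (×C) grid | the curves are multimodal in phase |

Degenerate inputs: perfectly polarized limits return signed-infinity
sentinels from the forward model only — fitting never produces them because
parameter bounds keep denominators positive; zero-variance data flag r² as
undefined while RMSD stays valid; empty masks, blank images, insufficient
θ-span and single-object bootstraps raise errors naming the violated
precondition.

## Known limitations

* The wrapped-Gaussian family cannot represent fluorophores with an extra
  internal rotation axis (e.g. a dye swiveling about its attachment bond);
  for such probes the model fits poorly by construction, which the low r²
  of the combined fit makes visible.
* Restricted 2P fits and heat maps assume the θ convention established by
  the geometry module; externally produced θ tables must follow it.
* The mixture search ranks but cannot disambiguate near-equivalent pairs;
  goodness differences between candidates are typically far below
  experimental reproducibility.
* Bleaching correction assumes a global mono-exponential; strongly
  heterogeneous bleaching biases stack-mode r_max.
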