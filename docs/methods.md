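# Methods

`mmgrowth` implements, as tested reusable code, the quantitative analyses
used to ask what limits *E. coli* growth in dead-end mother-machine
channels: sub-pixel cell dimensioning from fluorescence images, closed-form
1D transport models for nutrient shielding and solute accumulation, the
universal growth-law fit, and a thin-shell estimate of the growth-stalling
force. No raw imaging data for this system is publicly deposited, so the
package ships a first-class synthetic-data generator and validates every
stage against known ground truth.

## Synthetic scenes

A scene is a dead-end channel (width *W*, height *H*, length *L*; defaults
0.9 × 1.15 μm in cross-section) holding a single row of non-overlapping
spherocylindrical cells, described by pole-to-pole length *L*_c, outer
diameter *W*_c, centre and axis angle. The rendered silhouette is the
*cytoplasmic* fluorophore distribution: a 2D capsule of total length *L*_c
whose diameter is *W*_c − 0.08 μm. The 0.08 μm is the sum of the two
corrections the measurement stage later adds back — 0.04 μm because a
Gaussian fitted to a diffraction-blurred rod profile underestimates the
cytoplasmic diameter by about that much at this scale, and 0.04 μm for the
periplasm and outer membrane that the cytoplasmic label does not fill.

Rendering uses 8×8 sub-pixel area-coverage sampling (so edges carry
sub-pixel information), an isotropic Gaussian PSF (default σ = 0.10 μm),
Poisson shot noise on background-plus-signal, and additive Gaussian read
noise (default sd 2 photons). With `psf_sigma = 0` the renderer switches to
pixel-centre membership, producing an exactly binary image — the discrete
limit used by the area oracle. Defaults: pixel size 0.065 μm (100×
objective onto a 16 μm-pixel camera scale, typical for this hardware class;
the instrument scale is not published), background 100 and peak 400
photons. The imaging hardware is named in the source study but not its
camera settings, so the optics parameters are calibration knobs, not
published values.

The canonical `typical_scene` places ~10 cells of *L*_c = 2.12 ± 0.12 μm,
*W*_c = 0.78 ± 0.02 μm (the measured channel-cell scale) with 0.35 μm
inter-cell gaps. Real channel colonies grow without gaps; the gaps exist so
segmentation has a countable ground truth, and the generator makes no
attempt to emulate division lineages, phase-contrast contrast, deformed
(pear-shaped) cells, or 3D sectioning. Passing tests on these scenes
demonstrate correctness of the measurement operators under the stated
optics, not performance on crowded or deformed real images.

The growth-law generator samples doubling times uniformly (default 100–220
min, the channel-regime range) and applies mean-one lognormal noise to
birth volumes (default CV 3%).

## Cell dimensioning

1. **Edge operator.** The image is mapped to the sum of its Laplacian and
   its second derivative along the local gradient direction, computed with
   Gaussian-derivative kernels (default scale 1 px). The discrete truncated
   second-derivative kernel has a small nonzero DC sum; the operator
   subtracts that response explicitly so constant images map exactly to
   zero and the zero crossing is unbiased.
2. **Segmentation.** Interior = negative side of the zero crossing
   (threshold at −10⁻⁹ of the map scale to exclude float round-off in flat
   background), one erosion and one dilation with a 3×3 cross, connected
   components, then an area filter (default 20 px) and a contrast filter
   (component mean above the median background by 2 robust noise sd, with
   a 10⁻⁶-of-dynamic-range floor for noise-free images). The contrast
   filter is what makes pure-noise images return zero masks.
3. **Length.** Greatest Feret diameter over the convex hull of the mask.
   Two vertex conventions are provided: `"boundary"` (pixels as unit
   squares; the default, unbiased for blurred-edge masks — a 10×3-pixel
   rectangle measures √109 px) and `"centers"` (pixel centres; shifts
   lengths by ~1 px, a single pixel measures 0).
4. **Width.** Intensity profiles through the gray-value centre of mass,
   perpendicular to the long axis ± 15° in 1° steps, sampled bilinearly at
   0.25 px; each profile is fitted to a four-parameter Gaussian and the
   smallest fitted width wins, ties resolved toward the exact
   perpendicular. The fitted width (FWHM by default; 1/e and σ conventions
   available) plus the diffraction offset gives the cytoplasmic diameter;
   adding the envelope offset gives the outer diameter.
5. **Volume.** V = (π/6)W³ + (π/4)W²(L − W) applied to (length, outer
   width).

**Offset calibration.** The 0.04 μm diffraction offset is an
instrument-specific constant. `calibrate_diffraction_offset` renders a
noise-free reference rod with the scene optics and returns the offset that
makes the full pipeline recover its known diameter — the synthetic analogue
of calibrating against cells of known size. At the default optics it
returns ≈ 0.037 μm at *W*_c = 0.78, close to the published constant, but
it drifts with diameter (≈ 0.044 at 0.72 μm, ≈ 0.003 at 0.84 μm) because a
single Gaussian is an imperfect model of a blurred top-hat; width accuracy
claims therefore hold in the mean over a scene's population, and the offset
should be recalibrated when optics or cell scale change materially.

On noise-free scenes at the defaults the pipeline recovers lengths with
mean absolute error below one pixel and outer widths with mean absolute
error below 0.02 μm, and segmentation counts equal ground truth on noisy
scenes with ≥ 3 px gaps.

## Transport models

All transport works in μm, seconds and molecules/μm³ internally
(1 mM = 6.022 × 10⁵ molecules/μm³); mM, minutes and kg-based fluxes are
converted at the interface.

**Nutrient screening (absorption-limited).** A continuum of absorbing
cells (radius *R*_c) with first-order uptake *k*_abs per unit cell surface
gives

  (WH − πR_c²) D c″ = 2πR_c k_abs c,  c(0) = c₀, c′(L) = 0,

whose solution is c(x) = c₀ cosh((x−L)/λ)/cosh(L/λ) with screening length
λ = √((WH − πR_c²)D / (2πR_c k_abs)). Coupling to Michaelis–Menten growth
kinetics, T_d(x) = T_d,min + (T_d,liquid − T_d,min)·cosh(L/λ)/cosh((x−L)/λ),
and the mother cell at x ≈ L has T_d = T_d,min +
(T_d,liquid − T_d,min)·cosh(L/λ) — constant for L ≪ λ, exponential for
L ≫ λ. No measured value of *k*_abs exists, so λ is exercised
parametrically. Wall adsorption can be folded into *k*_abs additively. The
cosh ratio is evaluated via exponentials so deep-screening channels
(L/λ ≫ 1) do not overflow.

**Kinetically limited depletion.** When uptake is saturated at *I*_max per
cell, the drop over a cell-filled channel is
Δc = L²I_max / (2(WH − πR_c²)L_c D). With *I*_max = 2×10⁵ s⁻¹, D = 700
μm²/s, L = 50 μm, L_c = 2.12 μm, R_c = 0.4 μm this evaluates to ≈ 0.53 mM.
The source study prints 2.7 mM for this scenario without stating its
(R_c, L_c); forward evaluation cannot reproduce that number for any
plausible cell geometry, so the package reports the formula's value and
leaves both geometry arguments explicit rather than tuning to the printed
one. Either value supports the same scientific conclusion (depletion ≪ the
22 mM entrance concentration). Results are flagged invalid when Δc ≥ c₀.

**Permeation-driven accumulation.** Water permeating into the PDMS walls
(flux J over the wetted perimeter 2H + W; the floor is glass) drags a
non-permeating solute toward the dead end of an empty channel:

  W·H·D c′ = (J/ρ)(2H + W)(L − x) c,

giving c(x) = c₀ exp(L²/2σ²) exp(−(L−x)²/2σ²) with accumulation length
σ = √((ρD/J)·WH/(2H+W)), independent of L. For BSA (D = 70 μm²/s,
J = 7×10⁻⁶ kg/m²s, ρ = 1000 kg/m³ — the density is the obvious default,
not a published number) σ ≈ 57 μm, so dead-end enrichment is ≈1.5× at
50 μm, ≈5× at 100 μm and ≈500× at 200 μm, while a small molecule with
D = 700 μm²/s stays below 2× even at 200 μm.

**Numerical oracle.** Both ODEs are also solved by second-order finite
differences (Dirichlet entrance; ghost-node Neumann closure for the
screening model, one-sided second-order closure at the dead end for the
first-order accumulation balance; default 10⁴ points, sparse tridiagonal
solves). The oracle shares no code with the closed forms; tests verify
< 0.1% agreement over random parameter draws and the ≈4× error reduction
under grid halving expected of a second-order scheme.

## Growth-law fit and replicate statistics

The universal growth law V_b = ½V_i·2^((C+D)/T_d) is linear in log2 space,
so (V_i, C+D) come from unweighted OLS of log2 V_b on 1/T_d (weighting is
exposed as a future option; the fitting procedure of the source analysis is
not stated, and on noiseless data the log-linear route coincides with
direct nonlinear least squares, which the tests check). Standard errors
propagate from the OLS covariance by the delta method:
se(V_i) = V_i ln2 · se(intercept). Noiseless round trips are exact to
10⁻⁹; with 3% noise and n = 30 the mean recovered parameters over 100
seeds are within 2% of truth. The mean-one lognormal noise convention
biases log2 V_b by −σ²/(2 ln 2) ≈ 3×10⁻⁴, negligible at these levels.

Replicate summaries follow the replicate-averaging rule: the grand mean and
s.e.m. are computed from the per-replicate means (sd/√n_rep), never from
pooled single cells, so unequal cell counts per replicate do not reweight
anything; a single replicate yields a flagged undefined s.e.m. Group
comparisons use Welch's unequal-variance t-test with Welch–Satterthwaite
degrees of freedom (more reliable than Student's t at unequal n);
correlations and straight-line fits use Pearson R with OLS. No
multiple-testing correction is applied, matching the source analysis.

## Mechanics

A cell jammed against the channel walls behaves on pressure release like a
compressed elastic rod. Treating the load-bearing envelope as a thin
cylindrical shell (diameter d, wall thickness t, Young's modulus E) under
uniform axial strain ε, the axial force is F = E·ε·π·d·t. The source
discussion states the inputs (E = 50–150 MPa, t = 4 nm, d = 0.8 μm,
ε = 0.25) and the resulting 0.1–0.4 μN but not the formula; the thin-shell
axial-load expression is adopted as a reconstruction because it reproduces
both printed endpoints (0.126 and 0.377 μN), assuming a pure cylinder wall
(no cap contribution) and strain referred to the relaxed post-release
length. The linear friction model fits T_d against channel length (excess
doubling time ∝ opposing friction force ∝ L) and extrapolates the
friction-free doubling time at L = 0.

## Pipeline, determinism and problem sizes

`run_pipeline` (and `mmgrowth run-all`) executes simulate → measure →
summarize → fit → transport → mechanics into a run directory containing
16-bit TIFF scenes, ground-truth and measurement CSVs, fit and report
JSONs, the resolved YAML config and a log. Every random stream derives
from the single pipeline seed, so identical config + seed gives
byte-identical CSV/JSON outputs; floats are serialized to 9 significant
digits. Default problem sizes — three replicate scenes of ten cells,
30-sample growth-law datasets, 100-seed recovery simulations, 10⁴-point
oracle grids — keep a full run near one second and the entire test suite
near ten, while leaving every estimate's Monte-Carlo error well inside the
asserted tolerances.

## Known limitations

- The measurement stage handles single frames of well-separated,
  rod-shaped cells; no lineage tracking, division detection,
  phase-contrast segmentation, or deformed-cell shape models.
- The diffraction offset is diameter-dependent at the few-hundredths-of-a-
  micrometre level; per-population calibration is required for accuracy
  claims tighter than ~0.03 μm on individual cells.
- Transport models are steady-state and 1D; no time dependence,
  multi-species competition, or BSA precipitation kinetics.
- The screening model treats the colony as a continuum absorber; discrete
  cell positions are not modelled.
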