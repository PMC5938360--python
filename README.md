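# mmgrowth

What limits bacterial growth in the dead-end channels of a mother machine?
`mmgrowth` packages the quantitative analyses needed to answer that for
*E. coli* in narrow (≈0.9 × 1.15 μm) PDMS channels: sub-pixel cell
dimensioning from fluorescence images, closed-form 1D transport models for
nutrient shielding and permeation-driven solute accumulation, fitting of
the universal growth law, and an elastic thin-shell estimate of the force
that stalls growth when cells jam against the channel walls. It is aimed
at microbial physiologists and microfluidics users who want these analyses
as tested, reusable building blocks.

Because no raw time-lapse data is publicly deposited for this system, the
package includes a first-class synthetic-data generator: spherocylindrical
cells of known length *L*_c and outer diameter *W*_c rendered into
channels, blurred by a Gaussian PSF and corrupted with shot and read
noise, plus (birth volume, doubling time) datasets drawn from the growth
law. Every downstream stage is validated against this ground truth.

## The models at the core

**Cell geometry.** Each rod cell is a spherocylinder, so its volume is

    V_c = (π/6) W_c³ + (π/4) W_c² (L_c − W_c).

Length is the greatest Feret diameter of the segmented mask (zero crossing
of Laplacian + second directional derivative, one erosion + dilation);
width is the smallest Gaussian width fitted to intensity profiles scanned
in small angular steps about the perpendicular to the cell axis, plus a
0.04 μm diffraction correction (calibratable) and a 0.04 μm envelope
correction.

**Nutrient screening.** Cells between the channel entrance and the mother
cell absorb nutrients; with first-order uptake k_abs the concentration
obeys (WH − πR_c²) D c″ = 2πR_c k_abs c, giving

    c(x) = c₀ cosh((x−L)/λ) / cosh(L/λ),
    λ = sqrt((WH − πR_c²) D / (2π R_c k_abs)),

and the mother-cell doubling time T_d = T_d,min + (T_d,liquid −
T_d,min)·cosh(L/λ). For saturated (kinetically limited) uptake the drop is
instead quadratic: Δc = L² I_max / (2(WH − πR_c²) L_c D).

**Solute accumulation.** Water permeating into PDMS (flux J) concentrates
non-permeating solutes at the dead end of an empty channel:

    c(x) = c₀ exp(L²/2σ²) exp(−(L−x)²/2σ²),
    σ = sqrt((ρ D / J) · WH / (2H + W)).

**Growth law.** V_b = ½ V_i · 2^((C+D)/T_d), fitted by least squares of
log2 V_b on 1/T_d; replicate statistics use the s.e.m. over replicate
means, Welch's t-test, and Pearson R with straight-line fits.

**Stall force.** A compressed cell behaves as an elastic rod; the axial
force carried by a thin cylindrical envelope of thickness t at strain ε is
F = E·ε·π·d·t.

## Worked example

```python
import numpy as np
from mmgrowth import synthetic, measure, growthlaw, transport, mechanics

# render a ten-cell scene at the study scale and measure it back
spec = synthetic.typical_scene(rng_seed=1, n_cells=10)
image, truth = synthetic.render_scene(spec)
offset = measure.calibrate_diffraction_offset(0.78)
config = measure.MeasurementConfig(diffraction_offset=offset)
table = measure.measure_scene(image, config, spec.pixel_size)
print(f"calibrated diffraction offset: {offset:.3f} um")
print(f"{len(table)} cells; mean L = {table.length_um.mean():.2f} um, "
      f"mean W = {table.width_outer_um.mean():.2f} um, "
      f"mean V = {table.volume_um3.mean():.2f} um^3")

# growth-law fit on a synthetic dataset (V_i = 0.79 um^3, C+D = 103 min)
samples = synthetic.generate_growth_law_dataset(0.79, 103.0, n=30, rng_seed=1)
fit = growthlaw.fit_growth_law([s.birth_volume for s in samples],
                               [s.doubling_time for s in samples])
print(f"V_i = {fit.v_i:.2f} +/- {fit.v_i_se:.2f} um^3, "
      f"C+D = {fit.cd_period:.0f} +/- {fit.cd_period_se:.0f} min")

# BSA accumulation in a 100 um channel, and the stall-force range
geom = transport.ChannelGeometry(width=0.9, height=1.15, length=100.0)
perm = transport.PermeationParams(water_flux=7e-6, diffusion=70.0)
sigma = transport.accumulation_length(geom, perm)
print(f"sigma = {sigma:.1f} um; 100 um dead-end fold = "
      f"{transport.dead_end_fold_increase(geom, perm):.1f}x")
for E in (50.0, 150.0):
    f = mechanics.stall_force(mechanics.ShellMechanics(E))
    print(f"stall force at E = {E:.0f} MPa: {f:.2f} uN")
```

Output:

```
calibrated diffraction offset: 0.037 um
10 cells; mean L = 2.14 um, mean W = 0.77 um, mean V = 0.88 um^3
V_i = 0.80 +/- 0.02 um^3, C+D = 101 +/- 5 min
sigma = 56.9 um; 100 um dead-end fold = 4.7x
stall force at E = 50 MPa: 0.13 uN
stall force at E = 150 MPa: 0.38 uN
```

Reading the numbers: the measurement stage recovers the generator's cell
scale (2.12 × 0.78 μm) to within a pixel in length and a few hundredths of
a micrometre in width; the growth-law fit recovers the generating
parameters within their standard errors from 30 noisy points; σ ≈ 57 μm
means BSA builds up ~5-fold at the dead end of a 100 μm channel (and
~500-fold at 200 μm) while small molecules barely accumulate; and the
0.13–0.38 μN range is the elastic estimate of the force at which envelope
growth stalls.

## Command line

A thin CLI wraps the same functions:

```sh
mmgrowth run-all --seed 3 --out runs/demo     # simulate → measure → fit → reports
mmgrowth mechanics                            # stall-force JSON
mmgrowth transport --out runs/transport      # profiles CSV + JSON sidecar
mmgrowth fit --out fit.json                  # growth-law fit report
```

Runs are driven by a validated YAML config (see `mmgrowth.config`); the
resolved config is written beside the outputs and identical config + seed
reproduces outputs byte-for-byte.

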