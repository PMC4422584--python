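# vibrostim

Analysis toolkit for localized substrate-vibration mechanostimulation
experiments: a glass probe, driven by an impact-triggered cantilever rig,
vibrates a bead-embedded polyacrylamide gel under a cell while a FRET
calcium biosensor reports the response, and an orbital-shaker assay scores
how well the cells adhere. `vibrostim` implements the complete
post-experimental analysis for this kind of setup, plus a ground-truthed
synthetic-data generator so every estimator can be validated without the
original (undeposited) microscopy recordings.

It is written for experimentalists and image-analysis people who need to

* measure substrate deformation from high-speed bead videos,
* model the vibration rig's resonant frequencies,
* quantify ratiometric calcium responses, and
* score adhesion with the peripheral-annulus attachment ratio.

## The quantities at the core

**Substrate deformation.** Bead displacement fields u(x, y) are estimated by
normalized cross-correlation block matching between a resting reference
frame and a displaced frame, with a coarse predictor pass, iterative
window-deformation refinement and fractional-NCC subpixel localization.
Strain uses only the two normal gradients, by finite differences (central
3-point stencils inside, one-sided 2-point at boundaries):

    Ex = dux/dx,  Ey = duy/dy,  E = sqrt(Ex^2 + Ey^2)

The vibration frequency comes from the mean interval between per-period
peaks of the near-probe displacement series, with a periodogram cross-check.

**Rig model.** The arm and the probe rod are Euler-Bernoulli cantilevers:

    f1 = (lambda1^2 / 2 pi) sqrt(E I / (rho A L^4)),   lambda1 = 1.8751

and a Rayleigh estimate `f = (1/2 pi) sqrt((3 E I / L^3) / (m_tip + (33/140)
rho A L))` captures how a probe mass at the free end lowers the frequency.

**Calcium response.** In a 50-px circular ROI near the stimulation site,
after per-frame background subtraction, the YPet/ECFP ratio time course
gives

    RelDiff = (maxRatio - basalRatio) / basalRatio

with basalRatio the mean ratio before stimulation and maxRatio the maximum
at or after it.

**Adhesion.** Cells are counted only in the annulus from the gel edge to
200 µm inward (shear is strongest at the periphery of an orbitally shaken
dish). Each post-shaking screenshot yields an attachment ratio
`AttRatio = C_after / mean(C_before)`.

**Statistics.** Pooled-variance two-tailed Student's t-tests; per-experiment-
day normalization of treatment responses by same-day controls; and the
normal-tail probability that a day-normalized response exceeds 100%.

## Worked example

```python
import numpy as np
from vibrostim import beam
from vibrostim.synthetic import BeadSimConfig, FretSimConfig, \
    generate_bead_stack, generate_fret_stack
from vibrostim.deformation import estimate_displacement, compute_strain, \
    max_timecourse, estimate_frequency
from vibrostim.fret import ratio_timecourse

print(f"arm first mode: {beam.first_mode_frequency(beam.stimulation_arm()):.0f} Hz")
print(f"rod first mode: {beam.first_mode_frequency(beam.probe_rod()):.0f} Hz")

cfg = BeadSimConfig()                       # 207 Hz, 8.8 um amplitude defaults
sim = generate_bead_stack(cfg)
vf = estimate_displacement(sim.frames[0], sim.frames[1], cfg.pixel_size_um)
sf = compute_strain(vf)
print(f"peak frame: max |u| = {vf.max_displacement_um():.2f} um, "
      f"max E = {sf.max_strain():.3f}")

tc = max_timecourse(sim.truth, sim.times_ms, probe_xy_um=cfg.probe_xy_um)
est = estimate_frequency(tc)
print(f"vibration frequency: {est.frequency_hz:.1f} Hz "
      f"from {est.n_peaks} per-period peaks")

fret_cfg = FretSimConfig()
fret_sim = generate_fret_stack(fret_cfg)
rtc = ratio_timecourse(fret_sim.donor, fret_sim.acceptor, fret_cfg.roi,
                       fret_sim.times_s, fret_sim.stim_index)
print(f"FRET: basalRatio = {rtc.basal_ratio:.3f}, maxRatio = {rtc.max_ratio:.3f}, "
      f"RelDiff = {rtc.rel_diff:.3f}")
```

prints

```
arm first mode: 1113 Hz
rod first mode: 221 Hz
peak frame: max |u| = 5.26 um, max E = 0.186
vibration frequency: 205.9 Hz from 8 per-period peaks
FRET: basalRatio = 1.300, maxRatio = 1.625, RelDiff = 0.250
```

The two beam frequencies round to the rig's nominal 1,100 Hz and 220 Hz.
The displacement/strain line describes the estimator's view of the peak
deformation frame over the nodes it can measure reliably (the most extreme
near-probe ring is flagged measurement-limited; the configured field itself
peaks near 50% strain there). The 205.9 Hz estimate reflects the 1 ms frame
quantization of a 4.83 ms vibration period, and the recovered RelDiff of
0.250 matches the configured calcium transient exactly to three decimals.

A `vibrostim` command-line interface wraps the same functionality
(`vibrostim simulate ...`, `vibrostim displacement ...`, `vibrostim
beam-freq ...`, `vibrostim fret-ratio ...`, `vibrostim adhesion-score ...`,
`vibrostim report ...`); see `vibrostim --help`.

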