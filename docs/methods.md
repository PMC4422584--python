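# Methods

This note documents the models, estimators and numerical choices behind
`vibrostim`, and what the synthetic-data validation does and does not show.

## The experimental setting being modelled

A glass micro-probe (~35 µm tip), carried by an aluminum rod on an aluminum
arm, rests on a polyacrylamide gel with 1 µm fluorescent beads embedded in a
single focal layer. An impact mechanism excites a damped vertical vibration
(~207 Hz observed) that locally deforms the gel; a high-speed camera records
the beads at 1,000 frames/s. Cells on the gel carry a Cameleon FRET calcium
biosensor imaged as donor/acceptor (ECFP/YPet) channel pairs at 30 s
intervals before and 5 s intervals after stimulation. Adhesion is assayed by
counting cells in the peripheral 200 µm annulus of the circular gel before
and after orbital shaking, where shear stress is highest.

## Synthetic bead stacks (`synthetic.BeadSimConfig`)

The generator renders beads as 2-D Gaussian spots (sigma = bead radius / 2
in pixels, standing in for diffraction blur at 40x) displaced by

    u(p, t) = A0 · exp(-r/lambda) · exp(-t/tau) · s(2 pi f t) · r_hat(p)

with r the distance from the probe contact point and r_hat the outward
radial direction. The temporal cycle s is a *half-sine* by default: the
probe pulls the gel away from rest once per cycle and releases it, so the
displacement magnitude peaks once per period — matching how per-period peak
frames are identified from the beads nearest the probe. (A signed-sine mode
exists for generality; its magnitude peaks at twice the frequency.)

A purely radial exponential field has a hoop strain u/r that diverges at
the probe point. The physical resolution is occlusion: the probe tip
shadows the gel directly beneath it, so no beads are rendered within
`occlusion_radius_um` (default 12 µm) and ground-truth nodes there are
flagged invalid. With A0 = 8.8 µm, lambda = 40 µm, tau = 50 ms, f = 207 Hz
and 1 ms frames, the analytic strain of the configured field then peaks at
~0.50 over the visible region at the realized frame times — jointly
consistent with the characterized stimulation (max displacement ~8.8 µm,
max strain ~50%, frequency ~207 Hz, decay well within 180 ms). These
defaults were fixed analytically from the configured field, not fitted to
any estimator output.

Bead surface density is a free parameter (the physical dilution is not
informative); the default of 1,200 beads on a 102 µm field (~0.11 µm^-2,
3-4 beads per interrogation block) is typical of traction-microscopy-style
imaging. Generation rejects configurations in which more than
`max_overlap_fraction` of beads touch a neighbour, since displacement
estimation is then ill-posed. Camera noise is additive Gaussian (read-noise
regime); FRET frames instead use Poisson-plus-offset (photon-limited
regime). All generators are bit-reproducible for a fixed seed.

The ground-truth displacement fields are sampled on exactly the grid the
estimator reports on (shared `matching_grid`), and a closed-form strain
(`analytic_strain`) provides the independent derivative oracle.

## Displacement estimation (`deformation.estimate_displacement`)

Normalized cross-correlation block matching (16 px blocks on an 8 px grid),
organized as:

1. **Pre-smoothing** (Gaussian, sigma 1 px): sub-pixel bead spots
   decorrelate under the slightest within-block shear; a mild common blur
   keeps the correlation peak intact without biasing its position.
2. **Coarse predictor**: 48 px blocks over the full search radius, median
   filtered. Individual beads look alike, so an unguided fine search locks
   onto the wrong bead at large displacements; the predictor removes that
   ambiguity.
3. **Iterative window deformation** (3 iterations): the displaced frame is
   warped back by the current field estimate and the residual re-matched
   with an 8 px search. This removes the systematic bias translation-only
   matching suffers where the field varies across a block. Corrections are
   lightly smoothed before application, and the warp field itself is
   smoothed (sigma 0.8 nodes): node-scale wiggle in the warp cannot be
   cancelled by block residuals (blocks average it away), so it must not
   enter the warp at all. Outliers deviating more than 5 px from the local
   median are substituted during warping (universal outlier substitution);
   the threshold must exceed max-strain x grid-step, or genuine gradients
   get clamped.
4. **Fractional-NCC subpixel localization** (final iteration): 3-point
   interpolation of the integer correlation surface is unreliable on sparse
   bead patterns (errors up to ~0.4 px), whereas the continuous NCC maximum
   sits exactly at the true alignment; per-axis parabolic steps on
   actually-evaluated fractional correlations reach ~0.01 px.

Validity flags: textureless blocks, correlation peaks below
`min_correlation` (0.6), refinement pegged at its search border, local-
median outliers, and nodes whose local gradient times the half-block
exceeds ~1.5 px (about the blurred bead-image radius) — beyond that the
pattern deforms too much within one block for a translation fit, a known
limit of correlation PIV. On the default simulation this leaves ~80% of
nodes valid with ~0.07 px RMSE against ground truth (well under the 0.3 px
target), at the cost of not reporting the most extreme near-probe ring.
Pixel size is a required input with no default: the original camera
calibration is not recorded, and silently assuming one would corrupt every
micrometre quantity downstream.

## Strain (`deformation.compute_strain`)

Only the two normal gradients enter (no shear terms, matching how the
total strain map is defined for this assay): central differences
`(u[i+1] - u[i-1]) / 2Δ` at interior nodes, one-sided `(u[1] - u[0]) / Δ`
at boundaries — `np.gradient(edge_order=1)` implements exactly this
scheme, and a hand-rolled loop oracle verifies it in the tests. Strain
validity is the displacement validity eroded by one node (a conservative
stencil rule). Exact for affine fields; agrees with the closed-form
derivative of the synthetic field to <1% of the field maximum at 0.5 µm
spacing (the 1/r hoop terms near the probe, not the decay length, set the
accuracy-limiting scale).

## Deformation time course and frequency

Per-frame maxima of |u| and E are taken over valid nodes. Per-period peak
frames are local maxima of the near-probe series (nodes within 30 µm of
the contact point), standing in for the unobservable probe motion. The
frequency estimate is 1 / (mean inter-peak interval); a periodogram of the
mean-removed maximum-displacement series is reported as a cross-check only,
since 40 ms records give ~25 Hz spectral resolution while inter-peak timing
resolves a 4.83 ms period to a few percent at 1 ms sampling. Recovery
suites run at the time-series level (damped half-sine plus measurement
noise, 150-250 Hz, 20 seeds each, median relative error < 3%); one deeper
test exercises the full image pipeline at a reduced geometry (144 px field,
25 frames) to keep the default suite fast, and recovers 207 Hz within 5%.

## Cantilever model (`beam`)

Euler-Bernoulli clamped-free first mode with lambda1 = 1.87510407;
rectangular sections use I = w h^3 / 12 with the *bending-direction*
thickness h, circular sections I = pi r^4 / 4. Standard aluminum constants
(E = 69 GPa, rho = 2700 kg/m^3) reproduce both printed rig frequencies from
the printed dimensions — 16.7 x 1.25 x 3.8 cm arm: 1113 Hz (~1,100), 8 cm x
1 mm-radius rod: 221 Hz (~220). The 3.8 cm dimension must be the bending
thickness (vertical vibration); the alternative assignment gives ~370 Hz.
The alloy actually used is unrecorded; these constants are documented as
the ones consistent with the printed outputs. The tip-mass effect uses the
Rayleigh single-degree-of-freedom estimate with the classical 33/140
effective-mass fraction (within 1.5% of the exact mode at zero mass,
strictly decreasing in the tip mass), which is why any probe mass lowers
the rod below 220 Hz.

## FRET quantification (`fret`)

Background is estimated per frame and per channel from the same cell-free
region (lamp drift differs between channels) and subtracted with clipping
at zero; whether the original procedure clipped is unrecorded, so the clip
is a documented choice here. ROI membership is pixel centers within
diameter/2 of the ROI center. basalRatio averages *all* pre-stimulus
frames with no trimming; maxRatio maximizes at/after the stimulation
index; RelDiff may be negative. Frame times are explicit throughout — the
acquisition cadence changes at stimulation — and are never assumed uniform.

The synthetic FRET generator adds diffuse background light everywhere
(including under the cell), so background subtraction is exact in
expectation, and normalizes the transient so the ROI-averaged true RelDiff
equals the configured value exactly; estimator bias is then measurable
directly (< 0.005 at default noise, against a 0.02 budget, for configured
responses 0-0.5).

## Adhesion scoring (`adhesion`)

Peripheral membership is inclusive at exactly the band width ("up to
200 µm" read as a closed interval; the boundary has measure zero in
practice). Screenshots are square fields of view whose outer edge touches
the gel rim at random angles; a count is cells ∩ field ∩ annulus. The
shaking protocol (3 x 10 s at ~220 rpm) is summarized by a logistic
detachment-probability profile in distance from the edge — no fluid
mechanics is modelled, only the one stated qualitative fact that shear is
stronger at the periphery; baseline 0.02 and edge 0.17 defaults put the
well-adhering regime near the 83% attachment ratio scale. Cell detection
from images is out of scope: inputs are centroid tables, as counts were
taken manually in the assay this reproduces. The statistic is called
attachment ratio throughout; the source protocol labels the same formula
DetRatio — they are one quantity, C_after / mean(C_before).

## Statistics (`stats`)

"Student's t-test" is implemented as the pooled-variance (equal-variance)
two-sample test, not Welch, since that is what the name denotes; degenerate
zero-variance inputs return p = 1 (equal means) or p = 0 (unequal) by
contract. Day-normalized responses are 100 x treatment mean / control mean
per day; the across-day spread is the sample SD over day-level values
(undefined, reported as absent, for a single day). The tail probability
above 100% treats the quoted ±spread as a standard deviation — z = (100 -
80)/4 = 5 reproduces the 3e-7 regime, which the SEM interpretation would
not. Reports (summary table, pairwise p-value matrix, SEM bar chart) are
byte-deterministic for fixed inputs.

## What passing tests do and do not show

The generators emulate the *structure* of the real data — localized decaying
deformation, photon-limited ratio imaging, edge-weighted detachment — not
its full physics: no gel viscoelasticity or thickness dependence, no
optical PSF beyond Gaussian blur, no spectral bleed-through, no
out-of-plane bead motion, no cell segmentation. Passing recovery suites
therefore demonstrates that the estimators are unbiased and accurate under
the stated image formation models, at the stated noise levels; they cannot
certify performance on real microscopy with artifacts outside those models.
The deliberately measurement-limited flagging of high-shear interrogation
blocks means maximum-strain estimates from images are conservative; the
configured ~50% peak strain is verified against the analytic field, not
recovered from rendered images.

## Problem sizes

Default suite sizes — a 256 px / 41-frame bead stack shared across tests,
128-144 px reduced geometries for Monte-Carlo and pipeline sweeps, 25-40
seeds per MC estimate, 2,000 replicates for the type-I-error check — were
chosen so the statistical assertions have comfortable margins while the
whole suite runs in well under a minute on one core.
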