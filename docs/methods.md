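# Methods

This note documents the models and numerical choices behind `lv4dflow`: the
flow-component decomposition and kinetic energy, the preprocessing steps,
the repeatability statistics, and — at more length, because it is the part
with genuine design freedom — the synthetic phantom and what validating
against it does and does not demonstrate.

## Data model and conventions

A 4D-flow acquisition is held as a `(nx, ny, nz, n_frames, 3)` array of
velocity in cm/s with voxel spacing (mm), frame interval (ms) and VENC
(cm/s). The time axis is periodic: the acquisition covers exactly one
averaged cardiac cycle, so the last and first frames are consecutive and
all frame arithmetic is modulo `n_frames`. Internal units are mm, ms and
cm/s (1 cm/s = 0.01 mm/ms); conversions to SI happen only inside the
kinetic-energy formula. Voxel indices are 0-based; voxel centre `i` sits at
`origin + i·spacing`; a voxel contains the half-open box `centre ± s/2`
with a face point belonging to the lower-index voxel, so containment is
deterministic.

Velocity sampling is trilinear in space between voxel centres and linear in
time between the two bracketing frames (wrapped). Positions outside the
convex hull of voxel centres return zero velocity with an out-of-bounds
flag — the sampler is total and the pathline engine decides policy. Linear
temporal interpolation matches the information content of ~52 ms frames; no
spline option is offered.

## Pathline engine

One pathline is emitted per ED-mask voxel centre, in raster order (results
are reproducible run to run). Trajectories solve `dx/dt = v(x, t)` with
classical fixed-step RK4, default step `frame_interval/10` (5.2 ms at the
default timing); backward tracking integrates the same field with negative
steps, exploiting the closed temporal loop. The forward span runs to the
next ES, the backward span to the preceding ES; the two spans always sum to
one cycle. The integrator subdivides each requested interval into equal
steps so the final sample lands on the end time exactly. At this step size
RK4 error is far below the data's interpolation error: on a rigid rotation
(linear field, hence interpolation-exact) the radius drift per cycle is
below 0.01 mm, and forward-then-backward integration over a quarter cycle
returns to the seed within 10⁻⁶ mm.

Out-of-FOV policy: once a particle's position leaves the centre hull its
position is frozen and the track flagged; classification treats frozen
positions as outside the LV. Ejected blood legitimately exits the imaging
volume, so this is a modelling statement, not an error.

## Classification, QC and kinetic energy

A pathline's label depends only on its two ES endpoint positions: "inside"
means the flow voxel containing the endpoint is labelled inside the ES
mask (nearest-voxel lookup, no sub-voxel surface — honest to the mask
resolution). Intermediate excursions out of and back into the cavity are
deliberately ignored; only the ES snapshots matter. The four labels are
exhaustive and mutually exclusive, so component volumes always sum to the
seeded EDV to machine precision and ratios to 100%.

The QC rule compares inflow (direct + retained) against outflow (direct +
delayed): the relative difference is normalised by the mean of the two (the
source rule states "10% difference" without naming a denominator; the
symmetric mean is the standard choice) and datasets above 0.10 fail.

Kinetic energy uses `rho_blood = 1060 kg/m³` (configurable; a standard
literature value — acquisition protocols do not measure it). Per-component
curves are defined at every stored timestep over the full cycle: times
before ED come from the backward track, after ED from the forward track,
and both tracks store the identical seed-time sample at ED. Zero-volume
components report volume 0 and KE-per-ml as NaN rather than being dropped.

## Preprocessing

*Background offsets.* Eddy currents leave a spatially smooth, temporally
static spurious baseline. Static tissue is identified by thresholding the
temporal standard deviation of speed (default 2 cm/s) with a mean-speed
guard at twice the threshold; the fit then regresses the temporal mean
velocity of those voxels, per direction, on the 20 monomials `x^a y^b z^c`
(`a+b+c ≤ 3`) of world coordinates centred on the FOV midpoint and scaled
to [−1, 1] per axis (conditioning; coefficients are reported in that scaled
basis). A single spatial polynomial per direction is subtracted at all
frames: offsets are temporally static by physical origin, and per-frame
fits would only fit noise. Consequences worth knowing: the correction is a
projection (refitting the corrected field gives a null model to 10⁻⁹), and
temporal differences v(t₁)−v(t₂) are untouched. A pure variance threshold
will also admit genuinely slow-moving blood (near-stagnation regions); on
phantoms the known rest region can be passed explicitly.

*ED-mask resampling.* The ED segmentation, drawn on an anisotropic cine
grid, is resampled to the flow grid by nearest neighbour: a flow voxel is
inside when its centre falls in an inside cine voxel. This preserves
binarity and defines the seeding EDV as `count x voxel volume`. ES masks
are taken as already on the flow grid.

*Volumetric indices.* EDV and ESV are voxel counts times voxel volume;
SV = EDV − ESV, EF = 100·SV/EDV, CO = SV·HR/1000. ESV ≥ EDV raises — it
almost always means swapped masks.

## Repeatability statistics

For duplicate measurements the within-subject SD is `|x1 − x2|/√2` and the
subject CoV divides it by the pair mean (scale-free; undefined for
non-positive means). The group CoV is the root mean square of subject CoVs
— by the RMS–AM inequality it is at least their arithmetic mean.
Bland-Altman reports bias = mean(x2 − x1) and limits of agreement
bias ± 1.96·SD(d) with the n−1 sample SD. Paired mean differences are
reported with the observed-difference interval (the LoA) by default — the
construction whose width matches the spread of individual differences — and
a true CI of the mean (`SD/√n`) is available as an option. Mann-Whitney
comparisons use the exact U null distribution when `min(n) ≤ 8`,
`n₁+n₂ ≤ 20` and the pooled data are tie-free, otherwise the normal
approximation with tie and continuity corrections; the thresholds are fixed
for reproducibility (scipy provides both branches; tests cross-check the
exact branch against direct enumeration of group assignments).

## The synthetic phantom

The generator's job is a dataset whose per-voxel component label is *known
exactly*, at realistic acquisition geometry. Verifiability drives every
choice below; fluid-dynamical realism is secondary and its limits are
stated at the end.

**Geometry.** An elliptical-cylinder chamber (length 48 mm, section radii
16×14 mm, ≈ 1250 seeds) tilted obliquely to the grid (axis ≈ (0.72, 0.50,
0.48)) inside a smooth torso-like envelope that tapers the velocity to zero
over 6 mm; everything outside is static tissue (where injected polynomial
offsets and noise still apply). The oblique tilt stops the voxel lattice
from quantising the truth coarsely.

**Transport.** The velocity is separable along the chamber axis:
`u(ξ, ρ, t) = g(t) · U(ξ) · s(ρ) · e`, with `g` periodic and piecewise
linear between frames, `U(ξ) = u0(1 + d·q + c·q²)` a downward-opening
quadratic (`q` the scaled axial coordinate, `c = −0.18 < 0`) and
`s(ρ) = 1 + 0.45(1 − 2ρ²)` a zero-area-mean jet (fast core, slow wall).
Because `U` vanishes at two stagnation points bracketing the chamber, every
trajectory is bounded, and the flow map is closed-form:
`ξ(t) = H⁻¹(H(ξ₀) + s·τ(t))` with `H = ∫dξ/U` a log ratio and
`τ = ∫g dt`. Truth labels are therefore exact evaluations, not integrations.

**Hitting the requested fractions.** The four label regions are laid out
along the axis (a slab of direct flow at *both* chamber ends — legitimate,
since direct flow is "resident at neither ES" — so that every ES-window
edge has seeded blood on both sides at both ES times). For a separable
field, demanding one ES window whose backward image and forward preimage
are the two resident intervals reduces to one condition on the shape of
`H`; the linear tilt `d` is solved for it (symmetric layouts need `d = 0`).
The pseudo-time split between systole and diastole is sized so each
half-cycle transports blood by roughly a quarter chamber length — both
physiological-looking and important numerically: endpoint displacements
then vary by several voxels across each classification cut (via the jet),
dithering the ES-mask voxel lattice instead of shifting all seeds
coherently. A damped fixed-point loop finally adjusts the continuum cuts
until the voxel-seeded truth fractions match the request (the voxelised
lookup and the jet's second-order averaging shift cuts by fractions of a
voxel; the loop absorbs both). The report `discretisation_error` states the
residual gap, typically ≤ 0.4 percentage points. Patterns with
`|retained − delayed|` beyond ≈ 4.5 points of EDV have no realisation in
this family and raise; pure-direct and pure-residual patterns use dedicated
degenerate constructions.

**Noise and offsets.** Gaussian noise of configurable sd is added
independently per voxel, frame and direction (the phase-difference noise
model; no Rician magnitude component), then velocities are clipped at VENC
with a clip count reported (zero at default settings). Background offsets
are injected as scaled-basis cubic coefficients, exactly the
representation the correction fits, so recovery tests have a sharp target.
All randomness flows from one integer seed; datasets are bit-reproducible.

**Scan pairs.** `make_scan_pair` builds same-subject repeats. Rescan pairs
share the anatomy and flow program and vary only the noise realisation and
a sub-voxel rigid repositioning of the anatomy in the FOV (re-voxelising
masks and truth, as repositioning does in practice). Interval pairs
additionally perturb the flow program: component fractions are jittered
(Gaussian, sd 3 points of EDV — the magnitude implied by reported interval
variability of the ratios once technique error is removed — with the
retained/delayed difference kept inside the generator's feasible range;
physiologically the two are coupled, since delayed ejection is largely the
previous cycle's retained inflow and cavity volume is conserved) and the
cycle timing is rescaled by a heart-rate-like factor (sd 7%). The
simulated-study layer (`lv4dflow.study`) runs cohorts of such pairs through
the full pipeline with seed-paired designs: an interval pair reuses its
subject's rescan noise and repositioning, so the design comparison
isolates added physiological variability. Its default technique-noise
level (1.5 cm/s) is chosen so simulated scan-rescan CoVs of the component
ratios land in the few-percent range reported for repeat acquisitions in
vivo; the phantom's peak speeds are a factor of a few below peak
intracardiac velocities, and per-voxel velocity noise scales with them.

**The brute-force oracle.** `oracle_fractions` integrates `dense_factor³`
sub-seeds per ED voxel with RK4 at a finer step directly on the analytic
velocity function — no grid interpolation — and classifies them against the
same voxelised ES mask. It shares nothing with the pipeline's sampling
path, so agreement (≤ ~0.5 points at default settings) checks grid
interpolation, integration and seeding density at once.

**What phantom validation does not show.** The phantom's trajectories are
straight lines along the chamber axis: there is no swirl, no through-plane
shear, and no blood outside the chamber section, so noise-driven *radial*
diffusion of endpoints past the ES section has no compensating inward flux
— the residual volume reads low by ~2–3 points of EDV at 3 cm/s noise.
Real LV flow has neighbouring blood on all sides of the cavity surface and
transports at higher speeds; the phantom's noise-recovery figures are
conservative in that respect. The phantom's ejection fraction (~36% with
the padded ES section) and cavity volumes are not physiological and are
not meant to be; the volumetric-index formulas are verified separately
against standard worked values. Passing these tests demonstrates the
correctness of the analysis chain, not the physiology of any cohort.

## Problem sizes

Default validation runs use the (48, 36, 36)-voxel phantom (~1250 seeds,
200 RK4 steps per pathline), five noise realisations for recovery bias,
8 sub-seeds per voxel at a quarter step for the oracle, and 14 subjects
per design for the simulated repeatability study; each piece completes in
seconds to about a minute on one CPU.

## Known limitations

Velocity aliasing unwrap, Maxwell-term and gradient-nonlinearity
corrections are out of scope (only the polynomial offset model is
provided). The ES segmentation must already be on the flow grid.
Adaptive step-size control and stochastic pathline ensembles are not
implemented; the fixed-step RK4 is accuracy-dominant over the data's
interpolation error at the default step. The transport family cannot
realise strongly asymmetric retained/delayed patterns (see above), and
`identify_static_tissue` will admit slow-flowing blood under a pure
variance threshold.
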