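# Methods

This note documents the models behind each pipeline, the synthetic data
that exercises them, the numerical choices, and what passing tests do
and do not establish.

## Scope and data model

All image analysis operates on `ImageStack` objects: 4-D arrays indexed
(channel, z, y, x) with physical pixel size and z-step carried as
metadata. Every size rule (minimum punctum area, shift distance,
densities) is stated in micrometres and converted at the point of use;
nothing is hard-coded in pixels. Arrays are 0-based and y increases
downward. Cell and ROI outlines are supplied (from annotation tables or
generator truth); automated segmentation of microglia or spines is
deliberately out of scope — the pipelines quantify, they do not trace.

## Engulfment scoring

A microglia in a single analyzed z-plane is *engulfment-positive* when
the triple intersection PSD-95 ∩ CD68 ∩ cell mask contains at least one
8-connected region of ≥ `min_pixels` (default 3) pixels. The area
metric is 100 × (kept overlap area)/(cell area). Pairwise
colocalization (e.g. GFP/Iba1) and CD68 reactivity are the same
construction with one signal channel; reactivity applies no minimum
size (it is a plain area ratio).

Binarization supports fixed, percentile and Otsu thresholds. For any
group comparison the caller pins one fixed threshold across the whole
batch, reproducing the same-settings-between-groups constraint;
per-stack Otsu is available for exploratory single images. A constant
image under Otsu yields an empty mask with a warning rather than an
arbitrary split.

**Pixel-shift null.** Each stained channel is translated by a fixed
physical distance (default 12 µm, i.e. 44 px at 0.27 µm/px) along one
of {+x, −x, +y, −y} drawn independently and uniformly per channel, and
the triple score is recomputed against the unmoved cell masks.
Translation is toroidal so total signal is conserved; a crop/zero-fill
mode exists behind a flag. Edge handling is a genuine design choice —
wrap-around was picked because it preserves signal density, which is
what the chance-overlap rate depends on. The null is repeated
(default 100 rounds) to give a distribution rather than a single
shifted value; a single round is the degenerate case.

**Depth and layers.** Cortical depth is the soma's distance from the
pia (in the generator, the y = 0 edge). The depth–engulfment
correlation uses engulfment-positive cells at depth ≤ 300 µm only;
Pearson r with the regression slope and its 95% CI are reported, and a
zero-variance response is flagged degenerate instead of fabricating a
coefficient. Layer density divides cell counts by per-layer tissue
volume with L1 = [0, 120] µm (closed at 120) and L2/3 = (120, 300] µm.

## Spine typing

Inclusion: a candidate protrusion must extend ≥ 3 px beyond the shaft,
measured as the maximum Euclidean distance of its pixels from the shaft
mask (distance transform); candidates with no pixel within a small
attachment radius of the shaft are rejected as detached. TIB is the
mean intensity of the protrusion ROI at its brightest focal plane
(argmax over z of the ROI mean — the plane rule stated qualitatively in
the field is made deterministic this way) divided by the mean intensity
of the adjacent shaft at that same plane. TIB is invariant to global
intensity scaling, undefined (flagged) when the shaft mean is zero.

Classification uses the 25th/75th percentiles (linear interpolation
between order statistics — stable at the reference sizes of a few dozen
values) of a *control-condition* TIB sample; cutoffs never depend on
the sample being classified, so there is no leakage between arms. The
reference is per-analysis and configurable because pooling across
timepoints versus per-timepoint references is a genuinely open choice.

## Expansion microscopy

The per-cell linear scaling factor is the mean of the long- and
short-axis post/pre ratios of the soma measured on max-intensity
projections; lengths divide by the factor, areas by its square. Factors
below 1 (shrinkage) are returned but flagged by callers.

Lysosome rule, applied within a cell mask: candidate CD68 regions come
from an Otsu threshold over the cell's voxels (a relative threshold, so
detection is invariant to global intensity rescaling); a candidate is a
lysosome iff its area at the brightest plane is ≥ 9 px (0.216 µm² at
0.155 µm/px; configurable 7–9), its mean intensity is ≥ 2× the local
background, and it appears in ≥ 2 consecutive z-planes (implemented as
3-D connectivity spanning adjacent planes). Local background is the
mean over an annulus of width 2× the region-equivalent radius,
excluding all candidate pixels — the annulus geometry is our
concretization of "a region surrounding each ROI".

PSD-95 positivity needs all of: ROI mean ≥ background mean + 2 SD; a
connected supra-threshold PSD punctum of ≥ 4 px (0.0961 µm²) inside the
ROI at ≥ 2× background; and PSD/CD68 z-profiles peaking within one
plane of each other. On pure-noise PSD channels the 2-SD rule bounds
the false-positive rate by the corresponding normal tail, which the
Monte-Carlo test checks.

## Electrophysiology

**Detection.** The template is a difference of exponentials
(defaults 0.5/5 ms for EPSC-like events, configurable; the field's
tools leave these as user parameters). At every position a scale and
offset are least-squares fitted; the detection criterion is
scale/SE(scale), the template-fit t-statistic. We deliberately do not
threshold scale/residual-SD: that statistic equals amplitude/noise, so
at amplitude CV 0.3 and SNR 5 a 3.5 threshold structurally misses the
small-amplitude tail (~20% of events) no matter how the threshold is
tuned, while the t-statistic uses the full matched-filter power of the
~250-sample template. Detection is sequential left-to-right with
fit-and-subtract: the best local alignment (argmax within one template
peak-offset, then hill-climb) is accepted, its fitted template
subtracted, and the criterion refreshed locally — this resolves events
sitting on another event's decay and prevents decay tails from
retriggering. A small absolute noise floor (1e-3 pA) keeps the
statistic finite on noiseless traces. Default threshold 5.0: on the
generator's study conditions this gives recall ≥ 0.95, precision
≥ 0.97 and zero false positives on noise-only traces.

**Kinetics.** Amplitude is peak minus the median of the 10 ms before
onset; on noisy traces the argmax peak picking carries the usual
positive bias (the maximum of ~2.6 ms of noise), which cancels in
ratio and distribution comparisons. Rise is the interpolated 10→90%
crossing time; decay τ is a bounded single-exponential fit starting
0.2 τ after the peak so the residual rise component does not inflate it
(bias ≤ 1% on ideal events). Events whose decay is cut off by the trace
edge are flagged and excluded from τ statistics.

**Passive properties.** From the −5 mV seal-test response:
Rs = ΔV/I₀ with I₀ the t = 0 amplitude *extrapolated* from the fitted
exponential (the sampled peak is attenuated at 10 kHz when τ ≈ 1 ms),
R_total = ΔV/I_ss, Rm = R_total − Rs, and Cm = τ/(Rs‖Rm). Units work
out as mV/pA = GΩ and ms/MΩ = nF. Noiseless recovery is within 2%,
and a 50-sweep average at 5 pA noise within 5%.

**F–I.** An AP is an upward 0 mV crossing with preceding slope
≥ 2 mV/ms (the definition is ours; robust on the simulated sweeps).
Rheobase is the smallest step with ≥ 1 AP; an all-subthreshold family
reports it as missing. Input sweep order is irrelevant (sorted by step).

## Behavior

A frame is in a zone iff the centroid is inside the zone geometry,
boundary inclusive; each frame contributes one frame interval of dwell.
Overlapping zones are a configuration error. Zone extents are config
(cup discs of radius 10 cm, 15 cm corner squares by default) because
the source protocols never state them; all group comparisons must use
one config. DI, latency, first choice and grooming summaries are the
plain formulas; kinematics smooths the path with a 5-frame boxcar
before centered differences because raw tracking jitter otherwise sets
the maximum velocity. Bregma interpolation is linear between counted
sections with extrapolation refused.

## Morphometry and expression

Sholl counts are computed analytically: a straight segment's distance
to the soma is convex in its parameter, so it crosses a circle of
radius r 0, 1, or 2 times (endpoints straddling, or both outside with
the interior minimum inside); re-entrant branches therefore count once
per crossing, matching the tracing-plugin convention. The test suite
pins this to a dense-sampling oracle (0.1 µm steps, sign changes of
‖p − soma‖ − r) on 50 random trees. Branch order starts at 1 at the
soma and increments after each branch point. Soma diameter is the
pixel-projection extent (plus one pixel width) along the direction
perpendicular to a user-supplied apical axis. ΔΔCt combines the three
reference genes by the arithmetic mean of their Ct values (equivalent
to a geometric mean of expression); a geometric-Ct option exists since
the combination rule is not standardized. Ct values outside 5–40 are
rejected; samples missing any reference are excluded with a log entry.

## Synthetic data: what it emulates and what it does not

Scenes are anti-aliased ellipsoids/capsules rasterized at pixel
centers, Gaussian-blurred (PSF stand-in, σ 0.25 µm) with additive
Gaussian noise (SD 4 at signal amplitude 100). Defaults encode the
study conditions: 280 × 350 µm ROIs at 0.27 µm/px with 14 microglia
(somata 8–16 µm with 3–6 straight processes, ~3 lysosomes of radius
0.9–1.5 µm); an engulfment rate of 0.3 with a 2.3-fold arm for
comparisons; free PSD-95 puncta at 0.005/µm² in the analyzed plane
(puncta resolvable in a single confocal section, not the full neuropil
synapse density); spine images at 0.12 µm/px with a tri-modal
(25/50/25) volume mixture and brightness ∝ volume; ExM pairs at
0.155 µm/px post-expansion; mPSC trains at 10 kHz with Poisson timing
and truncated-normal amplitudes (CV 0.3); trajectories as Metropolis
random walks whose zone weights set dwell preferences. Every generator
is a pure function of its parameters and seed (single `default_rng`
stream, bit-identical reruns).

Not emulated: Poisson shot noise and detector gain, realistic microglial
ramification, gel distortion fields, tracking identity errors, serial
correlation in Ct replicates. Passing tests therefore demonstrate that
the *quantification rules* are implemented correctly and recover known
ground truth under controlled conditions — not that the pipelines are
robust to every artifact of real acquisitions.

## Problem sizes

The cohort analyses and tests run at sizes chosen to keep a full run on
one CPU comfortable while preserving the statistical structure: 26
ROIs/arm at full 280 × 350 µm for the pixel-shift bound (2 shift rounds
in the test, 10 in the acceptance script), 26 reduced-field ROIs/arm
for rate-ratio recovery, 20 segments/arm × ~24 spines for the class
comparisons, 60 s traces for detection quality, 20 walkers/arm for the
DI cohort, and 50 random trees for the Sholl oracle.
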