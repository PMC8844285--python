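# Methods

## Displacement and overlap metrics

The displacement index (MDI) is the mean absolute per-pixel difference of
two frames over the ROI.  It is symmetric, zero on identical frames,
positively homogeneous, and obeys a triangle-type bound — the property
tests assert exactly these.  The frame-to-frame variant is divided by each
pair's own time interval (which reduces to multiplication by the frame rate
for uniform sampling, the default 2.47 frames/s) and timestamped at pair
midpoints.  Endpoint MDI uses single nearest frames at the requested pre-
and post-train times rather than multi-frame averages: the measure is
defined on two time instants, and averaging would entangle it with motion
inside the averaging window.

Raw intensities are promoted to float64 on stack construction so integer
camera data cannot wrap around under subtraction.

**Gain correction.**  TIRF cameras adjust gain automatically during long
recordings, multiplying whole frames by slowly varying factors.  Each frame
is divided by the mean intensity of a background rectangle whose filaments
are never affected by the field (default: the upper-right 15 % × 15 % corner
of the frame, configurable).  After correction the background mean is
exactly 1 per frame, so corrected MDI is invariant to arbitrary positive
per-frame gains in the noise-free limit (asserted to 1e-10 relative).

**Thresholding (modified Otsu).**  The binarisation threshold is the
histogram bin edge maximising the between-class variance of the ROI
histogram (256 bins), computed after discarding the brightest 0.1 % of
pixels.  The exclusion is the "modification": it immunises the histogram
range against hot pixels and saturated specks which would otherwise stretch
the binning.  Ties break toward the lower edge; a constant ROI returns the
constant with a degenerate flag.  Setting the exclusion quantile to zero
recovers the textbook method, which the tests pin against both an
exhaustive variance scan and scikit-image's implementation.

**MOR threshold policy.**  By default one threshold is computed on the t₁
frame and reused for t₂, so the ratio measures area change rather than
re-thresholding artefacts; a per-frame mode exists.  Supra-threshold
counting uses strict inequality.  `run_analysis` reports MOR both per train
(t₁ immediately before each train) and cumulatively (t₁ before the first
train); accumulation builds over successive trains, so the cumulative
variant is the more sensitive indicator and is the one the qualitative
tests assert on.

## Force balance and calibration

Linear MT charge density ρ_MT = N·Q_TUB·e/L_TUB with defaults N = 13,
Q_TUB = 23 e (magnitude; the sign only sets the migration direction, a
separate polarity flag), L_TUB = 8 nm, giving 5.988 × 10⁻⁹ C/m.  The
detachment balance E·ρ_MT > D_AB·F_AB uses F_AB = 50 pN per antibody.
Voltage maps to field linearly through the 300 V ↔ 25 kV/cm anchor; the
spatial profile is a plateau across the 60 µm electrode gap with
exponential decay (default length 50 µm, of the order of the channel
height) beyond either electrode edge — a parametric stand-in adequate for
qualitative accumulation, not a field solution.

Pulse trains are ideal rectangles: 100 pulses of 5 µs at 10 Hz by default
(10 s treatment, 500 µs total on-time, duty 5 × 10⁻⁵).  The spectral
density is that of a single ideal rectangular pulse, V₀·τ·|sinc(fτ)|;
measured pulse shapes are not modelled.  The Debye length uses the standard
electrolyte closed form with ionic strength as an explicit input (a helper
computes I = ½ Σ cᵢzᵢ² from ion tables); physical constants are CODATA 2018
at full precision.

## Synthetic TIRF generator

What it emulates: a dense network of straight filaments with midpoints
uniform over the field of view; axial orientations from a halved von Mises
draw about the flow axis (κ = 2 by default — "partially oriented"; κ = 0 is
isotropic); lognormal lengths (mean 8 µm, CV 0.4 — an assumption, the
assay's true length distribution being unknown); per-filament anchor counts
Poisson(mean·L) so anchoring density varies statistically as a surface-
density-limited binding process would.  Detachment is all-or-none per
filament at its midpoint field; partial peeling is not modelled.

Dynamics per frame interval: bound filaments detach when the local balance
is exceeded (permanent — effects are cumulative across trains); mobile
filaments drift toward the anode at mobility × E_local during pulse-on time
only (default mobility 800 µm·s⁻¹ per kV/cm, chosen so a mobile filament
crosses ~10 µm during one 100-pulse train at 300 V); mobile filaments
arrest where the profile drops below 3 kV/cm; without the crowding agent,
mobile filaments leave the imaging plane with probability 0.15 per frame.
A consequence of constant mobility is that within-train MDI-speed curves
stay elevated for the whole train rather than decaying as the fastest
filaments clear the ROI early; the voltage ordering of the peaks is
reproduced, the within-train decay shape is not.

Rendering: filaments are sampled at half-pixel steps and deposited
bilinearly (so co-located filaments add and total deposited intensity is
length-proportional and position-independent up to frame-edge clipping),
convolved with a Gaussian PSF (σ = 0.30 µm), added to a planar background
(150 counts plus a gentle gradient), then Poisson shot noise, Gaussian read
noise (σ = 6), multiplication by the frame gain and quantisation to the
camera bit depth (16 by default; 0.217 µm/px).  Gain drift is a seeded
lognormal random walk, σ = 1 %/frame — strong enough that uncorrected MDI
on a static scene is visibly biased.  Filament brightness defaults to
12 000 counts/µm: bright, EMCCD-scale filaments whose displacement signal
is clearly resolved above the shot-noise floor, as in the recordings the
generator emulates.

Default sweep geometry: 60 × 40 µm field of view with the anode-side
electrode edge at 47 % of the width, so the plateau covers the left part of
the frame, filaments sweep rightward into the decaying field, and the
upper-right background corner sits far enough beyond the edge that its
filaments never detach even at 300 V.  The recovery studies use 0.25
filaments/µm² (600 filaments) — a deliberately thinned network that keeps a
20-seed Monte-Carlo inexpensive while preserving the statistical structure;
real networks are one to two orders denser, which only strengthens the
population statistics.

What the generator does *not* emulate: filament bending and Brownian
motion, kinesin gliding, evanescent-field depth effects, electrochemistry,
or inter-filament depletion bundling.  Passing recovery tests therefore
show that the analysis chain is correct and sensitive under the modelled
statistics, not that it is robust to every artefact of real recordings.

## Threshold-voltage estimation

Per train, the peak MDI speed inside the train window is compared against
the noise floor (median pre-pulse MDI speed); the estimated threshold is
the lowest voltage whose peak exceeds k × floor, with k = 3 by default.
Because the MDI averages ~5 × 10⁴ ROI pixels, its relative noise is well
below 1 %: sub-threshold peaks land within ~1 % of the floor, so k = 3
leaves two orders of magnitude of false-positive margin while detecting
genuine displacement of even a modest mobile fraction.  Endpoint frames are
chosen with 0.5 s margins around each train (last frame ≥ 0.5 s before the
start, first ≥ 0.5 s after the end) to avoid mid-train frames at 2.47
frames/s; the margins are configurable since the original frame selection
convention is not fixed.

## Numerical choices and degenerate inputs

Zero-amplitude protocols are legal (sham treatments); zero background mean
raises a degenerate-background error; an all-sub-threshold t₂ frame raises
an undefined-MOR error; single-frame stacks cannot yield a speed series;
overlapping pulse trains are rejected.  Rasterisation, PSF and gain
pipelines are exactly linear before quantisation, and the simulator can
skip quantisation where exact mass bookkeeping is being tested.  All
randomness flows from explicit integer seeds through `numpy` Generators;
identical seeds give bit-identical stacks and ground truth.

## Problem sizes

Default study sizes: 600 filaments per scene, 235 frames per sweep
(95 s at 2.47 frames/s, 276 × 184 px), 20 seeds per Monte-Carlo — about
two seconds per simulated-plus-analysed sweep, chosen as the smallest
configuration that leaves the recovery statistics comfortably stable.
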