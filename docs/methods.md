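# Methods

This note documents the models, conventions and numerical choices behind
`wakekin`. The package implements the computational chain of a study
design in which undulatory swimmers (juvenile rainbow trout) hold
station in the wake of a 3×5 cylinder array: wake generation and
characterization, spacing optimization, midline kinematics, and the
factorial statistics. Flow-solver output and tracked video are replaced
by synthetic generators with recorded ground truth so the whole chain is
testable.

## Synthetic vortex streets

A wake is the superposition of a uniform convection flow `Uc` and a
train of finite-core vortices with the Lamb–Oseen swirl profile

    u_theta(r) = Γ / (2πr) · (1 − exp(−r²/r_c²)),

which is bounded on the grid (the velocity tends to zero at the center,
unlike a point vortex) and costs one parameter, the core radius `r_c`.
Each vortex is released on a seeding line one diameter downstream of the
most-downstream cylinder column (the coordinate origin; x positive
downstream, y positive to the left of the flow) and advected at `Uc`.

* **staggered** mode releases one vortex every half period `1/(2f)`,
  alternating sign and cross-stream side, so same-sign vortices sit one
  street spacing `a = Uc/f` apart — the alternating (Kármán) pattern.
  The cross-stream velocity at a centerline probe then oscillates at the
  shedding frequency `f`.
* **symmetric_parallel** mode releases a mirror-image pair (±Γ at ±y)
  once per period. By symmetry the pair's cross-stream velocities cancel
  exactly on the centerline, which is the physically meaningful signature
  of a parallel street: no coherent centerline flapping.

Circulation may decay downstream with an e-folding length, and i.i.d.
Gaussian noise of a chosen standard deviation is added per sample to
both components (measurement/turbulence surrogate). Vortices are deleted
two spacings past the grid, where their induced velocity on the grid is
negligible. Release indices extend to negative times, so the street
already fills the grid at `t = 0` and the field is statistically
stationary from the first sample; no spin-up needs to be discarded.

The generator is a *kinematic* stand-in: there is no Navier–Stokes
solving, no boundary layer, no vortex interaction or turbulence model.
Its job is controllable spectral structure (shedding line, spatial
wavelength, coherence) — not fluid-dynamic fidelity. Superposed
Lamb–Oseen vortices are analytically divergence-free, and the discrete
divergence of generated fields stays below 1% of `|u|/dx` more than four
core radii from every core (verified in the test suite).

## Wake descriptors

**Spectra.** Signals are mean-subtracted and transformed with a plain
FFT — no window, no detrending — to a one-sided amplitude spectrum; the
zero-frequency bin is excluded from both the peak search and the
L-kurtosis sample. The dominant frequency is the maximal bin, ties
breaking toward lower frequency. A series whose spectrum is entirely
below 1e−12 of the signal scale has "no dominant frequency". The
instantaneous wake wavelength is one over the dominant *spatial*
frequency of `u_y` along a streamwise line.

**Strouhal chain.** `St = f·D/U`. In a tank of width `W`, the nominal
speed `Uf` is blockage-corrected by continuity across the section
obstructed by one cylinder diameter, `U = W·Uf/(W − D)`. This reading of
the correction is adopted deliberately: with `W = 0.25 m`,
`D = 0.019 m`, `Uf = 0.74 m/s` it gives `U = 0.8009 m/s`, and
`f = St·U/D` then reproduces the study's two predicted shedding
frequencies (8.85 and 9.69 Hz for St = 0.21 and 0.23) exactly to two
decimals. `W` and `D` remain explicit arguments so alternative readings
can be evaluated. The default kinematic viscosity is water at 15 °C,
`ν = 1.139e−6 m²/s`, configurable.

**Periodicity.** The periodicity score is the L-kurtosis
`τ₄ = l₄ / l₂` of the spectrum's amplitude values, computed with
Hosking's unbiased probability-weighted-moment estimators
(`b_r = n⁻¹ Σᵢ C(i−1,r)/C(n−1,r)·x₍ᵢ₎`; `l₁ = b₀`, `l₂ = 2b₁ − b₀`,
`l₃ = 6b₂ − 6b₁ + b₀`, `l₄ = 20b₃ − 30b₂ + 12b₁ − b₀`). The sample is
the multiset of all retained bin amplitudes, unweighted — the most
literal reading of "L-kurtosis of the spectrum". A single-line spectrum
is an extremely heavy-tailed sample (τ₄ near 1); broadband noise gives
Rayleigh-like amplitudes (τ₄ ≈ 0.1). L-moment ratios are scale-free, so
the score is invariant under positive scaling of the probe series. When
`l₂` falls below 1e−12 of the amplitude scale the score is undefined
(NaN) rather than 0/0. The default probe sits on the centerline two
array pitches (pitch = gap + diameter) downstream of the last cylinder
column; the probe is configurable because published descriptions of
such scores rarely state the probe location.

**TKE.** Fluctuations are taken per grid node about that node's time
mean; TKE is the time mean of `½(u_x′² + u_y′²)` averaged over the
requested region. Over whole periods a uniform fluctuation `a·sin(ωt)`
gives exactly `a²/4`.

## Spacing optimization

The design variables are the gap ratios `Lx/D` and `Ly/D`. Tandem
cylinder gap ratios are classified into bluff-body (< 0.7),
transitional ([0.7, 1.1]), reattachment ((1.1, 1.8]) and co-shedding
(> 1.8) regimes; the boundary assignments (closed on the transitional
side) are this module's convention. Feasibility for the search means
*both* coordinates co-shedding, applied as a screen before surrogate
fitting — the study kept only co-shedding designs from its initial
sample, without stating a finer rule.

The search is one-shot surrogate-based optimization: a Latin-hypercube
sample (each axis stratified exactly once per design; reproducible by
seed), objective evaluation per design, an interpolating thin-plate
radial-basis surface, and maximization over a dense 201×201 grid of the
feasible box followed by a local L-BFGS-B polish. Grid ties resolve
toward the smallest `Lx/D`, then smallest `Ly/D`. Optional infill
rounds (re-evaluate the optimum, refit, ≤ 5 rounds) are provided but
off by default, matching a single surrogate build. Undefined objectives
(degenerate flow, flat spectrum) are penalized to the worst observed
finite value minus one spread, so they can never win yet keep the
surface interpolable; the penalty needs the batch context, so it is
applied in the batch evaluator while the single-point operation reports
NaN. Failed evaluations are excluded from the surrogate entirely.

**Benchmark.** End-to-end recovery is exercised on two benchmarks: an
analytic paraboloid peaking at (2.1, 3.0), and a synthetic wake
benchmark in which each design is rendered as a staggered street whose
circulation falls off with design-space distance from the peak
(Gaussian, e-folding 0.4) under fixed noise, so signal-to-noise — and
hence τ₄ — peaks at the known optimum. The benchmark's SNR regime is
chosen to keep τ₄ on the steep part of its response (away from its
high-SNR saturation plateau): a saturated objective is flat at the top
and no interpolating surrogate can localize its maximum against
evaluation noise. Each evaluation uses 32 shedding periods on a
48×17 grid, making the τ₄ sampling noise (sd ≈ 0.01) small against the
peak's curvature.

## Synthetic swimmer

The midline is a head-to-tail traveling wave in the streamwise body
coordinate,

    y(x, t) = L · A(x/ℓx) · sin(2π(f·t − x/(λL))),

with amplitude envelope `A` in body lengths (default linear from the
snout value, 0.02 L, to the tail value, 0.15 L), tail-beat frequency
`f` and body wavelength `λ` in body lengths. Because the body is
inextensible, the streamwise extent `ℓx` is re-solved each frame
(bracketed root find, tolerance 1e−9 L) so the midline arc length stays
equal to `L` within 0.1%. The wave is parameterized in `x` rather than
in arc length deliberately: prescribing the lateral offset as a
function of arc length is geometrically impossible once
`2πA/λ > 1` (the curve would need `|dy| > |dℓ|`), which the intended
test ranges (A up to 0.2 L, λ down to 0.8 L) exceed. With the x-wave,
the imposed `λ` is recovered by the crest-tracking estimator to ~2% in
the noise-free case, the residual coming from the arc-length/streamwise
distinction.

The whole body may translate laterally at the tail-beat frequency
(center-of-mass recoil, default amplitude 0); the ground-truth lateral
amplitude at arc fraction `s` combines the body wave and the recoil as
two same-frequency sinusoids with phase lag `2πs/λ`. Fourteen landmarks
are emitted in the pose-export layout: snout and tail tip at the
midline endpoints and six left/right outline points at arc fractions
i/7, offset along the local normal by a fixed fusiform half-width
profile (maximum 0.12 L at 0.25 L from the snout, tapering to zero at
the tail; monotone-cubic interpolation of a small table). The true body
shape of the study animals is unknown and irrelevant here — only
midline recovery matters, and left/right midpoints recover the midline
exactly by construction. Gaussian jitter (default study condition
0.002 L) and random dropout are applied per point per frame; dropped
points receive a likelihood drawn below 0.1 and a gross position error,
emulating tracking failures. All randomness flows from one integer seed
per call; identical seeds give bit-identical tables.

An envelope exceeding 0.5 L is refused (the outline would
self-intersect), as is a recording shorter than four tail-beat periods.

## Kinematics extraction

**QC.** A landmark point is bad if its likelihood is below 0.9 or it
jumps more than 0.2 body lengths away from *both* temporal neighbors
(an isolated outlier; a genuine fast motion moves both neighbors with
it). Bad runs of ≤ 5 frames bracketed by good frames are linearly
interpolated; longer runs are left missing and those frames are dropped
downstream with a report. If more than 10% of all points are bad the
table is flagged `needs_manual_review` — processing continues and the
flag propagates to every output row, mirroring a workflow in which such
recordings are re-digitized by hand. The body length used by the jump
rule is the median snout→midpoints→tail polyline length.

**Midline.** Per frame, left/right outline points are paired into
midpoints; a cubic smoothing spline is fit through snout, the six
midpoints and tail tip, parameterized by chord length, with residual
budget `m·(0.003·L)²` (the 0.003 L default reflects the assumed
landmark residual after QC; it is a configuration key, since the
upstream smoothing of such digitization toolchains is typically
unpublished). The curve is resampled to N = 20 points at equal arc
length. Frames whose midpoint sequence is non-monotonic along the
snout–tail chord (crossed left/right pairs) are dropped and reported.
The recording's body length is the median per-frame arc length.

**Mean swimming axis.** The lateral reference is the principal axis of
the COM-point trajectory *when that trajectory actually extends*
(≥ 0.5 body lengths along its principal axis); otherwise — the usual
case for station-holding fish, whose COM barely travels — the axis
falls back to the time-mean snout→tail direction. A pure-PCA rule fails
exactly in the station-holding regime this package targets: for a body
oscillating laterally in place, the leading principal axis of the COM
path *is* the lateral direction. All outputs are invariant under global
translation, rotation and uniform scaling of the landmark coordinates
because every threshold is expressed relative to body length or to the
series' own dispersion.

**Tail-beat frequency.** Lateral excursion extrema are located with a
prominence threshold of 25% of the series' interquartile range,
alternation enforced (of two same-kind neighbors the more extreme
survives) and timing refined by local parabolic interpolation. The time
between a maximum and the next minimum is half a period; the frequency
is the inverse of twice the mean opposite-extremum interval — exact on
a pure sinusoid. Fewer than four alternating extrema is an
"insufficient beats" error. For amplitude extraction the excursion is
first smoothed with a Savitzky–Golay filter whose window is a quarter
of the estimated beat period (order 3, minimum 5 frames): wide enough
to suppress landmark jitter, short enough (< 1% attenuation) not to
bite into the oscillation itself, which is why the window adapts to a
first-pass frequency estimate rather than being fixed.

**Segmentation.** One beat spans two successive extremum intervals;
sequences are consecutive, non-overlapping windows of exactly four full
beats, trailing partial beats dropped. Sixteen complete beats therefore
yield exactly four sequences.

**Amplitudes.** At the snout (s = 0), the center of mass (s = the
per-fish COM fraction, default 0.35 with an `assumed` flag when not
measured) and the tail tip (s = 1), the amplitude within a sequence
window is half the distance between maxima and minima of the lateral
excursion, read as (mean of peak values − mean of trough values)/2.
Averaging over the window's extrema rather than taking the single
global max−min makes the estimator nearly unbiased under tracking
noise; with no detectable extrema (a straight steady swimmer) it falls
back to half the window's range, which is then appropriately tiny.

**Body wavelength.** Crests (local excursion maxima along the body) are
located each frame on a spline-refined profile (200 points), linked
across frames by nearest-position matching, and each track's phase
speed is the least-squares slope of arc-length position versus time.
Tracks must persist at least half a beat period, travel at least 0.1
body lengths tailward, and keep clear of the body ends (s ∈ [0.02,
0.98]). The wavelength is the track-length-weighted mean phase speed
divided by the tail-beat frequency. Standing-wave deformation produces
only stationary, short-lived tracks and correctly raises "wavelength
undetermined".

## Statistics

Responses are analyzed per sequence (sequences as replicates, no
fish-level random effect — matching the study design being emulated; a
per-fish averaging helper is provided for sensitivity checks). The
two-way fixed-effects ANOVA with interaction uses Type II sums of
squares, appropriate for the mild imbalance that QC-dropped sequences
introduce; the implementation is the standard OLS/anova machinery, and
the test suite checks it against an independent projection-based Type
II oracle to 1e−8 in F. Amplitude responses are log-transformed before
fitting (their synthetic errors are multiplicative, so logs are
normal); a global rescaling of amplitudes then shifts only the
intercept and changes no F or p.

The false-discovery-rate family is, by default, each ANOVA term across
the five response variables, adjusted by Benjamini–Hochberg; the
effective threshold `α·k/m` is reported alongside. The family
definition is a configuration choice (`pooled` adjusts all terms of
all responses together) because "FDR across the analyses" is genuinely
ambiguous. Post hoc comparisons use Tukey's HSD on the studentized
range, which reduces to Tukey–Kramer under unequal cell sizes; groups
with fewer than two observations are skipped and reported. The
one-sample comparison of tail-beat frequencies against a predicted
shedding frequency is a left-tailed t-test (alternative: the fish beat
slower than the wake sheds). Degenerate inputs are refused with
messages rather than returning NaN: zero-variance t-tests,
single-level factors, empty p-value families. Zero residual variance
with nonzero effects reports an underflow-safe minimal p rather than
zero; all-identical observations report F = 0, p = 1.

## Synthetic study design

`synthetic.study` replicates the experimental layout: 5 fish × 3
treatments (freestream, high-periodicity KVS array, low-periodicity PVS
array) × 3 speeds (22/48/74 cm/s), sixteen tail beats per combination
in four four-beat sequences, 100 frames/s, body length 7.4 cm. Cell
means encode the qualitative response pattern of station-holding trout
— tail-beat frequency rising with speed but less steeply behind
cylinders, snout and COM amplitudes rising with speed and behind
cylinders, tail amplitude largest in the KVS array, near-flat
wavelength — with a 4% between-fish multiplicative intercept and 7%
per-sequence noise (multiplicative for amplitudes). Two levels are
offered: direct draws of the per-sequence kinematics table, and full
swimmer specs per trial for exercising the landmark → midline →
kinematics chain.

What passing tests show — and what they do not: the synthetic data
share the *structure* of the real recordings (layout, noise character,
dropout, factorial design) but none of their hard parts: no occlusion
or shadowing, no fish leaving the zone of interest, no non-stationary
gaits (casting, entraining, burst-and-coast), no correlated tracking
error, and the synthetic wake has no vortex interaction or decay
physics. Green tests certify the computational chain recovers known
parameters under stated noise; they are silent on tracking quality and
flow fidelity of any particular real dataset.

## Problem sizes and determinism

Default analysis sizes: wake grids of 64×33 nodes sampled 24 times per
shedding period for 16 periods; 60-design searches with 201×201
surrogate grids; swimmer recordings of 2–4 s at 100 frames/s; study
statistics on 180 sequences; the null-calibration suite uses 2,000
ANOVA replicates of a 3×3 design with five observations per cell. These
sizes were chosen so every property is measured with comfortable margin
at desk scale. Every stochastic component takes one integer seed and is
bit-reproducible; the pipeline manifest (package version, seed, config
hash) suffices to regenerate every artifact.

## Known limitations

* The wake generator's vortices neither interact nor deform; decay is a
  prescribed envelope, not physics. Strouhal numbers measured on
  synthetic streets are imposed, not emergent.
* The dimensional "periodicity" (m²/s) sometimes quoted alongside
  L-kurtosis in the literature on this design has no stated definition
  that reconciles with a dimensionless τ₄; the package reports only the
  dimensionless score.
* The swimmer's amplitude envelope is reported against the streamwise
  body fraction; at interior points the arc-length fraction differs by
  up to a few percent at large amplitude, which is inside the stated
  recovery tolerances but visible in exacting comparisons.
* Crest tracking needs at least about two-thirds of a wavelength on the
  body and half a period of persistence; very long wavelengths
  (λ > ~1.5 L) on short recordings go "undetermined" rather than wrong.
* The statistics stage deliberately mirrors a sequences-as-replicates
  analysis; it does not model within-fish correlation.
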