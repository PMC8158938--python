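# Methods

This note documents the models, numerical choices and known limitations of
`echowall`. Everything quantitative stated here is computed by the test
suite or the examples; nothing is asserted that the code does not measure.

## Scene geometry

Six parametric wall textures are modelled in a 2D plane: flat, circular
convex, flat-with-aperture, concave parabolic (focus at the source),
crenelated (square-wave profile) and staircase. The source sits at the
origin with the wall in the `+x` half-plane; the receiver is 3.5 cm above
the source (the self-hearing geometry of an echolocator). The staircase is
defined in a vertical section; the solver is orientation-agnostic and the
plane is metadata only.

Default dimensions — lateral extent 2.0 m, thickness 0.3 m, circle radius
1.0 m, aperture width 0.3 m, crenel period 0.3 m and depth 0.15 m,
staircase 6 steps of 0.175 m rise and 0.28 m run — are plausible
architectural values, declared here and overridable through
`make_texture(..., overrides=...)`. The two study distances are 0.81 m
(echo overlaps the click) and 5.03 m (fully separated). A subtlety: for
the aperture wall the nearest solid point is the aperture rim at
`sqrt(d² + (w/2)²)`, not `d`; the rasterization tests account for this.

Rasterization classifies cell centers against the closed-form texture
profile. Lateral coordinates are constructed exactly sign-symmetric so
mirror-symmetric textures produce bit-identical mirror masks (floating
point accumulation would otherwise flip boundary cells).

## FDTD solver

Standard 2D staggered-grid leapfrog (pressure at cell centers, velocities
on faces). Rigid outer boundaries and rigid (100 % reflective) solid
cells: face velocities touching a solid cell are forced to zero. The
source is an initial Gaussian pressure distribution; by default its width
σ is set so the radiated spectrum is −20 dB re peak at 13 kHz
(σ ≈ 9 mm at 342 m/s). Whether the original study drove the source or
used an initial condition is not documented anywhere we could rely on;
the initial-condition form is this package's declared choice.

The nominal output rate (192 kHz) is far above the 2D CFL limit of a
1.3 mm grid, so the solver runs internally at the CFL-limited step —
snapped to an integer subdivision of the output rate — and decimates the
receiver trace with a polyphase anti-aliasing filter. Courant number 0.7
by default.

**Problem sizes.** The full-scale configuration (1.3 mm, 192 kHz) is
available but costs hours per response. The test suite and examples run
"desk scale": 10 mm spacing with a widened σ = 20 mm source for
arrival-time checks (a 9 mm source on a 10 mm grid is under-resolved and
disperses), and 5 mm with σ = 12 mm where spectra up to 12 kHz matter.
These choices keep each simulated response in the 0.5–20 s range.

**Component splitting.** Direct and reflected parts are separated by
subtracting an identical run without solids — exact under linearity, and
the only correct option at 0.81 m where click and echo overlap in time.
The study's analysis windows are applied afterwards: 6.0 ms (near) and
31.3 ms (far), which at the default sound speed of 342 m/s correspond to
propagation distances of 2.05 m and 10.72 m. That correspondence is also
why 342 m/s is the default. `first_reflection_time` marks the first
sample whose reflected magnitude exceeds −40 dB re the echo peak.

**Arrival metrology.** Arrival separations are measured at the
half-maximum point of each component's envelope leading edge (Hilbert
envelope, with the record tail cosine-tapered so an end-truncated echo
does not leak through the FFT-based analytic signal). Cross-correlation
lags are biased late by a few percent because the 2D cylindrical
impulse response carries a `1/sqrt(t² − r²/c²)`-type tail that grows with
distance; the leading edge tracks the geometric arrival to < 1 % at desk
scale. The −40 dB first-energy marker sits on the dispersive skirt and is
the less stable of the two, which is why the grid-refinement check uses
the half-max separation.

**Spectra.** Component spectra are unwindowed FFT magnitudes of segments
starting 0.05 ms before the direct peak (direct) and 3.85 ms / 20.6 ms
after it (reflected, near/far), both normalized to 0 dB at 1.5 kHz.

## Click surrogate

The original recorded palatal click is not redistributed, so the package
synthesizes a surrogate: `s(t) = env(t)·sin(2π·4100·t)` with a 0.8 ms
raised-cosine attack and a two-stage exponential decay that breaks at
−26 dB. The two decay constants are solved by bisection so that the
package's own duration estimator returns 3.7 ms at the −26 dBFS criterion
and 8.5 ms at −32 dBFS — the documented metrology of the study click.
Generation is at 44.1 kHz (the recording rate) with polyphase resampling
to 48 kHz. The envelope family is a declared surrogate; no claim is made
that the real click had this shape.

The estimator: envelope = |analytic signal|; onset = first crossing of
the 0.4 ms moving-averaged envelope above the threshold; offset = the
threshold crossing of a decaying exponential fitted to the post-peak
envelope (nonlinear least squares with relative-error weighting, which
keeps the tail from being swamped by the early decay). The 0.8 ms attack
makes the moving-average onset unbiased to within ~0.03 ms, so the raw
envelope-span and the estimator agree.

## Auralization

The direct RIR component is convolved with a mouth-to-ear transfer
function (OBTF) and the reflected component with a 0°-azimuth HRTF pair;
their sum is the oral-binaural room impulse response (OBRIR). Components
are kept separate inside the `OBRIR` object, which is what makes the
configuration transforms exact: `rdld_plus6` multiplies the reflected
part by precisely `10^(6/20)`, `reflections_only` zeroes the direct part.

Measured OBTF/HRTF sets are external inputs (loadable from paired WAV
files). The built-in fixture filters are synthetic: OBTF = 0.3 ms delay
at unity gain with a small seeded ripple; HRTF = 0.45 gain, 0.5 ms delay,
9 kHz low-pass head shadow, identical left/right (0° incidence). They
reproduce the one structural property the analysis relies on — the direct
path is louder than the echo path (RDLD < 0 dB on a flat-wall OBRIR).

**Loudness equalization.** The impulsive-loudness model used to equalize
the echo-only stimuli in the original experiment is not publicly
reproducible, so the metric is a pluggable interface. Default:
A-weighted sound exposure (energy); a Stevens-law option
(exposure^0.3, sone-like compressive growth) is included. The
package-defined part — equalize every echo to the loudest member's
loudness by gain bisection ("dichotomy"), gains ≥ 1, spread below a
relative tolerance — is metric-independent and is what the tests pin.

**Levels.** A-weighting is applied in the frequency domain with the exact
analog A-curve magnitude (bilinear IIR A-filters at 48 kHz err near
Nyquist; the IIR serves as an independent oracle in the tests, run
oversampled). Digital-full-scale ↔ SPL defaults to "full-scale sine =
94 dB SPL", configurable. One session-global gain maps the direct-only
reference stimulus to SEL 51 dB(A); echo-only stimuli are additionally
level-matched (rms) to their normal-case counterpart. Whether the
original calibration interacted per stimulus or per session is not
documented; the session-global choice is this package's declared
convention.

## SNQ features

SNQs are computed on the full binaural stimuli (channels processed
separately, then averaged). Because the direct part is identical across
textures within a configuration, SNQ1 automatically reduces to the echo
difference. Spectra are magnitude FFTs of the whole stimulus zero-padded
to a common power-of-two length per block (so SNQ3's bin spacing is
comparable across pairs), in dB, normalized at the 1.5 kHz bin,
restricted to 0.5–12 kHz. Band, scale and full-vs-echo-only signal choice
are not externally documented; all three are declared here and recorded
in the output metadata.

## ANN predictor

Exactly 2 tanh hidden units with bias, linear output, features
standardized on the training set. Training: full-batch gradient descent,
learning rate 0.05, initialization scale 0.1, max 5000 iterations —
declared choices where no external ones exist. The 15 ordered pairs
(i, j) train; the 15 reversed pairs (j, i) — identical SNQ features,
independent DF noise — test. Training returns the parameter state from
the iteration preceding the first test-MSE increase. With 15 training
points fits are seed-sensitive, so `train_restarts` reports the
median-test-MSE run across seeds. DF targets are used untransformed (the
output unit is linear).

## Listening-test statistics

Scoring: correct iff answered and the response matches the X assignment;
timeouts (30 s limit) are incorrect. DF = n_correct / n_trials for any
grouping; per-texture DFs average the 5 pairs containing the texture,
which reproduces the design's degrees of freedom (texture F(5,65),
distance F(1,13), configuration F(2,26) with 14 participants).

The three-way repeated-measures ANOVA is a complete sums-of-squares
decomposition of the balanced subject × texture × distance ×
configuration table; each within effect is tested against its
subject-interaction error term. Univariate uncorrected F tests are the
default (the decomposition is verified against `statsmodels.AnovaRM` in
the tests); `correction="gg"` adds per-effect Greenhouse–Geisser
epsilons (orthonormal-contrast covariance form) and adjusted p-values.
Effect sizes: partial η² = SS_eff/(SS_eff + SS_err) and
η² = SS_eff/SS_total. Post-hocs are Bonferroni-corrected paired t-tests
on per-subject marginal means; the exact error terms behind the
originally printed pairwise p-values are not fully documented, so these
are flagged approximate.

## Synthetic listeners

`P(correct) = 0.5 + (0.5 − lapse)·(1 − exp(−s·d))`: anchored at the 2AFC
guessing limit, saturating, with closed-form test values. The saturating
exponential was chosen over a probit link for those closed forms; both
behave the same for the suite's purposes. Discriminability `d` defaults
to the pair's SNQ2 scaled by the cohort mean (non-negative,
order-preserving) because spectral coloration is the dominant texture
cue; any SNQ combination can be supplied. Per-participant sensitivity is
log-normal (sd 0.3 — moderate between-subject spread); lapse rate 0.02
(attentive adults); timeout rate 0.005 (the observed rate of the study
procedure). Cohort defaults are the study design: 14 participants,
3 repetitions, 15 pairs × 2 distances × 3 configurations.

What the generator does *not* emulate: learning across sessions,
response-time structure beyond the timeout flag, lapses correlated with
difficulty, and any acoustic path from stimulus to decision other than
the scalar discriminability. Passing tests therefore show the analysis
chain is correct and sensitive at the study's trial volume — not that
human listeners behave like the link function.

## Degenerate inputs and tolerances

Zero-variance ANN features raise with the feature named; silent
waveforms are rejected by the equalizer and the duration estimator;
unbalanced ANOVA designs raise listing the missing cells; an OBRIR with
no echo becomes a flagged degenerate (silent) echo-only stimulus rather
than an error. Bisections (click calibration, loudness equalization) run
to relative tolerances of 1e-6/1e-4 with explicit bracket expansion and
iteration caps.

## Known limitations

- 2D acoustics: a point source in the plane is a line source in 3D, so
  echo levels are systematically stronger than a 3D scene would give.
- No perfectly-matched layers; domain truncation is handled by the
  analysis windows, so margins must keep edge reflections outside them.
- Fixed 0° head orientation; no click directivity; no room reverberation.
- Absolute per-texture echo levels depend on wall dimensions that are not
  machine-readable from the available drawings; only ordering and
  qualitative spectral properties (aperture high-frequency deficit,
  parabolic > circular echo level) are asserted at desk scale.
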