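# Methods

`saccvis` implements the computational chain of a psychophysics paradigm that
asks when rapidly moving stimuli stop being visibly *in motion*: stimuli that
traverse a finite distance at speeds comparable to saccadic eye movements are
perceived as jumping rather than moving, and the speed at which this happens
tracks the saccadic *main sequence*. The package covers four layers: stimulus
kinematics, an early-vision model that predicts visibility, psychometric and
signal-detection threshold analysis, and saccade kinematics extracted from eye
traces — plus synthetic-data generators that give every layer a known-truth
input.

## Stimulus kinematics

The main sequence is parameterised as

    D_sac(A) = 2.7 ms/dva · A + 23 ms        (saccade duration)
    v_p(A)   = c · A / D_sac(A),  c = 1.64   (peak velocity, dva/s)

A stimulus condition is an amplitude `A` (dva) plus a relative speed `v_rel`
(fraction of `v_p`); absolute speed, movement duration `D = A/v`, and relative
duration `D_rel = 1/(c·v_rel)` follow. Internal units are dva / ms / dva/s,
with explicit conversion wherever a formula mixes seconds and milliseconds.
Full precision is kept internally; rounding to one decimal happens only in
reporting (`condition_table(round_digits=1)`, the `condition-table` CLI
command), which is also where the embedded published grid is checked.

Time-varying ("saccadic") velocity profiles use a gamma kernel
`v(t) = α (t/β)^{γ−1} e^{−t/β}` with shape `γ = 4/(3.26·D + 0.77)²`
(D in seconds). The kernel has infinite support, so a truncation rule is
needed to speak of a movement *duration*: `gamma_velocity_profile` defines the
motion window as the leading interval containing 99.9% of the displacement,
scales `β` so that window equals `D`, and `α` so the displacement equals `A`.
Shapes ≤ 1 (durations beyond ~377 ms) lose the unimodal skewed form and are
rejected with a diagnostic. Whether the original stimuli held peak or mean
speed at `v_rel·v_p` is not decidable from the printed description; the
displacement/duration rule above is our documented choice and the truncation
mass is a parameter.

Trajectories are sampled at the display rate (1440 Hz, dt = 1000/1440 ms) on
a circular arc whose sagitta is 15% of the amplitude; "constant horizontal
velocity" is implemented as the along-chord coordinate being linear in time
with the orthogonal coordinate following the circle (arc-length speed
therefore varies by a few percent — the display constraint, not constant
arc-length speed, is what the stimulus specifies). Two layouts exist:
`centered` (500-ms presentation, motion centered, 100-ms linear contrast
ramps at the extremes) and `endpoints` (static endpoints of exactly
`endpoint_ms` per side at full contrast). Motion-absent twins share endpoint
samples bit-for-bit: a `gap` variant blanks the motion window; a
`contrast_jump` variant runs contrast through `1 − v(t)/max v` and steps the
position at the single zero-contrast sample.

## Early-vision model

The model is a deliberately minimal linear-filter + normalization account.
The Gabor is simplified to a Gaussian blob (σ_stim = 1/3 dva); no
orientation, motion-energy, or eccentricity-dependent filtering is modeled.
The chain is:

1. `R(x,y,t)`: contrast-weighted point deposits at the (drift-jittered)
   stimulus position, convolved with a spatial Gaussian (σ_RF = 0.15 dva)
   and a causal temporal gamma kernel (shape 1.6, scale 12.5 ms, latency
   40 ms, truncated at 99.9% mass, renormalized to unit mass). The spatial
   step uses the closed form `σ_eff = sqrt(σ_stim² + σ_RF²) ≈ 0.365 dva`.
   The temporal scale is printed unitless in the source material; we read it
   as milliseconds, which puts the kernel mean at 60 ms — physiologically
   sensible — and keep it configurable. The "modified" gamma is implemented
   as shift-by-latency + truncate + renormalize.
2. Naka-Rushton normalization `O = R²/(R² + C²)` with `C` = 30% of the
   maximum noise-free response over the condition set being run (two-pass;
   the value is cached in the run output so runs are comparable).
3. Spatial max readout `O(t) = max_xy O(x,y,t)` (first occurrence wins on
   ties), compared between the motion-present trajectory and its
   endpoints-only twin; evidence is Minkowski-pooled,
   `E = (Σ_t |ΔO|^1.5)^{1/1.5}`.
4. Reports: correct iff `N(E, σ_E = 4) > 0`; with probability λ = 0.02 the
   response is a uniform guess instead (the lapse convention is ours — only
   the existence of a lapse rate is specified).
5. Position decoding: coordinate mean weighted by `O/max O` times a Gaussian
   window (σ_I = 2 dva) centered on the output peak.

Noise: fixational drift is an Engbert-style self-avoiding lattice walk
(2-dva lattice, 101 sites, activation relaxation 0.001/step, quadratic
potential of steepness 1, 5-point smoothed output), applied as jitter to the
stimulus position (applying it to the lattice instead is equivalent up to
grid interpolation). Response noise is `N(0, R/8)` per cell, read as an SD
(a variance mode is available), drawn independently for the motion-present
and endpoints-only trajectories; negative noisy responses are rectified to
zero before normalization, which also licenses the fast path
`max_xy O = O(max_xy R⁺)` since the normalization is monotone on
non-negative responses.

The retinotopic grid per condition is the drift-jittered trajectory bounding
box plus a 4·σ_eff margin; the time axis is extended by the kernel length so
late responses are not clipped. Arrays are float32 (t, y, x); the temporal
convolution exploits the one-deposit-per-frame sparsity, and the full
pipeline is verified against a brute-force triple-loop oracle on a tiny grid
to 1e-9 in float64.

Simulated experiments fit decreasing Weibull psychometric functions
(guess 0.5, lapse 0.02 fixed) to proportion correct versus *linear* relative
speed per amplitude × endpoint cell; non-convergent cells are flagged NaN,
not raised. Reference resolution is dx = 0.05 dva / dt = 0.69 ms with 250
runs × 200 trials; the package's demo/test scale is dx = 0.1 dva, dt = 2 ms,
50 runs per condition, amplitudes {4, 8, 12} dva, endpoint durations
{0, 200} ms and a 5-level relative-speed grid {1/4, 1/2, 2/3, 1, 5/4} — at
that scale the two qualitative signatures hold: evidence decreases
monotonically with relative speed in every cell, and fitted relative-speed
thresholds vary far more across amplitudes at 0-ms endpoints (CoV ≈ 0.15)
than at 200-ms endpoints (CoV ≈ 0.05).

## Psychometric analysis

Performance versus a stimulus variable is fitted with a Gumbel (log-Weibull)
function on log10-transformed values,
`Ψ(x) = γ + (1−γ−λ)(1 − exp(−10^{β(x−θ)}))`, guess γ fixed at 0.5 for 2AFC;
variables where performance *falls* with the stimulus (speed, relative
duration) are sign-inverted on the log scale before fitting and reported
back on the original scale. At `x = θ` the curve has covered
`1 − e⁻¹ = 63.21%` of its range — 81.6% correct with no lapses. (One printed
variant of this identity carries a `(γ−λ)` factor where the general Gumbel
identity gives `(1−γ−λ)`; the two coincide at γ = 0.5 and we use the general
form.)

Fitting is binomial maximum likelihood with multi-start L-BFGS-B and
parametric-bootstrap percentile CIs. This deliberately replaces hierarchical
Bayesian MCMC estimation: shrinkage toward the group mean is therefore
absent, which mostly matters for poorly constrained observers; rank
correlations are used downstream exactly so that this difference is benign.
The lapse rate is either fixed or free within [0, 0.25] (the bound is our
choice), shared across conditions within an observer in the joint fit.
Thresholds outside the sampled range are flagged `extrapolated_`.

Threshold profiles over equally spaced design levels are decomposed with
orthonormal polynomial contrasts (5 amplitudes) or orthonormal Helmert
contrasts (4 endpoint durations); bootstrap draws propagate to per-term CIs.

Detection-task sensitivity is `d' = z(hit) − z(fa)` with 1/(2N) clipping of
extreme rates. Because visibility falls with speed, the d'-versus-speed fit
uses the decreasing Naka-Rushton branch `d'(v) = d_max·v50ⁿ/(vⁿ + v50ⁿ)`
(exponent 2 by default): the asymptote is approached at low speed and the
detection threshold is the speed at half the asymptote. Flat or unsaturated
data are flagged degenerate rather than raised.

The threshold–kinematics analysis pairs, per observer and motion direction,
a visibility threshold with a saccadic kinematic value under two matchings:
*retinal* (saccades in the opposite direction, whose retinal image motion
matches the stimulus) and *spatial* (same direction), compared by Spearman
rank correlation; a demeaned variant removes the across-observer mean per
direction × amplitude cell first, stripping main effects (e.g. the amplitude
dependence both variables share). Competing OLS regressions are compared via
`ΔBIC = BIC(retinal) − BIC(spatial)` and `BF = exp(−ΔBIC/2)`, so BF > 1
favors the retinal matching.

## Saccade analysis

Velocity is the central finite difference smoothed with a centered
five-sample moving average. Saccades are runs where the 2-D speed exceeds
the median speed by 5 median-based standard deviations
(`sqrt(median((s − median s)²))`, a deliberately robust, slightly
conservative spread estimate) for at least 8 ms; events separated by ≤ 10 ms
are merged afterwards (overshoot double-detections). The ordering matters:
applying the minimum duration *before* merging keeps isolated noise blips
from pooling into spurious events. The per-component elliptic threshold
variant common in microsaccade work is intentionally not used here.

Trial filters: saccadic gain within [0.5, 1.5] of the instructed amplitude,
peak velocity ≤ 800 dva/s, duration ≤ 100 ms, no pre-response saccade
> 1 dva, no missing data — each with a reason code. Fixation (perceptual)
trials reject on any saccade > 1 dva inside the stimulus window, blinks, or
skipped frames.

Main sequences are fitted per observer × direction:
`v_p = v0(1 − exp(−A/a0))` by nonlinear least squares with a grid of starts,
`D = d0 + c·A` by ordinary least squares. Mixed-effects estimation is
replaced by per-group fits plus aggregation. The pupil-to-eyeball
biophysical correction used with video eye-trackers is out of scope (its
governing equations are not part of this package's sources); synthetic
traces are generated directly at eyeball level so the downstream analysis
remains testable.

## Synthetic data

Generators return `(data, ground_truth)` pairs and define the package's test
conditions.

* **Psychometric observers**: binomial counts per condition from the Gumbel
  model with thresholds at `threshold_ratio · v_p(A)` — default ratio 0.53
  and duration-ratio ≈ 0.8, mirroring the human summary values as
  *demonstration defaults*, not reproduced results. Slope β = 6 on the
  −log10 speed scale (transition over ~±0.15 log units, a realistic
  steepness for this task), lapse 0.02, 120 trials per level as in the
  original per-cell counts. Direction-specific main sequences tie the
  threshold for motion direction d to the *opposite*-direction saccade, so
  retinal-direction specificity exists in the generative truth.
* **Eye traces**: sums of gamma-profile saccades plus optional smoothed
  drift and white measurement noise at 500/1000 Hz. A gamma profile cannot
  satisfy amplitude, duration *and* peak velocity simultaneously, so
  generated saccades fix displacement = A and peak velocity = v_p(A) exactly
  and choose the truncation mass that brings the peak-to-mean speed ratio
  closest to c = 1.64; realized durations then land within a few percent of
  D_sac(A) for 4–12 dva. Not emulated: pupil wobble, post-saccadic
  oscillations, blinks beyond simple validity gaps, tracker filtering — so
  detector performance on these traces bounds, but does not guarantee,
  performance on real recordings.
* **Detection trials**: hit/false-alarm counts from a decreasing
  Naka-Rushton d'(v) observer with an unbiased criterion
  (hit = Φ(d'/2), fa = Φ(−d'/2)).

## Reproducibility and numerics

All randomness flows from `numpy` `SeedSequence` roots with spawned child
streams per condition / run / noise source; identical seed + config give
identical outputs. Degenerate inputs are handled explicitly: all-zero
velocity profiles warn and return unit contrast, all-zero decoder frames
return NaN, perfect-separation psychometric data hit parameter bounds with a
flag, flat d' is flagged degenerate. Known limitations: the model omits
orientation/motion-selective and eccentricity-dependent filtering by design;
MLE fits do not shrink like hierarchical Bayesian fits; the Weibull cell
fits at the demo resolution are qualitative, not calibrated to human
thresholds.
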