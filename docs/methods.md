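# Methods

This note documents the models, estimators and numerical choices behind
`pupilspan`, and what its synthetic-data validation does and does not
establish about real recordings.

## The trial model and the synthetic cohort

Within a trial (3.2 s, 500 Hz), the generated pupil trace is

```
p(t) = b                                          t < L
       b − A · ½(1 − cos(π (t − L)/(P − L)))      L ≤ t ≤ P
       b − A + r (t − P)/1000                     t > P
```

with baseline `b` (mm), constriction latency `L` (ms), amplitude `A`
(mm), peak time `P` (ms) and dilation rate `r` (mm/s), plus additive
Gaussian noise (default SD 0.02 mm). The half-cosine pulse and linear
ramp are deliberate: the trace's minimum is exactly `b − A` at `P` and
its pre-stimulus slope exactly `r`, so every extracted measure has a
closed-form target and parameter-recovery tests are analytic. Gaze
fixates near 0° and executes one saccade with a raised-cosine velocity
profile; its peak velocity follows the main sequence
`Vp = 500·(1 − e^(−amp/15))` °/s, enough to exercise any
velocity-threshold detector. Blinks are runs of invalid samples with
±0.5 mm artifact spikes on the flanking samples, exercising both the
validity handling and the despike rule.

Cohort-level trends (the study conditions the generator emulates):
baseline declines linearly from ~7.5 mm at age 5 (≈ −0.031 mm/yr, the
lifespan miosis trend); the PRO dilation rate declines steeply to age 20
and slowly after; the ANTI−PRO dilation gap is `0.2·e^(−age/40)` mm/s
and the ANTI constriction is weaker by `0.06·e^(−age/40)` mm, both
non-negative and non-increasing with age; anti-saccade direction errors
are frequent in children (~30% at age 5), low in young adults and
elevated again in old age; SRT is U-shaped with ANTI ≈ PRO + 60 ms;
females run ~0.35 mm smaller than males before age 18 and equal after.
Between-trial parameter spread (baseline, amplitude, latency, peak,
rate, SRT jitter) is scaled by a single `param_jitter` factor so
parameter-level invariants can be tested exactly at zero jitter. Ages
are uniform over 5–93 unless a census list is supplied — the
original cohort's age histogram is not public, so no attempt is made to
imitate its non-uniform group sizes. Two blocks of 120 trials with
conditions and sides exactly balanced are the default; conditions are
reshuffled per block.

What this generator does **not** emulate: pupillary light-reflex gain
and its spectral content, carry-over of one trial's response into the
next (real IPAST responses outlast the 3.2 s trial), foreshortening of
pupil area with gaze angle, slow arousal drifts, and realistic blink
kinematics. Passing recovery tests therefore demonstrates correctness
of the *estimators* under the stated signal model, not robustness to
every artifact of real recordings.

The saccade-measure table is generated directly from a 12×4
common-factor model (task disengagement, visual transient, frontal
inhibition/voluntary generation, brainstem generation) and mapped
affinely to natural scales (percentages clipped to [0, 100], SRTs to
[90, 800] ms); clipping is kept improbable (>10 SD) so correlations are
preserved. The analogous 14×3 pupil-row generator groups constriction,
dilation and tonic measures. With only two indicators (baseline, onset
latency), the third factor's score determinacy is ≈ 0.87; score-recovery
tests that demand r > 0.9 use structures with ≥ 3 strong indicators per
factor.

## Calibration

Nodes are (√mean recorded area, diameter) per false-pupil size,
replicates averaged in area space (unbiased under additive area noise).
Conversion is piecewise-linear in √area with linear extrapolation from
the terminal segments — child pupils can exceed the largest false pupil;
a log warning fires when >5% of valid samples extrapolate. The default
synthetic device map is quadratic in diameter, making the round trip
exact at and between nodes; for a real tracker the error is the
deviation of √area from linearity between nodes.

## Cleaning and events

Despiking invalidates samples whose change from the previous valid
sample exceeds 0.1 mm/ms; invalid gaps ≤ 200 ms are linearly
interpolated and revalidated (longer gaps stay invalid — no data are
invented, and a long gap in fixation trips viability); each valid sample
is then replaced by the mean of valid samples within ±25 samples, the
window shrinking at edges and across invalid runs. Blinks are maximal
invalid runs padded 50 ms each side (eyelid artifacts flank tracker
loss), merged when overlapping. Saccades: 2-D gaze speed (central
differences on 5-sample-smoothed position) above 30 °/s for ≥ 6 ms;
amplitude is the displacement between the samples flanking the event.
These detector constants are field-standard values, config-exposed.

SRT is the onset of the first ≥2° saccade in [stim −110, stim +800] ms.
The latency classes use half-open windows `[-110, 90)`, `[90, 140)`,
`[140, 800]`, resolving the seam at 90 ms and the overlap at 140 ms
deterministically. Pupil viability requires SRT > 90 ms — express and
regular correct trials are retained; a trial with SRT ≤ 90 ms is
recorded under the reason `anticipatory` even at the 90 ms boundary
(where its latency class is express).

## Measures

Velocity is the central difference of the (smoothed) pupil trace in
mm/s; all windows are closed, so the 50 ms baseline and pre-stimulus
windows hold 26 samples at 500 Hz. Onset latency slides a 20 ms
(10-sample) velocity window from 200 ms after FP onset and requires a
two-sided one-sample t-test against the mean baseline-epoch velocity at
p < 0.05, sustained by every window starting within the following
40 ms. On noise-free traces the baseline velocity variance is exactly
zero and the t-test is undefined; the criterion then degenerates to an
absolute threshold of 1e-6 mm/ms. Test and sustain length are
config-exposed. The peak-constriction search floor (200 ms after FP
onset) prevents locking onto pre-response noise minima; a trace whose
minimum sits at the search floor (monotone dilation) is degenerate and
yields NaN measures for that trial.

Feature extraction is a pure function of the trace it receives. The
pipeline feeds it despiked, smoothed traces; noiseless recovery tests
feed raw generator output, because the ±25-sample boxcar necessarily
biases the constriction minimum (by ~A·π²/4 · Var(window)/h² ≈ 3×10⁻³ mm
on the default pulse) and sub-millisecond claims are only meaningful
without it. With the default noise and 40 trials per condition, medians
after full cleaning recover generator parameters within 5%.

Subject-level aggregation uses the median within condition. The
14-variable row keeps six measures split by condition and pools baseline
size and onset latency across conditions (they show no task
modulation). Participants missing any of the 14 entries are flagged
incomplete and excluded from factor analysis.

## ANTI-effect

Effect = ANTI median − PRO median per participant and measure. The
group test is the two-sided Wilcoxon signed-rank at α = 0.05: exact null
distribution for n ≤ 25 without ties, normal approximation with
continuity correction otherwise; zero effects are dropped and counted.
Two-sided because no direction is pre-registered; swapping condition
labels negates every effect and leaves p-values unchanged.

## Factor pipeline

Factoring runs on the Pearson correlation matrix of complete cases
(the convention of mainstream factor-analysis tooling); a Spearman
matrix is available for display and sensitivity analysis. KMO is
Σr²/(Σr² + Σq²) with q the anti-image partial correlations (for p = 2
it is exactly 0.5 — the statistic is uninformative there). Bartlett's
χ² = −(n − 1 − (2p+5)/6)·ln det R with df = p(p−1)/2 (91 at p = 14).
Retention is Kaiser's criterion on the unreduced matrix, strictly > 1
(an identity matrix retains zero factors).

Extraction is iterated principal-axis factoring: squared multiple
correlations initialize the communalities, the reduced matrix is
eigendecomposed, and communalities are iterated to max|Δh²| < 1e-4.
Convergence is linear and can take several hundred iterations on real
samples, so the ceiling is 2000 (each iteration is one p×p
eigendecomposition); genuine non-convergence raises. Heywood cases are
clamped at 0.999 with a warning. Rotation is direct oblimin at γ = 0
(direct quartimin, the SPSS default) via the oblique
gradient-projection algorithm; communalities are invariant under the
rotation to 1e-8, which the tests assert. Factor scores are Thurstone
regression scores `Z R⁻¹ (P Φ)`. Salience is |loading| > 0.3, strict.
Recovery diagnostics use Tucker congruence with greedy factor matching
and sign alignment. Pupil×saccade factor score coupling is Spearman
with Bonferroni over all k₁·k₂ pairs.

## Lifespan models

The GAM is a Gaussian penalized regression spline: cubic B-spline basis
(k = 10, equally spaced knots), second-order difference penalty, and
the smoothing parameter chosen by minimizing the restricted likelihood
(profiled scale; golden-section search on log λ for one smooth,
Nelder–Mead over both log λs for the sex-difference model). The
coefficient posterior `N(β̂, σ²(XᵀX + λS)⁻¹)` supplies the bands. One
test cross-checks the fit against an independent REML cubic-spline
implementation in R (`mgcv`) on the same data.

The derivative is a central finite difference (ε = 0.1 yr) of the
fitted smooth on a 200-point age grid. Its 95% band is *simultaneous*
across the grid: the critical multiplier is the 0.95 quantile of the
max-|standardized deviation| statistic over seeded posterior draws
(10,000 by default in the pipeline; 2,000 in Monte-Carlo tests, where
the multiplier estimate is already stable). Significant periods of
change are maximal grid runs where the band excludes zero; pointwise
bands are available behind a flag for comparison. Simultaneous bands
hold the null any-window rate near α (measured ≤ 0.07); pointwise bands
would not.

Two numerical notes. First, with the second-difference penalty the
unpenalized null space is *linear*, so the reported effective degrees of
freedom of even a constant fit approach 2, not 1; edf is tr of the
influence matrix throughout. Second, data fitted exactly (RSS = 0, e.g.
a constant response) make REML indifferent to λ; the fitter then prefers
the smoothest equivalent optimum.

The sex-difference model is the difference-smooth construction
`y = α + β·1[F] + f(age) + 1[F]·d(age)` with both smooths under
sum-to-zero constraints (reparameterized into the constraint null
space, which also keeps the penalized system full-rank); the reported
curve is `β + d(age)`, the total F − M difference, with a simultaneous
band and windows as above.

Qualitative per-measure age curves use a cross-validated cubic
smoothing spline (GCV), replicate ages averaged with count weights; no
inference is attached to them. Age groups default to eleven bins
(5–8, 9–12, 13–16, 17–20, 21–29, …, 84–93) with a closed-upper
convention; the bin edges are configurable because the original
grouping is not published in full.

## Problem sizes and runtime

Monte-Carlo checks use sizes chosen to make each rate estimate stable
while keeping the whole suite a desk-scale run: 2,000 replicates for
the Wilcoxon type-I error, 1,000 (test) / 600 (script) for the
Bonferroni family-wise error at n = 567, 300 for planted-correlation
power, 400/300 for the GAM null any-window rate, and 40 for the
detection-rate scenarios (where true rates are near 1, so 40 Bernoulli
trials bound the estimate well). The planted ANTI-effect cohort uses
200 participants with 2 blocks × 20 trials; the end-to-end determinism
check runs the full default 2 × 120-trial protocol on 50 participants.
All simulations are seeded; reruns are byte-identical.

## Known limitations

- The onset-latency t-test treats smoothed velocity samples as
  independent; it is a detector with a calibrated sustain criterion, not
  an inference procedure.
- Complete-case factor analysis; no missing-data imputation, parallel
  analysis, or confirmatory modelling.
- Gaussian GAMs only; no longitudinal (repeated-measures) structure,
  quantile smooths, or non-Gaussian families.
- The EyeLink ASC importer is a stub entry point; the canonical input
  formats are the documented TSVs.
- Monocular, horizontal-saccade geometry; no gaze-angle pupil
  foreshortening correction (fixed head mount, central fixation).
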