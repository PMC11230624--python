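# Methods

This note documents the models implemented in `v1energy`, the defaults
and why they were chosen, what the synthetic-data generators do and do
not emulate, and the numerical decisions a maintainer would want
written down.

## Trace processing

Raw ROI fluorescence is converted to ΔF/F with a percentile baseline:
each trace is low-pass filtered (windowed-sinc FIR, Hamming window,
order 60, 1 Hz cutoff at the acquisition rate, default 40 Hz), applied
forward–backward for zero phase with reflection padding at the edges,
and F₀ is the 5th percentile of the filtered trace over the whole
recording.  A rolling baseline was considered and rejected: the
protocols here are tens of minutes with no slow drift in the synthetic
data, and a whole-recording percentile is the simpler, more
reproducible choice.  Traces shorter than the filter warm-up
(3×(order+1) samples) and non-positive baselines are rejected with
errors rather than silently patched.

The grating response is the maximum over frame-aligned placements of
the 2-s-window mean ΔF/F inside the 4-s window starting at grating
onset (the 2-s grating plus the first 2 s of the following grey
screen), minus the mean ΔF/F in the 1 s immediately before onset.  The
placement step is one frame.  The baseline window is anchored to
grating onset, not to the chosen response window, so that every trial
of a condition shares the same baseline epoch.  Events whose windows
extend past the recording are dropped and logged; responses may be
negative.

## Direction tuning and responsiveness

Direction-mean responses are modelled with a two-lobed Gaussian tuning
curve: offset C, preferred lobe Rp at θ_pref, null lobe Rn at
θ_pref + 180°, common width σ, with angular differences wrapped onto
[0°, 180°] by `angdir`.  Fitting is nonlinear least squares with
multi-start initialization (θ_pref started at every observed direction;
σ started at 15°, 30° and 60°), σ bounded to [5°, 120°], and C, Rp, Rn
unconstrained in sign.  Because the curve is invariant under swapping
the two lobes and rotating θ_pref by 180°, fits are canonicalized to
Rp ≥ Rn after optimization.

Model selection uses BIC = n·ln(σ̄²) + k·ln(n) with σ̄² the mean
residual sum of squares, k = 5 for the tuning curve and k = 0 for the
null model (a flat line at zero, predictions identically 0).  A neuron
is grating-responsive when BIC_null − BIC_Gauss ≥ 10, threshold
inclusive.  Perfect fits floor σ̄² at 1e-12 before the logarithm; this
is only reachable on noiseless synthetic data.

**n is the number of responses, not the number of directions.**  The
fit accepts either one mean per direction or all per-trial responses;
the full pipeline passes per-trial responses (e.g. n = 120 for 12
directions × 10 trials).  The two are numerically identical for the
fitted parameters (balanced designs; implemented as count-weighted
least squares on the direction means plus the constant within-direction
sum of squares), but the BIC differs, and the trial-level count is the
statistically meaningful one.  The window-maximum response definition
gives every neuron — tuned or not — a small positive mean response
bias; with only 12 direction means this bias is large relative to
their standard error *at any noise level* (both scale identically), and
a flat-at-zero null model would misclassify a large fraction of
genuinely untuned neurons as responsive.  With the trial-level count
the within-trial scatter enters σ̄² directly and the decision becomes
well calibrated (in the simulations below: 100% classification
accuracy, untuned neurons' ΔBIC median ≈ −5).

Spatial-frequency selection takes, per neuron, the SF with the largest
response meaned across all orientations; exact ties break toward the
lowest SF (deterministic, logged).  OSI and DSI are computed from the
raw orientation/direction means — not from the fitted curve — with
negative means zeroed; neurons whose means are all non-positive have
undefined selectivity and are excluded with a log entry.  Per-animal
summaries are medians over grating-responsive neurons only.

## FRET ATP-sensor kinetics

The sensor readout is the YFP/CFP ratio, formed per ROI and averaged
across ROIs per trial.  Trial series are normalized to [0, 1]:
plateau = mean of the last three trials (subtracted), baseline = mean
of the pre-drug trials (divides, after plateau subtraction — required
for the result to be bound between 0 and 1).  The half-time is the
first downward 0.5 crossing after drug application, linearly
interpolated between the bracketing trials, in minutes from drug
application (baseline trials carry negative timestamps).  Traces that
never cross 0.5 are reported as censored, not as numbers.  The
normalization is exactly invariant to affine transforms of the raw
ratio.  Dark-condition experiments use the same code path with a
different protocol label.

## Pupil diametry

Operator chain per frame: optional rescale (anti-aliased), 2-D median
filter, contrast stretch, Otsu threshold with dark pixels as
foreground, removal of border-touching components, then the largest
component within a relative area band (default 0.1–35% of the
processed frame) is kept.  An ellipse is fitted from the region's
second-order central moments (semi-axes 2√eigenvalue of the coordinate
covariance) and the diameter reported as d = 2√(a·b).

Defaults were set by measuring recovery on synthetic ellipses with
semi-axes 5–40 px: full-resolution processing (downscale 1.0) with a
3×3 median kernel keeps the worst-case diameter error near 0.3 px,
whereas half-resolution processing and/or a 5×5 kernel erode the
smallest pupils by more than 1 px (a 5-px semi-axis is only ~2.5 px at
half scale).  Downscaling remains available as a throughput option for
long videos of large pupils.  The area band is wide because small
pupils in a full camera frame can occupy well under 1% of its area.

## Cohort statistics

Endpoints are analysed at the animal level.  The two-factor
between-subjects linear model with interaction supplies the pooled
error term (MSE, df = N − 4); each pairwise contrast is
t = (m₁−m₂)/√(MSE·(1/n₁+1/n₂)) with unadjusted two-sided p values
(Fisher's LSD; no further multiplicity adjustment — deliberate, and a
known limitation).  The default contrast set is the four sex-matched or
diet-matched pairs; cross pairs (e.g. CTR male vs FR female) are
configurable but not reported by default.

The JZS Bayes factor places a Cauchy(0, r = 1/√2) prior on the
standardized effect size δ; the marginal likelihood of the observed
two-sample t is ∫ T_ν(t; δ√N_eff)·Cauchy(δ; r) dδ with ν = n₁+n₂−2 and
N_eff = n₁n₂/(n₁+n₂), integrated by adaptive quadrature split at the
prior mode and likelihood peak, and BF₁₀ is its ratio to the central-t
density.  A relative quadrature error above 1e-6 raises.  Evidence
categories: BF₁₀ > 3 "evidence for effect", < 1/3 "evidence for
absence", else inconclusive.

Percent change is (FR − CTR)/CTR × 100 (reported to the nearest
integer), fold change FR/CTR (one decimal).  Note that changes
recomputed from group means printed at two decimals can differ by ±1
point from values computed on unrounded means.

## Synthetic data

The generators emulate the study conditions, not the physics of
imaging:

- **Grating sessions** — 12 drift directions in 30° steps, 2-s
  gratings, 4-s grey screens, four spatial frequencies (0.02–0.32
  cpd), 10 repeats per stimulus, 40 Hz.  (The canonical 12-direction
  set runs 0°–330°; printed direction lists sometimes drop one angle
  as a typo, so the full arithmetic sequence is used.)  Each event adds
  an evoked transient — a boxcar drive convolved with a
  single-exponential indicator kernel (τ = 1.5 s, GCaMP6s-like) —
  whose amplitude is the neuron's double-Gaussian curve at the event's
  direction, attenuated by 0.5 away from its preferred spatial
  frequency.  The unit transient is normalized so the downstream
  windowed extraction recovers the amplitude *exactly*, and truncated
  (with a smooth taper) before the next trial's baseline window so
  consecutive events never interact.  Noise has two components:
  additive white Gaussian on ΔF/F per frame, and additive Gaussian
  trial-to-trial jitter of the evoked amplitude.  The second component
  matters: real trial-level response variability is dominated by
  biological gain fluctuations that do not average down within a
  response window, and without it the window-maximum bias dwarfs
  trial scatter and no responsiveness criterion can behave sensibly.
  Not emulated: pixel-level movies, motion artefacts, neuropil
  contamination, photon shot noise, adaptation, correlated population
  variability — so passing tests validate the estimators, not
  robustness to those artefacts.

- **FRET experiments** — 3 baseline trials and 30 post-drug trials at
  1-min spacing; baseline YFP/CFP ratio 2.0 decaying to a plateau of
  1.0 (the sensor's approximate dynamic range under full ATP
  depletion), with i.i.d. Gaussian trial noise.  The decay is a
  *shifted* exponential that reaches the plateau exactly at the first
  of the last three trials, with its rate solved numerically so the
  normalized trace crosses 0.5 exactly at the requested half-time.  A
  pure exponential never reaches its asymptote, and because the
  analysis estimates the plateau from the last three trials it would
  recover a half-time systematically ~1 min short of the nominal one;
  pinning the crossing makes the generator's parameter the true
  recoverable quantity.  Requested half-times must be shorter than
  half the plateau time to be observable.

- **Pupil frames** — a dark ellipse of known semi-axes on a brighter
  iris background, edges area-sampled at 4× so partial pixels carry
  intermediate intensity, plus Gaussian pixel noise.  No eyelids,
  corneal reflections or blinks.

- **Cohorts** — per-animal normal draws from per-cell (sex × diet)
  means and SDs with exact cell counts; SDs can be derived from
  printed 95% CIs assuming normal-theory intervals
  (SEM = half-width/1.96, SD = SEM·√n).  Group summaries in the
  source material are means ± SEM, so normality is an assumption, not
  a fact.

All generators are deterministic given their seed (single
`numpy.random.Generator` per call).

## Verification scale

The test suite and `scripts/acceptance.py` use: 200 simulated neurons
(70% tuned, preferred-amplitude SNR ≥ 5 relative to frame noise 0.2
ΔF/F, trial jitter 0.15 ΔF/F) for tuning recovery; 1,000 random
response vectors for selectivity-oracle agreement; 4 half-times × 100
seeds (trial noise 0.02 ratio units) for FRET recovery; a 10⁶-draw
Monte-Carlo marginal likelihood for the Bayes factor; 50 ellipse
frames for pupil diametry; and 3-animal-per-cell toy tables for the
ANOVA sums-of-squares oracle.  These sizes give stable statistics
while keeping a full run within a couple of minutes on one CPU.

## Known limitations

- The responsiveness criterion inherits the positive bias of the
  window-maximum response definition; it is calibrated for the trial
  counts simulated here, and very different trial counts shift the
  BIC's sensitivity.
- The pooled-error LSD assumes homoscedastic cells; no Welch-type
  correction is offered.
- Cohort simulations cannot reproduce published t statistics exactly —
  those depend on the raw per-animal data — only their design (cell
  sizes, df) and approximate magnitudes via the printed means and CIs.
- The pupil chain assumes the pupil is the darkest coherent region
  away from the frame border; occlusions and reflections are out of
  scope.
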