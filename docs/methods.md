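# Methods

`resilnet` reimplements, as a tested pipeline on synthetic data, a
cross-species analysis of stress resilience: microcircuit physiology of
mouse primary visual cortex measured by two-photon calcium imaging, and
human EEG-derived neural predictors of an outcome-based resilience score.
This note documents the models, the estimators, the synthetic data the
package runs on, and the design decisions taken where the procedure was
genuinely open.

## Resilience operationalization

**Human (SR proxy).** Stressor reactivity is the residual of the ordinary
least-squares regression of mental-health problems (GHQ score) on
life-event count (LE): `sr_proxy = GHQ − (a + b·LE)`. A positive residual
means worse-than-expected mental health given the stressor load, i.e.
lower resilience. Subjects with negative SR proxy are dichotomized as
"resilient" where a group split is needed. OLS identities (residuals sum
to zero and are orthogonal to LE) hold to machine precision and are
asserted in tests.

**Mouse (SI score).** After chronic social defeat, the social-interaction
score is `100 × dwell(aggressor present) / dwell(empty enclosure)`;
animals above 100 are resilient, below 100 nonresilient. The boundary
SI = 100 is undefined by strict inequalities; we assign it to
`nonresilient` (conservative, configurable via `boundary_group`).

## Mouse arm: calcium transient detection

The detector operates on ΔF/F traces, `(F − F0)/F0`, with F0 the mean over
a 10-s quiescent window (auto-selected as the minimum-variance 10-s span
when not given). The trace is smoothed by 25 passes of the binomial
`[1/4, 1/2, 1/4]` kernel (≈ one Gaussian of σ ≈ 3.5 frames; the procedure
specifies 20–30 passes, we fix 25 and expose it) and high-pass filtered
with a zero-phase 2nd-order Butterworth at 0.12 Hz. Peaks are local maxima
exceeding mean + 2.5 SD of the analyzed trace (2.5 is the lower end of the
stated 2.5–3 range) with a +→− first-difference sign change and negative
second difference. Onset is the last pre-peak frame below 0.5 SD; a
single exponential `A·exp(−(t−t_peak)/τ)` is fitted from the peak to the
tail (next threshold down-crossing or 3 s); offset is where the fitted
curve falls below 0.5 SD. Overlapping events are merged into the earlier
event's span, so binarized rasters encode event spans losslessly.

**Amplitude estimation.** Repeated smoothing attenuates an
instantaneous-rise transient's peak by ~35% (measured analytically and
numerically), so amplitudes are estimated on the *unsmoothed* ΔF/F: the
raw local maximum near the detected peak anchors the exponential fit, and
the fitted A is divided by the sampling-phase factor
`τ·fs·(1 − exp(−1/(τ·fs)))` — the expected sub-frame decay of the first
sampled point of an instantaneous-rise transient (≈ 3% at τ = 0.5 s,
30.8 Hz). Residual bias on planted events at SNR 5 is ≈ −6%, within the
10% tolerance the acceptance suite asserts; timing F1 is ≈ 0.92–0.94.

The manual peak-correction step of the original interactive procedure is
replaced by deterministic rules; the mean/SD used for thresholding are
computed on the full filtered trace (no iterative event exclusion).

**Windowed-median detrending** (connectivity path): ΔF/F is
`(median_101 − median_5401)/median_5401` with centered rolling medians
(truncated at the edges). Refined activity intervals bound each peak by
its half-peak crossings; peaks inside an existing interval are absorbed.

**Microcircuit statistics.** Activity frequency is events/min; IEIs are
successive peak-to-peak differences (the definition used for γ bursts,
applied identically to calcium events). Group comparisons use two-sided
two-sample Kolmogorov–Smirnov tests with the asymptotic p-value; neuron
density uses a two-sided t test. Connectivity is the Pearson correlation
(φ coefficient) of binarized rows restricted to frames where at least one
neuron is active; rows constant on that restriction get zero weight and a
flag. Graph summaries are limited to mean edge weight and weighted degree.

## Orientation tuning

The stimulation paradigm per repetition is 5 s gray, then the 8 directions
(0°–315° in 45° steps) in a fresh seeded permutation, each 5 s static then
5 s drifting; 10 repetitions. Responses `r_k` are drifting-window means
minus the gray-period mean, clipped at zero (static windows excluded by
default). Circular variance uses the doubled angle for orientation
symmetry:

    CV = 1 − |Σ_k r_k e^{i·2θ_k}| / Σ_k r_k

The modulus in the numerator is required for a real result and is the
standard definition. CV ∈ [0, 1]; CV is NaN (flagged) when all r_k = 0.
Invariance under response scaling and global angle rotation, and
monotonicity under adding mass at the preferred orientation, are property
tests. There is no canonical "well-tuned" CV cutoff; the primary output is
the full CV distribution, with an optional cutoff fraction.

## Human arm: time–frequency interactions

Low frequencies (β, 10–44 Hz extraction band) use Morlet wavelet power at
2–44 Hz in 1-Hz steps, wavelet width linear from 3 to 8 cycles; high
frequencies (γ, 44–150 Hz) use DPSS multitaper power in 2-Hz steps with
~7-cycle sliding windows and spectral smoothing of 20% of the center
frequency (time–bandwidth product 2.8). Both are computed with MNE behind
the module surface. Short trials are reflect-padded so the longest wavelet
fits, then cropped. The interaction map is the double difference
`(Incong.Neg − Incong.Neut) − (Cong.Neg − Cong.Neut)`: additive main
effects cancel exactly. Band-restricted minimum and maximum of this signed
map (over the full post-stimulus window by default; the analysis window is
configurable) are the subject-level predictors. Results-section band
variants (γ to 160 Hz, β 9–33 Hz) are reachable through configuration; the
Methods-section values are the defaults.

## γ-burst detection

Source trials are bandpass-filtered 40–80 Hz with a zero-phase FIR of
order 11 centered at 60 Hz. The stated low order has a shallow roll-off;
we keep it, but subtract the coefficient mean (exact null at DC, otherwise
the short design passes DC with gain > 1) and normalize to unit gain at
60 Hz.

A dictionary of 30 unit-norm burst waveforms is learned from the first 100
trials by sparse coding: candidate segments are cut around high-power
windows of the filtered training trials, and the algorithm alternates
1-sparse matching-pursuit assignment with atom re-estimation under a
correntropy (Welsch) loss via iteratively reweighted least squares, which
discounts outlier segments. Atom length defaults to **6 cycles of the
center frequency** (100 ms at 60 Hz): a parameter study at SNR 2 showed
3-cycle atoms integrate only half a burst's energy and sit at a marginal
operating point (hit 0.92, false alarms 0.08/s), while 6-cycle atoms reach
hit ≈ 0.98 at 0.03 false alarms/s.

Detection convolves each filtered trial with every atom; the maximum
squared projection across atoms, smoothed over one atom length, is the
instantaneous matched power. A per-trial adaptive threshold at
median + k·MAD with **k = 5** (chosen in the same parameter study; k = 3
admits ≈ 1–2 false alarms/s on pure 1/f background) marks burst peaks;
peaks closer than two atom lengths — the envelope support of one burst
after matched filtering — are merged keeping the stronger. Burst IEIs are
within-trial successive peak differences, pooled across trials; cross-trial
gaps are never counted.

**IEI analysis window.** Within-trial IEIs discriminate burst rates only
when trials are long relative to 1/rate: conditioning two peaks into a
short window truncates the IEI distribution and compresses group
differences (with 4-s trials even the ground-truth IEIs of 0.6 vs 1.0
bursts/s separate with KS power ≈ 0.7 at 200 IEIs). The group-comparison
analyses therefore use 8-s trials, where power reaches 1.0 at ≥ 200 IEIs
per group.

## Bayesian regressions

All models are normal-likelihood linear regressions of the SR proxy on
subject-level neural predictors, `y_j ~ N(α + Σ β_i x_ij, σ²)`. The
connectivity-link family uses Normal(0, 0.5) priors on α and β with a
half-Normal(1) prior on σ; the power-interaction family (Models 1–6) uses
Normal(0, 1) with half-Cauchy(1) (the half-Cauchy scale is not pinned down
by the procedure; 1 is the default and configurable). Variables are
z-normalized before modeling by default (`standardize` flag; parameter-
recovery tests against generator coefficients run unstandardized, since
z-scoring the outcome rescales the true coefficient by sd(x)/sd(y)).

Sampling is a Gibbs scheme: the coefficient block is conditionally
conjugate given σ and drawn exactly from its multivariate normal; σ is
updated by slice sampling on log σ. Four chains with 3,000 tuning and
10,000 kept draws are the defaults (reduced sizes are used in simulation
studies; every run reports R-hat). The sampler was validated against the
conjugate closed form in the known-σ limit (posterior mean and SD match to
Monte-Carlo error). A run with any R-hat ≥ 1.05 is flagged
(`converged=False`, warning), never silently accepted.

Summaries report posterior means and 94% highest-density intervals; the
HDI is computed as the narrowest window of ⌈0.94·n⌉ consecutive sorted
draws (exact for unimodal posteriors; never wider than the equal-tailed
interval). Model comparison uses Pareto-smoothed importance-sampling
LOO-CV through ArviZ on the deviance scale, so *lower scores imply better
models*, and the ranking table states the direction explicitly. Reported
coefficients are posterior means.

## Synthetic data: what it emulates, and what it does not

All analyses run on seeded generators with ground truth attached
(identical seed ⇒ byte-identical output):

- **Calcium traces** — baseline fluorescence × (1 + signal): Poisson-timed
  transients with instantaneous rise and single-exponential decay
  (τ = 0.5 s), Gaussian amplitudes, Gaussian noise, optional slow drift;
  30.8 Hz sampling, 512×512 px / 277×277 µm movie geometry with ~66
  disc-shaped somata when rendered. Group defaults encode the observed
  effect directions: nonresilient rate 2.0/min > nonstressed 1.2 >
  resilient 1.0; nonresilient amplitude 1.0 ΔF/F > nonstressed 0.9 >
  resilient 0.8; resilient tuning κ 2.0 > others 1.0; resilient burst rate
  0.6/s < nonstressed 0.8 < nonresilient 1.0. Magnitudes are free,
  documented choices.
- **Tuned responses** — drifting-window event rates scale with a von-Mises
  profile on the doubled angle, mean rate preserved across directions.
- **Burst trials** — unit-variance 1/f Gaussian background (spectral
  exponent 1) plus Hann-windowed 60-Hz sinusoids of 6 cycles; burst SNR is
  peak amplitude in background SDs. Planted bursts keep a refractory gap
  of two burst durations so every ground-truth peak is an identifiable
  event.
- **Cohort tables** — LE ~ Poisson(4), GHQ linear in LE with Gaussian
  residuals (default residual SD 1.9 puts the LE–GHQ correlation near the
  weak ≈ 0.2 regime these cohorts show); exclusion flags drawn as disjoint
  subject subsets (4 technical / 13 MRI / 1 EEG noise on the 121-subject
  roster).
- **Flanker schedule** — 1,120 trials, 5 blocks × 224, 280 per 2×2
  condition, left/right balanced 140/140, with an optional linear RT model
  (main effects + interaction + Gaussian noise) and Bernoulli accuracy.

The generators deliberately omit: GCaMP indicator nonlinearity and rise
kinetics, motion artifacts and neuropil contamination, realistic EEG
forward models and volume conduction, non-stationary 1/f backgrounds, and
RT distributions' right skew. Passing tests therefore demonstrate that the
estimators recover the *structure the analyses assume*, not that they are
robust to every artifact of real recordings.

One stated total ("12.5 min of visually evoked activity") does not match
10 × (5 s gray + 8 × 10 s) = 850 s ≈ 14.2 min; the schedule builder
follows the per-sequence structure and leaves the total as its
consequence.

## Problem sizes and numerical choices

Simulation studies in the test suite and acceptance script use: 100
neurons × 10 min at SNR 5 for detector characterization; 200 somata per
group for group-comparison power (50 repetitions) and 1,000 repetitions
for KS type-I error; 100 training + 100 test 2-s trials for burst ROC and
12 repetitions of 80 8-s trials per group for IEI power; n = 103 subjects
per regression with 200 coverage replicates and 100 model-recovery
simulations at reduced sampler sizes (2 chains, 300 tuning, 900 draws).
Curve fits bound τ to [1 ms, 60 s] and flag non-convergent fits with
τ = NaN (events retained, excluded from τ statistics). Division-by-zero
guards: CV of an all-zero response vector and correlations of constant
raster rows are flagged rather than propagated.

## Known limitations

- The transient detector assumes sparse activity; at high rates (> ~10
  events/min at τ = 0.5 s) overlapping transients merge and frequency is
  underestimated.
- The FIR order-11 bandpass barely attenuates 100–150 Hz content; burst
  specificity comes from the matched filter, not the front-end filter.
- PSIS-LOO with n = 103 and ≤ 5 predictors is well-behaved here; the
  exact-refit fallback for unstable importance weights is advisory.
- The Gibbs sampler covers normal-prior linear models only — by design,
  since that is the entire model family used.
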