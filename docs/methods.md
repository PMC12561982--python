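# Methods

## The problem

In a cued reaction-time ("foreperiod") task, a warning signal is followed
after a variable delay by a target the participant must respond to.  The
moment-to-moment expectation that the target is about to appear is classically
modeled by the hazard function of the foreperiod distribution.  When trials
are organized into two-trial sequences, the second foreperiod (FP2) is
predictable at two levels: from the unconditional distribution of single
foreperiods, and from the distribution of FP2 conditioned on the preceding
foreperiod (FP1).  This package simulates that paradigm, derives both hazards,
and implements the two analyses that test whether responses reflect their
integration: linear mixed-effects regression of reaction times on the two
hazards and their product, and a lagged ridge ("temporal response function")
forward encoding model of multichannel neural time series, with cluster-based
permutation statistics for group-level maps.

No recorded data are consumed; a synthetic-data module generates behavior and
source-like neural signals from the same models the analyses fit, so every
stage is testable against known ground truth.

## Paradigm model

Foreperiods live on a 16-point grid (0.4–2.0 s, 0.1-s step, 1.2 s excluded),
partitioned into short (S: 0.4–1.1 s) and long (L: 1.3–2.0 s).  Four
50-sequence blocks vary the sequence-type composition (LL/SS/LS/SL counts
25/25/0/0, 0/0/25/25, 20/20/5/5, 5/5/20/20), holding the unconditional S/L
split at exactly 50–50 at each position while the conditional probability of
FP2 given the FP1 category ranges from deterministic (Blocks 1–2) to 80–20
(Blocks 3–4).  A session is 12 runs: the four blocks in a fresh random order,
repeated three times (600 FP1 + 600 FP2 trials).

Within a sequence, the FP2 warning follows the FP1 target offset by 1.2 s;
sequences are separated by gaps drawn from 3.0–3.2 s in 0.05-s steps.  All
times are integer centiseconds internally, so grid membership and joins are
exact.

Two duration-assignment modes are provided:

- `idealized` — a discrete triangular profile over each category sub-grid,
  peaking at 0.8 s (S: counts 1/2/3/4/6/4/3/2) and 1.6 s (L: 2/3/4/6/4/3/2/1),
  25 trials per category and position.  The profile is a design choice: the
  design distributions are specified by their peaks and unimodality, not a
  printed table.
- `actual` — an emulation of a sampled per-participant configuration: nine
  padding durations (0.4, 0.5, 0.6, 1.0, 1.1, 1.3, 1.4, 1.9, 2.0 s) appear
  exactly once per position category, and the remaining trials are spread as
  evenly as possible over the three durations around each peak (0.7/0.8/0.9
  and 1.5/1.6/1.7 s).  Exact per-duration counts of the original sampled
  configurations are not published; this emulation preserves the category
  totals, the padding rule, and the dominant durations.

## Hazard functions

For a discrete foreperiod distribution f on the grid, the hazard is

    HF(t) = f(t) / (1 − C(t)),

where C(t) is the cumulative mass strictly *before* t (exclusive convention;
the inclusivity is not specified by the source analyses, and the exclusive
choice makes the final supported grid point hazard exactly 1, with the
near-zero-denominator cap reachable only for truncated or near-deterministic
distributions).  Where 1 − C(t) < 1e−9 the hazard takes the running maximum of
the preceding values.  The series is then divided by its maximum, mapping it
to [0, 1].

HF_U derives from the pooled foreperiod distribution (identical in every
block by design); HF_C derives from the FP2 distribution conditioned on the
FP1 category, per block.  `idealized_hazards()` builds both analytically from
the design profiles and sequence-type proportions; `empirical_hazards()`
estimates them from a generated trial table (the faithful route for `actual`
-mode configurations, where conditional distributions include the padding
trials and are only *near*-deterministic).

Native hazard series are sampled at 10 Hz (17 points, 0.4–2.0 s, value 0 at
the excluded 1.2 s) and upsampled to the neural rate of 250 Hz by a cubic
spline (not-a-knot ends), clipped to [0, 1]; knots are reproduced exactly.

Two blurred variants model timing uncertainty: *temporal* blurring convolves
the hazard with a Gaussian kernel whose SD grows linearly with time
(sigma = phi·t, scalar-uncertainty convention; kernel truncated at ±4 SD),
and *probabilistic* blurring applies the same time-scaled, mass-conserving
kernel to the probability distribution before the hazard transform.  Blurring
happens before the final [0, 1] normalization; phi defaults to the 0.15–0.35
range.  As phi → 0 both variants converge to the unblurred series.

A 5-segment shuffle (contiguous fifths of the series rearranged by a uniform
non-identity permutation) provides the encoding-model control regressor: local
hazard structure is preserved, global alignment destroyed.  The identity
permutation is excluded so the null regressor always differs from the intact
one.

## Reaction-time model

Generative model (and the analysis model — they coincide by construction):

    RT = b0 + bU·HF_U(fp) [+ bC·HF_C(fp) + bUC·HF_U·HF_C]   (FP2 terms)
         + u_participant [+ u_FP1category] + eps

with hazards evaluated at the trial's foreperiod on the native 10-Hz grid,
Gaussian random intercepts and residuals, and reaction times floored at
0.1 s.  Default fixed effects are the full model's estimated coefficients
(b0 = 0.243 s, bU = −0.049, bC = −0.008, bUC = +0.042 s per normalized-hazard
unit; the FP1-only analysis uses bU = −0.021).  Default random SDs are
40 ms between participants (consistent with the intercept standard error at
31 participants), 10 ms for the FP1-category intercept (the asymmetric
sequential effect — responses after a long FP1 are slower), and 50 ms of
residual noise, which reproduces t statistics of the same order as the
reported fits.  Residuals are Gaussian on the raw-seconds scale; a log-normal
option supports the log-RT model variants.  An optional false-alarm process
flags an independent Bernoulli subset of trials, which lose their reaction
time and are excluded (the only exclusion — outliers are retained by
default; a ±2.5-SD exclusion knob exists for sensitivity analyses).

Fitting is delegated to statsmodels `MixedLM`.  The FP1 model uses the
participant grouping directly; FP2 models fit crossed participant and
FP1-category intercepts as independent variance components on a single group.
Estimates and standard errors come from REML; AIC/BIC for model comparison
come from a maximum-likelihood refit (parameter count: fixed effects +
variance components + residual variance).  p values are large-sample Wald
tests; the degrees-of-freedom method for mixed-model fixed effects is not
pinned down by the source analyses, and Wald is the documented default.
Conditional R² is (fixed + random variance) / (fixed + random + residual).
A boundary (zero) estimate of the 2-level category variance is tolerated and
flagged, not treated as failure.  Model comparison ranks the four FP2 models
(HF_U, HF_C, HF_U+HF_C, full) by AIC/BIC and tests each reduced model against
the full one by a chi-square likelihood-ratio test on the ML likelihoods.

Note a structural feature inherited from the design: the three hazard
regressors are substantially collinear, and the FP1-category intercept has
only two levels which are themselves correlated with HF_C.  Per-term
uncertainty is therefore much larger than the residual noise alone would
suggest, and single-replicate estimates can sit 1–2 standard errors from the
planted values even at low noise.  Recovery is unbiased across replicates
up to a small (2–3%) attenuation caused by the 0.1-s reaction-time floor,
which censors the fastest responses and pulls slopes slightly toward zero;
tests and the acceptance script assess coverage and replicate means, not
single draws.

## Encoding model

Source-like signals are segmented from 0.4 s after the warning to the target
onset (trials with foreperiods > 0.7 s only) at 250 Hz.  The temporal
response function (TRF) maps lagged hazard values to each channel:

    r(t, n) = Σ_τ w(τ, n) s(t − τ) + ε,   w = (SᵀS + λI)⁻¹ Sᵀr,

with 76 lags from −0.1 to +0.2 s in 4-ms steps and λ = 1 by default.
Multi-trial fits sum per-trial cross-products (algebraically identical to
concatenation with zero padding, without cross-trial edge artifacts).  DC is
removed by mean-centering the *lagged design columns* and the response per
trial — centering the stimulus before lagging would interact with the
zero-padded segment edges and bias the weights, whereas column centering
leaves the forward model exact (a noiseless simulation is recovered with
profile correlation 1.0).

Evaluation is leave-one-trial-out: the TRF trained on n−1 trials reconstructs
the held-out trial using only the lag-0 weight slice (a per-channel scaling
of the regressor — the convention for "reconstruction at lag zero"), and the
Pearson correlation with the actual signal is averaged over folds per
channel.  Folds with a constant held-out channel are excluded from that
channel's mean.  Variable trial lengths are handled natively.  The
hyperparameter search evaluates λ over 10⁻³…10³ (7 log-spaced values) and
four lag windows ({−0.2, −0.1} × {0.2, 0.3} s) with the same leave-one-out
procedure, selecting the highest grand-mean held-out correlation.  The
shuffled-hazard control runs the identical pipeline on per-trial 5-segment-
shuffled regressors.

The synthetic neural generator plants per-channel TRFs (Gaussian lag bumps;
negative for HF_U on one lattice patch, negative for HF_C on another,
positive for the interaction on a third, mirroring the reported topography
at desk scale) on an 8×8 channel lattice with 4-neighbor adjacency, plus
pure-noise null channels.  It emulates linear stimulus-to-signal convolution
with stationary Gaussian noise; it does not emulate volume conduction,
evoked responses, oscillatory structure, or realistic EEG spectra — passing
tests demonstrate correctness of the estimation chain, not realism of the
signals.

## Cluster statistics

Group-level maps (participants × nodes) are tested against zero with a
sign-flip Monte-Carlo permutation test: per-node one-sample t values are
thresholded two-sided at a cluster-forming alpha of 0.025 per tail,
supra-threshold nodes of equal sign are grouped into connected clusters on
the adjacency graph (positive and negative clusters formed separately), each
cluster is scored by its summed t, and the null distribution keeps the
maximum absolute cluster sum per resample (1,000 permutations by default).
Cluster p values are (1 + #{null ≥ observed}) / (1 + n_perm) — equivalent to
always counting the observed assignment — so p ≥ 1/(n_perm + 1) and the test
is exact-valid.  Zero-variance nodes are excluded with a warning.  An
exhaustive mode enumerates all 2ⁿ sign assignments for n ≤ 12 participants
and serves as the oracle for the Monte-Carlo mode.  Paired comparisons test
per-participant difference maps with the same machinery.

## Pipeline and problem sizes

`fpseq.pipeline.run_pipeline` chains simulate → hazards → behavior fits →
encoding → cluster tests, with a single master seed fanned out to per-stage
seeds by a counter-based derivation, plain-text outputs (TSV + JSON
sidecars), and hash-based stage caching.  Defaults run the behavioral arm at
the study scale of 31 participants; the encoding arm defaults to 4
participants × 40 trials on the 8×8 lattice with 500 permutations, the
package's desk-scale choice for routine runs (the full EEG analysis operated
on thousands of sources and millions of voxels, which is out of scope here —
the statistics are identical, only the spatial scale differs).  The
simulation studies in the test suite use 100 replicates at 31 participants
for behavioral recovery and calibration, 150 trials for TRF recovery, and
200 replicates for cluster-test family-wise-error calibration.

## Known limitations

- The `actual`-mode per-duration counts are an emulation (category totals,
  padding rule and dominant durations preserved; exact sampled counts were
  never published).
- The blurred-hazard formulas follow the time-scaled Gaussian convention of
  the temporal-blurring literature; normalization is applied after blurring.
- The 2-level FP1-category random intercept is weakly identified; its
  variance estimate is noisy and coverage of fixed-effect confidence
  intervals at 31 participants runs at roughly the nominal level but not
  above it.
- Wald p values are anticonservative in small samples; at the study's
  observation counts (≈18,000) the approximation is good.
- The encoding generator and estimator share the lagged-design convention;
  the ridge solver is validated against an independent normal-equations
  oracle, and the hazard transform against direct evaluation, but no
  independent end-to-end TRF implementation is bundled.
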