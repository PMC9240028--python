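# Methods

This note documents the models, statistics and numerical choices behind
`btbc`, in the spirit of a package methods appendix. Everything stated
here is computed by the test suite or by `scripts/acceptance.py`; nothing
is quoted from external data.

## The measurement chain

### Motion energy

Motion energy for a fixed rectangular region of interest (ROI) is the
count of pixels whose grayscale value (ITU-R BT.601 luma) changes by more
than `diff_threshold` between consecutive frames. A video of N frames
yields series of length N − 1, with sample *i* timestamped at frame
*i* + 1 — frame differences are between-frame quantities. Two design
choices are deliberate:

* **Count, not magnitude.** Summing supra-threshold *counts* (rather than
  absolute differences) follows the frame-differencing tradition this
  method comes from and makes the statistic robust to lighting gain.
* **Threshold default 12/255.** Real sensors flicker by a few grayscale
  levels per pixel; a threshold near 10–15 suppresses that noise floor
  while keeping genuine motion. The value is configurable and the series
  is monotone non-increasing in it (tested). Area normalization
  (counts / ROI pixels) is available but off by default; with
  whole-body ROIs of similar size it only rescales, and the downstream
  statistic is scale-free anyway (within-window Pearson correlations).

### Preprocessing

Fixed order, enforced by `preprocess_series`: (1) centred moving average,
0.5 s window rounded to the nearest odd sample count (13 samples at
25 Hz), shrinking at the edges so length is preserved; (2) samples above
mean + 10 SD of the smoothed series are flagged and **interpolated**
(linear between nearest clean neighbours, nearest-value at edges) rather
than deleted — the windowed cross-correlation needs a regular time grid
shared by both partners, and deletion would desynchronize them; (3)
z-scoring (population SD). Standardization last guarantees every series
entering the coupling stage has mean 0, SD 1.

Note the 10-SD rule can only ever fire if the series is long enough: the
largest attainable z-score in n samples is √(n−1), so n must exceed 101.
On the simulator's bursty defaults the flagged fraction is far below
0.2% (tested as an order-of-magnitude property).

### The coupling statistic

For window starts every 1 s (30-s windows, anchored on the learner's
clock) and signed lags −5 … +5 s in 0.04-s steps (251 lags at 25 Hz):

    r(t, ℓ) = corr( learner[t, t+W),  instructor[t+ℓ, t+ℓ+W) )

computed with per-window means and SDs (windows are the unit of analysis;
global moments would defeat the point of windowing non-stationary motion).
**Positive lag = learner leads**: at positive ℓ the instructor segment is
taken later in time, so high correlation there means the instructor echoes
the learner. The per-lag coupling value is the window-average of
|atanh(r)| — absolute Fisher-z — so in-phase and anti-phase correlation
both count toward coupling. Since atanh is odd, |atanh r| = atanh|r|
(asserted numerically). Scalar summaries: *overall* (mean over all lags),
*learner-leading* (strictly positive lags), *instructor-leading* (strictly
negative), *zero-lag*, and *peak lag* (ties broken toward smaller |lag|,
then the negative one).

Numerical choices:

* r is clipped to ±(1 − 1e−6) before atanh, capping a perfect-copy window
  at |z| ≈ 7.25 and keeping every profile finite.
* Windows whose lag-shifted segment would run off the series are skipped
  (no zero-padding — padding deflates |r|); `n_windows_used` records the
  per-lag count.
* Windows with per-sample variance below 1e−10 (on the unit-SD scale) in
  either segment are skipped as degenerate; a lag with no usable window
  raises.
* Implementation: per-window sums come from prefix sums; when the window
  and step are commensurate (the 30 s / 1 s defaults are), the
  cross-products for all 251 lags are assembled from step-sized block
  sums via one batched matmul. Both paths agree with a nested-loop
  two-pass Pearson oracle to ~1e−16 (tested at 1e−10 tolerance).

## Surrogate null and group permutation test

A surrogate dyad re-pairs 60-s segments that never co-occurred: the
instructor's segment order is permuted (uniform non-identity permutation;
draws with replacement across the ensemble) while the learner stays
intact, preserving each person's marginal distribution and within-segment
autocorrelation exactly (multiset conservation is tested). Trailing
samples beyond a whole number of segments are dropped and logged; both
series are re-standardized after trimming, which is exact because
per-window Pearson r is affine-invariant.

The group test compares the grand mean of genuine per-record overall
couplings with a null built by repeatedly drawing one value per record
from its pool and averaging, with the add-one p-value. Two properties of
this construction were established during development and are worth
knowing:

* **The pool must contain the genuine value.** Resampling only from the
  100 surrogate values leaves the observed arrangement outside its own
  null and inflates the type-I error (≈ 0.063 at nominal 0.05 in an
  abstract Monte-Carlo; ≈ 0.07–0.10 on full simulations). Each record's
  pool is therefore its surrogate ensemble plus its genuine value — the
  standard requirement that a permutation null include the observed
  arrangement.
* **Don't scale the series below ~6 segments.** With only 4 segments
  there are 23 distinct orderings; surrogate draws collide and the null
  loses diversity (type-I ≈ 0.059 vs 0.045 in the same abstract model).
  Calibration experiments therefore keep the full 8-min duration
  (8 segments, 5039 orderings), where the measured type-I rate is
  0.058 ± 0.015 over 240 null cohorts — consistent with nominal.

## Group-level inference

* **Mixed models** delegate to REML estimation in statsmodels
  (`MixedLM`), treatment coding with explanation / nonpersonalized as
  reference levels, random intercept per dyad (plus participant nested in
  dyad for individual-level motion models, via a variance component).
  Wald t = β/SE and p-values are reported; convergence/singularity
  warnings are surfaced in the summary, never swallowed.
* **Outcome prediction** is linear SVR with nested CV: outer leave-one-out
  (a leave-one-dyad-out option exists because a dyad's two records are
  dependent), inner 10-fold selection of C over 2⁻¹⁰ … 2¹⁰, features
  standardized with training-fold statistics, performance = Pearson r of
  pooled outer predictions vs actuals (R² = r²), and a residualized
  variant after regressing both on a covariate. **C is selected by the
  metric the analysis reports** (Pearson r of pooled inner-validation
  predictions), not by inner MSE: when the within-cohort signal is weak,
  MSE is minimized by the near-constant model, and pooled leave-one-out
  predictions of near-constant models are *anti-correlated* with the
  held-out outcome (each prediction is essentially the training mean,
  (Σy − yᵢ)/(n−1)), which can push a cohort's r to ≈ −0.3. Selecting by
  the reported metric cannot pick flat models.
* **Lag decoding** fits, at each lag, a univariate logistic classifier
  scored by leave-one-dyad-out cross-validated AUC (an `in-sample` switch
  mirrors a non-CV reading). The permutation null re-runs the identical
  procedure on dyad-paired shuffled labels — a dyad's two records swap or
  keep labels together, respecting repeated-measures exchangeability —
  drawn once per rendition and scored at every lag; per-lag add-one
  p-values are Benjamini–Hochberg-corrected across lags. The logistic
  fits use a small batched Newton-IRLS (2 parameters, vectorized across
  all permutations; ridge 1e−6 and step damping bound the separable
  case, which cannot affect the score ranking and hence the AUC). The
  batched solver matches sklearn's LogisticRegression to within an
  occasional single rank-swap of near-tied pooled scores (tested), and
  makes the full 251-lag × 1000-permutation analysis a ~20-s computation
  instead of ~40 minutes of per-fit overhead.

## Synthetic dyads

Each person's stream is AR(1) jitter (φ = 0.9 at 25 Hz, amplitude 0.3 of
the bout scale) plus movement bouts — Poisson events (0.5/s) with
Gamma(2, scale) amplitudes convolved with a 0.5-s half-sine — clipped at
zero. This reproduces the bursty, non-negative, autocorrelated character
of motion energy; it does not attempt realistic kinematics, posture,
faces or speech, so passing tests demonstrate correct *recovery of
injected structure*, not validity on human video.

Coupling is lag-shifted additive mixing: the follower is
(1 − γ)·own + γ·leader(t − lag) + noise. The sign convention is shared
with the coupling module through one constant: positive lag ⇒ the learner
is the driver. Mixing (rather than phase coupling) keeps γ interpretable
and matches a cross-correlation readout: injected lags are recovered as
the profile peak within one lag step for γ ≥ 0.5 (tested over 20 seeds
per lag, including a non-round 2.68-s lag).

Cohorts: per dyad, γ_d = max(0, γ + 0.15·z) — between-dyad spread is
needed for any meaningful outcome regression — with the scaffolding
record's γ raised by `condition_effect` (0.2). Outcome = 1.5 + 10·γ_rec +
ε, post = pre + outcome exactly. Outcome noise σε = 2.7 comes from the
calibration σε = slope·σγ·√(1/c² − 1) with the underlying link c ≈ 0.55,
chosen so that the *measured* nested-CV correlation — which sits
~0.07–0.10 below the population correlation even for an ideal linear
predictor, a known property of pooled leave-one-out Pearson r — lands in
the moderate ≈ 0.45 regime at the 24-dyad design size.

The toy renderer draws one bright square blob per ROI whose per-frame
horizontal displacement is proportional to the series value (scaled so
the largest step stays within the blob, keeping changed-pixel counts
linear in displacement), reflecting off the ROI edges (never crossing
into the other ROI). Round trip render → extract → preprocess recovers
the injected series with rank correlation > 0.9 (tested).

## Problem sizes

Defaults everywhere are the study parameters (25 Hz, 480 s, 30-s/1-s
windows, ±5 s/0.04 s lags, 60-s segments, 100 surrogates, 10000 null
resamples, 1000 label permutations, 24 dyads). The validation
experiments use smaller replicate counts chosen as the package's own
desk-scale designs: 200 null cohorts of 4 dyads (full 8-min series — see
the segment-count caveat above) with 16 surrogates and 500 resamples for
type-I calibration; 50 null cohorts of 8 dyads, 2-min series, a 51-lag
grid and 100 permutations for decoder null calibration; 50 cohorts of 24
dyads for mixed-model recovery; 20 cohorts of 24 dyads at full duration
for the SVR experiment; 20 seeds × 3 lags for lag recovery.

## Known limitations

* The generator's γ → measured-coupling map is monotone but nonlinear
  and has no closed form; effect-recovery checks on *measured* coupling
  are therefore directional (sign/ordering), while exact-magnitude
  recovery is checked on the outcome, where the injected effect is
  analytic (slope × condition effect).
* Pooled leave-one-out Pearson r is a biased estimator of predictive
  correlation and can go strongly negative on null data; treat small
  values as noise, not as weak-but-real prediction.
* MP4 decoding requires an ffmpeg-backed imageio plugin; TIFF stacks and
  in-memory frame streams are always available.
* Fixed ROIs cannot track people who move across the frame; this is a
  property of the motion-energy method itself.
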