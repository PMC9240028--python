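# btbc — body-to-body coupling in instructor–learner dyads

`btbc` quantifies how much two interacting people's body movements are
coupled in time, from video alone, and links that coupling to experimental
conditions and outcomes. It is aimed at researchers studying nonverbal
coordination in dyadic interaction — instruction and learning, psychotherapy,
collaborative tasks — who record two seated people with a fixed camera and
want a tested, scriptable pipeline instead of ad-hoc notebooks.

## The method

1. **Motion energy.** For each person's fixed rectangular ROI, motion
   energy is the number of pixels whose grayscale value changes by more
   than a threshold between consecutive frames — a sequence *m(t)* at the
   video frame rate (25 Hz typical), no markers or pose estimation needed.
2. **Preprocessing.** 0.5-s moving average; values above mean + 10 SD
   interpolated; z-scoring.
3. **Body-to-body coupling (BtBC).** With standardized series *x* (instructor)
   and *y* (learner), for 30-s windows advancing in 1-s steps and lags
   ℓ ∈ [−5 s, +5 s] in 0.04-s steps (251 lags):

   BtBC(ℓ) = mean over windows *t* of | atanh r( y[t, t+W), x[t+ℓ, t+ℓ+W) ) |

   Positive lags mean the learner's motion occurs earlier (learner leads).
   *Overall* BtBC averages all lags; learner-leading / instructor-leading
   BtBC average the positive / negative half.
4. **Chance level.** Surrogate dyads re-pair 60-s segments that never
   co-occurred (segment-order permutation of one partner); a group
   permutation test compares genuine mean BtBC against resampled
   pseudo-couplings.
5. **Inference.** Mixed-effects condition contrasts (random intercept per
   dyad), nested-CV linear SVR predicting the learning outcome from
   overall BtBC, and per-lag logistic decoding of the instructional
   approach with permutation p-values and Benjamini–Hochberg FDR across
   the 251 lags.

A synthetic dyad generator (coupled AR-plus-burst streams with a known
coupling strength γ, lag, condition effect and outcome link, plus a toy
video renderer) makes the whole pipeline runnable and testable with no
external data.

## Worked example

```python
import numpy as np
from btbc import SimulationConfig, generate_dyad_series, DyadCoupling

cfg = SimulationConfig(duration=480.0, coupling_strength=0.6,
                       coupling_lag=2.0, n_dyads=2)
instructor, learner = generate_dyad_series(cfg, seed=7)

res = DyadCoupling(instructor, learner, dyad_id="d01",
                   condition="scaffolding").fit()
print(res.summary())
test = res.surrogate_test(n=100, segment=60.0, seed=7)
print(f"surrogate mean {test.null_values.mean():.4f}, p = {test.p:.4g}")
```

```
Body-to-Body Coupling (windowed lagged cross-correlation)
==========================================================
dyad: d01    condition: scaffolding
window 30 s, step 1 s, lags ±5 s in 0.04-s steps (251 lags)
----------------------------------------------------------
overall BtBC                0.1628
learner-leading BtBC        0.2213
instructor-leading BtBC     0.1048
zero-lag BtBC               0.0911
peak lag                     +2.00 s (learner leads)
surrogate mean 0.1116, p = 0.009901
```

Reading it: the injected γ = 0.6 coupling at +2 s shows up as a profile
peak exactly at +2.00 s; learner-leading coupling (0.22) dominates
instructor-leading (0.10) because the learner drives the interaction; and
the genuine overall coupling (0.163) sits well above its own segment-shuffled
chance level (0.112), with the add-one permutation p at its floor of 1/101.

The same stages run from the shell: `btbc simulate`, `btbc mea` (video →
motion series), `btbc preprocess`, `btbc btbc`, `btbc surrogate`,
`btbc permtest`, `btbc model`, `btbc predict`, `btbc decode`, or
`btbc run-all --config pipeline.yaml` for the full bundle with a manifest
of parameters, seeds and checksums.

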