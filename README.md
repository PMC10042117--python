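# pulsepop

Analysis pipeline for pulse-based motion direction discrimination with
simultaneously recorded cortical ensembles (e.g., macaque area MT).

## The problem

In the task this package analyzes, a subject watches seven consecutive
150 ms motion pulses (1050 ms total). The strength of pulse *i* is a
signed count of coherently drifting "signal" elements, drawn from
N(&mu;<sub>k</sub>, s) and rounded; the subject reports net direction with
a saccade. Three session regimes manipulate the *temporal* profile of
expected motion strength — flat, late (logistic ramp up), early (its time
reversal) — shifting when in the trial the subject weights the evidence.
Sessions include repeated zero-sum "frozen noise" trials for
choice-conditioned analyses with the stimulus held fixed.

Given trial tables, pulse strengths, and spike times from a recorded
population, `pulsepop` answers, with ground-truth-validated estimators:

* **Behavior** — the psychometric function
  p(x) = &gamma; + (1&minus;2&gamma;) / (1 + e<sup>&minus;&beta;(x&minus;&alpha;)</sup>)
  by maximum likelihood, and the 7-weight psychophysical kernel **w**
  (ridge logistic regression of choice on per-pulse strengths, ridge set
  by evidence optimization) summarizing *when* evidence drives choices.
* **Population decoding** — logistic-regression readouts of direction
  (non-frozen trials) or choice (frozen trials only) from trial spike
  counts; the weighted projection of binned rates yields time-resolved
  choice probability (CP), the ROC area between choice-conditioned
  responses.
* **Latent factors** — a GP-Poisson factor model
  y<sub>t</sub> ~ Poisson(exp(A x<sub>t</sub> + b)), with squared-
  exponential GP priors per latent dimension, fit by variational EM with
  a provably non-decreasing evidence lower bound; dimensionality by
  leave-one-neuron-out cross-validation; factors rotated (SVD of the PTA
  regression weights) so dimension 1 is the stimulus axis.
* **Pulse-triggered average (PTA)** — the population response change per
  unit-strength pulse at each pulse position, via 28-column raised-cosine
  ridge regression with GCV, smoothed, peak-normalized, and summarized by
  an exponential fit a&middot;e<sup>b&middot;i</sup> across pulse index.
* **Choice mapping** — stimulus-residualized, cross-validated logistic
  decoding of choice from latent factors on low-coherence "weak" trials;
  the sigmoid mapping c = 1/(1 + e<sup>&minus;&beta;&#8348;r&minus;&beta;&#8320;</sup>)
  is evaluated only on held-out folds, and CP is the fold-stratified ROC
  area — guaranteed not to overestimate choice information.

Because no public recordings exist for this paradigm, the `synth` module
generates full sessions with known ground truth (observer kernel,
stimulus gain time course, injected choice-correlated latent), and every
estimator is validated by parameter recovery against it.

## Worked example

```python
import numpy as np
from pulsepop import synth, behavior, popdecode, pta

pop = synth.PopulationSpec(n_units=20, gain_profile=synth.decaying_gain)
bundle = synth.simulate_session(500, "flat", pop=pop, rng=3,
                                spike_window="stimulus")

pulses = bundle.pulse_matrix()
choices = bundle.trials["choice"].to_numpy()
kernel = behavior.fit_temporal_kernel(pulses, choices)
print("kernel slope:", round(kernel.slope_linear_fit, 3))

decoder = popdecode.fit_direction_decoder(bundle)
proj = popdecode.project_rates(decoder, bundle)
design = pta.build_design(pulses, resolution_ms=10)
resp = pta.upsample_response(proj.values, 10, 1200, 10)
result = pta.fit_pta(resp, design)
peaks = result.normalized_curves.max(axis=1)[:, 0]
fit = pta.fit_exponential(peaks)
print("normalized PTA peaks:", np.round(peaks, 2))
print("exp fit b:", round(fit.b, 3), "R2:", round(fit.r_squared, 2))
```

prints

```
kernel slope: -0.099
normalized PTA peaks: [1.   0.94 0.75 0.81 0.83 0.5  0.55]
exp fit b: -0.099 R2: 0.78
```

The negative kernel slope says this simulated observer weights early
pulses most; the PTA peaks fall off across the seven pulse positions and
are reasonably described by an exponential decay (b &asymp; &minus;0.1,
R&sup2; &asymp; 0.8 at this single-session size), recovering the decaying
stimulus gain the session was generated with.

A thin CLI mirrors the main stages:

```bash
pulsepop simulate --n-trials 200 --n-units 15 --seed 1 --out session/
pulsepop behavior --session-dir session/ --out behavior.json
pulsepop decode --session-dir session/ --target direction --out dir.json
pulsepop report --seed 1 --out pipeline_out/
```

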