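# Methods

This note documents the models, estimators, numerical choices and known
limitations of `pulsepop`.

## Stimulus model

A trial is seven 150 ms motion pulses; pulse *i* carries a signed signal-
element count drawn from N(&mu;<sub>k</sub>, s), rounded to the nearest
integer and clipped to &plusmn;19 (a 19-element display cannot show more
signal elements than elements). The per-pulse mean follows the session's
condition:

* **flat** — constant &mu;<sub>k</sub>;
* **late** — the logistic L(i) = 1/(1 + e^(−slope·(i−midpoint))) with
  midpoint 4 (pulses) and slope 0.3, affinely rescaled so the pulse-1
  mean is exactly 0 and the pulse-7 mean exactly &mu;<sub>k</sub>. The
  raw logistic does not reach 0/1 at the endpoints; the endpoint values
  are the defining property of the schedule, so the rescaled form is
  used and `early` is its exact time reversal.

Defaults not fixed by the task description: per-pulse s.d. s = 1.5
signal elements and trial-type means {−3, −1, 0, +1, +3}, spanning weak
to strong motion on a 19-element display; trial types are assigned
uniformly i.i.d. Frozen-noise trials (default 5% of a session) repeat a
single session-level zero-sum sequence, generated by drawing a zero-mean
sequence and absorbing the rounding residual one element at a time
across pulses.

## Synthetic sessions and what they do (not) emulate

Choices come from a logistic observer,
P(choice=1) = &gamma; + (1−2&gamma;)·&sigma;(b + w&middot;s), with a
configurable 7-weight kernel. Spikes come from an inhomogeneous Poisson
population with exponential link:

log r&#8345;(t) = log baseline&#8345; + gain&#8345;·g(t)·drive(t−50 ms) +
loading&#8345;·(2·choice−1)·c(t)

where `drive` holds the active pulse value, g(t) is the dimensionless
stimulus-gain profile (the PTA ground truth), and c(t) a shared rank-1
choice latent (the CP ground truth). Defaults: baselines uniform on
[5, 30] spikes/s; direction-gain magnitudes N(0.06, 0.02) per signal
element, chosen so empirical per-unit d&prime; spans ~0.2–1.5, the range
typical of direction-selective MT units; a 50 ms response latency keeps
the pulse response inside the 0–250 ms PTA basis support; reaction times
lognormal with median 0.29 s; reward 0.3 s after the saccade so the
"target onset to reward" fitting window is well defined. Event jitters
(fixation offset 0.5–1.0 s after motion offset, targets 0.5–1.0 s before
motion onset) are uniform.

For choice analyses at the factor level, `simulate_factor_session`
generates latent trajectories directly (stimulus axis = pulse drive +
smooth noise; choice latent in the non-stimulus dimensions through a
random unit-norm loading). Its default choice amplitude (0.2) was
calibrated so delay-period CP lands at ~0.7–0.8, the magnitude regime
reported for this paradigm, before any pass/fail threshold was evaluated.

The simulator deliberately omits refractoriness, adaptation dynamics,
spike-count correlations beyond the shared latent, and eye-movement
artifacts. Passing recovery tests therefore shows the estimators are
correct under the model's assumptions, not that real recordings satisfy
those assumptions.

## Behavioral fits

The psychometric function is fit by L-BFGS-B on the exact negative
log-likelihood with analytic gradients, three starts, lapse bounded in
[0, 0.25] (configurable) for stability; standard errors are the square
root of the diagonal of the inverse of a central-difference Hessian of
the negative log-likelihood at the MLE.

The temporal kernel maximizes the Bernoulli log-likelihood of choices
given the 7 pulse strengths plus an intercept, minus
&lambda;‖w‖&sup2; on the pulse weights (the intercept is unpenalized —
penalizing it would shrink the bias toward zero for no statistical
benefit). &lambda; is chosen by empirical Bayes: the Laplace-approximated
log marginal likelihood is maximized over a 25-point log grid spanning
10&#8315;&sup3;–10&#8308;, then refined on a 9-point local grid. Reported
summaries: raw weights, unit-norm weights, and the OLS slope of the
normalized weights over pulse index (negative = early weighting).
Permutation nulls (choices shuffled, refit at the data's &lambda;)
provide bands for the slope and for the maximum absolute weight (a
family-wise band; per-weight 95% bands would produce false positives at
a ~30% family rate).

## Population decoding and CP

Spike counts are summed over [0, 1.2) s from stimulus onset (half-open,
as are all windows). The direction decoder trains on non-frozen trials
with nonzero pulse sum; the choice decoder trains only on frozen trials.
Counts are standardized per unit and fit with a small ridge
(&lambda; = 10&#8315;&#8308;) that stabilizes separable or ill-posed
fits (frozen trials are few relative to units); weights are mapped back
to the raw-count scale. Projections apply the weights (no intercept —
it shifts both choice-conditioned distributions equally and cannot
change an ROC) to 10 ms binned rates smoothed with a centered 50 ms
boxcar, edge-truncated and renormalized so constants are preserved.
ROC areas use the rank formulation of the Mann–Whitney statistic with
ties counted 1/2; time bins where one choice class is empty yield NaN
rather than a fabricated 0.5.

## Latent factor model

Counts binned at 10 ms over the target-onset-to-reward window are
modeled as y<sub>t</sub> ~ Poisson(exp(A x<sub>t</sub> + b)) with
independent squared-exponential GP priors per latent dimension (fixed
lengthscale 100 ms, unit variance, jitter 10&#8315;&#8310;; the loading
scale absorbs amplitude, so learning the GP variance would only
re-parameterize the same model). The variational posterior is Gaussian
per trial and dimension; its covariance is parameterized as
(K&#8315;&sup1; + diag(&omega;))&#8315;&sup1;, which is the exact form of
the stationary point, keeps memory linear in trial length, and makes the
KL and marginal variances cheap via one Cholesky per trial/dimension.

Fitting is coordinate ascent on the ELBO: damped Newton updates of each
posterior mean (the per-trial objective is concave), fixed-point updates
of &omega; accepted only when the trial ELBO does not decrease, and
per-unit Newton updates of loadings/biases with backtracking and a small
L2 penalty (10&#8315;&sup3;) on A for identifiability. Every accepted
step is a non-decreasing move on the ELBO, so the trace is monotone by
construction (tolerance 10&#8315;&#8312;). Initialization: PCA of
square-root-transformed, lightly smoothed counts, slightly perturbed;
two restarts by default, best final ELBO wins. Convergence: relative
ELBO change < 10&#8315;&#8310; or the iteration cap.

Dimensionality is selected by leave-one-neuron-out cross-validation: for
each candidate K, latents are re-inferred with each unit excluded and
that unit's counts scored under its fitted loading (Poisson
log-likelihood including the variance correction); ties break toward
smaller K. The SVD rotation of the PTA weight matrix
(W&#8314; = USV&#8314;, factors &rarr; U&#8314;x) concentrates stimulus
signal in dimension 1; a `rotated` flag guards double application, and
the stimulus-axis sign is aligned with the d&prime;-weighted loadings
when d&prime; is supplied.

## Pulse-triggered average

Each pulse contributes four raised-cosine bases
(1 − cos(2&pi;t/100 ms))/2 starting 0/50/100/150 ms after pulse onset
(100 ms support each; the exact cosine form is not prescribed —
raised cosines tile smoothly and are the field's standard temporal
basis). Trials are concatenated on a uniform grid (1 ms nominal; the
estimator is resolution-agnostic and tests run at 10 ms, which is
lossless for a response already carried on 10 ms bins). The response is
centered per time bin across trials before regression: pulse strengths
average ~0 across trials, so removing the common PSTH is unbiased and
suppresses a large noise term. Ridge weights use the SVD form; GCV
minimizes ‖(I−H)X‖&sup2;/(T(1−tr H/T))&sup2; over a log grid
(10&#8315;&sup2;–10&#8310;), with edge selections flagged.

Reconstructed unit-strength curves are smoothed with a Gaussian of 40 ms
width read as FWHM (&sigma; &asymp; 17 ms) — smoothing precedes
normalization — then peak-normalized per dimension; each dimension's
sign is set so its dominant response is positive. The per-pulse peak is
the maximum of the smoothed curve within [0, 250] ms of pulse onset, and
a·e^(b·i) is fit to the seven peaks by nonlinear least squares with a
log-linear fallback. Single-session peak estimates at 500 trials/20
units carry Monte-Carlo s.d. ~0.05–0.08 per (normalized) peak; recovery
checks therefore average normalized peaks over three sessions, matching
the standard practice of reporting across-session mean PTAs.

## Choice mapping

Weak trials are the largest prefix of |pulse-sum| levels, starting at
zero, whose pooled accuracy stays below 65%; sessions with fewer than
100 weak trials are flagged excluded. Factors are rebinned to 100 ms
(sums; trailing partial bins dropped) and the per-bin linear pulse
contribution removed by ridge regression with one GCV-chosen strength
shared across bins (both sides centered, so zero-pulse designs reduce to
centering). The choice decoder is an L2-penalized logistic model on
window-summed residuals; its penalty comes from a 13-point log grid
(10&#8315;&#8308;–10&sup2;) by stratified five-fold cross-validated
log-likelihood, per session. Mapping values c are produced only by
decoders that never saw the trial.

CP is the **fold-stratified** ROC area: per-fold AUCs averaged with
pair-count weights. Pooling all out-of-fold c values into a single ROC
is measurably pessimistic (~0.488 under the null at 100 trials — each
fold's decoder shifts its test scores jointly, and cross-fold score
comparisons are incoherent); the stratified estimator is unbiased at 0.5
under the null while keeping the guarantee that choice information is
never overestimated. Fixed readout fits the decoder once on an epoch
(stimulus period, or −0.5–0 s before the saccade) and applies each
fold's weights per 100 ms bin; dynamic readout refits per bin. The RT
median split assigns ties to the lower half and requires enough trials
per half for five folds. CP time courses live on the 100 ms residual
grid; optional boxcar smoothing is display-level only.

Open choices resolved as defaults (flags provided): residualization
weights are fit on weak trials only; residualization is applied
uniformly including post-stimulus windows; kernel fitting does not
z-score pulse strengths.

## Problem sizes

Recovery and calibration checks run at sizes chosen to make each
property measurable with margin rather than to mirror the original
dataset: 5,000 trials for kernel recovery, 20,000 × 20 seeds for
psychometric recovery, three 500-trial/20-unit sessions for PTA
recovery, 200 sessions of 200 trials for CP null calibration, and
GP-Poisson sessions of 40–50 trials, 10–12 units, 0.4–0.5 s windows for
latent-model recovery and leave-one-neuron-out selection.

## Known limitations

* The generative model is an artifact-level assumption; the original
  study provides no generative account of its neural data.
* GP hyperparameters are fixed, not learned; inter-trial dependence is
  ignored (each trial has an independent GP draw).
* The choice latent is rank-1 by default; higher-rank choice structure
  is configurable but untested beyond rank 1.
* Dynamic-readout CP needs every 100 ms window to support balanced
  five-fold splits; sparse windows yield NaN.
* The exponential PTA summary is descriptive; it is the wrong model for
  non-monotone (U-shaped) gain profiles by design, and its R&sup2; is
  the misfit diagnostic.
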