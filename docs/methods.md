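# Methods

## Model

`neuralcox` estimates the Cox proportional-hazards log-risk function
with a feed-forward neural network. The hazard of patient `x` is
assumed to factor as

    lambda(t | x) = lambda0(t) * exp(h(x)),

where `lambda0` is an unspecified baseline hazard shared by all
patients and `h` is the log-risk. The classical linear model takes
`h(x) = beta' x`; the network replaces it with `h_theta(x)`, a stack of
fully connected layers (SELU or ReLU activation, each followed by
dropout) ending in a single linear output node.

Both models are fitted by maximizing the Cox partial likelihood. For a
record `i` with an observed event at time `T_i`, the likelihood term is
its relative risk within the risk set `R(T_i) = {j : T_j >= T_i}`; the
baseline hazard cancels. The network's training loss is the average
negative log partial likelihood plus a ridge penalty on the connection
weights:

    l(theta) = -(1/N_events) * sum_{i: E_i = 1}
               [ h_i - log sum_{j in R(T_i)} exp(h_j) ]
               + lambda * sum ||W||^2.

Tied event times use the Breslow convention (tied events keep each
other in the denominator) in both the network loss and the linear
baseline, so the two optimize the same objective family. The log-risk
is identifiable only up to an additive constant; comparisons against a
ground truth therefore mean-center both vectors first (`log_risk_mse`
exposes both conventions).

### Training

Training is full batch: the risk-set denominator spans the entire
training set, so minibatching would silently change the objective. The
cohort sizes involved (n <= 4000) make this cheap in numpy; gradients
are computed by reverse-mode differentiation written out by hand, and
the loss/gradient evaluation sorts by time once and uses a running
log-sum-exp over the cumulative risk set for numerical stability (the
gradient is verified against central finite differences in the test
suite).

Optimizers: SGD with Nesterov momentum, or Adam (the preset's momentum
column maps to Adam's first-moment constant beta1; beta2 = 0.999). The
learning rate follows inverse time decay, `LR / (1 + epoch *
lr_decay)`. Weights use variance-scaling initialization (LeCun-normal
for SELU, He-normal for ReLU); dropout is standard (inverted) dropout,
disabled at inference, so prediction is deterministic. The l2 penalty
applies to connection weights only, never biases.

The validation concordance index is evaluated every epoch and the
returned model carries the weights of the best epoch. The default
budget is 2000 epochs with no early stopping; a training run on the
standard 4000-record cohort takes ~10-30 s on one CPU. With the
shipped presets' l2 coefficients the penalty gradually shrinks the
weights over training, so the best-validation epoch typically occurs
well before the final epoch; best-epoch selection is what makes those
presets usable as published.

A zero-hidden-layer configuration (`n_layers=0`) is allowed and reduces
the network to a gradient-descent linear Cox fit; the test suite checks
it matches the Newton-Raphson baseline to within 0.005 C-index.

### Linear baseline

`fit_linear_cph` maximizes the (optionally ridge-penalized) Breslow log
partial likelihood by Newton-Raphson with step-halving, standardizing
covariates internally for conditioning and reporting coefficients on
the original scale (the penalty is also defined on the original scale).
Monotone-likelihood separation is detected as a diverging coefficient
norm and raised as an error naming the covariate. Constant columns are
dropped with a warning and reported as zero coefficients.

## Evaluation statistics

* **Concordance index** (Harrell): over directed comparable pairs —
  record `i` has an event and `time_i < time_j`, or `time_i == time_j`
  with two events (both directions) or with `j` censored (event first)
  — score 1 if `risk_i > risk_j`, 0.5 on a risk tie. Equal to exhaustive
  pair enumeration by construction (property-tested), and to lifelines
  on tie-free data.
* **Kaplan-Meier**: product-limit estimate with Greenwood variance and
  a log-transformed pointwise band (bounded within [0, 1]); the median
  is the first event time with `S(t) <= 0.5`, with an explicit
  "not reached" sentinel.
* **Log-rank test**: unweighted two-sample test, hypergeometric
  expectation and variance accumulated per distinct event time,
  chi-squared with 1 df.
* **Bootstrap**: percentile intervals from resampling records with
  replacement; the point estimate is computed on the full sample, the
  seed is a required argument, and degenerate resamples (no comparable
  pairs) are redrawn with a warning up to a retry cap.

## Simulator

Cohorts are generated from the exponential proportional-hazards model:
covariates uniform on [-1, 1)^d (d = 10 by default), latent draw
`u ~ Exp(mean 5)`, event time `T = u / exp(h(x))`. Only the first two
covariates ever enter `h`; the rest are noise, so variable selection is
testable. Log-risk forms:

* linear: `h(x) = x0 + 2*x1`
* gaussian: `h(x) = log(lambda_max) * exp(-(x0^2+x1^2) / (2 r^2))`
* constant: `h = 0`

With a treatment arm, `tau ~ Bernoulli(1/2)` and `T = u / exp(tau *
h(x))`: controls are unaffected by the covariates, treated patients
carry the full (Gaussian) effect, so the benefit of treatment depends
on the patient's position relative to the bump.

Censoring emulates a fixed end of study: the threshold `T0` is the
empirical `observed_fraction` quantile of the cohort's own event times
(not an analytic quantile), so the requested share of records has an
observed event up to binomial noise. The standard experiments use
4000/1000/1000 train/validation/test cohorts. The linear and nonlinear
experiments censor at the 50% quantile. The treatment experiment uses
90% observed events: with the end of study at the median, the
better-surviving (recommendation-concordant) half of a cohort can never
reach survival 0.5 before `T0`, so its median would be structurally
unobservable; the lighter censoring makes both subset medians finite,
which matches the reference results this package reproduces.

What the simulator does *not* emulate: covariate correlation,
non-exponential event-time families (no Weibull), informative
censoring, and measurement noise on covariates. Passing the simulated
checks therefore demonstrates correctness of the estimators under the
proportional-hazards generating model, not robustness on real clinical
data.

### Ranking ceilings

Because the generator is known, the C-index of the *true* log-risk on a
test cohort upper-bounds any fitted model in expectation. Under the
formulas above the ceilings are roughly 0.78 (linear), 0.61 (gaussian,
lambda_max = 5) and 0.65 (treatment, lambda_max = 10, 90% observed).
The gaussian ceiling is low because `|h|` never exceeds `log 5 = 1.61`
and the pairwise win probability is `sigmoid(|h_i - h_j|)`; reference
C-index values above such a ceiling cannot be reproduced by any
implementation of these formulas; the acceptance suite reports the
shortfall honestly rather than hiding it.

## Treatment recommender

For a model trained with the arm label as an input column, the
recommender function is the log hazard ratio between prescribing `i`
versus `j` to the same patient:

    rec_ij(x) = h(x, tau=i) - h(x, tau=j),

computed as two forward passes with the treatment input overwritten.
Positive values recommend `j`, negative recommend `i`; an exact tie
keeps the patient's actual arm (and counts as concordant), which makes
the degenerate constant-model case well defined. For a linear Cox model
with treatment coefficient beta0 the function collapses to the constant
`beta0 * (i - j)` — the model recommends the same arm to everyone — and
the test suite asserts this identity at machine precision. More than
two arms are handled by an argmin over per-arm predicted log-risks.

Evaluation splits a cohort into the Recommendation subset (actual arm
equals recommended arm) and the Anti-Recommendation subset and compares
them by Kaplan-Meier curves, median survival and the log-rank test.

## Hyper-parameter search

`random_search` draws configurations from a scrambled Sobol sequence
over declared ranges (log-uniform for scale parameters) and scores each
by k-fold cross-validation (k = 3 by default): train on k-1 folds with
the held-out fold as the validation set, score the best validation
C-index, average over folds. Folds are shared across trials (paired
comparisons) and re-drawn if a fold lacks events. The shipped default
space brackets the preset values by roughly a factor of ten each way.
The per-fold epoch budget defaults to 250 — a search is a screening
pass, not a final fit.

## Presets

The seven shipped presets (`sim_linear`, `sim_nonlinear`,
`sim_treatment`, `whas`, `support`, `metabric`, `gbsg`) carry the
published per-experiment hyper-parameters verbatim: optimizer,
activation, depth, width, learning rate, l2 coefficient, dropout, LR
decay and momentum. The epoch budget is not part of the published
table; the default of 2000 with best-validation selection is this
package's choice. "sgd" presets use Nesterov momentum with the table's
momentum value; "adam" presets map that value to beta1.

## Numerical choices

* Loss and gradient: stable log-sum-exp over sorted times; tie groups
  share one denominator (Breslow).
* Newton-Raphson: step-halving line search guarantees ascent; a
  singular Hessian falls back to a gradient step; separation threshold
  at coefficient norm 500 on the standardized scale.
* KM band: where S reaches exactly 0 the band collapses to [0, 0];
  alpha outside (0, 1) is rejected.
* Bootstrap seed is mandatory in the library API (the CLI defaults it).
* All randomness flows through `numpy.random.default_rng` seeds; same
  seed implies byte-identical cohorts, training runs and bootstrap
  intervals.

## Known limitations

* Full-batch training limits cohort sizes to what fits in memory
  comfortably (~10^5 records); no minibatch approximation is offered on
  purpose.
* Efron tie handling, stratified baselines, time-varying covariates and
  competing risks are out of scope.
* The centered mean-squared error of the network's log-risk against the
  simulator truth depends strongly on the l2 coefficient: the verbatim
  preset values shrink the output amplitude over training, so ranking
  quality (C-index) is preserved while the amplitude — and hence the
  MSE — is not. Both centered and uncentered MSE are reported for
  transparency, but neither is a tuned quantity.
* Plotting is out of scope; curves export as tables (time, S, band).
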