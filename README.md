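# neuralcox

Nonlinear Cox proportional-hazards modelling for right-censored
survival data, built around a feed-forward neural network that
estimates the Cox log-risk function — together with a linear Cox
baseline, a fully calibrated survival-data simulator with known ground
truth, the survival statistics needed to evaluate such models
(Harrell's concordance index, Kaplan-Meier with confidence bands,
log-rank test, bootstrap intervals), a personalized treatment
recommender, and Sobol random hyper-parameter search.

It is written for biostatisticians and methods researchers who want a
transparent, fully reproducible reference implementation of
neural-network survival regression: every estimator is plain
numpy/scipy, every random quantity is seeded, and the simulator makes
every claim checkable against a known truth.

## The model

The hazard of a patient with covariates *x* is assumed proportional,

    lambda(t | x) = lambda0(t) * exp(h(x)),

and the log-risk *h* is estimated by a configurable feed-forward
network *h<sub>theta</sub>* (fully connected layers, SELU/ReLU + dropout, single
linear output). Training minimizes the average negative log Cox
partial likelihood with an l2 penalty,

    l(theta) = -(1/N_E) * sum_{i: E_i=1} [ h_i - log sum_{j: T_j >= T_i} exp(h_j) ]
               + lambda * ||W||^2,

by full-batch gradient descent (SGD with Nesterov momentum or Adam,
inverse-time learning-rate decay), keeping the weights with the best
validation concordance index. The linear baseline maximizes the same
(Breslow) partial likelihood by Newton-Raphson.

Because each treatment arm can carry its own risk function under a
shared baseline hazard, a model trained with the arm label as an input
yields the per-patient log hazard ratio between prescribing arm *i*
versus *j*,

    rec_ij(x) = h(x, tau=i) - h(x, tau=j),

and recommending the lower-risk arm partitions a cohort into
recommendation-concordant and -discordant subsets whose survival can
be compared. For a linear Cox model this function is constant in *x*
(it recommends the same arm to everyone); the network makes it
genuinely personalized.

See `docs/methods.md` for assumptions, numerical choices and known
limitations.

## Worked example

```python
import neuralcox as nc

train_c, val_c, test_c = nc.experiment_cohorts("linear", seed=1)
cph = nc.fit_linear_cph(train_c.dataset)
net = nc.train(train_c.dataset, val_c.dataset, nc.load_preset("sim_linear", seed=1))

t, e = test_c.dataset.time, test_c.dataset.event
print(nc.concordance_index(t, e, test_c.true_h))                             # ceiling
print(nc.concordance_index(t, e, cph.predict_log_risk(test_c.dataset.covariates)))
print(nc.concordance_index(t, e, net.predict_log_risk(test_c.dataset.covariates)))
```

prints (about a minute on one CPU):

```
0.793   # true log-risk — no model can rank better in expectation
0.792   # linear Cox baseline
0.791   # risk network
```

Both models order ~79 % of comparable patient pairs' failure times
correctly, essentially saturating the information in the data (the
generating log-risk is linear, h(x) = x0 + 2*x1, and the fitted
coefficients come out at (0.955, 1.934)).

The treatment experiment shows the recommender at work
(`python examples/treatment_recommendation.py`):

```
recommendation-concordant patients: 486 / 1000
median survival, Rec subset:      3.415871492055566
median survival, Anti-Rec subset: 1.3979066110564746
log-rank chi2 114.4, p = 1.07e-26
```

Patients whose randomized arm matches the network's recommendation
live more than twice as long at the median; the log-rank test confirms
the two survival curves are separated far beyond chance.

The `examples/` directory has one short script per capability
(linear/nonlinear experiments, treatment recommendation, survival
statistics, hyper-parameter search), each printing what it computes
and what the numbers mean. A thin CLI wraps the same pipelines:

```bash
neuralcox simulate treatment --seed 1 --out data/
neuralcox run linear --seed 1 --out results/
neuralcox recommend results/treatment_seed1_model.json data/treatment_test.csv
neuralcox search data/linear_train.csv --n-trials 10
```

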