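"""Linear simulated experiment: network vs. linear Cox baseline.

Generates cohorts whose event times follow an exponential
proportional-hazards model with the linear log-risk h(x) = x0 + 2*x1
(eight further covariates are pure noise), fits both models on the
training cohort, and scores the held-out test cohort.  Because the
linear assumption holds, both models should reach roughly the same
concordance index — close to the C-index of the true log-risk, which
upper-bounds any model.
"""

import neuralcox as nc

train_c, val_c, test_c = nc.experiment_cohorts("linear", seed=1)

cph = nc.fit_linear_cph(train_c.dataset)
net = nc.train(train_c.dataset, val_c.dataset, nc.load_preset("sim_linear", seed=1))

t, e = test_c.dataset.time, test_c.dataset.event
for name, risk in [
    ("true log-risk (ceiling)", test_c.true_h),
    ("linear CPH", cph.predict_log_risk(test_c.dataset.covariates)),
    ("risk network", net.predict_log_risk(test_c.dataset.covariates)),
]:
    print(f"{name:24s} test C-index {nc.concordance_index(t, e, risk):.3f}")

print(f"\nfitted coefficients on (x0, x1): "
      f"({cph.beta[0]:.3f}, {cph.beta[1]:.3f})  [truth: (1, 2)]")
print("A C-index of ~0.79 means the model orders ~79% of comparable "
      "patient pairs' failure times correctly; 0.5 would be random.")
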