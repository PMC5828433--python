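"""The survival-statistics toolkit on a small simulated cohort.

Demonstrates the Kaplan-Meier estimator with its confidence band, the
median-survival accessor, the two-sample log-rank test, and a bootstrap
confidence interval for the concordance index.
"""

import numpy as np

import neuralcox as nc

cohort = nc.generate(nc.SimSpec(n=400, d=10, risk_form="linear",
                                observed_fraction=0.7, seed=7))
ds = cohort.dataset

km = nc.kaplan_meier(ds.time, ds.event, alpha=0.05)
print(f"Kaplan-Meier: {km.event_times.size} distinct event times, "
      f"S at last event {km.survival[-1]:.3f} "
      f"[{km.ci_lower[-1]:.3f}, {km.ci_upper[-1]:.3f}]")
print(f"median survival: {nc.median_survival(km):.3f} time units")

# split on the strongest covariate: high x1 = high risk = shorter survival
high = ds.covariates[:, 1] > 0
res = nc.logrank_test(ds.subset(high), ds.subset(~high))
print(f"log-rank high-x1 vs low-x1: chi2 {res.statistic:.1f}, p {res.p_value:.2e}")

ci = nc.bootstrap_ci(
    lambda d: nc.concordance_index(d.time, d.event, d.covariates[:, 0] + 2 * d.covariates[:, 1]),
    ds, n_boot=500, level=0.95, seed=1,
)
print(f"C-index of the true risk ranking: {ci.point:.3f} "
      f"(95% bootstrap CI {ci.lower:.3f}-{ci.upper:.3f})")
print("\nSplitting on x1 separates the survival curves sharply because "
      "h(x) = x0 + 2*x1 makes x1 the dominant risk factor.")
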