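"""Survival statistics against brute-force and lifelines oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as ll_logrank
from lifelines.utils import concordance_index as ll_cindex

from neuralcox import (
    NOT_REACHED,
    SurvivalDataset,
    bootstrap_ci,
    concordance_index,
    kaplan_meier,
    logrank_test,
    median_survival,
)

from conftest import random_survival


# --------------------------------------------------------------------------
# concordance index
# --------------------------------------------------------------------------

def cindex_bruteforce(time, event, risk):
    """Exhaustive O(n^2) pair enumeration with the documented tie rules.

    Directed pair (i, j) is comparable when i has an event and failed at
    or before j's observed time (strictly before, or tied with any other
    record).  Written independently of the vectorized implementation.
    """
    num = den = 0.0
    n = len(time)
    for i in range(n):
        if not event[i]:
            continue
        for j in range(n):
            if j == i:
                continue
            if time[i] < time[j] or time[i] == time[j]:
                den += 1
                if risk[i] > risk[j]:
                    num += 1
                elif risk[i] == risk[j]:
                    num += 0.5
    if den == 0:
        raise ValueError("no comparable pairs")
    return num / den


def test_perfect_ranking_gives_one(rng):
    t = np.sort(rng.exponential(1.0, 20))
    risk = -t  # earlier death = higher risk, exact reverse order
    assert concordance_index(t, np.ones(20), risk) == 1.0


def test_constant_risk_gives_half(rng):
    ds = random_survival(rng, 30)
    assert concordance_index(ds.time, ds.event, np.zeros(30)) == 0.5


@pytest.mark.parametrize("n,tie_times,tie_risks", [
    (6, False, False),
    (50, True, False),
    (120, True, True),
    (200, False, True),
])
def test_matches_bruteforce_enumeration(rng, n, tie_times, tie_risks):
    ds = random_survival(rng, n, tie_times=tie_times)
    risk = rng.normal(size=n)
    if tie_risks:
        risk = np.round(risk, 1)
    assert concordance_index(ds.time, ds.event, risk) == pytest.approx(
        cindex_bruteforce(ds.time, ds.event, risk), abs=1e-12
    )


def test_agrees_with_lifelines_on_tie_free_data(rng):
    ds = random_survival(rng, 150)
    risk = rng.normal(size=150)
    ours = concordance_index(ds.time, ds.event, risk)
    # lifelines' convention: higher predicted survival time = concordant
    theirs = ll_cindex(ds.time, -risk, ds.event)
    assert ours == pytest.approx(theirs, abs=1e-12)


@settings(derandomize=True, max_examples=25, deadline=None)
@given(st.integers(0, 10_000), st.floats(0.1, 5.0))
def test_invariant_under_increasing_transform(seed, scale):
    rng = np.random.default_rng(seed)
    ds = random_survival(rng, 40)
    risk = rng.normal(size=40)
    c1 = concordance_index(ds.time, ds.event, risk)
    c2 = concordance_index(ds.time, ds.event, np.exp(scale * risk))
    assert c1 == pytest.approx(c2, abs=1e-12)


def test_sign_flip_maps_c_to_one_minus_c(rng):
    ds = random_survival(rng, 60)
    risk = rng.normal(size=60)  # continuous, ties have probability zero
    c = concordance_index(ds.time, ds.event, risk)
    assert concordance_index(ds.time, ds.event, -risk) == pytest.approx(1 - c)


def test_no_comparable_pairs_raises():
    with pytest.raises(ValueError, match="comparable"):
        concordance_index([1.0, 2.0], [0, 0], [0.5, 0.3])


# --------------------------------------------------------------------------
# Kaplan-Meier and median survival
# --------------------------------------------------------------------------

def test_km_no_censoring_is_empirical_survival():
    km = kaplan_meier([1.0, 2.0, 3.0, 4.0], [1, 1, 1, 1])
    assert np.allclose(km.survival, [0.75, 0.5, 0.25, 0.0])


def test_km_all_censored_is_flat_one():
    km = kaplan_meier([1.0, 2.0, 3.0], [0, 0, 0])
    assert km.survival_at(0.0) == 1.0
    assert km.survival_at(100.0) == 1.0
    assert median_survival(km) == NOT_REACHED


def test_km_hand_computed_product_limit_table():
    # 10 records, interleaved censoring; product-limit by hand:
    # t=1: 1 event /10 at risk -> 0.9
    # t=2: censored only
    # t=3: 2 events /8  -> 0.9 * 6/8 = 0.675
    # t=4: censored
    # t=5: 1 event /5   -> 0.675 * 4/5 = 0.54
    # t=7: 1 event /3   -> 0.54 * 2/3 = 0.36
    # t=9: censored x2
    time = [1, 2, 3, 3, 4, 5, 5, 7, 9, 9]
    event = [1, 0, 1, 1, 0, 1, 0, 1, 0, 0]
    km = kaplan_meier(time, event)
    assert np.allclose(km.event_times, [1, 3, 5, 7])
    assert np.allclose(km.survival, [0.9, 0.675, 0.54, 0.36])
    assert np.array_equal(km.n_at_risk, [10, 8, 5, 3])


def test_km_matches_lifelines_survival(rng):
    ds = random_survival(rng, 80, tie_times=True)
    km = kaplan_meier(ds.time, ds.event)
    kmf = KaplanMeierFitter().fit(ds.time, ds.event)
    theirs = kmf.survival_function_at_times(km.event_times).to_numpy()
    assert np.allclose(km.survival, theirs)


def test_km_band_brackets_curve_and_is_monotone(rng):
    ds = random_survival(rng, 60, tie_times=True)
    km = kaplan_meier(ds.time, ds.event, alpha=0.05)
    assert np.all(km.ci_lower <= km.survival + 1e-12)
    assert np.all(km.survival <= km.ci_upper + 1e-12)
    assert np.all((km.ci_lower >= 0) & (km.ci_upper <= 1))
    assert np.all(np.diff(km.survival) <= 1e-12)  # non-increasing
    wide = kaplan_meier(ds.time, ds.event, alpha=0.01)
    assert np.all(wide.ci_upper >= km.ci_upper - 1e-12)


def test_km_rejects_bad_alpha():
    with pytest.raises(ValueError, match="alpha"):
        kaplan_meier([1.0], [1], alpha=1.5)


def test_median_survival_first_crossing():
    km = kaplan_meier([1.0, 2.0, 3.0, 4.0], [1, 1, 1, 1])
    # S = .75, .5, .25, 0 -> first time with S <= 0.5 is t=2
    assert median_survival(km) == 2.0


# --------------------------------------------------------------------------
# log-rank test
# --------------------------------------------------------------------------

def _ds(time, event):
    return SurvivalDataset(covariates=np.zeros((len(time), 1)),
                           time=time, event=event)


def test_logrank_identical_groups_is_null(toy6):
    res = logrank_test(toy6, toy6)
    assert res.statistic == pytest.approx(0.0, abs=1e-12)
    assert res.p_value == pytest.approx(1.0)


def test_logrank_hand_computed_two_groups():
    # Two 8-record groups; O/E/V accumulated per event time by hand below.
    ta, ea = [1, 2, 4, 4, 6, 7, 9, 12], [1, 1, 1, 0, 1, 0, 1, 0]
    tb, eb = [3, 5, 5, 8, 10, 11, 13, 15], [1, 1, 1, 1, 0, 1, 1, 0]
    time = np.array(ta + tb, float)
    event = np.array(ea + eb)
    in_a = np.array([1] * 8 + [0] * 8, bool)
    o_minus_e = var = 0.0
    for t in sorted(set(time[event == 1])):
        at = time >= t
        n, na = at.sum(), (at & in_a).sum()
        d = ((time == t) & (event == 1)).sum()
        da = ((time == t) & (event == 1) & in_a).sum()
        o_minus_e += da - d * na / n
        var += d * (na / n) * (1 - na / n) * (n - d) / (n - 1)
    expected = o_minus_e**2 / var

    res = logrank_test(_ds(ta, ea), _ds(tb, eb))
    assert res.statistic == pytest.approx(expected, rel=1e-12)

    theirs = ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    assert res.statistic == pytest.approx(theirs.test_statistic, rel=1e-9)
    assert res.p_value == pytest.approx(theirs.p_value, rel=1e-9)


def test_logrank_symmetric_in_group_labels(rng):
    a = random_survival(rng, 25, tie_times=True)
    b = random_survival(rng, 35, tie_times=True)
    r1 = logrank_test(a, b)
    r2 = logrank_test(b, a)
    assert r1.statistic == pytest.approx(r2.statistic, rel=1e-12)


def test_logrank_detects_separated_groups(rng):
    t = rng.exponential(1.0, 50)
    a = _ds(t, np.ones(50, int))
    b = _ds(2 * t, np.ones(50, int))
    res = logrank_test(a, b)
    assert res.statistic > 0
    assert res.p_value < 1.0


def test_logrank_requires_pooled_events():
    with pytest.raises(ValueError, match="event"):
        logrank_test(_ds([1.0], [0]), _ds([2.0], [0]))


# --------------------------------------------------------------------------
# bootstrap
# --------------------------------------------------------------------------

def test_bootstrap_constant_statistic_collapses(toy6):
    ci = bootstrap_ci(lambda ds: 3.25, toy6, n_boot=50, level=0.95, seed=1)
    assert ci.lower == ci.point == ci.upper == 3.25


def test_bootstrap_deterministic_given_seed(toy6):
    def stat(ds):
        return float(np.mean(ds.time * (1 + ds.event)))

    a = bootstrap_ci(stat, toy6, n_boot=200, level=0.9, seed=7)
    b = bootstrap_ci(stat, toy6, n_boot=200, level=0.9, seed=7)
    assert (a.lower, a.upper) == (b.lower, b.upper)
    c = bootstrap_ci(stat, toy6, n_boot=200, level=0.9, seed=8)
    assert (a.lower, a.upper) != (c.lower, c.upper)


def test_bootstrap_interval_brackets_point(rng):
    ds = random_survival(rng, 100)
    risk = ds.covariates[:, 0]

    def stat(d):
        return concordance_index(d.time, d.event, d.covariates[:, 0])

    ci = bootstrap_ci(stat, ds, n_boot=200, level=0.95, seed=3)
    assert ci.lower <= ci.point <= ci.upper


def test_bootstrap_requires_seed(toy6):
    with pytest.raises(ValueError, match="seed"):
        bootstrap_ci(lambda ds: 0.0, toy6, n_boot=10, level=0.95, seed=None)
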