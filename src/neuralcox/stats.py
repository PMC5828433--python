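"""Survival statistics: concordance index, Kaplan-Meier, log-rank, bootstrap.

Tie conventions (shared by the concordance index and the product-limit
estimator, in the sense that both treat records with equal observed time
as simultaneous):

* A directed pair (i, j) is *comparable* when record i has an observed
  event and either ``time_i < time_j``, or ``time_i == time_j`` with j a
  different record (two events at the same time are comparable in both
  directions; an event tied with a censoring time counts the event as
  having failed first).
* A comparable pair scores 1 when the earlier-failing record has the
  strictly larger risk, 0.5 on a risk tie, 0 otherwise; the concordance
  index is the mean score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import stats as sps

from .data import SurvivalDataset

__all__ = [
    "concordance_index",
    "comparable_pairs",
    "KaplanMeierCurve",
    "kaplan_meier",
    "median_survival",
    "NOT_REACHED",
    "LogRankResult",
    "logrank_test",
    "BootstrapCI",
    "bootstrap_ci",
]

#: Sentinel returned by :func:`median_survival` when S(t) never reaches 0.5.
NOT_REACHED = "not reached"


def comparable_pairs(time: np.ndarray, event: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices (i, j) of all directed comparable pairs.

    Record i failed (event observed) no later than record j was last seen,
    so a risk model should rank i above j.  Precomputing the pairs lets a
    training loop re-score the same validation set cheaply each epoch.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(bool)
    n = time.shape[0]
    lt = time[:, None] < time[None, :]
    eq = time[:, None] == time[None, :]
    np.fill_diagonal(eq, False)
    mask = event[:, None] & (lt | eq)
    return np.nonzero(mask)


def concordance_index(time, event, risk) -> float:
    """Harrell's concordance index of risk scores against observed outcomes.

    0.5 is the expected value of a random ranking, 1 a perfect ranking of
    failure times (higher risk = earlier failure).

    Raises
    ------
    ValueError
        If no comparable pair exists (e.g. everything censored).
    """
    risk = np.asarray(risk, dtype=float)
    i_idx, j_idx = comparable_pairs(time, event)
    if i_idx.size == 0:
        raise ValueError("no comparable pairs: concordance index is undefined")
    ri, rj = risk[i_idx], risk[j_idx]
    score = np.where(ri > rj, 1.0, np.where(ri == rj, 0.5, 0.0))
    return float(score.mean())


def _scored_pairs(risk: np.ndarray, i_idx: np.ndarray, j_idx: np.ndarray) -> float:
    """Concordance from precomputed comparable-pair indices."""
    ri, rj = risk[i_idx], risk[j_idx]
    return float(np.mean(np.where(ri > rj, 1.0, np.where(ri == rj, 0.5, 0.0))))


@dataclass
class KaplanMeierCurve:
    """Product-limit survival curve with a pointwise confidence band.

    ``survival[k]`` is S(t) for ``event_times[k] <= t < event_times[k+1]``;
    S is 1 before the first event time.  The band is the log-transformed
    Greenwood interval at level 1 - alpha, clipped to [0, 1].
    """

    event_times: np.ndarray
    survival: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    n_at_risk: np.ndarray
    alpha: float

    def survival_at(self, t: float) -> float:
        """Step-function value S(t)."""
        k = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if k < 0 else float(self.survival[k])


def kaplan_meier(time, event, alpha: float = 0.05) -> KaplanMeierCurve:
    """Kaplan-Meier estimate S(t) = prod_{t_k <= t} (1 - d_k / n_k).

    d_k is the number of events and n_k the number at risk at the k-th
    distinct event time.  The variance follows Greenwood's formula and the
    band uses the log transform, exp(log S +/- z * sqrt(var)/S), so it
    stays within [0, 1].
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(bool)
    if time.size == 0:
        raise ValueError("empty sample")

    uniq = np.unique(time[event])
    if uniq.size == 0:
        # everything censored: S(t) = 1 with no uncertainty about drops
        one = np.array([1.0])
        return KaplanMeierCurve(np.array([]), one[:0], one[:0], one[:0],
                                np.array([], dtype=int), alpha)

    # counts per distinct event time
    d = np.array([(event & (time == t)).sum() for t in uniq], dtype=float)
    n_at_risk = np.array([(time >= t).sum() for t in uniq], dtype=float)
    frac = 1.0 - d / n_at_risk
    surv = np.cumprod(frac)

    # Greenwood: Var[S] = S^2 * cumsum(d / (n (n - d)))
    with np.errstate(divide="ignore", invalid="ignore"):
        inc = np.where(n_at_risk > d, d / (n_at_risk * (n_at_risk - d)), np.inf)
        greenwood = np.cumsum(inc)
        z = sps.norm.ppf(1.0 - alpha / 2.0)
        se_log = np.sqrt(greenwood)
        log_s = np.log(np.where(surv > 0, surv, np.nan))
        lower = np.exp(log_s - z * se_log)
        upper = np.exp(log_s + z * se_log)
    lower = np.clip(np.nan_to_num(lower, nan=0.0), 0.0, 1.0)
    upper = np.clip(np.nan_to_num(upper, nan=0.0), 0.0, 1.0)
    # where S hits exactly 0 the band collapses
    lower[surv == 0] = 0.0
    upper[surv == 0] = 0.0
    return KaplanMeierCurve(uniq, surv, lower, upper, n_at_risk.astype(int), alpha)


def median_survival(curve: KaplanMeierCurve) -> float | str:
    """Smallest event time t with S(t) <= 0.5, or ``NOT_REACHED``."""
    below = np.nonzero(curve.survival <= 0.5)[0]
    if below.size == 0:
        return NOT_REACHED
    return float(curve.event_times[below[0]])


@dataclass
class LogRankResult:
    """Two-sample log-rank test: chi-squared statistic (1 df) and p-value."""

    statistic: float
    p_value: float


def logrank_test(ds_a: SurvivalDataset, ds_b: SurvivalDataset) -> LogRankResult:
    """Standard (unweighted) two-sample log-rank test.

    At each distinct pooled event time the observed number of events in
    group a is compared with its hypergeometric expectation given the
    pooled risk set; the statistic is (sum O - sum E)^2 / sum Var.
    """
    if ds_a.n == 0 or ds_b.n == 0:
        raise ValueError("both groups must be non-empty")
    time = np.concatenate([ds_a.time, ds_b.time])
    event = np.concatenate([ds_a.event, ds_b.event]).astype(bool)
    group_a = np.concatenate([np.ones(ds_a.n, bool), np.zeros(ds_b.n, bool)])
    if not event.any():
        raise ValueError("log-rank test requires at least one pooled event")

    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(time[event]):
        at_risk = time >= t
        n_tot = at_risk.sum()
        n_a = (at_risk & group_a).sum()
        d_tot = (event & (time == t)).sum()
        d_a = (event & (time == t) & group_a).sum()
        o_minus_e += d_a - d_tot * n_a / n_tot
        if n_tot > 1:
            var += (
                d_tot * (n_a / n_tot) * (1 - n_a / n_tot) * (n_tot - d_tot) / (n_tot - 1)
            )
    if var == 0.0:
        # degenerate: no variability (e.g. all events in risk sets of one)
        return LogRankResult(0.0, 1.0)
    statistic = o_minus_e**2 / var
    p_value = float(sps.chi2.sf(statistic, df=1))
    return LogRankResult(float(statistic), p_value)


@dataclass
class BootstrapCI:
    """Percentile bootstrap interval around a full-sample point estimate."""

    point: float
    lower: float
    upper: float
    n_boot: int
    level: float


def bootstrap_ci(
    stat: Callable[[SurvivalDataset], float],
    ds: SurvivalDataset,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int | None = None,
    max_retries: int = 100,
) -> BootstrapCI:
    """Resample rows with replacement and form a percentile interval.

    A replicate on which ``stat`` raises (e.g. a resample with no
    comparable pairs) is redrawn, up to ``max_retries`` extra draws in
    total; exhausting the retries is an error.
    """
    if seed is None:
        raise ValueError("bootstrap_ci requires an explicit seed")
    rng = np.random.default_rng(seed)
    point = float(stat(ds))
    values = np.empty(n_boot)
    retries = 0
    k = 0
    while k < n_boot:
        idx = rng.integers(0, ds.n, size=ds.n)
        try:
            values[k] = stat(ds.subset(idx))
        except ValueError:
            retries += 1
            if retries > max_retries:
                raise ValueError(
                    f"bootstrap exceeded {max_retries} retries on degenerate resamples"
                )
            warnings.warn("degenerate bootstrap resample redrawn", stacklevel=2)
            continue
        k += 1
    lo, hi = np.quantile(values, [(1 - level) / 2, 1 - (1 - level) / 2])
    return BootstrapCI(point, float(lo), float(hi), n_boot, level)
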