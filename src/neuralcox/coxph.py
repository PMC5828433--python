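"""Linear Cox proportional-hazards regression by Newton-Raphson.

The model assumes lambda(t | x) = lambda0(t) * exp(beta' x) and estimates
beta by maximizing the Cox partial likelihood with the Breslow convention
for tied event times (tied events keep each other in the risk-set
denominator).  An optional ridge penalty ``l2 * ||beta||^2`` is
subtracted from the log partial likelihood.

Covariates are standardized internally for Newton conditioning;
coefficients are reported on the original scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .data import SurvivalDataset

__all__ = ["LinearCoxModel", "fit_linear_cph", "breslow_log_partial_likelihood"]

_SEPARATION_NORM = 500.0  # ||beta|| on the standardized scale that flags separation


@dataclass
class LinearCoxModel:
    """Fitted linear Cox model: log-risk h(x) = beta' x."""

    beta: np.ndarray
    converged: bool
    n_iter: int
    final_gradient_norm: float
    log_likelihood: float
    feature_names: list[str]

    def predict_log_risk(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.beta.shape[0]:
            raise ValueError(
                f"X has {X.shape[1]} columns, model expects {self.beta.shape[0]}"
            )
        return X @ self.beta


def _risk_set_sums(time: np.ndarray, order: np.ndarray):
    """Group boundaries for Breslow risk sets on descending-time-sorted data.

    Returns, for each sorted position k, the index ``last[k]`` such that
    the risk set of the record at k is the sorted prefix ``[0, last[k]]``
    (records with time >= time_k, ties included).
    """
    t_sorted = time[order]
    n = t_sorted.size
    last = np.empty(n, dtype=int)
    k = 0
    while k < n:
        j = k
        while j + 1 < n and t_sorted[j + 1] == t_sorted[k]:
            j += 1
        last[k : j + 1] = j
        k = j + 1
    return t_sorted, last


def breslow_log_partial_likelihood(
    beta: np.ndarray, X: np.ndarray, time: np.ndarray, event: np.ndarray, l2: float = 0.0
) -> float:
    """Penalized Breslow log partial likelihood at ``beta`` (original scale)."""
    beta = np.asarray(beta, dtype=float)
    eta = X @ beta
    order = np.argsort(-time, kind="stable")
    _, last = _risk_set_sums(time, order)
    eta_s = eta[order]
    ev_s = np.asarray(event).astype(bool)[order]
    m = eta_s.max()
    cum = np.cumsum(np.exp(eta_s - m))
    log_denom = m + np.log(cum[last])
    return float(np.sum(eta_s[ev_s] - log_denom[ev_s]) - l2 * beta @ beta)


def fit_linear_cph(
    ds: SurvivalDataset,
    l2: float = 0.0,
    tol: float = 1e-9,
    max_iter: int = 100,
) -> LinearCoxModel:
    """Fit the linear Cox model on ``ds.covariates``.

    Parameters
    ----------
    l2 : ridge coefficient on ||beta||^2 (0 = classical unpenalized fit).
    tol : convergence threshold on the gradient norm (standardized scale).
    max_iter : Newton iteration cap; hitting it returns ``converged=False``
        with a warning rather than raising.

    Raises
    ------
    ValueError
        If the dataset has no events, or monotone-likelihood separation is
        detected (a coefficient diverging without bound).
    """
    if ds.n_events < 1:
        raise ValueError("Cox regression requires at least one observed event")

    X = ds.covariates
    names = list(ds.feature_names)
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    constant = scale == 0.0
    if constant.any():
        dropped = [names[i] for i in np.flatnonzero(constant)]
        warnings.warn(f"dropping constant covariate column(s): {dropped}", stacklevel=2)
    keep = ~constant
    Xs = (X[:, keep] - mean[keep]) / scale[keep]
    d = Xs.shape[1]
    # the ridge penalty is defined on the original scale; expressed in the
    # standardized coordinates b = beta * scale it becomes b' D b
    pen = np.diag(1.0 / scale[keep] ** 2)

    time = ds.time
    event = ds.event.astype(bool)
    order = np.argsort(-time, kind="stable")
    _, last = _risk_set_sums(time, order)
    Xo = Xs[order]
    ev = event[order]
    ev_idx = np.flatnonzero(ev)

    def negloglik_grad_hess(b):
        eta = Xo @ b
        m = eta.max()
        w = np.exp(eta - m)  # (n,)
        cw = np.cumsum(w)
        cwx = np.cumsum(w[:, None] * Xo, axis=0)
        cwxx = np.cumsum(w[:, None, None] * (Xo[:, :, None] * Xo[:, None, :]), axis=0)
        li = last[ev_idx]
        denom = cw[li]
        xbar = cwx[li] / denom[:, None]
        ll = float(np.sum(eta[ev_idx] - (np.log(denom) + m)) - l2 * b @ pen @ b)
        grad = (Xo[ev_idx] - xbar).sum(axis=0) - 2.0 * l2 * pen @ b
        s2 = cwxx[li] / denom[:, None, None]
        hess = -(s2 - xbar[:, :, None] * xbar[:, None, :]).sum(axis=0)
        hess -= 2.0 * l2 * pen
        return ll, grad, hess

    b = np.zeros(d)
    ll, grad, hess = negloglik_grad_hess(b)
    n_iter = 0
    gnorm = float(np.linalg.norm(grad))
    converged = gnorm < tol
    while not converged and n_iter < max_iter:
        n_iter += 1
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError:
            step = grad  # singular Hessian: fall back to gradient ascent
        # step-halving line search on the penalized log likelihood
        alpha = 1.0
        for _ in range(40):
            b_new = b + alpha * step
            ll_new, grad_new, hess_new = negloglik_grad_hess(b_new)
            if ll_new >= ll - 1e-12:
                break
            alpha *= 0.5
        b, ll, grad, hess = b_new, ll_new, grad_new, hess_new
        gnorm = float(np.linalg.norm(grad))
        if not np.isfinite(b).all() or np.linalg.norm(b) > _SEPARATION_NORM:
            ref = b if np.isfinite(b).all() else step
            worst = names[int(np.flatnonzero(keep)[np.argmax(np.abs(ref))])]
            raise ValueError(
                f"monotone likelihood: coefficient for '{worst}' diverges "
                "(perfect separation of event order)"
            )
        if gnorm < tol:
            converged = True
    if not converged:
        warnings.warn(
            f"Newton-Raphson did not converge in {max_iter} iterations "
            f"(gradient norm {gnorm:.3g})",
            stacklevel=2,
        )

    beta = np.zeros(X.shape[1])
    beta[keep] = b / scale[keep]
    return LinearCoxModel(
        beta=beta,
        converged=converged,
        n_iter=n_iter,
        final_gradient_norm=gnorm,
        log_likelihood=ll,
        feature_names=names,
    )
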