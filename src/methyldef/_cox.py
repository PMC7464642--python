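"""Low-level Cox proportional-hazards numerics.

Shared by the permutation survival screen (score statistics for many
features / permutations at once) and the optimal-cutpoint scan (hundreds of
small Newton fits).  Event-time ties are handled with the Breslow
convention throughout: tied events share the risk set that starts at the
first index of the tie group.

The public model-fitting surface of the package goes through lifelines;
these routines exist because the screen and the cutpoint scan evaluate the
statistic thousands of times and are cross-checked against lifelines in the
test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class SortedSurvival:
    """Survival data pre-sorted by time with Breslow risk-set bookkeeping.

    Attributes
    ----------
    order : permutation that sorts the original rows by ascending time
    time, event : sorted arrays
    event_idx : sorted positions at which an event occurs
    risk_start : for each event, the first sorted index of its tie group
        (the risk set is ``[risk_start, n)``)
    """

    order: np.ndarray
    time: np.ndarray
    event: np.ndarray
    event_idx: np.ndarray
    risk_start: np.ndarray

    @property
    def n(self) -> int:
        return self.time.shape[0]

    @property
    def n_events(self) -> int:
        return self.event_idx.shape[0]


def sort_survival(time, event) -> SortedSurvival:
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    if time.ndim != 1 or time.shape != event.shape:
        raise ValueError("time and event must be 1-d arrays of equal length")
    if np.any(time <= 0):
        raise ValueError("survival times must be positive")
    order = np.argsort(time, kind="stable")
    t = time[order]
    e = event[order].astype(bool)
    # first index of each tie group
    starts = np.searchsorted(t, t, side="left")
    event_idx = np.flatnonzero(e)
    return SortedSurvival(order, t, e, event_idx, starts[event_idx])


def _suffix_cumsum(a: np.ndarray, axis: int) -> np.ndarray:
    """Cumulative sum from the end of the array (suffix sums)."""
    return np.flip(np.cumsum(np.flip(a, axis=axis), axis=axis), axis=axis)


def cox_score_components(x: np.ndarray, ss: SortedSurvival):
    """Score-test numerator U and variance V for features against survival.

    ``x`` has shape ``(..., n, p)`` in the ORIGINAL (unsorted) sample order;
    leading axes batch over e.g. permutations.  Returns ``(U, V)`` each of
    shape ``(..., p)``:

        U = sum over events of (x_event - risk-set mean of x)
        V = sum over events of the risk-set variance of x

    the standard log-rank/Cox score decomposition with Breslow ties.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[-2] != ss.n:
        raise ValueError("feature rows must match number of samples")
    xs = np.take(x, ss.order, axis=-2)
    s1 = _suffix_cumsum(xs, axis=-2)
    s2 = _suffix_cumsum(xs * xs, axis=-2)
    m = (ss.n - ss.risk_start).astype(float)[:, None]  # risk-set sizes
    s1r = np.take(s1, ss.risk_start, axis=-2)
    s2r = np.take(s2, ss.risk_start, axis=-2)
    x_ev = np.take(xs, ss.event_idx, axis=-2)
    mean_r = s1r / m
    U = (x_ev - mean_r).sum(axis=-2)
    V = (s2r / m - mean_r**2).sum(axis=-2)
    return U, V


def cox_score_stat(x: np.ndarray, ss: SortedSurvival, s0: float = 0.0) -> np.ndarray:
    """Modified Cox score d = U / (sqrt(V) + s0); shape ``(..., p)``.

    Positive d means higher feature values associate with higher hazard.
    Features with zero risk-set variance yield NaN when ``s0 == 0``.
    """
    U, V = cox_score_components(x, ss)
    denom = np.sqrt(np.maximum(V, 0.0)) + s0
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(denom > 0, U / denom, np.nan)


class CoxConvergenceError(RuntimeError):
    pass


def cox_newton(
    X: np.ndarray,
    ss: SortedSurvival,
    max_iter: int = 40,
    tol: float = 1e-9,
    ridge: float = 1e-10,
):
    """Newton–Raphson maximum partial likelihood (Breslow ties).

    X : (n, p) design in original sample order.
    Returns ``(beta, loglik, cov)`` with ``cov`` the inverse observed
    information (Wald covariance).  Raises CoxConvergenceError on failure
    (monitors divergence / separation via exploding coefficients).
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n != ss.n:
        raise ValueError("design rows must match number of samples")
    Xs = X[ss.order]
    beta = np.zeros(p)
    ll_old = -np.inf
    for _ in range(max_iter):
        ll, grad, info = _breslow_ll_grad_info(Xs, ss, beta)
        info_r = info + ridge * np.eye(p)
        try:
            step = np.linalg.solve(info_r, grad)
        except np.linalg.LinAlgError as exc:  # singular information
            raise CoxConvergenceError("singular information matrix") from exc
        # step-halving safeguard
        new_beta = beta + step
        new_ll = _breslow_ll(Xs, ss, new_beta)
        halvings = 0
        while not np.isfinite(new_ll) or new_ll < ll - 1e-12:
            step *= 0.5
            new_beta = beta + step
            new_ll = _breslow_ll(Xs, ss, new_beta)
            halvings += 1
            if halvings > 30:
                raise CoxConvergenceError("step halving failed")
        beta = new_beta
        if np.any(np.abs(beta) > 50):
            raise CoxConvergenceError(
                "coefficients diverging (possible perfect separation)"
            )
        if abs(new_ll - ll_old) < tol * (abs(new_ll) + 1.0):
            ll_old = new_ll
            break
        ll_old = new_ll
    ll, grad, info = _breslow_ll_grad_info(Xs, ss, beta)
    try:
        cov = np.linalg.inv(info + ridge * np.eye(p))
    except np.linalg.LinAlgError as exc:
        raise CoxConvergenceError("singular information at optimum") from exc
    return beta, ll, cov


def _risk_quantities(Xs: np.ndarray, ss: SortedSurvival, beta: np.ndarray):
    eta = Xs @ beta
    eta = eta - eta.max()  # overflow guard; cancels in ratios and loglik diffs
    w = np.exp(eta)
    S0 = _suffix_cumsum(w, axis=0)
    return eta, w, S0


def _breslow_ll(Xs, ss, beta) -> float:
    eta, _, S0 = _risk_quantities(Xs, ss, beta)
    return float(eta[ss.event_idx].sum() - np.log(S0[ss.risk_start]).sum())


def _breslow_ll_grad_info(Xs, ss, beta):
    eta, w, S0 = _risk_quantities(Xs, ss, beta)
    S1 = _suffix_cumsum(w[:, None] * Xs, axis=0)
    S2 = _suffix_cumsum(w[:, None, None] * (Xs[:, :, None] * Xs[:, None, :]), axis=0)
    r = ss.risk_start
    s0 = S0[r][:, None]
    xbar = S1[r] / s0
    ll = float(eta[ss.event_idx].sum() - np.log(S0[r]).sum())
    grad = (Xs[ss.event_idx] - xbar).sum(axis=0)
    info = (S2[r] / s0[:, :, None] - xbar[:, :, None] * xbar[:, None, :]).sum(axis=0)
    return ll, grad, info


def wald_p(beta: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """Two-sided Wald p-values per coefficient."""
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = beta / se
    return 2.0 * stats.norm.sf(np.abs(z))
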