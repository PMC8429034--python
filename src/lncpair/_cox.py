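"""Cox partial-likelihood utilities.

A fast single-covariate Newton fitter (Breslow tie handling) backs the
mass univariate screens (hundreds of candidate pairs, AIC cutoff scans),
where per-fit overhead of a full modelling package would dominate the
pipeline runtime.  Multivariable models go through lifelines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

Z975 = stats.norm.ppf(0.975)

# |beta| beyond this is treated as a monotone-likelihood / separation fit
BETA_BOUND = 15.0


def breslow_loglik(eta: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    """Breslow partial log-likelihood at a fixed linear predictor.

    Each event contributes ``eta_i - log(sum_{j in R(t_i)} exp(eta_j))``
    with the full risk set used for tied event times.
    """
    eta = np.asarray(eta, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=float)
    order = np.argsort(time, kind="stable")
    t, e, et = time[order], event[order], eta[order]
    exp_eta = np.exp(et)
    risk_sum = np.cumsum(exp_eta[::-1])[::-1]
    # subjects tied on time share the risk-set sum of the first tied index
    first = np.searchsorted(t, t, side="left")
    return float(np.sum(e * (et - np.log(risk_sum[first]))))


def _cox1_derivs(x, time, event, beta):
    """Log-likelihood, score and information for a 1-covariate Cox model."""
    order = np.argsort(time, kind="stable")
    t, e, xs = time[order], event[order], x[order]
    eta = beta * xs
    w = np.exp(eta)
    s0 = np.cumsum(w[::-1])[::-1]
    s1 = np.cumsum((xs * w)[::-1])[::-1]
    s2 = np.cumsum((xs * xs * w)[::-1])[::-1]
    first = np.searchsorted(t, t, side="left")
    s0f, s1f, s2f = s0[first], s1[first], s2[first]
    mu = s1f / s0f
    ll = float(np.sum(e * (eta - np.log(s0f))))
    score = float(np.sum(e * (xs - mu)))
    info = float(np.sum(e * (s2f / s0f - mu * mu)))
    return ll, score, info


@dataclass
class Cox1Fit:
    """Result of a single-covariate Cox fit."""

    coef: float
    se: float
    loglik: float
    converged: bool
    n_iter: int

    @property
    def hr(self) -> float:
        return float(np.exp(self.coef))

    @property
    def hr_low(self) -> float:
        return float(np.exp(self.coef - Z975 * self.se))

    @property
    def hr_high(self) -> float:
        return float(np.exp(self.coef + Z975 * self.se))

    @property
    def p(self) -> float:
        if self.se == 0 or not np.isfinite(self.se):
            return float("nan")
        return float(2.0 * stats.norm.sf(abs(self.coef) / self.se))

    @property
    def aic(self) -> float:
        return 2.0 - 2.0 * self.loglik


def cox1_fit(x, time, event, max_iter: int = 50, tol: float = 1e-10) -> Cox1Fit:
    """Newton-Raphson fit of a one-covariate Cox model (Breslow ties).

    Monotone-likelihood fits (coefficient diverging beyond ``BETA_BOUND``)
    are returned with ``converged=False``.
    """
    x = np.asarray(x, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=float)
    if x.std() == 0:
        raise ValueError("covariate has no variation")
    beta = 0.0
    ll, score, info = _cox1_derivs(x, time, event, beta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        if info <= 0:
            break
        step = score / info
        # step-halving to guarantee likelihood ascent
        for _ in range(30):
            new_beta = beta + step
            new_ll, new_score, new_info = _cox1_derivs(x, time, event, new_beta)
            if new_ll >= ll - 1e-12:
                break
            step /= 2.0
        beta, ll, score, info = new_beta, new_ll, new_score, new_info
        if abs(beta) > BETA_BOUND:
            break
        if abs(step) < tol:
            converged = True
            break
    se = 1.0 / np.sqrt(info) if info > 0 else float("inf")
    if abs(beta) > BETA_BOUND:
        converged = False
    return Cox1Fit(coef=float(beta), se=float(se), loglik=float(ll),
                   converged=converged, n_iter=it)
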