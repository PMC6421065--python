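"""Maximum-likelihood estimation of diversification rates from branching times.

The likelihood is the constant-rate reconstructed ("Nee-type") birth-death
process conditioned on the crown age ``t`` and on survival of both crown
lineages.  Writing r = lambda - mu, eps = mu/lambda,

    g(s) = (1 - e^{-r s}) / (lambda - mu e^{-r s}),      u = lambda * g(t),

the number of extant tips satisfies P(N = n) = (n-1) (1-u)^2 u^{n-2}, and
given N = n the n - 2 post-root speciation ages are i.i.d. with density

    f(s) = r^2 e^{-r s} / (lambda - mu e^{-r s})^2 / g(t).

The default log-likelihood is log P(N = n) + sum_i log f(x_i) (constants in
the data only, such as topology counts, are dropped).  A switch additionally
conditions on the tip count n, dropping the P(N = n) term.  The Yule model
is the eps = 0 boundary of the same expressions.

Internally ages are rescaled so the crown age is 1; rate estimates are then
divided by the crown age, which makes time-rescaling equivariance of the
MLEs exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize, minimize_scalar

#: optimizer search bounds (rates in units of 1/crown_age after rescaling)
_R_LO, _R_HI = 1e-6, 10.0
_EPS_HI = 0.999
#: below this, an estimated eps is reported as sitting on the eps = 0 boundary
_EPS_BOUNDARY_TOL = 1e-4


@dataclass(frozen=True)
class DivEstimate:
    """Fitted diversification parameters.

    ``lambda_hat`` is the speciation rate: the fitted rate under Yule, or the
    derived r_hat / (1 - eps_hat) under birth-death.  ``r_hat`` is the net
    diversification rate (equal to lambda_hat under Yule, where eps = 0).
    """

    model: str  # "yule" | "bd"
    lambda_hat: float
    r_hat: float
    eps_hat: float
    loglik: float
    converged: bool
    boundary: bool = False


def _check_bt(bt: np.ndarray, min_n: int = 3) -> np.ndarray:
    bt = np.sort(np.asarray(bt, dtype=float))[::-1]
    n = len(bt) + 1
    if n < min_n:
        raise ValueError(f"need at least {min_n} tips ({min_n - 1} branching times)")
    if not np.all(bt > 0):
        raise ValueError("branching times must be positive ages")
    if not np.all(bt <= bt[0]):
        raise ValueError("crown age must be the largest branching time")
    return bt


def bd_loglik(bt, r: float, eps: float, conditioning: str = "survival") -> float:
    """Log-likelihood of branching times under the reconstructed BD process.

    ``bt`` holds the n - 1 internal-node ages including the crown age (which
    enters only through the conditioning).  ``conditioning`` is ``"survival"``
    (crown age + survival of both crown lineages; the tip count is part of
    the data) or ``"n"`` (additionally condition on the tip count).
    """
    if not r > 0:
        return -math.inf
    if not (0.0 <= eps < 1.0):
        raise ValueError("eps must be in [0, 1)")
    if conditioning not in ("survival", "n"):
        raise ValueError("conditioning must be 'survival' or 'n'")
    bt = _check_bt(bt)
    t = bt[0]
    x = bt[1:]
    n = len(bt) + 1
    lam = r / (1.0 - eps)
    mu = lam * eps

    et = math.exp(-r * t)
    g_t = (1.0 - et) / (lam - mu * et)
    # i.i.d. age densities f(x) = r^2 e^{-rx} / (lam - mu e^{-rx})^2 / g(t)
    ex = np.exp(-r * x)
    ll = float(
        np.sum(2.0 * math.log(r) - r * x - 2.0 * np.log(lam - mu * ex))
        - (n - 2) * math.log(g_t)
    )
    if conditioning == "survival":
        # u = lam * g_t; 1 - u = r e^{-rt} / (lam - mu e^{-rt}) exactly,
        # which stays finite in log space even as u -> 1
        log_denom = math.log(lam - mu * et)
        log_u = math.log(lam) + math.log(g_t)
        log_1mu = math.log(r) - r * t - log_denom
        ll += math.log(n - 1) + (n - 2) * log_u + 2.0 * log_1mu
    return ll


def yule_loglik(bt, lam: float, conditioning: str = "survival") -> float:
    """Pure-birth log-likelihood; the eps = 0 case of :func:`bd_loglik`."""
    if not lam > 0:
        return -math.inf
    _check_bt(bt, min_n=3)
    return bd_loglik(bt, r=lam, eps=0.0, conditioning=conditioning)


def yule_mle(bt, conditioning: str = "survival") -> DivEstimate:
    """ML speciation rate under the Yule model (1-D bounded optimization)."""
    bt = _check_bt(bt, min_n=3)
    t = bt[0]
    bts = bt / t  # crown age 1; makes rescaling equivariance exact

    res = minimize_scalar(
        lambda lam: -bd_loglik(bts, lam, 0.0, conditioning),
        bounds=(_R_LO, _R_HI),
        method="bounded",
        options={"xatol": 1e-10},
    )
    lam_hat = float(res.x) / t
    return DivEstimate(
        model="yule",
        lambda_hat=lam_hat,
        r_hat=lam_hat,
        eps_hat=0.0,
        loglik=bd_loglik(bt, lam_hat, 0.0, conditioning),
        converged=bool(res.success),
    )


def _bd_negll(theta, bts, conditioning):
    logr, z = theta
    r = math.exp(logr)
    eps = _EPS_HI / (1.0 + math.exp(-z))  # logistic onto [0, 0.999)
    if not (_R_LO <= r <= _R_HI):
        return math.inf
    return -bd_loglik(bts, r, eps, conditioning)


def bd_mle(bt, conditioning: str = "survival") -> DivEstimate:
    """ML (r, eps) under birth-death via multi-start bounded simplex search.

    Five starts on a coarse grid around the Yule estimate; eps is mapped to
    [0, 0.999) by a logistic transform and r constrained to (1e-6, 10]
    (in units of 1/crown_age).  An optimum with eps within 1e-4 of a bound
    is reported with ``boundary=True``.
    """
    bt = _check_bt(bt, min_n=3)
    n = len(bt) + 1
    if n < 4:
        import warnings

        warnings.warn("bd_mle with fewer than 4 tips is weakly informative")
    t = bt[0]
    bts = bt / t

    r0 = yule_mle(bt, conditioning).r_hat * t  # in scaled units
    r0 = min(max(r0, 10 * _R_LO), 0.5 * _R_HI)
    starts = [
        (math.log(r0), _logit(0.05)),
        (math.log(r0), _logit(0.5)),
        (math.log(r0), _logit(0.9)),
        (math.log(0.5 * r0), _logit(0.5)),
        (math.log(min(2 * r0, 0.9 * _R_HI)), _logit(0.5)),
    ]
    best = None
    any_converged = False
    for theta0 in starts:
        res = minimize(
            _bd_negll,
            np.array(theta0),
            args=(bts, conditioning),
            method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000},
        )
        any_converged = any_converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    logr, z = best.x
    r_hat = math.exp(logr) / t
    eps_hat = _EPS_HI / (1.0 + math.exp(-z))
    boundary = eps_hat < _EPS_BOUNDARY_TOL or eps_hat > _EPS_HI - _EPS_BOUNDARY_TOL
    lam_hat = r_hat / (1.0 - eps_hat)
    return DivEstimate(
        model="bd",
        lambda_hat=lam_hat,
        r_hat=r_hat,
        eps_hat=eps_hat,
        loglik=bd_loglik(bt, r_hat, eps_hat, conditioning),
        converged=any_converged,
        boundary=boundary,
    )


def _logit(p: float) -> float:
    q = p / _EPS_HI
    return math.log(q / (1.0 - q))
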