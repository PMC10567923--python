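"""Per-term partial pooling of subject-level coefficients.

The edge models place participant random effects on every block-activation and
timepoint-interaction column with a diagonal random-effects covariance.  With
that structure the mixed model factorizes per term into the classic
random-effects location model: subject OLS coefficients ``b_i`` with sampling
variances ``v_i`` around a common mean with between-subject variance ``tau^2``.
``tau^2`` is estimated by scalar REML and per-subject estimates are the
empirical-Bayes BLUPs, ``mu + tau^2/(tau^2+v_i) * (b_i - mu)`` — the group
fixed effect plus a shrunken subject deviation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar


def _neg_reml(tau2: float, beta: np.ndarray, v: np.ndarray) -> float:
    w = 1.0 / (v + tau2)
    mu = np.sum(w * beta) / np.sum(w)
    return 0.5 * (np.sum(np.log(v + tau2)) + np.log(np.sum(w))
                  + np.sum(w * (beta - mu) ** 2))


def reml_tau2(beta: np.ndarray, v: np.ndarray) -> float:
    """REML estimate of the between-subject variance for one coefficient."""
    beta = np.asarray(beta, dtype=float)
    v = np.asarray(v, dtype=float)
    if beta.size < 2:
        raise ValueError("need at least two subjects to estimate tau^2")
    hi = max(10.0 * float(np.var(beta)), float(np.max(v)), 1e-12)
    res = minimize_scalar(_neg_reml, bounds=(0.0, hi), args=(beta, v),
                          method="bounded",
                          options={"xatol": 1e-10 * hi})
    tau2 = float(res.x)
    # boundary polish: the optimum may sit at exactly zero
    if _neg_reml(0.0, beta, v) <= _neg_reml(tau2, beta, v):
        tau2 = 0.0
    return tau2


@dataclass
class PooledTerm:
    """Pooling result for one coefficient across subjects."""

    fixed: float           # group fixed effect (precision-weighted mean)
    tau2: float            # between-subject variance
    estimates: np.ndarray  # per-subject partial-pooled estimates
    shrinkage: np.ndarray  # per-subject shrinkage factors in [0, 1]


def pool_term(beta: np.ndarray, v: np.ndarray,
              tau2: float | None = None) -> PooledTerm:
    """Partially pool subject coefficients; ``tau2=None`` estimates it by REML.

    Passing a very large ``tau2`` fixes the random-effect variance so the
    per-subject estimates reduce to the subject OLS coefficients.
    """
    beta = np.asarray(beta, dtype=float)
    v = np.asarray(v, dtype=float)
    if beta.size == 1:
        return PooledTerm(float(beta[0]), np.nan, beta.copy(),
                          np.ones(1))
    if tau2 is None:
        tau2 = reml_tau2(beta, v)
    if np.isinf(tau2):
        mu = float(np.mean(beta))
        return PooledTerm(mu, tau2, beta.copy(), np.ones_like(beta))
    w = 1.0 / (v + tau2)
    mu = float(np.sum(w * beta) / np.sum(w))
    shrink = tau2 / (tau2 + v)
    return PooledTerm(mu, tau2, mu + shrink * (beta - mu), shrink)
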