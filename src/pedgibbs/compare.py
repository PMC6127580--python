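"""Model comparison: deviance information criterion and Bayes factors.

DIC = Dbar + pD with Dbar the posterior mean deviance and
pD = Dbar - D(theta_bar) the effective number of parameters; smaller is
better.  The Bayes factor is the ratio of marginal likelihoods, estimated
from per-draw log-likelihoods by the harmonic-mean estimator (stabilized on
the log scale).  The harmonic-mean estimator is simple but high-variance, so
DIC is the primary criterion; BF is reported with the conventional verdict:
BF > 1 favours the numerator model, BF < 1 the denominator, BF = 1 a tie.
"""

from __future__ import annotations

import warnings
from typing import NamedTuple

import numpy as np
from scipy.special import logsumexp

__all__ = ["DICResult", "BayesFactorResult", "dic", "bayes_factor", "log_marginal_harmonic"]


class DICResult(NamedTuple):
    dic: float
    p_d: float
    dbar: float


class BayesFactorResult(NamedTuple):
    bf: float
    log_bf: float
    verdict: str
    log_ml_num: float
    log_ml_den: float


def dic(deviance_draws, deviance_at_mean: float) -> DICResult:
    """DIC from posterior deviance draws and the deviance at posterior means."""
    d = np.asarray(deviance_draws, dtype=float)
    if d.size < 2:
        raise ValueError("need at least 2 deviance draws")
    dbar = float(d.mean())
    p_d = dbar - float(deviance_at_mean)
    return DICResult(dbar + p_d, p_d, dbar)


def log_marginal_harmonic(loglik_draws) -> float:
    """Harmonic-mean estimate of the log marginal likelihood.

    log f(y) ~= -[logsumexp(-loglik) - log n]; stabilized on the log scale.
    """
    ll = np.asarray(loglik_draws, dtype=float)
    if ll.size < 100:
        warnings.warn("harmonic-mean estimator unstable with < 100 draws")
    return float(-(logsumexp(-ll) - np.log(ll.size)))


def bayes_factor(loglik_draws_i, loglik_draws_j, tie_tol: float = 1e-9) -> BayesFactorResult:
    """BF_{i,j} = f(y|M_i) / f(y|M_j) from per-draw log-likelihoods.

    Model i is the numerator.  The verdict string follows the usual reading:
    BF > 1 prefers the numerator, BF < 1 the denominator, BF = 1 a tie.
    """
    lmi = log_marginal_harmonic(loglik_draws_i)
    lmj = log_marginal_harmonic(loglik_draws_j)
    log_bf = lmi - lmj
    if abs(log_bf) <= tie_tol:
        verdict = "tie: both models of equal quality"
    elif log_bf > 0:
        verdict = "numerator model preferred"
    else:
        verdict = "denominator model preferred"
    return BayesFactorResult(float(np.exp(log_bf)), log_bf, verdict, lmi, lmj)
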