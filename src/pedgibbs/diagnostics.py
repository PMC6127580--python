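"""Post-Gibbs chain diagnostics and posterior summaries.

Monte Carlo error (MCE) is the square root of the sample variance of the
retained draws divided by their number — the standard error of the posterior
mean under (approximate) independence of thinned draws.  The Geweke statistic
compares the mean of an early window against a late window, with the window
variances estimated by the spectral density at frequency zero (non-overlapping
batch means), and is referred to the standard normal.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["mce", "geweke", "summarize", "posterior_report"]


def mce(chain) -> float:
    """Monte Carlo error: sqrt(sample variance / number of draws)."""
    x = np.asarray(chain, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 draws")
    return float(np.sqrt(np.var(x, ddof=1) / x.size))


def _spectrum0_batch(x: np.ndarray, n_batches: int = 20) -> float:
    """Spectral density at frequency zero via non-overlapping batch means."""
    n = x.size
    b = n // n_batches
    if b < 1:
        raise ValueError("window too small for batch-means variance")
    means = x[: b * n_batches].reshape(n_batches, b).mean(axis=1)
    return float(b * np.var(means, ddof=1))


def geweke(chain, frac_a: float = 0.1, frac_b: float = 0.5, n_batches: int = 20):
    """Geweke convergence Z-test between an early and a late chain window.

    Z = (mean_A - mean_B) / sqrt(s_A/n_A + s_B/n_B) with s the batch-means
    spectral estimate within each window; returns (Z, two-sided p).
    """
    x = np.asarray(chain, dtype=float)
    na = int(frac_a * x.size)
    nb = int(frac_b * x.size)
    if na < n_batches or nb < n_batches:
        raise ValueError("windows too small; need at least one draw per batch")
    xa = x[:na]
    xb = x[-nb:]
    sa = _spectrum0_batch(xa, n_batches)
    sb = _spectrum0_batch(xb, n_batches)
    denom = sa / na + sb / nb
    if denom <= 0:
        raise ValueError("zero spectral variance; degenerate chain")
    z = float((xa.mean() - xb.mean()) / np.sqrt(denom))
    p = float(2.0 * stats.norm.sf(abs(z)))
    return z, p


def summarize(chain, ci: float = 0.95, hpd: bool = False) -> dict:
    """One report row: mean, median, equal-tail (or HPD) interval, MCE, Geweke.

    The ``mce_stable`` flag records the convergence heuristic that adding the
    MCE to the posterior mean leaves the second decimal place unchanged.
    """
    x = np.asarray(chain, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 draws")
    mean = float(x.mean())
    med = float(np.median(x))
    alpha = 1.0 - ci
    if hpd:
        lo, hi = _hpd(x, ci)
    else:
        lo, hi = (float(v) for v in np.percentile(x, [100 * alpha / 2, 100 * (1 - alpha / 2)]))
    err = mce(x)
    try:
        z, p = geweke(x)
    except ValueError:
        z, p = np.nan, np.nan
    return {
        "mean": mean,
        "median": med,
        "ci_lower": lo,
        "ci_upper": hi,
        "mce": err,
        "geweke_z": z,
        "geweke_p": p,
        "n": int(x.size),
        "mce_stable": bool(round(mean + err, 2) == round(mean, 2)),
    }


def _hpd(x: np.ndarray, ci: float):
    xs = np.sort(x)
    n = xs.size
    k = max(int(np.floor(ci * n)), 1)
    widths = xs[k:] - xs[: n - k]
    j = int(np.argmin(widths))
    return float(xs[j]), float(xs[j + k])


def posterior_report(draws, params=None, ci: float = 0.95, hpd: bool = False) -> pd.DataFrame:
    """Summarize a chain table (DataFrame or ChainSamples): one row per parameter."""
    if hasattr(draws, "draws"):
        draws = draws.draws
    if params is None:
        params = [c for c in draws.columns if c not in ("loglik", "deviance")]
    rows = {p: summarize(draws[p].to_numpy(), ci=ci, hpd=hpd) for p in params}
    return pd.DataFrame(rows).T
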