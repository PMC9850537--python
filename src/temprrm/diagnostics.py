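"""MCMC convergence diagnostics: Geweke and Heidelberger-Welch.

Both operate on a single scalar chain and rely on an estimate of the spectral
density at frequency zero, computed from the autocovariance sequence with a
Bartlett taper (lag window ~ sqrt(n)), so autocorrelated chains are handled
without assuming independence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["spectral_density_zero", "geweke_diagnostic", "heidelberger_welch",
           "GewekeResult", "HeidelbergerWelchResult"]


def spectral_density_zero(x: np.ndarray, max_lag: int | None = None) -> float:
    """Spectral density of the chain at frequency zero (Bartlett window).

    Equals the variance of the sample mean times n, asymptotically.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("need at least two samples")
    if max_lag is None:
        max_lag = max(int(np.sqrt(n)), 1)
    max_lag = min(max_lag, n - 1)
    xc = x - x.mean()
    acov = np.correlate(xc, xc, mode="full")[n - 1:] / n
    w = 1.0 - np.arange(1, max_lag + 1) / (max_lag + 1)
    return float(acov[0] + 2.0 * np.sum(w * acov[1:max_lag + 1]))


@dataclass
class GewekeResult:
    z: float
    degenerate: bool = False


def geweke_diagnostic(chain, frac_a: float = 0.1,
                      frac_b: float = 0.5) -> GewekeResult:
    """Geweke's z: difference of early-window and late-window means scaled by
    spectral-density variance estimates.  |z| > ~2 flags non-stationarity."""
    x = np.asarray(chain, dtype=float)
    if x.size < 50:
        raise ValueError("need at least 50 samples")
    if np.ptp(x) == 0.0:
        return GewekeResult(z=float("nan"), degenerate=True)
    na = max(int(frac_a * x.size), 2)
    nb = max(int(frac_b * x.size), 2)
    a, b = x[:na], x[-nb:]
    var = spectral_density_zero(a) / na + spectral_density_zero(b) / nb
    if var <= 0:
        return GewekeResult(z=float("nan"), degenerate=True)
    return GewekeResult(z=float((a.mean() - b.mean()) / np.sqrt(var)))


@dataclass
class HeidelbergerWelchResult:
    passed: bool
    start_index: int
    cvm_statistic: float


# 5% asymptotic critical value of the Cramer-von Mises statistic
_CVM_CRIT_05 = 0.461


def _cvm_statistic(x: np.ndarray) -> float:
    """Cramer-von Mises functional of the standardized Brownian bridge of
    cumulative sums, with long-run variance from the spectral density."""
    n = x.size
    s0 = spectral_density_zero(x)
    if s0 <= 0:
        return np.inf
    t = np.arange(1, n + 1)
    csum = np.cumsum(x)
    bridge = (csum - t * x.mean()) / np.sqrt(n * s0)
    return float(np.mean(bridge ** 2))


def heidelberger_welch(chain, alpha: float = 0.05) -> HeidelbergerWelchResult:
    """Stationarity test on successively trimmed chains.

    Tests the full chain, then drops 10% increments of the start up to 50%;
    returns the first start index whose remaining chain passes the
    Cramer-von Mises stationarity test at the 5% level, or failure.
    """
    x = np.asarray(chain, dtype=float)
    if x.size < 100:
        raise ValueError("need at least 100 samples")
    n = x.size
    for frac in (0.0, 0.1, 0.2, 0.3, 0.4, 0.5):
        start = int(frac * n)
        stat = _cvm_statistic(x[start:])
        if stat < _CVM_CRIT_05:
            return HeidelbergerWelchResult(True, start, stat)
    return HeidelbergerWelchResult(False, n // 2, stat)
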