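"""GEBV transforms and the plasticity classification.

Coefficient-level breeding values (intercept, slope) map onto age groups via
the Legendre basis (u* = T u); liability-scale age GEBV convert to the
percent probability of scoring docile, GEBV_p = 100 * Phi(t - u_j) with t the
docile threshold (0 on the fitted scale).

Sign convention: higher liability means flightier, so a *negative* liability
slope means the probability of being docile rises with age - habituation; a
positive liability slope is sensitization.  A neutrality band of half-width
``eps`` around zero gives the neutral class; by default eps is 10% of the SD
of the slope GEBV being classified.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .legendre import LegendreBasis, basis_matrix

__all__ = ["coeff_to_age_gebv", "gebv_to_probability", "classify_plasticity",
           "gebv_report"]


def coeff_to_age_gebv(coeffs: pd.DataFrame, basis: LegendreBasis,
                      ages) -> pd.DataFrame:
    """Per-age GEBV: u* = T u, one column per age group."""
    T = basis_matrix(np.asarray(ages, dtype=float), basis)
    if T.shape[1] != coeffs.shape[1]:
        raise ValueError(
            f"basis order {T.shape[1] - 1} does not match the "
            f"{coeffs.shape[1]} fitted coefficients")
    vals = coeffs.to_numpy(dtype=float) @ T.T
    return pd.DataFrame(vals, index=coeffs.index,
                        columns=[f"age_{a:g}" for a in np.asarray(ages)])


def gebv_to_probability(age_gebv, threshold: float = 0.0):
    """Percent probability of being docile: 100 * Phi(t - u_j).

    Monotone decreasing in the liability GEBV; bounded in [0, 100].
    """
    arr = np.asarray(age_gebv, dtype=float)
    out = 100.0 * ndtr(threshold - arr)
    if isinstance(age_gebv, pd.DataFrame):
        return pd.DataFrame(out, index=age_gebv.index, columns=age_gebv.columns)
    return out


def classify_plasticity(slope_gebv, eps: float | None = None):
    """Habituation / neutral / sensitization from the liability slope.

    slope < -eps: habituation (docility rises with age); |slope| <= eps:
    neutral; slope > eps: sensitization.  ``eps=None`` uses 10% of the SD of
    the supplied slopes.
    """
    arr = np.asarray(slope_gebv, dtype=float)
    if eps is None:
        eps = 0.1 * float(np.std(arr)) if arr.size > 1 else 0.0
    if eps < 0:
        raise ValueError("eps must be non-negative")
    labels = np.where(arr < -eps, "habituation",
                      np.where(arr > eps, "sensitization", "neutral"))
    if isinstance(slope_gebv, pd.Series):
        return pd.Series(labels, index=slope_gebv.index, name="plasticity")
    return labels if arr.ndim else str(labels)


def gebv_report(coeffs: pd.DataFrame, basis: LegendreBasis, ages,
                threshold: float = 0.0, eps: float | None = None) -> pd.DataFrame:
    """Augment a coefficient GEBV table with per-age liabilities, per-age
    docility probabilities and the plasticity class."""
    age_gebv = coeff_to_age_gebv(coeffs, basis, ages)
    probs = gebv_to_probability(age_gebv, threshold)
    probs.columns = [c.replace("age_", "prob_docile_") for c in probs.columns]
    out = pd.concat([coeffs, age_gebv, probs], axis=1)
    if "slope" in coeffs.columns:
        out["plasticity"] = classify_plasticity(coeffs["slope"], eps)
    return out
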