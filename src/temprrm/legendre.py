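"""Legendre covariance-function machinery for random-regression models.

A first-order random regression assigns every animal an (intercept, slope)
coefficient pair; the basis evaluated at a standardized age maps coefficient
(co)variances onto age-specific variances, heritabilities and repeatabilities.
Normalized Legendre polynomials ``phi_m(a*) = sqrt((2m+1)/2) * P_m(a*)`` on
``a* in [-1, 1]`` are used, the usual convention in animal breeding; note that
normalization rescales the coefficient-level components, so the coefficient
matrices reported here are only comparable across software using the same
convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial import legendre as npleg

__all__ = [
    "LegendreBasis",
    "CoeffCovariances",
    "AgeCovariances",
    "standardize_age",
    "legendre_row",
    "basis_matrix",
    "coeff_to_age_cov",
    "heritability_repeatability_by_age",
    "component_ratio_summaries",
]

#: Mean ages (days) of the nine adult age groups, first (~3 y) to last (>10 y).
DEFAULT_AGE_GROUP_MEANS = (760.0, 1317.0, 1682.0, 2048.0, 2414.0, 2778.0,
                           3144.0, 3511.0, 4128.0)


@dataclass(frozen=True)
class LegendreBasis:
    """Normalized Legendre basis on ages standardized to [-1, 1].

    Parameters
    ----------
    order : int
        Polynomial order; 0 gives a constant (repeatability model), 1 gives
        intercept + slope.
    age_min, age_max : float
        Days mapped to -1 and +1. Defaults are the mean ages of the first and
        last adult age groups.
    """

    order: int = 1
    age_min: float = 760.0
    age_max: float = 4128.0

    def __post_init__(self) -> None:
        if self.order < 0:
            raise ValueError("order must be >= 0")
        if not self.age_max > self.age_min:
            raise ValueError("age_max must exceed age_min")

    @property
    def n_coeff(self) -> int:
        return self.order + 1


def standardize_age(age, basis: LegendreBasis):
    """Linearly map age in days onto [-1, 1]; ages outside the range clamp."""
    age = np.asarray(age, dtype=float)
    a = -1.0 + 2.0 * (age - basis.age_min) / (basis.age_max - basis.age_min)
    if np.any(a < -1.0) or np.any(a > 1.0):
        warnings.warn("age outside [age_min, age_max]; clamped to [-1, 1]",
                      stacklevel=2)
        a = np.clip(a, -1.0, 1.0)
    return a if a.ndim else float(a)


def legendre_row(a_star, order: int) -> np.ndarray:
    """Normalized Legendre values phi_0..phi_order at standardized age(s).

    phi_m(a*) = sqrt((2m+1)/2) * P_m(a*); for order 1 this is
    (sqrt(1/2), sqrt(3/2)*a*).
    """
    a_star = np.asarray(a_star, dtype=float)
    scalar = a_star.ndim == 0
    a = np.atleast_1d(a_star)
    out = np.empty((a.size, order + 1))
    for m in range(order + 1):
        coef = np.zeros(m + 1)
        coef[m] = 1.0
        out[:, m] = np.sqrt((2 * m + 1) / 2.0) * npleg.legval(a, coef)
    return out[0] if scalar else out


def basis_matrix(ages, basis: LegendreBasis) -> np.ndarray:
    """T matrix: one normalized-Legendre row per age (days)."""
    return np.atleast_2d(legendre_row(standardize_age(ages, basis), basis.order))


def _check_symmetric(K: np.ndarray, name: str, tol: float = 1e-8) -> np.ndarray:
    K = np.asarray(K, dtype=float)
    if K.ndim != 2 or K.shape[0] != K.shape[1]:
        raise ValueError(f"{name} must be square")
    if not np.allclose(K, K.T, atol=tol):
        raise ValueError(f"{name} must be symmetric")
    return K


@dataclass
class CoeffCovariances:
    """Coefficient-level (co)variance components of the random regression.

    G_u, R_p, R_q are (order+1)x(order+1) covariance matrices of the additive,
    permanent-environment and contemporary-group regression coefficients;
    sigma2_e is the (homogeneous) residual variance on the liability scale.
    """

    G_u: np.ndarray
    R_p: np.ndarray
    R_q: np.ndarray
    sigma2_e: float

    def __post_init__(self) -> None:
        self.G_u = _check_symmetric(self.G_u, "G_u")
        self.R_p = _check_symmetric(self.R_p, "R_p")
        self.R_q = _check_symmetric(self.R_q, "R_q")
        for name in ("G_u", "R_p", "R_q"):
            M = getattr(self, name)
            if np.linalg.eigvalsh(M).min() < -1e-8:
                raise ValueError(f"{name} must be positive semi-definite")
        if not self.sigma2_e > 0:
            raise ValueError("sigma2_e must be positive")

    @property
    def n_coeff(self) -> int:
        return self.G_u.shape[0]


def cov2x2(var_a: float, var_b: float, corr: float) -> np.ndarray:
    """Build a 2x2 covariance matrix from two variances and a correlation."""
    cov = corr * np.sqrt(var_a * var_b)
    return np.array([[var_a, cov], [cov, var_b]])


@dataclass
class AgeCovariances:
    """Age-group-level (co)variance matrices Sigma (additive), theta (PE),
    phi (CG), obtained as T K T' from the coefficient matrices."""

    additive: np.ndarray
    pe: np.ndarray
    cg: np.ndarray
    age_labels: list = field(default_factory=list)


def coeff_to_age_cov(K: np.ndarray, T: np.ndarray) -> np.ndarray:
    """Map a coefficient covariance K to the age scale: T K T'."""
    K = _check_symmetric(K, "K")
    T = np.atleast_2d(np.asarray(T, dtype=float))
    out = T @ K @ T.T
    return 0.5 * (out + out.T)


def age_covariances(cc: CoeffCovariances, T: np.ndarray,
                    age_labels=None) -> AgeCovariances:
    return AgeCovariances(
        additive=coeff_to_age_cov(cc.G_u, T),
        pe=coeff_to_age_cov(cc.R_p, T),
        cg=coeff_to_age_cov(cc.R_q, T),
        age_labels=list(age_labels) if age_labels is not None else [],
    )


def heritability_repeatability_by_age(ac: AgeCovariances, sigma2_e: float):
    """Per-age heritability and repeatability.

    h2_j = s2_u_j / (s2_u_j + s2_cg_j + s2_pe_j + s2_e);
    rep_j = (s2_u_j + s2_pe_j) / same denominator.
    Returns (h2, rep) arrays over age groups.
    """
    s2_u = np.diag(ac.additive)
    s2_pe = np.diag(ac.pe)
    s2_cg = np.diag(ac.cg)
    if np.any(s2_u < 0) or np.any(s2_pe < 0) or np.any(s2_cg < 0):
        raise ValueError("age-level variances must be non-negative")
    denom = s2_u + s2_cg + s2_pe + sigma2_e
    if np.any(denom <= 0):
        raise ValueError("zero phenotypic variance at some age")
    h2 = s2_u / denom
    rep = (s2_u + s2_pe) / denom
    return h2, rep


def component_ratio_summaries(cc: CoeffCovariances) -> dict:
    """Headline coefficient-variance ratios, rounded the way they are usually
    quoted: PE/additive for the slope, additive/PE for the intercept, and the
    slope additive variance as a percentage of the intercept additive
    variance."""
    if cc.n_coeff < 2:
        raise ValueError("ratio summaries need intercept and slope components")
    u_int, u_slope = cc.G_u[0, 0], cc.G_u[1, 1]
    pe_int, pe_slope = cc.R_p[0, 0], cc.R_p[1, 1]
    out = {}
    out["slope_pe_over_additive"] = (
        round(pe_slope / u_slope, 1) if u_slope > 0 else float("nan"))
    out["intercept_additive_over_pe"] = (
        round(u_int / pe_int, 1) if pe_int > 0 else float("nan"))
    out["slope_additive_pct_of_intercept"] = (
        round(100.0 * u_slope / u_int, 1) if u_int > 0 else float("nan"))
    return out
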