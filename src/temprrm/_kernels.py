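"""Numba kernels for the single-site / small-block Gibbs location updates.

Every model term (fixed level, contemporary-group regression, permanent
environment, additive genetic) is a collection of coefficient blocks of size
K; each block owns a list of records with a K-covariate row per record.  The
kernels draw each block from its Gaussian full conditional and keep the
residual vector e = l - linear_predictor in sync.
"""

import numpy as np
from numba import njit


@njit(cache=True, inline="always")
def _chol_small(C, L):
    """In-place Cholesky of a small SPD matrix C into L (lower)."""
    K = C.shape[0]
    for i in range(K):
        for j in range(K):
            L[i, j] = 0.0
    for i in range(K):
        for j in range(i + 1):
            s = C[i, j]
            for k in range(j):
                s -= L[i, k] * L[j, k]
            if i == j:
                L[i, i] = np.sqrt(s) if s > 1e-300 else 1e-150
            else:
                L[i, j] = s / L[j, j]


@njit(cache=True, inline="always")
def _draw_block(C, rhs, z, out):
    """out = C^-1 rhs + sample from N(0, C^-1), via C = L L'."""
    K = C.shape[0]
    L = np.empty((K, K))
    _chol_small(C, L)
    y = np.empty(K)
    for i in range(K):  # L y = rhs
        s = rhs[i]
        for k in range(i):
            s -= L[i, k] * y[k]
        y[i] = s / L[i, i]
    for i in range(K - 1, -1, -1):  # L' out = y + z
        s = y[i] + z[i]
        for k in range(i + 1, K):
            s -= L[k, i] * out[k]
        out[i] = s / L[i, i]


@njit(cache=True)
def update_iid_term(val, e, indptr, indices, cov, prior_prec, sigma2e, z):
    """Gibbs update of every block of an i.i.d.-prior term (flat prior when
    prior_prec is zero).  ``val`` (n_levels, K) and ``e`` are updated in
    place; ``cov`` rows align with ``indices``."""
    n_levels, K = val.shape
    inv_se = 1.0 / sigma2e
    C = np.empty((K, K))
    rhs = np.empty(K)
    vnew = np.empty(K)
    for lev in range(n_levels):
        lo, hi = indptr[lev], indptr[lev + 1]
        if hi == lo and prior_prec[0, 0] == 0.0:
            continue
        for a in range(K):
            rhs[a] = 0.0
            for b in range(K):
                C[a, b] = prior_prec[a, b]
        for idx in range(lo, hi):
            r = indices[idx]
            ypart = e[r]
            for b in range(K):
                ypart += cov[idx, b] * val[lev, b]
            for a in range(K):
                pa = cov[idx, a]
                rhs[a] += pa * ypart * inv_se
                for b in range(K):
                    C[a, b] += pa * cov[idx, b] * inv_se
        _draw_block(C, rhs, z[lev], vnew)
        for idx in range(lo, hi):
            r = indices[idx]
            delta = 0.0
            for b in range(K):
                delta += cov[idx, b] * (vnew[b] - val[lev, b])
            e[r] -= delta
        for b in range(K):
            val[lev, b] = vnew[b]


@njit(cache=True)
def update_genetic_pe_joint(u, p, pe_level, e, indptr, indices, cov, Ginv,
                            Rpinv, a_indptr, a_indices, a_data, sigma2e, z):
    """Joint Gibbs update of the additive and permanent-environment blocks of
    each animal (2K-dimensional draw).  Sampling them together removes the
    strong within-animal posterior correlation between u_i and p_i that makes
    single-site scans mix slowly.  ``pe_level[i]`` is the PE row of animal i,
    or -1 for animals without records (additive-only update)."""
    n, K = u.shape
    K2 = 2 * K
    inv_se = 1.0 / sigma2e
    C = np.empty((K2, K2))
    rhs = np.empty(K2)
    s = np.empty(K)
    vnew = np.empty(K2)
    for i in range(n):
        a_ii = 0.0
        for b in range(K):
            s[b] = 0.0
        for ptr in range(a_indptr[i], a_indptr[i + 1]):
            j = a_indices[ptr]
            if j == i:
                a_ii += a_data[ptr]
            else:
                w = a_data[ptr]
                for b in range(K):
                    s[b] += w * u[j, b]
        lev = pe_level[i]
        if lev == -1:
            # no records: u-only update against the pedigree prior
            for a in range(K):
                acc = 0.0
                for b in range(K):
                    C[a, b] = a_ii * Ginv[a, b]
                    acc += Ginv[a, b] * s[b]
                rhs[a] = -acc
            lo, hi = indptr[i], indptr[i + 1]
            for idx in range(lo, hi):
                r = indices[idx]
                ypart = e[r]
                for b in range(K):
                    ypart += cov[idx, b] * u[i, b]
                for a in range(K):
                    pa = cov[idx, a]
                    rhs[a] += pa * ypart * inv_se
                    for b in range(K):
                        C[a, b] += pa * cov[idx, b] * inv_se
            _draw_block(C[:K, :K], rhs[:K], z[i, :K], vnew[:K])
            for idx in range(lo, hi):
                r = indices[idx]
                delta = 0.0
                for b in range(K):
                    delta += cov[idx, b] * (vnew[b] - u[i, b])
                e[r] -= delta
            for b in range(K):
                u[i, b] = vnew[b]
            continue
        # joint (u_i, p_i)
        for a in range(K2):
            for b in range(K2):
                C[a, b] = 0.0
        for a in range(K):
            acc = 0.0
            for b in range(K):
                C[a, b] = a_ii * Ginv[a, b]
                C[K + a, K + b] = Rpinv[a, b]
                acc += Ginv[a, b] * s[b]
            rhs[a] = -acc
            rhs[K + a] = 0.0
        lo, hi = indptr[i], indptr[i + 1]
        for idx in range(lo, hi):
            r = indices[idx]
            ypart = e[r]
            for b in range(K):
                ypart += cov[idx, b] * (u[i, b] + p[lev, b])
            for a in range(K):
                pa = cov[idx, a] * inv_se
                rhs[a] += pa * ypart
                rhs[K + a] += pa * ypart
                for b in range(K):
                    pb = cov[idx, b]
                    C[a, b] += pa * pb
                    C[a, K + b] += pa * pb
                    C[K + a, b] += pa * pb
                    C[K + a, K + b] += pa * pb
        _draw_block(C, rhs, z[i], vnew)
        for idx in range(lo, hi):
            r = indices[idx]
            delta = 0.0
            for b in range(K):
                delta += cov[idx, b] * (vnew[b] - u[i, b]
                                        + vnew[K + b] - p[lev, b])
            e[r] -= delta
        for b in range(K):
            u[i, b] = vnew[b]
            p[lev, b] = vnew[K + b]


@njit(cache=True)
def update_genetic_term(u, e, indptr, indices, cov, Ginv, a_indptr, a_indices,
                        a_data, sigma2e, z):
    """Gibbs update of the additive blocks with prior N(0, G_u (x) A):
    block i has prior precision a^ii Ginv and prior mean pulled toward
    -sum_{j!=i} a^ij u_j."""
    n, K = u.shape
    inv_se = 1.0 / sigma2e
    C = np.empty((K, K))
    rhs = np.empty(K)
    s = np.empty(K)
    vnew = np.empty(K)
    for i in range(n):
        a_ii = 0.0
        for b in range(K):
            s[b] = 0.0
        for ptr in range(a_indptr[i], a_indptr[i + 1]):
            j = a_indices[ptr]
            if j == i:
                a_ii += a_data[ptr]
            else:
                w = a_data[ptr]
                for b in range(K):
                    s[b] += w * u[j, b]
        for a in range(K):
            acc = 0.0
            for b in range(K):
                C[a, b] = a_ii * Ginv[a, b]
                acc += Ginv[a, b] * s[b]
            rhs[a] = -acc
        lo, hi = indptr[i], indptr[i + 1]
        for idx in range(lo, hi):
            r = indices[idx]
            ypart = e[r]
            for b in range(K):
                ypart += cov[idx, b] * u[i, b]
            for a in range(K):
                pa = cov[idx, a]
                rhs[a] += pa * ypart * inv_se
                for b in range(K):
                    C[a, b] += pa * cov[idx, b] * inv_se
        _draw_block(C, rhs, z[i], vnew)
        for idx in range(lo, hi):
            r = indices[idx]
            delta = 0.0
            for b in range(K):
                delta += cov[idx, b] * (vnew[b] - u[i, b])
            e[r] -= delta
        for b in range(K):
            u[i, b] = vnew[b]
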