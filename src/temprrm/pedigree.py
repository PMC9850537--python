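"""Numerator relationship matrix machinery.

Pedigrees are plain DataFrames with columns ``animal``, ``sire``, ``dam``
(0 or blank meaning unknown) and optionally ``generation``.  Internally they
are converted to integer parent indices in topological (parents-first) order.
Unknown parents are treated as unrelated, non-inbred founders.

A is built by the tabular method with inbreeding; A-inverse by Henderson's
rules with inbreeding coefficients from the Meuwissen & Luo recursion, kept
sparse.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from numba import njit
from scipy import sparse

__all__ = [
    "PedigreeIndex",
    "sort_pedigree",
    "trace_generations",
    "inbreeding",
    "build_A",
    "build_A_inverse",
    "extract_A22",
    "RelationshipMatrix",
]

UNKNOWN = 0


class RelationshipMatrix:
    """A symmetric relationship matrix with its animal ordering."""

    def __init__(self, ids, values):
        self.ids = list(ids)
        self.values = values  # dense ndarray or scipy sparse
        n = len(self.ids)
        if values.shape != (n, n):
            raise ValueError("matrix shape does not match id list")
        self._pos = {a: i for i, a in enumerate(self.ids)}

    def toarray(self) -> np.ndarray:
        v = self.values
        return v.toarray() if sparse.issparse(v) else np.asarray(v)

    def loc(self, a, b) -> float:
        return float(self.toarray()[self._pos[a], self._pos[b]])

    def submatrix(self, ids) -> "RelationshipMatrix":
        idx = np.array([self._pos[a] for a in ids])
        dense = self.toarray()
        return RelationshipMatrix(list(ids), dense[np.ix_(idx, idx)])

    def to_coo_frame(self) -> pd.DataFrame:
        """Coordinate-format (i, j, value) export for inspection."""
        m = sparse.coo_matrix(self.values)
        return pd.DataFrame({
            "i": [self.ids[k] for k in m.row],
            "j": [self.ids[k] for k in m.col],
            "value": m.data,
        })


class PedigreeIndex:
    """Topologically sorted pedigree with integer parent pointers (-1 unknown)."""

    def __init__(self, ids, sire_idx, dam_idx):
        self.ids = list(ids)
        self.sire = np.asarray(sire_idx, dtype=np.int64)
        self.dam = np.asarray(dam_idx, dtype=np.int64)
        self.pos = {a: i for i, a in enumerate(self.ids)}

    @property
    def n(self) -> int:
        return len(self.ids)


def _as_ped_frame(ped: pd.DataFrame) -> pd.DataFrame:
    ped = ped.copy()
    for col in ("sire", "dam"):
        ped[col] = ped[col].fillna(UNKNOWN)
    return ped


def sort_pedigree(ped: pd.DataFrame) -> PedigreeIndex:
    """Topologically sort so parents precede offspring; raises on cycles."""
    ped = _as_ped_frame(ped)
    parents = {row.animal: (row.sire, row.dam) for row in ped.itertuples()}
    order: list = []
    state: dict = {}  # 0 visiting, 1 done

    for root in parents:
        if root in state:
            continue
        stack = [(root, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                state[node] = 1
                order.append(node)
                continue
            if state.get(node) == 1:
                continue
            if state.get(node) == 0:
                raise ValueError(f"pedigree cycle involving animal {node!r}")
            state[node] = 0
            stack.append((node, True))
            for par in parents.get(node, (UNKNOWN, UNKNOWN)):
                if par != UNKNOWN and state.get(par) != 1:
                    if par in parents:
                        stack.append((par, False))
                    else:
                        # parent appears only as a parent: implicit founder
                        state[par] = 1
                        order.append(par)
                        parents.setdefault(par, (UNKNOWN, UNKNOWN))

    pos = {a: i for i, a in enumerate(order)}
    sire = np.array([pos.get(parents[a][0], -1) if parents[a][0] != UNKNOWN
                     else -1 for a in order])
    dam = np.array([pos.get(parents[a][1], -1) if parents[a][1] != UNKNOWN
                    else -1 for a in order])
    return PedigreeIndex(order, sire, dam)


def trace_generations(ped: pd.DataFrame, phenotyped, k: int = 4) -> pd.DataFrame:
    """Restrict a pedigree to ancestors within ``k`` generations of the
    phenotyped animals (plus the phenotyped animals); parents beyond the
    horizon become unknown.  ``k=None`` traces the full ancestor closure."""
    ped = _as_ped_frame(ped)
    parents = {row.animal: (row.sire, row.dam) for row in ped.itertuples()}
    missing = [a for a in phenotyped if a not in parents]
    if missing:
        raise KeyError(f"phenotyped animals absent from pedigree: {missing[:5]}")

    depth = {a: 0 for a in phenotyped}
    frontier = list(phenotyped)
    while frontier:
        nxt = []
        for a in frontier:
            d = depth[a]
            if k is not None and d >= k:
                continue
            for par in parents.get(a, (UNKNOWN, UNKNOWN)):
                if par == UNKNOWN:
                    continue
                if par not in depth or depth[par] > d + 1:
                    depth[par] = d + 1
                    nxt.append(par)
        frontier = nxt

    keep = set(depth)
    rows = []
    for a in sorted(keep, key=lambda x: -depth[x]):
        s, d = parents.get(a, (UNKNOWN, UNKNOWN))
        rows.append({
            "animal": a,
            "sire": s if s in keep else UNKNOWN,
            "dam": d if d in keep else UNKNOWN,
        })
    return pd.DataFrame(rows, columns=["animal", "sire", "dam"])


@njit(cache=True)
def _inbreeding_ml(sire, dam):
    """Meuwissen & Luo recursion for inbreeding coefficients."""
    n = sire.size
    F = np.zeros(n)
    point = np.zeros(n, dtype=np.int64)
    w = np.zeros(n)
    for i in range(n):
        s, d = sire[i], dam[i]
        if s == -1 or d == -1:
            F[i] = 0.0
            continue
        # accumulate contributions of ancestors of i
        fi = -1.0
        point[:] = -1
        w[:] = 0.0
        w[i] = 1.0
        # process animals from i downwards (indices decrease toward founders)
        # maintain a linked list of active ancestors via boolean scan
        for j in range(i, -1, -1):
            if w[j] == 0.0:
                continue
            r = w[j]
            sj, dj = sire[j], dam[j]
            # additive variance of mendelian sampling for j
            if sj != -1 and dj != -1:
                vj = 0.5 - 0.25 * (F[sj] + F[dj])
            elif sj != -1 or dj != -1:
                vj = 0.75 - 0.25 * (F[sj] if sj != -1 else F[dj])
            else:
                vj = 1.0
            fi += r * r * vj
            if sj != -1:
                w[sj] += 0.5 * r
            if dj != -1:
                w[dj] += 0.5 * r
            w[j] = 0.0
        # a_ii = sum_j w_j^2 d_j over ancestors; F_i = a_ii - 1
        F[i] = fi
    return F


@njit(cache=True)
def _tabular_A(sire, dam):
    n = sire.size
    A = np.zeros((n, n))
    for i in range(n):
        s, d = sire[i], dam[i]
        if s != -1 and d != -1:
            A[i, i] = 1.0 + 0.5 * A[s, d]
        else:
            A[i, i] = 1.0
        for j in range(i):
            val = 0.0
            if s != -1:
                val += 0.5 * A[j, s]
            if d != -1:
                val += 0.5 * A[j, d]
            A[i, j] = val
            A[j, i] = val
    return A


def inbreeding(ped) -> np.ndarray:
    """Inbreeding coefficients F (diagonal of A minus one), by the
    ancestor-contribution recursion (no dense A needed)."""
    pidx = ped if isinstance(ped, PedigreeIndex) else sort_pedigree(ped)
    return _inbreeding_ml(pidx.sire, pidx.dam)


def build_A(ped: pd.DataFrame) -> RelationshipMatrix:
    """Numerator relationship matrix by the tabular method (with inbreeding)."""
    pidx = ped if isinstance(ped, PedigreeIndex) else sort_pedigree(ped)
    A = _tabular_A(pidx.sire, pidx.dam)
    return RelationshipMatrix(pidx.ids, A)


def build_A_inverse(ped: pd.DataFrame, sparse_out: bool = True) -> RelationshipMatrix:
    """Sparse A-inverse by Henderson's rules with inbreeding.

    Uses the Mendelian-sampling variances d_i = 0.5 - 0.25 (F_s + F_d)
    (0.75 - 0.25 F for one known parent, 1 for founders).
    """
    pidx = ped if isinstance(ped, PedigreeIndex) else sort_pedigree(ped)
    F = inbreeding(pidx)
    n = pidx.n
    rows, cols, vals = [], [], []
    for i in range(n):
        s, d = pidx.sire[i], pidx.dam[i]
        if s != -1 and d != -1:
            di = 0.5 - 0.25 * (F[s] + F[d])
        elif s != -1 or d != -1:
            di = 0.75 - 0.25 * (F[s] if s != -1 else F[d])
        else:
            di = 1.0
        inv_d = 1.0 / di
        rows.append(i); cols.append(i); vals.append(inv_d)
        for p in (s, d):
            if p == -1:
                continue
            rows += [i, p]; cols += [p, i]; vals += [-0.5 * inv_d, -0.5 * inv_d]
        for p in (s, d):
            if p == -1:
                continue
            for q in (s, d):
                if q == -1:
                    continue
                rows.append(p); cols.append(q); vals.append(0.25 * inv_d)
    Ainv = sparse.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    if not sparse_out:
        Ainv = Ainv.toarray()
    return RelationshipMatrix(pidx.ids, Ainv)


def extract_A22(A: RelationshipMatrix, genotyped) -> RelationshipMatrix:
    """Principal submatrix of A for the genotyped animals, in their order."""
    missing = [g for g in genotyped if g not in A._pos]
    if missing:
        raise KeyError(f"genotyped animals absent from A: {missing[:5]}")
    return A.submatrix(list(genotyped))
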