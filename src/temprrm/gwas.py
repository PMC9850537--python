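"""Single-step GWAS by back-solving GEBV into SNP and window effects.

Coefficient-level GEBV of the genotyped animals are projected onto SNP space
through u_c = M'(MM')^-1 GEBV_c with M the frequency-centered genotype
matrix; per-SNP coefficient pairs map to per-age-group effects through the
Legendre basis; overlapping 5-SNP windows within chromosome are summed, their
explained share of the additive variance computed from the empirical variance
of the window's genomic values, and the top windows selected with greedy
non-overlap.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .legendre import LegendreBasis, basis_matrix

__all__ = ["backsolve_snp_effects", "snp_effects_by_age", "window_effects",
           "window_variance_explained", "select_top_windows",
           "interval_overlap", "read_bed"]


def backsolve_snp_effects(M: pd.DataFrame, gebv: pd.DataFrame,
                          p: np.ndarray | None = None) -> pd.DataFrame:
    """SNP solutions per regression coefficient: u_c = M'(MM')^-1 GEBV_c.

    ``M`` holds {-1,0,1} codes indexed by animal (centered internally by the
    observed allele frequencies, or by ``p`` when given); ``gebv`` holds one
    column per coefficient for a subset of the genotyped animals.  A singular
    MM' falls back to the pseudo-inverse (minimum-norm projection) with a
    warning.
    """
    missing = set(gebv.index) - set(M.index)
    if missing:
        raise KeyError(f"GEBV animals not genotyped: {sorted(missing)[:5]}")
    Msub = M.loc[gebv.index]
    if p is None:
        p = (M.to_numpy(dtype=float) + 1.0).mean(axis=0) / 2.0
    Z = Msub.to_numpy(dtype=float) - (2.0 * p - 1.0)
    ZZt = Z @ Z.T
    rhs = gebv.to_numpy(dtype=float)
    if np.linalg.matrix_rank(ZZt) < ZZt.shape[0]:
        warnings.warn("MM' is singular; using the pseudo-inverse "
                      "(minimum-norm projection)", stacklevel=2)
        sol = np.linalg.lstsq(ZZt, rhs, rcond=None)[0]
    else:
        sol = np.linalg.solve(ZZt, rhs)
    effects = Z.T @ sol
    return pd.DataFrame(effects, index=pd.Index(M.columns, name="snp"),
                        columns=list(gebv.columns))


def snp_effects_by_age(effects: pd.DataFrame, basis: LegendreBasis,
                       ages, snp_map: pd.DataFrame | None = None,
                       docility_sign: bool = False) -> pd.DataFrame:
    """Per-age-group SNP effects: each SNP's age profile is T times its
    coefficient vector.  ``docility_sign=True`` negates the liability-scale
    effects so that increasing values mean becoming more docile."""
    T = basis_matrix(np.asarray(ages, dtype=float), basis)
    vals = effects.to_numpy(dtype=float) @ T.T
    if docility_sign:
        vals = -vals
    out = pd.DataFrame(vals, index=effects.index,
                       columns=[f"age_{a:g}" for a in ages])
    if snp_map is not None:
        meta = snp_map.set_index("snp").loc[out.index, ["chrom", "pos"]]
        out = pd.concat([meta, out], axis=1)
    return out


def _window_spans(snp_map: pd.DataFrame, size: int, step: int):
    """Yield (chrom, index array) per window; SNPs must be map-sorted."""
    for chrom, grp in snp_map.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        if len(idx) < size:
            warnings.warn(f"chromosome {chrom} has fewer than {size} SNPs; "
                          "emitting one short window", stacklevel=3)
            yield chrom, idx
            continue
        for start in range(0, len(idx) - size + 1, step):
            yield chrom, idx[start:start + size]


def window_effects(effects: pd.DataFrame, snp_map: pd.DataFrame,
                   size: int = 5, step: int = 1) -> pd.DataFrame:
    """Sliding-window sums of SNP effects within chromosome.

    ``effects`` is indexed by SNP (any set of effect columns: coefficients or
    age groups); windows never span chromosomes.  Positions reported 1-based
    inclusive.
    """
    snp_map = snp_map.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    eff = effects.loc[snp_map["snp"]].to_numpy(dtype=float)
    rows = []
    for wid, (chrom, idx) in enumerate(_window_spans(snp_map, size, step)):
        sums = eff[idx].sum(axis=0)
        rows.append({
            "window": wid, "chrom": chrom,
            "start_snp": snp_map.loc[idx[0], "snp"],
            "end_snp": snp_map.loc[idx[-1], "snp"],
            "start_pos": int(snp_map.loc[idx[0], "pos"]),
            "end_pos": int(snp_map.loc[idx[-1], "pos"]),
            "first_index": int(idx[0]), "last_index": int(idx[-1]),
            **{c: s for c, s in zip(effects.columns, sums)},
        })
    return pd.DataFrame(rows)


def window_variance_explained(M: pd.DataFrame, effects: pd.DataFrame,
                              snp_map: pd.DataFrame, total_variance: dict,
                              size: int = 5, step: int = 1,
                              p: np.ndarray | None = None) -> pd.DataFrame:
    """Percentage of the additive variance explained per window and
    coefficient: 100 * Var(Z_w u_w,c) / sigma2_u,c, with Var the empirical
    variance of the window's genomic values across genotyped animals."""
    snp_map = snp_map.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    if p is None:
        p = (M.to_numpy(dtype=float) + 1.0).mean(axis=0) / 2.0
    Zfull = M.to_numpy(dtype=float) - (2.0 * p - 1.0)
    col_of = {s: j for j, s in enumerate(M.columns)}
    eff = effects.loc[snp_map["snp"]].to_numpy(dtype=float)
    rows = []
    for wid, (chrom, idx) in enumerate(_window_spans(snp_map, size, step)):
        cols = [col_of[s] for s in snp_map.loc[idx, "snp"]]
        Zw = Zfull[:, cols]
        row = {"window": wid, "chrom": chrom,
               "start_pos": int(snp_map.loc[idx[0], "pos"]),
               "end_pos": int(snp_map.loc[idx[-1], "pos"])}
        for c_i, cname in enumerate(effects.columns):
            tot = total_variance[cname]
            gv = Zw @ eff[idx, c_i]
            if tot <= 0:
                row[f"pct_var_{cname}"] = float("nan")
            else:
                row[f"pct_var_{cname}"] = 100.0 * float(np.var(gv)) / tot
        rows.append(row)
    out = pd.DataFrame(rows)
    if any(v <= 0 for v in total_variance.values()):
        warnings.warn("zero total additive variance for some coefficient; "
                      "explained shares undefined", stacklevel=2)
    return out


def select_top_windows(w: pd.DataFrame, criterion: str,
                       mode: str = "top_n", n: int = 20,
                       pct: float = 0.20) -> pd.DataFrame:
    """Rank windows on |criterion| and keep the best with greedy non-overlap.

    ``mode='top_n'`` keeps the ``n`` best; ``mode='min_pct'`` keeps every
    non-overlapping window with criterion above ``pct``.  Overlap means
    sharing any SNP index on the same chromosome; ties break by
    (chromosome, position).
    """
    if w.empty:
        raise ValueError("empty window table")
    if mode not in ("top_n", "min_pct"):
        raise ValueError("mode must be 'top_n' or 'min_pct'")
    tab = w.copy()
    key = tab[criterion].abs() if mode == "top_n" else tab[criterion]
    tab["_key"] = key
    tab = tab.sort_values(["_key", "chrom", "start_pos"],
                          ascending=[False, True, True], kind="stable")
    chosen = []
    occupied: dict = {}
    for _, row in tab.iterrows():
        if mode == "min_pct" and row["_key"] <= pct:
            break
        span = set(range(int(row.get("first_index", row["start_pos"])),
                         int(row.get("last_index", row["end_pos"])) + 1))
        used = occupied.setdefault(row["chrom"], set())
        if span & used:
            continue
        used |= span
        chosen.append(row)
        if mode == "top_n" and len(chosen) >= n:
            break
    out = pd.DataFrame(chosen).drop(columns="_key", errors="ignore")
    return out.reset_index(drop=True)


def read_bed(path) -> pd.DataFrame:
    """Read a BED file (0-based, half-open) into chrom/start/end (+name)."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed interval at line {ln}")
            try:
                chrom = parts[0]
                start, end = int(parts[1]), int(parts[2])
            except ValueError as err:
                raise ValueError(f"malformed interval at line {ln}") from err
            rows.append({"chrom": chrom, "start": start, "end": end,
                         "name": parts[3] if len(parts) > 3 else f"iv{ln}"})
    return pd.DataFrame(rows)


def interval_overlap(windows: pd.DataFrame,
                     annotation: pd.DataFrame) -> pd.DataFrame:
    """List every (window, interval) pair overlapping by at least 1 bp.

    Windows carry 1-based inclusive [start_pos, end_pos]; annotation rows are
    0-based half-open [start, end) as read from BED.
    """
    rows = []
    ann = annotation.copy()
    ann["chrom_str"] = ann["chrom"].astype(str)
    for _, wrow in windows.iterrows():
        w_lo0 = int(wrow["start_pos"]) - 1        # 0-based half-open window
        w_hi0 = int(wrow["end_pos"])
        sub = ann[ann["chrom_str"] == str(wrow["chrom"])]
        for _, arow in sub.iterrows():
            ov = min(w_hi0, arow["end"]) - max(w_lo0, arow["start"])
            if ov > 0:
                rows.append({"window": wrow["window"], "chrom": wrow["chrom"],
                             "window_start": int(wrow["start_pos"]),
                             "window_end": int(wrow["end_pos"]),
                             "interval": arow["name"],
                             "interval_start": int(arow["start"]),
                             "interval_end": int(arow["end"]),
                             "overlap_bp": int(ov)})
    return pd.DataFrame(rows, columns=["window", "chrom", "window_start",
                                       "window_end", "interval",
                                       "interval_start", "interval_end",
                                       "overlap_bp"])
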