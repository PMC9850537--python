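"""SNP quality control, genomic relationship matrix, and the single-step
H-inverse combination of pedigree and genomic information.

Genotypes are DataFrames of {-1, 0, 1} codes (aa/Aa/AA) indexed by animal,
with missing calls as NaN, accompanied by a SNP map (snp, chrom, pos,
1-based).  G follows VanRaden's first method: with allele frequencies p from
the observed post-QC data, Z = M - (2p - 1) and G = ZZ' / (2 * sum p(1-p)).
H-inverse adds the genomic deviation (G*^-1 - A22^-1) on the genotyped block
of A-inverse.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

from .pedigree import RelationshipMatrix

__all__ = ["QCReport", "snp_qc", "allele_frequencies", "center_genotypes",
           "build_G", "blend_and_tune_G", "build_H_inverse"]

CATTLE_AUTOSOMES = frozenset(range(1, 30))


@dataclass
class QCReport:
    """Per-filter removal counts; removals + survivors = input."""

    n_animals_in: int = 0
    n_snps_in: int = 0
    animals_low_call_rate: int = 0
    snps_low_call_rate: int = 0
    snps_low_maf: int = 0
    snps_hwe_deviation: int = 0
    snps_non_autosomal: int = 0
    n_animals_out: int = 0
    n_snps_out: int = 0
    extra: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(self)]).drop(columns="extra")


def allele_frequencies(M: pd.DataFrame) -> np.ndarray:
    """Observed frequency of the A allele per SNP (codes -1/0/1 = 0/1/2
    copies), ignoring missing calls."""
    vals = M.to_numpy(dtype=float)
    return np.nanmean(vals + 1.0, axis=0) / 2.0


def snp_qc(M: pd.DataFrame, snp_map: pd.DataFrame,
           animal_cr: float = 0.90, snp_cr: float = 0.90,
           maf: float = 0.01, hwe_dev: float = 0.15,
           autosomes=CATTLE_AUTOSOMES):
    """Apply the standard genotype filters, in an order-independent way.

    Removes animals with call rate below ``animal_cr``; then SNPs with call
    rate below ``snp_cr``, minor allele frequency below ``maf``, an absolute
    deviation of the observed heterozygote frequency from its Hardy-Weinberg
    expectation 2p(1-p) above ``hwe_dev``, or a chromosome outside
    ``autosomes``.  Remaining missing calls are imputed to the heterozygote
    code 0 (the mean after frequency centering).  Returns
    ``(M_clean, snp_map_clean, report)``.
    """
    report = QCReport(n_animals_in=M.shape[0], n_snps_in=M.shape[1])
    vals = M.to_numpy(dtype=float)

    a_cr = 1.0 - np.isnan(vals).mean(axis=1)
    keep_a = a_cr >= animal_cr
    report.animals_low_call_rate = int((~keep_a).sum())
    vals = vals[keep_a]

    s_cr = 1.0 - np.isnan(vals).mean(axis=0)
    p = np.nanmean(vals + 1.0, axis=0) / 2.0
    with np.errstate(invalid="ignore"):
        maf_obs = np.minimum(p, 1.0 - p)
        het_obs = np.nanmean(vals == 0.0, axis=0)
        het_exp = 2.0 * p * (1.0 - p)
    chrom = snp_map.set_index("snp").loc[M.columns, "chrom"].to_numpy()
    auto_ok = np.isin(chrom, list(autosomes))

    fail_cr = s_cr < snp_cr
    fail_maf = maf_obs < maf
    fail_hwe = np.abs(het_obs - het_exp) > hwe_dev
    # order-independent accounting: each SNP counted under every filter it fails
    report.snps_low_call_rate = int(fail_cr.sum())
    report.snps_low_maf = int(np.nan_to_num(fail_maf, nan=True).sum())
    report.snps_hwe_deviation = int(np.nan_to_num(fail_hwe, nan=False).sum())
    report.snps_non_autosomal = int((~auto_ok).sum())
    keep_s = ~(fail_cr | np.nan_to_num(fail_maf, nan=True)
               | np.nan_to_num(fail_hwe, nan=False) | ~auto_ok)

    if not keep_s.any():
        raise ValueError("quality control removed every SNP")

    out = M.loc[keep_a, M.columns[keep_s]].copy()
    out = out.fillna(0.0).astype(np.int8)
    map_out = snp_map[snp_map["snp"].isin(out.columns)].reset_index(drop=True)
    report.n_animals_out, report.n_snps_out = out.shape
    return out, map_out, report


def center_genotypes(M: pd.DataFrame, p: np.ndarray | None = None) -> np.ndarray:
    """Frequency-centered genotype matrix Z = M - (2p - 1)."""
    if p is None:
        p = allele_frequencies(M)
    return M.to_numpy(dtype=float) - (2.0 * p - 1.0)


def build_G(M: pd.DataFrame, p: np.ndarray | None = None) -> RelationshipMatrix:
    """Genomic relationship matrix, VanRaden method 1."""
    if p is None:
        p = allele_frequencies(M)
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    if denom <= 0:
        raise ValueError("all SNPs monomorphic; G scaling denominator is zero")
    Z = center_genotypes(M, p)
    G = Z @ Z.T / denom
    return RelationshipMatrix(list(M.index), 0.5 * (G + G.T))


def blend_and_tune_G(G: RelationshipMatrix, A22: RelationshipMatrix,
                     blend: float = 0.05, tune: bool = False) -> RelationshipMatrix:
    """G* = (1 - blend) G + blend A22, guaranteeing invertibility.

    With ``tune=True`` G is first rescaled so its mean diagonal and mean
    off-diagonal match those of A22 (simple two-coefficient tuning).
    """
    if not 0.0 <= blend <= 1.0:
        raise ValueError("blend must lie in [0, 1]")
    if G.ids != A22.ids:
        raise ValueError("G and A22 must index the same animals in the same order")
    Gm, Am = G.toarray(), A22.toarray()
    if tune and len(G.ids) > 1:
        n = Gm.shape[0]
        off = ~np.eye(n, dtype=bool)
        a_diag, g_diag = Am.diagonal().mean(), Gm.diagonal().mean()
        a_off, g_off = Am[off].mean(), Gm[off].mean()
        beta = (a_diag - a_off) / max(g_diag - g_off, 1e-12)
        alpha = a_off - beta * g_off
        Gm = alpha + beta * Gm
    return RelationshipMatrix(G.ids, (1.0 - blend) * Gm + blend * Am)


def build_H_inverse(A_inv: RelationshipMatrix, A22: RelationshipMatrix,
                    G_star: RelationshipMatrix,
                    tau: float = 1.0, omega: float = 1.0) -> RelationshipMatrix:
    """Single-step H-inverse: A-inverse plus the genomic deviation
    tau G*^-1 - omega A22^-1 added on the genotyped block."""
    if A22.ids != G_star.ids:
        raise ValueError("A22 and G* orderings differ")
    idx = [A_inv._pos[a] for a in A22.ids]
    try:
        G_inv = np.linalg.inv(G_star.toarray())
    except np.linalg.LinAlgError as err:
        raise ValueError("G* is singular; blend with A22 first") from err
    try:
        A22_inv = np.linalg.inv(A22.toarray())
    except np.linalg.LinAlgError as err:
        raise ValueError("A22 is singular") from err
    delta = tau * G_inv - omega * A22_inv

    n = len(A_inv.ids)
    base = sparse.lil_matrix(sparse.csr_matrix(A_inv.values)
                             if not sparse.issparse(A_inv.values)
                             else A_inv.values.copy())
    for r, i in enumerate(idx):
        for c, j in enumerate(idx):
            base[i, j] += delta[r, c]
    return RelationshipMatrix(A_inv.ids, base.tocsr())
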