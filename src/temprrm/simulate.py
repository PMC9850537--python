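"""Synthetic herds for the longitudinal temperament analysis.

Generates (i) a multi-generation pedigree, (ii) gene-dropped biallelic SNP
genotypes, and (iii) repeated ordinal temperament records per cow at roughly
yearly ages, produced from the threshold (liability) random-regression model
the analysis assumes: each cow carries additive (intercept, slope) breeding
values correlated through the pedigree (``u ~ N(0, G_u (x) A)``), independent
permanent-environment and contemporary-group regression coefficients, fixed
liability shifts for conception type and herd-year-season, and an i.i.d.
normal residual.  The liability is cut by ordered thresholds into scores.

Defaults mirror the study conditions this package targets: coefficient
(co)variances G_u = [[0.396, c], [c, 0.013]] with genetic correlation 0.744,
PE [[0.143, 0], [0, 0.021]], CG [[0.004, 0], [0, 0.005]], residual 0.129,
thresholds (0, 1, 1.4) for four collapsed score categories, ages on a yearly
grid from 760 to 4128 days, and 1-11 records per cow with mean ~1.7.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .legendre import CoeffCovariances, LegendreBasis, cov2x2, legendre_row, standardize_age
from .pedigree import PedigreeIndex, inbreeding, sort_pedigree

__all__ = ["SimConfig", "simulate_pedigree", "gene_drop_genotypes",
           "simulate_phenotypes", "simulate_breeding_values",
           "write_dataset", "read_dataset", "default_components"]


def default_components() -> CoeffCovariances:
    """Ground-truth coefficient (co)variances used as simulation defaults."""
    return CoeffCovariances(
        G_u=cov2x2(0.396, 0.013, 0.744),
        R_p=np.diag([0.143, 0.021]),
        R_q=np.diag([0.004, 0.005]),
        sigma2_e=0.129,
    )


def _default_age_schedule() -> tuple:
    # yearly grid from first to last adult age-group mean
    return tuple(760.0 + 365.25 * k for k in range(10))


@dataclass
class SimConfig:
    """Configuration of the synthetic herd generator."""

    n_founders: int = 40
    n_generations: int = 3
    n_per_generation: int | None = None  # defaults to n_founders
    n_snps: int = 500
    allele_freq_range: tuple = (0.05, 0.95)
    age_schedule: tuple = field(default_factory=_default_age_schedule)
    true_components: CoeffCovariances = field(default_factory=default_components)
    thresholds: tuple = (0.0, 1.0, 1.4)
    cg_count: int = 20
    fixed_effects: dict = field(default_factory=lambda: {
        "conception": {"natural": -0.10, "et": 0.05},
        "hys": {"h1": 0.00, "h2": 0.08, "h3": -0.08},
    })
    mean_records: float = 1.7
    min_records: int = 1
    max_records: int = 11
    et_fraction: float = 0.3  # share of embryo-transfer conceptions
    sire_fraction: float = 0.05  # share of males used as sires (half-sib families)
    basis: LegendreBasis = field(default_factory=LegendreBasis)
    n_chromosomes: int = 29
    seed: int = 0

    def __post_init__(self) -> None:
        t = np.asarray(self.thresholds, dtype=float)
        if t.size and (np.any(np.diff(t) <= 0)):
            raise ValueError("thresholds must be strictly increasing")
        if t.size and t[0] != 0.0:
            raise ValueError("first threshold must equal 0")
        ages = np.asarray(self.age_schedule, dtype=float)
        if np.any(ages < 760.0):
            raise ValueError("age_schedule entries must be >= 760 days")
        if ages.size > 1 and np.any(np.diff(ages) < 268.0):
            raise ValueError("consecutive schedule ages must be >= 268 days apart")
        if not (0 <= self.allele_freq_range[0] <= self.allele_freq_range[1] <= 1):
            raise ValueError("allele_freq_range must be an ordered pair in [0,1]")
        if self.min_records < 1 or self.max_records < self.min_records:
            raise ValueError("invalid record-count bounds")


def simulate_pedigree(cfg: SimConfig) -> pd.DataFrame:
    """Random multi-generation pedigree with both sexes in every generation.

    Returns columns animal, sire, dam, generation, sex ('M'/'F'); 0 denotes
    an unknown parent.  Non-founders always take their sire and dam from the
    previous generation.
    """
    if cfg.n_founders < 2:
        raise ValueError("need at least two founders to mate")
    rng = np.random.default_rng(cfg.seed)
    n_gen = cfg.n_per_generation or cfg.n_founders

    rows = []
    next_id = 1

    def draw_sexes(n):
        sexes = rng.integers(0, 2, size=n)
        if sexes.min() == sexes.max():  # force both sexes present
            sexes[rng.integers(0, n)] = 1 - sexes[0]
        return sexes

    sexes = draw_sexes(cfg.n_founders)
    males = [next_id + i for i in range(cfg.n_founders) if sexes[i] == 0]
    females = [next_id + i for i in range(cfg.n_founders) if sexes[i] == 1]
    for i in range(cfg.n_founders):
        rows.append((next_id, 0, 0, 0, "M" if sexes[i] == 0 else "F"))
        next_id += 1

    for g in range(1, cfg.n_generations + 1):
        sexes = draw_sexes(n_gen)
        # few sires with many progeny, as in commercial herds; dams spread
        n_sires = max(1, int(round(cfg.sire_fraction * len(males))))
        active_sires = rng.choice(males, size=n_sires, replace=False)
        sires = rng.choice(active_sires, size=n_gen)
        dams = rng.choice(females, size=n_gen)
        males, females = [], []
        for i in range(n_gen):
            sex = "M" if sexes[i] == 0 else "F"
            rows.append((next_id, int(sires[i]), int(dams[i]), g, sex))
            (males if sex == "M" else females).append(next_id)
            next_id += 1

    return pd.DataFrame(rows, columns=["animal", "sire", "dam", "generation", "sex"])


def gene_drop_genotypes(ped: pd.DataFrame, cfg: SimConfig):
    """Drop founder alleles through the pedigree at unlinked biallelic SNPs.

    Founders are drawn in Hardy-Weinberg proportions at frequencies uniform in
    ``allele_freq_range``; each offspring receives one allele per parent by
    Mendelian segregation (a missing parent's gamete is sampled from the
    founder frequency).  Returns ``(M, snp_map, freqs)`` where ``M`` is a
    DataFrame of {-1, 0, 1} codes (aa/Aa/AA) indexed by animal.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    pidx = sort_pedigree(ped)
    n, m = pidx.n, cfg.n_snps
    lo, hi = cfg.allele_freq_range
    p = rng.uniform(lo, hi, size=m)

    # paternal/maternal allele per animal per SNP
    pat = np.empty((n, m), dtype=np.int8)
    mat = np.empty((n, m), dtype=np.int8)
    for i in range(n):
        s, d = pidx.sire[i], pidx.dam[i]
        if s == -1:
            pat[i] = rng.random(m) < p
        else:
            het = rng.integers(0, 2, size=m).astype(np.int8)
            pat[i] = np.where(pat[s] == mat[s], pat[s],
                              np.where(het == 1, pat[s], mat[s]))
        if d == -1:
            mat[i] = rng.random(m) < p
        else:
            het = rng.integers(0, 2, size=m).astype(np.int8)
            mat[i] = np.where(pat[d] == mat[d], pat[d],
                              np.where(het == 1, pat[d], mat[d]))

    codes = (pat.astype(np.int16) + mat.astype(np.int16) - 1).astype(np.int8)
    snp_ids = [f"snp{j + 1}" for j in range(m)]
    chrom = np.arange(m) % cfg.n_chromosomes + 1
    # positions increase within chromosome, 1-based
    pos = np.arange(m) // cfg.n_chromosomes * 10_000 + 1
    order = np.lexsort((pos, chrom))
    M = pd.DataFrame(codes[:, order], index=pd.Index(pidx.ids, name="animal"),
                     columns=[snp_ids[j] for j in order])
    snp_map = pd.DataFrame({"snp": [snp_ids[j] for j in order],
                            "chrom": chrom[order], "pos": pos[order]})
    return M, snp_map, p[order]


def simulate_breeding_values(ped: pd.DataFrame, G_u: np.ndarray,
                             rng: np.random.Generator) -> pd.DataFrame:
    """Draw coefficient breeding values u ~ N(0, G_u (x) A) by the pedigree
    recursion: u_i = (u_s + u_d)/2 + m_i with Mendelian-sampling covariance
    G_u * d_i, d_i = 0.5 - 0.25 (F_s + F_d)."""
    pidx = ped if isinstance(ped, PedigreeIndex) else sort_pedigree(ped)
    F = inbreeding(pidx)
    k = G_u.shape[0]
    L = np.linalg.cholesky(G_u + 1e-12 * np.eye(k))
    u = np.zeros((pidx.n, k))
    z = rng.standard_normal((pidx.n, k))
    for i in range(pidx.n):
        s, d = pidx.sire[i], pidx.dam[i]
        if s != -1 and d != -1:
            mean = 0.5 * (u[s] + u[d])
            di = 0.5 - 0.25 * (F[s] + F[d])
        elif s != -1 or d != -1:
            par = s if s != -1 else d
            mean = 0.5 * u[par]
            di = 0.75 - 0.25 * F[par]
        else:
            mean, di = 0.0, 1.0
        u[i] = mean + np.sqrt(di) * (L @ z[i])
    return pd.DataFrame(u, index=pd.Index(pidx.ids, name="animal"),
                        columns=[f"u_{c}" for c in ("intercept", "slope", "quad")[:k]])


def simulate_phenotypes(ped: pd.DataFrame, cfg: SimConfig):
    """Longitudinal ordinal records for every female in the pedigree.

    Record counts are drawn from a geometric distribution truncated to
    ``[min_records, max_records]`` with mean matched to ``mean_records``; each
    cow's record ages are a sorted random subset of the yearly age schedule
    (cows enter the recorded herd at different ages and are not scored at
    every weaning), which spreads records across the age range the way field
    recording does.  Returns ``(phenotypes, truth)`` where ``truth`` holds
    the per-animal true (intercept, slope) breeding values.
    """
    cc = cfg.true_components
    thresholds = np.asarray(cfg.thresholds, dtype=float)
    if np.any(np.diff(thresholds) <= 0):
        raise ValueError("thresholds must be strictly increasing")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    k = cc.n_coeff

    u = simulate_breeding_values(ped, cc.G_u, rng)
    cows = ped.loc[ped["sex"] == "F", "animal"].tolist() if "sex" in ped else \
        ped["animal"].tolist()

    # per-animal PE and per-CG coefficients
    Lp = np.linalg.cholesky(cc.R_p + 1e-12 * np.eye(k))
    Lq = np.linalg.cholesky(cc.R_q + 1e-12 * np.eye(k))
    p_coef = {a: Lp @ rng.standard_normal(k) for a in cows}
    q_coef = {c: Lq @ rng.standard_normal(k) for c in range(cfg.cg_count)}

    # truncated-geometric record counts matched to the target mean
    succ = _geometric_success_prob(cfg.mean_records, cfg.min_records,
                                   cfg.max_records)
    counts = cfg.min_records + rng.geometric(succ, size=len(cows)) - 1
    counts = np.minimum(counts, cfg.max_records)

    conc_levels = list(cfg.fixed_effects.get("conception", {"natural": 0.0}))
    hys_levels = list(cfg.fixed_effects.get("hys", {"h1": 0.0}))
    schedule = np.asarray(cfg.age_schedule, dtype=float)

    rows = []
    for ci, animal in enumerate(cows):
        n_rec = int(min(counts[ci], schedule.size))
        ages = np.sort(rng.choice(schedule, size=n_rec, replace=False))
        conception = conc_levels[0] if rng.random() > cfg.et_fraction else conc_levels[-1]
        ui = u.loc[animal].to_numpy()
        pi = p_coef[animal]
        for age in ages:
            cg = int(rng.integers(0, cfg.cg_count))
            hys = hys_levels[int(rng.integers(0, len(hys_levels)))]
            phi = legendre_row(standardize_age(age, cfg.basis), cc.n_coeff - 1)
            liab = (cfg.fixed_effects["conception"][conception]
                    + cfg.fixed_effects["hys"][hys]
                    + phi @ ui + phi @ pi + phi @ q_coef[cg]
                    + np.sqrt(cc.sigma2_e) * rng.standard_normal())
            score = 1 + int(np.searchsorted(thresholds, liab, side="left"))
            rows.append((animal, score, float(age), f"cg{cg}", conception, hys))

    pheno = pd.DataFrame(rows, columns=["animal", "score", "age_days", "cg",
                                        "conception", "hys"])
    truth = u.reset_index()
    return pheno, truth


def _geometric_success_prob(mean: float, lo: int, hi: int) -> float:
    """Success probability of a geometric count shifted to start at ``lo``
    whose truncated mean matches ``mean`` (bisection; mean clipped to the
    attainable range)."""
    mean = min(max(mean, lo + 1e-6), hi - 1e-6)

    def trunc_mean(p):
        ks = np.arange(lo, hi + 1)
        pmf = (1 - p) ** (ks - lo) * p
        pmf[-1] = (1 - p) ** (hi - lo)  # lump the tail at the cap
        pmf /= pmf.sum()
        return float((ks * pmf).sum())

    lo_p, hi_p = 1e-6, 1 - 1e-6
    for _ in range(80):
        mid = 0.5 * (lo_p + hi_p)
        if trunc_mean(mid) > mean:
            lo_p = mid
        else:
            hi_p = mid
    return 0.5 * (lo_p + hi_p)


# ---------------------------------------------------------------------------
# dataset round-trip

def write_dataset(ped: pd.DataFrame, geno, pheno: pd.DataFrame,
                  outdir, truth: pd.DataFrame | None = None,
                  components: CoeffCovariances | None = None,
                  thresholds=None) -> dict:
    """Write pedigree.csv, phenotypes.csv, genotypes.tsv + snps.map and,
    when supplied, truth.csv / truth.json to ``outdir``.

    ``geno`` is the (M, snp_map, freqs) triple from :func:`gene_drop_genotypes`
    or None.  Raises if phenotype or genotype animals are missing from the
    pedigree.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ped_ids = set(ped["animal"])
    bad = sorted(set(pheno["animal"]) - ped_ids)
    if bad:
        raise ValueError(f"phenotyped animals absent from pedigree: {bad[:10]}")

    paths = {"pedigree": outdir / "pedigree.csv",
             "phenotypes": outdir / "phenotypes.csv"}
    ped.to_csv(paths["pedigree"], index=False)
    pheno.to_csv(paths["phenotypes"], index=False)

    if geno is not None:
        M, snp_map, _ = geno
        bad = sorted(set(M.index) - ped_ids)
        if bad:
            raise ValueError(f"genotyped animals absent from pedigree: {bad[:10]}")
        paths["genotypes"] = outdir / "genotypes.tsv"
        paths["snp_map"] = outdir / "snps.map"
        M.to_csv(paths["genotypes"], sep="\t")
        snp_map.to_csv(paths["snp_map"], sep="\t", index=False)

    if truth is not None:
        paths["truth"] = outdir / "truth.csv"
        truth.to_csv(paths["truth"], index=False)
    if components is not None:
        paths["truth_components"] = outdir / "truth.json"
        payload = {"G_u": components.G_u.tolist(),
                   "R_p": components.R_p.tolist(),
                   "R_q": components.R_q.tolist(),
                   "sigma2_e": components.sigma2_e}
        if thresholds is not None:
            payload["thresholds"] = list(map(float, thresholds))
        paths["truth_components"].write_text(json.dumps(payload, indent=1))
    return {k: str(v) for k, v in paths.items()}


def read_dataset(outdir) -> dict:
    """Read back a directory written by :func:`write_dataset`."""
    outdir = Path(outdir)
    out = {"pedigree": pd.read_csv(outdir / "pedigree.csv"),
           "phenotypes": pd.read_csv(outdir / "phenotypes.csv")}
    if (outdir / "genotypes.tsv").exists():
        out["genotypes"] = pd.read_csv(outdir / "genotypes.tsv", sep="\t",
                                       index_col="animal")
        out["snp_map"] = pd.read_csv(outdir / "snps.map", sep="\t")
    if (outdir / "truth.csv").exists():
        out["truth"] = pd.read_csv(outdir / "truth.csv")
    if (outdir / "truth.json").exists():
        out["truth_components"] = json.loads((outdir / "truth.json").read_text())
    return out
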