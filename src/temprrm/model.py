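"""Threshold (liability) random-regression animal model, fitted by Gibbs
sampling.

The ordinal score is modelled through a latent liability
``l = X b + X_q q + Z u + W p + e`` cut by ordered thresholds; ``q``
(contemporary group), ``u`` (additive genetic, pedigree- or H-correlated) and
``p`` (permanent environment) are random regression coefficient vectors on a
normalized Legendre basis of the standardized age, and ``e`` is homogeneous
normal residual.  Order 0 reduces to a repeatability model.

Identifiability: with four score categories (three thresholds) the first two
thresholds are fixed at 0 and 1 and the residual variance is estimated; with
two categories the single threshold is fixed at 0 and the residual variance
at 1.  The sampler augments liabilities from truncated normals, updates
locations by small-block single-site Gibbs, draws coefficient covariance
blocks from inverse Wishart and the residual from a scaled inverse
chi-square, and samples free thresholds uniformly between the adjacent
liability extremes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.special import ndtr, ndtri
from scipy.stats import invwishart

from . import _kernels
from .legendre import LegendreBasis, basis_matrix
from .pedigree import RelationshipMatrix

__all__ = ["ModelSpec", "GibbsConfig", "PosteriorChain", "build_design",
           "sample_liabilities", "gibbs_run", "summarize_posterior",
           "hpd_interval"]


@dataclass
class ModelSpec:
    """Which terms enter the liability model.

    order 0 is the repeatability model (constant covariate); order 1 adds the
    learning-and-behavioral-plasticity slope.  ``fixed_factors`` are
    categorical phenotype columns fitted with reference (drop-first) coding
    plus a global intercept; ``age_within_hys`` adds a fixed linear age
    regression nested in the ``hys`` factor.
    """

    order: int = 1
    fixed_factors: tuple = ("conception", "hys")
    age_within_hys: bool = False
    cg_term: bool = True
    pe_term: bool = True
    basis: LegendreBasis = field(default_factory=LegendreBasis)

    def __post_init__(self) -> None:
        if self.order not in (0, 1, 2):
            raise ValueError("order must be 0, 1 or 2")
        if self.basis.order != self.order:
            self.basis = LegendreBasis(order=self.order,
                                       age_min=self.basis.age_min,
                                       age_max=self.basis.age_max)

    @property
    def n_coeff(self) -> int:
        return self.order + 1


@dataclass
class GibbsConfig:
    """Chain settings.  Defaults mirror a full variance-component run;
    reduced settings are passed explicitly in tests and examples."""

    iterations: int = 500_000
    burn_in: int = 250_000
    thin: int = 50
    seed: int = 0
    prior_df: float | None = None  # None = flat prior on covariance blocks
    prior_scale: float = 1e-8      # ridge (times I) added to IW scale
    start_sigma2_e: float = 0.5

    def __post_init__(self) -> None:
        if self.burn_in >= self.iterations:
            raise ValueError("burn_in must be smaller than iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_samples(self) -> int:
        return (self.iterations - self.burn_in) // self.thin


class _Term:
    """One model term: per-level record lists (CSR) and covariate rows."""

    def __init__(self, name, level_ids, level_of_record, cov, kind):
        self.name = name
        self.level_ids = list(level_ids)
        self.kind = kind  # "flat" | "iid" | "genetic"
        n_levels = len(level_ids)
        n_rec = len(level_of_record)
        order = np.argsort(level_of_record, kind="stable")
        counts = np.bincount(level_of_record, minlength=n_levels)
        self.indptr = np.concatenate([[0], np.cumsum(counts)]).astype(np.int64)
        self.indices = order.astype(np.int64)
        self.cov = np.ascontiguousarray(cov[order], dtype=np.float64)
        self.K = self.cov.shape[1]
        self.values = np.zeros((n_levels, self.K))
        assert self.indptr[-1] == n_rec


@dataclass
class DesignData:
    scores: np.ndarray          # 1..n_cat
    n_categories: int
    terms: list
    record_animals: list        # animal id per record (for reporting)
    animal_ids: list            # genetic-term level order


def build_design(pheno: pd.DataFrame, spec: ModelSpec,
                 kinship_ids) -> DesignData:
    """Assemble incidence/covariate structures for every model term.

    ``kinship_ids`` is the animal ordering of the relationship matrix used
    for the additive term (all pedigree animals, or the H ordering).
    """
    n_rec = len(pheno)
    scores = pheno["score"].to_numpy(dtype=np.int64)
    n_cat = int(scores.max())
    T_rec = basis_matrix(pheno["age_days"].to_numpy(dtype=float), spec.basis)
    if T_rec.shape[1] != spec.n_coeff:
        raise ValueError("basis order mismatch")

    terms: list = []
    ones = np.ones((n_rec, 1))

    # global intercept
    terms.append(_Term("intercept", ["(intercept)"],
                       np.zeros(n_rec, dtype=np.int64), ones, "flat"))
    # reference-coded factors: one scalar block per non-reference level
    for fac in spec.fixed_factors:
        if fac not in pheno.columns:
            raise KeyError(f"fixed factor {fac!r} missing from phenotypes")
        levels = sorted(pheno[fac].astype(str).unique())
        if len(levels) < 2:
            continue
        codes = pheno[fac].astype(str).map(
            {lv: i for i, lv in enumerate(levels)}).to_numpy()
        for i, lv in enumerate(levels[1:], start=1):
            mask = codes == i
            t = _Term(f"{fac}={lv}", [lv],
                      np.zeros(int(mask.sum()), dtype=np.int64),
                      ones[mask], "flat")
            t._mask = np.where(mask)[0].astype(np.int64)
            t.indices = t._mask[t.indices]
            terms.append(t)
    if spec.age_within_hys:
        if "hys" not in pheno.columns:
            raise KeyError("age_within_hys requires an 'hys' column")
        levels = sorted(pheno["hys"].astype(str).unique())
        codes = pheno["hys"].astype(str).map(
            {lv: i for i, lv in enumerate(levels)}).to_numpy(dtype=np.int64)
        a_star = T_rec[:, 1:2] if spec.order >= 1 else \
            np.zeros((n_rec, 1))
        terms.append(_Term("age|hys", levels, codes, a_star, "flat"))

    if spec.cg_term:
        levels = sorted(pheno["cg"].astype(str).unique())
        codes = pheno["cg"].astype(str).map(
            {lv: i for i, lv in enumerate(levels)}).to_numpy(dtype=np.int64)
        terms.append(_Term("cg", levels, codes, T_rec, "iid"))

    # additive genetic: levels follow the kinship ordering
    kin_pos = {a: i for i, a in enumerate(kinship_ids)}
    missing = set(pheno["animal"]) - set(kin_pos)
    if missing:
        raise KeyError(f"phenotyped animals missing from kinship: "
                       f"{sorted(missing)[:5]}")
    codes = pheno["animal"].map(kin_pos).to_numpy(dtype=np.int64)
    terms.append(_Term("additive", list(kinship_ids), codes, T_rec, "genetic"))

    if spec.pe_term:
        levels = sorted(pheno["animal"].unique())
        pe_codes = pheno["animal"].map(
            {a: i for i, a in enumerate(levels)}).to_numpy(dtype=np.int64)
        terms.append(_Term("pe", levels, pe_codes, T_rec, "iid"))

    return DesignData(scores=scores, n_categories=n_cat, terms=terms,
                      record_animals=pheno["animal"].tolist(),
                      animal_ids=list(kinship_ids))


def _interval_bounds(scores, thresholds):
    """(lower, upper) liability bounds per record given its category."""
    t = np.concatenate([[-np.inf], thresholds, [np.inf]])
    return t[scores - 1], t[scores]


def sample_liabilities(scores, lin, thresholds, sigma2_e, rng):
    """Draw liabilities from normals truncated to the category interval.

    Uses inverse-CDF sampling with probabilities clipped away from 0/1 so
    extreme linear predictors still yield finite draws.
    """
    thresholds = np.asarray(thresholds, dtype=float)
    if thresholds.size > 1 and np.any(np.diff(thresholds) <= 0):
        raise ValueError("thresholds must be strictly increasing")
    lo, hi = _interval_bounds(np.asarray(scores), thresholds)
    sd = np.sqrt(sigma2_e)
    with np.errstate(invalid="ignore"):
        a = ndtr((lo - lin) / sd)
        b = ndtr((hi - lin) / sd)
    u = a + rng.random(np.shape(lin)) * (b - a)
    u = np.clip(u, 1e-12, 1.0 - 1e-12)
    out = lin + sd * ndtri(u)
    # extreme linear predictors can underflow the interval probability; the
    # draw then lands at the nearer interval bound instead of outside it
    return np.clip(out, lo, hi)


@dataclass
class PosteriorChain:
    """Thinned post-burn-in samples of all (co)variance components and
    thresholds, plus posterior-mean coefficient (G)EBV per animal."""

    spec: ModelSpec
    cfg: GibbsConfig
    G_u: np.ndarray             # (S, K, K)
    R_p: np.ndarray | None
    R_q: np.ndarray | None
    sigma2_e: np.ndarray        # (S,)
    thresholds: np.ndarray      # (S, n_thresh)
    gebv: pd.DataFrame          # posterior-mean coefficients per animal
    gebv_sd: pd.DataFrame
    location_samples: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return self.G_u.shape[0]

    def save_npz(self, path) -> None:
        np.savez_compressed(
            path, G_u=self.G_u,
            R_p=self.R_p if self.R_p is not None else np.empty(0),
            R_q=self.R_q if self.R_q is not None else np.empty(0),
            sigma2_e=self.sigma2_e, thresholds=self.thresholds,
            gebv=self.gebv.to_numpy(), gebv_sd=self.gebv_sd.to_numpy(),
            animals=np.array(self.gebv.index.tolist(), dtype=object))

    def component_frame(self) -> pd.DataFrame:
        """Flat per-sample table of variance components (CSV export)."""
        K = self.G_u.shape[1]
        cols = {}
        names = ["intercept", "slope", "quad"][:K]
        for a in range(K):
            for b in range(a, K):
                cols[f"u_{names[a]}_{names[b]}"] = self.G_u[:, a, b]
                if self.R_p is not None:
                    cols[f"pe_{names[a]}_{names[b]}"] = self.R_p[:, a, b]
                if self.R_q is not None:
                    cols[f"cg_{names[a]}_{names[b]}"] = self.R_q[:, a, b]
        cols["sigma2_e"] = self.sigma2_e
        for j in range(self.thresholds.shape[1]):
            cols[f"threshold_{j + 1}"] = self.thresholds[:, j]
        return pd.DataFrame(cols)


def _prior_precision(term, comp):
    if term.kind == "flat":
        return np.zeros((term.K, term.K))
    return np.linalg.inv(comp)


def gibbs_run(pheno: pd.DataFrame, spec: ModelSpec, cfg: GibbsConfig,
              kinship: RelationshipMatrix,
              fix_components=None, store_location: bool = False) -> PosteriorChain:
    """Run the threshold RRM Gibbs sampler.

    ``kinship`` is the *inverse* relationship matrix (A-inverse or H-inverse)
    over all animals in the evaluation.  ``fix_components`` may be a
    :class:`~temprrm.legendre.CoeffCovariances` to hold every (co)variance
    fixed (the GWAS-stage configuration).  Reproducible under ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    design = build_design(pheno, spec, kinship.ids)
    K = spec.n_coeff
    n_rec = len(design.scores)
    n_cat = design.n_categories
    n_thresh = n_cat - 1

    Ainv = sparse.csr_matrix(kinship.values)
    a_indptr = Ainv.indptr.astype(np.int64)
    a_indices = Ainv.indices.astype(np.int64)
    a_data = Ainv.data.astype(np.float64)

    # identifiability scheme
    thresholds = np.arange(n_thresh, dtype=float)  # 0, 1, 2, ...
    n_fixed_thr = min(2, n_thresh)
    estimate_sigma_e = n_fixed_thr >= 2 and fix_components is None
    sigma2_e = (fix_components.sigma2_e if fix_components is not None
                else (cfg.start_sigma2_e if estimate_sigma_e else 1.0))

    # starting components
    comps = {}
    for term in design.terms:
        if term.kind == "flat":
            continue
        if fix_components is not None:
            src = {"cg": fix_components.R_q, "pe": fix_components.R_p,
                   "additive": fix_components.G_u}[term.name]
            comps[term.name] = np.array(src, dtype=float)
        else:
            comps[term.name] = 0.1 * np.eye(term.K)

    lin = np.zeros(n_rec)
    liab = sample_liabilities(design.scores, lin, thresholds, sigma2_e, rng)
    e = liab - lin

    S = cfg.n_samples
    out_Gu = np.empty((S, K, K))
    out_Rp = np.empty((S, K, K)) if spec.pe_term else None
    out_Rq = np.empty((S, K, K)) if spec.cg_term else None
    out_se = np.empty(S)
    out_thr = np.empty((S, n_thresh))
    loc_samples = {t.name: [] for t in design.terms} if store_location else {}

    gen_term = next(t for t in design.terms if t.kind == "genetic")
    pe_term = next((t for t in design.terms if t.name == "pe"), None)
    if pe_term is not None:
        pe_pos = {a: i for i, a in enumerate(pe_term.level_ids)}
        pe_level = np.array([pe_pos.get(a, -1) for a in design.animal_ids],
                            dtype=np.int64)
        # PE record lists must be addressable through the animal's kinship
        # index inside the joint kernel: reuse the genetic term's record CSR
        # (same records, same covariates), so only values/prior differ.
    u_sum = np.zeros_like(gen_term.values)
    u_sumsq = np.zeros_like(gen_term.values)
    n_kept = 0
    s_idx = 0

    prior_nu, prior_s = cfg.prior_df, cfg.prior_scale

    for it in range(cfg.iterations):
        # 1. liabilities
        lin = liab - e
        liab = sample_liabilities(design.scores, lin, thresholds, sigma2_e, rng)
        e = liab - lin

        # 2. free thresholds (uniform between adjacent category extremes)
        for j in range(n_fixed_thr, n_thresh):
            in_below = design.scores == j + 1
            in_above = design.scores == j + 2
            lo = liab[in_below].max() if in_below.any() else thresholds[j - 1]
            hi = liab[in_above].min() if in_above.any() else lo + 1.0
            lo = max(lo, thresholds[j - 1] if j > 0 else -np.inf)
            thresholds[j] = lo + rng.random() * max(hi - lo, 0.0)

        # 3. location updates; additive and PE jointly per animal (mixing)
        for term in design.terms:
            if term.kind == "genetic" or (pe_term is not None
                                          and term is pe_term):
                continue
            z = rng.standard_normal(term.values.shape)
            prior = _prior_precision(term, comps.get(term.name))
            _kernels.update_iid_term(
                term.values, e, term.indptr, term.indices, term.cov,
                prior, sigma2_e, z)
        if pe_term is not None:
            z = rng.standard_normal((gen_term.values.shape[0], 2 * K))
            _kernels.update_genetic_pe_joint(
                gen_term.values, pe_term.values, pe_level, e,
                gen_term.indptr, gen_term.indices, gen_term.cov,
                np.linalg.inv(comps["additive"]),
                np.linalg.inv(comps["pe"]),
                a_indptr, a_indices, a_data, sigma2_e, z)
        else:
            z = rng.standard_normal(gen_term.values.shape)
            _kernels.update_genetic_term(
                gen_term.values, e, gen_term.indptr, gen_term.indices,
                gen_term.cov, np.linalg.inv(comps["additive"]),
                a_indptr, a_indices, a_data, sigma2_e, z)

        # 4. (co)variance components
        if fix_components is None:
            for term in design.terms:
                if term.kind == "flat":
                    continue
                n_lev = term.values.shape[0]
                if term.kind == "genetic":
                    Sc = term.values.T @ (Ainv @ term.values)
                else:
                    Sc = term.values.T @ term.values
                scale = Sc + prior_s * np.eye(term.K)
                # flat prior on the covariance block: df = n - K - 1
                nu0 = -(term.K + 1) if prior_nu is None else prior_nu
                df = max(n_lev + nu0, term.K)
                comps[term.name] = invwishart.rvs(
                    df=df, scale=scale, random_state=rng).reshape(term.K, term.K)
            if estimate_sigma_e:
                sse = float(e @ e)
                sigma2_e = sse / rng.chisquare(n_rec)

        if not np.isfinite(sigma2_e) or not np.isfinite(e).all():
            raise FloatingPointError(f"sampler diverged at iteration {it}")

        # 5. store
        if (it >= cfg.burn_in and (it - cfg.burn_in) % cfg.thin == 0
                and s_idx < S):
            out_Gu[s_idx] = comps["additive"]
            if out_Rp is not None:
                out_Rp[s_idx] = comps["pe"]
            if out_Rq is not None:
                out_Rq[s_idx] = comps["cg"]
            out_se[s_idx] = sigma2_e
            out_thr[s_idx] = thresholds
            u_sum += gen_term.values
            u_sumsq += gen_term.values ** 2
            n_kept += 1
            if store_location:
                for t in design.terms:
                    loc_samples[t.name].append(t.values.copy())
            s_idx += 1

    names = ["intercept", "slope", "quad"][:K]
    mean = u_sum / max(n_kept, 1)
    var = np.maximum(u_sumsq / max(n_kept, 1) - mean ** 2, 0.0)
    gebv = pd.DataFrame(mean, index=pd.Index(design.animal_ids, name="animal"),
                        columns=names)
    gebv_sd = pd.DataFrame(np.sqrt(var), index=gebv.index, columns=names)
    if store_location:
        loc_samples = {k: np.array(v) for k, v in loc_samples.items()}
    return PosteriorChain(spec=spec, cfg=cfg, G_u=out_Gu[:s_idx],
                          R_p=out_Rp[:s_idx] if out_Rp is not None else None,
                          R_q=out_Rq[:s_idx] if out_Rq is not None else None,
                          sigma2_e=out_se[:s_idx], thresholds=out_thr[:s_idx],
                          gebv=gebv, gebv_sd=gebv_sd,
                          location_samples=loc_samples)


def hpd_interval(samples, prob: float = 0.95):
    """Shortest interval containing ``prob`` posterior mass."""
    x = np.sort(np.asarray(samples, dtype=float))
    n = x.size
    m = max(int(np.ceil(prob * n)), 2)
    if m >= n:
        return float(x[0]), float(x[-1])
    widths = x[m - 1:] - x[:n - m + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + m - 1])


def summarize_posterior(chain: PosteriorChain, hpd_prob: float = 0.95):
    """Posterior means/SDs of all components, derived intercept-slope
    correlations, HPD intervals, and the per-animal coefficient GEBV table.

    The genetic correlation is G_u[0,1]/sqrt(G_u[0,0] G_u[1,1]) per sample;
    the phenotypic correlation uses the summed coefficient covariances with
    the residual added to both diagonal terms.
    """
    if chain.n_samples == 0:
        raise ValueError("empty chain")
    frame = chain.component_frame()
    rows = []
    for col in frame.columns:
        x = frame[col].to_numpy()
        lo, hi = hpd_interval(x, hpd_prob)
        rows.append({"component": col, "mean": x.mean(),
                     "sd": x.std(ddof=1) if x.size > 1 else 0.0,
                     "hpd_low": lo, "hpd_high": hi})
    K = chain.G_u.shape[1]
    if K >= 2:
        g = chain.G_u
        with np.errstate(invalid="ignore", divide="ignore"):
            r_g = g[:, 0, 1] / np.sqrt(g[:, 0, 0] * g[:, 1, 1])
            tot = g.copy()
            if chain.R_p is not None:
                tot = tot + chain.R_p
            if chain.R_q is not None:
                tot = tot + chain.R_q
            v0 = tot[:, 0, 0] + chain.sigma2_e
            v1 = tot[:, 1, 1] + chain.sigma2_e
            r_p = tot[:, 0, 1] / np.sqrt(v0 * v1)
        for name, x in (("genetic_correlation", r_g),
                        ("phenotypic_correlation", r_p)):
            x = x[np.isfinite(x)]
            if x.size:
                lo, hi = hpd_interval(x, hpd_prob)
                rows.append({"component": name, "mean": x.mean(),
                             "sd": x.std(ddof=1) if x.size > 1 else 0.0,
                             "hpd_low": lo, "hpd_high": hi})
    return pd.DataFrame(rows), chain.gebv.copy()
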