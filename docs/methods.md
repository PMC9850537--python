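# Methods

## Model

The ordinal temperament score `y ∈ {1..4}` (raw scores 4–6 collapsed) is the
category of a latent liability cut by ordered thresholds `t_1 < t_2 < t_3`.
The liability follows a random-regression animal model

    l = X b + X_q q + Z u + W p + e,

with fixed effects `b`, contemporary-group regression coefficients
`q ~ N(0, R_q ⊗ I)`, additive coefficients `u ~ N(0, G_u ⊗ A)` (pedigree
numerator relationship `A`, or single-step `H`), permanent-environment
coefficients `p ~ N(0, R_p ⊗ I)` and homogeneous residual
`e ~ N(0, I σ²_e)`. Random-regression covariates are normalized Legendre
polynomials `φ_m(a*) = sqrt((2m+1)/2) P_m(a*)` of the standardized age
`a* ∈ [−1, 1]`; order 1 (intercept + slope) is the default, order 0 is the
repeatability model. Normalization is the animal-breeding convention; it
rescales all coefficient-level components, so coefficient matrices are only
comparable between software using the same convention. Age standardization
maps 760 d → −1 and 4128 d → +1 by default (the mean ages of the first and
last adult age groups); both endpoints are configurable.

Coefficient covariances map to the age scale as `Σ = T K T'`. Per-age
heritability and repeatability are

    h²_j  = σ²_u_j / (σ²_u_j + σ²_cg_j + σ²_pe_j + σ²_e)
    rep_j = (σ²_u_j + σ²_pe_j) / (same denominator),

so `rep_j ≥ h²_j` always, strictly when PE variance is positive. Only
per-age heritabilities are reported; a single coefficient-level
"heritability" is not computed because no unambiguous denominator exists for
it (the coefficient variances of intercept and slope sit on different parts
of the basis).

### Identifiability

A threshold model determines location and scale only up to the thresholds.
With four categories (three thresholds) the package fixes `t_1 = 0` and
`t_2 = 1` and *estimates* the residual variance; the remaining thresholds
are free. With two categories the single threshold is fixed at 0 and
`σ²_e = 1`. Fixing two thresholds rather than one-threshold-plus-residual
is what makes an estimated residual variance meaningful alongside a
zero threshold for the docility probability transform.

## Gibbs sampler

Each iteration:

1. **Liabilities** are drawn from normals truncated to the record's category
   interval, by inverse-CDF sampling with the interval probabilities clipped
   away from 0/1; if an extreme linear predictor underflows the interval
   probability entirely, the draw is placed at the nearer interval bound, so
   the chain never leaves the feasible region.
2. **Free thresholds** are drawn uniformly between the adjacent liability
   extremes.
3. **Locations** are updated by small-block Gibbs: every fixed-effect level
   and contemporary-group block from its Gaussian full conditional, and the
   additive and permanent-environment blocks of each animal *jointly* as one
   2(order+1)-dimensional draw. The joint draw is an internal blocking that
   leaves the stationary distribution unchanged; it exists because `u_i` and
   `p_i` share identical covariates within an animal and single-site updates
   mix very slowly along their sum–difference ridge.
4. **Covariance blocks** are drawn from their inverse-Wishart full
   conditionals under a flat prior: `IW(df = n − K − 1, scale = S)` with `S`
   the coefficient scatter (`U' A⁻¹ U` for the additive block) and a 1e-8
   ridge for numerical safety. An earlier small-df/near-zero-scale prior
   (`df0 = 4`, scale 1e-4·I) was found to place substantial density on
   near-singular matrices, dragging the intercept–slope correlation toward
   ±1 and collapsing weakly informed variances; the flat prior removes that
   pathology. The residual is drawn as `SSE / χ²_n`.

Chains are exactly reproducible under a fixed seed, and runs with A⁻¹ and
with an H⁻¹ whose genomic block cancels (`G* = A22`) are bit-identical.
Default chain lengths mirror full-scale practice (500k/250k/50 for variance
components; 10k/5k/5 when components are fixed for the GWAS stage); all
examples and tests use explicitly reduced settings.

Convergence is checked with Geweke's z (spectral-density variance with a
Bartlett lag window of ~sqrt(n) lags) and a Heidelberger–Welch-style
Cramér–von Mises stationarity test (5% critical value 0.461) on successively
trimmed chains.

## Single-step GWAS

Genotypes are coded {−1, 0, 1}; QC removes animals with call rate < 0.90 and
SNPs with call rate < 0.90, MAF < 0.01, |observed − expected heterozygote
frequency| > 0.15, or a non-autosomal chromosome (cattle autosomes 1–29 by
default); remaining missing calls are imputed to 0 (the post-centering
mean). Allele frequencies are computed from the observed post-QC data —
base-population frequencies are not available, and this choice is declared
rather than inferred from any reference. `G` is the frequency-centered
cross-product scaled by `2Σp(1−p)`; `G* = 0.95 G + 0.05 A22` guarantees
invertibility (blend and the optional mean/diagonal tuning configurable);
`H⁻¹ = A⁻¹ + [0, 0; 0, τG*⁻¹ − ωA22⁻¹]` with `τ = ω = 1`.

Coefficient GEBV of genotyped animals are back-solved as
`û_c = M'(MM')⁻¹ GEBV_c` (pseudo-inverse with a warning when `MM'` is
singular, e.g. because frequency centering removes the constant vector —
the solution is then the minimum-norm projection). Age-group effects are
`SNP_k = T û_k`. Windows are overlapping runs of 5 consecutive SNPs within a
chromosome (step 1 by default — "sliding" — both configurable). The share
of additive variance per window and coefficient is
`100 · Var(M_w û_w,c) / σ²_u,c` with `Var` the empirical variance of the
window's genomic values across genotyped animals; per-age shares are *not*
computed because the age transform is linear in effects, not in variances.
Top-window selection ranks by absolute summed effect (or keeps windows above
a percentage threshold) with greedy non-overlap, ties broken by
(chromosome, position). Annotation overlap uses BED (0-based half-open)
against 1-based inclusive window coordinates.

## GEBV transforms and plasticity classes

Liability GEBV at age `j` convert to the percent probability of scoring
docile, `GEBV_p = 100 · Φ(t − û_j)` with `t = 0` (the docile threshold on
the fitted scale). Because higher liability means flightier, a *negative*
liability slope is habituation (docility probability rising with age) and a
positive slope is sensitization; a neutrality band of half-width `eps`
(default 10% of the SD of the slopes being classified — "close to zero" has
no canonical definition) gives the neutral class.

## Synthetic herds

The generator emulates the data structure the analysis assumes:

* **Pedigree** — discrete generations, both sexes, non-founder parents drawn
  from the previous generation; a small fraction of males (5% by default)
  serve as sires, producing the large paternal half-sib families typical of
  commercial beef populations. These families are what lets the sampler
  separate additive from permanent-environment (co)variances.
* **Genotypes** — unlinked biallelic SNPs gene-dropped from founders in
  Hardy–Weinberg proportions at frequencies uniform in a configurable range;
  offspring receive one allele per parent by Mendelian segregation.
* **Phenotypes** — liabilities built exactly from the model above with
  configurable true components; defaults are the reference estimates
  (intercept/slope additive 0.396/0.013 with correlation 0.744, PE
  0.143/0.021, CG 0.004/0.005, residual 0.129, thresholds (0, 1, 1.4)).
  Record counts per cow follow a truncated geometric matched to a mean of
  1.7 on 1–11 records; record ages are a sorted random subset of a yearly
  grid from 760 to ~4050 days, emulating cows that enter the recorded herd
  at different ages and are not scored at every weaning. PE and CG slope
  coefficients are independent of their intercepts by default (no reference
  values exist for those correlations; configurable).

Not emulated: linkage disequilibrium and genetic trend (no selection), culling
or censoring, heterogeneous residuals, dam–offspring environmental
covariance, and the yearling-trait recording window. Passing recovery tests
therefore show the estimator is consistent with its own generating model at
realistic parameter values — not that field data meet those assumptions.

## Calibration experiment (recovery study)

`temprrm.recovery.recovery_study` simulates 1,000 founders plus five
generations of 1,000 (≈3,000 recorded cows, ≈12,000 records; every cow ≥2
records, mean ≈4, 3% of males as sires) and refits with 60,000 iterations,
half burn-in, ≈3,000 stored samples. These sizes keep a full run near 7
minutes on one CPU while the posterior SDs (≈0.03 for the intercept
variance, ≈0.004 for the slope variance, ≈0.14 for the genetic correlation)
remain small enough for meaningful 2-SD coverage checks. The slope-related
PE and CG components mix slowly at this scale (Geweke |z| can exceed 3 over
thirds of the chain); the additive components targeted by the coverage
checks are the best-mixing of the set, but their posterior means still carry
a few percent of Monte-Carlo drift — a known cost of single-site/blocked
Gibbs on threshold models, addressed in practice only by much longer chains.

## Known limitations

* Multivariate (two-trait) threshold models are out of scope.
* The gene drop has no linkage map, so the GWAS stage sees no LD structure;
  window selection logic is exercised, but realistic peak shapes are not.
* `build_A` is dense (fine to ~10k animals); `A⁻¹`/`H⁻¹` are sparse.
* Unknown parents are unrelated non-inbred founders; no metafounders or
  unknown-parent groups.
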