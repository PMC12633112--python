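# Methods

This note documents the statistical models implemented in `famgwas`, the
choices made where the design was genuinely open, and what the synthetic
data can and cannot show about real cohorts.

## Generative model

Genotypes are unlinked biallelic SNPs.  Parents are drawn in Hardy–Weinberg
proportions at per-SNP frequencies f_l (uniform on a configurable range,
default 0.05–0.5); each offspring allele is transmitted independently per
parent with probability g/2.  The offspring phenotype is

    Y_i = Σ_l δ_l g_il + c Σ_l δ_l (g_p(i)l + g_m(i)l) + m_deme(i) + e_i,

with e_i ~ N(0, 1 − h²_direct).  Direct effects δ_l are i.i.d. normal on
the causal set, scaled once so the direct component has variance h²_direct
under Hardy–Weinberg equilibrium.

**Indirect effects.**  The parental channel is parameterized as
proportional to the direct effects with coefficient c (`ige_coefficient`),
so the true per-parent coefficient is α_l = c·δ_l.  Indirect effects in
real families need not be proportional to direct effects; this is one
admissible choice, made so that indirect effects project onto PGIs built
from direct-effect weights (a uniform, effect-independent channel would be
invisible to every DGE-weighted analysis and would exercise nothing).

**Stratification.**  Two demes in equal proportion; per-SNP frequencies
f ∓ d/2 with d ~ U(0, divergence) drawn once, and an environmental mean
offset ±env_shift/2 per deme.  Mating is within deme.  This is the minimal
structure on which marginal (population-effect) regressions confound while
within-family contrasts do not.

**Assortative mating.**  A population of 2·n_families individuals is
iterated for n_generations (default 20; ≥10 enforced).  Each round, mates
are paired by sorting both sexes on a noisy index u = t/sd(t) + e where t is
the matching trait (phenotype or the DGE component Σ_l δ_l g_il).  Under
near-perfect sorting on u, the cross-mate correlation of t is
corr(t, u)² = 1/(1 + Var(e)), so Var(e) = 1/r − 1 targets correlation r in
closed form; the realized correlation is recorded in the output
(`truth["r_delta_realized"]`), and downstream equilibrium checks use the
realized value.  Variance inflation of the genetic component under AM (the
Bulmer-type buildup of positive inter-locus correlations) is deliberate and
not re-normalized.

**Cross-trait AM.**  A single composite index can only realize rank-one
cross-mate correlation structures: sorting both sexes on u gives
corr(t_i^female, t_j^male) ≈ corr(t_i, u)·corr(t_j, u).  The 2×2 target
matrix R is therefore matched through its best rank-one factorization
R ≈ cc′, with the index weights solved from the realized phenotypic
correlation matrix each generation.  Non-positive-definite targets are
rejected; targets requiring corr(t, u) combinations the phenotypic
correlation cannot support raise a calibration error carrying the
achievable value.

**What the generator does not emulate:** linkage and recombination maps
(SNPs are unlinked, so LD-aware estimators cannot be tested here), phased
haplotypes, multi-allelic sites, realistic demography or selection, binary
phenotypes, genotyping error.  Passing tests demonstrate the estimators'
algebra and calibration under the stated model, not robustness to LD or to
ascertainment patterns of real cohorts.

## Mendelian imputation

Missing-parent posteriors are exact conditional distributions: HWE(f) prior
times the product of per-offspring transmission likelihoods, enumerated
over the 3 missing-parent states (one parent observed) or the 9 ordered
parental pairs (siblings only).  By symmetry E[g_p | sibs] = E[g_m | sibs],
so sibling-only families contribute the imputed sum split evenly when a
full design matrix is assembled.  The prior frequency is the sample
frequency — from parental rows when any exist, else all rows — floored at
1/(2n + 2) to avoid degenerate monomorphic priors.  IBD state is not used;
the enumeration marginalizes over transmissions, which is exact under
random mating.  Under within-sample structure the HWE prior is
misspecified; for the simulated homogeneous samples the imputation is
unbiased (verified to Monte-Carlo precision over 10⁵ families).

## Per-SNP regressions

The phenotype is residualized on covariates once.  The family random
intercept's variance components are estimated once per phenotype by REML:
the exchangeable covariance σ²[(1−ρ)I + ρJ] admits a profiled likelihood in
the within-family correlation ρ alone, computed from per-family sums in
O(n) and maximized by bounded scalar search (cross-checked against
statsmodels MixedLM in the test suite).  Each SNP is then fit by GLS with
the components fixed.  Because Σ = σ_e²I + σ_f²J per family, whitening is
partial demeaning: x̃ = x − c_k x̄_fam with c_k = 1 − √(σ_e²/(σ_e² + kσ_f²)),
after which each fit is a small OLS with model-based covariance
σ_e²(X̃'X̃)⁻¹.  The joint covariance between the family-based and
population fits (needed for the per-SNP sampling correlation of δ̂ and β̂)
is (X̃₁'X̃₁)⁻¹X̃₁'X̃₂(X̃₂'X̃₂)⁻¹σ_e², available because both regressions share
the response and the whitening.

SNPs are skipped (and logged) when monomorphic or with fewer than 30
informative offspring (configurable).  Model-based SEs are validated
against a nonparametric family-level bootstrap (elementwise SD ratio within
[0.8, 1.25] in the test suite).

**Limitation — sibling clusters and marginal effects.**  When families
contribute several siblings, GLS with a family random intercept partially
absorbs any family-constant component that is correlated with the
regressor.  For a single SNP this correlation is negligible, but for
aggregate regressors (a PGI) or under assortative mating (where the rest of
the genome is a family-constant confounder correlated with each SNP) the
fitted "population effect" is shrunk toward the within-family slope and is
no longer the marginal association that the equilibrium identities
β = δ/(1 − r_δ) and β = δ + (1 + r_par)α refer to.  The equilibrium and PGI
analyses in the tests and the acceptance script therefore use one analyzed
offspring per family, which is also the situation of typical validation
cohorts; with sibling clusters the identities hold for marginal OLS, not
for the mixed model.

## Meta-analysis

The estimator is the GLS/MLE θ̂_l = (Σ_j A_j'Σ_jl⁻¹A_j)⁻¹ Σ_j A_j'Σ_jl⁻¹z_jl
with Var = (Σ_j A_j'Σ_jl⁻¹A_j)⁻¹, where A_j = I₃ for full designs and
[[1,0,0],[0,½,½]] for collapsed (parental-sum) cohorts.  Expansion to
(δ, α_p, α_m, α, β) uses the fixed linear map B, so α = (α_p+α_m)/2 and
β = δ + α hold exactly on every output row.  When the pooled information
matrix is numerically singular (condition number > 1e10 — e.g. only
collapsed cohorts), the estimate is returned in the collapsed space with
the paternal/maternal slots NaN and a flag, never pseudo-inverted.
Harmonization aligns effect alleles to a reference, flipping all components
and the frequency together; strand-ambiguous SNPs with frequency in
[0.4, 0.6] and SNPs with post-alignment frequency mismatch > 0.2 are
dropped and counted.  Cohort summaries built from sumstats files enter in
the collapsed space, because the fixed sumstats columns determine the
(δ, α) covariance exactly but not the full (δ, α_p, α_m) covariance; the
full-space route is available for in-memory estimates.

## Genome-wide effect comparison

Effects are treated as mean-zero across SNPs; moments are computed about
weighted means anyway (harmless when means ≈ 0, protective against allele
orientation artifacts).  Default weights w_l = 1/(σ_δl² + σ_βl²), with an
unweighted option.  The sampling-error subtractions give c_δβ, v_δ, v_β;
then r_δβ = c/√(v_δ v_β), a = c/v_δ, and
σ_s² = Var(u) − Var(â)v_δ − E[σ_β² − 2â r σ_δσ_β + â²σ_δ²] with
u = β̂ − âδ̂.  All SEs are delete-one-block jackknives over 100 contiguous
blocks (the jackknife re-estimates â within each replicate, so its
uncertainty propagates).  Negative variance estimates are reported as-is
with machine-readable flags, never clipped; when v_δ ≤ 0, a is undefined
and is set to 0 with a flag so that σ_s² degrades gracefully to the
noise-corrected variance of population effects (this makes the
pure-confounding limit δ ≡ 0 → fraction ≈ 1 well-defined).

Effective sample size is N_eff = σ_y²/(2f_l(1−f_l)Var(γ̂_l)) — the
unrelated-sample size of equal precision — and the precision filter retains
SNPs with N_eff(δ) ≥ 0.8 × median.

## PGI analysis

Scores are Σ_l w_l g_il on the harmonized orientation; parental scores use
observed genotypes or Mendelian-imputed expectations with the same SNPs and
weights.  Phenotype and PGI are standardized to unit variance in the
analysis sample (parental scores share the offspring scale), so
coefficients are partial correlations.  The regression machinery is the
same REML + whitened GLS as the per-SNP module; weight estimation is out of
scope (weights are inputs; simulated analyses use true effects).  The ratio
α/δ uses the delta method, Var(α/δ) ≈ Var(α)/δ² + α²Var(δ)/δ⁴ − 2αCov/δ³,
flagged unstable when |δ̂| < 2 SE; r_par is the correlation of parents'
PGIs over families with both parents genotyped, and the equilibrium
diagnostic reports β̂ − [δ̂ + (1 + r̂_par)α̂] with the SE propagated through
the joint covariance of both fits plus an α̂²Var(r̂_par) term.

## Cross-mate correlations and errors-in-variables

Continuous phenotypes are winsorized at the 0.005/0.995 empirical quantiles
within sex, then residualized on age within sex.  The two cross
correlations (female-i × male-j and female-j × male-i) are combined under
an equality constraint by Fisher-z averaging; their dependence is ignored
in the averaged-z variance (slightly conservative).

The errors-in-variables model treats each trait pair's estimates as
x̂ ~ N(x, se_x), ŷ ~ N(y, se_y) with latent (x, y) bivariate normal; the
latents integrate out analytically, leaving a bivariate normal likelihood
with per-observation noise added to the diagonal.  Priors: N(0,1) on the
means, half-normal(1) on the latent scales, uniform(−1,1) on ρ — weakly
informative on the correlation scale, recorded in the output metadata.
Sampling is adaptive component-wise random-walk Metropolis on
(μ_x, μ_y, log τ, log τ, atanh ρ), 2 chains, with the split-chain potential
scale reduction factor required to be < 1.05 before any summary is
reported; non-convergence raises rather than returning a summary, and
callers retry with longer chains.  Posterior means of ρ are shrunk toward 0
by O(1/n); the "noiseless limit equals the sample correlation" property is
therefore an information-limit statement and is checked at 200 pairs.

## Numerical and reproducibility notes

- All randomness flows through `numpy.random.default_rng` from explicit
  seeds; generators are bit-reproducible, and the pipeline manifest records
  seeds and file hashes.
- Coordinates are 1-based (VCF convention) everywhere.  Dosages count the
  A1 (effect) allele; VCF records are written REF = A2, ALT = A1.
- Collinearity is detected by condition number (> 1e10) and raised with the
  offending SNP named; the PGI fit falls back to the collapsed
  parameterization when the parental columns are duplicated.
- Problem sizes in the test suite and acceptance script (e.g. 5,000
  families × 500 SNPs for the stratified null; 12,000 families × 400 SNPs ×
  18 generations for the AM equilibrium run; 100 errors-in-variables
  replicates at 30 pairs with short chains) were chosen as the smallest
  scales at which the targeted third-significant-figure algebra and
  3-SE-level calibration statements are comfortably resolved.
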