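"""Per-SNP estimation of population effects and family-based GWAS parameters.

Two regressions per SNP, both with a family-level random intercept:

* population model:  Y_i = beta_l g_il + gamma' z_i + eps_i
* family-based model: Y_i = delta_l g_il + alpha_pl g_p(i)l + alpha_ml g_m(i)l
                            + gamma' z_i + eps_i

``delta`` is the direct genetic effect (DGE); ``alpha_p`` / ``alpha_m``
are the paternal/maternal non-transmitted coefficients (NTCs).  Missing
parental genotypes are replaced by their Mendelian conditional
expectations; when no family in the sample has a genotyped parent, only
the collapsed vector (delta, average NTC) is identifiable and the model
regresses on the imputed parental sum instead.

Fitting strategy: the phenotype is residualized on covariates once, the
family-intercept variance components are estimated once per phenotype by
REML on the covariate-residualized phenotype, and each SNP is then fit by
GLS with those fixed components.  The exchangeable within-family
covariance sigma_e^2 I + sigma_f^2 J admits an O(n) whitening (partial
demeaning by family), after which every per-SNP fit is a small OLS.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from famgwas.simulate import FamilyDataset

logger = logging.getLogger(__name__)

__all__ = [
    "CollinearityError",
    "SnpThetaEstimate",
    "RegressionFit",
    "VarianceComponents",
    "estimate_variance_components",
    "prepare_design",
    "fit_population_model",
    "fit_fgwas_model",
    "run_fgwas",
    "SUMSTATS_COLUMNS",
]

SUMSTATS_COLUMNS = [
    "SNP", "CHR", "BP", "A1", "A2", "freq",
    "n_eff_direct", "direct", "direct_SE", "avg_NTC", "avg_NTC_SE",
    "population", "population_SE", "cov_direct_avgNTC", "cov_direct_population",
    "paternal", "paternal_SE", "maternal", "maternal_SE",
]


class CollinearityError(ValueError):
    pass


@dataclass
class VarianceComponents:
    sigma2_family: float
    sigma2_resid: float

    @property
    def total(self) -> float:
        return self.sigma2_family + self.sigma2_resid


@dataclass
class RegressionFit:
    coefficients: np.ndarray
    covariance: np.ndarray  # sampling covariance of the genetic terms
    names: list[str]
    sigma2_resid: float
    sigma2_family: float
    n_individuals: int
    n_families: int


@dataclass
class SnpThetaEstimate:
    snp: str
    mode: str  # "full" -> (delta, alpha_p, alpha_m); "collapsed" -> (delta, alpha)
    estimate: np.ndarray
    covariance: np.ndarray
    freq: float
    population: float = np.nan
    population_var: float = np.nan
    cov_direct_population: float = np.nan
    n_individuals: int = 0
    n_families: int = 0
    n_eff: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        dim = 3 if self.mode == "full" else 2
        if self.estimate.shape != (dim,) or self.covariance.shape != (dim, dim):
            raise ValueError(f"estimate/covariance dimension mismatch for mode {self.mode!r}")
        if np.any(np.diag(self.covariance) <= 0):
            raise ValueError("sampling variances must be positive")


def estimate_variance_components(y: np.ndarray, fam_codes: np.ndarray) -> VarianceComponents:
    """REML for the one-way family random-intercept model on a centered vector.

    Profiles the within-family correlation rho = sigma_f^2 / sigma^2 of the
    exchangeable covariance sigma^2 [(1-rho) I + rho J]; sigma^2 is profiled
    out in closed form.  Uses per-family sums only, so cost is O(n).
    """
    y = np.asarray(y, dtype=float)
    y = y - y.mean()
    n = y.size
    order = np.argsort(fam_codes, kind="stable")
    yo = y[order]
    fo = fam_codes[order]
    bounds = np.flatnonzero(np.r_[True, fo[1:] != fo[:-1]])
    sizes = np.diff(np.r_[bounds, n])
    fam_sums = np.add.reduceat(yo, bounds)
    fam_ss = np.add.reduceat(yo**2, bounds)

    def neg2ll(rho: float) -> float:
        one_m = 1.0 - rho
        denom = 1.0 + (sizes - 1) * rho
        quad = (fam_ss - rho * fam_sums**2 / denom) / one_m
        q = quad.sum()
        logdet = np.sum((sizes - 1) * np.log(one_m) + np.log(denom))
        sigma2 = q / n
        return n * np.log(sigma2) + logdet + n

    res = minimize_scalar(neg2ll, bounds=(1e-6, 1 - 1e-6), method="bounded")
    rho = float(res.x)
    one_m = 1.0 - rho
    denom = 1.0 + (sizes - 1) * rho
    sigma2 = float(np.sum((fam_ss - rho * fam_sums**2 / denom) / one_m) / n)
    # treat a boundary solution as no family variance
    if rho < 1e-4:
        rho = 0.0
    return VarianceComponents(sigma2_family=rho * sigma2, sigma2_resid=(1 - rho) * sigma2)


@dataclass
class DesignMatrices:
    """Offspring-level arrays ready for per-SNP GLS."""

    y: np.ndarray  # covariate-residualized phenotype
    fam_codes: np.ndarray
    G: np.ndarray  # offspring dosages (n x L)
    GP: np.ndarray  # paternal dosages, observed or imputed (n x L)
    GM: np.ndarray  # maternal dosages
    mode: str  # "full" or "collapsed"
    freqs: np.ndarray
    snps: pd.DataFrame
    vc: VarianceComponents
    shrink: np.ndarray  # per-row whitening shrinkage factor c_k
    sigma2_y: float

    @property
    def parental_sum(self) -> np.ndarray:
        return self.GP + self.GM


def _residualize(y: np.ndarray, Z: np.ndarray | None) -> np.ndarray:
    if Z is None:
        return y - y.mean()
    Z1 = np.column_stack([np.ones(len(y)), Z])
    if np.linalg.matrix_rank(Z1) < Z1.shape[1]:
        raise CollinearityError("rank-deficient covariate matrix")
    coef, *_ = np.linalg.lstsq(Z1, y, rcond=None)
    return y - Z1 @ coef


def _impute_parents(dataset: FamilyDataset) -> tuple[np.ndarray, np.ndarray, np.ndarray, str]:
    """Per-offspring paternal/maternal dosage matrices with Mendelian imputation.

    Enumerates the missing parent (or parental pair) states in vectorized
    form per family-design stratum; equals the exact per-family posterior
    expectation of the ``impute`` module.
    """
    from famgwas.impute import hwe_prior, offspring_prob

    f = dataset.freqs
    L = dataset.n_snps
    G = dataset.genotypes
    off_rows, gp_rows, gm_rows = [], [], []
    any_parent_observed = False
    prior = np.stack([hwe_prior(fl) for fl in f])  # (L, 3)

    for fam in dataset.families():
        offs = fam.offspring_rows
        if not offs:
            continue
        g_off = G[offs]  # (k, L)
        fa = G[fam.father_row] if fam.father_row is not None else None
        mo = G[fam.mother_row] if fam.mother_row is not None else None
        if fa is not None and mo is not None:
            gp, gm = fa, mo
            any_parent_observed = True
        elif fa is not None or mo is not None:
            any_parent_observed = True
            obs = fa if fa is not None else mo
            mass = np.empty((3, L))
            for m in range(3):
                lik = np.ones(L)
                for o in g_off:
                    lik = lik * offspring_prob(o, obs, np.full(L, m))
                mass[m] = prior[:, m] * lik
            tot = mass.sum(axis=0)
            tot = np.where(tot > 0, tot, np.nan)
            exp_missing = (np.arange(3)[:, None] * mass).sum(axis=0) / tot
            if fa is not None:
                gp, gm = obs, exp_missing
            else:
                gp, gm = exp_missing, mo
        else:
            # sibling-only family: enumerate the 9 ordered parental pairs
            mass_sum = np.zeros(L)
            mass_tot = np.zeros(L)
            for p in range(3):
                for m in range(3):
                    lik = prior[:, p] * prior[:, m]
                    for o in g_off:
                        lik = lik * offspring_prob(o, np.full(L, p), np.full(L, m))
                    mass_tot += lik
                    mass_sum += (p + m) * lik
            with np.errstate(invalid="ignore", divide="ignore"):
                exp_sum = mass_sum / np.where(mass_tot > 0, mass_tot, np.nan)
            gp = gm = exp_sum / 2.0  # symmetric: E[g_p|sibs] = E[g_m|sibs]
        for oi in offs:
            off_rows.append(oi)
            gp_rows.append(gp)
            gm_rows.append(gm)

    mode = "full" if any_parent_observed else "collapsed"
    idx = np.asarray(off_rows)
    return idx, np.asarray(gp_rows, dtype=float), np.asarray(gm_rows, dtype=float), mode


def prepare_design(
    dataset: FamilyDataset,
    covariates: np.ndarray | None = None,
    phenotype: np.ndarray | None = None,
) -> DesignMatrices:
    """Residualize, impute parental terms, estimate variance components, whiten."""
    idx, GP, GM, mode = _impute_parents(dataset)
    y_all = dataset.phenotype if phenotype is None else phenotype
    y = np.asarray(y_all, dtype=float)[idx]
    Z = None if covariates is None else np.asarray(covariates, dtype=float)[idx]
    y = _residualize(y, Z)
    fam_codes = pd.factorize(dataset.fids[idx])[0]
    vc = estimate_variance_components(y, fam_codes)

    # whitening shrinkage per row: x_tilde = x - c_k * fam_mean(x)
    sizes = np.bincount(fam_codes)
    k = sizes[fam_codes].astype(float)
    with np.errstate(divide="ignore"):
        c = 1.0 - np.sqrt(vc.sigma2_resid / (vc.sigma2_resid + k * vc.sigma2_family))
    return DesignMatrices(
        y=y,
        fam_codes=fam_codes,
        G=dataset.genotypes[idx],
        GP=GP,
        GM=GM,
        mode=mode,
        freqs=dataset.freqs,
        snps=dataset.snps,
        vc=vc,
        shrink=c,
        sigma2_y=float(np.var(y)),
    )


def _whiten(x: np.ndarray, fam_codes: np.ndarray, shrink: np.ndarray) -> np.ndarray:
    """Partial family demeaning so the error covariance becomes sigma_e^2 I."""
    counts = np.bincount(fam_codes)
    means = (np.bincount(fam_codes, weights=x) / counts)[fam_codes]
    return x - shrink * means


def _gls_fit(Xw: np.ndarray, yw: np.ndarray, sigma2_e: float):
    XtX = Xw.T @ Xw
    cond = np.linalg.cond(XtX)
    if cond > 1e10:
        raise CollinearityError(f"collinear design (condition number {cond:.2e})")
    XtX_inv = np.linalg.inv(XtX)
    coef = XtX_inv @ (Xw.T @ yw)
    cov = sigma2_e * XtX_inv
    return coef, cov, XtX_inv


def _neff(sigma2_y: float, freq: float, var: float) -> float:
    return sigma2_y / (2.0 * freq * (1.0 - freq) * var)


def _fit_one(design: DesignMatrices, li: int, min_n: int = 30):
    """Fit population and family-based models for SNP index ``li``.

    Returns (SnpThetaEstimate, None) on success or (None, reason).
    """
    g = design.G[:, li]
    gp = design.GP[:, li]
    gm = design.GM[:, li]
    ok = np.isfinite(g) & np.isfinite(gp) & np.isfinite(gm) & np.isfinite(design.y)
    if ok.sum() < min_n:
        return None, "too_few_informative"
    g, gp, gm = g[ok], gp[ok], gm[ok]
    y = design.y[ok]
    fam = design.fam_codes[ok]
    shrink = design.shrink[ok]
    if np.var(g) == 0:
        return None, "monomorphic"

    ones = np.ones(ok.sum())
    yw = _whiten(y, fam, shrink)
    ones_w = _whiten(ones, fam, shrink)
    gw = _whiten(g, fam, shrink)

    # population model
    Xp = np.column_stack([ones_w, gw])
    coef_p, cov_p, _ = _gls_fit(Xp, yw, design.vc.sigma2_resid)
    beta, var_beta = float(coef_p[1]), float(cov_p[1, 1])

    # family-based model
    if design.mode == "full":
        gpw, gmw = _whiten(gp, fam, shrink), _whiten(gm, fam, shrink)
        Xf = np.column_stack([ones_w, gw, gpw, gmw])
        names = ["delta", "alpha_p", "alpha_m"]
    else:
        gsw = _whiten(gp + gm, fam, shrink)
        Xf = np.column_stack([ones_w, gw, gsw])
        names = ["delta", "alpha"]
    try:
        coef_f, cov_f, XtXf_inv = _gls_fit(Xf, yw, design.vc.sigma2_resid)
    except CollinearityError as exc:
        snp = design.snps["snp"].iloc[li]
        raise CollinearityError(f"{snp}: {exc}") from exc
    theta = coef_f[1:]
    cov_theta = cov_f[1:, 1:]

    # cross-covariance between the two fits (same response, same whitening)
    XtXp_inv = np.linalg.inv(Xp.T @ Xp)
    cross = design.vc.sigma2_resid * (XtXf_inv @ (Xf.T @ Xp) @ XtXp_inv)
    cov_delta_beta = float(cross[1, 1])

    freq = float(design.freqs[li])
    est = SnpThetaEstimate(
        snp=str(design.snps["snp"].iloc[li]),
        mode=design.mode,
        estimate=theta,
        covariance=cov_theta,
        freq=freq,
        population=beta,
        population_var=var_beta,
        cov_direct_population=cov_delta_beta,
        n_individuals=int(ok.sum()),
        n_families=int(len(np.unique(fam))),
        n_eff={
            "direct": _neff(design.sigma2_y, freq, float(cov_theta[0, 0])),
            "population": _neff(design.sigma2_y, freq, var_beta),
        },
    )
    return est, None


def fit_population_model(
    dataset: FamilyDataset,
    snp: str,
    covariates: np.ndarray | None = None,
    min_n: int = 30,
) -> SnpThetaEstimate:
    """Mixed-model population-effect estimate for one SNP (model with no parental terms)."""
    est = fit_fgwas_model(dataset, snp, covariates=covariates, min_n=min_n)
    return est


def fit_fgwas_model(
    dataset: FamilyDataset,
    snp: str,
    covariates: np.ndarray | None = None,
    min_n: int = 30,
) -> SnpThetaEstimate:
    """Joint (delta, alpha_p, alpha_m) or collapsed (delta, alpha) estimate for one SNP."""
    design = prepare_design(dataset, covariates=covariates)
    li = int(np.flatnonzero(design.snps["snp"].to_numpy() == snp)[0])
    est, reason = _fit_one(design, li, min_n=min_n)
    if est is None:
        raise ValueError(f"SNP {snp} skipped: {reason}")
    return est


def run_fgwas(
    dataset: FamilyDataset,
    covariates: np.ndarray | None = None,
    phenotype: np.ndarray | None = None,
    min_n: int = 30,
) -> pd.DataFrame:
    """Per-SNP family-based GWAS over the whole panel; returns a sumstats table.

    One row per SNP that passes QC (polymorphic, >= ``min_n`` informative
    offspring); skipped SNPs are logged with a reason.  In collapsed mode
    the paternal/maternal columns are left empty.
    """
    design = prepare_design(dataset, covariates=covariates, phenotype=phenotype)
    rows = []
    skipped = {}
    for li in range(design.G.shape[1]):
        est, reason = _fit_one(design, li, min_n=min_n)
        if est is None:
            skipped[str(design.snps["snp"].iloc[li])] = reason
            continue
        meta = design.snps.iloc[li]
        if est.mode == "full":
            delta, ap, am = est.estimate
            C = est.covariance
            alpha = 0.5 * (ap + am)
            var_alpha = 0.25 * (C[1, 1] + C[2, 2] + 2 * C[1, 2])
            cov_d_a = 0.5 * (C[0, 1] + C[0, 2])
            pat, pat_se = ap, np.sqrt(C[1, 1])
            mat, mat_se = am, np.sqrt(C[2, 2])
        else:
            delta, alpha = est.estimate
            C = est.covariance
            var_alpha = C[1, 1]
            cov_d_a = C[0, 1]
            pat = pat_se = mat = mat_se = np.nan
        rows.append(
            {
                "SNP": est.snp,
                "CHR": int(meta["chrom"]),
                "BP": int(meta["pos"]),
                "A1": meta["a1"],
                "A2": meta["a2"],
                "freq": est.freq,
                "n_eff_direct": est.n_eff["direct"],
                "direct": delta,
                "direct_SE": np.sqrt(C[0, 0]),
                "avg_NTC": alpha,
                "avg_NTC_SE": np.sqrt(var_alpha),
                "population": est.population,
                "population_SE": np.sqrt(est.population_var),
                "cov_direct_avgNTC": cov_d_a,
                "cov_direct_population": est.cov_direct_population,
                "paternal": pat,
                "paternal_SE": pat_se,
                "maternal": mat,
                "maternal_SE": mat_se,
            }
        )
    for snp, reason in skipped.items():
        logger.info("skipped %s: %s", snp, reason)
    if not rows:
        raise ValueError("no SNP passed QC; empty summary statistics")
    out = pd.DataFrame(rows, columns=SUMSTATS_COLUMNS)
    out.attrs["skipped"] = skipped
    out.attrs["mode"] = design.mode
    out.attrs["sigma2_y"] = design.sigma2_y
    return out
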