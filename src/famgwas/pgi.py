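"""Polygenic-index (PGI) computation and family-based PGI regression.

A PGI is a weighted sum of allele dosages.  The family-based regression

    Y_i = X b + delta PGI_i + alpha_p PGI_p(i) + alpha_m PGI_m(i)
          + mu_F(i) + eps_i

separates the direct effect ``delta`` of the PGI from the paternal and
maternal non-transmitted coefficients; the companion regression without
parental PGIs gives the population effect ``beta``.  Phenotype and PGI
are standardized to unit variance in the analysis sample, so coefficients
are partial correlations.  Parental PGIs for ungenotyped parents are
computed from the Mendelian-imputed expected dosages with the same SNPs
and weights.  Under equilibrium assortative mating,
beta = delta + (1 + r_par) alpha, where r_par is the correlation between
parents' PGIs; ``equilibrium_diagnostic`` reports the departure from this
identity with a propagated standard error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from famgwas.fgwas import (
    CollinearityError,
    _gls_fit,
    _impute_parents,
    _residualize,
    _whiten,
    estimate_variance_components,
)
from famgwas.simulate import FamilyDataset

__all__ = [
    "PgiWeights",
    "PgiScores",
    "PgiRegressionResult",
    "compute_pgi",
    "fit_family_pgi_regression",
    "equilibrium_diagnostic",
]


@dataclass
class PgiWeights:
    """SNP weights with effect alleles; ``source`` labels the training
    effects ("direct" or "population")."""

    table: pd.DataFrame  # columns: snp, A1, weight
    source: str = "direct"

    def __post_init__(self):
        if self.table["snp"].duplicated().any():
            raise ValueError("duplicate SNPs in weights")
        required = {"snp", "A1", "weight"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"weights table must have columns {sorted(required)}")


@dataclass
class PgiScores:
    """Per-offspring PGI with matching parental scores (observed or imputed)."""

    offspring: np.ndarray
    paternal: np.ndarray
    maternal: np.ndarray
    fam_codes: np.ndarray
    phenotype: np.ndarray
    covariates: np.ndarray | None
    parents_observed: np.ndarray  # bool: both parental scores from observed genotypes
    mode: str  # "full" or "collapsed"
    n_overlap: int = 0
    overlap_fraction: float = 1.0


@dataclass
class PgiRegressionResult:
    delta: float
    alpha_p: float
    alpha_m: float
    alpha: float
    beta: float
    covariance: np.ndarray  # 4x4 joint sampling covariance of (delta, a_p, a_m, beta)
    ratio: float
    ratio_se: float
    maternal_minus_paternal: float
    maternal_minus_paternal_se: float
    r_par: float
    r_par_se: float
    sigma2_family: float
    n_individuals: int
    n_families: int
    mode: str = "full"
    flags: list[str] = field(default_factory=list)

    @property
    def alpha_se(self) -> float:
        C = self.covariance
        return float(np.sqrt(0.25 * (C[1, 1] + C[2, 2] + 2 * C[1, 2])))

    @property
    def delta_se(self) -> float:
        return float(np.sqrt(self.covariance[0, 0]))

    @property
    def beta_se(self) -> float:
        return float(np.sqrt(self.covariance[3, 3]))

    def to_dict(self) -> dict:
        return {
            "delta": self.delta, "delta_SE": self.delta_se,
            "alpha_p": self.alpha_p, "alpha_m": self.alpha_m,
            "alpha": self.alpha, "alpha_SE": self.alpha_se,
            "beta": self.beta, "beta_SE": self.beta_se,
            "ratio_alpha_delta": self.ratio, "ratio_SE": self.ratio_se,
            "maternal_minus_paternal": self.maternal_minus_paternal,
            "maternal_minus_paternal_SE": self.maternal_minus_paternal_se,
            "r_par": self.r_par, "mode": self.mode, "flags": list(self.flags),
        }


def _harmonized_weights(weights: PgiWeights, snps: pd.DataFrame) -> tuple[np.ndarray, int]:
    """Per-panel-SNP signed weight vector (0 for SNPs absent from the weights)."""
    w = np.zeros(len(snps))
    table = weights.table.set_index("snp")
    n_overlap = 0
    for li, row in enumerate(snps.itertuples()):
        if row.snp not in table.index:
            continue
        rec = table.loc[row.snp]
        if str(rec["A1"]) == str(row.a1):
            w[li] = float(rec["weight"])
        elif str(rec["A1"]) == str(row.a2):
            w[li] = -float(rec["weight"])  # flipped coding; constant absorbed by intercept
        else:
            continue
        n_overlap += 1
    return w, n_overlap


def compute_pgi(
    dataset: FamilyDataset,
    weights: PgiWeights,
    phenotype: np.ndarray | None = None,
    covariates: np.ndarray | None = None,
) -> PgiScores:
    """Score offspring and parents with harmonized weights.

    Parental scores use observed parental genotypes where available and
    Mendelian-imputed expected dosages otherwise (same SNP set, same
    weights).
    """
    w, n_overlap = _harmonized_weights(weights, dataset.snps)
    if n_overlap == 0:
        raise ValueError("no overlap between weights and genotype panel")
    idx, GP, GM, mode = _impute_parents(dataset)
    score_off = dataset.genotypes[idx] @ w
    score_p = GP @ w
    score_m = GM @ w

    observed = []
    fam_lookup = {fam.family_id: fam for fam in dataset.families()}
    for i in idx:
        fam = fam_lookup[dataset.fids[i]]
        observed.append(fam.father_row is not None and fam.mother_row is not None)

    y_all = dataset.phenotype if phenotype is None else np.asarray(phenotype, dtype=float)
    return PgiScores(
        offspring=score_off,
        paternal=score_p,
        maternal=score_m,
        fam_codes=pd.factorize(dataset.fids[idx])[0],
        phenotype=y_all[idx],
        covariates=None if covariates is None else np.asarray(covariates)[idx],
        parents_observed=np.asarray(observed),
        mode=mode,
        n_overlap=n_overlap,
        overlap_fraction=n_overlap / len(weights.table),
    )


def fit_family_pgi_regression(scores: PgiScores) -> PgiRegressionResult:
    """Family-based and population PGI regressions with joint covariance."""
    y = np.asarray(scores.phenotype, dtype=float)
    ok = (
        np.isfinite(y)
        & np.isfinite(scores.offspring)
        & np.isfinite(scores.paternal)
        & np.isfinite(scores.maternal)
    )
    y = y[ok]
    pgi_sd = np.std(scores.offspring[ok])
    y_sd = np.std(y)
    if pgi_sd <= 0 or y_sd <= 0:
        raise ValueError("phenotype and PGI must be non-constant")
    po = (scores.offspring[ok] - np.mean(scores.offspring[ok])) / pgi_sd
    # parental scores share the offspring scale so coefficients are comparable
    pp = (scores.paternal[ok] - np.mean(scores.paternal[ok])) / pgi_sd
    pm = (scores.maternal[ok] - np.mean(scores.maternal[ok])) / pgi_sd
    Z = None if scores.covariates is None else scores.covariates[ok]
    y = _residualize(y, Z) / y_sd
    fam = pd.factorize(scores.fam_codes[ok])[0]

    vc = estimate_variance_components(y, fam)
    sizes = np.bincount(fam)
    k = sizes[fam].astype(float)
    shrink = 1.0 - np.sqrt(vc.sigma2_resid / (vc.sigma2_resid + k * vc.sigma2_family))

    ones_w = _whiten(np.ones(len(y)), fam, shrink)
    yw = _whiten(y, fam, shrink)
    pow_, ppw, pmw = (_whiten(v, fam, shrink) for v in (po, pp, pm))

    mode = scores.mode
    if mode == "full":
        Xf = np.column_stack([ones_w, pow_, ppw, pmw])
    else:
        Xf = np.column_stack([ones_w, pow_, ppw + pmw])
    try:
        coef_f, cov_f, XtXf_inv = _gls_fit(Xf, yw, vc.sigma2_resid)
    except CollinearityError:
        if mode == "full":
            # duplicated parental columns (e.g. sib-only subsample): collapse
            mode = "collapsed"
            Xf = np.column_stack([ones_w, pow_, ppw + pmw])
            coef_f, cov_f, XtXf_inv = _gls_fit(Xf, yw, vc.sigma2_resid)
        else:
            raise

    Xr = np.column_stack([ones_w, pow_])
    coef_r, cov_r, XtXr_inv = _gls_fit(Xr, yw, vc.sigma2_resid)
    beta = float(coef_r[1])
    cross = vc.sigma2_resid * (XtXf_inv @ (Xf.T @ Xr) @ XtXr_inv)

    if mode == "full":
        delta, ap, am = (float(c) for c in coef_f[1:])
        C3 = cov_f[1:, 1:]
        cov_b = cross[1:, 1]
    else:
        delta, a_half = float(coef_f[1]), float(coef_f[2])
        ap = am = a_half
        C2 = cov_f[1:, 1:]
        C3 = np.array(
            [
                [C2[0, 0], C2[0, 1], C2[0, 1]],
                [C2[0, 1], C2[1, 1], C2[1, 1]],
                [C2[0, 1], C2[1, 1], C2[1, 1]],
            ]
        )
        cov_b = np.array([cross[1, 1], cross[2, 1], cross[2, 1]])
    alpha = 0.5 * (ap + am)

    C4 = np.zeros((4, 4))
    C4[:3, :3] = C3
    C4[3, 3] = cov_r[1, 1]
    C4[:3, 3] = cov_b
    C4[3, :3] = cov_b

    var_alpha = 0.25 * (C3[1, 1] + C3[2, 2] + 2 * C3[1, 2])
    cov_da = 0.5 * (C3[0, 1] + C3[0, 2])
    flags = []
    se_delta = np.sqrt(C3[0, 0])
    if abs(delta) < 2 * se_delta:
        flags.append("ratio_unstable_small_delta")
        ratio, ratio_se = np.nan, np.nan
    else:
        ratio = alpha / delta
        # delta method: Var(a/d) = Va/d^2 + a^2 Vd/d^4 - 2 a Cov/d^3
        ratio_var = (
            var_alpha / delta**2
            + alpha**2 * C3[0, 0] / delta**4
            - 2 * alpha * cov_da / delta**3
        )
        ratio_se = float(np.sqrt(max(ratio_var, 0.0)))

    dmp = am - ap
    dmp_se = float(np.sqrt(C3[1, 1] + C3[2, 2] - 2 * C3[1, 2]))

    # parental-PGI correlation among families with both parents genotyped
    obs = scores.parents_observed[ok]
    fam_first = pd.Series(np.arange(len(fam))).groupby(fam).first().to_numpy()
    first_obs = fam_first[obs[fam_first]]
    if len(first_obs) >= 10:
        r_par = float(np.corrcoef(pp[first_obs], pm[first_obs])[0, 1])
        r_par_se = float((1 - r_par**2) / np.sqrt(max(len(first_obs) - 3, 1)))
    else:
        r_par, r_par_se = np.nan, np.nan
        flags.append("r_par_unavailable")

    return PgiRegressionResult(
        delta=delta, alpha_p=ap, alpha_m=am, alpha=alpha, beta=beta,
        covariance=C4, ratio=ratio, ratio_se=ratio_se,
        maternal_minus_paternal=dmp, maternal_minus_paternal_se=dmp_se,
        r_par=r_par, r_par_se=r_par_se,
        sigma2_family=vc.sigma2_family,
        n_individuals=int(ok.sum()), n_families=int(len(sizes)),
        mode=mode, flags=flags,
    )


def equilibrium_diagnostic(result: PgiRegressionResult) -> dict:
    """Departure of beta from delta + (1 + r_par) alpha, with propagated SE.

    Under random mating (r_par ~ 0) the relation reduces to
    beta = delta + alpha.  Skipped when no mate pairs were available to
    estimate r_par.
    """
    if not np.isfinite(result.r_par):
        return {"available": False, "reason": "r_par unavailable (no mate pairs)"}
    r = result.r_par
    d = result.beta - (result.delta + (1 + r) * result.alpha)
    # gradient wrt (delta, alpha_p, alpha_m, beta)
    g = np.array([-1.0, -(1 + r) / 2, -(1 + r) / 2, 1.0])
    var = float(g @ result.covariance @ g)
    var += (result.alpha * result.r_par_se) ** 2  # r_par uncertainty
    return {
        "available": True,
        "discrepancy": float(d),
        "se": float(np.sqrt(var)),
        "z": float(d / np.sqrt(var)) if var > 0 else np.nan,
        "r_par": r,
        "naive_discrepancy": float(result.beta - result.delta - result.alpha),
    }
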