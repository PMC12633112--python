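"""Cross-mate cross-phenotype correlations and the errors-in-variables model.

Cross-mate cross-phenotype correlations measure cross-trait assortative
mating (xAM): the correlation between one mate's phenotype i and the
other mate's phenotype j.  Phenotypes are winsorized at the 0.005/0.995
empirical quantiles within sex and residualized on age within sex before
correlation; the two cross correlations (female-i x male-j and
female-j x male-i) are combined under an equality constraint by
Fisher-z averaging.

The errors-in-variables (EIV) model relates noisy correlation estimates
across trait pairs: observed x_hat ~ N(x, se_x) and y_hat ~ N(y, se_y)
with the latent (x, y) bivariate normal; the target of inference is the
latent correlation rho (and R^2 = rho^2), free of the attenuation that
sampling error induces in the naive correlation of (x_hat, y_hat).  The
latents integrate out analytically, so the marginal likelihood of each
pair is bivariate normal with per-observation noise added to the
diagonal.  Posterior sampling is by adaptive random-walk Metropolis over
(mu_x, mu_y, log tau_x, log tau_y, atanh rho) with half-normal priors on
the latent scales and a uniform(-1, 1) prior on rho; convergence is
checked with the split-chain potential scale reduction factor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MatePairPhenotypes",
    "EIVResult",
    "cross_mate_correlation",
    "fit_eiv_correlation",
    "split_rhat",
]


@dataclass
class MatePairPhenotypes:
    """Paired phenotype records for putative mate pairs (continuous traits)."""

    female: pd.DataFrame  # one row per pair; phenotype columns + 'age'
    male: pd.DataFrame

    def __post_init__(self):
        if len(self.female) != len(self.male):
            raise ValueError("female and male tables must pair row-by-row")
        for frame in (self.female, self.male):
            if "age" not in frame.columns:
                raise ValueError("mate tables need an 'age' column")
            if (frame["age"] <= 0).any():
                raise ValueError("ages must be positive")


def _winsorize(x: np.ndarray, lo: float = 0.005, hi: float = 0.995) -> np.ndarray:
    ql, qh = np.nanquantile(x, [lo, hi])
    return np.clip(x, ql, qh)


def _age_residualize(x: np.ndarray, age: np.ndarray) -> np.ndarray:
    ok = np.isfinite(x) & np.isfinite(age)
    A = np.column_stack([np.ones(ok.sum()), age[ok]])
    coef, *_ = np.linalg.lstsq(A, x[ok], rcond=None)
    out = np.full_like(x, np.nan, dtype=float)
    out[ok] = x[ok] - A @ coef
    return out


def _prepare(frame: pd.DataFrame, trait: str) -> np.ndarray:
    x = _winsorize(frame[trait].to_numpy(dtype=float))
    if np.nanstd(x) == 0:
        raise ValueError(f"phenotype {trait!r} constant after winsorization")
    return _age_residualize(x, frame["age"].to_numpy(dtype=float))


def cross_mate_correlation(
    pairs: MatePairPhenotypes, trait_i: str, trait_j: str
) -> dict:
    """Equality-constrained cross-mate correlation of traits i and j.

    Returns the Fisher-z-averaged estimate of corr(female i, male j) and
    corr(female j, male i), with the SE of the averaged z back-transformed
    to the correlation scale.
    """
    fi = _prepare(pairs.female, trait_i)
    fj = _prepare(pairs.female, trait_j)
    mi = _prepare(pairs.male, trait_i)
    mj = _prepare(pairs.male, trait_j)

    def _corr(a, b):
        ok = np.isfinite(a) & np.isfinite(b)
        if ok.sum() < 50:
            raise ValueError("need at least 50 complete mate pairs")
        return float(np.corrcoef(a[ok], b[ok])[0, 1]), int(ok.sum())

    clip = lambda r: np.clip(r, -1 + 1e-12, 1 - 1e-12)  # noqa: E731
    if trait_i == trait_j:
        r, n = _corr(fi, mj)
        z, z_var = np.arctanh(clip(r)), 1.0 / (n - 3)
    else:
        r1, n1 = _corr(fi, mj)
        r2, n2 = _corr(fj, mi)
        z = 0.5 * (np.arctanh(clip(r1)) + np.arctanh(clip(r2)))
        # treats the two cross correlations as independent; conservative
        # dependence between them is second-order for weak correlations
        z_var = 0.25 * (1.0 / (n1 - 3) + 1.0 / (n2 - 3))
        n = min(n1, n2)
    r_hat = float(np.tanh(z))
    se = float((1 - r_hat**2) * np.sqrt(z_var))
    return {"estimate": r_hat, "se": se, "n_pairs": n}


# ---------------------------------------------------------------------------
# errors-in-variables posterior
# ---------------------------------------------------------------------------


@dataclass
class EIVResult:
    rho_mean: float
    rho_ci: tuple[float, float]
    r2_mean: float
    r2_ci: tuple[float, float]
    naive_correlation: float
    rhat: float
    converged: bool
    n_pairs: int
    draws: np.ndarray  # posterior rho draws (chains x iters)
    priors: dict

    def to_dict(self) -> dict:
        return {
            "rho_mean": self.rho_mean,
            "rho_ci_95": list(self.rho_ci),
            "r2_percent_mean": 100 * self.r2_mean,
            "r2_percent_ci_95": [100 * v for v in self.r2_ci],
            "naive_correlation": self.naive_correlation,
            "rhat": self.rhat,
            "converged": self.converged,
            "n_pairs": self.n_pairs,
            "priors": self.priors,
        }


def _loglik(params: np.ndarray, x, y, sx2, sy2) -> float:
    mux, muy, ltx, lty, zrho = params
    tx, ty = np.exp(ltx), np.exp(lty)
    rho = np.tanh(zrho)
    # marginal covariance per pair: latent BVN + independent sampling noise
    vx = tx**2 + sx2
    vy = ty**2 + sy2
    cxy = rho * tx * ty
    det = vx * vy - cxy**2
    if np.any(det <= 0):
        return -np.inf
    dx, dy = x - mux, y - muy
    quad = (vy * dx**2 - 2 * cxy * dx * dy + vx * dy**2) / det
    return float(-0.5 * np.sum(np.log(det) + quad))


def _logprior(params: np.ndarray) -> float:
    mux, muy, ltx, lty, zrho = params
    # normal(0,1) on the means (up to constants)
    lp = -0.5 * (mux**2 + muy**2)
    # half-normal(1) on tau with the log-scale Jacobian: -tau^2/2 + log(tau)
    for lt in (ltx, lty):
        t = np.exp(lt)
        lp += -0.5 * t**2 + lt
    # uniform(-1,1) on rho with the atanh Jacobian: drho/dz = 1 - rho^2
    rho = np.tanh(zrho)
    lp += np.log1p(-(rho**2))
    return float(lp)


def fit_eiv_correlation(
    xhat: np.ndarray,
    se_x: np.ndarray,
    yhat: np.ndarray,
    se_y: np.ndarray,
    n_chains: int = 2,
    n_iter: int = 2000,
    n_warmup: int = 1000,
    seed: int = 0,
    rhat_limit: float = 1.05,
) -> EIVResult:
    """Posterior for the latent correlation rho between two noisy series.

    Raises ``RuntimeError`` if the split-chain scale-reduction diagnostic
    exceeds ``rhat_limit`` (the result is withheld; diagnostics are in the
    exception message).
    """
    x = np.asarray(xhat, dtype=float)
    y = np.asarray(yhat, dtype=float)
    sx2 = np.asarray(se_x, dtype=float) ** 2
    sy2 = np.asarray(se_y, dtype=float) ** 2
    if np.any(np.asarray(se_x) <= 0) or np.any(np.asarray(se_y) <= 0):
        raise ValueError("standard errors must be positive")
    n = len(x)
    if n < 10:
        raise ValueError("need at least 10 trait pairs")

    rng = np.random.default_rng(seed)
    naive = float(np.corrcoef(x, y)[0, 1])

    def logpost(p):
        return _loglik(p, x, y, sx2, sy2) + _logprior(p)

    chains = np.empty((n_chains, n_iter, 5))
    for c in range(n_chains):
        p = np.array(
            [
                np.mean(x) + 0.1 * rng.standard_normal(),
                np.mean(y) + 0.1 * rng.standard_normal(),
                np.log(max(np.std(x), 0.05)) + 0.1 * rng.standard_normal(),
                np.log(max(np.std(y), 0.05)) + 0.1 * rng.standard_normal(),
                np.arctanh(np.clip(naive, -0.9, 0.9)) + 0.1 * rng.standard_normal(),
            ]
        )
        lp = logpost(p)
        step = np.full(5, 0.15)
        accepted = np.zeros(5)
        for it in range(n_warmup + n_iter):
            # component-wise random-walk Metropolis with warmup adaptation
            for j in range(5):
                prop = p.copy()
                prop[j] += step[j] * rng.standard_normal()
                lp_prop = logpost(prop)
                if np.log(rng.random()) < lp_prop - lp:
                    p, lp = prop, lp_prop
                    accepted[j] += 1
            if it < n_warmup and (it + 1) % 100 == 0:
                rate = accepted / 100
                step *= np.where(rate > 0.5, 1.3, np.where(rate < 0.25, 0.75, 1.0))
                accepted[:] = 0
            if it >= n_warmup:
                chains[c, it - n_warmup] = p

    rho_draws = np.tanh(chains[:, :, 4])
    rhat = split_rhat(rho_draws)
    converged = bool(rhat < rhat_limit)
    if not converged:
        raise RuntimeError(
            f"MCMC did not converge: split-chain R-hat for rho = {rhat:.3f} "
            f"(limit {rhat_limit}); increase n_iter"
        )
    flat = rho_draws.reshape(-1)
    lo, hi = np.quantile(flat, [0.025, 0.975])
    r2 = flat**2
    r2lo, r2hi = np.quantile(r2, [0.025, 0.975])
    return EIVResult(
        rho_mean=float(flat.mean()),
        rho_ci=(float(lo), float(hi)),
        r2_mean=float(r2.mean()),
        r2_ci=(float(r2lo), float(r2hi)),
        naive_correlation=naive,
        rhat=float(rhat),
        converged=converged,
        n_pairs=n,
        draws=rho_draws,
        priors={
            "mu": "normal(0, 1)",
            "tau": "half-normal(1)",
            "rho": "uniform(-1, 1)",
        },
    )


def split_rhat(draws: np.ndarray) -> float:
    """Split-chain potential scale reduction factor (rank-free version)."""
    c, n = draws.shape
    half = n // 2
    split = draws[:, : 2 * half].reshape(2 * c, half)
    m, nn = split.shape
    means = split.mean(axis=1)
    W = split.var(axis=1, ddof=1).mean()
    B = nn * means.var(ddof=1)
    var_plus = (nn - 1) / nn * W + B / nn
    return float(np.sqrt(var_plus / W))
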