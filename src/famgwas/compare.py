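"""Genome-wide comparison of effect classes from noisy per-SNP estimates.

Given per-SNP estimate pairs (delta_hat_l, beta_hat_l) with known sampling
SDs sigma_dl, sigma_bl and sampling correlation r_l, the non-sampling
(co)variances follow from the law of total variance (effects assumed
mean-centered across SNPs):

    c_db = Cov(delta_hat, beta_hat) - E[r_l sigma_dl sigma_bl]
    v_d  = Var(delta_hat) - E[sigma_dl^2]
    v_b  = Var(beta_hat)  - E[sigma_bl^2]

from which the genome-wide correlation r_db = c_db / sqrt(v_d v_b) and the
noise-adjusted regression (inflation) coefficient a = c_db / v_d.  Writing
beta_l = a delta_l + s_l with s_l uncorrelated with delta_l, the variance
of population effects not explained by DGEs is estimated from the
residual u_l = beta_hat_l - a_hat delta_hat_l:

    sigma_s^2 ~= Var(u) - Var(a_hat) v_d
                 - E[sigma_bl^2 - 2 a_hat r_l sigma_dl sigma_bl + a_hat^2 sigma_dl^2]

and sigma_s^2 / v_b is the fraction of non-sampling population-effect
variance uncorrelated with DGEs.  Standard errors come from a
delete-one-block jackknife over contiguous genome blocks.  Negative
variance estimates are possible and are reported as-is with a flag, never
clipped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "EffectPairSeries",
    "EffectComparisonResult",
    "estimate_moments",
    "estimate_effect_correlation",
    "estimate_inflation",
    "estimate_uncorrelated_variance",
    "compare_effects",
    "effective_sample_size",
    "neff_filter",
    "series_from_sumstats",
]


@dataclass
class EffectPairSeries:
    """Per-SNP estimate pairs with their sampling-error structure."""

    delta: np.ndarray
    beta: np.ndarray
    sd_delta: np.ndarray
    sd_beta: np.ndarray
    sampling_corr: np.ndarray
    weights: np.ndarray | None = None  # default: 1 / (sd_delta^2 + sd_beta^2)
    blocks: np.ndarray | None = None  # jackknife block labels

    def __post_init__(self):
        n = len(self.delta)
        for name in ("beta", "sd_delta", "sd_beta", "sampling_corr"):
            if len(getattr(self, name)) != n:
                raise ValueError("all series must have equal length")
        if np.any(np.abs(self.sampling_corr) > 1 + 1e-12):
            raise ValueError("|sampling correlation| must be <= 1")
        if self.weights is None:
            self.weights = 1.0 / (self.sd_delta**2 + self.sd_beta**2)
        if np.any(self.weights < 0) or not np.any(self.weights > 0):
            raise ValueError("weights must be nonnegative and not all zero")
        if self.blocks is None:
            n_blocks = min(100, max(2, n // 10))
            self.blocks = (np.arange(n) * n_blocks // n).astype(int)

    def __len__(self) -> int:
        return len(self.delta)

    def subset(self, mask: np.ndarray) -> "EffectPairSeries":
        return EffectPairSeries(
            delta=self.delta[mask],
            beta=self.beta[mask],
            sd_delta=self.sd_delta[mask],
            sd_beta=self.sd_beta[mask],
            sampling_corr=self.sampling_corr[mask],
            weights=self.weights[mask],
            blocks=self.blocks[mask],
        )


@dataclass
class EffectComparisonResult:
    c_db: float
    v_delta: float
    v_beta: float
    r: float = np.nan
    r_se: float = np.nan
    a: float = np.nan
    a_var: float = np.nan
    sigma_s2: float = np.nan
    sigma_s2_se: float = np.nan
    fraction_uncorrelated: float = np.nan
    fraction_se: float = np.nan
    c_db_se: float = np.nan
    v_delta_se: float = np.nan
    v_beta_se: float = np.nan
    n_snps: int = 0
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "r_dge_pop": self.r, "r_se": self.r_se,
            "a": self.a, "a_se": float(np.sqrt(self.a_var)) if self.a_var >= 0 else np.nan,
            "sigma_s2": self.sigma_s2, "sigma_s2_se": self.sigma_s2_se,
            "fraction_uncorrelated": self.fraction_uncorrelated,
            "fraction_se": self.fraction_se,
            "v_delta": self.v_delta, "v_beta": self.v_beta, "c_db": self.c_db,
            "n_snps": self.n_snps, "flags": list(self.flags),
        }


def _wmean(x, w):
    return float(np.sum(w * x) / np.sum(w))


def _raw_moments(s: EffectPairSeries) -> dict:
    """Weighted sample moments with sampling-error subtractions."""
    w = s.weights
    dbar, bbar = _wmean(s.delta, w), _wmean(s.beta, w)
    c_hat = _wmean((s.delta - dbar) * (s.beta - bbar), w)
    vd_hat = _wmean((s.delta - dbar) ** 2, w)
    vb_hat = _wmean((s.beta - bbar) ** 2, w)
    e_cross = _wmean(s.sampling_corr * s.sd_delta * s.sd_beta, w)
    e_vd = _wmean(s.sd_delta**2, w)
    e_vb = _wmean(s.sd_beta**2, w)
    return {
        "c_db": c_hat - e_cross,
        "v_delta": vd_hat - e_vd,
        "v_beta": vb_hat - e_vb,
    }


def _point_estimates(
    s: EffectPairSeries, a_var: float = 0.0, a_fixed: float | None = None
) -> dict:
    m = _raw_moments(s)
    c, vd, vb = m["c_db"], m["v_delta"], m["v_beta"]
    out = dict(m)
    out["r"] = c / np.sqrt(vd * vb) if vd > 0 and vb > 0 else np.nan
    a = (c / vd if vd > 0 else np.nan) if a_fixed is None else a_fixed
    out["a"] = a
    if np.isfinite(a):
        w = s.weights
        u = s.beta - a * s.delta
        ubar = _wmean(u, w)
        var_u = _wmean((u - ubar) ** 2, w)
        noise = _wmean(
            s.sd_beta**2 - 2 * a * s.sampling_corr * s.sd_delta * s.sd_beta
            + a**2 * s.sd_delta**2,
            w,
        )
        sigma_s2 = var_u - a_var * vd - noise
        out["sigma_s2"] = sigma_s2
        out["fraction"] = sigma_s2 / vb if vb > 0 else np.nan
    else:
        out["sigma_s2"] = np.nan
        out["fraction"] = np.nan
    return out


def _jackknife(
    s: EffectPairSeries, a_var: float = 0.0, a_fixed: float | None = None
) -> tuple[dict, dict]:
    """Delete-one-block jackknife point estimates and SEs for all quantities."""
    labels = np.unique(s.blocks)
    keys = ["c_db", "v_delta", "v_beta", "r", "a", "sigma_s2", "fraction"]
    reps = {k: [] for k in keys}
    for b in labels:
        sub = s.subset(s.blocks != b)
        est = _point_estimates(sub, a_var=a_var, a_fixed=a_fixed)
        for k in keys:
            reps[k].append(est[k])
    n_b = len(labels)
    ses = {}
    for k in keys:
        vals = np.asarray(reps[k], dtype=float)
        ok = np.isfinite(vals)
        if ok.sum() < 2:
            ses[k] = np.nan
        else:
            v = vals[ok]
            ses[k] = float(np.sqrt((len(v) - 1) / len(v) * np.sum((v - v.mean()) ** 2)))
    return reps, ses


def estimate_moments(series: EffectPairSeries) -> EffectComparisonResult:
    """Noise-corrected genome-wide covariance and variances with jackknife SEs."""
    if len(series) < 1000:
        warnings.warn(
            f"only {len(series)} SNPs; genome-wide moment estimates may be unstable",
            stacklevel=2,
        )
    m = _point_estimates(series)
    _, ses = _jackknife(series)
    flags = []
    if m["v_delta"] <= 0:
        flags.append("negative_v_delta")
    if m["v_beta"] <= 0:
        flags.append("negative_v_beta")
    return EffectComparisonResult(
        c_db=m["c_db"], v_delta=m["v_delta"], v_beta=m["v_beta"],
        c_db_se=ses["c_db"], v_delta_se=ses["v_delta"], v_beta_se=ses["v_beta"],
        n_snps=len(series), flags=flags,
    )


def estimate_effect_correlation(series: EffectPairSeries) -> EffectComparisonResult:
    """Genome-wide correlation between the two effect classes, with SE."""
    res = estimate_moments(series)
    if res.v_delta <= 0 or res.v_beta <= 0:
        res.flags.append("correlation_NA_negative_variance")
        return res
    m = _point_estimates(series)
    _, ses = _jackknife(series)
    res.r, res.r_se = m["r"], ses["r"]
    return res


def estimate_inflation(series: EffectPairSeries) -> EffectComparisonResult:
    """Noise-adjusted regression coefficient of beta on delta (a = c_db / v_d)."""
    res = estimate_moments(series)
    if res.v_delta <= 0:
        res.flags.append("inflation_NA_negative_variance")
        return res
    m = _point_estimates(series)
    _, ses = _jackknife(series)
    res.a = m["a"]
    res.a_var = ses["a"] ** 2
    res.r, res.r_se = m["r"], ses["r"]
    return res


def estimate_uncorrelated_variance(
    series: EffectPairSeries,
    a: float | None = None,
    a_var: float | None = None,
) -> EffectComparisonResult:
    """sigma_s^2 and the fraction of population-effect variance it explains.

    When ``a``/``a_var`` are omitted they are estimated from the series
    first (the jackknife then re-estimates a within each replicate, so the
    reported SEs propagate the uncertainty in a).  When v_delta <= 0 there
    is no detectable DGE variance to subtract: a is set to 0 with a flag
    and sigma_s^2 reduces to the noise-corrected variance of the
    population effects.
    """
    res = estimate_inflation(series)
    a_fixed = a
    if a is not None:
        res.a = a
    if a_var is not None:
        res.a_var = a_var
    if not np.isfinite(res.a):
        a_fixed = 0.0
        res.a, res.a_var = 0.0, 0.0
        res.flags.append("a_set_to_zero_nonpositive_v_delta")
    m = _point_estimates(series, a_var=res.a_var, a_fixed=a_fixed)
    _, ses = _jackknife(series, a_var=res.a_var, a_fixed=a_fixed)
    res.sigma_s2, res.sigma_s2_se = m["sigma_s2"], ses["sigma_s2"]
    res.fraction_uncorrelated, res.fraction_se = m["fraction"], ses["fraction"]
    if res.sigma_s2 < 0:
        res.flags.append("negative_sigma_s2")
    if not (0.0 <= res.fraction_uncorrelated <= 1.0):
        res.flags.append("fraction_outside_unit_interval")
    return res


def compare_effects(series: EffectPairSeries) -> EffectComparisonResult:
    """Full comparison: moments, correlation, inflation, uncorrelated variance."""
    return estimate_uncorrelated_variance(series)


def effective_sample_size(
    var_estimate: np.ndarray | float,
    freq: np.ndarray | float,
    sigma2_y: float = 1.0,
):
    """N_eff = sigma_y^2 / (2 f (1-f) Var(gamma_hat)) per SNP and component."""
    freq = np.asarray(freq, dtype=float)
    var_estimate = np.asarray(var_estimate, dtype=float)
    if np.any((freq <= 0) | (freq >= 1)):
        raise ValueError("frequencies must lie in (0, 1)")
    if np.any(var_estimate <= 0):
        raise ValueError("sampling variances must be positive")
    out = sigma2_y / (2.0 * freq * (1.0 - freq) * var_estimate)
    return float(out) if out.ndim == 0 else out


def neff_filter(
    sumstats: pd.DataFrame,
    neff_column: str = "n_eff_direct",
    fraction_of_median: float = 0.8,
) -> pd.DataFrame:
    """Drop SNPs whose DGE effective sample size is < 0.8x the median.

    Mirrors the pre-heritability QC step: low-precision variants would
    otherwise dominate downstream weighted analyses.
    """
    neff = sumstats[neff_column].to_numpy(dtype=float)
    med = float(np.median(neff))
    keep = neff >= fraction_of_median * med
    out = sumstats.loc[keep].copy()
    if out.empty:
        raise ValueError("effective-sample-size filter removed every SNP")
    out.attrs["n_removed"] = int((~keep).sum())
    out.attrs["median_neff"] = med
    return out


def series_from_sumstats(
    sumstats: pd.DataFrame,
    pair: tuple[str, str] = ("direct", "population"),
    n_blocks: int = 100,
    weighted: bool = True,
) -> EffectPairSeries:
    """Build an EffectPairSeries from a (meta) sumstats table.

    ``pair`` names two effect columns, e.g. ("direct", "population") or
    ("direct", "avg_NTC"); the matching SE and covariance columns must be
    present.
    """
    a, b = pair
    sa, sb = a.replace("avg_NTC", "avgNTC"), b.replace("avg_NTC", "avgNTC")
    candidates = [f"cov_{sa}_{sb}", f"cov_{sb}_{sa}"]
    cov_col = next(c for c in candidates if c in sumstats.columns)
    sd_a = sumstats[f"{a}_SE"].to_numpy(dtype=float)
    sd_b = sumstats[f"{b}_SE"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        r = sumstats[cov_col].to_numpy(dtype=float) / (sd_a * sd_b)
    n = len(sumstats)
    blocks = (np.arange(n) * min(n_blocks, max(2, n // 2)) // n).astype(int)
    return EffectPairSeries(
        delta=sumstats[a].to_numpy(dtype=float),
        beta=sumstats[b].to_numpy(dtype=float),
        sd_delta=sd_a,
        sd_beta=sd_b,
        sampling_corr=np.clip(r, -1, 1),
        weights=None if weighted else np.ones(n),
        blocks=blocks,
    )
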