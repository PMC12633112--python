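"""Generalized multivariate fixed-effects meta-analysis of family-GWAS estimates.

Each cohort j reports, for SNP l, an estimate vector z_jl with sampling
covariance Sigma_jl, modelled as z_jl ~ N(A_j theta_l, Sigma_jl), where
theta_l = (delta_l, alpha_pl, alpha_ml) and A_j maps the full parameter
vector to what the cohort's design identifies: A = I_3 for cohorts with
parental genotypes and A = [[1, 0, 0], [0, 1/2, 1/2]] for collapsed
(parental-sum) cohorts.  The MLE is

    theta_hat = (sum_j A_j' Sigma_jl^-1 A_j)^-1 sum_j A_j' Sigma_jl^-1 z_jl

with Var(theta_hat) = (sum_j A_j' Sigma_jl^-1 A_j)^-1, i.e. generalized
least squares on the stacked system.  The expanded vector
(delta, alpha_p, alpha_m, alpha, beta) with alpha = (alpha_p + alpha_m)/2
and beta = delta + alpha follows by the fixed linear map B below.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "A_FULL",
    "A_COLLAPSED",
    "EXPANSION_MATRIX",
    "CohortSummary",
    "MetaSnpRecord",
    "harmonize_alleles",
    "multivariate_meta",
    "expand_theta",
    "univariate_meta_dge",
    "meta_analyze",
]

A_FULL = np.eye(3)
A_COLLAPSED = np.array([[1.0, 0.0, 0.0], [0.0, 0.5, 0.5]])
EXPANSION_MATRIX = np.array(
    [
        [1.0, 0.0, 0.0],
        [0.0, 1.0, 0.0],
        [0.0, 0.0, 1.0],
        [0.0, 0.5, 0.5],
        [1.0, 0.5, 0.5],
    ]
)
# collapsed-space analogue: (delta, alpha) -> (delta, ., ., alpha, beta)
_EXPANSION_COLLAPSED = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])

_PALINDROMIC = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class CohortSummary:
    """One cohort's per-SNP estimates in meta-analysis form.

    ``estimates[snp]`` is the estimate vector (length 2 or 3) and
    ``covariances[snp]`` its sampling covariance; ``A`` is the
    transformation matrix with one row per estimated component and
    columns (delta, alpha_p, alpha_m).  ``alleles`` carries per-SNP
    (A1, A2, freq) for harmonization.
    """

    cohort_id: str
    A: np.ndarray
    estimates: dict[str, np.ndarray]
    covariances: dict[str, np.ndarray]
    alleles: pd.DataFrame  # index snp, columns A1, A2, freq

    def __post_init__(self):
        self.A = np.atleast_2d(np.asarray(self.A, dtype=float))
        if self.A.shape[1] != 3:
            raise ValueError("A must have 3 columns (delta, alpha_p, alpha_m)")
        if np.linalg.matrix_rank(self.A) < self.A.shape[0]:
            raise ValueError("A must have full row rank")

    @property
    def mode(self) -> str:
        return "full" if self.A.shape[0] == 3 else "collapsed"


@dataclass
class MetaSnpRecord:
    snp: str
    theta: np.ndarray  # length 3 (or 2 when only the collapsed space is identified)
    var_theta: np.ndarray
    expanded: np.ndarray  # (delta, alpha_p, alpha_m, alpha, beta); NaN where unidentified
    var_expanded: np.ndarray  # 5x5 with NaN rows/cols where unidentified
    freq: float
    n_cohorts: int
    collapsed_only: bool = False
    n_eff: dict[str, float] = field(default_factory=dict)


def _flip(est: np.ndarray, cov: np.ndarray, freq: float):
    return -est, cov, 1.0 - freq


def harmonize_alleles(
    cohorts: list[CohortSummary],
    reference: pd.DataFrame,
    freq_tolerance: float = 0.2,
    palindromic_band: float = 0.4,
) -> tuple[list[CohortSummary], dict]:
    """Align every cohort's effect alleles to a reference orientation.

    ``reference`` is indexed by SNP with columns A1, A2, freq.  Alleles
    matching after swap flip the sign of every component and the
    frequency together.  Strand-ambiguous (palindromic) SNPs with
    frequency within ``palindromic_band``..1-``palindromic_band`` are
    dropped, as are SNPs whose post-alignment frequency differs from the
    reference by more than ``freq_tolerance``.  Returns aligned cohorts
    and a per-reason drop count dict.
    """
    dropped = {"palindromic": 0, "freq_mismatch": 0, "allele_mismatch": 0}
    aligned = []
    for cohort in cohorts:
        est, cov = {}, {}
        rows = []
        for snp, z in cohort.estimates.items():
            if snp not in reference.index:
                continue
            ref = reference.loc[snp]
            rec = cohort.alleles.loc[snp]
            a1, a2, f = str(rec["A1"]), str(rec["A2"]), float(rec["freq"])
            z = np.asarray(z, dtype=float)
            S = np.asarray(cohort.covariances[snp], dtype=float)
            if (a1, a2) in _PALINDROMIC and palindromic_band <= f <= 1 - palindromic_band:
                dropped["palindromic"] += 1
                continue
            if (a1, a2) == (ref["A1"], ref["A2"]):
                pass
            elif (a1, a2) == (ref["A2"], ref["A1"]):
                z, S, f = _flip(z, S, f)
            elif (_COMPLEMENT.get(a1), _COMPLEMENT.get(a2)) == (ref["A1"], ref["A2"]):
                pass  # strand flip, same orientation
            elif (_COMPLEMENT.get(a1), _COMPLEMENT.get(a2)) == (ref["A2"], ref["A1"]):
                z, S, f = _flip(z, S, f)
            else:
                dropped["allele_mismatch"] += 1
                continue
            if abs(f - float(ref["freq"])) > freq_tolerance:
                dropped["freq_mismatch"] += 1
                continue
            est[snp] = z
            cov[snp] = S
            rows.append((snp, ref["A1"], ref["A2"], f))
        frame = pd.DataFrame(rows, columns=["snp", "A1", "A2", "freq"]).set_index("snp")
        aligned.append(
            CohortSummary(
                cohort_id=cohort.cohort_id,
                A=cohort.A,
                estimates=est,
                covariances=cov,
                alleles=frame,
            )
        )
    return aligned, dropped


def expand_theta(theta: np.ndarray, var_theta: np.ndarray):
    """(delta, alpha_p, alpha_m) -> (delta, alpha_p, alpha_m, alpha, beta)."""
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (3,):
        raise ValueError("expand_theta expects a 3-vector")
    B = EXPANSION_MATRIX
    return B @ theta, B @ var_theta @ B.T


def multivariate_meta(
    cohorts: list[CohortSummary],
    snp: str,
    condition_limit: float = 1e10,
) -> MetaSnpRecord:
    """MLE of theta_l across cohorts carrying SNP ``snp``, with expansion.

    When the pooled information matrix is (numerically) singular — e.g.
    only collapsed cohorts contribute, leaving alpha_p - alpha_m
    unidentified — the estimate is returned in the collapsed
    (delta, alpha) space with ``collapsed_only=True`` and NaN in the
    paternal/maternal slots, rather than pseudo-inverting.
    """
    info = np.zeros((3, 3))
    score = np.zeros(3)
    n_used = 0
    freqs = []
    for cohort in cohorts:
        if snp not in cohort.estimates:
            continue
        A = cohort.A
        S_inv = np.linalg.inv(cohort.covariances[snp])
        info += A.T @ S_inv @ A
        score += A.T @ S_inv @ cohort.estimates[snp]
        freqs.append(float(cohort.alleles.loc[snp, "freq"]))
        n_used += 1
    if n_used == 0:
        raise KeyError(f"SNP {snp} absent from every cohort")
    freq = float(np.mean(freqs))

    if np.linalg.cond(info) < condition_limit:
        var_theta = np.linalg.inv(info)
        theta = var_theta @ score
        expanded, var_expanded = expand_theta(theta, var_theta)
        return MetaSnpRecord(
            snp=snp, theta=theta, var_theta=var_theta,
            expanded=expanded, var_expanded=var_expanded,
            freq=freq, n_cohorts=n_used,
        )

    # collapsed-space fallback: theta_c = (delta, alpha), A_j^c maps it to z_jl
    C = np.array([[1.0, 0.0, 0.0], [0.0, 0.5, 0.5]])  # theta -> theta_c
    info_c = np.zeros((2, 2))
    score_c = np.zeros(2)
    for cohort in cohorts:
        if snp not in cohort.estimates:
            continue
        # rows of A expressed on (delta, alpha): works when each row touches
        # alpha_p and alpha_m symmetrically (true for A_FULL rows? no) —
        # instead map through least squares: A = A_c C  =>  A_c = A C^+
        A_c = cohort.A @ np.linalg.pinv(C)
        S_inv = np.linalg.inv(cohort.covariances[snp])
        info_c += A_c.T @ S_inv @ A_c
        score_c += A_c.T @ S_inv @ cohort.estimates[snp]
    if np.linalg.cond(info_c) > condition_limit:
        raise np.linalg.LinAlgError(f"SNP {snp}: not identifiable even in collapsed space")
    var_c = np.linalg.inv(info_c)
    theta_c = var_c @ score_c
    exp_c = _EXPANSION_COLLAPSED @ theta_c  # (delta, alpha, beta)
    var_exp_c = _EXPANSION_COLLAPSED @ var_c @ _EXPANSION_COLLAPSED.T
    expanded = np.array([exp_c[0], np.nan, np.nan, exp_c[1], exp_c[2]])
    var_expanded = np.full((5, 5), np.nan)
    for i5, i3 in ((0, 0), (3, 1), (4, 2)):
        for j5, j3 in ((0, 0), (3, 1), (4, 2)):
            var_expanded[i5, j5] = var_exp_c[i3, j3]
    return MetaSnpRecord(
        snp=snp, theta=theta_c, var_theta=var_c,
        expanded=expanded, var_expanded=var_expanded,
        freq=freq, n_cohorts=n_used, collapsed_only=True,
    )


def univariate_meta_dge(cohorts: list[CohortSummary]) -> pd.DataFrame:
    """Inverse-variance-weighted meta-analysis of the DGE component alone."""
    snps: dict[str, list[tuple[float, float]]] = {}
    for cohort in cohorts:
        for snp, z in cohort.estimates.items():
            var = float(cohort.covariances[snp][0, 0])
            snps.setdefault(snp, []).append((float(z[0]), var))
    rows = []
    for snp, entries in snps.items():
        w = np.array([1.0 / v for _, v in entries])
        d = np.array([e for e, _ in entries])
        var = 1.0 / w.sum()
        rows.append({"SNP": snp, "direct": float((w * d).sum() * var), "direct_SE": np.sqrt(var)})
    return pd.DataFrame(rows)


def cohort_from_sumstats(cohort_id: str, sumstats: pd.DataFrame) -> CohortSummary:
    """Build a collapsed-space cohort summary from a sumstats table.

    The fixed sumstats columns determine the joint (delta, avg-NTC)
    sampling covariance exactly, so cohorts enter the meta-analysis on the
    collapsed parameterization regardless of their original design.
    """
    est, cov = {}, {}
    for row in sumstats.itertuples():
        z = np.array([row.direct, row.avg_NTC])
        S = np.array(
            [
                [row.direct_SE**2, row.cov_direct_avgNTC],
                [row.cov_direct_avgNTC, row.avg_NTC_SE**2],
            ]
        )
        est[row.SNP] = z
        cov[row.SNP] = S
    alleles = sumstats.set_index("SNP")[["A1", "A2", "freq"]]
    return CohortSummary(
        cohort_id=cohort_id, A=A_COLLAPSED, estimates=est, covariances=cov, alleles=alleles
    )


def meta_analyze(
    cohorts: list[CohortSummary],
    reference: pd.DataFrame | None = None,
    min_cohorts: int = 2,
    sigma2_y: float = 1.0,
) -> pd.DataFrame:
    """Harmonize, meta-analyze every SNP present in >= ``min_cohorts`` cohorts.

    Returns a meta sumstats table with the five expanded components, SEs,
    the 10 distinct covariance entries, frequency and per-component
    effective sample sizes (phenotypic variance ``sigma2_y``).
    """
    if reference is None:
        reference = cohorts[0].alleles.rename(columns=str).copy()
    aligned, dropped = harmonize_alleles(cohorts, reference)
    counts: dict[str, int] = {}
    for cohort in aligned:
        for snp in cohort.estimates:
            counts[snp] = counts.get(snp, 0) + 1
    comp = ["direct", "paternal", "maternal", "avg_NTC", "population"]
    rows = []
    for snp, c in counts.items():
        if c < min_cohorts:
            continue
        rec = multivariate_meta(aligned, snp)
        row = {"SNP": snp, "freq": rec.freq, "n_cohorts": rec.n_cohorts,
               "collapsed_only": rec.collapsed_only}
        for i, name in enumerate(comp):
            row[name] = rec.expanded[i]
            row[f"{name}_SE"] = np.sqrt(rec.var_expanded[i, i])
        short = {"avg_NTC": "avgNTC"}
        for i in range(5):
            for j in range(i + 1, 5):
                ci, cj = short.get(comp[i], comp[i]), short.get(comp[j], comp[j])
                row[f"cov_{ci}_{cj}"] = rec.var_expanded[i, j]
        denom = 2 * rec.freq * (1 - rec.freq)
        row["n_eff_direct"] = sigma2_y / (denom * rec.var_expanded[0, 0])
        row["n_eff_population"] = sigma2_y / (denom * rec.var_expanded[4, 4])
        rows.append(row)
    out = pd.DataFrame(rows)
    out.attrs["dropped"] = dropped
    return out
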