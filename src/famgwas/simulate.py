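"""Forward simulation of nuclear-family genotype-phenotype data.

Generates unlinked biallelic SNPs in nuclear families (trios, sibling
pairs without parents, single-parent duos) with known direct genetic
effects (DGEs), an optional parental indirect-effect channel, two-deme
population stratification (allele-frequency divergence plus an
environmental mean shift), and equilibrium assortative mating (AM)
produced by forward iteration of rank-matched mating.

Phenotype model for offspring i:

    Y_i = sum_l delta_l g_il
        + c * sum_l delta_l (g_p(i)l + g_m(i)l)
        + env_shift[deme(i)] + e_i,   e_i ~ N(0, 1 - h2_direct)

where ``c`` is the indirect-effect coefficient; the parental channel is
parameterized as proportional to the direct effects, so the true average
parental coefficient is alpha_l = c * delta_l.  Direct effects are drawn
i.i.d. normal on causal SNPs and scaled so the direct component has
variance ``h2_direct`` under Hardy-Weinberg equilibrium; AM subsequently
inflates this variance (Bulmer-type inflation), which is deliberate and
recorded rather than re-normalized away.

Mate matching is sort-and-pair on a noisy index: with the matching trait
standardized, an index u = t + e with Var(e) = 1/r - 1 gives cross-mate
trait correlation ~= corr(t, u)^2 = r under near-perfect sorting on u.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Literal

import numpy as np
import pandas as pd

__all__ = [
    "ConfigurationError",
    "CalibrationError",
    "StratificationConfig",
    "AssortativeMatingConfig",
    "SimulationConfig",
    "FamilyView",
    "FamilyDataset",
    "simulate_random_mating",
    "simulate_assortative_mating",
    "simulate_cross_trait_am",
]


class ConfigurationError(ValueError):
    """Invalid simulation configuration (variance budget, proportions...)."""


class CalibrationError(RuntimeError):
    """Requested mating-correlation target unattainable; carries achieved value."""

    def __init__(self, message: str, achieved: float | None = None):
        super().__init__(message)
        self.achieved = achieved


@dataclass(frozen=True)
class StratificationConfig:
    """Two-deme stratification: per-SNP frequencies f -/+ d/2, d ~ U(0, divergence)."""

    n_demes: int = 2
    fst_like_divergence: float = 0.1
    env_shift: float = 0.0  # deme mean offsets -shift/2, +shift/2

    def __post_init__(self):
        if self.n_demes != 2:
            raise ConfigurationError("only two demes are supported")
        if self.fst_like_divergence < 0:
            raise ConfigurationError("divergence must be nonnegative")


@dataclass(frozen=True)
class AssortativeMatingConfig:
    target_cross_mate_corr: float = 0.3
    n_generations: int = 20
    matching_trait: Literal["phenotype", "dge_component"] = "dge_component"

    def __post_init__(self):
        if not (-1.0 < self.target_cross_mate_corr < 1.0):
            raise ConfigurationError("target cross-mate correlation must be in (-1, 1)")
        if self.target_cross_mate_corr < 0:
            raise ConfigurationError("negative AM targets are not supported by rank matching")
        if self.n_generations < 10:
            raise ConfigurationError("need >=10 generations to approach AM equilibrium")


_DESIGNS = ("trio", "sib_pair_no_parents", "one_parent_duo")


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design and generative parameters for one simulated cohort."""

    n_families: int = 1000
    n_snps: int = 100
    maf_spec: float | tuple[float, float] = (0.05, 0.5)
    h2_direct: float = 0.3
    ige_coefficient: float = 0.0
    n_causal: int | None = None  # default: all SNPs causal
    strat: StratificationConfig | None = None
    am: AssortativeMatingConfig | None = None
    family_design: dict[str, float] = field(
        default_factory=lambda: {"trio": 1.0}
    )
    n_offspring: int = 2
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.h2_direct < 1.0):
            raise ConfigurationError("h2_direct must be in [0, 1)")
        if isinstance(self.maf_spec, tuple):
            lo, hi = self.maf_spec
            if not (0.0 < lo <= hi <= 0.5):
                raise ConfigurationError("maf range must satisfy 0 < lo <= hi <= 0.5")
        elif not (0.0 < self.maf_spec <= 0.5):
            raise ConfigurationError("maf must be in (0, 0.5]")
        tot = sum(self.family_design.values())
        if abs(tot - 1.0) > 1e-8:
            raise ConfigurationError(f"family_design proportions must sum to 1, got {tot}")
        for k in self.family_design:
            if k not in _DESIGNS:
                raise ConfigurationError(f"unknown family design {k!r}")
        if self.n_offspring < 1:
            raise ConfigurationError("need at least one offspring per family")

    def draw_freqs(self, rng: np.random.Generator) -> np.ndarray:
        if isinstance(self.maf_spec, tuple):
            lo, hi = self.maf_spec
            return rng.uniform(lo, hi, size=self.n_snps)
        return np.full(self.n_snps, float(self.maf_spec))


@dataclass
class FamilyView:
    family_id: str
    offspring_rows: list[int]
    father_row: int | None
    mother_row: int | None
    design: str


@dataclass
class FamilyDataset:
    """Genotypes, pedigree, phenotypes and (when simulated) ground truth.

    Rows cover genotyped individuals only; ungenotyped parents appear in
    offspring pedigree records by id and, for simulated data, in
    ``truth['father_geno'] / ['mother_geno']`` (one row per family).
    """

    genotypes: np.ndarray  # (n_rows, L), dosages; NaN = missing
    fids: np.ndarray
    iids: np.ndarray
    father_ids: np.ndarray  # "0" when unrecorded
    mother_ids: np.ndarray
    sex: np.ndarray  # 1 male, 2 female, 0 unknown
    role: np.ndarray  # "offspring" | "father" | "mother"
    phenotype: np.ndarray  # NaN for parents
    snps: pd.DataFrame  # columns: snp, chrom, pos, a1, a2
    freqs: np.ndarray
    covariates: np.ndarray | None = None
    phenotype2: np.ndarray | None = None
    family_design: dict[str, str] = field(default_factory=dict)  # fid -> design
    truth: dict = field(default_factory=dict)

    def __post_init__(self):
        n = self.genotypes.shape[0]
        for arr in (self.fids, self.iids, self.role, self.phenotype):
            if len(arr) != n:
                raise ValueError("row-aligned arrays must match genotype rows")
        if not np.all((self.freqs > 0) & (self.freqs < 1)):
            raise ValueError("allele frequencies must lie in (0, 1)")

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    @property
    def snp_ids(self) -> np.ndarray:
        return self.snps["snp"].to_numpy()

    @property
    def offspring_mask(self) -> np.ndarray:
        return self.role == "offspring"

    def families(self) -> Iterator[FamilyView]:
        order: dict[str, dict] = {}
        for i, fid in enumerate(self.fids):
            d = order.setdefault(fid, {"off": [], "fa": None, "mo": None})
            if self.role[i] == "offspring":
                d["off"].append(i)
            elif self.role[i] == "father":
                d["fa"] = i
            else:
                d["mo"] = i
        for fid, d in order.items():
            yield FamilyView(
                family_id=fid,
                offspring_rows=d["off"],
                father_row=d["fa"],
                mother_row=d["mo"],
                design=self.family_design.get(fid, "unknown"),
            )

    def pedigree_frame(self) -> pd.DataFrame:
        pheno = np.where(np.isfinite(self.phenotype), self.phenotype, -9.0)
        return pd.DataFrame(
            {
                "FID": self.fids,
                "IID": self.iids,
                "father": self.father_ids,
                "mother": self.mother_ids,
                "sex": self.sex,
                "phenotype": pheno,
            }
        )


# ---------------------------------------------------------------------------
# internal generative machinery
# ---------------------------------------------------------------------------


def _draw_effects(config: SimulationConfig, freqs: np.ndarray, rng: np.random.Generator):
    """Direct effects scaled so the HWE direct-component variance is h2_direct."""
    L = config.n_snps
    delta = np.zeros(L)
    n_causal = L if config.n_causal is None else min(config.n_causal, L)
    causal = rng.choice(L, size=n_causal, replace=False) if n_causal < L else np.arange(L)
    if config.h2_direct > 0 and n_causal > 0:
        raw = rng.standard_normal(n_causal)
        var_hwe = np.sum(2 * freqs[causal] * (1 - freqs[causal]) * raw**2)
        delta[causal] = raw * np.sqrt(config.h2_direct / var_hwe)
    return delta, causal


def _transmit(parent_geno: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One transmitted allele per SNP per parent row: Bernoulli(g/2)."""
    return (rng.random(parent_geno.shape) < parent_geno / 2.0).astype(np.int8)


def _deme_freqs(freqs: np.ndarray, strat: StratificationConfig | None, rng):
    if strat is None:
        return None
    d = rng.uniform(0, strat.fst_like_divergence, size=freqs.shape)
    f0 = np.clip(freqs - d / 2, 0.01, 0.99)
    f1 = np.clip(freqs + d / 2, 0.01, 0.99)
    return np.stack([f0, f1])


def _offspring_phenotype(
    g_off, g_fa, g_mo, delta, ige_coefficient, noise_sd, rng, shift=None
):
    y = g_off @ delta
    if ige_coefficient != 0.0:
        y = y + ige_coefficient * ((g_fa + g_mo) @ delta)
    if shift is not None:
        y = y + shift
    return y + noise_sd * rng.standard_normal(len(y))


def _assemble(
    config: SimulationConfig,
    g_fa: np.ndarray,
    g_mo: np.ndarray,
    g_off: list[np.ndarray],
    y_off: np.ndarray,  # (n_fam * n_offspring,) stacked per family-major order
    freqs: np.ndarray,
    truth: dict,
    rng: np.random.Generator,
    y2_off: np.ndarray | None = None,
) -> FamilyDataset:
    """Apply the genotyping design and pack rows into a FamilyDataset."""
    n_fam = config.n_families
    designs = list(config.family_design)
    probs = np.array([config.family_design[d] for d in designs])
    fam_design = rng.choice(len(designs), size=n_fam, p=probs)

    rows_g, fids, iids, fathers, mothers, sexes, roles, phenos = [], [], [], [], [], [], [], []
    phenos2 = [] if y2_off is not None else None
    design_map: dict[str, str] = {}
    k = config.n_offspring
    for fi in range(n_fam):
        fid = f"F{fi}"
        design = designs[fam_design[fi]]
        design_map[fid] = design
        fa_id, mo_id = f"F{fi}_P", f"F{fi}_M"
        include_fa = design == "trio"
        include_mo = design == "trio"
        if design == "one_parent_duo":
            if rng.random() < 0.5:
                include_fa = True
            else:
                include_mo = True
        if include_fa:
            rows_g.append(g_fa[fi])
            fids.append(fid); iids.append(fa_id)
            fathers.append("0"); mothers.append("0")
            sexes.append(1); roles.append("father"); phenos.append(np.nan)
            if phenos2 is not None:
                phenos2.append(np.nan)
        if include_mo:
            rows_g.append(g_mo[fi])
            fids.append(fid); iids.append(mo_id)
            fathers.append("0"); mothers.append("0")
            sexes.append(2); roles.append("mother"); phenos.append(np.nan)
            if phenos2 is not None:
                phenos2.append(np.nan)
        for oi in range(k):
            rows_g.append(g_off[oi][fi])
            fids.append(fid); iids.append(f"F{fi}_O{oi}")
            fathers.append(fa_id); mothers.append(mo_id)
            sexes.append(0); roles.append("offspring")
            phenos.append(y_off[fi * k + oi])
            if phenos2 is not None:
                phenos2.append(y2_off[fi * k + oi])

    L = config.n_snps
    snps = pd.DataFrame(
        {
            "snp": [f"snp{l}" for l in range(L)],
            "chrom": np.full(L, 1),
            "pos": np.arange(1, L + 1) * 1000,
            "a1": ["A"] * L,
            "a2": ["G"] * L,
        }
    )
    truth = dict(truth)
    truth["father_geno"] = g_fa
    truth["mother_geno"] = g_mo
    return FamilyDataset(
        genotypes=np.asarray(rows_g, dtype=float),
        fids=np.asarray(fids),
        iids=np.asarray(iids),
        father_ids=np.asarray(fathers),
        mother_ids=np.asarray(mothers),
        sex=np.asarray(sexes),
        role=np.asarray(roles),
        phenotype=np.asarray(phenos, dtype=float),
        phenotype2=None if phenos2 is None else np.asarray(phenos2, dtype=float),
        snps=snps,
        freqs=freqs,
        family_design=design_map,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# public generators
# ---------------------------------------------------------------------------


def simulate_random_mating(config: SimulationConfig) -> FamilyDataset:
    """Simulate families under random mating (optionally with stratification)."""
    if config.am is not None:
        raise ConfigurationError("config.am must be absent for random mating")
    rng = np.random.default_rng(config.seed)
    base_freqs = config.draw_freqs(rng)
    delta, causal = _draw_effects(config, base_freqs, rng)
    noise_sd = np.sqrt(1.0 - config.h2_direct)
    deme_f = _deme_freqs(base_freqs, config.strat, rng)

    n_fam, L, k = config.n_families, config.n_snps, config.n_offspring
    if deme_f is None:
        demes = np.zeros(n_fam, dtype=int)
        g_fa = rng.binomial(2, base_freqs, size=(n_fam, L)).astype(np.int8)
        g_mo = rng.binomial(2, base_freqs, size=(n_fam, L)).astype(np.int8)
        shift = None
    else:
        demes = (np.arange(n_fam) % 2).astype(int)
        g_fa = rng.binomial(2, deme_f[demes], size=(n_fam, L)).astype(np.int8)
        g_mo = rng.binomial(2, deme_f[demes], size=(n_fam, L)).astype(np.int8)
        shift = np.where(demes == 0, -config.strat.env_shift / 2, config.strat.env_shift / 2)

    g_off = []
    y_parts = []
    for _ in range(k):
        go = _transmit(g_fa, rng) + _transmit(g_mo, rng)
        g_off.append(go)
        y_parts.append(
            _offspring_phenotype(go, g_fa, g_mo, delta, config.ige_coefficient, noise_sd, rng, shift)
        )
    # family-major stacking: offspring oi of family fi at index fi*k + oi
    y_off = np.column_stack(y_parts).reshape(-1)

    truth = {
        "true_delta": delta,
        "true_alpha": config.ige_coefficient * delta,
        "causal": causal,
        "demes": demes,
        "deme_freqs": deme_f,
    }
    ds = _assemble(config, g_fa, g_mo, g_off, y_off, base_freqs, truth, rng)
    # realized frequencies among all simulated individuals (parents + offspring)
    stacks = [g_fa, g_mo] + g_off
    ds.freqs = np.clip(np.mean(np.concatenate(stacks, axis=0), axis=0) / 2.0, 1e-6, 1 - 1e-6)
    return ds


def _rank_match(index_f, index_m):
    """Pair females and males by sorting on a (noisy) matching index."""
    return np.argsort(index_f, kind="stable"), np.argsort(index_m, kind="stable")


def simulate_assortative_mating(config: SimulationConfig) -> FamilyDataset:
    """Iterate rank-matched mating to equilibrium, then emit final families.

    The population holds ``2 * n_families`` individuals per generation;
    each of the ``n_generations`` rounds pairs them on the matching trait
    plus calibrated Gaussian noise and produces the next generation by
    Mendelian transmission.  Ground truth records the realized cross-mate
    correlation of DGE components (``truth['r_delta_realized']``).
    """
    if config.am is None:
        raise ConfigurationError("config.am is required")
    if config.strat is not None:
        raise ConfigurationError("stratification with AM is not supported")
    am = config.am
    rng = np.random.default_rng(config.seed)
    freqs = config.draw_freqs(rng)
    delta, causal = _draw_effects(config, freqs, rng)
    noise_sd = np.sqrt(1.0 - config.h2_direct)

    n_fam, L = config.n_families, config.n_snps
    n_pop = 2 * n_fam
    geno = rng.binomial(2, freqs, size=(n_pop, L)).astype(np.int8)
    parent_sum = None  # previous-generation parental genotype sums, row-aligned

    r = am.target_cross_mate_corr
    if r > 0:
        match_noise_var = 1.0 / r - 1.0
    achieved = np.nan
    for gen in range(am.n_generations):
        dge = geno @ delta
        if am.matching_trait == "phenotype":
            if parent_sum is None:
                par_channel = 2 * freqs @ delta  # population-mean stand-in at gen 0
                trait = dge + par_channel + noise_sd * rng.standard_normal(n_pop)
            else:
                trait = (
                    dge
                    + config.ige_coefficient * (parent_sum @ delta)
                    + noise_sd * rng.standard_normal(n_pop)
                )
        else:
            trait = dge
        females, males = geno[:n_fam], geno[n_fam:]
        tf, tm = trait[:n_fam], trait[n_fam:]
        sd = float(np.std(trait))
        if r > 0:
            if sd <= 0:
                raise CalibrationError(
                    "matching trait has zero variance; AM target unattainable", achieved=0.0
                )
            idx_f = tf / sd + np.sqrt(match_noise_var) * rng.standard_normal(n_fam)
            idx_m = tm / sd + np.sqrt(match_noise_var) * rng.standard_normal(n_fam)
            of, om = _rank_match(idx_f, idx_m)
        else:
            of, om = rng.permutation(n_fam), rng.permutation(n_fam)
        g_mo, g_fa = females[of], males[om]
        achieved = float(np.corrcoef(tf[of], tm[om])[0, 1]) if np.std(tf) > 0 else 0.0

        if gen < am.n_generations - 1:
            child1 = _transmit(g_fa, rng) + _transmit(g_mo, rng)
            child2 = _transmit(g_fa, rng) + _transmit(g_mo, rng)
            geno = np.concatenate([child1, child2], axis=0)
            parent_sum = np.concatenate([g_fa + g_mo, g_fa + g_mo], axis=0)

    # final generation of families from the last mated pairs
    g_off, y_parts = [], []
    for _ in range(config.n_offspring):
        go = _transmit(g_fa, rng) + _transmit(g_mo, rng)
        g_off.append(go)
        y_parts.append(
            _offspring_phenotype(go, g_fa, g_mo, delta, config.ige_coefficient, noise_sd, rng)
        )
    y_off = np.column_stack(y_parts).reshape(-1)

    dge_fa, dge_mo = g_fa @ delta, g_mo @ delta
    r_delta = (
        float(np.corrcoef(dge_fa, dge_mo)[0, 1])
        if np.std(dge_fa) > 0 and np.std(dge_mo) > 0
        else 0.0
    )
    truth = {
        "true_delta": delta,
        "true_alpha": config.ige_coefficient * delta,
        "causal": causal,
        "r_delta_realized": r_delta,
        "match_trait_corr_realized": achieved,
        "target_corr": r,
    }
    ds = _assemble(config, g_fa, g_mo, g_off, y_off, freqs, truth, rng)
    stacks = [g_fa, g_mo] + g_off
    ds.freqs = np.clip(np.mean(np.concatenate(stacks, axis=0), axis=0) / 2.0, 1e-6, 1 - 1e-6)
    return ds


def simulate_cross_trait_am(
    config: SimulationConfig,
    cross_mate_matrix: np.ndarray,
    causal_overlap: Literal["disjoint", "identical"] = "disjoint",
    h2_second: float | None = None,
) -> FamilyDataset:
    """Two phenotypes under cross-trait assortative mating (xAM).

    Mates are rank-matched on a single composite index u chosen so the
    2x2 cross-mate cross-trait correlation matrix approximates the target
    ``cross_mate_matrix``: under near-perfect sorting on u, the cross-mate
    correlation of traits i (in one mate) and j (in the other) factorizes
    as corr(t_i, u) * corr(t_j, u), so the target is matched through its
    best rank-one factorization.  ``causal_overlap`` controls whether the
    two traits share their causal SNP set (genetic correlation 1 in the
    shared-effects sense) or use disjoint halves of the panel.
    """
    R = np.asarray(cross_mate_matrix, dtype=float)
    if R.shape != (2, 2) or not np.allclose(R, R.T):
        raise ConfigurationError("cross_mate_matrix must be a symmetric 2x2 matrix")
    full = np.block(
        [[np.eye(2), R], [R.T, np.eye(2)]]
    )  # joint (t1_f, t2_f, t1_m, t2_m) correlation under exchangeable mates
    if np.linalg.eigvalsh(full).min() < -1e-10:
        raise ConfigurationError("target cross-mate matrix is not positive semi-definite")
    if config.am is None:
        raise ConfigurationError("config.am is required (n_generations, matching on phenotype)")

    # rank-one factorization R ~ c c^T
    w, V = np.linalg.eigh(R)
    if w[-1] <= 0:
        c = np.zeros(2)
    else:
        c = V[:, -1] * np.sqrt(w[-1])
        if c.sum() < 0:
            c = -c

    rng = np.random.default_rng(config.seed)
    freqs = config.draw_freqs(rng)
    L = config.n_snps
    h2b = config.h2_direct if h2_second is None else h2_second

    half = L // 2
    if causal_overlap == "disjoint":
        delta1 = np.zeros(L)
        delta2 = np.zeros(L)
        raw1 = rng.standard_normal(half)
        raw2 = rng.standard_normal(L - half)
        if config.h2_direct > 0:
            v1 = np.sum(2 * freqs[:half] * (1 - freqs[:half]) * raw1**2)
            delta1[:half] = raw1 * np.sqrt(config.h2_direct / v1)
        if h2b > 0:
            v2 = np.sum(2 * freqs[half:] * (1 - freqs[half:]) * raw2**2)
            delta2[half:] = raw2 * np.sqrt(h2b / v2)
    elif causal_overlap == "identical":
        raw = rng.standard_normal(L)
        vv = np.sum(2 * freqs * (1 - freqs) * raw**2)
        delta1 = raw * np.sqrt(config.h2_direct / vv) if config.h2_direct > 0 else np.zeros(L)
        delta2 = raw * np.sqrt(h2b / vv) if h2b > 0 else np.zeros(L)
    else:
        raise ConfigurationError(f"unknown causal_overlap {causal_overlap!r}")

    noise1 = np.sqrt(max(1.0 - config.h2_direct, 0.0))
    noise2 = np.sqrt(max(1.0 - h2b, 0.0))
    n_fam = config.n_families
    n_pop = 2 * n_fam
    geno = rng.binomial(2, freqs, size=(n_pop, L)).astype(np.int8)

    achieved = np.full((2, 2), np.nan)
    for gen in range(config.am.n_generations):
        t1 = geno @ delta1 + noise1 * rng.standard_normal(n_pop)
        t2 = geno @ delta2 + noise2 * rng.standard_normal(n_pop)
        T = np.column_stack([t1, t2])
        T = (T - T.mean(axis=0)) / T.std(axis=0)
        P = np.corrcoef(T.T)
        # composite index with corr(t_i, u) = c_i: u = q' t + e
        q = np.linalg.solve(P, c)
        evar = 1.0 - float(c @ q)
        if evar < -1e-8:
            raise CalibrationError(
                "cross-mate target exceeds what the phenotypic correlation allows",
                achieved=float(c @ q),
            )
        evar = max(evar, 0.0)
        u = T @ q + np.sqrt(evar) * rng.standard_normal(n_pop)
        uf, um = u[:n_fam], u[n_fam:]
        of, om = _rank_match(uf, um)
        g_mo, g_fa = geno[:n_fam][of], geno[n_fam:][om]
        Tf, Tm = T[:n_fam][of], T[n_fam:][om]
        for i in range(2):
            for j in range(2):
                achieved[i, j] = float(np.corrcoef(Tf[:, i], Tm[:, j])[0, 1])
        if gen < config.am.n_generations - 1:
            child1 = _transmit(g_fa, rng) + _transmit(g_mo, rng)
            child2 = _transmit(g_fa, rng) + _transmit(g_mo, rng)
            geno = np.concatenate([child1, child2], axis=0)

    g_off, y1_parts, y2_parts = [], [], []
    for _ in range(config.n_offspring):
        go = _transmit(g_fa, rng) + _transmit(g_mo, rng)
        g_off.append(go)
        y1_parts.append(go @ delta1 + noise1 * rng.standard_normal(n_fam))
        y2_parts.append(go @ delta2 + noise2 * rng.standard_normal(n_fam))
    y1 = np.column_stack(y1_parts).reshape(-1)
    y2 = np.column_stack(y2_parts).reshape(-1)

    truth = {
        "true_delta": delta1,
        "true_delta2": delta2,
        "true_alpha": np.zeros(L),
        "cross_mate_target": R,
        "cross_mate_achieved": achieved,
    }
    ds = _assemble(config, g_fa, g_mo, g_off, y1, freqs, truth, rng, y2_off=y2)
    stacks = [g_fa, g_mo] + g_off
    ds.freqs = np.clip(np.mean(np.concatenate(stacks, axis=0), axis=0) / 2.0, 1e-6, 1 - 1e-6)
    return ds
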