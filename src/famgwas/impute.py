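"""Mendelian imputation of missing parental genotypes.

For a nuclear family observed at one biallelic SNP, the genotype of a
missing parent (or the sum of both missing parents' genotypes) is replaced
by its exact conditional expectation given the observed family members,
under Mendelian transmission and a Hardy-Weinberg prior at the sample
allele frequency.  With allele dosage ``g`` in {0, 1, 2}, each parent
transmits the counted allele with probability ``g / 2`` independently, so

    P(offspring = o | g_p, g_m) = sum over transmitted pairs (a, b)
        with a + b = o of  P(a | g_p) P(b | g_m).

The posterior over the missing parent's dosage m is proportional to

    HWE(m; f) * prod_offspring P(o | g_obs, m)

and for sibling-only families the posterior runs over the 9 ordered
parental pairs with an HWE(f)^2 prior.  The returned expectation is the
posterior-weighted mean; an observed configuration with zero posterior
mass is a Mendelian impossibility and raises.

The conditional expectation is unbiased under random mating: averaging
the imputed parental sum over offspring configurations returns the
population mean 4f (law of total expectation), which downstream
regressions rely on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FamilyObservation",
    "ImputedParentRecord",
    "MendelianInconsistencyError",
    "transmission_prob",
    "offspring_prob",
    "hwe_prior",
    "impute_missing_parent",
    "impute_parental_sum_from_sibs",
    "imputation_tables",
    "mendelian_consistency_report",
]


class MendelianInconsistencyError(ValueError):
    """Observed family genotypes impossible under Mendelian transmission."""

    def __init__(self, message: str, family_id: str | None = None, snp: str | None = None):
        super().__init__(message)
        self.family_id = family_id
        self.snp = snp


@dataclass(frozen=True)
class FamilyObservation:
    """Observed genotypes for one nuclear family at one SNP.

    ``father`` / ``mother`` are dosages in {0, 1, 2} or ``None`` when the
    parent is ungenotyped.  At least one offspring must be observed, and
    at least one parent must be missing for imputation to be meaningful.
    """

    freq: float
    offspring: tuple[int, ...]
    father: int | None = None
    mother: int | None = None
    family_id: str | None = None
    snp: str | None = None

    def __post_init__(self):
        if not (0.0 < self.freq <= 1.0):
            raise ValueError(f"allele frequency must be in (0, 1], got {self.freq}")
        if len(self.offspring) == 0:
            raise ValueError("at least one offspring genotype is required")
        for g in self.offspring + tuple(g for g in (self.father, self.mother) if g is not None):
            if g not in (0, 1, 2):
                raise ValueError(f"dosages must be in {{0,1,2}}, got {g}")


@dataclass
class ImputedParentRecord:
    """Posterior summary for a missing parent (or the parental sum)."""

    kind: str  # "father", "mother" or "sum"
    expectation: float
    posterior: dict[int, float] = field(default_factory=dict)
    configuration: str = ""  # e.g. "one_parent_duo", "sib_pair"

    def __post_init__(self):
        total = sum(self.posterior.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"posterior must sum to 1, sums to {total}")
        mean = sum(k * v for k, v in self.posterior.items())
        if abs(mean - self.expectation) > 1e-9:
            raise ValueError("expectation inconsistent with posterior")


def transmission_prob(dosage: np.ndarray | int) -> np.ndarray:
    """P(transmit counted allele | parent dosage) = g / 2."""
    return np.asarray(dosage, dtype=float) / 2.0


def offspring_prob(o, g_p, g_m):
    """P(offspring dosage o | parental dosages), vectorized.

    Transmitted alleles are independent Bernoulli(g/2) draws per parent.
    """
    o = np.asarray(o, dtype=int)
    tp = transmission_prob(g_p)
    tm = transmission_prob(g_m)
    p0 = (1 - tp) * (1 - tm)
    p1 = tp * (1 - tm) + (1 - tp) * tm
    p2 = tp * tm
    return np.select([o == 0, o == 1, o == 2], [p0, p1, p2], default=0.0)


def hwe_prior(f: float) -> np.ndarray:
    """Hardy-Weinberg genotype probabilities ((1-f)^2, 2f(1-f), f^2)."""
    return np.array([(1 - f) ** 2, 2 * f * (1 - f), f**2])


def impute_missing_parent(obs: FamilyObservation) -> ImputedParentRecord:
    """Impute one missing parent given the other parent and >=1 offspring."""
    observed = obs.father if obs.father is not None else obs.mother
    if observed is None:
        raise ValueError("impute_missing_parent requires exactly one observed parent")
    if obs.father is not None and obs.mother is not None:
        raise ValueError("both parents observed: imputation is a no-op")
    missing_kind = "mother" if obs.father is not None else "father"

    states = np.array([0, 1, 2])
    mass = hwe_prior(obs.freq).copy()
    for o in obs.offspring:
        if missing_kind == "mother":
            mass *= offspring_prob(o, observed, states)
        else:
            mass *= offspring_prob(o, states, observed)
    total = mass.sum()
    if total <= 0.0:
        raise MendelianInconsistencyError(
            f"no parental genotype is consistent with parent={observed}, "
            f"offspring={obs.offspring} at f={obs.freq}",
            family_id=obs.family_id,
            snp=obs.snp,
        )
    post = mass / total
    expectation = float(np.dot(states, post))
    return ImputedParentRecord(
        kind=missing_kind,
        expectation=expectation,
        posterior={int(s): float(p) for s, p in zip(states, post)},
        configuration="one_parent_duo",
    )


def impute_parental_sum_from_sibs(obs: FamilyObservation) -> ImputedParentRecord:
    """Impute E[g_p + g_m] from >=2 sibling genotypes (no parents observed)."""
    if obs.father is not None or obs.mother is not None:
        raise ValueError("parental-sum imputation requires no observed parent")
    if len(obs.offspring) < 2:
        raise ValueError("parental-sum imputation requires at least two siblings")

    prior = hwe_prior(obs.freq)
    gp, gm = np.meshgrid([0, 1, 2], [0, 1, 2], indexing="ij")
    mass = prior[gp] * prior[gm]
    for o in obs.offspring:
        mass = mass * offspring_prob(o, gp, gm)
    total = mass.sum()
    if total <= 0.0:
        raise MendelianInconsistencyError(
            f"no parental pair is consistent with siblings={obs.offspring} at f={obs.freq}",
            family_id=obs.family_id,
            snp=obs.snp,
        )
    post_pairs = mass / total
    sums = gp + gm
    expectation = float((sums * post_pairs).sum())
    posterior_sum: dict[int, float] = {}
    for s in range(5):
        p = float(post_pairs[sums == s].sum())
        if p > 0:
            posterior_sum[s] = p
    return ImputedParentRecord(
        kind="sum",
        expectation=expectation,
        posterior=posterior_sum,
        configuration="sib_pair" if len(obs.offspring) == 2 else "sibship",
    )


def imputation_tables(freq: float, n_sibs: int = 2):
    """Precompute imputation lookup tables at one allele frequency.

    Returns ``(duo, sib_sum)`` where ``duo[p, o]`` is E[missing parent |
    observed parent p, single offspring o] (NaN when impossible) and
    ``sib_sum[s1, s2]`` is E[g_p + g_m | two siblings] (NaN when
    impossible).  Used to vectorize imputation across many families that
    share an allele frequency.
    """
    duo = np.full((3, 3), np.nan)
    for p in range(3):
        for o in range(3):
            try:
                duo[p, o] = impute_missing_parent(
                    FamilyObservation(freq=freq, offspring=(o,), father=p)
                ).expectation
            except MendelianInconsistencyError:
                pass
    sib_sum = np.full((3, 3), np.nan)
    for s1 in range(3):
        for s2 in range(3):
            try:
                sib_sum[s1, s2] = impute_parental_sum_from_sibs(
                    FamilyObservation(freq=freq, offspring=(s1, s2))
                ).expectation
            except MendelianInconsistencyError:
                pass
    return duo, sib_sum


def mendelian_consistency_report(dataset) -> dict:
    """Scan a FamilyDataset for Mendelian violations and sib-correlation QC.

    Checks, per SNP and family: trio transmission impossibilities
    (P(o | g_p, g_m) = 0) and parent-offspring impossibilities (parent 2
    with offspring 0, or parent 0 with offspring 2).  Also estimates the
    genome-wide correlation between sibling dosages, which Mendelian
    segregation fixes at ~0.5 for unlinked SNPs; values far below (the
    reported flag threshold is 0.35) indicate mislabelled "siblings".

    Returns a dict with a ``violations`` DataFrame (family, snp, kind),
    ``n_violations``, ``sib_correlation``, ``sib_correlation_se`` and
    ``sib_correlation_flag``.
    """
    rows = []
    G = dataset.genotypes
    snp_ids = dataset.snp_ids
    for fam in dataset.families():
        offs = fam.offspring_rows
        fa, mo = fam.father_row, fam.mother_row
        for li, snp in enumerate(snp_ids):
            odos = [int(G[i, li]) for i in offs if np.isfinite(G[i, li])]
            gfa = int(G[fa, li]) if fa is not None and np.isfinite(G[fa, li]) else None
            gmo = int(G[mo, li]) if mo is not None and np.isfinite(G[mo, li]) else None
            if gfa is not None and gmo is not None:
                for o in odos:
                    if offspring_prob(o, gfa, gmo) == 0.0:
                        rows.append((fam.family_id, snp, "trio_transmission"))
            else:
                for parent in (gfa, gmo):
                    if parent is None:
                        continue
                    for o in odos:
                        if (parent == 2 and o == 0) or (parent == 0 and o == 2):
                            rows.append((fam.family_id, snp, "parent_offspring"))
    violations = pd.DataFrame(rows, columns=["family", "snp", "kind"])

    # genome-wide sibling dosage correlation, pooled over SNPs and sib pairs
    s1, s2 = [], []
    for fam in dataset.families():
        offs = fam.offspring_rows
        if len(offs) >= 2:
            a, b = offs[0], offs[1]
            s1.append(G[a])
            s2.append(G[b])
    if s1:
        A = np.asarray(s1, dtype=float)
        B = np.asarray(s2, dtype=float)
        # standardize per SNP so pooling across SNPs does not mix frequencies
        mu = np.nanmean(np.concatenate([A, B]), axis=0)
        sd = np.nanstd(np.concatenate([A, B]), axis=0)
        sd[sd == 0] = np.nan
        x = ((A - mu) / sd).ravel()
        y = ((B - mu) / sd).ravel()
        ok = np.isfinite(x) & np.isfinite(y)
        x, y = x[ok], y[ok]
        n = x.size
        if n > 3 and np.std(x) > 0 and np.std(y) > 0:
            r = float(np.corrcoef(x, y)[0, 1])
            se = float((1 - r**2) / np.sqrt(n - 3))
        else:
            r, se = np.nan, np.nan
    else:
        r, se, n = np.nan, np.nan, 0
    return {
        "violations": violations,
        "n_violations": len(violations),
        "sib_correlation": r,
        "sib_correlation_se": se,
        "sib_correlation_flag": bool(np.isfinite(r) and r < 0.35),
        "n_sib_observations": int(n),
    }
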