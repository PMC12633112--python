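"""Generator invariants: Mendelian transmission, stratification, AM equilibrium."""

import numpy as np
import pytest

from famgwas.simulate import (
    AssortativeMatingConfig,
    ConfigurationError,
    SimulationConfig,
    StratificationConfig,
    simulate_assortative_mating,
    simulate_cross_trait_am,
    simulate_random_mating,
)


def test_config_validation():
    with pytest.raises(ConfigurationError):
        SimulationConfig(h2_direct=1.2)
    with pytest.raises(ConfigurationError):
        SimulationConfig(maf_spec=0.7)
    with pytest.raises(ConfigurationError):
        SimulationConfig(family_design={"trio": 0.4})
    with pytest.raises(ConfigurationError):
        AssortativeMatingConfig(n_generations=3)
    with pytest.raises(ConfigurationError):
        simulate_random_mating(
            SimulationConfig(am=AssortativeMatingConfig(), family_design={"trio": 1.0})
        )


def test_bit_reproducibility():
    cfg = SimulationConfig(n_families=200, n_snps=10, seed=42)
    a = simulate_random_mating(cfg)
    b = simulate_random_mating(cfg)
    np.testing.assert_array_equal(a.genotypes, b.genotypes)
    np.testing.assert_array_equal(a.phenotype, b.phenotype)
    c = simulate_random_mating(SimulationConfig(n_families=200, n_snps=10, seed=43))
    assert not np.array_equal(a.phenotype, c.phenotype)


def test_deterministic_single_snp_limit():
    """One SNP, delta fixed by h2 -> phenotype proportional to dosage when noise-free."""
    cfg = SimulationConfig(
        n_families=50, n_snps=1, maf_spec=0.5, h2_direct=1.0 - 1e-12,
        family_design={"trio": 1.0}, seed=1,
    )
    ds = simulate_random_mating(cfg)
    off = ds.offspring_mask
    delta = ds.truth["true_delta"][0]
    np.testing.assert_allclose(
        ds.phenotype[off], ds.genotypes[off, 0] * delta, atol=1e-5
    )


def test_null_phenotype_independent_of_genotype():
    cfg = SimulationConfig(n_families=2000, n_snps=20, h2_direct=0.0, seed=2)
    ds = simulate_random_mating(cfg)
    assert np.all(ds.truth["true_delta"] == 0)
    off = ds.offspring_mask
    cors = [
        abs(np.corrcoef(ds.genotypes[off, l], ds.phenotype[off])[0, 1])
        for l in range(20)
    ]
    assert np.mean(cors) < 0.03


def test_offspring_frequency_matches_parents(trio_dataset):
    """No allele-frequency drift through transmission under random mating."""
    ds = trio_dataset
    off = ds.offspring_mask
    par = ~off
    f_off = ds.genotypes[off].mean(axis=0) / 2
    f_par = ds.genotypes[par].mean(axis=0) / 2
    n = off.sum()
    se = np.sqrt(f_par * (1 - f_par) / (2 * n))
    assert np.all(np.abs(f_off - f_par) < 4 * se + 1e-9)


def test_sibling_correlation_half():
    cfg = SimulationConfig(
        n_families=10000, n_snps=5, maf_spec=0.3, h2_direct=0.0,
        family_design={"sib_pair_no_parents": 1.0}, seed=3,
    )
    ds = simulate_random_mating(cfg)
    s1 = np.array([ds.genotypes[f.offspring_rows[0]] for f in ds.families()])
    s2 = np.array([ds.genotypes[f.offspring_rows[1]] for f in ds.families()])
    for l in range(5):
        r = np.corrcoef(s1[:, l], s2[:, l])[0, 1]
        assert abs(r - 0.5) < 3.0 / np.sqrt(len(s1))


def test_stratified_null_confounds_population_effects():
    """With delta = 0 and an environmental deme shift, marginal genotype-phenotype
    associations track the deme frequency differences; within-family transmitted
    minus expected dosage does not."""
    cfg = SimulationConfig(
        n_families=5000, n_snps=60, h2_direct=0.0,
        strat=StratificationConfig(fst_like_divergence=0.2, env_shift=0.6),
        family_design={"trio": 1.0}, seed=4,
    )
    ds = simulate_random_mating(cfg)
    off = ds.offspring_mask
    G = ds.genotypes[off]
    y = ds.phenotype[off]
    Gc = G - G.mean(axis=0)
    beta = Gc.T @ (y - y.mean()) / (Gc**2).sum(axis=0)
    fdiff = ds.truth["deme_freqs"][1] - ds.truth["deme_freqs"][0]
    r_pop = np.corrcoef(beta, fdiff)[0, 1]
    assert r_pop > 0.5

    # within-family deviation from the parental expectation is unconfounded
    gp = np.repeat(ds.truth["father_geno"], 2, axis=0)
    gm = np.repeat(ds.truth["mother_geno"], 2, axis=0)
    dev = G - (gp + gm) / 2
    delta_hat = (dev * (y - y.mean())[:, None]).sum(axis=0) / (dev**2).sum(axis=0)
    r_dge = np.corrcoef(delta_hat, fdiff)[0, 1]
    assert abs(r_dge) < 0.25


class TestAssortativeMating:
    def test_zero_target_reduces_to_random(self):
        cfg = SimulationConfig(
            n_families=4000, n_snps=50, h2_direct=0.5,
            am=AssortativeMatingConfig(target_cross_mate_corr=0.0, n_generations=10),
            family_design={"trio": 1.0}, seed=5,
        )
        ds = simulate_assortative_mating(cfg)
        assert abs(ds.truth["r_delta_realized"]) < 3.0 / np.sqrt(cfg.n_families)

    def test_equilibrium_inflation_and_ntc_sign(self):
        """Population effects regress on true delta with slope ~ 1/(1 - r)."""
        cfg = SimulationConfig(
            n_families=8000, n_snps=150, h2_direct=0.5,
            am=AssortativeMatingConfig(target_cross_mate_corr=0.3, n_generations=15),
            family_design={"trio": 1.0}, seed=6,
        )
        ds = simulate_assortative_mating(cfg)
        r = ds.truth["r_delta_realized"]
        assert r == pytest.approx(0.3, abs=0.06)
        off = ds.offspring_mask
        G = ds.genotypes[off]
        y = ds.phenotype[off]
        Gc = G - G.mean(axis=0)
        beta = Gc.T @ (y - y.mean()) / (Gc**2).sum(axis=0)
        slope = np.polyfit(ds.truth["true_delta"], beta, 1)[0]
        assert slope == pytest.approx(1.0 / 0.7, abs=0.12)
        # alpha_l = beta_l - delta_l positively correlated with delta_l
        alpha = beta - ds.truth["true_delta"]
        assert np.corrcoef(alpha, ds.truth["true_delta"])[0, 1] > 0.2

    def test_bulmer_inflation_of_dge_variance(self):
        """AM inflates the variance of the DGE component above its HWE value."""
        base = dict(
            n_families=8000, n_snps=50, n_causal=50, h2_direct=0.5,
            family_design={"trio": 1.0}, seed=7,
        )
        rm = simulate_random_mating(SimulationConfig(**base))
        am = simulate_assortative_mating(
            SimulationConfig(
                **base, am=AssortativeMatingConfig(target_cross_mate_corr=0.4, n_generations=15)
            )
        )
        d_rm = rm.genotypes[rm.offspring_mask] @ rm.truth["true_delta"]
        d_am = am.genotypes[am.offspring_mask] @ am.truth["true_delta"]
        assert np.var(d_am) > np.var(d_rm)


class TestCrossTraitAM:
    def test_invalid_target_rejected(self):
        cfg = SimulationConfig(
            n_families=500, n_snps=20, am=AssortativeMatingConfig(), seed=8
        )
        with pytest.raises(ConfigurationError):
            simulate_cross_trait_am(cfg, np.array([[1.0, 2.0], [2.0, 1.0]]))

    def test_cross_trait_correlation_achieved(self):
        cfg = SimulationConfig(
            n_families=5000, n_snps=60, h2_direct=0.4,
            am=AssortativeMatingConfig(target_cross_mate_corr=0.3, n_generations=10),
            family_design={"trio": 1.0}, seed=9,
        )
        R = np.array([[0.3, 0.2], [0.2, 0.3]])
        ds = simulate_cross_trait_am(cfg, R, causal_overlap="disjoint")
        achieved = ds.truth["cross_mate_achieved"]
        assert achieved[0, 1] == pytest.approx(0.2, abs=0.07)
        assert ds.phenotype2 is not None

    def test_xam_induces_population_level_cross_trait_covariance(self):
        """Disjoint causal sets + xAM: marginal effects of trait-2 SNPs on
        trait 1 become correlated with the trait-2 effects, while the
        within-family (transmission-deviation) effects stay uncorrelated."""
        cfg = SimulationConfig(
            n_families=8000, n_snps=240, h2_direct=0.5,
            am=AssortativeMatingConfig(target_cross_mate_corr=0.4, n_generations=12),
            family_design={"trio": 1.0}, seed=10,
        )
        R = np.array([[0.4, 0.4], [0.4, 0.4]])
        ds = simulate_cross_trait_am(cfg, R, causal_overlap="disjoint")
        off = ds.offspring_mask
        G = ds.genotypes[off]
        y1 = ds.phenotype[off]
        Gc = G - G.mean(axis=0)
        beta1 = Gc.T @ (y1 - y1.mean()) / (Gc**2).sum(axis=0)
        d2 = ds.truth["true_delta2"]
        mask2 = d2 != 0  # trait-2 causal SNPs have zero direct effect on trait 1
        r_pop = np.corrcoef(beta1[mask2], d2[mask2])[0, 1]
        gp = np.repeat(ds.truth["father_geno"], 2, axis=0)
        gm = np.repeat(ds.truth["mother_geno"], 2, axis=0)
        dev = G - (gp + gm) / 2
        delta1_hat = (dev * (y1 - y1.mean())[:, None]).sum(axis=0) / (dev**2).sum(axis=0)
        r_dge = np.corrcoef(delta1_hat[mask2], d2[mask2])[0, 1]
        assert abs(r_pop) > abs(r_dge)
        assert abs(r_pop) > 0.4
        assert abs(r_dge) < 0.3  # noise scale ~ 1/sqrt(120) for a null correlation

    def test_zero_cross_mate_matrix_keeps_traits_independent(self):
        cfg = SimulationConfig(
            n_families=3000, n_snps=40, h2_direct=0.4,
            am=AssortativeMatingConfig(target_cross_mate_corr=0.3, n_generations=10),
            family_design={"trio": 1.0}, seed=12,
        )
        ds = simulate_cross_trait_am(cfg, np.zeros((2, 2)), causal_overlap="disjoint")
        off = ds.offspring_mask
        r = np.corrcoef(ds.phenotype[off], ds.phenotype2[off])[0, 1]
        assert abs(r) < 0.06
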