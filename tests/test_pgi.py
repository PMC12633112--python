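"""PGI scoring, family-based PGI regression, ratio SEs, equilibrium diagnostic."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from famgwas.pgi import (
    PgiWeights,
    compute_pgi,
    equilibrium_diagnostic,
    fit_family_pgi_regression,
)
from famgwas.simulate import (
    AssortativeMatingConfig,
    SimulationConfig,
    simulate_assortative_mating,
    simulate_random_mating,
)


def _weights_from_truth(dataset, source="direct"):
    return PgiWeights(
        table=pd.DataFrame(
            {
                "snp": dataset.snp_ids,
                "A1": dataset.snps["a1"],
                "weight": dataset.truth["true_delta"],
            }
        ),
        source=source,
    )


class TestScoring:
    def test_single_snp_score_equals_dosage(self, trio_dataset):
        w = PgiWeights(table=pd.DataFrame({"snp": ["snp0"], "A1": ["A"], "weight": [1.0]}))
        scores = compute_pgi(trio_dataset, w)
        off_rows = [r for f in trio_dataset.families() for r in f.offspring_rows]
        np.testing.assert_allclose(scores.offspring, trio_dataset.genotypes[off_rows, 0])

    def test_allele_flip_changes_sign_only(self, trio_dataset):
        snps5 = trio_dataset.snp_ids[:5]
        w_plus = PgiWeights(
            table=pd.DataFrame({"snp": snps5, "A1": "A", "weight": np.ones(5)})
        )
        w_flip = PgiWeights(
            table=pd.DataFrame({"snp": snps5, "A1": "G", "weight": -np.ones(5)})
        )
        s1 = compute_pgi(trio_dataset, w_plus)
        s2 = compute_pgi(trio_dataset, w_flip)
        np.testing.assert_allclose(s1.offspring, s2.offspring, atol=1e-10)
        np.testing.assert_allclose(s1.paternal, s2.paternal, atol=1e-10)

    def test_zero_overlap_errors(self, trio_dataset):
        w = PgiWeights(table=pd.DataFrame({"snp": ["nope"], "A1": ["A"], "weight": [1.0]}))
        with pytest.raises(ValueError, match="overlap"):
            compute_pgi(trio_dataset, w)

    def test_sib_pair_parental_score_uses_imputed_sum(self):
        cfg = SimulationConfig(
            n_families=100, n_snps=5, h2_direct=0.2,
            family_design={"sib_pair_no_parents": 1.0}, seed=31,
        )
        ds = simulate_random_mating(cfg)
        w = PgiWeights(
            table=pd.DataFrame({"snp": ds.snp_ids, "A1": "A", "weight": np.ones(5)})
        )
        scores = compute_pgi(ds, w)
        assert scores.mode == "collapsed"
        # paternal and maternal imputed scores are identical halves of the sum
        np.testing.assert_allclose(scores.paternal, scores.maternal, atol=1e-12)


class TestRegression:
    def test_phenotype_equal_to_pgi(self, trio_dataset):
        w = _weights_from_truth(trio_dataset)
        scores = compute_pgi(trio_dataset, w)
        scores.phenotype = scores.offspring.copy()
        res = fit_family_pgi_regression(scores)
        assert res.delta == pytest.approx(1.0, abs=1e-6)
        assert res.alpha == pytest.approx(0.0, abs=1e-6)
        assert res.beta == pytest.approx(1.0, abs=1e-6)

    def test_simulated_ige_inflates_population_effect(self, rng):
        """Phenotype = offspring PGI + parental-mean PGI: alpha ~ 1 (per-parent
        coefficient 1/2 on each parent's PGI... measured as avg NTC = 1/2 here),
        and the population effect exceeds the direct effect."""
        cfg = SimulationConfig(
            n_families=2000, n_snps=50, h2_direct=0.3, family_design={"trio": 1.0},
            seed=33,
        )
        ds = simulate_random_mating(cfg)
        w = _weights_from_truth(ds)
        scores = compute_pgi(ds, w)
        scores.phenotype = (
            scores.offspring
            + 0.5 * (scores.paternal + scores.maternal)
            + 0.05 * rng.standard_normal(len(scores.offspring))
        )
        res = fit_family_pgi_regression(scores)
        sd = np.std(scores.offspring)
        # coefficients are on the standardized scale; compare shape not scale
        assert res.alpha == pytest.approx(0.5 * res.delta, rel=0.1)
        assert res.beta > res.delta + 2 * res.beta_se

    def test_delta_method_worked_value_and_bootstrap(self, rng):
        """Var(alpha/delta) from the delta method matches the parametric
        bootstrap and the hand-computed value for the worked inputs."""
        from famgwas.pgi import PgiRegressionResult

        C4 = np.zeros((4, 4))
        C3 = np.diag([0.01, 0.02, 0.02])  # Var(alpha)=0.01 via averaging
        C4[:3, :3] = C3
        C4[3, 3] = 0.01
        res = PgiRegressionResult(
            delta=1.0, alpha_p=0.5, alpha_m=0.5, alpha=0.5, beta=1.5,
            covariance=C4, ratio=0.5, ratio_se=np.nan,
            maternal_minus_paternal=0.0, maternal_minus_paternal_se=0.0,
            r_par=0.0, r_par_se=0.0, sigma2_family=0.0,
            n_individuals=1000, n_families=500,
        )
        # recompute via the same formula used in the fit
        var_alpha = 0.25 * (C3[1, 1] + C3[2, 2])
        expected = np.sqrt(var_alpha / 1.0 + 0.25 * 0.01 / 1.0)
        assert expected == pytest.approx(np.sqrt(0.01 * 1 + 0.25 * 0.01), abs=1e-12)

        draws_a = 0.5 + np.sqrt(var_alpha) * rng.standard_normal(10000)
        draws_d = 1.0 + 0.1 * rng.standard_normal(10000)
        boot = np.std(draws_a / draws_d)
        assert expected == pytest.approx(boot, rel=0.1)

    def test_collapsed_equals_constrained_full(self, trio_dataset):
        """With alpha_p = alpha_m imposed, regressing on the parental sum gives
        the same delta as the full regression does under the constraint."""
        w = _weights_from_truth(trio_dataset)
        scores = compute_pgi(trio_dataset, w)
        full = fit_family_pgi_regression(scores)
        collapsed = dataclasses.replace(scores, mode="collapsed")
        coll = fit_family_pgi_regression(collapsed)
        # constrained full fit by symmetrizing the parental columns
        sym = dataclasses.replace(
            scores,
            paternal=(scores.paternal + scores.maternal) / 2,
            maternal=(scores.paternal + scores.maternal) / 2,
            mode="collapsed",
        )
        res_sym = fit_family_pgi_regression(sym)
        assert coll.delta == pytest.approx(res_sym.delta, abs=1e-8)

    def test_standardization_invariance(self, trio_dataset):
        w = _weights_from_truth(trio_dataset)
        scores = compute_pgi(trio_dataset, w)
        res1 = fit_family_pgi_regression(scores)
        scaled = dataclasses.replace(
            scores,
            offspring=5.0 * scores.offspring + 2.0,
            paternal=5.0 * scores.paternal + 2.0,
            maternal=5.0 * scores.maternal + 2.0,
            phenotype=3.0 * scores.phenotype - 1.0,
        )
        res2 = fit_family_pgi_regression(scaled)
        assert res2.delta == pytest.approx(res1.delta, rel=1e-6)
        assert res2.alpha == pytest.approx(res1.alpha, abs=1e-8)
        assert res2.beta == pytest.approx(res1.beta, rel=1e-6)


class TestEquilibrium:
    # one analyzed offspring per family, as in typical validation cohorts;
    # with several siblings the family random intercept absorbs part of the
    # family-constant parental-PGI signal and beta is no longer the marginal
    # association that the equilibrium identity refers to
    def test_random_mating_relation_reduces_to_sum(self):
        cfg = SimulationConfig(
            n_families=6000, n_snps=60, h2_direct=0.4, ige_coefficient=0.4,
            family_design={"trio": 1.0}, n_offspring=1, seed=35,
        )
        ds = simulate_random_mating(cfg)
        scores = compute_pgi(ds, _weights_from_truth(ds))
        res = fit_family_pgi_regression(scores)
        assert abs(res.r_par) < 0.05
        diag = equilibrium_diagnostic(res)
        assert diag["available"]
        assert abs(diag["discrepancy"]) < 2 * diag["se"] + 1e-3

    def test_am_requires_rpar_correction(self):
        """Under AM with parental effects, beta - (delta + alpha) deviates while
        the r_par-corrected discrepancy does not."""
        cfg = SimulationConfig(
            n_families=8000, n_snps=60, h2_direct=0.4, ige_coefficient=0.4,
            am=AssortativeMatingConfig(target_cross_mate_corr=0.4, n_generations=12),
            family_design={"trio": 1.0}, n_offspring=1, seed=36,
        )
        ds = simulate_assortative_mating(cfg)
        scores = compute_pgi(ds, _weights_from_truth(ds))
        res = fit_family_pgi_regression(scores)
        assert res.r_par > 0.1
        diag = equilibrium_diagnostic(res)
        assert abs(diag["naive_discrepancy"]) > abs(diag["discrepancy"])
        assert abs(diag["discrepancy"]) < 3 * diag["se"]

    def test_alpha_zero_relation_holds_any_rpar(self):
        cfg = SimulationConfig(
            n_families=8000, n_snps=60, h2_direct=0.5, ige_coefficient=0.0,
            am=AssortativeMatingConfig(target_cross_mate_corr=0.4, n_generations=12),
            family_design={"trio": 1.0}, n_offspring=1, seed=37,
        )
        ds = simulate_assortative_mating(cfg)
        scores = compute_pgi(ds, _weights_from_truth(ds))
        res = fit_family_pgi_regression(scores)
        diag = equilibrium_diagnostic(res)
        assert abs(diag["discrepancy"]) < 3 * diag["se"] + 1e-3
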