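"""Multivariate meta-analysis against a stacked-GLS oracle; harmonization rules."""

import numpy as np
import pandas as pd
import pytest
from scipy.linalg import block_diag

from famgwas.meta import (
    A_COLLAPSED,
    A_FULL,
    EXPANSION_MATRIX,
    CohortSummary,
    cohort_from_sumstats,
    expand_theta,
    harmonize_alleles,
    meta_analyze,
    multivariate_meta,
    univariate_meta_dge,
)


def _alleles(snps, freq=0.3, a1="A", a2="G"):
    return pd.DataFrame(
        {"A1": a1, "A2": a2, "freq": freq}, index=pd.Index(snps, name="snp")
    )


def _random_pd(rng, dim):
    Q = rng.standard_normal((dim, dim))
    return Q @ Q.T + 0.1 * np.eye(dim)


def _stacked_gls(As, Ss, zs):
    """Independent oracle: GLS on the stacked observation system."""
    A = np.vstack(As)
    S = block_diag(*Ss)
    z = np.concatenate(zs)
    W = np.linalg.inv(S)
    V = np.linalg.inv(A.T @ W @ A)
    return V @ (A.T @ W @ z), V


def test_single_cohort_identity():
    z = np.array([0.1, 0.05, -0.02])
    S = np.diag([0.01, 0.02, 0.02])
    cohort = CohortSummary("c1", A_FULL, {"s": z}, {"s": S}, _alleles(["s"]))
    rec = multivariate_meta([cohort], "s")
    np.testing.assert_allclose(rec.theta, z, atol=1e-12)
    np.testing.assert_allclose(rec.var_theta, S, atol=1e-12)


def test_two_identity_cohorts_average():
    z1, z2 = np.array([1.0, 0.0, 2.0]), np.array([3.0, 4.0, 0.0])
    I = np.eye(3)
    cohorts = [
        CohortSummary("c1", A_FULL, {"s": z1}, {"s": I}, _alleles(["s"])),
        CohortSummary("c2", A_FULL, {"s": z2}, {"s": I}, _alleles(["s"])),
    ]
    rec = multivariate_meta(cohorts, "s")
    np.testing.assert_allclose(rec.theta, (z1 + z2) / 2, atol=1e-12)
    np.testing.assert_allclose(rec.var_theta, I / 2, atol=1e-12)


def test_mle_equals_stacked_gls_on_random_instances(rng):
    """100 random mixes of full and collapsed cohorts agree with GLS to 1e-10."""
    for _ in range(100):
        n_full = rng.integers(1, 4)
        n_coll = rng.integers(0, 4)
        theta = rng.standard_normal(3)
        As, Ss, zs = [], [], []
        for _ in range(n_full):
            As.append(A_FULL)
            Ss.append(_random_pd(rng, 3))
            zs.append(theta + rng.standard_normal(3))
        for _ in range(n_coll):
            As.append(A_COLLAPSED)
            Ss.append(_random_pd(rng, 2))
            zs.append(A_COLLAPSED @ theta + rng.standard_normal(2))
        cohorts = [
            CohortSummary(f"c{j}", A, {"s": z}, {"s": S}, _alleles(["s"]))
            for j, (A, S, z) in enumerate(zip(As, Ss, zs))
        ]
        rec = multivariate_meta(cohorts, "s")
        oracle_theta, oracle_var = _stacked_gls(As, Ss, zs)
        np.testing.assert_allclose(rec.theta, oracle_theta, atol=1e-10)
        np.testing.assert_allclose(rec.var_theta, oracle_var, atol=1e-10)
        # expansion identities hold exactly
        d, ap, am, a, b = rec.expanded
        assert a == pytest.approx(0.5 * (ap + am), abs=1e-12)
        assert b == pytest.approx(d + a, abs=1e-12)
        np.testing.assert_allclose(
            rec.var_expanded, EXPANSION_MATRIX @ rec.var_theta @ EXPANSION_MATRIX.T, atol=1e-12
        )


def test_collapsed_only_cohorts_fall_back_without_pseudoinversion(rng):
    cohorts = [
        CohortSummary(
            f"c{j}",
            A_COLLAPSED,
            {"s": np.array([0.2, 0.1]) + 0.01 * rng.standard_normal(2)},
            {"s": _random_pd(rng, 2) * 0.01},
            _alleles(["s"]),
        )
        for j in range(3)
    ]
    rec = multivariate_meta(cohorts, "s")
    assert rec.collapsed_only
    assert np.isnan(rec.expanded[1]) and np.isnan(rec.expanded[2])
    assert np.isfinite(rec.expanded[0]) and np.isfinite(rec.expanded[4])
    assert rec.expanded[4] == pytest.approx(rec.expanded[0] + rec.expanded[3], abs=1e-12)


def test_adding_a_cohort_never_inflates_variance(rng):
    theta = rng.standard_normal(3)
    base = [
        CohortSummary(
            "c0", A_FULL, {"s": theta + rng.standard_normal(3)},
            {"s": _random_pd(rng, 3)}, _alleles(["s"]),
        )
    ]
    rec0 = multivariate_meta(base, "s")
    for j in range(5):
        A = A_FULL if j % 2 == 0 else A_COLLAPSED
        dim = A.shape[0]
        base.append(
            CohortSummary(
                f"c{j + 1}", A, {"s": (A @ theta) + rng.standard_normal(dim)},
                {"s": _random_pd(rng, dim)}, _alleles(["s"]),
            )
        )
        rec1 = multivariate_meta(base, "s")
        assert np.all(np.diag(rec1.var_theta) <= np.diag(rec0.var_theta) + 1e-12)
        rec0 = rec1


def test_expand_theta_worked_values():
    t, v = expand_theta(np.array([1.0, 0.0, 0.0]), np.eye(3))
    np.testing.assert_allclose(t, [1, 0, 0, 0, 1])
    t, _ = expand_theta(np.array([0.1, 0.2, 0.4]), np.eye(3))
    assert t[3] == pytest.approx(0.3)
    assert t[4] == pytest.approx(0.4)
    _, v = expand_theta(np.zeros(3), np.eye(3))
    assert v[3, 3] == pytest.approx(0.5)
    assert v[4, 4] == pytest.approx(1.5)
    assert v[0, 4] == pytest.approx(1.0)


class TestHarmonization:
    def _ref(self):
        return pd.DataFrame(
            {"A1": ["A", "A", "C"], "A2": ["G", "T", "G"], "freq": [0.3, 0.5, 0.1]},
            index=pd.Index(["s1", "s2", "s3"], name="snp"),
        )

    def test_swapped_alleles_flip_back(self):
        ref = self._ref()
        z = np.array([0.2, 0.1, 0.05])
        S = np.eye(3) * 0.01
        swapped = CohortSummary(
            "c", A_FULL, {"s1": -z}, {"s1": S},
            _alleles(["s1"], freq=0.7, a1="G", a2="A"),
        )
        aligned, dropped = harmonize_alleles([swapped], ref)
        np.testing.assert_allclose(aligned[0].estimates["s1"], z)
        assert aligned[0].alleles.loc["s1", "freq"] == pytest.approx(0.3)
        assert sum(dropped.values()) == 0

    def test_palindromic_near_half_dropped(self):
        ref = self._ref()
        cohort = CohortSummary(
            "c", A_FULL, {"s2": np.zeros(3)}, {"s2": np.eye(3)},
            _alleles(["s2"], freq=0.5, a1="A", a2="T"),
        )
        aligned, dropped = harmonize_alleles([cohort], ref)
        assert dropped["palindromic"] == 1
        assert "s2" not in aligned[0].estimates

    def test_frequency_mismatch_dropped(self):
        ref = self._ref()
        cohort = CohortSummary(
            "c", A_FULL, {"s3": np.zeros(3)}, {"s3": np.eye(3)},
            _alleles(["s3"], freq=0.35, a1="C", a2="G"),
        )
        aligned, dropped = harmonize_alleles([cohort], ref)
        assert dropped["freq_mismatch"] == 1
        assert "s3" not in aligned[0].estimates


class TestUnivariateDge:
    def test_equal_variance_is_plain_mean(self):
        cohorts = [
            CohortSummary(
                f"c{j}", A_FULL, {"s": np.array([v, 0, 0])},
                {"s": np.eye(3)}, _alleles(["s"]),
            )
            for j, v in enumerate([0.1, 0.3])
        ]
        out = univariate_meta_dge(cohorts).set_index("SNP")
        assert out.loc["s", "direct"] == pytest.approx(0.2)

    def test_huge_variance_cohort_ignored(self):
        cohorts = [
            CohortSummary(
                "a", A_FULL, {"s": np.array([0.1, 0, 0])},
                {"s": np.eye(3) * 1e-4}, _alleles(["s"]),
            ),
            CohortSummary(
                "b", A_FULL, {"s": np.array([5.0, 0, 0])},
                {"s": np.eye(3) * 1e4}, _alleles(["s"]),
            ),
        ]
        out = univariate_meta_dge(cohorts).set_index("SNP")
        assert out.loc["s", "direct"] == pytest.approx(0.1, abs=1e-3)

    def test_univariate_tracks_multivariate_in_homogeneous_setting(self, rng):
        """5 homogeneous cohorts: the two DGE meta-analyses correlate > 0.99."""
        n_snps = 150
        snps = [f"s{i}" for i in range(n_snps)]
        # high-precision regime (large effective N): per-cohort SE well below
        # the effect scale, as in a well-powered meta-analysis
        theta = rng.standard_normal((n_snps, 3)) * 0.1
        cohorts = []
        for j in range(5):
            est, cov = {}, {}
            for i, s in enumerate(snps):
                S = _random_pd(rng, 3) * 2e-4
                est[s] = theta[i] + np.linalg.cholesky(S) @ rng.standard_normal(3)
                cov[s] = S
            cohorts.append(CohortSummary(f"c{j}", A_FULL, est, cov, _alleles(snps)))
        uni = univariate_meta_dge(cohorts).set_index("SNP")
        multi = np.array([multivariate_meta(cohorts, s).theta[0] for s in snps])
        r = np.corrcoef(uni.loc[snps, "direct"].to_numpy(), multi)[0, 1]
        assert r > 0.99


def test_meta_analyze_from_sumstats_roundtrip(trio_dataset):
    """Cohort summaries built from sumstats files meta-analyze cleanly and
    preserve the linear identities in the expanded output."""
    from famgwas.fgwas import run_fgwas

    ss = run_fgwas(trio_dataset)
    half = len(trio_dataset.fids) // 2
    cohorts = [cohort_from_sumstats("c1", ss), cohort_from_sumstats("c2", ss)]
    table = meta_analyze(cohorts, min_cohorts=2)
    assert len(table) == len(ss)
    np.testing.assert_allclose(
        table["population"], table["direct"] + table["avg_NTC"], atol=1e-10
    )
    # two identical cohorts halve every sampling variance
    np.testing.assert_allclose(
        table.set_index("SNP").loc[ss["SNP"], "direct_SE"],
        ss.set_index("SNP").loc[ss["SNP"], "direct_SE"] / np.sqrt(2),
        rtol=1e-8,
    )
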