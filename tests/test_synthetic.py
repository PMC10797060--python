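"""Planted-structure simulators against exact small-system oracles."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import mminet as mm
from mminet.synthetic import (
    ConfigError,
    ValidityError,
    default_truth_network,
    make_truth_network,
    sample_gaussian,
    sample_ising_gibbs,
    sample_mixed,
)


def test_make_truth_network_construction():
    t = make_truth_network(4, [(0, 1, 0.5)])
    assert np.count_nonzero(t.weights, axis=1).tolist() == [1, 1, 0, 0]
    assert make_truth_network(3, []).weights.sum() == 0
    with pytest.raises(ConfigError):
        make_truth_network(4, [(2, 3, 0.4)], isolated={3})


def test_default_truth_structure():
    t = default_truth_network()
    assert t.isolated_names() == {"Can", "DVT", "Dia", "HBP", "LD"}
    hub_degree = np.count_nonzero(t.weights[t.index("AD")])
    assert hub_degree >= 6
    assert np.all(t.weights == t.weights.T) and np.all(np.diag(t.weights) == 0)
    assert np.all(t.weights[t.weights != 0] > 0)  # predominantly positive items


class TestGaussianSampler:
    def test_independence(self):
        t = make_truth_network(4, [])
        X = sample_gaussian(t, n=10000, seed=3)
        C = np.corrcoef(X.to_numpy(), rowvar=False)
        assert np.max(np.abs(C - np.eye(4))) < 0.05

    def test_partial_correlation_matches_precision_oracle(self):
        """Sample partial correlations reproduce the planted weight; the
        oracle is the population covariance from inverting I - W."""
        t = make_truth_network(3, [(0, 1, 0.5)])
        cov_oracle = np.linalg.inv(np.eye(3) - t.weights)
        X = sample_gaussian(t, n=20000, seed=11)
        # empirical covariance close to the oracle
        assert np.max(np.abs(np.cov(X.to_numpy(), rowvar=False) - cov_oracle)) < 0.05
        K = np.linalg.inv(np.cov(X.to_numpy(), rowvar=False))
        d = np.sqrt(np.diag(K))
        pcor = -K / np.outer(d, d)
        assert pcor[0, 1] == pytest.approx(0.5, abs=0.03)

    def test_determinism_and_pd_check(self):
        t = make_truth_network(3, [(0, 1, 0.5)])
        a = sample_gaussian(t, 50, seed=5)
        b = sample_gaussian(t, 50, seed=5)
        pd.testing.assert_frame_equal(a, b)
        bad = make_truth_network(2, [(0, 1, 1.2)])
        with pytest.raises(ValidityError, match="eigenvalue"):
            sample_gaussian(bad, 10, seed=0)


class TestIsingSampler:
    def test_fair_coin_marginals(self):
        t = make_truth_network(3, [])
        X = sample_ising_gibbs(t, n=10000, burn_in=30, seed=2)
        assert np.all((X.mean() > 0.47) & (X.mean() < 0.53))

    def test_two_node_agreement_with_enumeration(self, ising_oracle):
        """P(both nodes equal) matches exhaustive 4-state enumeration."""
        t = make_truth_network(2, [(0, 1, 1.0)])
        probs, _, second = ising_oracle(t.weights, t.fields)
        p_equal_exact = probs[(0.0, 0.0)] + probs[(1.0, 1.0)]
        X = sample_ising_gibbs(t, n=20000, burn_in=60, seed=9).to_numpy()
        p_equal_mc = np.mean(X[:, 0] == X[:, 1])
        assert p_equal_mc == pytest.approx(p_equal_exact, abs=0.02)
        # positive coupling -> positive phi correlation (oracle sign check)
        cov_exact = second[0, 1] - probs[(1.0, 0.0)] * 0  # E[xy]
        assert np.corrcoef(X[:, 0], X[:, 1])[0, 1] > 0

    def test_pairwise_moments_match_enumeration(self, ising_oracle):
        """Sampled second moments converge to the exact enumeration values
        (p = 4, n = 20000, tolerance 0.03)."""
        t = make_truth_network(
            4, [(0, 1, 0.8), (1, 2, -0.6), (2, 3, 0.5)], fields=[-0.5, 0.2, 0.0, -0.3]
        )
        _, marg, second = ising_oracle(t.weights, t.fields)
        X = sample_ising_gibbs(t, n=20000, burn_in=80, seed=17).to_numpy()
        assert np.max(np.abs(X.mean(axis=0) - marg)) < 0.03
        assert np.max(np.abs((X.T @ X) / len(X) - second + np.diag(np.diag(second))
                             - np.diag(X.mean(axis=0)))) < 0.03

    def test_type_and_determinism(self):
        t = make_truth_network(2, [(0, 1, 0.5)], kinds=("binary", "continuous"))
        with pytest.raises(ConfigError):
            sample_ising_gibbs(t, 10)
        t2 = make_truth_network(2, [(0, 1, 0.5)])
        a = sample_ising_gibbs(t2, 100, seed=4)
        b = sample_ising_gibbs(t2, 100, seed=4)
        pd.testing.assert_frame_equal(a, b)


def test_mixed_sampler_shifts_continuous_child():
    """A planted binary->continuous coupling shifts the child's mean by the
    coupling (unit conditional SD)."""
    t = make_truth_network(
        3, [(0, 2, 1.0)], fields=[0.0, 0.0, 0.0],
        kinds=("binary", "binary", "continuous"),
    )
    X = sample_mixed(t, n=8000, seed=21)
    g1 = X.loc[X.V0 == 1, "V2"].mean()
    g0 = X.loc[X.V0 == 0, "V2"].mean()
    assert g1 - g0 == pytest.approx(1.0, abs=0.08)
    assert abs(X.loc[X.V1 == 1, "V2"].mean() - X.loc[X.V1 == 0, "V2"].mean()) < 0.08


class TestGenerateCohort:
    def test_null_outcome_effect(self):
        """With the count effect (and the separate depression->MCS channel)
        switched off, the index is uncorrelated with every outcome."""
        ds, _ = mm.generate_cohort(
            mm.CohortConfig(n=5000, seed=3, outcome_effect=0.0, depression_effect=0.0)
        )
        dv = mm.dichotomized_view(ds)
        score = mm.score_mmi(ds, mm.MMIDefinition(tuple(ds.shc_names)))
        for outcome in ("Care", "PCS", "MCS", "Satis", "QoL"):
            assert abs(np.corrcoef(score, dv.values[outcome])[0, 1]) < 0.05

    def test_positive_effect_recovered_by_logistic(self, small_cohort):
        """The generative count effect on the unmet-care flag is recovered
        with a positive, significant logistic coefficient."""
        dataset, truth = small_cohort
        score = mm.score_mmi(dataset, mm.MMIDefinition(tuple(dataset.shc_names)))
        fit = sm.Logit(dataset.values["Care"], sm.add_constant(score.rename("MMI"))).fit(disp=False)
        assert fit.params["MMI"] > 0
        assert fit.pvalues["MMI"] < 0.001

    def test_planted_isolation_and_determinism(self):
        config = mm.CohortConfig(n=200, seed=42)
        ds1, truth = mm.generate_cohort(config)
        t = truth["truth"]
        for item in truth["isolated_items"]:
            assert not np.any(t.weights[t.index(item)])
            assert item not in truth["linked_items"]
        ds2, _ = mm.generate_cohort(mm.CohortConfig(n=200, seed=42))
        pd.testing.assert_frame_equal(ds1.values, ds2.values)

    def test_config_errors(self):
        with pytest.raises(ConfigError):
            mm.CohortConfig(n=5)
        with pytest.raises(ConfigError):
            mm.CohortConfig(hub_item="Can")  # hub inside isolated set
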