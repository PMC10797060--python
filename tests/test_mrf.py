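"""EBIC selection and the three network estimators against closed-form and
planted-truth oracles."""

import numpy as np
import pandas as pd
import pytest

import mminet as mm
from mminet.mrf import (
    InputError,
    PenaltyPath,
    _symmetrize_nodewise,
    ebic_score,
    fit_ggm,
    fit_ising,
    fit_mgm,
    select_on_path,
)
from mminet.synthetic import make_truth_network, sample_gaussian, sample_ising_gibbs, sample_mixed


class TestEbic:
    def test_formula_arithmetic(self):
        assert ebic_score(-100, 3, 50, 10, 0.5) == pytest.approx(218.64, abs=0.005)
        assert ebic_score(-100, 3, 50, 10, 0.0) == pytest.approx(211.74, abs=0.005)
        assert ebic_score(-100, 0, 50, 10, 1.0) == pytest.approx(200.0)

    def test_argument_errors(self):
        with pytest.raises(ValueError):
            ebic_score(-1, 2, 10, 0, 0.5)  # k > 0 needs candidate predictors
        with pytest.raises(ValueError):
            ebic_score(-1, -1, 10, 5, 0.5)

    def test_selection_and_tie_break(self):
        single = [(0.5, -10.0, 1, "only")]
        assert select_on_path(single, n=100, p=5, gamma=0.5)[3] == "only"
        # equal EBIC at two penalties -> the sparser (larger penalty) wins
        tied = [(0.9, -10.0, 1, "sparse"), (0.1, -10.0, 1, "dense")]
        assert select_on_path(tied, n=100, p=5, gamma=0.5)[3] == "sparse"

    def test_gamma_raises_sparsity_on_fixed_path(self):
        """On a fixed candidate path the selected parameter count is
        non-increasing in gamma (the 2 gamma k ln p term grows with k)."""
        # log-likelihood improves with k at a decaying rate
        fits = [(1.0 / (k + 1), -50.0 + 3.5 * np.sqrt(k), k, k) for k in range(8)]
        chosen = [select_on_path(fits, n=100, p=10, gamma=g)[2]
                  for g in (0.0, 0.25, 0.5, 1.0)]
        assert all(a >= b for a, b in zip(chosen, chosen[1:]))

    def test_penalty_path_validation(self):
        with pytest.raises(InputError):
            PenaltyPath(lambdas=(0.5, 0.5))
        with pytest.raises(InputError):
            PenaltyPath(lambdas=(0.5, -0.1))
        with pytest.raises(InputError):
            PenaltyPath(min_ratio=1.5)
        lams = PenaltyPath(n_points=7, min_ratio=0.1).materialize(2.0)
        assert len(lams) == 7 and lams[0] == pytest.approx(2.0)
        assert np.all(np.diff(lams) < 0)


def _exact_corr_data(C: np.ndarray, n: int, seed: int = 0) -> np.ndarray:
    """Data whose *sample* correlation matrix equals C exactly."""
    rng = np.random.default_rng(seed)
    p = C.shape[0]
    Z = rng.standard_normal((n, p))
    Z -= Z.mean(axis=0)
    Q, _ = np.linalg.qr(Z)
    Z = Q[:, :p] * np.sqrt(n)  # exactly uncorrelated, unit variance
    return Z @ np.linalg.cholesky(C).T


class TestGGM:
    def test_unpenalized_limit_matches_closed_form(self):
        """At vanishing penalty the three-variable partial correlation
        equals (r_xy - r_xz r_zy) / sqrt((1-r_xz^2)(1-r_zy^2)) = 1/3 when
        all pairwise correlations are 0.5."""
        C = np.full((3, 3), 0.5)
        np.fill_diagonal(C, 1.0)
        X = _exact_corr_data(C, n=500)
        model = fit_ggm(X, gamma=0.5, path=PenaltyPath(lambdas=(1e-12,)),
                        threshold=False)
        iu = np.triu_indices(3, k=1)
        assert np.max(np.abs(model.weights[iu] - 1 / 3)) < 1e-6

    def test_independent_columns_give_empty_network(self, fast_path):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((5000, 6))
        assert fit_ggm(X, gamma=0.5, path=fast_path).n_edges() == 0

    def test_planted_edge_recovered(self, fast_path):
        truth = make_truth_network(5, [(0, 1, 0.5)])
        X = sample_gaussian(truth, n=5000, seed=8)
        model = fit_ggm(X, gamma=0.5, path=fast_path)
        assert model.weights[0, 1] > 0.3
        assert model.n_edges() <= 2  # at most one spurious edge at this size

    def test_weight_bounds_and_symmetry(self, small_dv, fast_path):
        data = small_dv.values[small_dv.shc_names].dropna()
        model = fit_ggm(data, path=fast_path)
        assert np.all(np.abs(model.weights) <= 1.0)
        assert np.allclose(model.weights, model.weights.T)
        assert np.all(np.diag(model.weights) == 0)

    def test_zero_variance_column_named(self, fast_path):
        X = pd.DataFrame({"A": [1.0, 2.0, 3.0, 4.0], "B": [1.0, 1.0, 1.0, 1.0]})
        with pytest.raises(InputError, match="B"):
            fit_ggm(X, path=fast_path)


class TestIsing:
    def test_independent_coins_no_edge(self, fast_path):
        rng = np.random.default_rng(2)
        X = (rng.random((5000, 2)) < 0.5).astype(float)
        assert fit_ising(X, path=fast_path).n_edges() == 0

    def test_two_node_coupling_recovered(self, fast_path):
        truth = make_truth_network(2, [(0, 1, 1.0)])
        X = sample_ising_gibbs(truth, n=5000, burn_in=60, seed=3)
        model = fit_ising(X, path=fast_path)
        assert model.weights[0, 1] == pytest.approx(1.0, abs=0.2)

    def test_and_rule_requires_both_directions(self):
        B = np.array([[0.0, 0.5], [0.0, 0.0]])  # selected in one direction only
        assert _symmetrize_nodewise(B, "AND")[0, 1] == 0.0
        assert _symmetrize_nodewise(B, "OR")[0, 1] == pytest.approx(0.25)

    def test_input_validation(self, fast_path):
        with pytest.raises(InputError, match="not binary"):
            fit_ising(np.array([[0.0, 2.0], [1.0, 0.0], [0.0, 1.0]]), path=fast_path)
        with pytest.raises(InputError, match="constant"):
            fit_ising(np.array([[0.0, 1.0], [1.0, 1.0], [0.0, 1.0]]), path=fast_path)


@pytest.fixture(scope="module")
def six_node_gaussian():
    truth = make_truth_network(6, [(0, 1, 0.5), (2, 3, 0.45), (3, 4, 0.4)])
    return sample_gaussian(truth, n=4000, seed=5), truth


class TestMGM:
    def test_all_continuous_matches_ggm_pattern(self, six_node_gaussian, fast_path):
        X, truth = six_node_gaussian
        mgm = fit_mgm(X, kinds=["continuous"] * 6, gamma=0.25, path=fast_path)
        ggm = fit_ggm(X, gamma=0.25, path=fast_path)
        assert np.array_equal(mgm.weights != 0, ggm.weights != 0)
        assert np.array_equal(mgm.weights != 0, truth.weights != 0)

    def test_all_binary_matches_ising_pattern(self, fast_path):
        truth = make_truth_network(6, [(0, 1, 1.2), (2, 3, 1.0), (3, 4, 0.9)])
        X = sample_ising_gibbs(truth, n=4000, burn_in=60, seed=6)
        mgm = fit_mgm(X, kinds=["binary"] * 6, gamma=0.25, path=fast_path)
        ising = fit_ising(X, gamma=0.25, path=fast_path)
        assert np.array_equal(mgm.weights != 0, ising.weights != 0)

    def test_binary_continuous_edge_recovered(self, fast_path):
        """A binary node shifting a continuous node by one SD appears as a
        positive mixed edge."""
        truth = make_truth_network(
            4, [(0, 2, 1.0), (1, 3, 0.0)], fields=np.zeros(4),
            kinds=("binary", "binary", "continuous", "continuous"),
        )
        X = sample_mixed(truth, n=5000, seed=7)
        kinds = ["binary", "binary", "continuous", "continuous"]
        model = fit_mgm(X, kinds=kinds, gamma=0.25, path=fast_path)
        assert model.weights[0, 2] > 0
        assert model.weights[1, 3] == 0

    def test_unsupported_categorical(self, fast_path):
        X = pd.DataFrame({"A": [0.0, 1.0, 2.0, 1.0], "B": [0.1, 0.4, 0.2, 0.9]})
        with pytest.raises(InputError, match="unsupported"):
            fit_mgm(X, kinds=["categorical", "continuous"], path=fast_path)


def test_gamma_sparsity_monotone_on_data(small_dv, fast_path):
    """Higher EBIC gamma never adds edges, for both global and nodewise
    selection."""
    data = small_dv.values[small_dv.shc_names[:12]].dropna()
    ggm_counts = [fit_ggm(data, gamma=g, path=fast_path).n_edges() for g in (0.0, 0.5, 1.0)]
    assert ggm_counts[0] >= ggm_counts[1] >= ggm_counts[2]
    ising_counts = [fit_ising(data, gamma=g, path=fast_path).n_edges() for g in (0.0, 0.5, 1.0)]
    assert ising_counts[0] >= ising_counts[1] >= ising_counts[2]


def test_model_roundtrip(tmp_path, fast_path):
    rng = np.random.default_rng(0)
    X = (rng.random((600, 4)) < 0.4).astype(float)
    model = fit_ising(X, path=fast_path)
    out = tmp_path / "model.json"
    model.to_json(out)
    back = mm.NetworkModel.from_json(out)
    assert back.family == "ising"
    assert np.allclose(back.weights, model.weights)
    assert back.node_names == model.node_names
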