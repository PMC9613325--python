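"""Spearman/CLR arithmetic, PCLRC edge probabilities, connectivity and
differential-connectivity statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import milknet as mn


def _frame(values: np.ndarray) -> pd.DataFrame:
    return pd.DataFrame(values, columns=[f"P{j}" for j in range(values.shape[1])])


class TestSpearmanMatrix:
    def test_monotone_pairs(self):
        x = np.arange(6.0)
        data = _frame(np.column_stack([x, x**3, -x]))
        corr = mn.spearman_matrix(data)
        assert corr.iloc[0, 1] == pytest.approx(1.0)
        assert corr.iloc[0, 2] == pytest.approx(-1.0)
        np.testing.assert_allclose(np.diag(corr), 1.0)

    def test_rank_invariance_under_exp(self, rng):
        data = _frame(rng.normal(size=(20, 6)))
        np.testing.assert_allclose(
            mn.spearman_matrix(data).to_numpy(),
            mn.spearman_matrix(np.exp(data)).to_numpy(),
            atol=1e-12,
        )

    def test_ties_match_rank_then_pearson_oracle(self):
        values = np.array(
            [[1.0, 2.0], [2.0, 2.0], [2.0, 5.0], [4.0, 1.0], [5.0, 4.0]]
        )
        corr = mn.spearman_matrix(_frame(values))
        ranks = np.column_stack(
            [stats.rankdata(values[:, 0]), stats.rankdata(values[:, 1])]
        )
        oracle = np.corrcoef(ranks, rowvar=False)[0, 1]
        assert corr.iloc[0, 1] == pytest.approx(oracle, abs=1e-12)

    def test_constant_protein_warns_and_zeroes(self):
        values = np.column_stack([np.arange(5.0), np.full(5, 3.0)])
        with pytest.warns(UserWarning, match="constant"):
            corr = mn.spearman_matrix(_frame(values))
        assert corr.iloc[0, 1] == 0.0
        assert corr.iloc[1, 1] == 1.0


class TestClrTransform:
    def test_uniform_similarities_give_zero(self):
        m = np.full((5, 5), 0.4)
        np.fill_diagonal(m, 1.0)
        np.testing.assert_array_equal(mn.clr_transform(m), np.zeros((5, 5)))

    def test_four_by_four_hand_computation(self):
        m = np.array(
            [
                [1.0, 0.8, 0.1, 0.3],
                [0.8, 1.0, 0.2, 0.4],
                [0.1, 0.2, 1.0, 0.6],
                [0.3, 0.4, 0.6, 1.0],
            ]
        )
        clr = mn.clr_transform(m)
        # independent arithmetic: per-row off-diagonal mean/population sd
        a = np.abs(m).astype(float)
        expected = np.zeros((4, 4))
        for i in range(4):
            for j in range(4):
                if i == j:
                    continue
                zs = []
                for row in (i, j):
                    other = j if row == i else i
                    off = [a[row, c] for c in range(4) if c != row]
                    mu, sd = np.mean(off), np.std(off)
                    zs.append(max(0.0, (a[row, other] - mu) / sd))
                expected[i, j] = np.sqrt(zs[0] ** 2 + zs[1] ** 2)
        np.testing.assert_allclose(clr, expected, atol=1e-12)

    def test_symmetry_nonnegativity_zero_diagonal(self, rng):
        for _ in range(20):
            raw = rng.uniform(-1, 1, size=(8, 8))
            m = (raw + raw.T) / 2
            np.fill_diagonal(m, 1.0)
            clr = mn.clr_transform(m)
            np.testing.assert_allclose(clr, clr.T, atol=1e-12)
            assert (clr >= 0).all()
            np.testing.assert_array_equal(np.diag(clr), 0.0)

    def test_asymmetric_input_rejected(self):
        m = np.array([[1.0, 0.5], [0.2, 1.0]])
        with pytest.raises(ValueError, match="symmetric"):
            mn.clr_transform(m)


def _planted_pair_data(n=75, n_proteins=30, rho=0.95, seed=0) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n, n_proteins))
    x[:, 1] = rho * x[:, 0] + np.sqrt(1 - rho**2) * rng.standard_normal(n)
    return _frame(x)


class TestEdgeProbabilities:
    def test_defaults_match_published_protocol(self):
        import inspect

        sig = inspect.signature(mn.estimate_edge_probabilities)
        assert sig.parameters["n_iterations"].default == 1000
        assert sig.parameters["subsample_fraction"].default == 0.75
        assert sig.parameters["keep_fraction"].default == 0.30

    def test_planted_pair_reaches_near_certain_probability(self):
        data = _planted_pair_data(seed=5)
        probs = mn.estimate_edge_probabilities(
            data, n_iterations=200, seed=1
        ).probabilities
        assert probs.iloc[0, 1] >= 0.99
        iu = np.triu_indices(30, k=1)
        independent = np.delete(probs.to_numpy()[iu], 0)  # drop the (0,1) pair
        assert np.median(independent) < 0.30

    def test_mean_probability_equals_keep_fraction(self, rng):
        """Each iteration retains exactly keep_fraction of the upper triangle,
        so the mean retention probability is keep_fraction exactly."""
        data = _frame(rng.normal(size=(20, 25)))  # 300 edges; 0.3 * 300 = 90
        probs = mn.estimate_edge_probabilities(
            data, n_iterations=50, keep_fraction=0.30, seed=2
        ).probabilities
        iu = np.triu_indices(25, k=1)
        assert np.mean(probs.to_numpy()[iu]) == pytest.approx(0.30, abs=1e-9)

    def test_same_seed_reproduces_probabilities_exactly(self, rng):
        data = _frame(rng.normal(size=(16, 10)))
        p1 = mn.estimate_edge_probabilities(data, n_iterations=25, seed=9)
        p2 = mn.estimate_edge_probabilities(data, n_iterations=25, seed=9)
        pd.testing.assert_frame_equal(p1.probabilities, p2.probabilities)

    def test_invalid_fractions_rejected(self, rng):
        data = _frame(rng.normal(size=(16, 6)))
        with pytest.raises(ValueError, match="keep_fraction"):
            mn.estimate_edge_probabilities(data, keep_fraction=0.0)
        with pytest.raises(ValueError, match="subsample"):
            mn.estimate_edge_probabilities(data, subsample_fraction=1.5)


class TestBuildNetwork:
    def test_threshold_rule(self):
        sim = pd.DataFrame(
            [[1.0, 0.7, -0.5], [0.7, 1.0, 0.2], [-0.5, 0.2, 1.0]],
            index=list("abc"), columns=list("abc"),
        )
        probs = pd.DataFrame(
            [[1.0, 0.995, 0.98], [0.995, 1.0, 0.999], [0.98, 0.999, 1.0]],
            index=list("abc"), columns=list("abc"),
        )
        net = mn.build_network(sim, probs, tau=0.99)
        assert net.weights.loc["a", "b"] == 0.7   # p=0.995 retained
        assert net.weights.loc["a", "c"] == 0.0   # p=0.98 dropped
        assert net.weights.loc["b", "c"] == 0.2
        np.testing.assert_array_equal(np.diag(net.weights), 1.0)

    def test_tau_zero_returns_full_similarity(self, rng):
        data = _frame(rng.normal(size=(20, 8)))
        sim = mn.spearman_matrix(data)
        probs = mn.estimate_edge_probabilities(data, n_iterations=20, seed=0)
        net = mn.build_network(sim, probs, tau=0.0)
        np.testing.assert_allclose(net.weights.to_numpy(), sim.to_numpy())

    def test_nonzero_weights_equal_full_data_spearman(self):
        data = _planted_pair_data(n=40, n_proteins=12, seed=3)
        sim = mn.spearman_matrix(data)
        net = mn.infer_group_network(data, n_iterations=100, seed=4)
        w = net.weights.to_numpy()
        s = sim.to_numpy()
        nonzero = (w != 0) & ~np.eye(12, dtype=bool)
        np.testing.assert_array_equal(w[nonzero], s[nonzero])

    def test_bad_tau_rejected(self):
        sim = pd.DataFrame(np.eye(2))
        with pytest.raises(ValueError, match="tau"):
            mn.build_network(sim, sim, tau=1.5)


class TestConnectivity:
    def test_binary_hub_counts_edges(self):
        adj = np.eye(13)
        adj[0, 1:7] = adj[1:7, 0] = 1.0
        chi = mn.connectivity(pd.DataFrame(adj))
        assert chi.iloc[0] == 6.0
        assert chi.iloc[1] == 1.0

    def test_identity_network_is_isolated(self):
        chi = mn.connectivity(pd.DataFrame(np.eye(5)))
        np.testing.assert_array_equal(chi.to_numpy(), 0.0)

    def test_weighted_row(self):
        w = np.array(
            [
                [1.0, 0.5, -0.3, 0.0],
                [0.5, 1.0, 0.0, 0.0],
                [-0.3, 0.0, 1.0, 0.0],
                [0.0, 0.0, 0.0, 1.0],
            ]
        )
        chi = mn.connectivity(pd.DataFrame(w))
        assert chi.iloc[0] == pytest.approx(0.8)

    def test_matches_networkx_degree_on_random_graphs(self, rng):
        nx = pytest.importorskip("networkx")
        for i in range(100):
            g = nx.gnp_random_graph(20, 0.25, seed=int(rng.integers(1 << 30)))
            adj = nx.to_numpy_array(g) + np.eye(20)
            chi = mn.connectivity(pd.DataFrame(adj))
            degrees = np.array([d for _, d in sorted(g.degree())], dtype=float)
            np.testing.assert_array_equal(chi.to_numpy(), degrees)

    def test_diagonal_convention_enforced(self):
        with pytest.raises(ValueError, match="diagonal"):
            mn.connectivity(pd.DataFrame(np.zeros((3, 3))))


class TestDifferentialConnectivity:
    def test_worked_example_difference(self):
        chi_a = pd.Series([6.0, 1.0], index=["Pi", "Pj"])
        chi_b = pd.Series([4.0, 1.0], index=["Pi", "Pj"])
        delta = mn.differential_connectivity(chi_a, chi_b)
        assert delta["Pi"] == 2.0
        assert delta["Pj"] == 0.0

    def test_antisymmetry(self, rng):
        idx = [f"P{j}" for j in range(10)]
        chi_a = pd.Series(rng.uniform(0, 5, 10), index=idx)
        chi_b = pd.Series(rng.uniform(0, 5, 10), index=idx)
        forward = mn.differential_connectivity(chi_a, chi_b)
        np.testing.assert_allclose(
            forward, -mn.differential_connectivity(chi_b, chi_a)
        )

    def test_mismatched_proteins_rejected(self):
        with pytest.raises(ValueError, match="different protein sets"):
            mn.differential_connectivity(
                pd.Series([1.0], index=["a"]), pd.Series([1.0], index=["b"])
            )


class TestDcPermutations:
    def test_p_value_floor_and_table_contract(self, rng):
        a = _frame(rng.normal(size=(20, 8)))
        b = _frame(rng.normal(size=(20, 8)))
        b.index = [f"b{i}" for i in range(20)]
        out = mn.dc_permutation_pvalues(
            a, b, n_permutations=19, n_iterations=20, seed=0
        )
        floor = 1.0 / 20.0
        assert (out.table["p_value"] >= floor - 1e-12).all()
        assert (out.table["p_adjusted"] >= out.table["p_value"] - 1e-12).all()

    def test_too_few_permutations_rejected(self, rng):
        a = _frame(rng.normal(size=(10, 4)))
        b = _frame(rng.normal(size=(10, 4)))
        b.index = [f"b{i}" for i in range(10)]
        with pytest.raises(ValueError, match="19"):
            mn.dc_permutation_pvalues(a, b, n_permutations=5)

    def test_shared_samples_rejected(self, rng):
        a = _frame(rng.normal(size=(10, 4)))
        with pytest.raises(ValueError, match="disjoint"):
            mn.dc_permutation_pvalues(a, a, n_permutations=19)


class TestSelectCandidates:
    def test_strict_threshold(self):
        delta = pd.Series([51.0, 49.0, -60.0], index=["a", "b", "c"])
        sets, shared = mn.select_candidates({"cmp": delta}, delta_threshold=50)
        assert sets["cmp"] == ["a", "c"]
        assert shared == ["a", "c"]

    def test_zero_threshold_selects_all_nonzero(self):
        delta = pd.Series([0.1, 0.0, -0.2], index=["a", "b", "c"])
        sets, _ = mn.select_candidates({"cmp": delta}, delta_threshold=0.0)
        assert sets["cmp"] == ["a", "c"]

    def test_intersection_matches_set_oracle(self, rng):
        idx = [f"P{j}" for j in range(30)]
        deltas = {
            name: pd.Series(rng.uniform(-100, 100, 30), index=idx)
            for name in ("one", "two", "three")
        }
        sets, shared = mn.select_candidates(deltas, delta_threshold=30)
        oracle = (
            set(sets["one"]) & set(sets["two"]) & set(sets["three"])
        )
        assert set(shared) == oracle
        for name, delta in deltas.items():
            assert set(sets[name]) == {
                p for p in idx if abs(delta[p]) > 30
            }

    def test_signed_mode(self):
        delta = pd.Series([51.0, -60.0], index=["a", "b"])
        sets, _ = mn.select_candidates({"cmp": delta}, 50, signed=True)
        assert sets["cmp"] == ["a"]


def test_connectivity_dominance_between_groups():
    """A group generated with planted correlations shows stochastically higher
    connectivity than a structure-free group (the connectivity-scatter pattern
    where the all-negative group sits lower)."""
    cfg = mn.SyntheticConfig(
        n_per_group=40, n_proteins=30,
        block_spec=(
            mn.BlockSpec(0, 6, 0.9, ("M+C+",)),
            mn.BlockSpec(6, 6, 0.85, ("M+C+",)),
            mn.BlockSpec(12, 6, 0.9, ("M+C+",)),
        ),
        seed=29,
    )
    _, design, _, truth = mn.generate_lfq_dataset(cfg)
    chis = {}
    for group, seed in (("M+C+", 1), ("M-C-", 2)):
        block = truth.true_log10.loc[design.samples_in(group)]
        net = mn.infer_group_network(block, n_iterations=200, seed=seed)
        chis[group] = mn.connectivity(net)
    assert chis["M+C+"].sum() > chis["M-C-"].sum()
    test = stats.wilcoxon(
        chis["M+C+"].to_numpy(), chis["M-C-"].to_numpy(), alternative="greater"
    )
    assert test.pvalue < 0.01


def test_graphml_export_round_trip(tmp_path, rng):
    nx = pytest.importorskip("networkx")
    data = _planted_pair_data(n=40, n_proteins=10, seed=8)
    net = mn.infer_group_network(data, n_iterations=100, seed=0)
    path = tmp_path / "net.graphml"
    mn.pclrc.to_graphml(net, path)
    g = nx.read_graphml(path)
    assert g.number_of_nodes() == 10
    assert g.number_of_edges() == len(net.edge_list())
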