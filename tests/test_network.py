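import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dualtraj.network import (
    ModuleAssignment,
    NetworkConfig,
    detect_modules,
    hub_metabolite,
    module_group_lme,
    module_scores,
    soft_adjacency,
    spearman_matrix,
    topological_overlap,
)

from conftest import minimal_design


def tom_oracle(A):
    """Triple-loop literal definition of topological overlap."""
    n = len(A)
    k = A.sum(axis=1)
    out = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(A[i, u] * A[u, j] for u in range(n) if u not in (i, j))
            out[i, j] = (shared + A[i, j]) / (min(k[i], k[j]) + 1 - A[i, j])
    return out


def planted_blocks(rng, sizes=(20, 15, 10), n=60, load=0.8):
    cols, truth = {}, []
    for b, s in enumerate(sizes, start=1):
        f = rng.normal(0, 1, n)
        for j in range(s):
            cols[f"b{b}m{j:02d}"] = np.sqrt(load) * f + np.sqrt(1 - load) * rng.normal(0, 1, n)
            truth.append(b)
    return pd.DataFrame(cols), np.asarray(truth)


class TestSpearman:
    def test_monotone_transforms(self):
        x = np.linspace(1, 5, 20)
        df = pd.DataFrame({"x": x, "up": 2 * x, "down": -(x**3)})
        rho = spearman_matrix(df)
        assert rho.loc["x", "up"] == pytest.approx(1.0)
        assert rho.loc["x", "down"] == pytest.approx(-1.0)

    def test_matches_rank_then_pearson_oracle(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(rng.normal(0, 1, (5, 4)), columns=list("abcd"))
        rho = spearman_matrix(df)
        ranks = np.column_stack([stats.rankdata(df[c]) for c in df])
        oracle = np.corrcoef(ranks.T)
        np.testing.assert_allclose(rho.to_numpy(), oracle, atol=1e-12)

    def test_constant_metabolite_rejected(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "flat": [5.0, 5.0, 5.0]})
        with pytest.raises(ValueError, match="flat"):
            spearman_matrix(df)


class TestAdjacency:
    @pytest.mark.parametrize("rho,beta,expected",
                             [(1.0, 6, 1.0), (-1.0, 6, 0.0), (0.0, 6, 0.015625),
                              (1.0, 3, 1.0)])
    def test_signed_values(self, rho, beta, expected):
        cor = pd.DataFrame([[1.0, rho], [rho, 1.0]], index=["a", "b"], columns=["a", "b"])
        a = soft_adjacency(cor, beta=beta, signed=True)
        assert a.loc["a", "b"] == pytest.approx(expected)
        assert a.loc["a", "a"] == 0.0  # diagonal zeroed for connectivity

    def test_unsigned(self):
        cor = pd.DataFrame([[1.0, -0.5], [-0.5, 1.0]], index=list("ab"), columns=list("ab"))
        a = soft_adjacency(cor, beta=2, signed=False)
        assert a.loc["a", "b"] == pytest.approx(0.25)


class TestTOM:
    def test_two_nodes_fully_connected(self):
        A = pd.DataFrame([[0.0, 1.0], [1.0, 0.0]], index=list("ab"), columns=list("ab"))
        tom = topological_overlap(A)
        assert tom.loc["a", "b"] == pytest.approx(1.0)

    def test_empty_network(self):
        A = pd.DataFrame(np.zeros((4, 4)), index=list("abcd"), columns=list("abcd"))
        tom = topological_overlap(A)
        off = tom.to_numpy()[~np.eye(4, dtype=bool)]
        assert (off == 0).all()

    def test_matches_triple_loop_oracle_on_random_instances(self):
        rng = np.random.default_rng(10)
        for n in range(2, 13):
            M = rng.uniform(0, 1, (n, n))
            A = (M + M.T) / 2
            np.fill_diagonal(A, 0.0)
            names = [f"m{i}" for i in range(n)]
            tom = topological_overlap(pd.DataFrame(A, index=names, columns=names))
            np.testing.assert_allclose(tom.to_numpy(), tom_oracle(A), atol=1e-12)
            assert (tom.to_numpy() <= 1 + 1e-12).all() and (tom.to_numpy() >= 0).all()
            np.testing.assert_allclose(tom.to_numpy(), tom.to_numpy().T)


class TestDetectModules:
    def test_identity_correlation_leaves_everything_unassigned(self):
        n = 20
        names = [f"m{i}" for i in range(n)]
        cor = pd.DataFrame(np.eye(n), index=names, columns=names)
        tom = topological_overlap(soft_adjacency(cor))
        asg = detect_modules(tom)
        assert (asg.modules == 0).all()

    def test_single_perfect_block(self):
        n = 8
        names = [f"m{i}" for i in range(n)]
        cor = pd.DataFrame(np.ones((n, n)), index=names, columns=names)
        tom = topological_overlap(soft_adjacency(cor))
        asg = detect_modules(tom)
        assert (asg.modules == 1).all()

    def test_planted_three_blocks_recovered(self):
        from sklearn.metrics import adjusted_rand_score

        rng = np.random.default_rng(0)
        X, truth = planted_blocks(rng)
        tom = topological_overlap(soft_adjacency(spearman_matrix(X)))
        asg = detect_modules(tom)
        assert adjusted_rand_score(truth, asg.modules.to_numpy()) >= 0.9
        # renumbered by decreasing size
        sizes = asg.modules[asg.modules > 0].value_counts()
        assert list(sizes.index) == sorted(sizes.index)

    def test_labels_invariant_to_input_order(self):
        rng = np.random.default_rng(2)
        X, _ = planted_blocks(rng, sizes=(10, 8), n=50)
        perm = rng.permutation(X.columns)
        a1 = detect_modules(topological_overlap(soft_adjacency(spearman_matrix(X))))
        a2 = detect_modules(topological_overlap(soft_adjacency(spearman_matrix(X[perm]))))
        m1 = a1.modules.sort_index()
        m2 = a2.modules.sort_index()
        pd.testing.assert_series_equal(m1, m2)

    def test_bad_config_rejected(self):
        with pytest.raises(ValueError):
            NetworkConfig(beta=0)
        with pytest.raises(ValueError):
            NetworkConfig(cut_height=1.5)


class TestHub:
    def test_star_center_is_hub(self):
        names = ["center", "s1", "s2", "s3"]
        A = np.full((4, 4), 0.1)
        A[0, :] = A[:, 0] = 0.9
        np.fill_diagonal(A, 0.0)
        adj = pd.DataFrame(A, index=names, columns=names)
        asg = ModuleAssignment(modules=pd.Series(1, index=names), hubs={})
        assert hub_metabolite(asg, adj)[1] == "center"

    def test_two_member_tie_breaks_lexicographically(self):
        names = ["zeta", "alpha"]
        adj = pd.DataFrame([[0.0, 0.5], [0.5, 0.0]], index=names, columns=names)
        asg = ModuleAssignment(modules=pd.Series(1, index=names), hubs={})
        assert hub_metabolite(asg, adj)[1] == "alpha"

    def test_matches_brute_force_rowsum(self):
        rng = np.random.default_rng(14)
        n = 9
        names = [f"m{i}" for i in rng.permutation(n)]
        M = rng.uniform(0, 1, (n, n))
        A = (M + M.T) / 2
        np.fill_diagonal(A, 0.0)
        adj = pd.DataFrame(A, index=names, columns=names)
        asg = ModuleAssignment(modules=pd.Series(1, index=names), hubs={})
        hub = hub_metabolite(asg, adj)[1]
        conn = {nm: sum(A[i, j] for j in range(n) if j != i)
                for i, nm in enumerate(names)}
        best = max(sorted(conn), key=lambda nm: conn[nm])
        assert hub == best


class TestModuleScores:
    def test_identical_columns_fully_explained(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, 40)
        panel = pd.DataFrame({"a": x, "b": x.copy()})
        asg = ModuleAssignment(modules=pd.Series(1, index=["a", "b"]), hubs={})
        scores, varex = module_scores(panel, asg)
        assert varex[1] == pytest.approx(1.0)
        xs = (x - x.mean()) / x.std()
        corr = np.corrcoef(scores[1], xs)[0, 1]
        assert corr == pytest.approx(1.0)

    def test_sign_oriented_to_module_mean(self):
        rng = np.random.default_rng(4)
        f = rng.normal(0, 1, 60)
        panel = pd.DataFrame(
            {f"m{j}": 0.9 * f + 0.3 * rng.normal(0, 1, 60) for j in range(4)}
        )
        asg = ModuleAssignment(modules=pd.Series(1, index=panel.columns), hubs={})
        scores, _ = module_scores(panel, asg)
        assert np.corrcoef(scores[1], panel.mean(axis=1))[0, 1] > 0

    def test_matches_power_iteration_oracle(self):
        rng = np.random.default_rng(5)
        panel = pd.DataFrame(rng.normal(0, 1, (30, 5)),
                             columns=[f"m{j}" for j in range(5)])
        asg = ModuleAssignment(modules=pd.Series(1, index=panel.columns), hubs={})
        scores, _ = module_scores(panel, asg)
        Xs = (panel - panel.mean()) / panel.std(ddof=0)
        C = Xs.T @ Xs
        v = np.ones(5)
        for _ in range(5000):
            v = C @ v
            v /= np.linalg.norm(v)
        oracle = Xs.to_numpy() @ v
        got = scores[1].to_numpy()
        if np.dot(oracle, got) < 0:
            oracle = -oracle
        np.testing.assert_allclose(got, oracle, atol=1e-8)

    def test_constant_scores_rejected_in_group_model(self):
        rng = np.random.default_rng(6)
        _, design, _ = minimal_design(rng, n_subjects=20)
        scores = pd.DataFrame({1: np.zeros(len(design.groups))})
        with pytest.raises(ValueError, match="constant"):
            module_group_lme(scores, design)

    def test_module_score_contrast_detects_planted_module_effect(self):
        """A module-wide planted slope is detected on the eigen-metabolite."""
        rng = np.random.default_rng(15)
        _, design, _ = minimal_design(rng, n_subjects=150)
        sid = design.groups.astype(int)
        inter = design.exog["group[dual_decline]:time"].to_numpy()
        f = rng.normal(0, 1, 150)[sid] + 0.5 * inter
        panel = pd.DataFrame(
            {f"m{j}": f + 0.4 * rng.normal(0, 1, len(sid)) for j in range(6)}
        )
        asg = ModuleAssignment(modules=pd.Series(1, index=panel.columns), hubs={})
        scores, _ = module_scores(panel, asg)
        out = module_group_lme(scores, design)
        assert out.loc[0, "p_dual_decline"] < 0.05
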