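"""Trees, phylogenetic covariances, GLS/REML, signal, runs test, selection."""

import itertools

import dendropy
import numpy as np
import pytest

from wingbone import scaling, synthetic
from wingbone.scaling import (
    RegressionFit,
    aicc,
    fit_gls,
    patristic_distances,
    phylo_signal_K,
    prune_tree,
    read_tree,
    resolve_polytomies,
    runs_test,
    select_model,
    tip_depths,
    vcv_brownian,
    vcv_ou,
)

NWK = "(((A:1,B:1):1,C:2):1,D:3);"


class TestTreeOps:
    def test_prune_preserves_path_lengths(self):
        tree = read_tree(NWK)
        pruned = prune_tree(tree, ["A", "C"])
        assert sorted(lf.taxon.label for lf in pruned.leaf_node_iter()) == ["A", "C"]
        labels, d = patristic_distances(pruned, ["A", "C"])
        assert d[0, 1] == pytest.approx(4.0)
        depths = tip_depths(pruned)
        assert depths["A"] == pytest.approx(3.0)

    def test_prune_to_all_tips_is_identity(self):
        tree = read_tree(NWK)
        pruned = prune_tree(tree, ["A", "B", "C", "D"])
        _, d0 = patristic_distances(tree, ["A", "B", "C", "D"])
        _, d1 = patristic_distances(pruned, ["A", "B", "C", "D"])
        np.testing.assert_allclose(d0, d1)

    def test_unknown_species_named_in_error(self):
        with pytest.raises(KeyError, match="E"):
            prune_tree(read_tree(NWK), ["A", "E"])

    def test_binary_tree_unchanged_by_resolution(self):
        tree = read_tree(NWK)
        out = resolve_polytomies(tree)
        _, d0 = patristic_distances(tree, ["A", "B", "C", "D"])
        _, d1 = patristic_distances(out, ["A", "B", "C", "D"])
        np.testing.assert_allclose(d0, d1)

    def test_trifurcation_resolved_with_zero_branch(self):
        tree = read_tree("((A:1,B:1,C:1):1,D:2);")
        out = resolve_polytomies(tree)
        degrees = [len(n.child_nodes()) for n in out.preorder_internal_node_iter()]
        assert all(deg == 2 for deg in degrees)
        labels = ["A", "B", "C", "D"]
        _, d0 = patristic_distances(tree, labels)
        _, d1 = patristic_distances(out, labels)
        np.testing.assert_allclose(d0, d1)

    def test_star_tree_gains_three_zero_branches(self):
        tree = read_tree("(A:1,B:1,C:1,D:1,E:1);")
        out = resolve_polytomies(tree)
        zero_internal = [
            e for e in out.preorder_edge_iter()
            if e.length == 0.0 and e.head_node.child_nodes()
        ]
        assert len(zero_internal) == 3  # tips - 2 new internal nodes
        _, d1 = patristic_distances(out, ["A", "B", "C", "D", "E"])
        off = d1[~np.eye(5, dtype=bool)]
        np.testing.assert_allclose(off, 2.0)


class TestCovariances:
    def test_two_tip_brownian(self):
        _, v = vcv_brownian(read_tree("(A:3,B:3);"), order=["A", "B"])
        np.testing.assert_allclose(v, [[3, 0], [0, 3]])

    def test_three_tip_brownian_shared_paths(self):
        _, v = vcv_brownian(read_tree("((A:1,B:1):1,C:2);"), order=["A", "B", "C"])
        assert v[0, 1] == pytest.approx(1.0)
        assert v[0, 0] == pytest.approx(2.0)
        assert v[0, 2] == pytest.approx(0.0)

    def test_negative_branch_rejected(self):
        with pytest.raises(ValueError):
            vcv_brownian(read_tree("(A:-1,B:1);"))

    def test_ou_two_tips(self):
        _, c = vcv_ou(read_tree("(A:1,B:1);"), alpha=0.5, order=["A", "B"])
        assert c[0, 1] == pytest.approx(np.exp(-1.0))
        assert c[0, 0] == 1.0

    def test_ou_alpha_zero_degenerates_to_all_ones(self):
        _, c = vcv_ou(read_tree("(A:1,B:1);"), alpha=0.0, order=["A", "B"])
        np.testing.assert_allclose(c, 1.0)

    def test_large_alpha_approaches_identity(self):
        tree = synthetic.simulate_pure_birth_tree(10, seed=5)
        labels = [f"s{i}" for i in range(1, 11)]
        _, c = vcv_ou(tree, 1e4, order=labels)
        np.testing.assert_allclose(c, np.eye(10), atol=1e-8)


class TestGLS:
    def test_identity_structure_reproduces_ols_exactly(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 5, 20)
        y = 1.5 * x - 2 + rng.normal(0, 0.3, 20)
        f = fit_gls(x, y)
        slope, intercept = np.polyfit(x, y, 1)
        assert f.slope == pytest.approx(slope, rel=1e-12)
        assert f.intercept == pytest.approx(intercept, rel=1e-12)

    def test_ols_ci_against_closed_form(self):
        from scipy.stats import t as t_dist
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 5, 15)
        y = 0.8 * x + rng.normal(0, 0.2, 15)
        f = fit_gls(x, y)
        resid = y - (f.intercept + f.slope * x)
        s2 = resid @ resid / 13
        se = np.sqrt(s2 / np.sum((x - x.mean()) ** 2))
        tcrit = t_dist.ppf(0.975, 13)
        assert f.slope_ci[0] == pytest.approx(f.slope - tcrit * se, rel=1e-9)

    def test_star_phylogeny_bm_equals_ols(self):
        tree = read_tree("(A:2,B:2,C:2,D:2,E:2,F:2);")
        labels = ["A", "B", "C", "D", "E", "F"]
        _, v = vcv_brownian(tree, order=labels)
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 3, 6)
        y = 0.7 * x + rng.normal(0, 0.1, 6)
        f_ols = fit_gls(x, y)
        f_bm = fit_gls(x, y, v)
        assert f_bm.slope == pytest.approx(f_ols.slope, abs=1e-13)
        assert f_bm.intercept == pytest.approx(f_ols.intercept, abs=1e-13)
        assert f_bm.slope_ci == pytest.approx(f_ols.slope_ci, abs=1e-12)

    def test_two_predictor_points_match_symbolic_gls(self):
        # hand-solvable 3-point GLS with explicit inverse
        x = np.array([0.0, 1.0, 2.0])
        y = np.array([0.1, 1.2, 1.9])
        v = np.array([[1.0, 0.5, 0.0], [0.5, 1.0, 0.0], [0.0, 0.0, 1.0]])
        f = fit_gls(x, y, v)
        X = np.column_stack([np.ones(3), x])
        vinv = np.linalg.inv(v)
        beta = np.linalg.solve(X.T @ vinv @ X, X.T @ vinv @ y)
        assert f.intercept == pytest.approx(beta[0], abs=1e-12)
        assert f.slope == pytest.approx(beta[1], abs=1e-12)

    @pytest.mark.parametrize("n", [3, 4, 5, 6])
    def test_matches_explicit_inversion_oracle(self, n):
        rng = np.random.default_rng(n)
        x = rng.uniform(0, 4, n)
        y = 0.75 * x - 2 + rng.normal(0, 0.2, n)
        a = rng.normal(size=(n, n))
        v = a @ a.T + n * np.eye(n)
        f = fit_gls(x, y, v)
        X = np.column_stack([np.ones(n), x])
        vinv = np.linalg.inv(v)
        beta = np.linalg.solve(X.T @ vinv @ X, X.T @ vinv @ y)
        assert f.intercept == pytest.approx(beta[0], abs=1e-10)
        assert f.slope == pytest.approx(beta[1], abs=1e-10)
        # REML log-likelihood against the standard dense formula
        resid = y - X @ beta
        rss = resid @ vinv @ resid
        s2 = rss / (n - 2)
        ll = -0.5 * ((n - 2) * np.log(2 * np.pi * s2) + (n - 2)
                     + np.linalg.slogdet(v)[1]
                     + np.linalg.slogdet(X.T @ vinv @ X)[1])
        assert f.loglik == pytest.approx(ll, abs=1e-10)

    def test_ou_converges_to_ols_at_large_alpha(self):
        tree, traits = synthetic.simulate_scaling_dataset(
            synthetic.SyntheticCladeSpec(n_tips=16, seed=3))
        labels = list(traits.species)
        _, d = patristic_distances(tree, labels)
        alpha = 20.0 / min(d[d > 0].min(), 1.0)
        _, c = vcv_ou(tree, alpha, order=labels)
        f_ols = fit_gls(traits.x.to_numpy(), traits.y.to_numpy())
        f_ou = fit_gls(traits.x.to_numpy(), traits.y.to_numpy(), c)
        assert abs(f_ou.slope - f_ols.slope) < 1e-6

    def test_singular_covariance_ridged(self):
        # duplicated tips joined by zero-length branches
        v = np.array([[2.0, 2.0, 1.0], [2.0, 2.0, 1.0], [1.0, 1.0, 2.0]])
        f = fit_gls(np.array([0.0, 1.0, 2.0]), np.array([0.0, 0.9, 2.1]), v)
        assert np.isfinite(f.slope)


class TestAICc:
    def test_direct_formula(self):
        assert aicc(-10.0, 3, 14) == pytest.approx(28.4)

    def test_approaches_aic_for_large_n(self):
        assert aicc(-10.0, 3, 10**7) == pytest.approx(26.0, abs=1e-5)

    def test_undefined_at_small_n(self):
        with pytest.raises(ValueError):
            aicc(-10.0, 3, 4)


class TestPhylogeneticSignal:
    def test_bm_traits_have_K_near_one(self, bm_tree_64):
        _, _, v, chol = bm_tree_64
        rng = np.random.default_rng(2)
        ks = []
        for _ in range(200):
            y = chol @ rng.standard_normal(64)
            res = phylo_signal_K(y, cov=v, n_permutations=99, seed=0)
            ks.append(res.k_statistic)
        assert 0.8 <= np.median(ks) <= 1.2

    def test_shuffled_traits_rarely_significant(self, bm_tree_64):
        _, _, v, _ = bm_tree_64
        rng = np.random.default_rng(3)
        not_sig = 0
        runs = 50
        for i in range(runs):
            y = rng.standard_normal(64)  # no phylogenetic structure
            res = phylo_signal_K(y, cov=v, n_permutations=199, seed=i)
            not_sig += res.p_value >= 0.05  # the selection gate's notion of n.s.
        assert not_sig >= 0.9 * runs

    def test_deterministic_under_seed(self, bm_tree_64):
        _, _, v, chol = bm_tree_64
        y = chol @ np.random.default_rng(4).standard_normal(64)
        a = phylo_signal_K(y, cov=v, n_permutations=199, seed=7)
        b = phylo_signal_K(y, cov=v, n_permutations=199, seed=7)
        assert a.p_value == b.p_value and a.k_statistic == b.k_statistic

    def test_constant_trait_rejected(self, bm_tree_64):
        _, _, v, _ = bm_tree_64
        with pytest.raises(ValueError):
            phylo_signal_K(np.ones(64), cov=v)


class TestRunsTest:
    @staticmethod
    def _enumerated_tails(n1, n2, r_obs):
        """Brute-force runs distribution over all arrangements."""
        lo = hi = total = 0
        for pos in itertools.combinations(range(n1 + n2), n1):
            seq = np.zeros(n1 + n2, bool)
            seq[list(pos)] = True
            r = 1 + int(np.sum(seq[1:] != seq[:-1]))
            total += 1
            lo += r <= r_obs
            hi += r >= r_obs
        return lo / total, hi / total

    @pytest.mark.parametrize("signs", [
        [True, False] * 4,                      # alternating: too many runs
        [True] * 4 + [False] * 4,               # two blocks: too few runs
        [True, True, False, True, False, False, True, False],
    ])
    def test_exact_p_matches_enumeration_oracle(self, signs):
        signs = np.array(signs)
        p, r = runs_test(signs)
        n1 = int(signs.sum())
        lo, hi = self._enumerated_tails(n1, len(signs) - n1, r)
        assert p == pytest.approx(min(1.0, 2 * min(lo, hi)), abs=1e-12)

    def test_well_specified_model_usually_random(self):
        ok = 0
        runs = 50
        for seed in range(runs):
            rng = np.random.default_rng(seed)
            x = rng.uniform(0, 5, 40)
            y = 2 * x + 1 + rng.normal(0, 0.5, 40)
            f = fit_gls(x, y)
            ok += bool(f.residual_random)
        assert ok >= 0.9 * runs

    def test_quadratic_misfit_flagged_nonrandom(self):
        x = np.linspace(-3, 3, 40)
        y = x**2
        f = fit_gls(x, y)
        assert f.residual_random is False

    def test_indeterminate_below_five(self):
        with pytest.raises(ValueError):
            runs_test(np.array([True, False, True]))


def _dummy_fit(model, aicc_value, random_resid):
    return RegressionFit(
        model=model, slope=1.0, intercept=0.0, slope_ci=(0.9, 1.1),
        intercept_ci=(-0.1, 0.1), loglik=0.0, method="REML", n=10, k=3,
        aicc=aicc_value, sigma2=1.0, residuals=np.zeros(10), fitted=np.zeros(10),
        residual_random=random_resid,
    )


class TestModelSelection:
    def test_no_signal_selects_ols_regardless_of_aicc(self):
        fits = {"OLS": _dummy_fit("OLS", 50.0, True),
                "PGLS-BM": _dummy_fit("PGLS-BM", 1.0, True)}
        sig = scaling.SignalTestResult(k_statistic=0.5, p_value=0.4,
                                       n_permutations=999, seed=0)
        chosen, trace = select_model(fits, sig)
        assert chosen.model == "OLS"

    def test_nonrandom_residuals_eliminate_candidates(self):
        fits = {"OLS": _dummy_fit("OLS", 5.0, True),
                "PGLS-BM": _dummy_fit("PGLS-BM", 1.0, False),
                "PGLS-OU(alpha=1.5)": _dummy_fit("PGLS-OU(alpha=1.5)", 18.6, True)}
        sig = scaling.SignalTestResult(k_statistic=1.2, p_value=0.01,
                                       n_permutations=999, seed=0)
        chosen, _ = select_model(fits, sig)
        assert chosen.model != "PGLS-BM"

    def test_lowest_aicc_among_survivors(self):
        fits = {"OLS": _dummy_fit("OLS", 12.0, True),
                "PGLS-BM": _dummy_fit("PGLS-BM", 10.0, True)}
        sig = scaling.SignalTestResult(k_statistic=1.0, p_value=0.01,
                                       n_permutations=999, seed=0)
        chosen, _ = select_model(fits, sig)
        assert chosen.model == "PGLS-BM"

    def test_all_eliminated_falls_back_to_ols(self):
        fits = {"OLS": _dummy_fit("OLS", 12.0, False),
                "PGLS-BM": _dummy_fit("PGLS-BM", 10.0, False)}
        sig = scaling.SignalTestResult(k_statistic=1.0, p_value=0.01,
                                       n_permutations=999, seed=0)
        chosen, trace = select_model(fits, sig)
        assert chosen.model == "OLS"
        assert any("eliminated" in line for line in trace)
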