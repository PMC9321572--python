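"""Birth-death likelihoods, model fitting, slicing, decline statistics."""

import math

import numpy as np
import pytest

from barcodediv import (
    RateModelSpec,
    TimeTree,
    aicc_compare,
    bd_loglik,
    compute_ltt,
    decline_statistic,
    fit_bd,
    fit_env,
    slice_tree,
)
from barcodediv.bdfit import _aicc, _E_Lambda
from barcodediv.synthdata import (
    SimulationConfig,
    simulate_env_curve,
    simulate_rate_tree,
    simulate_species_tree,
)

TREE4 = "((A:5,B:5):5,(C:3,D:3):7);"
TREE10 = (
    "(((a:2,b:2):6,(c:5,d:5):3):12,((e:4,f:4):9,((g:1,h:1):7,(i:3,j:3):5):5):7);"
)


def yule_loglik(tree: TimeTree, lam: float) -> float:
    """Independent closed-form Yule log-likelihood (crown-conditioned)."""
    return (tree.n_tips - 1) * math.log(lam) - lam * tree.total_branch_length()


class TestLTT:
    def test_two_tip_constant(self):
        ltt = compute_ltt(TimeTree.from_newick("(A:7,B:7);"))
        assert ltt["lineages"].tolist() == [2, 2]
        assert ltt["age"].tolist() == [7.0, 0.0]

    def test_balanced_four_tip_hand_enumeration(self):
        ltt = compute_ltt(TimeTree.from_newick("((A:5,B:5):5,(C:3,D:3):7);"))
        assert list(zip(ltt["age"], ltt["lineages"])) == [
            (10.0, 2),
            (5.0, 3),
            (3.0, 4),
            (0.0, 4),
        ]

    def test_final_count_is_tip_count(self):
        tree = simulate_species_tree(SimulationConfig(crown_age=100, speciation_rate=0.03, seed=2))
        ltt = compute_ltt(tree)
        assert ltt["lineages"].iloc[-1] == tree.n_tips
        assert ltt["lineages"].iloc[0] == 2


class TestLoglik:
    @pytest.mark.parametrize("newick", [TREE4, TREE10])
    @pytest.mark.parametrize("lam", [0.01, 0.07, 0.2])
    def test_matches_closed_form_yule(self, newick, lam):
        tree = TimeTree.from_newick(newick)
        model = RateModelSpec("constant", "none", {"lambda0": lam})
        assert bd_loglik(tree, model) == pytest.approx(
            yule_loglik(tree, lam), abs=1e-6
        )

    def test_ode_agrees_with_constant_closed_form(self):
        # exponential model with alpha=0 goes through the ODE integrator and
        # must reproduce the logistic closed form for constant rates
        tree = TimeTree.from_newick(TREE10)
        const = RateModelSpec(
            "constant", "constant", {"lambda0": 0.06, "mu": 0.02}, f=0.7
        )
        ode = RateModelSpec(
            "exponential", "constant", {"lambda0": 0.06, "alpha": 0.0, "mu": 0.02},
            f=0.7,
        )
        assert bd_loglik(tree, ode) == pytest.approx(bd_loglik(tree, const), abs=1e-6)

    def test_extinction_probability_stays_in_unit_interval(self):
        model = RateModelSpec(
            "exponential", "constant", {"lambda0": 0.05, "alpha": 0.01, "mu": 0.03},
            f=0.6,
        )
        ages = np.linspace(0, 400, 50)
        E, _, E_T = _E_Lambda(model, 400.0, ages)
        assert np.all(E >= -1e-9) and np.all(E <= 1 + 1e-9)
        assert 0 <= E_T < 1

    def test_complete_sampling_no_extinction_E_is_zero(self):
        model = RateModelSpec("constant", "none", {"lambda0": 0.05}, f=1.0)
        E, _, E_T = _E_Lambda(model, 300.0, np.linspace(0, 300, 20))
        assert np.allclose(E, 0.0, atol=1e-12) and E_T == 0.0

    def test_env_a_zero_equals_constant(self):
        tree = TimeTree.from_newick(TREE10)
        env = simulate_env_curve(
            "sinusoid", {"mean": 2, "amplitude": 4, "period": 60}, age_max=40
        )
        env_model = RateModelSpec(
            "environmental", "none", {"a": 0.0, "b": 0.08}, env=env
        )
        const = RateModelSpec("constant", "none", {"lambda0": 0.08})
        assert bd_loglik(tree, env_model) == pytest.approx(
            bd_loglik(tree, const), abs=1e-6
        )

    def test_env_reparameterisation_identity(self):
        # shifting/scaling the curve rescales (a, b) but not the likelihood
        tree = TimeTree.from_newick(TREE10)
        ages = np.linspace(0, 40, 60)
        vals = np.sin(ages / 7.0) + 2.0
        from barcodediv import EnvCurve

        c, d = 1.5, 0.25
        env1 = EnvCurve(ages, vals, df=20)
        env2 = EnvCurve(ages, (vals - c) / d, df=20)
        a, b = 0.8, 0.03
        m1 = RateModelSpec("environmental", "none", {"a": a, "b": b}, env=env1)
        m2 = RateModelSpec(
            "environmental", "none", {"a": a * d, "b": b * math.exp(a * c)}, env=env2
        )
        assert bd_loglik(tree, m1) == pytest.approx(bd_loglik(tree, m2), abs=1e-9)


class TestFitting:
    def test_yule_mle_matches_grid_search_oracle(self):
        tree = simulate_species_tree(
            SimulationConfig(crown_age=150, speciation_rate=0.03, seed=13)
        )
        fit = fit_bd(tree, models=("constant",), n_starts=4)[0]
        grid = np.geomspace(1e-4, 1.0, 200_001)
        lls = (tree.n_tips - 1) * np.log(grid) - grid * tree.total_branch_length()
        lam_grid = grid[np.argmax(lls)]
        assert fit.params["lambda0"] == pytest.approx(lam_grid, abs=1e-4)

    def test_exponential_nested_dominance(self):
        tree = simulate_species_tree(
            SimulationConfig(crown_age=150, speciation_rate=0.03, seed=17)
        )
        fits = fit_bd(tree, models=("constant", "exponential"), n_starts=4)
        ll = {f.model_id: f.loglik for f in fits}
        assert ll["exponential.mu0"] >= ll["constant.mu0"] - 1e-6

    def test_declining_rate_recovery_and_fixed_mu_robustness(self):
        # trees grown with lambda(t) = 0.03 exp(0.01 t): rates higher in the
        # past, so alpha_hat should be positive, and stay positive when
        # extinction is pinned at an arbitrary high value
        alphas, alphas_mu = [], []
        for i in range(8):
            tree = simulate_rate_tree(
                lambda age: 0.03 * np.exp(0.01 * age), 100.0, seed=300 + i
            )
            free = fit_bd(tree, models=("exponential",), n_starts=4)[0]
            alphas.append(free.params["alpha"])
            pinned = fit_bd(
                tree, models=("exponential",), fixed_mu=0.05, n_starts=2
            )[0]
            alphas_mu.append(pinned.params["alpha"])
        assert np.median(alphas) > 0
        same_sign = sum(np.sign(a) == np.sign(b) for a, b in zip(alphas, alphas_mu))
        assert same_sign > len(alphas) / 2

    def test_env_constant_curve_rejected(self):
        tree = TimeTree.from_newick(TREE10)
        env = simulate_env_curve("constant", {"value": 2.0}, age_max=40)
        with pytest.raises(ValueError, match="identifiable"):
            fit_env(tree, env)

    def test_too_few_tips_rejected(self):
        with pytest.raises(ValueError, match="3 tips"):
            fit_bd(TimeTree.from_newick("(A:3,B:3);"))


class TestAICc:
    def test_formula_worked_example(self):
        assert _aicc(-100.0, 2, 50) == pytest.approx(204 + 12 / 47)

    def test_identical_fits_no_support(self):
        tree = TimeTree.from_newick(TREE10)
        fits = fit_bd(tree, models=("constant",), n_starts=2) * 2
        tab = aicc_compare(fits)
        assert (tab["delta_aicc"] == 0).all()
        assert not tab["supported"].any()

    def test_mixed_trees_rejected(self):
        f1 = fit_bd(TimeTree.from_newick(TREE4), models=("constant",), n_starts=2)
        f2 = fit_bd(TimeTree.from_newick(TREE10), models=("constant",), n_starts=2)
        with pytest.raises(ValueError, match="different trees"):
            aicc_compare(f1 + f2)

    def test_env_supported_on_env_driven_trees(self):
        env = simulate_env_curve(
            "linear", {"value_at_0": 0.0, "value_at_max": 1.0}, age_max=120
        )
        wins = 0
        n = 10
        for i in range(n):
            tree = simulate_rate_tree(
                lambda age: 0.025 * np.exp(2.0 * env(age)), 100.0, seed=800 + i
            )
            fits = fit_bd(tree, models=("constant",), n_starts=3)
            fits.append(fit_env(tree, env, n_starts=3))
            tab = aicc_compare(fits)
            if tab.iloc[0]["model"].startswith("environmental"):
                wins += 1
        assert wins > n / 2


class TestSliceTree:
    def test_slice_at_zero_gives_singletons(self):
        tree = TimeTree.from_newick(TREE4)
        forest = slice_tree(tree, 0.0, min_tips=50)
        assert len(forest.subtrees) == 4
        assert all(t.n_tips == 1 for t in forest.subtrees)
        assert not any(forest.retained)

    def test_slice_above_crown_returns_whole_tree(self):
        tree = TimeTree.from_newick(TREE10)
        forest = slice_tree(tree, 999.0, min_tips=5)
        assert len(forest.subtrees) == 1
        assert forest.subtrees[0].n_tips == 10
        assert forest.retained == [True]

    def test_two_crossing_lineages_partition_tips(self):
        nwk = "((A:10,B:10):40,((C:20,D:20):10,(E:15,F:15):15):20);"
        tree = TimeTree.from_newick(nwk)
        forest = slice_tree(tree, 35.0, min_tips=1)
        tipsets = sorted(tuple(sorted(t.tip_labels)) for t in forest.subtrees)
        assert tipsets == [("A", "B"), ("C", "D", "E", "F")]
        assert forest.retained == [True, True]
        # stem above the slice is discarded: each subtree re-dated at its crown
        assert {round(t.crown_age) for t in forest.subtrees} == {10, 30}


class TestDeclineStatistic:
    def test_constant_rate_zero_everywhere(self):
        tree = simulate_species_tree(
            SimulationConfig(crown_age=200, speciation_rate=0.025, seed=4)
        )
        fit = fit_bd(tree, models=("constant",), n_starts=2)[0]
        stat = decline_statistic(fit, (150.0, 100.0, 50.0))
        assert all(v == pytest.approx(0.0) for v in stat.values())

    def test_direct_evaluation_of_exponential_fit(self):
        tree = TimeTree.from_newick("((A:100,B:100):100,C:200);")
        res = fit_bd(tree, models=("exponential",), n_starts=2)[0]
        # overwrite the fitted parameters with a known rate function
        res.params = {"lambda0": 0.02, "alpha": math.log(0.03 / 0.02) / 150.0}
        res.model.params.update(res.params)
        stat = decline_statistic(res, (150.0,))
        assert stat[150.0] == pytest.approx(-0.01)

    def test_reference_beyond_crown_rejected(self):
        tree = TimeTree.from_newick(TREE10)
        fit = fit_bd(tree, models=("constant",), n_starts=2)[0]
        with pytest.raises(ValueError, match="crown"):
            decline_statistic(fit, (1000.0,))
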