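"""Generators: species trees, coalescent grafting, sequence evolution,
environment curves, unit metadata."""

import numpy as np
import pytest

from barcodediv import (
    TimeTree,
    graft_intraspecific,
    pairwise_similarity,
    simulate_alignment,
    simulate_env_curve,
    simulate_species_tree,
    simulate_unit_metadata,
)
from barcodediv.synthdata import SimulationConfig


class TestSimulationConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"crown_age": 0.0},
            {"speciation_rate": 0.01, "extinction_rate": 0.02},
            {"p_variable": 0.0},
            {"n_ind_range": (0, 5)},
            {"n_ind_range": (5, 2)},
            {"subst_rate": -1e-3},
            {"seq_length": 0},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(**kwargs)

    def test_from_net_rate(self):
        cfg = SimulationConfig.from_net_rate(0.010, turnover=0.5)
        assert cfg.speciation_rate == pytest.approx(0.020)
        assert cfg.extinction_rate == pytest.approx(0.010)
        assert cfg.net_rate == pytest.approx(0.010)
        assert cfg.turnover == pytest.approx(0.5)


class TestSpeciesTree:
    def test_crown_age_and_ultrametricity(self):
        tree = simulate_species_tree(SimulationConfig(seed=3))
        assert tree.crown_age == pytest.approx(505.0)
        assert tree.is_ultrametric(tol=1e-8)
        assert tree.n_tips >= 2

    def test_pure_birth_mean_tip_count(self):
        # E[N] = 2 exp(r T) for a surviving pure-birth crown clade
        counts = [
            simulate_species_tree(SimulationConfig(seed=s)).n_tips
            for s in range(200)
        ]
        expected = 2 * np.exp(0.010 * 505.0)  # ~312
        # the tip-count distribution is long-tailed; 10% relative slack
        assert np.mean(counts) == pytest.approx(expected, rel=0.10)

    def test_birth_death_runs_and_dates(self):
        cfg = SimulationConfig.from_net_rate(
            0.02, turnover=0.5, crown_age=150.0, seed=11
        )
        tree = simulate_species_tree(cfg)
        assert tree.crown_age == pytest.approx(150.0)
        assert tree.is_ultrametric(tol=1e-8)

    def test_determinism(self):
        a = simulate_species_tree(SimulationConfig(crown_age=150, seed=5))
        b = simulate_species_tree(SimulationConfig(crown_age=150, seed=5))
        assert a.to_newick() == b.to_newick()


@pytest.fixture(scope="module")
def grafted():
    cfg = SimulationConfig(crown_age=150.0, speciation_rate=0.03, seed=21)
    sp = simulate_species_tree(cfg)
    return sp, graft_intraspecific(sp, cfg, seed=22), cfg


class TestGrafting:
    def test_species_conserved_and_tip_counts(self, grafted):
        sp, g, cfg = grafted
        assert set(g.tip_species.values()) == set(sp.tip_labels)
        sizes = {}
        for tip, spp in g.tip_species.items():
            sizes[spp] = sizes.get(spp, 0) + 1
        lo, hi = cfg.n_ind_range
        assert all(lo <= k <= hi for k in sizes.values())
        assert g.n_tips == sum(sizes.values())

    def test_ultrametric_and_subtree_age_bound(self, grafted):
        sp, g, cfg = grafted
        assert g.is_ultrametric(tol=1e-8)
        pend = sp.pendant_lengths()
        # every within-species coalescent must predate its species' last
        # speciation event (and the 30-Myr cap)
        for node in g.tree.postorder_node_iter():
            if node.is_leaf() or node.parent_node is None:
                continue
            tips = {lf.taxon.label for lf in node.leaf_iter()}
            species = {g.tip_species[t] for t in tips}
            if len(species) == 1:
                (spp,) = species
                assert node.age <= min(pend[spp], cfg.max_coal_age) + 1e-9

    def test_two_tip_subtree_single_node(self):
        sp = TimeTree.from_newick("(A:40,B:40);")
        cfg = SimulationConfig(crown_age=40, n_ind_range=(2, 2), seed=1)
        g = graft_intraspecific(sp, cfg, seed=1)
        assert g.n_tips == 4
        # each species subtree has exactly one internal (coalescent) node
        internal = [n for n in g.tree.preorder_node_iter() if not n.is_leaf()]
        assert len(internal) == 3  # root + one per species


class TestAlignmentSimulation:
    def test_zero_rate_identical_sequences(self):
        cfg = SimulationConfig(crown_age=100, speciation_rate=0.03, subst_rate=0.0, seed=2)
        tree = simulate_species_tree(cfg)
        aln = simulate_alignment(tree, cfg, seed=3)
        assert (aln.codes == aln.codes[0]).all()

    def test_variable_column_count_and_invariable_identity(self):
        cfg = SimulationConfig(crown_age=200, speciation_rate=0.02, seed=4)
        tree = simulate_species_tree(cfg)
        aln = simulate_alignment(tree, cfg, seed=5)
        assert aln.length == 520
        varying = (aln.codes != aln.codes[0]).any(axis=0)
        # exactly floor(0.25 * 520) = 130 columns are *allowed* to vary
        assert varying.sum() <= 130
        # invariable columns are bitwise identical (complement check)
        assert (~varying).sum() >= 390

    def test_jukes_cantor_pairwise_expectation(self):
        # two tips at path distance 100 Myr; expected p-distance =
        # p_variable * (3/4) (1 - exp(-(4/3) s * 100))
        tree = TimeTree.from_newick("(A:50,B:50);")
        cfg = SimulationConfig(crown_age=50, speciation_rate=0.03)
        expected = 0.25 * 0.75 * (1 - np.exp(-4.0 / 3.0 * 0.001 * 100.0))
        dists = []
        for rep in range(200):
            aln = simulate_alignment(tree, cfg, seed=rep)
            dists.append(1.0 - pairwise_similarity(aln).values[0, 1])
        assert np.mean(dists) == pytest.approx(expected, abs=0.004)

    def test_determinism(self):
        cfg = SimulationConfig(crown_age=100, speciation_rate=0.03, seed=6)
        tree = simulate_species_tree(cfg)
        a = simulate_alignment(tree, cfg, seed=7)
        b = simulate_alignment(tree, cfg, seed=7)
        assert np.array_equal(a.codes, b.codes) and a.names == b.names


class TestEnvCurve:
    def test_constant_everywhere(self):
        env = simulate_env_curve("constant", {"value": 3.5}, age_max=500)
        assert env(0.0) == pytest.approx(3.5)
        assert env(321.7) == pytest.approx(3.5)

    def test_linear_midpoint(self):
        env = simulate_env_curve(
            "linear", {"value_at_0": 0.0, "value_at_max": 1.0}, age_max=500
        )
        assert env(250.0) == pytest.approx(0.5, abs=1e-6)

    def test_sinusoid_smoothing_high_fidelity(self):
        env = simulate_env_curve(
            "sinusoid",
            {"mean": 0, "amplitude": 5, "period": 150},
            age_max=505,
            n_points=205,
            df=33,
        )
        grid = np.linspace(0, 505, 400)
        truth = 5 * np.sin(2 * np.pi * grid / 150)
        assert np.corrcoef(env(grid), truth)[0, 1] > 0.99

    def test_non_monotone_table_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            simulate_env_curve("table", {"ages": [0, 10, 5], "values": [1, 2, 3]})


class TestUnitMetadata:
    def test_zero_noise_rank_one(self):
        from barcodediv import niche_pca

        meta = simulate_unit_metadata(60, noise_sd=0.0, seed=1)
        res = niche_pca(meta.units, min_n=1)
        assert res.explained_variance_ratio[0] > 0.999

    def test_pc1_tracks_latent_factor(self):
        from barcodediv import niche_pca

        meta = simulate_unit_metadata(200, noise_sd=0.2, seed=2)
        res = niche_pca(meta.units, min_n=1)
        latent = meta.units.set_index("unit").loc[res.scores.index, "latent"]
        assert abs(np.corrcoef(res.scores["PC1"], latent)[0, 1]) > 0.9

    def test_abundance_long_tail_spans_size_filter(self):
        meta = simulate_unit_metadata(300, seed=3)
        n = meta.units["n_seq"]
        assert (n >= 10).sum() > 0 and (n < 10).sum() > 0

    def test_latitudes_in_range_and_determinism(self):
        a = simulate_unit_metadata(50, seed=9)
        b = simulate_unit_metadata(50, seed=9)
        assert a.occurrences["latitude"].between(-90, 90).all()
        assert a.units.equals(b.units)
        assert a.occurrences.equals(b.occurrences)
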