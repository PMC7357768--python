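"""Module correspondence, species-genus ratios, trait profiles and tests."""

import numpy as np
import pandas as pd
import pytest

from beenet import characterization, modularity, nullmodels, synth
from beenet.modularity import AnnealSchedule, ModulePartition
from beenet.network import BipartiteNetwork

LIGHT = AnnealSchedule.light()


def _partition(net, assignment):
    return ModulePartition(
        assignment=dict(assignment),
        Q=modularity.barber_modularity(net, assignment),
        n_modules=len(set(assignment.values())),
    )


def _block_net(label, bee_groups, plant_groups):
    """Complete-within-block network from explicit member lists."""
    edges = []
    for bees, plants in zip(bee_groups, plant_groups):
        edges += [(b, p) for b in bees for p in plants]
    net = BipartiteNetwork.from_edges(edges, period_label=label)
    assignment = {}
    for m, (bees, plants) in enumerate(zip(bee_groups, plant_groups)):
        for n in list(bees) + list(plants):
            assignment[n] = m
    return net, _partition(net, assignment)


class TestCorrespondence:
    def test_identical_partitions_match_at_distance_zero(self):
        net_a, part_a = _block_net(
            "A", [[f"b{i}" for i in range(3)], [f"c{i}" for i in range(3)]],
            [["pa", "pb"], ["pc", "pd"]])
        net_b = BipartiteNetwork(net_a.bees, net_a.plants,
                                 net_a.adjacency.copy(), "B")
        part_b = _partition(net_b, part_a.assignment)
        res = characterization.module_correspondence(
            [part_a, part_b], [net_a, net_b], min_bees=2)
        assert len(res.matched) == 2
        # each matched pair sits at Jaccard distance 0
        for group in res.matched:
            assert {p for p, _ in group} == {"A", "B"}

    def test_disjoint_species_sets_never_match(self):
        net_a, part_a = _block_net(
            "A", [["a1", "a2"], ["a3", "a4"]], [["pa"], ["pb"]])
        net_b, part_b = _block_net(
            "B", [["b1", "b2"], ["b3", "b4"]], [["pc"], ["pd"]])
        res = characterization.module_correspondence(
            [part_a, part_b], [net_a, net_b], min_bees=2)
        assert res.matched == []
        assert np.all(res.distance == 1.0)

    def test_membership_churn_still_recovers_pairs(self):
        """Modules sharing 70% of their bees across periods pair up."""
        groups_a = [[f"m{m}bee{i}" for i in range(10)] for m in range(3)]
        groups_b = [members[:7] + [f"new{m}bee{i}" for i in range(3)]
                    for m, members in enumerate(groups_a)]
        plants = [[f"m{m}plant{j}" for j in range(4)] for m in range(3)]
        net_a, part_a = _block_net("A", groups_a, plants)
        net_b, part_b = _block_net("B", groups_b, plants)
        res = characterization.module_correspondence(
            [part_a, part_b], [net_a, net_b], min_bees=5)
        assert len(res.matched) == 3
        for group in res.matched:
            modules = dict(group)
            assert modules["A"] == modules["B"]  # same planted block index

    def test_newick_written_for_every_leaf(self):
        net_a, part_a = _block_net(
            "A", [["a1", "a2"], ["a3", "a4"]], [["pa"], ["pb"]])
        net_b, part_b = _block_net(
            "B", [["a1", "a2"], ["a3", "a4"]], [["pc"], ["pd"]])
        res = characterization.module_correspondence(
            [part_a, part_b], [net_a, net_b], min_bees=2)
        assert res.newick.endswith(";")
        for period, module in res.module_ids:
            assert f"{period}|M{module}" in res.newick

    def test_single_period_rejected(self):
        net, part = _block_net("A", [["a1", "a2"]], [["pa"]])
        with pytest.raises(ValueError):
            characterization.module_correspondence([part], [net])


class TestSpeciesGenusRatio:
    def _net(self, plant_names):
        edges = [("b1", p) for p in plant_names] + [("b2", plant_names[0])]
        net = BipartiteNetwork.from_edges(edges)
        assignment = {n: 0 for n in net.node_names()}
        return net, _partition(net, assignment)

    def test_two_congeners_plus_one(self):
        net, part = self._net(["Aster alpinus", "Aster bellidiastrum",
                               "Rosa canina"])
        assert characterization.species_genus_ratio(net, part, 0) == 1.5

    def test_all_distinct_genera_is_minimum_one(self):
        net, part = self._net(["Aster a", "Rosa r", "Salix s"])
        assert characterization.species_genus_ratio(net, part, 0) == 1.0

    def test_all_congeneric_equals_species_count(self):
        net, part = self._net(["Aster a", "Aster b", "Aster c", "Aster d"])
        assert characterization.species_genus_ratio(net, part, 0) == 4.0

    def test_genus_map_overrides_name_token(self):
        net, part = self._net(["Aster a", "Rosa r"])
        ratio = characterization.species_genus_ratio(
            net, part, 0, genus_map={"Aster a": "Rosa", "Rosa r": "Rosa"})
        assert ratio == 2.0

    def test_planted_modules_more_homogeneous_than_null(self):
        spec = synth.SyntheticSpec(n_bees=24, n_plants=36, n_modules=3,
                                   p_in=0.6, p_out=0.02,
                                   generalist_fraction=0.0, seed=2)
        net, truth = synth.generate_planted_network(spec)
        part = _partition(net, truth.assignment())
        observed = [characterization.species_genus_ratio(net, part, m)
                    for m in range(3)]
        ens = nullmodels.build_null_ensemble(net, n_reps=8, seed=3,
                                             schedule=LIGHT)
        null_ratios = characterization.species_genus_ratio_null(ens,
                                                                min_bees=4)
        assert np.mean(observed) > np.quantile(null_ratios, 0.75)


class TestTraitProfile:
    def _setup(self):
        spec = synth.SyntheticSpec(n_bees=30, n_plants=45, n_modules=3,
                                   p_in=0.5, p_out=0.02,
                                   generalist_fraction=0.0, seed=8)
        net, truth = synth.generate_planted_network(spec)
        part = _partition(net, truth.assignment())
        return net, truth, part

    def test_counts_match_explicit_proportions(self):
        net, truth, part = self._setup()
        bees, plants = synth.generate_traits(truth, association=0.6, seed=8)
        module = part.main_modules(net, min_bees=5)[0]
        prof = characterization.trait_profile(net, part, module, bees, plants)
        members = part.module_members(net)[module]["bees"]
        sub = bees.set_index("species").loc[members, "nesting"]
        expected = (sub.value_counts() / len(sub)).to_dict()
        assert prof.bee_trait_proportions["nesting"] == pytest.approx(expected)
        assert prof.n_bees == len(members)

    def test_full_association_gives_pure_modal_categories(self):
        net, truth, part = self._setup()
        bees, plants = synth.generate_traits(truth, association=1.0, seed=1)
        for module in part.main_modules(net, min_bees=5):
            prof = characterization.trait_profile(net, part, module, bees,
                                                  plants)
            for trait in synth.BEE_TRAIT_CATEGORIES:
                _, prop = prof.modal(trait)
                assert prop == 1.0

    def test_plant_mode_species_vs_links(self):
        net, truth, part = self._setup()
        bees, plants = synth.generate_traits(truth, association=0.6, seed=2)
        module = part.main_modules(net, min_bees=5)[0]
        by_links = characterization.trait_profile(
            net, part, module, bees, plants, plant_mode="links")
        by_species = characterization.trait_profile(
            net, part, module, bees, plants, plant_mode="species")
        assert set(by_links.plant_trait_proportions) \
            == set(by_species.plant_trait_proportions)
        assert by_links.n_plants == by_species.n_plants


class TestTraitSpecializationTests:
    def _role_table(self, bees, c):
        return pd.DataFrame({"species": bees, "degree": np.ones(len(bees)),
                             "c": c, "z": np.zeros(len(bees))})

    def test_constant_response_gives_flat_quantile_fit(self):
        intercept, slope = characterization.quantile_fit(
            np.linspace(0, 1, 30), np.full(30, 2.2), q=0.3)
        assert slope == 0.0 and intercept == 2.2

    def test_quantile_fit_minimizes_pinball_loss(self):
        rng = np.random.default_rng(0)
        x = rng.random(200)
        y = 1.0 + 2.0 * x + rng.normal(0, 0.3, 200)
        intercept, slope = characterization.quantile_fit(x, y, q=0.3)

        def pinball(b0, b1):
            r = y - b0 - b1 * x
            return np.where(r >= 0, 0.3 * r, (0.3 - 1) * r).sum()

        fitted = pinball(intercept, slope)
        for db0 in (-0.05, 0.05):
            for db1 in (-0.05, 0.05):
                assert fitted <= pinball(intercept + db0, slope + db1) + 1e-9

    def test_planted_positive_itd_dependence_detected(self):
        rng = np.random.default_rng(3)
        c = rng.random(120)
        traits = pd.DataFrame({
            "species": [f"s{i}" for i in range(120)],
            "ITD": 1.0 + 2.0 * c + rng.normal(0, 0.2, 120),
            "lecty": rng.choice(["oligolectic", "polylectic"], 120),
        })
        table = self._role_table(traits["species"], c)
        results = characterization.trait_specialization_tests(
            table, traits, variables=("c",))
        itd = [r for r in results if r.trait == "ITD"][0]
        assert itd.extra["slope"] > 0
        assert itd.pvalue < 0.001

    def test_unassociated_traits_rarely_significant(self):
        """With exchangeable traits, the categorical tests reject at ~5%."""
        significant = total = 0
        for seed in range(30):
            rng = np.random.default_rng(seed)
            bees = [f"s{i}" for i in range(40)]
            traits = pd.DataFrame({
                "species": bees,
                "lecty": rng.choice(["oligolectic", "polylectic"], 40),
                "nesting": rng.choice(["carder", "excavator", "renter"], 40),
            })
            table = self._role_table(bees, rng.random(40))
            for res in characterization.trait_specialization_tests(
                    table, traits, variables=("c",)):
                total += 1
                significant += res.pvalue < 0.05
        assert significant / total <= 0.15

    def test_two_vs_multi_category_test_selection(self):
        rng = np.random.default_rng(1)
        bees = [f"s{i}" for i in range(30)]
        traits = pd.DataFrame({
            "species": bees,
            "lecty": rng.choice(["oligolectic", "polylectic"], 30),
            "sociality": rng.choice(["solitary", "communal",
                                     "cleptoparasite"], 30),
        })
        table = self._role_table(bees, rng.random(30))
        results = characterization.trait_specialization_tests(
            table, traits, variables=("c",))
        kinds = {r.trait: r.test for r in results}
        assert kinds["lecty"] == "rank-sum"
        assert kinds["sociality"] == "kruskal-wallis"
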