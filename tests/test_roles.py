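"""Participation and within-module degree coefficients, roles, group tests."""

import numpy as np
import pandas as pd
import pytest

from beenet import modularity, nullmodels, roles
from beenet.modularity import AnnealSchedule
from beenet.network import BipartiteNetwork
from conftest import random_bipartite

LIGHT = AnnealSchedule.light()


def brute_force_cz(net, assignment, ddof=1):
    """Independent oracle: per-species loops over raw adjacency entries."""
    out = {}
    kappas = {}
    for i, bee in enumerate(net.bees):
        per_module = {}
        for j, plant in enumerate(net.plants):
            if net.adjacency[i, j]:
                per_module[assignment[plant]] = \
                    per_module.get(assignment[plant], 0) + 1
        k = sum(per_module.values())
        c = 1.0 - sum((v / k) ** 2 for v in per_module.values())
        kappa = per_module.get(assignment[bee], 0)
        out[bee] = {"c": c, "kappa": kappa}
        kappas.setdefault(assignment[bee], []).append((bee, kappa))
    for mod, members in kappas.items():
        vals = np.array([kappa for _, kappa in members], dtype=float)
        sd = vals.std(ddof=ddof) if len(vals) > 1 else 0.0
        for (bee, kappa) in members:
            out[bee]["z"] = (kappa - vals.mean()) / sd if sd > 0 else np.nan
    return out


def _net_with_modules():
    """Bee 'hub' links 2 plants of module 0 and 1 of module 1; bee 'loyal'
    links only inside module 0."""
    edges = [("hub", "p0a"), ("hub", "p0b"), ("hub", "p1a"),
             ("loyal", "p0a"), ("loyal", "p0b"),
             ("other", "p1a"), ("other", "p1b")]
    net = BipartiteNetwork.from_edges(edges)
    assignment = {"hub": 0, "loyal": 0, "other": 1,
                  "p0a": 0, "p0b": 0, "p1a": 1, "p1b": 1}
    return net, assignment


class TestParticipation:
    def test_all_links_inside_module_gives_zero(self):
        net, assignment = _net_with_modules()
        assert roles.participation_coefficient(net, assignment, "loyal") == 0.0

    def test_degree_two_split_evenly_gives_half(self):
        net = BipartiteNetwork.from_edges([("b", "p0"), ("b", "p1"),
                                           ("x", "p0"), ("y", "p1")])
        assignment = {"b": 0, "x": 0, "y": 1, "p0": 0, "p1": 1}
        assert roles.participation_coefficient(net, assignment, "b") == 0.5

    def test_degree_three_split_two_one(self):
        net, assignment = _net_with_modules()
        assert roles.participation_coefficient(net, assignment, "hub") \
            == pytest.approx(4 / 9)

    def test_invariant_under_module_relabeling(self):
        net, assignment = _net_with_modules()
        relabeled = {k: {0: 3, 1: 8}[v] for k, v in assignment.items()}
        for bee in net.bees:
            assert roles.participation_coefficient(net, assignment, bee) \
                == roles.participation_coefficient(net, relabeled, bee)


class TestWithinModuleDegree:
    def _kappa_114_net(self):
        """One module whose bees have within-module degrees {1, 1, 4}."""
        edges = [("A", "x1"), ("B", "x2"),
                 ("C", "x1"), ("C", "x2"), ("C", "x3"), ("C", "x4")]
        net = BipartiteNetwork.from_edges(edges)
        assignment = {n: 0 for n in net.node_names()}
        return net, assignment

    def test_sample_sd_convention(self):
        net, assignment = self._kappa_114_net()
        # kappas {1,1,4}: mean 2, sample SD sqrt(3) -> z = 2/sqrt(3)
        assert roles.within_module_degree(net, assignment, "C") \
            == pytest.approx(2 / np.sqrt(3))

    def test_population_sd_switch(self):
        net, assignment = self._kappa_114_net()
        # population SD sqrt(2) -> z = sqrt(2)
        assert roles.within_module_degree(net, assignment, "C", ddof=0) \
            == pytest.approx(np.sqrt(2))

    def test_species_at_module_mean_gets_zero(self):
        edges = [("A", "x1"), ("B", "x1"), ("B", "x2"), ("C", "x1"),
                 ("C", "x2"), ("C", "x3")]
        net = BipartiteNetwork.from_edges(edges)
        assignment = {n: 0 for n in net.node_names()}
        assert roles.within_module_degree(net, assignment, "B") \
            == pytest.approx(0.0)

    def test_zero_variance_module_yields_missing(self):
        net = BipartiteNetwork.from_edges([("A", "x"), ("B", "y")])
        assignment = {n: 0 for n in net.node_names()}
        table = roles.cz_table(net, assignment)
        assert table["z"].isna().all()

    @pytest.mark.parametrize("seed", range(6))
    def test_cz_table_matches_brute_force(self, seed):
        net = random_bipartite(seed, 12, 16, p=0.3)
        rng = np.random.default_rng(seed)
        assignment = {n: int(rng.integers(3)) for n in net.node_names()}
        table = roles.cz_table(net, assignment).set_index("species")
        oracle = brute_force_cz(net, assignment)
        for bee in net.bees:
            assert table.loc[bee, "c"] == pytest.approx(oracle[bee]["c"])
            if np.isnan(oracle[bee]["z"]):
                assert np.isnan(table.loc[bee, "z"])
            else:
                assert table.loc[bee, "z"] == pytest.approx(oracle[bee]["z"])

    def test_defined_z_standardized_within_module(self):
        net = random_bipartite(11, 20, 25, p=0.3)
        rng = np.random.default_rng(11)
        assignment = {n: int(rng.integers(3)) for n in net.node_names()}
        table = roles.cz_table(net, assignment)
        for _, group in table.dropna(subset=["z"]).groupby("module"):
            assert group["z"].mean() == pytest.approx(0.0, abs=1e-12)
            assert group["z"].std(ddof=1) == pytest.approx(1.0)


class TestThresholdsAndClassification:
    def _thresholds(self, c_star, z_star):
        return roles.RoleThresholds(c_star=c_star, z_star=z_star,
                                    quantile=0.9)

    def test_quantile_convention_linear_interpolation(self):
        net = random_bipartite(5, 15, 20, p=0.3)
        ens = nullmodels.build_null_ensemble(net, n_reps=4, seed=0,
                                             schedule=LIGHT)
        thr90 = roles.role_thresholds(ens, quantile=0.90)
        thr95 = roles.role_thresholds(ens, quantile=0.95)
        assert thr95.c_star >= thr90.c_star
        assert thr95.z_star >= thr90.z_star

    def test_zero_null_pool_puts_every_positive_c_above(self):
        table = pd.DataFrame({"species": ["a", "b"], "degree": [2, 2],
                              "c": [0.4, 0.0], "z": [np.nan, np.nan]})
        out = roles.classify_roles(table, self._thresholds(0.0, 0.0))
        assert out.set_index("species").loc["a", "role"] == "connector"
        assert out.set_index("species").loc["b", "role"] == "peripheral"

    @pytest.mark.parametrize("c,z,expected", [
        (0.3, 0.5, "peripheral"),
        (0.8, 0.5, "connector"),
        (0.3, 2.0, "module hub"),
        (0.8, 2.0, "network hub"),
    ])
    def test_role_quadrants(self, c, z, expected):
        table = pd.DataFrame({"species": ["s"], "degree": [3],
                              "c": [c], "z": [z]})
        out = roles.classify_roles(table, self._thresholds(0.62, 1.0))
        assert out.loc[0, "role"] == expected

    def test_missing_z_cannot_be_hub(self):
        table = pd.DataFrame({"species": ["a", "b"], "degree": [2, 2],
                              "c": [0.9, 0.1], "z": [np.nan, np.nan]})
        out = roles.classify_roles(table, self._thresholds(0.62, 1.0))
        assert out["role"].tolist() == ["connector", "peripheral"]

    def test_raising_thresholds_never_promotes(self):
        rank = {"peripheral": 0, "connector": 1, "module hub": 1,
                "network hub": 2}
        rng = np.random.default_rng(0)
        table = pd.DataFrame({
            "species": [f"s{i}" for i in range(50)],
            "degree": rng.integers(1, 10, 50),
            "c": rng.random(50),
            "z": rng.normal(0, 1.5, 50),
        })
        low = roles.classify_roles(table, self._thresholds(0.3, 0.5))
        high = roles.classify_roles(table, self._thresholds(0.6, 1.5))
        for lo, hi in zip(low["role"], high["role"]):
            assert rank[hi] <= rank[lo]

    def test_classic_cutoffs_available(self):
        thr = roles.classic_thresholds()
        assert (thr.c_star, thr.z_star) == (0.62, 2.5)


class TestGroupComparisons:
    def _table(self, species, c, z=None):
        return pd.DataFrame({
            "species": species, "degree": np.ones(len(species)),
            "c": c, "z": z if z is not None else np.zeros(len(species)),
        })

    def test_identical_paired_samples_not_significant(self):
        t = self._table(list("abcde"), [0.1, 0.2, 0.3, 0.4, 0.5])
        res = roles.compare_groups(t, t.copy(), pairing="paired")
        assert res["c"].pvalue >= 0.5

    def test_uniform_increase_gives_minimal_one_tailed_p(self):
        a = self._table(list("abcdefgh"), np.linspace(0.1, 0.4, 8))
        b = self._table(list("abcdefgh"), np.linspace(0.3, 0.7, 8))
        res = roles.compare_groups(a, b, pairing="paired",
                                   alternative="greater")
        # all 8 signed ranks positive: p = 2^-8
        assert res["c"].pvalue == pytest.approx(2 ** -8)

    def test_unpaired_direction(self):
        a = self._table(list("abcd"), [0.1, 0.15, 0.2, 0.12])
        b = self._table(list("wxyz"), [0.6, 0.7, 0.8, 0.75])
        res = roles.compare_groups(a, b, pairing="unpaired",
                                   alternative="greater")
        assert res["c"].pvalue < 0.05

    def test_empty_group_raises(self):
        t = self._table(list("ab"), [0.1, 0.2])
        with pytest.raises(ValueError):
            roles.compare_groups(t, t.iloc[:0], pairing="unpaired")

    def test_disjoint_species_sets_cannot_be_paired(self):
        a = self._table(list("ab"), [0.1, 0.2])
        b = self._table(list("cd"), [0.1, 0.2])
        with pytest.raises(ValueError):
            roles.compare_groups(a, b, pairing="paired")


class TestDegreeCorrelation:
    def test_perfectly_linear(self):
        table = pd.DataFrame({"species": list("abcd"),
                              "degree": [1, 2, 3, 4],
                              "c": [0.1, 0.2, 0.3, 0.4],
                              "z": [4.0, 3.0, 2.0, 1.0]})
        out = roles.degree_cz_correlation(table)
        assert out["c"][0] == pytest.approx(1.0)
        assert out["z"][0] == pytest.approx(-1.0)

    def test_independent_pairs_near_zero(self):
        rng = np.random.default_rng(0)
        rs = []
        for _ in range(40):
            table = pd.DataFrame({"species": range(60),
                                  "degree": rng.integers(1, 20, 60),
                                  "c": rng.random(60),
                                  "z": rng.normal(size=60)})
            rs.append(roles.degree_cz_correlation(table)["c"][0])
        assert abs(np.mean(rs)) < 0.05

    def test_zero_variance_rejected(self):
        table = pd.DataFrame({"species": list("abc"), "degree": [2, 2, 2],
                              "c": [0.1, 0.2, 0.3], "z": [0.0, 1.0, 2.0]})
        with pytest.raises(ValueError):
            roles.degree_cz_correlation(table)


def test_planted_generalist_becomes_key_species():
    """A bee wired evenly across all modules ends up with a high c and a
    non-peripheral role against null-quantile thresholds."""
    from beenet import synth
    spec = synth.SyntheticSpec(n_bees=18, n_plants=30, n_modules=3,
                               p_in=0.7, p_out=0.0, generalist_fraction=0.0,
                               seed=21)
    net, truth = synth.generate_planted_network(spec)
    # wire one extra bee to the first twelve plants: round-robin block
    # assignment spreads them evenly over the three modules
    a = np.zeros((net.n_bees + 1, net.n_plants), dtype=np.uint8)
    a[: net.n_bees] = net.adjacency
    a[-1, :12] = 1
    big = BipartiteNetwork(net.bees + ["Super generalist"], net.plants, a)
    part = modularity.detect_modules(big, LIGHT, seed=2)
    table = roles.cz_table(big, part).set_index("species")
    # the planted generalist reaches the 3-module ceiling c = 1 - 1/3 and
    # tops the table; against the fixed cartographic cutoffs it is a
    # connector (high c, unremarkable z)
    assert table["c"].idxmax() == "Super generalist"
    assert table.loc["Super generalist", "c"] == pytest.approx(2 / 3)
    classified = roles.classify_roles(table.reset_index(),
                                      roles.classic_thresholds())
    assert classified.set_index("species").loc[
        "Super generalist", "role"] == "connector"
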