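import random
from itertools import combinations

import pytest

from sbmlpatterns.dfscode import is_isomorphic, minimum_dfs_code
from sbmlpatterns.errors import CapacityError, ConfigError
from sbmlpatterns.graphs import (
    HAS_PRODUCT,
    IS_REACTANT,
    LabelledDigraph,
    Network,
    NetworkSet,
)
from sbmlpatterns.match import supports
from sbmlpatterns.mining import MiningConfig, Pattern, mine
from sbmlpatterns.synth import two_species_cycle

from conftest import (
    REACTION_LABEL,
    SPECIES_LABEL,
    make_network_set,
    random_connected_network,
)
from oracles import brute_canonical_form, oracle_mine


def chain_graph():
    return LabelledDigraph(
        {"s": SPECIES_LABEL, "r": REACTION_LABEL, "s2": SPECIES_LABEL},
        {("s", "r", IS_REACTANT), ("r", "s2", HAS_PRODUCT)},
    )


class TestMineBasics:
    def test_threshold_above_corpus_size_yields_nothing(self, rng):
        nets = make_network_set([random_connected_network(rng, 3, 2, 3)])
        assert mine(nets, MiningConfig(min_support=2)) == []

    def test_zero_min_support_is_config_error(self, rng):
        nets = make_network_set([random_connected_network(rng, 3, 2, 3)])
        with pytest.raises(ConfigError):
            mine(nets, MiningConfig(min_support=0))

    def test_empty_corpus_yields_nothing(self):
        assert mine(NetworkSet(), MiningConfig(min_support=1)) == []

    def test_known_five_pattern_inventory(self):
        """Two identical chains + one lone species at support interval [2, 3]:
        the species node occurs in all three graphs, the reaction node,
        both single-edge patterns and the full chain in exactly two."""
        single = LabelledDigraph({"x": SPECIES_LABEL})
        nets = make_network_set([chain_graph(), chain_graph(), single])
        patterns = mine(nets, MiningConfig(min_support=2, max_support=3, max_edges=5))
        inventory = sorted((p.n_edges, p.support) for p in patterns)
        assert inventory == [(0, 2), (0, 3), (1, 2), (1, 2), (2, 2)]
        species_node = next(p for p in patterns if p.n_edges == 0 and p.support == 3)
        assert species_node.graph.nodes["Node_0"] == SPECIES_LABEL

    def test_max_support_excludes_ubiquitous_patterns_but_extends_them(self):
        """A pattern above max support is withheld, yet its extensions
        inside the interval are still found."""
        g1 = chain_graph()
        g2 = chain_graph()
        single = LabelledDigraph({"x": SPECIES_LABEL})
        nets = make_network_set([g1, g2, single])
        patterns = mine(nets, MiningConfig(min_support=2, max_support=2, max_edges=5))
        # species node (support 3) excluded; its one-edge extensions kept
        assert all(p.support == 2 for p in patterns)
        assert any(p.n_edges == 2 for p in patterns)

    def test_single_node_patterns_emitted(self, rng):
        nets = make_network_set([random_connected_network(rng, 3, 2, 4) for _ in range(4)])
        patterns = mine(nets, MiningConfig(min_support=4, max_edges=0))
        assert patterns and all(p.n_entities == 1 for p in patterns)

    def test_capacity_cap_raises_explicit_error(self, rng):
        nets = make_network_set([random_connected_network(rng, 5, 4, 8) for _ in range(3)])
        with pytest.raises(CapacityError):
            mine(nets, MiningConfig(min_support=1, max_edges=8, max_patterns=5))


class TestOracleEquivalence:
    def _as_forms(self, patterns):
        return {brute_canonical_form(p.graph): p.support for p in patterns}

    @pytest.mark.parametrize("seed,n_nets", [(1, 6), (2, 8), (3, 10)])
    def test_mine_equals_exhaustive_enumeration(self, seed, n_nets):
        rng = random.Random(seed)
        graphs = [random_connected_network(rng, 3, 3, rng.randint(2, 6)) for _ in range(n_nets)]
        nets = make_network_set(graphs)
        min_sup = 2
        cfg = MiningConfig(min_support=min_sup, max_edges=4)
        mined = self._as_forms(mine(nets, cfg))
        expected = oracle_mine([[g] for g in graphs], min_sup, n_nets, 4)
        assert mined == expected


class TestMinedInvariants:
    def _mine_random(self, seed):
        rng = random.Random(seed)
        graphs = [random_connected_network(rng, 3, 3, rng.randint(2, 6)) for _ in range(6)]
        nets = make_network_set(graphs)
        return mine(nets, MiningConfig(min_support=2, max_edges=4)), nets

    @pytest.mark.parametrize("seed", range(5))
    def test_canonicality_no_two_patterns_isomorphic(self, seed):
        patterns, _ = self._mine_random(seed)
        codes = [minimum_dfs_code(p.graph) for p in patterns]
        assert len(codes) == len(set(codes))

    @pytest.mark.parametrize("seed", range(5))
    def test_anti_monotonicity_of_emitted_supports(self, seed):
        """Every emitted pattern's sub-pattern relationship respects support:
        if P embeds in Q then support(P) >= support(Q)."""
        patterns, _ = self._mine_random(seed)
        for p, q in combinations(patterns, 2):
            if p.n_edges < q.n_edges and supports(p.graph, q.graph):
                assert p.support >= q.support
            if q.n_edges < p.n_edges and supports(q.graph, p.graph):
                assert q.support >= p.support

    @pytest.mark.parametrize("seed", range(3))
    def test_supporting_ids_are_exactly_the_embedding_networks(self, seed):
        patterns, nets = self._mine_random(seed)
        lookup = {n.network_id: n.graph for n in nets}
        for p in patterns:
            assert len(p.supporting_ids) == len(set(p.supporting_ids)) == p.support
            for nid, g in lookup.items():
                assert (nid in p.supporting_ids) == supports(p.graph, g)

    def test_determinism_across_runs(self, rng):
        graphs = [random_connected_network(rng, 4, 3, 5) for _ in range(6)]
        nets = make_network_set(graphs)
        cfg = MiningConfig(min_support=2, max_edges=4)
        a = mine(nets, cfg)
        b = mine(nets, cfg)
        assert [(p.pattern_id, p.code, p.supporting_ids) for p in a] == [
            (p.pattern_id, p.code, p.supporting_ids) for p in b
        ]


class TestSupportUnits:
    def test_model_unit_counts_each_model_once(self):
        # one model with two networks both containing the chain, another with one
        nets = NetworkSet(
            [
                Network(chain_graph(), "mA", 1),
                Network(chain_graph(), "mA", 2),
                Network(chain_graph(), "mB", 1),
            ]
        )
        network_level = mine(nets, MiningConfig(min_support=1, max_edges=2))
        model_level = mine(
            nets, MiningConfig(min_support=1, max_edges=2, support_unit="model")
        )
        chain_net = next(p for p in network_level if p.n_edges == 2)
        chain_mod = next(p for p in model_level if p.n_edges == 2)
        assert chain_net.support == 3
        assert chain_mod.support == 2
        assert chain_net.model_support == 2

    def test_planted_cycle_recovered_at_both_units(self):
        cyc = two_species_cycle()
        rng = random.Random(42)
        graphs = []
        for i in range(8):
            g = random_connected_network(rng, 3, 2, 4)
            graphs.append(g)
        nets = NetworkSet(
            [Network(g, f"m{i}", 1) for i, g in enumerate(graphs)]
            + [Network(cyc.copy(), f"m{i}", 2) for i in range(5)]
        )
        patterns = mine(nets, MiningConfig(min_support=5, max_edges=4))
        assert any(is_isomorphic(p.graph, cyc) and p.support >= 5 for p in patterns)
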