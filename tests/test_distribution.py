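import random
import re
from itertools import combinations

import pandas as pd
import pytest

from sbmlpatterns.distribution import (
    build_feature_matrix,
    pattern_to_graph_query,
    write_distribution_json,
    write_feature_matrix,
    write_queries,
)
from sbmlpatterns.errors import ContractError, DataError
from sbmlpatterns.graphs import (
    HAS_PRODUCT,
    IS_REACTANT,
    LabelledDigraph,
)
from sbmlpatterns.ingest import combined_networks
from sbmlpatterns.match import count_embeddings, supports
from sbmlpatterns.mining import MiningConfig, Pattern, mine
from sbmlpatterns.synth import SynthConfig, two_species_cycle, generate_corpus

from conftest import REACTION_LABEL, SPECIES_LABEL, random_connected_network


def reference_branch_pattern():
    """Five-node reference pattern: a species producing into two reactions,
    produced by one reaction that itself has another reactant."""
    g = LabelledDigraph(
        {
            "Node_0": REACTION_LABEL,
            "Node_1": SPECIES_LABEL,
            "Node_2": REACTION_LABEL,
            "Node_3": REACTION_LABEL,
            "Node_4": SPECIES_LABEL,
        },
        {
            ("Node_0", "Node_1", HAS_PRODUCT),
            ("Node_1", "Node_2", IS_REACTANT),
            ("Node_1", "Node_3", IS_REACTANT),
            ("Node_4", "Node_0", IS_REACTANT),
        },
    )
    return g


class TestQueryGeneration:
    def test_reference_pattern_query_shape(self):
        query = pattern_to_graph_query(reference_branch_pattern())
        assert query.count("<>") == 10  # C(5,2) pairwise inequalities
        # one relationship clause per pattern edge
        rel_clauses = re.findall(r"Node_\d+-\[: \w+\]->Node_\d+", query)
        assert len(rel_clauses) == 4
        assert "(m: SBML_MODEL)-->(d: DOCUMENT)" in query
        assert "m-[HAS_REACTION]->Node_0" in query
        assert "RETURN DISTINCT ID(m), d.FILENAME, COUNT(Node_0) AS sum" in query
        assert query.strip().endswith("ORDER BY sum DESC")

    def test_single_edge_pattern_has_one_clause_one_inequality(self):
        g = LabelledDigraph(
            {"Node_0": SPECIES_LABEL, "Node_1": REACTION_LABEL},
            {("Node_0", "Node_1", IS_REACTANT)},
        )
        query = pattern_to_graph_query(g)
        assert query.count("<>") == 1
        assert len(re.findall(r"Node_\d+-\[: \w+\]->Node_\d+", query)) == 1
        # species-anchored pattern uses the species anchor relation
        assert "m-[HAS_SPECIES]->Node_0" in query

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_random_pattern_query_combinatorics(self, seed):
        rng = random.Random(seed)
        g = random_connected_network(rng, 3, 3, rng.randint(2, 6))
        k = g.n_nodes
        query = pattern_to_graph_query(g)
        assert query.count("<>") == k * (k - 1) // 2
        edge_clause = re.compile(r"\S+-\[: (\w+)\]->\S+")
        labels = [m.group(1) for m in edge_clause.finditer(query)
                  if m.group(1) != "HAS_REACTION" and m.group(1) != "HAS_SPECIES"]
        assert sorted(labels) == sorted(l for _, _, l in g.edges)

    def test_empty_pattern_rejected(self):
        with pytest.raises(ContractError):
            pattern_to_graph_query(LabelledDigraph())


def _patterns_from(mined):
    return [p for p in mined]


class TestFeatureMatrix:
    def _corpus(self, seed=13, planted=()):
        models, ledger = generate_corpus(
            SynthConfig(n_models=8, seed=seed, planted=planted)
        )
        return models, ledger

    def test_zero_patterns_leaves_model_columns_only(self):
        models, _ = self._corpus()
        matrix = build_feature_matrix(models, [])
        assert list(matrix.columns) == ["model_id", "model_name"]
        assert len(matrix) == 8

    def test_duplicate_model_ids_rejected(self):
        models, _ = self._corpus()
        with pytest.raises(DataError):
            build_feature_matrix(models + models[:1], [])

    def test_planted_counts_are_lower_bounds(self):
        cyc = two_species_cycle()
        models, ledger = self._corpus(seed=4, planted=[(cyc, 0.5)])
        pattern = Pattern(graph=cyc, support=4, supporting_ids=[],
                          supporting_models=[], pattern_id="4_1")
        matrix = build_feature_matrix(models, [pattern]).set_index("model_id")
        for m in models:
            planted_copies = len(ledger.planted_copies[m.record.model_id])
            # each planted copy contributes both rotations of the cycle
            assert matrix.loc[m.record.model_id, "4_1"] >= 2 * planted_copies

    def test_positive_cells_match_miner_model_support(self):
        models, _ = self._corpus(seed=6)
        nets = combined_networks(models)
        patterns = mine(nets, MiningConfig(min_support=4, max_edges=2))
        matrix = build_feature_matrix(models, patterns)
        for p in patterns:
            positive = int((matrix[p.pattern_id] > 0).sum())
            assert positive == p.model_support

    def test_column_order_is_descending_frequency(self):
        models, _ = self._corpus(seed=6)
        nets = combined_networks(models)
        patterns = mine(nets, MiningConfig(min_support=4, max_edges=2))
        matrix = build_feature_matrix(models, patterns)
        supports_in_order = [
            next(p.support for p in patterns if p.pattern_id == c)
            for c in matrix.columns[2:]
        ]
        assert supports_in_order == sorted(supports_in_order, reverse=True)

    def test_csv_and_json_round_trip(self, tmp_path):
        models, _ = self._corpus(seed=6)
        nets = combined_networks(models)
        patterns = mine(nets, MiningConfig(min_support=6, max_edges=1))
        matrix = build_feature_matrix(models, patterns)
        csv_path = tmp_path / "matrix.csv"
        write_feature_matrix(matrix, csv_path)
        back = pd.read_csv(csv_path)
        assert list(back.columns) == list(matrix.columns)
        assert back.shape == matrix.shape
        pid = patterns[0].pattern_id
        json_path = tmp_path / "dist.json"
        write_distribution_json(matrix, pid, json_path)
        import json

        rows = json.loads(json_path.read_text())
        assert all(r["count"] > 0 for r in rows)
        assert [r["count"] for r in rows] == sorted(
            (r["count"] for r in rows), reverse=True
        )

    def test_query_files_written_per_pattern(self, tmp_path):
        models, _ = self._corpus(seed=6)
        nets = combined_networks(models)
        patterns = mine(nets, MiningConfig(min_support=6, max_edges=1))
        paths = write_queries(patterns, tmp_path / "queries")
        assert len(paths) == len(patterns)
        for p, path in zip(patterns, paths):
            assert path.name == f"{p.pattern_id}.cypher"
            assert "MATCH" in path.read_text()


class TestSupportEmbeddingConsistency:
    def test_supports_iff_positive_embedding_count(self, rng):
        for _ in range(15):
            g = random_connected_network(rng, 4, 3, 6)
            p = random_connected_network(rng, 2, 2, 2)
            assert supports(p, g) == (count_embeddings(p, [g]) > 0)
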